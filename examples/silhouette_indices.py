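"""Project a flower to its top and side silhouettes and score them.

Solidity S = A_t/A_c and convexity C = L_c/L_t compare the silhouette with
its convex hull: both are 1 for a convex outline, and drop as the notches
between tepals deepen.
"""

from lilymorph import FlowerParams, build_flower_geometry, project_silhouette, shape_indices

geometry = build_flower_geometry(FlowerParams())
for view in ("top", "side"):
    sil = project_silhouette(geometry, view=view, resolution=256)
    idx = shape_indices(sil)
    sil.save_png(f"silhouette_{view}.png")
    print(f"{view:>4} view: S = {idx.S:.3f}, C = {idx.C:.3f} "
          f"(area {idx.A_t:.1f}, hull area {idx.A_c:.1f} in ovary-radius^2 units)")
print("\nlower S/C in the top view reflect the gaps between narrow tepals;")
print("wrote silhouette_top.png and silhouette_side.png")
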
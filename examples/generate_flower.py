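"""Build one theoretical water-lily flower and export it as a 3-D mesh.

The default parameter set describes a 100-organ flower: 20 tepals whose
semi-axes shrink linearly with position in the spiral, then 80 stamens, all
placed at golden-angle azimuth increments around the ovary cylinder.
"""

from lilymorph import FlowerParams, build_flower_geometry, export_mesh, organ_table, tepal_count

params = FlowerParams()
table = organ_table(params)

print(f"flower with {params.n} organs, {tepal_count(params)} of them tepals")
print("\nfirst three organs (lengths in ovary-radius units, angles in degrees):")
print(table.head(3).to_string(index=False))

geometry = build_flower_geometry(params)
path = export_mesh(geometry, "flower.obj")
print(f"\nwrote {path} — open in any mesh viewer; the outermost tepal spans "
      f"{2 * params.y_0:g} ovary radii.")
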
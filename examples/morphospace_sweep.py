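"""Sweep a small shortening-rate morphospace and map top-view solidity.

Each grid cell is one theoretical flower with different tepal shortening
rates (s_x1 transverse, s_y1 longitudinal); the heatmap shows how fast-
narrowing tepals open notches in the silhouette and lower its solidity.
"""

from lilymorph import SweepConfig, index_heatmap, sweep

config = SweepConfig(
    axis1="s_x1", axis2="s_y1",
    values1=[0.0, 0.25, 0.5, 0.75, 1.0],
    values2=[0.0, 0.875, 1.75, 2.625, 3.5],
    outputs=("indices-top",),
)
result = sweep(config, resolution=96)
print("top-view solidity over the 5x5 grid (rows s_y1, cols s_x1):")
print(result.index_frame("S", "top").round(3).to_string())

csv_path, png_path = index_heatmap(result, "S", "top", "morphospace_out")
print(f"\nwrote {csv_path} and {png_path}")
print("solidity falls left-to-right: higher s_x1 narrows tepals and deepens notches.")
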
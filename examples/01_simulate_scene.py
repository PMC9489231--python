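"""Simulate a small synthetic field trial and inspect its ground truth.

Builds a 3 x 4 plot grid observed at four stages, prints the pooled trait
statistics (mean and coefficient of variation) and writes the scene to
``scratch_scene/``.  High CVs (> 50 %) reflect the wide span of growth
stages and genotypes a breeding trial covers.
"""

from phenofuse import SceneConfig, generate_ground_truth, render_scene, \
    write_scene

config = SceneConfig(n_plot_rows=3, n_plot_cols=4, seed=7)
truth = generate_ground_truth(config)
scene = render_scene(truth, config)

print(f"{config.n_plots} plots x {len(config.stages)} stages "
      f"-> {len(truth)} samples")
for col, label in [("LAI", "LAI (unitless)"), ("PH_m", "plant height (m)"),
                   ("FW_g_m2", "fresh weight (g/m2)"),
                   ("DW_g_m2", "dry weight (g/m2)")]:
    v = truth[col]
    print(f"  {label:22s} mean {v.mean():8.2f}   CV "
          f"{100 * v.std(ddof=1) / v.mean():5.1f} %")

out = write_scene(scene, "scratch_scene")
print(f"scene written to {out}/ (GeoTIFF rasters + plots.geojson + "
      "ground_truth.csv)")
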
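"""Generate a synthetic measured cohort and recover its parameters.

Flowers are drawn per shape class from Gaussian parameter distributions,
'measured' with 5% multiplicative length noise, and each flower's initial
lengths and shortening rates are recovered by least squares over its tepal
sequence, standardized by the ovary radius.
"""

from lilymorph import CohortSpec, NoiseModel, estimate_params, summarize_measurements, synth_cohort

spec = CohortSpec(
    flowers_per_class={"stellate": 10, "cup-like": 10},
    noise=NoiseModel(sigma_rel=0.05),
)
cohort = synth_cohort(spec, seed=42)
pairs = [(table, estimate_params(table, tepal_count=spec.tepal_count)[1]) for table, _ in cohort]
report = summarize_measurements(pairs)

print("recovered class statistics (s_y1, s_x1, y_0, x_0 in ovary-radius units):")
print(report.summary.round(3).to_string())
print("\nparameter correlations across the cohort:")
print(report.correlations.round(2).to_string())
print("\nstellate flowers show the larger s_y1/s_x1 ratio: their tepals shorten "
      "lengthwise faster than they narrow.")
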
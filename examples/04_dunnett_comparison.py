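"""Dunnett-adjusted comparison of every condition against a baseline.

Feeds the published per-condition log-noise summaries (bundled with the
package) through the difference-reporting stage: each algorithm/dose cell is
contrasted with the MBIR 1 mGy baseline and the p-values are adjusted for
the 34 simultaneous comparisons with Dunnett's single-step procedure.
"""

from ctiq import difference_vs_reference, study_noise_log_means

means = study_noise_log_means()
table = difference_vs_reference(means, reference=("MBIR", 1.0))

f = table.frame
show = f[(f.dose.isin([1.0, 12.0, 18.0])) & ~f.is_reference]
print("log-noise difference vs MBIR @ 1 mGy (positive = noisier = worse):")
print(
    show[["algorithm", "dose", "estimate", "lcl", "ucl", "adjusted_p"]]
    .round(3)
    .to_string(index=False)
)
# e.g. FBP at 1 mGy sits 1.52 log-units (a 4.6x noise ratio) above the
# baseline; around 12-18 mGy the ASiR blends cross zero: that is the dose at
# which conventional reconstruction first matches the baseline's noise,
# which is how the dose-reduction potential is quantified
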
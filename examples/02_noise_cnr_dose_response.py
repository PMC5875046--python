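"""Noise and CNR vs dose for FBP, an ASiR blend, and MBIR.

Runs the experiment pipeline on a reduced grid (3 algorithms x 3 doses,
5 replicates, 256-pixel matrix) and prints the dose response plus the
fold-improvement of each algorithm over FBP. Expect roughly five-fold less
noise with MBIR at 1 mGy and sqrt(dose) noise scaling everywhere.
"""

from ctiq.pipeline import ExperimentConfig, run_experiment

config = ExperimentConfig(
    algorithms=("FBP", "ASiR70", "MBIR"),
    doses=(1.0, 6.0, 24.0),
    pitches=(0.984,),
    n_replicates=5,
    matrix_size=256,
    seed=7,
    measure_mtf=False,
)
bundle = run_experiment(config)

noise = bundle["tables"]["noise_means"]
print("mean log-noise by condition (log HU; lower = less noise):")
print(noise[["algorithm", "dose", "mean", "lcl", "ucl"]].to_string(index=False))

print("\nnoise fold-improvement vs FBP (>1 = better):")
fold = bundle["tables"]["noise_fold"]
print(fold[["algorithm", "dose", "fold_improvement"]].to_string(index=False))

print("\nCNR fold-improvement vs FBP (>1 = better):")
cfold = bundle["tables"]["cnr_fold"]
print(cfold[["algorithm", "dose", "fold_improvement"]].to_string(index=False))
# MBIR's advantage is largest at the lowest dose and shrinks as dose rises,
# while the ASiR blend gives a constant moderate gain
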
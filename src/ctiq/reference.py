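"""Published per-condition summary tables bundled for validation.

The original phantom study this pipeline models published per-condition
summaries — estimated mean log-noise and mean CNR by algorithm and CTDIvol
(at the clinical pitch, with "MBIR" marketed as VEO) — but no raw images.
These printed summaries are shipped as package data so that the
difference-reporting stage can be exercised and checked against the study's
own printed difference tables without scanner data.

Both tables use the condition-mean schema consumed by
:func:`ctiq.stats.difference_vs_reference` (``algorithm, dose, mean, lcl,
ucl``); the noise table is on the natural-log scale, the CNR table is raw.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["study_cnr_means", "study_noise_log_means"]


def _load(name: str) -> pd.DataFrame:
    with resources.files("ctiq.data").joinpath(name).open("rb") as fh:
        return pd.read_csv(fh)


def study_noise_log_means() -> pd.DataFrame:
    """Estimated mean log-noise (95% CI) by algorithm and CTDIvol."""
    df = _load("study_noise_log_means.csv")
    df["scale"] = "log"
    return df


def study_cnr_means() -> pd.DataFrame:
    """Estimated mean CNR (95% CI) by algorithm and CTDIvol."""
    df = _load("study_cnr_means.csv")
    df["scale"] = "raw"
    return df
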
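"""End-to-end experiment orchestration over the algorithm x dose x pitch grid.

:func:`run_experiment` simulates the configured phantom stacks, measures ROI
noise (sensitometry-module background), CNR (low-contrast supraslice
target), insert HU and edge-method MTF, then produces the comparison
artifacts: per-condition mean tables, Dunnett-adjusted difference tables
against the baseline (MBIR at 1 mGy by default), fold-improvement tables
relative to FBP, HU deltas from the FBP high-dose reference, per-condition
aggregated MTF curves and the MTF ratio-vs-FBP table. Everything is
deterministic under the configured master seed: per-condition substream
seeds are derived with counter-based ``SeedSequence`` keys.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import roi as roi_mod
from .mtf import MTFCurve, aggregate_mtf, extract_edge_profiles, mtf_at_frequency
from .phantoms import PhantomLayout, builtin_layouts
from .roi import ROISpec, fold_improvement, hu_difference_from_reference
from .simulate import (
    ALGORITHMS,
    AlgorithmModel,
    ImageStack,
    ScanCondition,
    builtin_models,
    simulate_stack,
)
from .stats import difference_vs_reference, estimate_condition_means, mtf_ratio_table

__all__ = [
    "CATPHAN_NOISE_ROIS",
    "ExperimentConfig",
    "PipelineStageError",
    "cnr_rois_for_target",
    "run_experiment",
    "verify_manifest",
    "write_report",
]

log = logging.getLogger("ctiq.pipeline")

#: Three 0.4 cm^2 background ROIs at 120 degree spacing (sensitometry module).
CATPHAN_NOISE_ROIS = tuple(
    ROISpec(f"bg{i}", (30.0 * np.cos(np.radians(a)), 30.0 * np.sin(np.radians(a))), 0.4)
    for i, a in enumerate((90.0, 210.0, 330.0))
)


def cnr_rois_for_target(
    center: tuple[float, float] = (0.0, 45.0),
    roi_diameter_mm: float = 10.0,
    background_offset_mm: float = 25.0,
) -> tuple[ROISpec, list[ROISpec]]:
    """Target ROI centred on the supraslice disk plus three identical
    background ROIs at 120 degree spacing in the immediate background."""
    area = np.pi * (roi_diameter_mm / 20.0) ** 2  # cm^2
    target = ROISpec("target", center, area)
    bg = [
        ROISpec(
            f"cnr_bg{i}",
            (
                center[0] + background_offset_mm * np.cos(np.radians(a)),
                center[1] + background_offset_mm * np.sin(np.radians(a)),
            ),
            area,
        )
        for i, a in enumerate((30.0, 150.0, 270.0))
    ]
    return target, bg


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and condition cell."""

    def __init__(self, stage: str, condition: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for condition {condition}: {cause}")
        self.stage = stage
        self.condition = condition


@dataclass(frozen=True)
class ExperimentConfig:
    """Full description of one simulated image-quality experiment."""

    algorithms: tuple[str, ...] = ALGORITHMS
    doses: tuple[float, ...] = (1.0, 2.0, 3.0, 6.0, 12.0, 18.0, 24.0)
    pitches: tuple[float, ...] = (0.984,)
    n_replicates: int = 10
    seed: int = 0
    matrix_size: int = 512
    dfov_cm: float = 36.0
    mtf_length_mm: float = 14.0
    mtf_target_lp_cm: float = 5.0  # 5.625 is the alternative grid point
    noise_reference: tuple[str, float] = ("MBIR", 1.0)  # baseline condition
    hu_reference: tuple[str, float] = ("FBP", 24.0)
    measure_hu_inserts: bool = True
    measure_mtf: bool = True
    measure_cnr: bool = True
    persist_stacks: bool = False

    def __post_init__(self):
        if not (self.algorithms and self.doses and self.pitches):
            raise ValueError("condition grid must be non-empty")
        if any(d <= 0 for d in self.doses):
            raise ValueError("doses must be > 0")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates for statistical output")

    def conditions(self) -> list[ScanCondition]:
        return [
            ScanCondition(a, d, p)
            for p in self.pitches
            for d in self.doses
            for a in self.algorithms
        ]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        for key in ("algorithms", "doses", "pitches", "noise_reference", "hu_reference"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def _condition_seed(master_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0] % 2**31)


def run_experiment(
    config: ExperimentConfig,
    outdir=None,
    models: dict[str, AlgorithmModel] | None = None,
) -> dict:
    """Run the full generator -> metrics -> statistics pipeline.

    Returns a bundle: ``records`` (tidy per-replicate metrics), the mean and
    comparison tables, fold-improvement and HU-delta tables, per-condition
    MTF curves, and the manifest (when ``outdir`` is given the artifacts are
    also written there).
    """
    models = models or builtin_models()
    ctp404 = builtin_layouts("ctp404")
    ctp515 = builtin_layouts("ctp515")
    air = ctp404.feature("air")
    insert_rois = roi_mod.insert_rois_for_layout(ctp404)
    target_roi, cnr_bg = cnr_rois_for_target()

    records: list[dict] = []
    hu_rows: list[dict] = []
    curves: dict[str, MTFCurve] = {}

    for idx, cond in enumerate(config.conditions()):
        cell = cond.label()
        seed = _condition_seed(config.seed, idx)
        model = models[cond.algorithm]
        log.info("simulate %s seed=%d", cell, seed)
        try:
            stack404 = simulate_stack(
                ctp404, cond, model, config.n_replicates, seed,
                config.matrix_size, config.dfov_cm,
            )
        except Exception as e:  # noqa: BLE001
            raise PipelineStageError("simulate", cell, e) from e

        try:
            noise = roi_mod.measure_noise(stack404, list(CATPHAN_NOISE_ROIS))
            for r, v in enumerate(noise.per_replicate):
                records.append(_rec(cond, r, "noise", v))
        except PipelineStageError:
            raise
        except Exception as e:  # noqa: BLE001
            raise PipelineStageError("noise", cell, e) from e

        if config.measure_hu_inserts:
            try:
                for m in roi_mod.measure_hu(stack404, insert_rois, ctp404):
                    hu_rows.append(
                        dict(material=m.material, algorithm=cond.algorithm,
                             dose=cond.ctdi_vol, pitch=cond.pitch,
                             mean=m.mean, sd=m.sd)
                    )
            except Exception as e:  # noqa: BLE001
                raise PipelineStageError("hu", cell, e) from e

        if config.measure_mtf:
            try:
                sets = [
                    extract_edge_profiles(
                        stack404.images[k], stack404.pixel_spacing_mm, air.center,
                        config.mtf_length_mm, replicate=k,
                    )
                    for k in range(stack404.n_replicates)
                ]
                curves[cell] = aggregate_mtf(sets, spacing_mm=stack404.pixel_spacing_mm)
                for k, ps in enumerate(sets):
                    val = mtf_at_frequency(
                        aggregate_mtf([ps], spacing_mm=stack404.pixel_spacing_mm),
                        config.mtf_target_lp_cm,
                    )
                    records.append(_rec(cond, k, "mtf_at_f", val))
            except Exception as e:  # noqa: BLE001
                raise PipelineStageError("mtf", cell, e) from e

        if config.measure_cnr:
            try:
                stack515 = simulate_stack(
                    ctp515, cond, model, config.n_replicates, seed + 1,
                    config.matrix_size, config.dfov_cm,
                )
                cnr = roi_mod.measure_cnr(stack515, target_roi, cnr_bg)
                for r, v in enumerate(cnr.per_replicate):
                    records.append(_rec(cond, r, "cnr", v))
            except Exception as e:  # noqa: BLE001
                raise PipelineStageError("cnr", cell, e) from e

        if config.persist_stacks and outdir is not None:
            from .io import write_stack

            write_stack(stack404, Path(outdir) / "stacks" / cell.replace("/", "_"))

    rec_df = pd.DataFrame(records)
    tables: dict[str, pd.DataFrame] = {"records": rec_df}

    base_alg, base_dose = config.noise_reference
    if base_alg not in config.algorithms:
        base_alg = config.algorithms[-1]
    if base_dose not in config.doses:
        base_dose = min(config.doses)  # fall back to the lowest-dose cell
    baseline = (base_alg, base_dose)

    noise_means = estimate_condition_means(rec_df, "noise")
    tables["noise_means"] = noise_means
    tables["noise_diff"] = difference_vs_reference(noise_means, baseline).frame
    noise_sum = noise_means.assign(value=np.exp(noise_means["mean"]))[
        ["algorithm", "dose", "pitch", "value"]
    ]
    tables["noise_fold"] = fold_improvement(noise_sum, "noise")

    if config.measure_cnr:
        cnr_means = estimate_condition_means(rec_df, "cnr")
        tables["cnr_means"] = cnr_means
        tables["cnr_diff"] = difference_vs_reference(cnr_means, baseline).frame
        cnr_sum = cnr_means.rename(columns={"mean": "value"})[
            ["algorithm", "dose", "pitch", "value"]
        ]
        tables["cnr_fold"] = fold_improvement(cnr_sum, "cnr")

    if config.measure_hu_inserts:
        hu_df = pd.DataFrame(hu_rows)
        tables["hu_table"] = hu_df
        ref_alg, ref_dose = config.hu_reference
        if ref_alg not in config.algorithms:
            ref_alg = config.algorithms[0]
        if ref_dose not in config.doses:
            ref_dose = max(config.doses)  # fall back to the highest-dose cell
        tables["hu_delta"] = hu_difference_from_reference(hu_df, (ref_alg, ref_dose))

    if config.measure_mtf:
        tables["mtf_ratio"] = mtf_ratio_table(rec_df[rec_df["metric"] == "mtf_at_f"]).frame

    n_cells = len(config.conditions())
    for name in ("noise_means",):
        assert len(tables[name]) == n_cells, "grid cells must map 1:1 to table rows"

    bundle = {"config": config, "tables": tables, "curves": curves}
    if outdir is not None:
        bundle["manifest"] = write_report(tables, curves, outdir, config)
    return bundle


def _rec(cond: ScanCondition, replicate: int, metric: str, value: float) -> dict:
    return dict(
        algorithm=cond.algorithm, dose=cond.ctdi_vol, pitch=cond.pitch,
        replicate=replicate, metric=metric, value=float(value),
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_report(
    tables: dict[str, pd.DataFrame],
    curves: dict[str, MTFCurve],
    outdir,
    config: ExperimentConfig | None = None,
) -> dict:
    """Write tables as CSV and curves as CSV+JSON; return a checksum manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for name, df in sorted(tables.items()):
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        files.append(p)
    for name, curve in sorted(curves.items()):
        safe = name.replace("/", "_")
        p = out / f"mtf_curve_{safe}.csv"
        pd.DataFrame(
            {"frequency_lp_cm": curve.frequencies_lp_cm, "modulation": curve.modulation}
        ).to_csv(p, index=False)
        files.append(p)
        pj = out / f"mtf_curve_{safe}.json"
        pj.write_text(
            json.dumps(
                {
                    "nyquist_lp_cm": curve.nyquist_lp_cm,
                    "n_profiles_aggregated": curve.n_profiles_aggregated,
                    "provenance": curve.provenance,
                },
                indent=1,
            )
        )
        files.append(pj)
    manifest = {
        "schema_version": 1,
        "config_digest": config.digest() if config is not None else None,
        "seed": config.seed if config is not None else None,
        "files": [{"path": f.name, "sha256": _sha256(f)} for f in files],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def verify_manifest(outdir) -> None:
    """Raise ValueError if any listed artifact's checksum does not match."""
    out = Path(outdir)
    manifest = json.loads((out / "manifest.json").read_text())
    for entry in manifest["files"]:
        p = out / entry["path"]
        if not p.exists():
            raise ValueError(f"missing artifact {entry['path']}")
        if _sha256(p) != entry["sha256"]:
            raise ValueError(f"checksum mismatch for {entry['path']}")
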
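"""Condition-mean estimation and Dunnett-adjusted comparisons vs a reference.

Noise and MTF are analyzed on the natural-log scale (their dose scaling is
multiplicative and the log reduces skewness); CNR is analyzed raw. With
balanced single-level replication the estimator is closed form: the
per-condition sample mean with a t-based 95% CI. Contrasts against a
reference condition are adjusted for multiplicity with Dunnett's single-step
procedure under the equicorrelated multivariate-t null (the balanced
many-to-one design implies a common contrast correlation of 1/2), computed
by deterministic Gauss-Hermite x chi quadrature or optionally by seeded
Monte Carlo.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats as sps
from scipy.special import ndtr

__all__ = [
    "ComparisonTable",
    "difference_vs_reference",
    "dunnett_adjust",
    "estimate_condition_means",
    "mtf_ratio_table",
]

_COND_COLS = ["algorithm", "dose", "pitch"]


@dataclass
class ComparisonTable:
    """Per-condition estimates/contrasts with CIs and adjusted p-values."""

    frame: pd.DataFrame
    reference: tuple | None
    scale: str  # "log" | "raw" | "ratio"

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def _tcrit(df, alpha: float = 0.05):
    if df is None or not np.isfinite(df):
        return sps.norm.ppf(1 - alpha / 2)
    return sps.t.ppf(1 - alpha / 2, df)


def estimate_condition_means(
    records: pd.DataFrame,
    metric: str | None = None,
    log_scale: bool | None = None,
) -> pd.DataFrame:
    """Per-condition mean with a t-based 95% CI from replicate values.

    ``records`` is tidy: columns ``algorithm, dose, pitch, replicate, metric,
    value``. ``log_scale`` defaults to True for noise and MTF metrics and
    False for CNR. Single-replicate cells are flagged with NaN CIs.
    """
    df = records
    if metric is not None and "metric" in df.columns:
        df = df[df["metric"] == metric]
    if df.empty:
        raise ValueError(f"no records for metric {metric!r}")
    if log_scale is None:
        log_scale = (metric or "").lower() not in ("cnr",)
    vals = df["value"].to_numpy(dtype=float)
    if log_scale:
        if np.any(vals <= 0):
            raise ValueError("log-scale analysis requires strictly positive values")
    rows = []
    group_cols = [c for c in _COND_COLS if c in df.columns]
    for key, g in df.groupby(group_cols, sort=True):
        v = g["value"].to_numpy(dtype=float)
        if log_scale:
            v = np.log(v)
        n = v.size
        mean = float(v.mean())
        sd = float(v.std(ddof=1)) if n > 1 else math.nan
        se = sd / math.sqrt(n) if n > 1 else math.nan
        hw = _tcrit(n - 1) * se if n > 1 else math.nan
        row = dict(zip(group_cols, key if isinstance(key, tuple) else (key,)))
        row.update(
            n=n,
            mean=mean,
            sd=sd,
            lcl=mean - hw if n > 1 else math.nan,
            ucl=mean + hw if n > 1 else math.nan,
            scale="log" if log_scale else "raw",
            single_replicate=n < 2,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def _row_se_df(row) -> tuple[float, float]:
    """Standard error and df of one condition-mean row.

    Uses sd/sqrt(n) when available; otherwise backs the SE out of the CI
    half-width (with a normal critical value when n is unknown, as for
    published summary tables).
    """
    n = row.get("n", math.nan)
    sd = row.get("sd", math.nan)
    if np.isfinite(n) and np.isfinite(sd) and n > 1:
        return float(sd) / math.sqrt(n), float(n - 1)
    lcl, ucl = row.get("lcl", math.nan), row.get("ucl", math.nan)
    if np.isfinite(lcl) and np.isfinite(ucl):
        if np.isfinite(n) and n > 1:
            return float(ucl - lcl) / 2.0 / _tcrit(n - 1), float(n - 1)
        return float(ucl - lcl) / 2.0 / _tcrit(math.inf), math.inf
    return math.nan, math.nan


def difference_vs_reference(
    means: pd.DataFrame,
    reference: tuple,
    rho: float = 0.5,
) -> ComparisonTable:
    """Differences of condition means from a reference condition.

    ``means`` is the output of :func:`estimate_condition_means` (or any frame
    with ``algorithm, dose[, pitch], mean`` and optionally ``lcl/ucl/n/sd``),
    all on a common analysis scale. ``reference`` is ``(algorithm, dose)`` or
    ``(algorithm, dose, pitch)``. The difference is condition minus
    reference (for noise, positive = noisier = worse; for CNR, positive =
    better). When per-condition ``sd``/``n`` are available the contrasts use
    the variance pooled across all conditions (homoscedastic on the analysis
    scale, the balanced many-to-one Dunnett design, contrast correlation
    1/2); otherwise — e.g. for published summary rows carrying only CIs —
    standard errors are backed out of the CIs and combined per contrast.
    Adjusted p-values use Dunnett's procedure over all non-reference rows.
    """
    df = means.reset_index(drop=True)
    mask = (df["algorithm"] == reference[0]) & np.isclose(df["dose"], reference[1])
    if len(reference) > 2 and "pitch" in df.columns:
        mask &= np.isclose(df["pitch"], reference[2])
    ref_rows = df[mask]
    if len(ref_rows) == 0:
        raise ValueError(f"reference condition {reference} not found")
    if len(ref_rows) > 1:
        raise ValueError(f"reference condition {reference} is ambiguous")
    ref = ref_rows.iloc[0]

    # pooled-variance path (balanced replicated design on the analysis scale)
    ns = df.get("n", pd.Series(math.nan, index=df.index)).to_numpy(dtype=float)
    sds = df.get("sd", pd.Series(math.nan, index=df.index)).to_numpy(dtype=float)
    pooled = bool(np.all(np.isfinite(ns)) and np.all(ns > 1) and np.all(np.isfinite(sds)))
    if pooled:
        df_pool = float(np.sum(ns - 1))
        sp2 = float(np.sum((ns - 1) * sds**2) / df_pool)
        n_ref = float(ref["n"])
    else:
        se_r, df_r = _row_se_df(ref)

    rows = []
    tstats, dfs, idxs = [], [], []
    for i, row in df.iterrows():
        est = float(row["mean"] - ref["mean"])
        is_ref = bool(mask.iloc[i])
        if is_ref:
            rec = dict(row[[c for c in _COND_COLS if c in df.columns]])
            rec.update(estimate=0.0, lcl=0.0, ucl=0.0, se=0.0, t=math.nan,
                       adjusted_p=math.nan, is_reference=True)
            rows.append(rec)
            continue
        if pooled:
            se = math.sqrt(sp2 * (1.0 / float(row["n"]) + 1.0 / n_ref))
            dof = df_pool
        else:
            se_c, df_c = _row_se_df(row)
            se = math.hypot(se_c, se_r) if np.isfinite(se_c) and np.isfinite(se_r) else math.nan
            if np.isfinite(df_c) and np.isfinite(df_r) and np.isfinite(se) and se > 0:
                # Welch-Satterthwaite
                num = (se_c**2 + se_r**2) ** 2
                den = se_c**4 / df_c + se_r**4 / df_r
                dof = num / den if den > 0 else math.inf
            else:
                dof = math.inf
        hw = _tcrit(dof) * se if np.isfinite(se) else math.nan
        t = est / se if np.isfinite(se) and se > 0 else math.nan
        rec = dict(row[[c for c in _COND_COLS if c in df.columns]])
        rec.update(estimate=est, lcl=est - hw, ucl=est + hw, se=se, t=t,
                   adjusted_p=math.nan, is_reference=False)
        rows.append(rec)
        if np.isfinite(t):
            tstats.append(t)
            dfs.append(dof)
            idxs.append(len(rows) - 1)

    if tstats:
        dof = float(np.median(dfs))
        padj = dunnett_adjust(np.array(tstats), df=dof, rho=rho)
        for i, p in zip(idxs, padj):
            rows[i]["adjusted_p"] = float(p)
    out = pd.DataFrame(rows)
    return ComparisonTable(frame=out, reference=tuple(reference),
                          scale=str(means.get("scale", pd.Series(["raw"])).iloc[0]))


# ---------------------------------------------------------------------------
# Dunnett single-step adjustment, equicorrelated multivariate t


def _max_abs_cdf_given_s(c_s: float, k: int, rho: float, nodes, weights) -> float:
    """P(max_j |V_j| <= c_s) for equicorrelated standard normals V."""
    if rho == 0.0:
        return float((2.0 * ndtr(c_s) - 1.0) ** k)
    sr = math.sqrt(rho)
    s1 = math.sqrt(1.0 - rho)
    a = (c_s - sr * nodes) / s1
    b = (-c_s - sr * nodes) / s1
    probs = np.clip(ndtr(a) - ndtr(b), 0.0, 1.0)
    return float(np.sum(weights * probs**k))


def _max_abs_t_cdf(c: float, k: int, df: float, rho: float) -> float:
    """P(max_j |T_j| <= c) under the equicorrelated multivariate t null."""
    if c <= 0:
        return 0.0
    nodes, weights = np.polynomial.hermite_e.hermegauss(120)
    weights = weights / math.sqrt(2.0 * math.pi)
    if not np.isfinite(df):
        return _max_abs_cdf_given_s(c, k, rho, nodes, weights)
    chi = sps.chi(df)
    scale = 1.0 / math.sqrt(df)

    def integrand(s):
        return _max_abs_cdf_given_s(c * s, k, rho, nodes, weights) * chi.pdf(s / scale) / scale

    lo, hi = chi.ppf(1e-12) * scale, chi.ppf(1.0 - 1e-12) * scale
    val, _ = integrate.quad(integrand, lo, hi, limit=200, epsabs=1e-10, epsrel=1e-9)
    return min(val, 1.0)


def dunnett_adjust(
    t_stats: np.ndarray,
    df: float,
    rho: float = 0.5,
    method: str = "quadrature",
    n_draws: int = 1_000_000,
    seed: int = 0,
) -> np.ndarray:
    """Two-sided Dunnett-adjusted p-values for contrasts against a reference.

    ``p_adj = P(max_j |T_j| >= |t|)`` for ``k = len(t_stats)`` equicorrelated
    t variates with common correlation ``rho`` and ``df`` degrees of freedom
    (``df=inf`` for the normal case). ``method="montecarlo"`` uses a seeded
    max-|T| simulation instead of quadrature.
    """
    t_stats = np.atleast_1d(np.asarray(t_stats, dtype=float))
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must be in [0, 1)")
    if not (df > 0):
        raise ValueError("df must be positive")
    k = t_stats.size
    if k == 1:
        # no multiplicity: the adjusted p equals the unadjusted two-sided p
        if np.isfinite(df):
            return np.array([2.0 * sps.t.sf(abs(t_stats[0]), df)])
        return np.array([2.0 * sps.norm.sf(abs(t_stats[0]))])
    if method == "montecarlo":
        rng = np.random.default_rng(seed)
        out = np.zeros(k)
        thresh = np.abs(t_stats)
        counts = np.zeros(k)
        total = 0
        chunk = 200_000
        while total < n_draws:
            m = min(chunk, n_draws - total)
            x = rng.standard_normal((m, 1))
            z = rng.standard_normal((m, k))
            v = math.sqrt(rho) * x + math.sqrt(1 - rho) * z
            if np.isfinite(df):
                s = np.sqrt(rng.chisquare(df, (m, 1)) / df)
                v = v / s
            mx = np.abs(v).max(axis=1)
            counts += (mx[:, None] >= thresh[None, :]).sum(axis=0)
            total += m
        return counts / total
    if method != "quadrature":
        raise ValueError("method must be 'quadrature' or 'montecarlo'")
    return np.array([1.0 - _max_abs_t_cdf(abs(t), k, df, rho) for t in t_stats])


def mtf_ratio_table(
    records: pd.DataFrame,
    reference_algorithm: str = "FBP",
    rho: float = 0.5,
) -> ComparisonTable:
    """Back-transformed MTF ratios vs the reference algorithm, per cell.

    ``records`` holds per-replicate MTF values at the target frequency
    (columns ``algorithm, dose, pitch, replicate, value``). Within each
    pitch x dose cell the mean log-MTF difference (algorithm - reference) is
    exponentiated to a ratio; the CI is back-transformed likewise and the
    adjusted p-values use Dunnett's procedure across the cell's contrasts
    (pooled within-cell variance).
    """
    if np.any(records["value"].to_numpy(dtype=float) <= 0):
        raise ValueError("MTF values must be positive for log-scale analysis")
    rows = []
    for (pitch, dose), cell in records.groupby(["pitch", "dose"], sort=True):
        algs = cell["algorithm"].unique().tolist()
        if reference_algorithm not in algs:
            raise ValueError(
                f"{reference_algorithm} missing in cell pitch={pitch}, dose={dose}"
            )
        logv = {a: np.log(cell.loc[cell["algorithm"] == a, "value"].to_numpy(float))
                for a in algs}
        # pooled within-cell variance
        sums = [(v.size - 1, v.var(ddof=1)) for v in logv.values() if v.size > 1]
        df_pool = sum(d for d, _ in sums)
        sp2 = sum(d * v for d, v in sums) / df_pool if df_pool > 0 else math.nan
        vref = logv[reference_algorithm]
        contrasts = [a for a in algs if a != reference_algorithm]
        ts, recs = [], []
        for a in contrasts:
            v = logv[a]
            diff = float(v.mean() - vref.mean())
            se = math.sqrt(sp2 * (1 / v.size + 1 / vref.size)) if np.isfinite(sp2) else math.nan
            hw = _tcrit(df_pool) * se if df_pool > 0 else math.nan
            if se and np.isfinite(se) and se > 0:
                t = diff / se
            else:
                t = math.inf if diff != 0 else 0.0
            ts.append(t)
            recs.append(
                dict(pitch=pitch, dose=dose, ratio=f"{a}/{reference_algorithm}",
                     estimate=math.exp(diff),
                     lcl=math.exp(diff - hw) if np.isfinite(hw) else math.nan,
                     ucl=math.exp(diff + hw) if np.isfinite(hw) else math.nan,
                     t=t, df=df_pool)
            )
        finite = np.isfinite(ts)
        padj = np.full(len(ts), math.nan)
        if np.any(finite):
            padj_f = dunnett_adjust(np.asarray(ts)[finite], df=max(df_pool, 1), rho=rho)
            padj[finite] = padj_f
        padj[np.isinf(ts)] = 0.0
        for rec, p, t in zip(recs, padj, ts):
            rec["adjusted_p"] = 1.0 if (t == 0.0 and not np.isfinite(sp2)) else float(p)
            rows.append(rec)
    frame = pd.DataFrame(rows)
    return ComparisonTable(frame=frame, reference=(reference_algorithm,), scale="ratio")
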
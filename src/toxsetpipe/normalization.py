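"""Array normalization and probe-level preprocessing.

Two-color arrays: per-array MA transform and LOWESS normalization, which
removes intensity-dependent dye bias by subtracting a locally weighted
regression of the log-ratio M on the mean log-intensity A.

Single-channel arrays: quantile normalization across arrays, present calls
from labelled negative-control probes (trimmed mean + 3 trimmed SDs, strict
exceedance), technical-replicate collapsing by the median, and an advisory
correlation-based outlier-array flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class MAPair:
    """Per-probe, per-array M = log2(red/green) and A = mean log2 intensity."""

    M: pd.DataFrame
    A: pd.DataFrame


def ma_transform(red: ExpressionMatrix, green: ExpressionMatrix) -> MAPair:
    """MA transform of a two-color pair; probes non-positive in either
    channel become NaN (the log is undefined there)."""
    if list(red.probes) != list(green.probes) or red.samples != green.samples:
        raise ValueError("red and green matrices must share probes and samples")
    r = red.values.to_numpy(dtype=float)
    g = green.values.to_numpy(dtype=float)
    valid = (r > 0) & (g > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.where(valid, np.log2(r) - np.log2(g), np.nan)
        a = np.where(valid, 0.5 * (np.log2(r) + np.log2(g)), np.nan)
    idx, cols = red.probes, red.values.columns
    return MAPair(
        pd.DataFrame(m, index=idx, columns=cols),
        pd.DataFrame(a, index=idx, columns=cols),
    )


def lowess_normalize(
    red: ExpressionMatrix,
    green: ExpressionMatrix,
    span: float = 0.4,
    iterations: int = 3,
) -> ExpressionMatrix:
    """LOWESS-normalized log2 ratios, per array.

    For each array the smooth trend f(A) is estimated by robust locally
    weighted linear regression of M on A (span = fraction of probes in each
    local window, ``iterations`` robustifying reweighting passes) and the
    normalized ratio is M' = M - f(A). Probes with a non-positive value in
    either channel are excluded from smoothing and returned as NaN; the
    count is logged per array.
    """
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    ma = ma_transform(red, green)
    out = {}
    for col in ma.M.columns:
        m = ma.M[col].to_numpy()
        a = ma.A[col].to_numpy()
        valid = np.isfinite(m) & np.isfinite(a)
        n_dropped = int((~valid).sum())
        if n_dropped:
            logger.info(
                "lowess_normalize: array %s: %d probes dropped (non-positive channel)",
                col,
                n_dropped,
            )
        if valid.sum() < 10:
            raise ValueError(f"array {col}: too few valid probes to smooth")
        fitted = _sm_lowess(
            m[valid],
            a[valid],
            frac=span,
            it=iterations,
            return_sorted=False,
        )
        mprime = np.full_like(m, np.nan)
        mprime[valid] = m[valid] - fitted
        out[col] = mprime
    values = pd.DataFrame(out, index=red.probes)
    return ExpressionMatrix(
        values, annotations=red.annotations, log_scale=True, channel="log_ratio"
    )


def quantile_normalize(x: ExpressionMatrix) -> ExpressionMatrix:
    """Force every array to share one intensity distribution.

    Each column's order statistics are mapped to the across-array mean of
    the sorted columns; ties receive the average of the values assigned to
    the tied ranks. Within-column rank order is preserved; the operation is
    idempotent.
    """
    if x.n_samples < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    vals = x.values.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("quantile normalization rejects missing values")
    sorted_means = np.sort(vals, axis=0).mean(axis=1)
    n = vals.shape[0]
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        ranks = pd.Series(vals[:, j]).rank(method="average").to_numpy()
        # fractional ranks from ties interpolate between adjacent means,
        # i.e. tied probes get the average of the values they would share
        out[:, j] = np.interp(ranks - 1.0, np.arange(n), sorted_means)
    return ExpressionMatrix(
        pd.DataFrame(out, index=x.probes, columns=x.values.columns),
        annotations=x.annotations,
        log_scale=x.log_scale,
        channel=x.channel,
    )


def _trimmed_mean_sd(values: np.ndarray, trim: float) -> tuple[float, float]:
    """Mean and sample SD (ddof=1) after removing floor(trim*n) per tail."""
    v = np.sort(values[np.isfinite(values)])
    k = int(np.floor(trim * v.size))
    core = v[k : v.size - k] if k else v
    if core.size < 2:
        raise ValueError("too few values after trimming")
    return float(core.mean()), float(core.std(ddof=1))


def present_call(x: ExpressionMatrix, trim: float = 0.05) -> pd.DataFrame:
    """Detection calls from negative-control probes.

    Per sample the threshold is ``trimmed_mean(NC) + 3 * trimmed_SD(NC)``
    over the negative-control probe signals, with ``trim`` removed from each
    tail; a probe is called present iff its signal is strictly greater than
    the threshold.
    """
    if not 0 <= trim < 0.25:
        raise ValueError("trim must be in [0, 0.25)")
    nc_mask = x.negative_control_mask().to_numpy()
    if nc_mask.sum() < 3:
        raise ValueError("present_call needs >= 3 negative-control probes")
    vals = x.values.to_numpy(dtype=float)
    calls = np.zeros_like(vals, dtype=bool)
    for j in range(vals.shape[1]):
        mean, sd = _trimmed_mean_sd(vals[nc_mask, j], trim)
        calls[:, j] = vals[:, j] > mean + 3.0 * sd
    return pd.DataFrame(calls, index=x.probes, columns=x.values.columns)


def collapse_replicates(x: ExpressionMatrix) -> ExpressionMatrix:
    """Collapse technical replicate probes to targets by the median signal.

    Probes sharing a ``target`` annotation are summarised per sample by the
    median; a single probe per target passes through unchanged. The
    negative-control flag of a target is the logical OR of its probes.
    """
    targets = x.target_map()
    grouped = x.values.groupby(targets.to_numpy(), sort=True)
    values = grouped.median()
    nc = x.negative_control_mask().groupby(targets.to_numpy(), sort=True).any()
    ann = pd.DataFrame(
        {"negative_control": nc, "target": values.index.to_numpy()},
        index=values.index,
    )
    return ExpressionMatrix(
        values, annotations=ann, log_scale=x.log_scale, channel=x.channel
    )


def qc_flag_outlier_arrays(
    x: ExpressionMatrix, threshold: float = 0.5
) -> list[str]:
    """Advisory outlier-array flags from inter-array Spearman correlation.

    An array is flagged when its median Spearman correlation with all other
    arrays falls strictly below ``threshold``. The caller decides exclusion;
    this function only reports.
    """
    if x.n_samples < 3:
        raise ValueError("outlier QC needs >= 3 arrays")
    corr = x.values.corr(method="spearman").to_numpy()
    np.fill_diagonal(corr, np.nan)
    med = np.nanmedian(corr, axis=0)
    flagged = [s for s, c in zip(x.samples, med) if c < threshold]
    return flagged
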
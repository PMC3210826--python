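"""Gene-wise two-group differential expression.

Fits a fixed-effect two-group model per gene (least-square group means,
treatment sum of squares, residual mean square), computes either the
variance-shrinkage Fs statistic or the gene-specific parametric F1 test,
estimates p-values by residual-shuffling permutation, adjusts them by the
Benjamini-Hochberg step-up, and reports signed linear fold changes from the
least-square means.

The Fs statistic divides the treatment mean square by a James-Stein-type
shrinkage estimate of the gene's residual variance, computed on the
log-variance scale: with X_g = ln(residual MS_g),

    sigma~^2_g = exp( X_bar + B * (X_g - X_bar) ),
    B = max(0, 1 - (G - 3) * psi1(nu/2) / sum_g (X_g - X_bar)^2 ),

where psi1 is the trigamma function (the sampling variance of ln of a
chi-square_nu / nu variate) and G the number of genes entering the centre.
This form leaves the centre at the mean log residual variance, so a single
gene (G = 1) or a panel with identical residual variances reproduces the
ordinary F statistic exactly; B < 1 contracts the spread of the variance
estimates toward the centre, stabilising small-sample gene-wise variances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .containers import DesignTable, ExpressionMatrix


@dataclass
class TwoGroupFits:
    """Per-gene least-squares summaries of the two-group model."""

    genes: pd.Index
    control: str
    treated: str
    lsmean_control: pd.Series
    lsmean_treated: pd.Series
    ss_treatment: pd.Series
    ms_residual: pd.Series
    df_residual: pd.Series
    # raw data and masks retained for resampling
    y: np.ndarray
    mask_control: np.ndarray
    mask_treated: np.ndarray


def _two_group_summaries(
    y: np.ndarray, mask_c: np.ndarray, mask_t: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized one-way summaries; NaN cells are dropped per gene.

    Returns (mean_c, mean_t, ss_treatment, ms_residual, df_residual); genes
    with fewer than one residual degree of freedom, or with an empty group,
    get NaN statistics.
    """
    yc, yt = y[:, mask_c], y[:, mask_t]
    finite_c, finite_t = np.isfinite(yc), np.isfinite(yt)
    n_c = finite_c.sum(axis=1).astype(float)
    n_t = finite_t.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        sum_c = np.where(finite_c, yc, 0.0).sum(axis=1)
        sum_t = np.where(finite_t, yt, 0.0).sum(axis=1)
        mean_c = sum_c / n_c
        mean_t = sum_t / n_t
        grand = (sum_c + sum_t) / (n_c + n_t)
        ss_treat = n_c * (mean_c - grand) ** 2 + n_t * (mean_t - grand) ** 2
        sse = np.where(finite_c, (yc - mean_c[:, None]) ** 2, 0.0).sum(
            axis=1
        ) + np.where(finite_t, (yt - mean_t[:, None]) ** 2, 0.0).sum(axis=1)
        df = n_c + n_t - 2.0
        ms_resid = sse / df
    bad = (n_c < 1) | (n_t < 1) | (df < 1)
    for arr in (mean_c, mean_t, ss_treat, ms_resid):
        arr[bad] = np.nan
    df[bad] = np.nan
    return mean_c, mean_t, ss_treat, ms_resid, df


def fit_gene_models(
    y: ExpressionMatrix,
    design: DesignTable,
    control: str | None = None,
    treated: str | None = None,
) -> TwoGroupFits:
    """Least-squares two-group fit per gene.

    Works on normalized log2 ratios or log2 intensities. Genes left with
    fewer than one residual degree of freedom are reported as missing.
    """
    mask_c, mask_t, (ctrl, trt) = design.two_group_masks(
        y.samples, control=control, treated=treated
    )
    vals = y.values.to_numpy(dtype=float)
    mean_c, mean_t, ss_treat, ms_resid, df = _two_group_summaries(
        vals, mask_c, mask_t
    )
    idx = y.probes
    return TwoGroupFits(
        genes=idx,
        control=ctrl,
        treated=trt,
        lsmean_control=pd.Series(mean_c, index=idx),
        lsmean_treated=pd.Series(mean_t, index=idx),
        ss_treatment=pd.Series(ss_treat, index=idx),
        ms_residual=pd.Series(ms_resid, index=idx),
        df_residual=pd.Series(df, index=idx),
        y=vals,
        mask_control=mask_c,
        mask_treated=mask_t,
    )


def _shrunk_variances(ms_resid: np.ndarray, df: np.ndarray) -> np.ndarray:
    """Log-scale James-Stein shrinkage of residual variances (see module
    docstring). Genes with zero residual MS shrink to zero variance."""
    out = np.full_like(ms_resid, np.nan)
    ok = np.isfinite(ms_resid) & np.isfinite(df)
    if not ok.any():
        raise ValueError("no gene has a defined residual variance")
    ms = ms_resid[ok]
    if np.all(ms == 0.0):
        raise ValueError("all residual variances are zero (degenerate data)")
    pos = ms > 0.0
    x = np.log(ms[pos])
    g = int(pos.sum())
    center = x.mean()
    if g <= 3:
        b = 1.0
    else:
        ssq = ((x - center) ** 2).sum()
        if ssq == 0.0:
            b = 0.0
        else:
            nu = float(np.median(df[ok]))
            v = special.polygamma(1, nu / 2.0)
            b = max(0.0, 1.0 - (g - 3) * v / ssq)
    shrunk = np.zeros_like(ms)
    shrunk[pos] = np.exp(center + b * (x - center))
    out[ok] = shrunk
    return out


def fs_statistic(fits: TwoGroupFits) -> pd.Series:
    """Shrinkage Fs statistic per gene: MS_treatment / shrunken variance.

    With a single gene the shrunken variance equals the gene's own residual
    mean square, so Fs reduces to the ordinary F.
    """
    ms_resid = fits.ms_residual.to_numpy()
    df = fits.df_residual.to_numpy()
    shrunk = _shrunk_variances(ms_resid, df)
    with np.errstate(divide="ignore", invalid="ignore"):
        fs = fits.ss_treatment.to_numpy() / shrunk
    fs = np.where(
        (fits.ss_treatment.to_numpy() == 0.0) & (shrunk == 0.0), 0.0, fs
    )
    return pd.Series(fs, index=fits.genes, name="Fs")


def f_statistic(fits: TwoGroupFits) -> pd.Series:
    """Ordinary gene-specific one-way F statistic (F1)."""
    ss = fits.ss_treatment.to_numpy()
    ms = fits.ms_residual.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ss / ms
    f = np.where((ss == 0.0) & (ms == 0.0), 0.0, f)
    return pd.Series(f, index=fits.genes, name="F")


_STATISTICS: dict[str, Callable[[TwoGroupFits], pd.Series]] = {
    "fs": fs_statistic,
    "f1": f_statistic,
}


def permutation_pvalues(
    fits: TwoGroupFits,
    statistic: str | Callable[[TwoGroupFits], pd.Series] = "fs",
    n_perm: int = 1000,
    seed: int = 0,
    pooled: bool = False,
) -> pd.Series:
    """Permutation p-values by residual shuffling.

    Residuals of the null (intercept-only) fit are shuffled as whole sample
    columns — preserving gene-gene correlation — null data are rebuilt on
    the gene grand means, and the statistic is recomputed. The add-one
    convention p = (1 + #{perm >= obs}) / (n_perm + 1) keeps p-values off
    zero. ``pooled=True`` compares each observed value against the null
    values pooled across genes instead of its own gene's null.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    stat_fn = _STATISTICS[statistic] if isinstance(statistic, str) else statistic
    obs = stat_fn(fits).to_numpy()
    rng = np.random.default_rng(seed)
    used = fits.mask_control | fits.mask_treated
    y_used = fits.y[:, used]
    finite = np.isfinite(y_used)
    with np.errstate(invalid="ignore"):
        grand = np.where(finite, y_used, 0.0).sum(axis=1) / finite.sum(axis=1)
    resid = y_used - grand[:, None]
    mask_c = fits.mask_control[used]
    mask_t = fits.mask_treated[used]
    n_cols = y_used.shape[1]

    counts = np.zeros(y_used.shape[0])
    pooled_null: list[np.ndarray] = []
    perm_fits = TwoGroupFits(
        genes=fits.genes,
        control=fits.control,
        treated=fits.treated,
        lsmean_control=fits.lsmean_control,
        lsmean_treated=fits.lsmean_treated,
        ss_treatment=fits.ss_treatment,
        ms_residual=fits.ms_residual,
        df_residual=fits.df_residual,
        y=y_used,
        mask_control=mask_c,
        mask_treated=mask_t,
    )
    for _ in range(n_perm):
        perm = rng.permutation(n_cols)
        y_null = grand[:, None] + resid[:, perm]
        mc, mt, ss, ms, df = _two_group_summaries(y_null, mask_c, mask_t)
        perm_fits.lsmean_control = pd.Series(mc, index=fits.genes)
        perm_fits.lsmean_treated = pd.Series(mt, index=fits.genes)
        perm_fits.ss_treatment = pd.Series(ss, index=fits.genes)
        perm_fits.ms_residual = pd.Series(ms, index=fits.genes)
        perm_fits.df_residual = pd.Series(df, index=fits.genes)
        null_stat = stat_fn(perm_fits).to_numpy()
        if pooled:
            pooled_null.append(null_stat)
        else:
            counts += (null_stat >= obs).astype(float)
    if pooled:
        all_null = np.sort(np.concatenate(pooled_null))
        all_null = all_null[np.isfinite(all_null)]
        n_null = all_null.size
        ge = n_null - np.searchsorted(all_null, obs, side="left")
        p = (1.0 + ge) / (n_null + 1.0)
    else:
        p = (1.0 + counts) / (n_perm + 1.0)
    p = np.where(np.isfinite(obs), p, np.nan)
    return pd.Series(p, index=fits.genes, name="p_value")


def fdr_adjust(p: np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    NaN entries are passed through untouched and do not count toward the
    number of tests.
    """
    arr = np.asarray(p, dtype=float)
    out = np.full(arr.shape, np.nan)
    ok = np.isfinite(arr)
    if ok.any() and (arr[ok].min() < 0.0 or arr[ok].max() > 1.0):
        raise ValueError("p-values must lie in [0, 1]")
    if ok.any():
        out[ok] = multipletests(arr[ok], method="fdr_bh")[1]
    if isinstance(p, pd.Series):
        return pd.Series(out, index=p.index, name="q_value")
    return out


def fold_change_lsmeans(fits: TwoGroupFits) -> pd.Series:
    """Signed linear fold change from the least-square means.

    FC = 2^(LSmean_treated - LSmean_control); downregulation is reported as
    -1/FC, so |FC| >= 1 and the sign carries direction.
    """
    diff = fits.lsmean_treated - fits.lsmean_control
    fc = np.power(2.0, diff.to_numpy())
    signed = np.where(fc >= 1.0, fc, -1.0 / fc)
    return pd.Series(signed, index=fits.genes, name="fold_change")


def f1_test(
    y: ExpressionMatrix,
    design: DesignTable,
    control: str | None = None,
    treated: str | None = None,
) -> pd.DataFrame:
    """Gene-specific parametric F test (F1): ordinary one-way F with p from
    the F(1, n-2) distribution. Equivalent to a pooled two-sided t-test
    (F = t^2). Degenerate genes: F = 0 gives p = 1; zero residual variance
    with a real group difference gives p = 0."""
    fits = fit_gene_models(y, design, control=control, treated=treated)
    f = f_statistic(fits)
    df = fits.df_residual.to_numpy()
    with np.errstate(invalid="ignore"):
        p = stats.f.sf(f.to_numpy(), 1, df)
    p = np.where(np.isinf(f.to_numpy()), 0.0, p)
    return pd.DataFrame({"statistic": f, "p_value": p}, index=fits.genes)


def differential_expression(
    y: ExpressionMatrix,
    design: DesignTable,
    stat: str = "fs",
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    pooled: bool = False,
    control: str | None = None,
    treated: str | None = None,
) -> pd.DataFrame:
    """Full differential-expression table (the DEResult contract).

    ``stat="fs"`` uses the shrinkage Fs with residual-shuffling permutation
    p-values; ``stat="f1"`` uses the parametric gene-specific F test. Both
    are followed by Benjamini-Hochberg adjustment and signed fold changes
    from the least-square means. ``significant`` marks adjusted p < alpha.
    """
    fits = fit_gene_models(y, design, control=control, treated=treated)
    if stat == "f1":
        table = f1_test(y, design, control=control, treated=treated)
        statistic, p = table["statistic"], table["p_value"]
    elif stat == "fs":
        statistic = fs_statistic(fits)
        p = permutation_pvalues(fits, "fs", n_perm=n_perm, seed=seed, pooled=pooled)
    else:
        raise ValueError(f"unknown statistic '{stat}'")
    q = fdr_adjust(pd.Series(np.asarray(p, dtype=float), index=fits.genes))
    fc = fold_change_lsmeans(fits)
    return pd.DataFrame(
        {
            "statistic": np.asarray(statistic, dtype=float),
            "p_value": np.asarray(p, dtype=float),
            "q_value": np.asarray(q, dtype=float),
            "fold_change": fc,
            "lsmean_control": fits.lsmean_control,
            "lsmean_treated": fits.lsmean_treated,
            "significant": np.asarray(q, dtype=float) < alpha,
        },
        index=fits.genes,
    )
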
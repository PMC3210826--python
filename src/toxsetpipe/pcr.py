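"""Comparative-Ct relative quantification for PCR arrays.

Expression of a target gene is normalized per sample to the arithmetic
mean of the housekeeping Ct values (equivalent to the geometric mean of
housekeeping expression): dCt_s = Ct_gene,s - mean(Ct_HK,s). The group
contrast ddCt = mean_treated(dCt) - mean_control(dCt) converts to a fold
change FC = E^(-ddCt) with per-cycle amplification efficiency E (default
2.0). Significance comes from a REST-style fixed-reallocation randomization
test on dCt, or from a two-sample t-test.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CtTable


def delta_ct(t: CtTable) -> tuple[pd.DataFrame, pd.Series]:
    """Per-sample housekeeping-normalized Ct values.

    Returns (samples x genes dCt matrix, sample -> group mapping).
    Technical replicates are averaged first; samples missing any
    housekeeping gene are dropped with a warning.
    """
    wide = t.mean_ct()
    missing_hk = wide[list(t.housekeeping)].isna().any(axis=1)
    if missing_hk.any():
        dropped = list(wide.index[missing_hk])
        warnings.warn(f"samples missing a housekeeping well dropped: {dropped}")
        wide = wide[~missing_hk]
    hk_mean = wide[list(t.housekeeping)].mean(axis=1)
    dct = wide.sub(hk_mean, axis=0)
    groups = t.sample_groups().reindex(wide.index)
    return dct, groups


def _group_dct(
    t: CtTable, gene: str, treated_group: str, control_group: str
) -> tuple[np.ndarray, np.ndarray]:
    dct, groups = delta_ct(t)
    if gene not in dct.columns:
        raise ValueError(f"gene '{gene}' not in Ct table")
    col = dct[gene]
    x_t = col[groups == treated_group].dropna().to_numpy()
    x_c = col[groups == control_group].dropna().to_numpy()
    if x_t.size == 0 or x_c.size == 0:
        raise ValueError(f"gene '{gene}' missing in one of the groups")
    return x_t, x_c


def expression_ratio(
    t: CtTable, gene: str, treated_group: str = "treated",
    control_group: str = "control",
) -> float:
    """Unsigned relative expression E^(-ddCt) of treated over control."""
    x_t, x_c = _group_dct(t, gene, treated_group, control_group)
    ddct = x_t.mean() - x_c.mean()
    eff = t.efficiency_for(gene)
    return float(eff ** (-ddct))


def ddct_fold_change(
    t: CtTable,
    gene: str,
    treated_group: str = "treated",
    control_group: str = "control",
) -> float:
    """Signed comparative-Ct fold change.

    Ratios below 1 are reported as -1/ratio so that |FC| >= 1 and the sign
    carries direction (matching the differential-expression convention).
    With efficiency E = 1 the ratio is 1 regardless of ddCt.
    """
    ratio = expression_ratio(t, gene, treated_group, control_group)
    return float(ratio if ratio >= 1.0 else -1.0 / ratio)


def rest_randomization_test(
    t: CtTable,
    gene: str,
    n_rand: int = 2000,
    seed: int = 0,
    treated_group: str = "treated",
    control_group: str = "control",
) -> float:
    """REST-style fixed-reallocation randomization p-value.

    The observed statistic is the expression ratio from ddCt; samples are
    randomly reallocated between the treated and control labels (group
    sizes fixed) and the ratio recomputed. Two-sided:
    p = (1 + #{|log ratio*| >= |log ratio|}) / (n_rand + 1). Since the
    efficiency is a fixed per-gene constant, |log ratio| is proportional to
    |ddCt|, which is the quantity compared.
    """
    if n_rand < 1000:
        raise ValueError("n_rand must be >= 1000")
    x_t, x_c = _group_dct(t, gene, treated_group, control_group)
    if x_t.size < 3 or x_c.size < 3:
        raise ValueError("REST randomization needs >= 3 samples per group")
    # sorting makes the null depend only on the pooled dCt multiset and the
    # group sizes, so equal-sized designs give the same p after a label swap
    pooled = np.sort(np.concatenate([x_t, x_c]))
    n_t = x_t.size
    obs = abs(x_t.mean() - x_c.mean())
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(pooled.size) for _ in range(n_rand)])
    shuffled = pooled[perms]  # n_rand x n
    diff = shuffled[:, :n_t].mean(axis=1) - shuffled[:, n_t:].mean(axis=1)
    count = int((np.abs(diff) >= obs - 1e-12).sum())
    return float((1.0 + count) / (n_rand + 1.0))


def normalized_expression_ttest(
    t: CtTable,
    gene: str,
    treated_group: str = "treated",
    control_group: str = "control",
    equal_var: bool = True,
) -> tuple[float, float]:
    """Signed fold change plus two-sided two-sample t-test on dCt values.

    Degenerate cases are guarded: identical dCt vectors give p = 1; zero
    within-group variance with a real mean shift gives p = 0.
    """
    x_t, x_c = _group_dct(t, gene, treated_group, control_group)
    if x_t.size < 2 or x_c.size < 2:
        raise ValueError("t-test needs >= 2 samples per group")
    fc = ddct_fold_change(t, gene, treated_group, control_group)
    if x_t.var(ddof=1) == 0.0 and x_c.var(ddof=1) == 0.0:
        p = 1.0 if x_t.mean() == x_c.mean() else 0.0
    else:
        p = float(stats.ttest_ind(x_t, x_c, equal_var=equal_var).pvalue)
    return fc, p


def pcr_report(
    t: CtTable,
    n_rand: int = 2000,
    seed: int = 0,
    treated_group: str = "treated",
    control_group: str = "control",
) -> pd.DataFrame:
    """Fold change and REST randomization p for every non-housekeeping gene."""
    genes = [g for g in t.mean_ct().columns if g not in set(t.housekeeping)]
    seeds = np.random.SeedSequence(seed).spawn(len(genes))
    rows = []
    for g, ss in zip(genes, seeds):
        fc = ddct_fold_change(t, g, treated_group, control_group)
        p = rest_randomization_test(
            t,
            g,
            n_rand=n_rand,
            seed=int(ss.generate_state(1)[0] % (2**31)),
            treated_group=treated_group,
            control_group=control_group,
        )
        rows.append({"gene": g, "fold_change": fc, "p_value": p})
    return (
        pd.DataFrame.from_records(rows)
        .sort_values(["p_value", "gene"], kind="mergesort")
        .reset_index(drop=True)
    )
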
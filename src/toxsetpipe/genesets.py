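"""Gene-set enrichment tests for two-group expression experiments.

Two self-contained tests that make no distributional or gene-independence
assumptions:

* **rank-based test** — all measured genes are ranked within each sample
  (average ranks on ties); for each set gene the mean rank per treatment
  group is computed, and the test statistic is the Euclidean distance D
  between the two group mean-rank vectors. Significance comes from
  permuting sample-to-group labels, which preserves the within-sample
  gene-gene correlation.

* **design-based test** — D is the Euclidean distance between the two group
  mean vectors of the set genes on the expression scale. The null
  distribution is built by removing the treatment effect (centring each
  gene on its grand mean) and bootstrap-resampling whole sample columns of
  residuals with replacement, honouring the group sizes of the design.

Both use the add-one convention p = (1 + #{D* >= D}) / (n_resample + 1),
counting ties as exceedances (conservative), so p is never exactly zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DesignTable, ExpressionMatrix, GeneSetCollection


@dataclass
class GeneSetResult:
    """One gene set's test outcome (the Table-style row)."""

    name: str
    p_value: float
    statistic: float
    total: int
    changing: int | None = None


def _set_rows(y: ExpressionMatrix, genes: Sequence[str]) -> np.ndarray:
    members = set(genes)
    rows = np.array([g in members for g in y.probes])
    if not rows.any():
        raise ValueError("gene set has no measured members")
    return rows


def _ordered_columns(
    y: ExpressionMatrix,
    design: DesignTable,
    control: str | None,
    treated: str | None,
) -> tuple[np.ndarray, int, int]:
    """Values reordered to [control block | treated block] by design order.

    Working in design order makes both tests exactly invariant to the
    column order of the matrix.
    """
    mask_c, mask_t, (ctrl, trt) = design.two_group_masks(
        y.samples, control=control, treated=treated
    )
    cols_c = [s for s in design.samples_of(ctrl) if s in set(y.samples)]
    cols_t = [s for s in design.samples_of(trt) if s in set(y.samples)]
    vals = y.values[cols_c + cols_t].to_numpy(dtype=float)
    return vals, len(cols_c), len(cols_t)


def _contrast_weights(n_c: int, n_t: int) -> np.ndarray:
    w = np.empty(n_c + n_t)
    w[:n_c] = -1.0 / n_c
    w[n_c:] = 1.0 / n_t
    return w


def rank_based_test(
    y: ExpressionMatrix,
    design: DesignTable,
    genes: Sequence[str],
    n_perm: int = 1000,
    seed: int = 0,
    rank_scope: str = "global",
    control: str | None = None,
    treated: str | None = None,
) -> GeneSetResult:
    """Rank-based set test (see module docstring).

    ``rank_scope="global"`` ranks over all measured genes within a sample,
    so the magnitude of a set gene's intensity relative to the whole array
    drives the statistic; ``"within-set"`` ranks only among set members
    (for sensitivity analysis).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if rank_scope not in ("global", "within-set"):
        raise ValueError("rank_scope must be 'global' or 'within-set'")
    vals, n_c, n_t = _ordered_columns(y, design, control, treated)
    rows = _set_rows(y, genes)
    source = vals if rank_scope == "global" else vals[rows]
    ranks = stats.rankdata(source, axis=0)
    r_set = ranks[rows] if rank_scope == "global" else ranks

    w = _contrast_weights(n_c, n_t)
    d_obs = float(np.sqrt(((r_set @ w) ** 2).sum()))
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(w.size) for _ in range(n_perm)])
    w_mat = w[perms].T  # samples x n_perm: label permutation = weight permutation
    d_null = np.sqrt(((r_set @ w_mat) ** 2).sum(axis=0))
    p = (1.0 + float((d_null >= d_obs).sum())) / (n_perm + 1.0)
    return GeneSetResult(
        name="", p_value=p, statistic=d_obs, total=int(rows.sum())
    )


def design_based_test(
    y: ExpressionMatrix,
    design: DesignTable,
    genes: Sequence[str],
    n_boot: int = 1000,
    seed: int = 0,
    resample_unit: str = "column",
    control: str | None = None,
    treated: str | None = None,
) -> GeneSetResult:
    """Design-based bootstrap set test (see module docstring).

    ``resample_unit="column"`` (default) resamples whole sample columns of
    the treatment-removed residuals, retaining inter-gene correlation;
    ``"cell"`` resamples each gene's residuals independently, for
    comparison with the correlation-free null.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if resample_unit not in ("column", "cell"):
        raise ValueError("resample_unit must be 'column' or 'cell'")
    vals, n_cc, n_t = _ordered_columns(y, design, control, treated)
    rows = _set_rows(y, genes)
    yset = vals[rows]
    mc = np.arange(yset.shape[1]) < n_cc
    mt = ~mc
    d_obs = float(
        np.sqrt(((yset[:, mt].mean(axis=1) - yset[:, mc].mean(axis=1)) ** 2).sum())
    )
    resid = yset - yset.mean(axis=1, keepdims=True)  # treatment effect removed
    k, n = resid.shape
    rng = np.random.default_rng(seed)
    d_null = np.empty(n_boot)
    chunk = max(1, min(n_boot, int(2_000_000 / max(1, k * n))))
    pos = 0
    while pos < n_boot:
        b = min(chunk, n_boot - pos)
        if resample_unit == "column":
            idx = rng.integers(0, n, size=(b, n))
            draws = resid[:, idx]  # k x b x n
        else:
            idx = rng.integers(0, n, size=(k, b, n))
            draws = np.take_along_axis(resid[:, None, :], idx, axis=2)
        diff = draws[:, :, mt].mean(axis=2) - draws[:, :, mc].mean(axis=2)
        d_null[pos : pos + b] = np.sqrt((diff**2).sum(axis=0))
        pos += b
    p = (1.0 + float((d_null >= d_obs).sum())) / (n_boot + 1.0)
    return GeneSetResult(name="", p_value=p, statistic=d_obs, total=k)


def run_enrichment(
    y: ExpressionMatrix,
    design: DesignTable,
    collection: GeneSetCollection,
    de_result: pd.DataFrame | None = None,
    method: str = "both",
    n_resample: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    rank_scope: str = "global",
    control: str | None = None,
    treated: str | None = None,
) -> pd.DataFrame:
    """Enrichment report over a gene-set collection.

    One row per set and method, sorted ascending by p within method, with
    ``total`` = measured probes in the set and ``changing`` = set probes
    whose adjusted differential-expression p falls below ``alpha`` (zero
    when no DE table is supplied). Sets disjoint from the measured genes
    are skipped with a warning. Raw set p-values are reported unadjusted;
    an optional BH column ``q_value`` is included for convenience.
    """
    if method not in ("rank", "design", "both"):
        raise ValueError("method must be 'rank', 'design' or 'both'")
    methods = ["rank", "design"] if method == "both" else [method]
    measured = set(map(str, y.probes))
    sig: set[str] = set()
    if de_result is not None:
        qcol = "q_value" if "q_value" in de_result else "p_value"
        sig = set(map(str, de_result.index[de_result[qcol] < alpha]))
    seeds = np.random.SeedSequence(seed).spawn(len(collection.names) * len(methods))
    rows = []
    i = 0
    for meth in methods:
        for name in collection.names:
            members = [g for g in collection[name] if g in measured]
            sub_seed = int(seeds[i].generate_state(1)[0] % (2**31))
            i += 1
            if not members:
                warnings.warn(f"gene set '{name}' shares no genes with the matrix")
                continue
            if meth == "rank":
                res = rank_based_test(
                    y,
                    design,
                    members,
                    n_perm=n_resample,
                    seed=sub_seed,
                    rank_scope=rank_scope,
                    control=control,
                    treated=treated,
                )
            else:
                res = design_based_test(
                    y,
                    design,
                    members,
                    n_boot=n_resample,
                    seed=sub_seed,
                    control=control,
                    treated=treated,
                )
            rows.append(
                {
                    "method": meth,
                    "set": name,
                    "p_value": res.p_value,
                    "statistic": res.statistic,
                    "total": res.total,
                    "changing": len(sig.intersection(members)),
                }
            )
    table = pd.DataFrame.from_records(rows)
    if table.empty:
        return table
    table = table.sort_values(
        ["method", "p_value", "set"], kind="mergesort"
    ).reset_index(drop=True)
    from .diffexpr import fdr_adjust

    table["q_value"] = np.concatenate(
        [
            fdr_adjust(table.loc[table["method"] == m, "p_value"].to_numpy())
            for m in sorted(table["method"].unique())
        ]
    ) if len(methods) > 1 else fdr_adjust(table["p_value"].to_numpy())
    return table
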
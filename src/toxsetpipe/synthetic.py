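"""Synthetic array and qPCR experiments with known ground truth.

The generator emulates the designs the pipeline analyses:

* a two-color common-reference experiment (every sample co-hybridized
  against one universal reference; experimental channel red/Cy5, reference
  green/Cy3) with intensity-dependent dye bias, right-skewed gene-wise
  variances and exchangeable within-pathway correlation;
* single-channel arrays carrying labelled negative-control probes and
  technical replicate probes per target;
* long-format qPCR Ct tables with housekeeping genes.

All randomness flows from the single integer ``seed`` through one
``numpy.random.Generator``; no global state is touched, and a fixed seed
gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import CtTable, DesignTable, ExpressionMatrix, GeneSetCollection

#: Centre of the baseline log2-abundance distribution; the dye-bias
#: polynomial is evaluated in A minus this constant.
_A_CENTER = 10.0


def gene_ids(n: int, prefix: str = "g") -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def disjoint_gene_sets(
    n_genes: int, n_sets: int, set_size: int, prefix: str = "set"
) -> GeneSetCollection:
    """Consecutive, non-overlapping sets over the generated gene identifiers."""
    if n_sets * set_size > n_genes:
        raise ValueError("n_sets * set_size exceeds n_genes")
    ids = gene_ids(n_genes)
    sets = {
        f"{prefix}{k + 1:02d}": ids[k * set_size : (k + 1) * set_size]
        for k in range(n_sets)
    }
    return GeneSetCollection(sets)


@dataclass
class SimulationConfig:
    """Conditions of a simulated two-group expression experiment.

    Effect sizes (``perturbed_sets`` values and ``de_effect``) are in log2
    units; ``variance_df``/``variance_scale`` parameterise the scaled
    inverse-chi-square distribution of gene-wise variances (right-skewed,
    as in real array data); ``dye_bias`` holds polynomial coefficients
    (constant, linear, quadratic, ...) of the additive log-ratio trend as a
    function of centred mean log-intensity; ``rho_within_set`` is the
    exchangeable correlation of noise among genes of one set, injected via
    a shared per-set latent factor.
    """

    n_genes: int = 1000
    n_samples_per_group: int = 8
    n_groups: int = 2
    gene_sets: GeneSetCollection | None = None
    perturbed_sets: Mapping[str, float] = field(default_factory=dict)
    frac_de_genes: float = 0.0
    de_effect: float = 1.0
    dye_bias: tuple[float, ...] = (0.3, -0.35, -0.02)
    variance_df: float = 5.0
    variance_scale: float = 0.05
    rho_within_set: float = 0.0
    n_negative_controls: int = 50
    n_replicates: int = 1
    signal_margin: float = 4.0
    background_mean_log2: float = 6.0
    background_sd_log2: float = 0.5
    baseline_ct: float = 24.0
    noise_sd_ct: float = 0.25
    n_ct_replicates: int = 2
    housekeeping: tuple[str, ...] = ("Hprt", "Actb")
    ct_true_log2fc: Mapping[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups != 2:
            raise ValueError("only two treatment groups are supported")
        if not 0.0 <= self.frac_de_genes <= 1.0:
            raise ValueError("frac_de_genes must be in [0, 1]")
        if not 0.0 <= self.rho_within_set < 1.0:
            raise ValueError("rho_within_set must be in [0, 1)")
        for name, delta in self.perturbed_sets.items():
            if not np.isfinite(delta):
                raise ValueError(f"effect for set '{name}' is not finite")
            if self.gene_sets is None or name not in self.gene_sets:
                raise ValueError(f"perturbed set '{name}' not in gene_sets")
        if self.variance_df <= 0 or self.variance_scale < 0:
            raise ValueError("variance model parameters must be positive")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated experiment."""

    de_genes: dict[str, float]  # gene -> true log2 effect (treated - control)
    perturbed_sets: dict[str, float]
    true_variance: pd.Series


def _gene_variances(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Scaled inverse-chi-square draws: nu0*s0^2 / chi2(nu0)."""
    if config.variance_scale == 0.0:
        return np.zeros(config.n_genes)
    chi2 = rng.chisquare(config.variance_df, size=config.n_genes)
    return config.variance_df * config.variance_scale / chi2


def _treatment_effects(
    config: SimulationConfig, ids: list[str], rng: np.random.Generator
) -> dict[str, float]:
    """Per-gene true log2 effect in the treated group."""
    effects: dict[str, float] = {}
    in_sets: set[str] = set()
    if config.gene_sets is not None:
        for name, delta in config.perturbed_sets.items():
            members = [g for g in config.gene_sets[name] if g in set(ids)]
            if not members:
                raise ValueError(f"perturbed set '{name}' has no generated genes")
            for g in members:
                effects[g] = delta
            in_sets.update(members)
    n_extra = int(round(config.frac_de_genes * config.n_genes))
    if n_extra:
        pool = [g for g in ids if g not in in_sets]
        chosen = rng.choice(pool, size=min(n_extra, len(pool)), replace=False)
        signs = rng.choice([-1.0, 1.0], size=len(chosen))
        for g, s in zip(chosen, signs):
            effects[str(g)] = s * config.de_effect
    return {g: e for g, e in effects.items() if e != 0.0}


def _correlated_noise(
    config: SimulationConfig,
    ids: list[str],
    sigma: np.ndarray,
    n_samples: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gene x sample noise, equicorrelated within sets via a latent factor."""
    n_genes = len(ids)
    eps = rng.standard_normal((n_genes, n_samples))
    rho = config.rho_within_set
    if rho > 0.0 and config.gene_sets is not None:
        index = {g: i for i, g in enumerate(ids)}
        assigned = np.full(n_genes, -1)
        for k, name in enumerate(config.gene_sets.names):
            for g in config.gene_sets[name]:
                i = index.get(g)
                if i is not None and assigned[i] < 0:  # first set wins on overlap
                    assigned[i] = k
        factors = rng.standard_normal((len(config.gene_sets), n_samples))
        member = assigned >= 0
        eps[member] = np.sqrt(rho) * factors[assigned[member]] + np.sqrt(
            1.0 - rho
        ) * eps[member]
    return sigma[:, None] * eps


def _design(config: SimulationConfig, dye: bool) -> DesignTable:
    n = config.n_samples_per_group
    samples = [f"ctrl_{i + 1}" for i in range(n)] + [f"trt_{i + 1}" for i in range(n)]
    table = pd.DataFrame(
        {
            "sample": samples,
            "group": ["control"] * n + ["treated"] * n,
            "array": [f"array_{i + 1}" for i in range(2 * n)],
        }
    )
    if dye:
        table["dye"] = "Cy5"  # experimental channel; reference is Cy3
    return DesignTable(table)


def generate_two_color(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, DesignTable, SyntheticTruth]:
    """Simulate a common-reference two-color experiment.

    Returns raw-scale red (experimental) and green (reference) channel
    matrices, the design table and the ground truth. The true log-ratio of
    a null gene has zero expected treatment difference; dye bias enters as
    an additive polynomial trend of M in centred A.
    """
    rng = np.random.default_rng(config.seed)
    ids = gene_ids(config.n_genes)
    n_samples = 2 * config.n_samples_per_group
    baseline = rng.uniform(6.0, 14.0, size=config.n_genes)
    sigma2 = _gene_variances(config, rng)
    sigma = np.sqrt(sigma2)
    effects = _treatment_effects(config, ids, rng)
    effect_vec = np.array([effects.get(g, 0.0) for g in ids])

    m_true = _correlated_noise(config, ids, sigma, n_samples, rng)
    treated_cols = np.arange(config.n_samples_per_group, n_samples)
    m_true[:, treated_cols] += effect_vec[:, None]

    a = baseline[:, None] + 0.05 * rng.standard_normal((config.n_genes, n_samples))
    bias = np.polynomial.polynomial.polyval(a - _A_CENTER, np.asarray(config.dye_bias))
    m_obs = m_true + bias

    design = _design(config, dye=True)
    cols = design.samples
    red = pd.DataFrame(2.0 ** (a + m_obs / 2.0), index=ids, columns=cols)
    green = pd.DataFrame(2.0 ** (a - m_obs / 2.0), index=ids, columns=cols)
    ann = pd.DataFrame({"negative_control": False, "target": ids}, index=ids)
    truth = SyntheticTruth(
        de_genes=effects,
        perturbed_sets=dict(config.perturbed_sets),
        true_variance=pd.Series(sigma2, index=ids),
    )
    return (
        ExpressionMatrix(red, annotations=ann, channel="red"),
        ExpressionMatrix(green, annotations=ann.copy(), channel="green"),
        design,
        truth,
    )


def dye_bias_curve(config: SimulationConfig, a: np.ndarray) -> np.ndarray:
    """The injected dye-bias trend evaluated at mean log2 intensities ``a``."""
    return np.polynomial.polynomial.polyval(
        np.asarray(a, dtype=float) - _A_CENTER, np.asarray(config.dye_bias)
    )


def generate_single_channel(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, DesignTable, SyntheticTruth]:
    """Simulate single-channel arrays with negative-control probes.

    Every probe carries a background component N(background_mean,
    background_sd) on the log2 scale; target probes sit ``signal_margin``
    log2 units above it plus gene-level biological noise shared by the
    ``n_replicates`` technical replicate probes of the target. Negative
    controls are background-only.
    """
    if config.n_negative_controls < 3:
        raise ValueError("need >= 3 negative-control probes")
    rng = np.random.default_rng(config.seed)
    targets = gene_ids(config.n_genes, prefix="t")
    n_samples = 2 * config.n_samples_per_group
    sigma = np.sqrt(_gene_variances(config, rng))
    effects = _treatment_effects(config, targets, rng)
    effect_vec = np.array([effects.get(g, 0.0) for g in targets])

    gene_level = _correlated_noise(config, targets, sigma, n_samples, rng)
    gene_level += config.signal_margin
    gene_level[:, config.n_samples_per_group :] += effect_vec[:, None]

    k = max(1, int(config.n_replicates))
    probe_ids: list[str] = []
    target_of: list[str] = []
    rows = []
    for i, t in enumerate(targets):
        for r in range(k):
            probe_ids.append(t if k == 1 else f"{t}_r{r + 1}")
            target_of.append(t)
            bg = config.background_mean_log2 + config.background_sd_log2 * (
                rng.standard_normal(n_samples)
            )
            rows.append(bg + gene_level[i])
    nc_ids = [f"NC_{i + 1:03d}" for i in range(config.n_negative_controls)]
    for nc in nc_ids:
        probe_ids.append(nc)
        target_of.append(nc)
        rows.append(
            config.background_mean_log2
            + config.background_sd_log2 * rng.standard_normal(n_samples)
        )

    design = _design(config, dye=False)
    values = pd.DataFrame(
        2.0 ** np.asarray(rows), index=probe_ids, columns=design.samples
    )
    ann = pd.DataFrame(
        {
            "negative_control": [p in set(nc_ids) for p in probe_ids],
            "target": target_of,
        },
        index=probe_ids,
    )
    truth = SyntheticTruth(
        de_genes=effects,
        perturbed_sets=dict(config.perturbed_sets),
        true_variance=pd.Series(sigma**2, index=targets),
    )
    return ExpressionMatrix(values, annotations=ann), design, truth


def generate_ct_table(config: SimulationConfig) -> tuple[CtTable, dict[str, float]]:
    """Simulate a long-format qPCR Ct table.

    Ct = per-gene baseline - log2(relative expression) + N(0, noise_sd_ct)
    per well; housekeeping genes have zero treatment effect. Returns the
    table and the true linear fold change per target gene.
    """
    if not config.housekeeping:
        raise ValueError("at least one housekeeping gene must be declared")
    rng = np.random.default_rng(config.seed)
    targets = gene_ids(config.n_genes)
    if config.ct_true_log2fc is not None:
        log2fc = {g: float(config.ct_true_log2fc.get(g, 0.0)) for g in targets}
    else:
        log2fc = {g: 0.0 for g in targets}
        n_de = int(round(config.frac_de_genes * config.n_genes))
        if n_de:
            chosen = rng.choice(targets, size=n_de, replace=False)
            signs = rng.choice([-1.0, 1.0], size=n_de)
            for g, s in zip(chosen, signs):
                log2fc[str(g)] = s * config.de_effect
    genes = list(config.housekeeping) + targets
    baseline = {
        g: config.baseline_ct + rng.uniform(-3.0, 3.0) for g in genes
    }
    n = config.n_samples_per_group
    samples = [f"ctrl_{i + 1}" for i in range(n)] + [f"trt_{i + 1}" for i in range(n)]
    groups = ["control"] * n + ["treated"] * n
    records = []
    for s, grp in zip(samples, groups):
        for g in genes:
            fc = log2fc.get(g, 0.0) if (grp == "treated" and g not in config.housekeeping) else 0.0
            true_ct = baseline[g] - fc
            for rep in range(max(1, config.n_ct_replicates)):
                noise = config.noise_sd_ct * rng.standard_normal()
                records.append(
                    {
                        "sample": s,
                        "group": grp,
                        "gene": g,
                        "ct": true_ct + noise,
                        "replicate": rep + 1,
                    }
                )
    table = CtTable(
        pd.DataFrame.from_records(records), housekeeping=config.housekeeping
    )
    return table, {g: float(2.0**v) for g, v in log2fc.items()}
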
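"""End-to-end orchestrated run: simulate -> normalize -> DE -> GSEA ->
PCR -> dosimetry, with a run log and deterministic report tables.

No stage mutates its inputs; every output lands in a fresh run directory.
Given the same configuration (including seeds) the report is byte-identical
across runs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import dosimetry as dose_mod
from .containers import DesignTable, ExpressionMatrix
from .diffexpr import differential_expression
from .genesets import run_enrichment
from .io import (
    RunConfig,
    RunLog,
    write_ct_csv,
    write_design_csv,
    write_expression_tsv,
    write_gmt,
    write_table_tsv,
)
from .normalization import lowess_normalize
from .pcr import pcr_report
from .synthetic import (
    SimulationConfig,
    disjoint_gene_sets,
    generate_ct_table,
    generate_two_color,
)

#: Default simulated experiment for `run`: ten disjoint pathways, one
#: perturbed, within-pathway correlation, plus scattered single-gene effects.
_DEFAULT_SIMULATE: dict[str, Any] = {
    "n_genes": 500,
    "n_samples_per_group": 8,
    "n_sets": 10,
    "set_size": 30,
    "perturbed_set_delta": 2.0,
    "rho_within_set": 0.2,
    "frac_de_genes": 0.05,
    "de_effect": 1.5,
    "n_ct_genes": 8,
    "ct_frac_de": 0.25,
}


def _build_sim_config(params: dict[str, Any], seed: int) -> SimulationConfig:
    p = dict(_DEFAULT_SIMULATE)
    p.update(params)
    sets = disjoint_gene_sets(p["n_genes"], p["n_sets"], p["set_size"])
    perturbed = {sets.names[0]: p["perturbed_set_delta"]}
    return SimulationConfig(
        n_genes=p["n_genes"],
        n_samples_per_group=p["n_samples_per_group"],
        gene_sets=sets,
        perturbed_sets=perturbed,
        frac_de_genes=p["frac_de_genes"],
        de_effect=p["de_effect"],
        rho_within_set=p["rho_within_set"],
        seed=seed,
    )


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the configured stages and write the report directory.

    Returns a dict with the output directory and the per-stage tables.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = RunLog()
    results: dict[str, Any] = {"out_dir": str(out)}
    seed_children = np.random.SeedSequence(config.seed).spawn(4)
    stage_seed = {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(("de", "gsea", "pcr", "extra"), seed_children)
    }
    log.record("run", "seeds", base=config.seed, **stage_seed)

    red = green = design = truth = None
    sim_config = _build_sim_config(config.simulate, config.seed)
    if config.stages.get("simulate", True):
        red, green, design, truth = generate_two_color(sim_config)
        write_expression_tsv(red, out / "red.tsv")
        write_expression_tsv(green, out / "green.tsv")
        write_design_csv(design, out / "design.csv")
        write_gmt(sim_config.gene_sets, out / "gene_sets.gmt")
        log.record(
            "simulate",
            "generated",
            n_genes=sim_config.n_genes,
            n_samples=2 * sim_config.n_samples_per_group,
            n_true_de=len(truth.de_genes),
            seed=config.seed,
        )
        results["truth"] = truth
    else:
        log.record("simulate", "skipped")

    normalized = None
    if config.stages.get("normalize", True) and red is not None:
        if config.exclude_arrays:
            keep = [s for s in red.samples if s not in set(config.exclude_arrays)]
            red = ExpressionMatrix(
                red.values[keep], red.annotations, red.log_scale, red.channel
            )
            green = ExpressionMatrix(
                green.values[keep], green.annotations, green.log_scale, green.channel
            )
            tbl = design.table.copy()
            tbl.loc[tbl["sample"].isin(config.exclude_arrays), "include"] = False
            design = DesignTable(tbl)
            log.record(
                "normalize", "arrays_excluded", arrays=sorted(config.exclude_arrays)
            )
        span = float(config.normalize.get("span", 0.4))
        normalized = lowess_normalize(red, green, span=span)
        n_missing = int(normalized.values.isna().any(axis=1).sum())
        log.record(
            "normalize",
            "lowess",
            span=span,
            rows_in=red.n_probes,
            rows_out=red.n_probes - n_missing,
            rows_dropped=n_missing,
        )
        write_expression_tsv(normalized, out / "normalized.tsv")
        results["normalized"] = normalized
    else:
        log.record("normalize", "skipped")

    de_table = None
    if config.stages.get("de", True) and normalized is not None:
        de_params = config.de
        de_table = differential_expression(
            normalized,
            design,
            stat=de_params.get("stat", "fs"),
            n_perm=int(de_params.get("n_perm", 500)),
            seed=stage_seed["de"],
            alpha=float(de_params.get("alpha", 0.05)),
        )
        n_sig = int(de_table["significant"].sum())
        log.record(
            "de",
            "tested",
            statistic=de_params.get("stat", "fs"),
            n_perm=int(de_params.get("n_perm", 500)),
            alpha=de_params.get("alpha", 0.05),
            n_genes=len(de_table),
            n_significant=n_sig,
            seed=stage_seed["de"],
        )
        de_out = de_table.copy()
        de_out.index.name = "gene"
        write_table_tsv(de_out, out / "de.tsv")
        results["de"] = de_table
    else:
        log.record("de", "skipped")

    if config.stages.get("gsea", True) and normalized is not None:
        gsea_params = config.gsea
        enrichment = run_enrichment(
            normalized,
            design,
            sim_config.gene_sets,
            de_result=de_table,
            method=gsea_params.get("method", "both"),
            n_resample=int(gsea_params.get("n_resample", 500)),
            seed=stage_seed["gsea"],
            alpha=float(gsea_params.get("alpha", 0.05)),
            rank_scope=gsea_params.get("rank_scope", "global"),
        )
        log.record(
            "gsea",
            "tested",
            method=gsea_params.get("method", "both"),
            n_resample=int(gsea_params.get("n_resample", 500)),
            n_sets=len(sim_config.gene_sets),
            seed=stage_seed["gsea"],
        )
        write_table_tsv(enrichment, out / "enrichment.tsv", index=False)
        results["enrichment"] = enrichment
    else:
        log.record("gsea", "skipped")

    if config.stages.get("pcr", True):
        p = dict(_DEFAULT_SIMULATE)
        p.update(config.simulate)
        ct_config = SimulationConfig(
            n_genes=int(p["n_ct_genes"]),
            n_samples_per_group=6,
            frac_de_genes=float(p["ct_frac_de"]),
            de_effect=2.0,
            seed=stage_seed["pcr"],
        )
        ct_table, ct_truth = generate_ct_table(ct_config)
        write_ct_csv(ct_table, out / "ct.csv")
        pcr_table = pcr_report(
            ct_table,
            n_rand=int(config.pcr.get("n_rand", 2000)),
            seed=stage_seed["pcr"],
        )
        log.record(
            "pcr",
            "tested",
            n_genes=len(pcr_table),
            n_rand=int(config.pcr.get("n_rand", 2000)),
            seed=stage_seed["pcr"],
        )
        write_table_tsv(pcr_table, out / "pcr.tsv", index=False)
        results["pcr"] = pcr_table
        results["ct_truth"] = ct_truth
    else:
        log.record("pcr", "skipped")

    if config.stages.get("dose", True):
        d = config.dose
        regimen = dose_mod.ExposureRegimen(
            d.get("days", 11),
            d.get("hours_per_day", 1.0),
            d.get("concentration_mg_m3", 42.4),
            d.get("inhaled_volume_rate_m3_hr", 0.0018),
        )
        report = dose_mod.dose_report(
            regimen,
            dose_mod.EXAMPLE_DEPOSITION_FRACTIONS,
            organ_mass_mg=d.get("organ_mass_mg", 274.0),
            ssa_m2_per_g=d.get("ssa_m2_per_g"),
            measured_mg_per_kg=d.get("measured_mg_per_kg"),
        )
        dose_table = pd.DataFrame(
            {"quantity": list(report), "value": list(report.values())}
        )
        log.record("dose", "computed", n_quantities=len(report))
        write_table_tsv(dose_table, out / "dose.tsv", index=False)
        results["dose"] = report
    else:
        log.record("dose", "skipped")

    log.write(out / "run.log")
    config.to_yaml(out / "config.yaml")
    return results
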
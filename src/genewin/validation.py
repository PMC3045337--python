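"""Simulation studies that validate the pipeline end to end.

Each function runs one self-contained experiment on synthetic cohorts —
null calibration of the trend test and the permutation CIs, genomic
control under two-population structure, and recovery of planted exonic
effects — and returns plain numbers.  They are used by the test suite
and by ``scripts/acceptance.py``; the problem sizes are chosen so a full
run stays in the minutes range on one CPU.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats

from . import assoc, enrich, genemap, qc, simdata

#: Null-calibration study conditions: balanced 500+500 cohort, 5,000
#: SNPs, no effects, no structure.
NULL_CONFIG = simdata.SimConfig(
    n_cases=500, n_controls=500, n_snps=5000, n_causal=0, strat_fst=0.0,
    missing_rate=0.0,
)

#: Planted-effect study conditions: 30 causal exonic SNPs at OR 1.5 in a
#: 1,000+1,000 cohort.  6,000 SNPs over a 150-gene genome keeps the
#: exonic fraction at the ~1% of an array-era panel (coding exons are a
#: small sliver of the genome) while leaving enough exonic SNPs to host
#: the causal set.
PLANTED_CONFIG = simdata.SimConfig(
    n_cases=1000, n_controls=1000, n_snps=6000, n_chromosomes=2,
    chrom_length_bp=12_000_000, n_genes=150, gene_length_mean_bp=50_000,
    gene_length_sd_bp=50_000, exons_per_gene=(5, 11), exon_length_mean_bp=200.0,
    exon_length_sd_bp=80.0, missing_rate=0.0,
    n_causal=30, causal_or=1.5, causal_placement="exon",
)


def _subseed(seed: int, *parts: int) -> int:
    """A derived 31-bit seed, stable across runs."""
    ss = np.random.SeedSequence([seed, *parts])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def null_calibration(seed: int, n_perm: int = 1000,
                     alphas=(0.1, 0.01, 0.001)) -> dict:
    """One null cohort: p-value calibration, lambda, and CI exceedance.

    Returns the fraction of SNPs with p < alpha for each alpha, the
    genomic-control lambda_median, and the per-cell exceedance of the
    permutation CI upper bound across all (window, alpha) cells.
    """
    cfg = replace(NULL_CONFIG, seed=seed)
    genes, snps = simdata.simulate_annotation(cfg)
    cohort, _truth = simdata.simulate_cohort(cfg, genes, snps)
    cohort, _rep = qc.apply_qc(cohort)
    kept = {s.snp_id for s in snps} & set(cohort.snp_ids)
    loci = [s for s in snps if s.snp_id in kept]

    table, gc = assoc.association_scan(cohort, loci)
    pvals = pd.Series(table["p"].to_numpy(), index=table["snp_id"])
    # calibration of the trend test itself: uncorrected p-values
    p_raw = stats.chi2.sf(table["chi2_raw"].to_numpy(), df=1)
    p_raw[table["degenerate"].to_numpy(dtype=bool)] = 1.0
    fractions = {a: float((p_raw < a).mean()) for a in alphas}

    assignments = genemap.assign_all(loci, genes)
    observed = enrich.window_counts(assignments, pvals, alphas)
    stream = assoc.iter_permutation_pvalues(cohort, n_perm, _subseed(seed, 7))
    perm_counts = enrich.permutation_window_counts(
        assignments, list(pvals.index), (c for c, _l in stream), alphas)
    etable = enrich.build_enrichment_table(
        observed, perm_counts, enrich.EnrichConfig(alphas=tuple(alphas)))

    cells = etable[etable["n_total"] > 0]
    return {
        "fractions": fractions,
        "n_snps": int(cohort.n_snps),
        "lambda_median": float(gc.lambda_median),
        "n_cells": int(len(cells)),
        "n_exceed": int(cells["significant"].sum()),
        "exceed_rate": float(cells["significant"].mean()),
    }


def stratified_lambda(seed: int, fst: float = 0.05,
                      case_frac_pop1: float = 0.8) -> float:
    """lambda_median for a structured cohort with unequal case sampling."""
    cfg = replace(NULL_CONFIG, seed=seed, n_cases=1000, n_controls=1000,
                  strat_fst=fst, strat_case_frac_pop1=case_frac_pop1)
    genes, snps = simdata.simulate_annotation(cfg)
    cohort, _truth = simdata.simulate_cohort(cfg, genes, snps)
    cohort, _rep = qc.apply_qc(cohort)
    chi2, _p, degen = assoc.trend_scan(cohort.doses, cohort.is_case)
    return float(assoc.genomic_control(chi2, degen).lambda_median)


def planted_effect_run(seed: int, placement: str = "exon", n_perm: int = 500,
                       alpha: float = 0.01) -> dict:
    """One planted-effect cohort; did the exon stratum light up?

    Returns the exon-stratum significance flag at ``alpha`` and the
    smoothed proportions at the gene window and at the outermost
    (+/-100 kb) windows.
    """
    cfg = replace(PLANTED_CONFIG, seed=seed, causal_placement=placement)
    genes, snps = simdata.simulate_annotation(cfg)
    cohort, truth = simdata.simulate_cohort(cfg, genes, snps)
    cohort, _rep = qc.apply_qc(cohort)
    kept = set(cohort.snp_ids)
    loci = [s for s in snps if s.snp_id in kept]

    table, _gc = assoc.association_scan(cohort, loci)
    pvals = pd.Series(table["p"].to_numpy(), index=table["snp_id"])
    assignments = genemap.assign_all(loci, genes)
    observed = enrich.window_counts(assignments, pvals, (alpha,))
    stream = assoc.iter_permutation_pvalues(cohort, n_perm, _subseed(seed, 11))
    perm_counts = enrich.permutation_window_counts(
        assignments, list(pvals.index), (c for c, _l in stream), (alpha,))
    etable = enrich.build_enrichment_table(
        observed, perm_counts, enrich.EnrichConfig(alphas=(alpha,)))

    exon_row = etable[etable["window"].astype(str) == enrich.EXON].iloc[0]
    win = etable[etable["window"].astype(str) != enrich.EXON].copy()
    win["window"] = win["window"].astype(int)
    win = win.set_index("window")
    return {
        "exon_significant": bool(exon_row["significant"]),
        "exon_proportion": float(exon_row["proportion"]),
        "smoothed_center": float(win.loc[0, "smoothed"]),
        "smoothed_edge": float((win.loc[-10, "smoothed"] + win.loc[10, "smoothed"]) / 2),
        "n_causal_kept": int(len(set(truth.causal_snp_ids) & kept)),
    }


def planted_effect_study(seed: int, n_seeds: int = 20, n_perm: int = 500,
                         alpha: float = 0.01) -> dict:
    """Detection rates over seeds: exonic vs uniform causal placement."""
    exon_runs = [planted_effect_run(_subseed(seed, 1, i), "exon", n_perm, alpha)
                 for i in range(n_seeds)]
    unif_runs = [planted_effect_run(_subseed(seed, 2, i), "uniform", n_perm, alpha)
                 for i in range(n_seeds)]
    return {
        "exon_detection_rate": float(np.mean([r["exon_significant"] for r in exon_runs])),
        "uniform_detection_rate": float(np.mean([r["exon_significant"] for r in unif_runs])),
        "mean_smoothed_center": float(np.mean([r["smoothed_center"] for r in exon_runs])),
        "mean_smoothed_edge": float(np.mean([r["smoothed_edge"] for r in exon_runs])),
    }
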
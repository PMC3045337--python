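"""End-to-end pipeline orchestration and figure/table emission."""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import assoc, enrich, genemap, qc
from .enrich import EXON, EnrichConfig
from .qc import QcConfig


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: str):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    cohort_prefix: str  # <prefix>.ped / <prefix>.map
    annotation_path: str
    out_dir: str
    region_filter_path: str | None = None
    qc: QcConfig = field(default_factory=QcConfig)
    enrich: EnrichConfig = field(default_factory=EnrichConfig)
    n_perm: int = 1000
    seed: int = 0
    k_max: int = 10
    strand_aware: bool = True
    gc_in_perm: bool = True

    def validate(self) -> None:
        if self.n_perm < 1:
            raise PipelineError("config", "n_perm must be >= 1")
        for name, p in (("cohort PED", Path(self.cohort_prefix).with_suffix(".ped")),
                        ("cohort MAP", Path(self.cohort_prefix).with_suffix(".map")),
                        ("annotation", Path(self.annotation_path))):
            if not p.exists():
                raise PipelineError("config", f"{name} file not found: {p}")
        if self.region_filter_path and not Path(self.region_filter_path).exists():
            raise PipelineError("config",
                                f"region filter file not found: {self.region_filter_path}")


_CONFIG_KEYS = {
    "cohort_prefix": str, "annotation_path": str, "out_dir": str,
    "region_filter_path": str, "n_perm": int, "seed": int, "k_max": int,
    "strand_aware": lambda v: v.lower() in ("1", "true", "yes"),
    "gc_in_perm": lambda v: v.lower() in ("1", "true", "yes"),
    "hwe_p_min": float, "maf_min": float, "call_rate_min": float,
    "rare_maf_max": float, "alphas": str, "ci_level": float,
    "smooth_span_bp": int,
}


def read_config(path: str | Path, overrides: dict | None = None) -> PipelineConfig:
    """Flat ``key = value`` configuration file; CLI overrides win."""
    raw: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, sep, value = line.partition("=")
        if not sep:
            raise PipelineError("config", f"{path}:{lineno}: expected key = value")
        raw[key.strip()] = value.strip()
    raw.update({k: str(v) for k, v in (overrides or {}).items() if v is not None})
    unknown = set(raw) - set(_CONFIG_KEYS)
    if unknown:
        raise PipelineError("config", f"unknown keys: {sorted(unknown)}")
    conv = {k: _CONFIG_KEYS[k](v) for k, v in raw.items()}
    qc_kwargs = {k: conv.pop(k) for k in ("hwe_p_min", "maf_min", "call_rate_min",
                                          "rare_maf_max") if k in conv}
    en_kwargs = {}
    if "alphas" in conv:
        en_kwargs["alphas"] = tuple(float(a) for a in conv.pop("alphas").split(","))
    for k in ("ci_level", "smooth_span_bp"):
        if k in conv:
            en_kwargs[k] = conv.pop(k)
    return PipelineConfig(qc=QcConfig(**qc_kwargs), enrich=EnrichConfig(**en_kwargs), **conv)


def read_config_from_overrides(overrides: dict) -> PipelineConfig:
    """Build a config purely from CLI options (no config file)."""
    raw = {k: str(v) for k, v in overrides.items() if v is not None}
    missing = {"cohort_prefix", "annotation_path", "out_dir"} - set(raw)
    if missing:
        raise PipelineError("config", f"missing required options: {sorted(missing)}")
    conv = {k: _CONFIG_KEYS[k](v) for k, v in raw.items()}
    qc_kwargs = {k: conv.pop(k) for k in ("hwe_p_min", "maf_min", "call_rate_min",
                                          "rare_maf_max") if k in conv}
    en_kwargs = {}
    if "alphas" in conv:
        en_kwargs["alphas"] = tuple(float(a) for a in conv.pop("alphas").split(","))
    for k in ("ci_level", "smooth_span_bp"):
        if k in conv:
            en_kwargs[k] = conv.pop(k)
    return PipelineConfig(qc=QcConfig(**qc_kwargs), enrich=EnrichConfig(**en_kwargs), **conv)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run read -> QC -> association -> assignment -> enrichment -> figures.

    Writes all stage tables, figures and a machine-readable manifest into
    ``config.out_dir`` and returns the artifact paths.  Deterministic
    given the config (including seed).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    timings: dict[str, float] = {}

    def _stage(name):
        t0 = time.perf_counter()

        def done():
            timings[name] = round(time.perf_counter() - t0, 3)
        return done

    try:
        done = _stage("read")
        cohort, loci = qc.read_cohort(Path(config.cohort_prefix).with_suffix(".ped"),
                                      Path(config.cohort_prefix).with_suffix(".map"))
        genes = genemap.read_annotation(config.annotation_path)
        done()
    except Exception as exc:  # noqa: BLE001 - stage context added
        raise PipelineError("read", str(exc)) from exc

    try:
        done = _stage("region_filter")
        if config.region_filter_path:
            rf = genemap.read_region_filter(config.region_filter_path)
            loci, genes = genemap.apply_region_filter(loci, genes, rf)
            keep = [sid in {l.snp_id for l in loci} for sid in cohort.snp_ids]
            cohort = cohort.subset_snps(np.array(keep))
        done()
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("region_filter", str(exc)) from exc

    try:
        done = _stage("qc")
        cohort_qc, report = qc.apply_qc(cohort, config.qc)
        artifacts["qc_report"] = out / "qc_report.tsv"
        report.to_tsv(artifacts["qc_report"])
        kept = set(cohort_qc.snp_ids)
        loci = [l for l in loci if l.snp_id in kept]
        done()
    except Exception as exc:
        raise PipelineError("qc", str(exc)) from exc

    try:
        done = _stage("assoc")
        assoc_table, gc = assoc.association_scan(cohort_qc, loci)
        artifacts["association"] = out / "association.tsv"
        assoc.write_association(assoc_table, artifacts["association"])
        done()
    except Exception as exc:
        raise PipelineError("assoc", str(exc)) from exc

    try:
        done = _stage("assign")
        assignments = genemap.assign_all(loci, genes, k_max=config.k_max,
                                         strand_aware=config.strand_aware)
        artifacts["assignments"] = out / "assignments.tsv"
        genemap.write_assignments(assignments, artifacts["assignments"])
        done()
    except Exception as exc:
        raise PipelineError("assign", str(exc)) from exc

    try:
        done = _stage("enrich")
        pvals = pd.Series(assoc_table["p"].to_numpy(), index=assoc_table["snp_id"])
        observed = enrich.window_counts(assignments, pvals, config.enrich.alphas,
                                        config.k_max)
        perm_stream = assoc.iter_permutation_pvalues(
            cohort_qc, config.n_perm, config.seed, config.gc_in_perm)
        perm_counts = enrich.permutation_window_counts(
            assignments, list(pvals.index), (c for c, _l in perm_stream),
            config.enrich.alphas, config.k_max)
        table = enrich.build_enrichment_table(observed, perm_counts, config.enrich,
                                              config.k_max)
        artifacts["enrichment"] = out / "enrichment.tsv"
        enrich.write_table(table, artifacts["enrichment"])
        # gene counts need a second pass over permutations
        perm_stream = assoc.iter_permutation_pvalues(
            cohort_qc, config.n_perm, config.seed, config.gc_in_perm)
        gene_table = enrich.count_suggestive_genes(
            assignments, pvals, (c for c, _l in perm_stream), config.enrich.alphas,
            config.enrich.ci_level, config.k_max)
        artifacts["gene_counts"] = out / "gene_counts.tsv"
        enrich.write_table(gene_table, artifacts["gene_counts"])
        done()
    except Exception as exc:
        raise PipelineError("enrich", str(exc)) from exc

    try:
        done = _stage("figures")
        for a in config.enrich.alphas:
            fig_path = out / f"enrichment_alpha_{a:g}.svg"
            render_profile_figure(table, a, fig_path, k_max=config.k_max)
            artifacts[f"figure_{a:g}"] = fig_path
        done()
    except Exception as exc:
        raise PipelineError("figures", str(exc)) from exc

    manifest = {
        "inputs": {
            "cohort_prefix": str(config.cohort_prefix),
            "annotation_path": str(config.annotation_path),
            "region_filter_path": config.region_filter_path,
        },
        "qc": {"hwe_p_min": config.qc.hwe_p_min, "maf_min": config.qc.maf_min,
               "call_rate_min": config.qc.call_rate_min,
               "rare_maf_max": config.qc.rare_maf_max},
        "enrich": {"alphas": list(config.enrich.alphas),
                   "ci_level": config.enrich.ci_level,
                   "smooth_span_bp": config.enrich.smooth_span_bp},
        "n_perm": config.n_perm, "seed": config.seed, "k_max": config.k_max,
        "strand_aware": config.strand_aware, "gc_in_perm": config.gc_in_perm,
        "lambda_median": gc.lambda_median,
        "n_snps_after_qc": len(kept),
        "timings_s": timings,
        "versions": _versions(),
        "artifacts": {k: str(v) for k, v in artifacts.items()},
    }
    artifacts["manifest"] = out / "manifest.json"
    artifacts["manifest"].write_text(json.dumps(manifest, indent=2) + "\n")
    return artifacts


def _versions() -> dict[str, str]:
    import importlib.metadata as md

    out = {}
    for pkg in ("genewin", "numpy", "scipy", "pandas"):
        try:
            out[pkg] = md.version(pkg)
        except md.PackageNotFoundError:
            out[pkg] = "unknown"
    return out


def render_profile_figure(table: pd.DataFrame, alpha: float, path: str | Path,
                          k_max: int = 10) -> Path:
    """Enrichment profile for one threshold: observed points, smoothed
    line, permutation CI band, and the exon stratum as a separate marker
    at the gene position.  X axis in kb from the gene."""
    sub = table[np.isclose(table["alpha"].astype(float), alpha)]
    if sub.empty:
        raise ValueError(f"alpha {alpha} not present in the enrichment table")
    exon_rows = sub[sub["window"].astype(str) == EXON]
    if exon_rows.empty:
        raise ValueError("enrichment table lacks the exon stratum")
    windows = sub[sub["window"].astype(str) != EXON].copy()
    windows["window"] = windows["window"].astype(int)
    windows = windows.sort_values("window")
    x = windows["window"].to_numpy() * 10  # kb

    fig, ax = plt.subplots(figsize=(7, 4.2))
    ax.fill_between(x, 100 * windows["ci_low_prop"], 100 * windows["ci_high_prop"],
                    color="lightblue", alpha=0.8, label="95% CI (permutation)")
    ax.plot(x, 100 * windows["proportion"], "o", color="crimson", ms=4,
            label=f"observed, p < {alpha:g}")
    ax.plot(x, 100 * windows["smoothed"], "-", color="steelblue",
            label="smoothed (50 kb)")
    ax.plot([0], [100 * float(exon_rows["proportion"].iloc[0])], "^",
            color="purple", ms=9, label="coding exons")
    ax.set_xlabel("distance to closest gene (kb)")
    ax.set_ylabel(f"SNPs with p < {alpha:g} (%)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path)
    plt.close(fig)
    return path
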
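"""Cohort input and SNP-level quality control.

Filters are evaluated on the pooled case/control data, each against the
pre-filter cohort: a SNP is removed if its call rate is below 0.97, its
pooled minor allele frequency is below 0.01, or its Hardy-Weinberg exact
p-value is below 0.001 (defaults; all configurable).  An optional
``rare_maf_max`` additionally restricts the surviving set to rare SNPs
(MAF < 0.05 reproduces the rare-variant stratum).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .model import MISSING, CohortGenotypes, SnpLocus

_VALID_ALLELES = frozenset("ACGT0")


class PedParseError(ValueError):
    """Malformed PED/MAP input."""


@dataclass(frozen=True)
class QcConfig:
    hwe_p_min: float = 0.001
    maf_min: float = 0.01
    call_rate_min: float = 0.97
    rare_maf_max: float | None = None

    def __post_init__(self) -> None:
        for name in ("hwe_p_min", "maf_min", "call_rate_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.rare_maf_max is not None and not 0.0 <= self.rare_maf_max <= 1.0:
            raise ValueError(f"rare_maf_max must be in [0, 1], got {self.rare_maf_max}")


@dataclass
class QcReport:
    """Per-SNP QC outcome plus per-filter exclusion counts.

    A SNP failing several filters is reported once, under the first
    failing filter in the fixed order (call_rate, maf, hwe, rare).
    """

    table: pd.DataFrame  # snp_id, status (kept/excluded), reason
    n_input: int
    n_kept: int
    excluded_by: dict[str, int]

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def read_cohort(ped_path: str | Path, map_path: str | Path
                ) -> tuple[CohortGenotypes, list[SnpLocus]]:
    """Read a PLINK-dialect text PED/MAP pair into a dose matrix.

    The minor allele of each SNP is determined from the pooled sample
    allele frequency over non-missing calls (ties broken by the
    lexicographically smaller allele); doses count minor alleles and a
    "0 0" genotype is missing.
    """
    map_path, ped_path = Path(map_path), Path(ped_path)
    loci_raw: list[tuple[str, str, int]] = []
    seen: set[str] = set()
    with map_path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 4:
                raise PedParseError(f"{map_path}:{lineno}: expected 4 columns, got {len(fields)}")
            chrom, snp_id, _gd, pos = fields
            if snp_id in seen:
                raise PedParseError(f"{map_path}:{lineno}: duplicate SNP id {snp_id!r}")
            seen.add(snp_id)
            loci_raw.append((snp_id, chrom, int(pos)))
    n_snps = len(loci_raw)

    sample_ids: list[str] = []
    is_case: list[bool] = []
    allele_rows: list[np.ndarray] = []
    with ped_path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 6 + 2 * n_snps:
                raise PedParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_snps} columns "
                    f"({n_snps} SNPs), got {len(fields)}")
            _fid, iid, _pat, _mat, _sex, pheno = fields[:6]
            alleles = fields[6:]
            bad = [a for a in alleles if a not in _VALID_ALLELES]
            if bad:
                raise PedParseError(
                    f"{ped_path}:{lineno}: allele symbol {bad[0]!r} outside A/C/G/T/0")
            sample_ids.append(iid)
            is_case.append(pheno == "2")
            allele_rows.append(np.array(alleles))

    alleles = (np.stack(allele_rows) if allele_rows
               else np.empty((0, 2 * n_snps), dtype="<U1"))
    a1 = alleles[:, 0::2]
    a2 = alleles[:, 1::2]
    n_samples = len(sample_ids)
    doses = np.full((n_samples, n_snps), MISSING, dtype=np.int8)
    loci: list[SnpLocus] = []
    for j, (snp_id, chrom, pos) in enumerate(loci_raw):
        col1, col2 = a1[:, j], a2[:, j]
        missing = (col1 == "0") | (col2 == "0")
        observed = np.concatenate([col1[~missing], col2[~missing]])
        symbols, counts = np.unique(observed, return_counts=True)
        if len(symbols) > 2:
            raise PedParseError(f"{ped_path}: SNP {snp_id!r} has more than two alleles: "
                                f"{sorted(symbols)}")
        if len(symbols) == 0:
            minor, major = "N", "N"
        elif len(symbols) == 1:
            minor, major = "N", str(symbols[0])  # monomorphic: minor unobserved
        else:
            # minor = lower count; tie -> lexicographically smaller symbol
            order = np.lexsort((symbols, counts))
            minor, major = str(symbols[order[0]]), str(symbols[order[1]])
        d = (col1 == minor).astype(np.int8) + (col2 == minor).astype(np.int8)
        d[missing] = MISSING
        doses[:, j] = d
        loci.append(SnpLocus(snp_id, chrom, pos, minor, major))

    cohort = CohortGenotypes([l.snp_id for l in loci], sample_ids, doses,
                             np.array(is_case, dtype=bool))
    return cohort, loci


def genotype_counts(doses: np.ndarray) -> np.ndarray:
    """Counts of dose 0/1/2 per SNP over non-missing calls; shape (3, n_snps)."""
    return np.stack([(doses == g).sum(axis=0) for g in (0, 1, 2)])


def call_rates(doses: np.ndarray) -> np.ndarray:
    return (doses != MISSING).mean(axis=0)


def minor_allele_freqs(doses: np.ndarray) -> np.ndarray:
    """Pooled frequency of the dose-counted allele over non-missing calls.

    Because doses count the pooled minor allele, this is the MAF; SNPs
    with no observed calls get frequency 0.
    """
    obs = doses != MISSING
    n_obs = obs.sum(axis=0)
    alt = np.where(obs, doses, 0).sum(axis=0)
    return np.where(n_obs > 0, alt / (2.0 * np.maximum(n_obs, 1)), 0.0)


def hwe_exact_p(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Two-sided exact test of Hardy-Weinberg equilibrium.

    Conditional on the observed allele counts, sums the probabilities of
    all heterozygote counts whose probability does not exceed that of the
    observed count (the standard exact formulation used by GWAS QC
    toolkits).  Symmetric in the two homozygote counts; monomorphic
    genotype vectors return 1.
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise ValueError("at least one genotyped individual required")
    n_minor = 2 * min(n_hom1, n_hom2) + n_het
    if n_minor == 0:
        return 1.0
    # heterozygote counts share the parity of the minor-allele count
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_minor = (n_minor - hets) // 2
    hom_major = n - hets - hom_minor
    feasible = hom_major >= 0
    hets, hom_minor, hom_major = hets[feasible], hom_minor[feasible], hom_major[feasible]
    # P(het = h | allele counts) via log factorials
    logp = (gammaln(n + 1)
            - gammaln(hom_minor + 1) - gammaln(hets + 1) - gammaln(hom_major + 1)
            + hets * np.log(2.0)
            - gammaln(2 * n + 1)
            + gammaln(n_minor + 1) + gammaln(2 * n - n_minor + 1))
    p = np.exp(logp - logp.max())
    p /= p.sum()
    p_obs = p[hets == n_het][0]
    return float(min(1.0, p[p <= p_obs * (1.0 + 1e-12)].sum()))


def hwe_exact_p_vector(counts: np.ndarray) -> np.ndarray:
    """``hwe_exact_p`` over a (3, n_snps) genotype-count array."""
    out = np.ones(counts.shape[1])
    for j in range(counts.shape[1]):
        n0, n1, n2 = (int(c) for c in counts[:, j])
        out[j] = hwe_exact_p(n0, n1, n2) if (n0 + n1 + n2) > 0 else 1.0
    return out


def apply_qc(cohort: CohortGenotypes, config: QcConfig | None = None
             ) -> tuple[CohortGenotypes, QcReport]:
    """Remove SNPs failing any filter; report per-filter exclusion counts.

    Every filter is computed on the pooled pre-filter cohort, so the
    operation is idempotent.  If all SNPs are removed the (empty) cohort
    is still returned and the report records it.
    """
    if cohort.n_snps == 0:
        raise ValueError("cohort has no SNPs")
    config = config or QcConfig()
    doses = cohort.doses
    cr = call_rates(doses)
    maf = minor_allele_freqs(doses)
    hwe = hwe_exact_p_vector(genotype_counts(doses))

    reasons = np.full(cohort.n_snps, "", dtype=object)
    # fixed reporting order: call_rate, maf, hwe, then the rare stratum cut
    for name, failing in (
        ("call_rate", cr < config.call_rate_min),
        ("maf", maf < config.maf_min),
        ("hwe", hwe < config.hwe_p_min),
    ):
        reasons[(reasons == "") & failing] = name
    if config.rare_maf_max is not None:
        reasons[(reasons == "") & ~(maf < config.rare_maf_max)] = "common"

    kept_mask = reasons == ""
    table = pd.DataFrame({
        "snp_id": cohort.snp_ids,
        "status": np.where(kept_mask, "kept", "excluded"),
        "reason": reasons,
    })
    excluded_by = {name: int((reasons == name).sum())
                   for name in ("call_rate", "maf", "hwe", "common")
                   if (reasons == name).any()}
    report = QcReport(table=table, n_input=cohort.n_snps,
                      n_kept=int(kept_mask.sum()), excluded_by=excluded_by)
    return cohort.subset_snps(kept_mask), report
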
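"""Synthetic annotation and case/control cohort generator.

The real study data (array genotypes for ~2,000 cases and 3,000 shared
controls per disease) is controlled-access, so every downstream stage is
exercised on synthetic cohorts with known ground truth.  The generator
emulates the features the analysis depends on:

* biallelic SNPs with Beta-distributed allele frequencies scattered over
  autosomes;
* non-overlapping protein-coding genes with ordered coding exons (the
  nearest-gene assignment presumes disjoint primary transcripts);
* block LD: haplotypes are built left to right within blocks of
  ``ld_block_len_bp``, copying the previous allele with probability
  ``ld_r`` and otherwise redrawing from the SNP's population frequency;
* a logistic disease model with planted effects — log-odds =
  logit(prevalence_baseline) + sum over causal SNPs of
  log(OR) * (dose - 2 * frequency), the mean-centring anchoring the
  realised prevalence at the baseline for any number of causal SNPs —
  with causal SNPs placed in exons, transcripts, flanking regions or
  uniformly;
* optional two-population structure (Balding-Nichols drifted frequencies
  parameterised by Fst) with unequal case sampling, producing the
  test-statistic inflation that genomic control corrects.

Everything is a pure function of (config, seed): the annotation stream
uses ``SeedSequence([seed, 0])`` and the cohort stream
``SeedSequence([seed, 1])``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from . import genemap
from .model import MISSING, CohortGenotypes, CohortTruth, GeneModel, SnpLocus

_BASES = np.array(list("ACGT"))


class SimulationError(RuntimeError):
    """A requested configuration could not be realised."""


@dataclass(frozen=True)
class SimConfig:
    """Configuration for one synthetic study.

    Defaults describe a down-scaled autosomal genome whose composition
    matches the array-era landscape the analysis targets: ~37% of the
    sequence genic and under 1% of SNPs in coding exons, balanced
    case/control panels, mostly-common Beta(0.8, 0.8) allele frequencies
    and moderate block LD.  ``n_causal=0`` is the pure null.
    """

    seed: int = 0
    n_cases: int = 1000
    n_controls: int = 1000
    n_chromosomes: int = 4
    chrom_length_bp: int = 10_000_000
    n_genes: int = 300
    gene_length_mean_bp: float = 50_000.0
    gene_length_sd_bp: float = 60_000.0
    exons_per_gene: tuple[int, int] = (3, 12)
    exon_length_mean_bp: float = 200.0
    exon_length_sd_bp: float = 80.0
    n_snps: int = 5000
    maf_beta_a: float = 0.8
    maf_beta_b: float = 0.8
    ld_block_len_bp: int = 25_000
    ld_r: float = 0.7
    missing_rate: float = 0.01
    n_causal: int = 0
    causal_or: float = 1.5
    causal_placement: str = "exon"
    prevalence_baseline: float = 0.1
    strat_fst: float = 0.0
    strat_case_frac_pop1: float = 0.5

    def __post_init__(self) -> None:
        probs = {
            "missing_rate": self.missing_rate,
            "prevalence_baseline": self.prevalence_baseline,
            "strat_case_frac_pop1": self.strat_case_frac_pop1,
        }
        for name, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.ld_r <= 1.0:
            raise ValueError(f"ld_r must be in [0, 1], got {self.ld_r}")
        if not 0.0 <= self.strat_fst < 1.0:
            raise ValueError(f"strat_fst must be in [0, 1), got {self.strat_fst}")
        if self.n_causal > self.n_snps:
            raise ValueError("n_causal cannot exceed n_snps")
        if self.causal_or <= 0:
            raise ValueError("causal_or must be positive")
        if self.chrom_length_bp <= 0:
            raise ValueError("chrom_length_bp must be positive")
        placement = self.causal_placement
        if placement not in ("exon", "gene", "uniform") and not placement.startswith("flank:"):
            raise ValueError(
                f"causal_placement must be exon|gene|flank:<kb>|uniform, got {placement!r}")


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Underlying normal (mu, sigma) for a log-normal with given mean/sd."""
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _place_genes_on_chrom(rng: np.random.Generator, n: int, chrom_len: int,
                          mean_bp: float, sd_bp: float,
                          max_tries: int = 200) -> list[tuple[int, int]]:
    """Rejection-place n non-overlapping transcript spans on one chromosome."""
    mu, sigma = _lognormal_params(mean_bp, sd_bp)
    placed: list[tuple[int, int]] = []
    for _ in range(n):
        for _try in range(max_tries):
            length = int(np.clip(rng.lognormal(mu, sigma), 200, chrom_len // 2))
            start = int(rng.integers(1, chrom_len - length + 1))
            end = start + length - 1
            if all(end < s or start > e for s, e in placed):
                placed.append((start, end))
                break
        else:
            raise SimulationError(
                f"could not place {n} non-overlapping transcripts of mean "
                f"{mean_bp:.0f} bp on a {chrom_len} bp chromosome after "
                f"{max_tries} tries each; reduce n_genes or gene length")
    placed.sort()
    return placed


def _make_exons(rng: np.random.Generator, tx_start: int, tx_end: int,
                cfg: SimConfig) -> tuple[tuple[int, int], ...]:
    """Ordered, disjoint coding exons inside a transcript.

    The transcript is cut into k equal segments and one exon is placed
    uniformly inside each, which guarantees order and disjointness.
    """
    lo, hi = cfg.exons_per_gene
    k = int(rng.integers(lo, hi + 1))
    if k <= 0:
        return ()
    tx_len = tx_end - tx_start + 1
    seg = tx_len // k
    if seg < 4:
        k = max(1, tx_len // 4)
        seg = tx_len // k
    exons = []
    for i in range(k):
        seg_start = tx_start + i * seg
        length = int(np.clip(rng.normal(cfg.exon_length_mean_bp, cfg.exon_length_sd_bp),
                             10, seg))
        start = int(rng.integers(seg_start, seg_start + seg - length + 1))
        exons.append((start, start + length - 1))
    return tuple(exons)


def _unique_positions(rng: np.random.Generator, n: int, chrom_len: int) -> np.ndarray:
    """n distinct positions in [1, chrom_len], sorted."""
    if n > chrom_len:
        raise SimulationError(f"cannot place {n} distinct SNPs on {chrom_len} bp")
    pos: np.ndarray = np.unique(rng.integers(1, chrom_len + 1, size=int(n * 1.2) + 16))
    while pos.size < n:
        extra = rng.integers(1, chrom_len + 1, size=n)
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(rng.choice(pos, size=n, replace=False))


def simulate_annotation(config: SimConfig) -> tuple[list[GeneModel], list[SnpLocus]]:
    """Generate gene models and SNP loci for one synthetic genome."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    chroms = [str(c + 1) for c in range(config.n_chromosomes)]

    genes: list[GeneModel] = []
    per_chrom = [config.n_genes // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_genes % config.n_chromosomes):
        per_chrom[i] += 1
    gid = 0
    for chrom, n in zip(chroms, per_chrom):
        spans = _place_genes_on_chrom(rng, n, config.chrom_length_bp,
                                      config.gene_length_mean_bp, config.gene_length_sd_bp)
        for start, end in spans:
            strand = "+" if rng.random() < 0.5 else "-"
            exons = _make_exons(rng, start, end, config)
            genes.append(GeneModel(f"g{gid:05d}", chrom, strand, start, end, exons))
            gid += 1

    snps: list[SnpLocus] = []
    per_chrom_snps = [config.n_snps // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_snps % config.n_chromosomes):
        per_chrom_snps[i] += 1
    sid = 0
    for chrom, n in zip(chroms, per_chrom_snps):
        positions = _unique_positions(rng, n, config.chrom_length_bp)
        allele_idx = rng.integers(0, 4, size=n)
        other_idx = (allele_idx + rng.integers(1, 4, size=n)) % 4
        for pos, ai, oi in zip(positions, allele_idx, other_idx):
            snps.append(SnpLocus(f"s{sid:06d}", chrom, int(pos),
                                 str(_BASES[ai]), str(_BASES[oi])))
            sid += 1
    return genes, snps


def _causal_candidates(config: SimConfig, genes: Sequence[GeneModel],
                       snps: Sequence[SnpLocus]) -> np.ndarray:
    """Indices of SNPs eligible for a planted effect under the placement rule."""
    placement = config.causal_placement
    if placement == "uniform":
        return np.arange(len(snps))
    assignments = genemap.assign_all(snps, genes, k_max=genemap.DEFAULT_K)
    idx_by_id = {s.snp_id: i for i, s in enumerate(snps)}
    if placement == "exon":
        ids = assignments.loc[assignments["in_exon"], "snp_id"]
    elif placement == "gene":
        ids = assignments.loc[assignments["window_index"] == 0, "snp_id"]
    else:  # flank:<kb> — strictly outside transcripts, within the distance
        kb = float(placement.split(":", 1)[1])
        mask = (assignments["window_index"] != 0) & (assignments["distance_bp"] <= kb * 1000)
        ids = assignments.loc[mask, "snp_id"]
    return np.array([idx_by_id[i] for i in ids], dtype=int)


def _block_ids(snp_pos: np.ndarray, block_len: int) -> np.ndarray:
    return (snp_pos - 1) // block_len


def _draw_haplotypes(rng: np.random.Generator, n_hap: int, freqs: np.ndarray,
                     new_block: np.ndarray, ld_r: float) -> np.ndarray:
    """n_hap haplotypes over the SNPs (columns ordered along the genome).

    Within an LD block each allele copies its left neighbour with
    probability ``ld_r``, otherwise it is a fresh Bernoulli draw from the
    SNP's frequency; the first SNP of each block is always fresh.
    """
    n_snps = freqs.shape[0]
    hap = np.empty((n_hap, n_snps), dtype=np.int8)
    fresh = rng.random((n_hap, n_snps)) < freqs[None, :]
    if ld_r <= 0.0:
        return fresh.astype(np.int8)
    copy = rng.random((n_hap, n_snps)) < ld_r
    copy[:, new_block] = False
    hap[:, 0] = fresh[:, 0]
    for j in range(1, n_snps):
        hap[:, j] = np.where(copy[:, j], hap[:, j - 1], fresh[:, j])
    return hap


def simulate_cohort(config: SimConfig, genes: Sequence[GeneModel],
                    snps: Sequence[SnpLocus],
                    max_batches: int = 200) -> tuple[CohortGenotypes, CohortTruth]:
    """Draw a case/control cohort over a simulated annotation.

    Individuals are rejection-sampled: genotypes are generated in batches,
    disease status is drawn from the logistic model, and sampling stops
    when the case and control quotas (split across subpopulations when
    stratified) are filled.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n_snps = len(snps)
    snp_pos = np.array([s.pos for s in snps])
    chrom_codes = np.array([int(s.chrom) for s in snps])
    # block boundaries never span chromosomes
    block = _block_ids(snp_pos, config.ld_block_len_bp) + chrom_codes * 10_000_000
    new_block = np.ones(n_snps, dtype=bool)
    new_block[1:] = block[1:] != block[:-1]

    base_freq = np.clip(rng.beta(config.maf_beta_a, config.maf_beta_b, size=n_snps),
                        0.001, 0.999)

    two_pops = config.strat_fst > 0.0
    if two_pops:
        f = config.strat_fst
        a = base_freq * (1.0 - f) / f
        b = (1.0 - base_freq) * (1.0 - f) / f
        pop_freqs = [np.clip(rng.beta(a, b), 0.001, 0.999) for _ in range(2)]
    else:
        pop_freqs = [base_freq]

    if config.n_causal > 0 and config.causal_or != 1.0:
        cand = _causal_candidates(config, genes, snps)
        if cand.size < config.n_causal:
            raise SimulationError(
                f"only {cand.size} SNPs satisfy causal_placement="
                f"{config.causal_placement!r} but n_causal={config.n_causal}; "
                f"enlarge the annotation or relax the placement")
        causal_idx = np.sort(rng.choice(cand, size=config.n_causal, replace=False))
    else:
        causal_idx = np.array([], dtype=int)
    beta = math.log(config.causal_or)
    alpha0 = math.log(config.prevalence_baseline / (1.0 - config.prevalence_baseline))
    # anchor the intercept at the population-mean genotype so the realised
    # prevalence stays near prevalence_baseline for any number of causal SNPs
    causal_offset = 2.0 * base_freq[causal_idx]

    # quotas: (pop, is_case) -> remaining
    if two_pops:
        c1 = round(config.n_cases * config.strat_case_frac_pop1)
        k1 = round(config.n_controls * (1.0 - config.strat_case_frac_pop1))
        need = {(0, True): c1, (1, True): config.n_cases - c1,
                (0, False): k1, (1, False): config.n_controls - k1}
    else:
        need = {(0, True): config.n_cases, (0, False): config.n_controls}

    kept_doses: list[np.ndarray] = []
    kept_case: list[bool] = []
    kept_pop: list[int] = []
    batch = max(256, (config.n_cases + config.n_controls))
    for _ in range(max_batches):
        if all(v <= 0 for v in need.values()):
            break
        for pop, freqs in enumerate(pop_freqs):
            if not any(need[(p, s)] > 0 for (p, s) in need if p == pop):
                continue
            hap = _draw_haplotypes(rng, 2 * batch, freqs, new_block, config.ld_r)
            doses = hap[0::2] + hap[1::2]
            centered = doses[:, causal_idx].astype(float) - causal_offset
            logit = alpha0 + beta * centered.sum(axis=1)
            p_case = 1.0 / (1.0 + np.exp(-logit))
            case = rng.random(batch) < p_case
            for i in range(batch):
                key = (pop, bool(case[i]))
                if need.get(key, 0) > 0:
                    need[key] -= 1
                    kept_doses.append(doses[i])
                    kept_case.append(bool(case[i]))
                    kept_pop.append(pop)
            if all(v <= 0 for v in need.values()):
                break
    else:
        raise SimulationError(
            "case/control quotas not filled within the sampling budget; "
            "consider a higher prevalence_baseline")

    # deterministic ordering: cases first, then controls, in draw order
    order = sorted(range(len(kept_case)), key=lambda i: (not kept_case[i], i))
    doses = np.array([kept_doses[i] for i in order], dtype=np.int8)
    is_case = np.array([kept_case[i] for i in order], dtype=bool)
    population = np.array([kept_pop[i] for i in order], dtype=np.int8)

    if config.missing_rate > 0:
        miss = rng.random(doses.shape) < config.missing_rate
        doses[miss] = MISSING

    # orient doses so they count the pooled-sample minor allele with the
    # same convention the PED/MAP reader uses (ties -> lexicographic)
    snps = list(snps)
    obs = doses != MISSING
    with np.errstate(invalid="ignore"):
        freq = np.where(obs, doses, 0).sum(axis=0) / (2.0 * np.maximum(obs.sum(axis=0), 1))
    for j, s in enumerate(snps):
        a, b = s.allele_minor, s.allele_major
        flip = freq[j] > 0.5 or (freq[j] == 0.5 and a > b)
        if flip:
            col = doses[:, j]
            col[col != MISSING] = 2 - col[col != MISSING]
            snps[j] = replace(s, allele_minor=b, allele_major=a)

    sample_ids = ([f"case{i:05d}" for i in range(1, int(is_case.sum()) + 1)] +
                  [f"ctrl{i:05d}" for i in range(1, int((~is_case).sum()) + 1)])
    cohort = CohortGenotypes([s.snp_id for s in snps], sample_ids, doses, is_case)

    assignments = genemap.assign_all(snps, genes, k_max=genemap.DEFAULT_K)
    win_by_id: dict[str, int | None] = {s.snp_id: None for s in snps}
    for sid, widx in zip(assignments["snp_id"], assignments["window_index"]):
        win_by_id[sid] = int(widx)
    truth = CohortTruth(
        causal_snp_ids=[snps[i].snp_id for i in causal_idx],
        true_window_index=win_by_id,
        population=population,
    )
    return cohort, truth


def write_cohort(cohort: CohortGenotypes, snps: Sequence[SnpLocus],
                 path_prefix: str | Path) -> tuple[Path, Path]:
    """Write PLINK-dialect text PED/MAP files.

    PED columns: FID IID PAT MAT SEX PHENO then two alleles per SNP
    (phenotype 1=control, 2=case; missing genotype written "0 0").
    MAP columns: chrom, snp id, genetic-distance placeholder 0, position.
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    ped_path = prefix.with_suffix(".ped")
    map_path = prefix.with_suffix(".map")
    snp_by_id = {s.snp_id: s for s in snps}
    ordered = [snp_by_id[sid] for sid in cohort.snp_ids]

    with map_path.open("w") as fh:
        for s in ordered:
            fh.write(f"{s.chrom}\t{s.snp_id}\t0\t{s.pos}\n")

    with ped_path.open("w") as fh:
        for i, sample_id in enumerate(cohort.sample_ids):
            pheno = "2" if cohort.is_case[i] else "1"
            fields = [sample_id, sample_id, "0", "0", "0", pheno]
            row = cohort.doses[i]
            for j, s in enumerate(ordered):
                d = int(row[j])
                if d == MISSING:
                    fields.extend(("0", "0"))
                elif d == 0:
                    fields.extend((s.allele_major, s.allele_major))
                elif d == 1:
                    fields.extend((s.allele_minor, s.allele_major))
                else:
                    fields.extend((s.allele_minor, s.allele_minor))
            fh.write(" ".join(fields) + "\n")
    return ped_path, map_path


def write_truth(truth: CohortTruth, path: str | Path) -> None:
    """Ground-truth table (snp_id, is_causal, true_window_index) as TSV."""
    causal = set(truth.causal_snp_ids)
    with Path(path).open("w") as fh:
        fh.write("snp_id\tis_causal\ttrue_window_index\n")
        for sid, widx in truth.true_window_index.items():
            fh.write(f"{sid}\t{int(sid in causal)}\t{'' if widx is None else widx}\n")
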
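"""Per-SNP association testing, genomic control, and the permutation null.

The per-SNP statistic is the Cochran-Armitage trend test with dose
scores (0, 1, 2): a 1-df chi-square for a linear trend in the case
proportion across genotypes.  Uniform inflation from population
structure is corrected with genomic control, lambda_median = median
observed chi-square / median of the 1-df chi-square distribution,
floored at 1 before dividing.

The empirical null is built by shuffling case/control labels while the
genotype matrix stays fixed, so the correlation (LD) structure between
SNPs is preserved; the full pipeline — trend test plus a freshly
estimated genomic-control correction — is re-run inside each
permutation by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import CohortGenotypes, SnpLocus

#: Median of the chi-square distribution with 1 df (exact, not the
#: rounded 0.456 often quoted).
CHI2_1DF_MEDIAN: float = float(stats.chi2.ppf(0.5, df=1))


@dataclass(frozen=True)
class TrendStat:
    chi2: float
    p: float
    degenerate: bool = False


@dataclass(frozen=True)
class GcEstimate:
    """Genomic-control inflation factor lambda_median.

    ``lambda_median`` is reported as estimated (it may be < 1); the
    correction divisor is floored at 1 so deflated statistics are never
    inflated.
    """

    lambda_median: float
    n_snps_used: int

    @property
    def divisor(self) -> float:
        return max(self.lambda_median, 1.0)


@dataclass
class PermutationPvalues:
    """Pointwise per-SNP p-values for each label permutation.

    ``pvalues`` has shape (n_perm, n_snps), aligned to ``snp_ids``;
    ``lambdas`` holds the per-permutation genomic-control estimates
    (all 1.0 when the correction is disabled inside permutations).
    """

    seed: int
    n_perm: int
    snp_ids: list[str]
    pvalues: np.ndarray
    lambdas: np.ndarray


def trend_test(case_doses: Sequence[int], control_doses: Sequence[int]) -> TrendStat:
    """Cochran-Armitage trend test on genotype counts.

    ``case_doses`` / ``control_doses`` are counts of dose 0/1/2
    individuals.  Monomorphic tables (all individuals share one dose)
    have an undefined statistic and return chi2=0, p=1 with the
    degenerate flag set.
    """
    r = np.asarray(case_doses, dtype=float)
    m = np.asarray(control_doses, dtype=float)
    if r.shape != (3,) or m.shape != (3,):
        raise ValueError("expected dose-count triples (n0, n1, n2)")
    if r.sum() < 1 or m.sum() < 1:
        raise ValueError("need at least one case and one control")
    chi2, p, degen = _trend_from_counts(r[None].T, m[None].T)
    return TrendStat(float(chi2[0]), float(p[0]), bool(degen[0]))


def _trend_from_counts(case_counts: np.ndarray, control_counts: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised trend statistic; inputs shape (3, n_snps).

    chi2 = N (N*T - R*S)^2 / (R (N-R) (N*Q - S^2)) with T = sum k r_k,
    S = sum k n_k, Q = sum k^2 n_k, R = cases, N = total.
    """
    n_k = case_counts + control_counts
    big_n = n_k.sum(axis=0)
    big_r = case_counts.sum(axis=0)
    scores = np.array([0.0, 1.0, 2.0])[:, None]
    t = (scores * case_counts).sum(axis=0)
    s = (scores * n_k).sum(axis=0)
    q = (scores ** 2 * n_k).sum(axis=0)
    var_term = big_r * (big_n - big_r) * (big_n * q - s ** 2)
    degenerate = var_term <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(degenerate, 0.0,
                        big_n * (big_n * t - big_r * s) ** 2 / np.where(degenerate, 1.0, var_term))
    p = np.where(degenerate, 1.0, stats.chi2.sf(chi2, df=1))
    return chi2, p, degenerate


def trend_scan(doses: np.ndarray, is_case: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Trend test across all SNP columns of a dose matrix.

    Individuals with a missing call at a SNP are dropped from that SNP's
    table only.  Returns (chi2, p, degenerate) arrays.
    """
    case = np.stack([((doses == g) & is_case[:, None]).sum(axis=0) for g in (0, 1, 2)])
    ctrl = np.stack([((doses == g) & ~is_case[:, None]).sum(axis=0) for g in (0, 1, 2)])
    return _trend_from_counts(case.astype(float), ctrl.astype(float))


def genomic_control(chi2_raw: np.ndarray, degenerate: np.ndarray | None = None
                    ) -> GcEstimate:
    """Estimate lambda_median from raw 1-df chi-square statistics.

    Degenerate (monomorphic) SNPs carry no information and are excluded
    when a mask is given.
    """
    chi2_raw = np.asarray(chi2_raw, dtype=float)
    if degenerate is not None:
        chi2_raw = chi2_raw[~np.asarray(degenerate, dtype=bool)]
    if chi2_raw.size == 0:
        raise ValueError("no usable statistics to estimate lambda from")
    lam = float(np.median(chi2_raw) / CHI2_1DF_MEDIAN)
    return GcEstimate(lambda_median=lam, n_snps_used=int(chi2_raw.size))


def correct_chi2(chi2_raw: np.ndarray, gc: GcEstimate) -> tuple[np.ndarray, np.ndarray]:
    """Divide statistics by max(lambda, 1); p from the 1-df upper tail."""
    chi2_gc = np.asarray(chi2_raw, dtype=float) / gc.divisor
    return chi2_gc, stats.chi2.sf(chi2_gc, df=1)


def association_scan(cohort: CohortGenotypes, loci: Sequence[SnpLocus] | None = None,
                     gc_correct: bool = True) -> tuple[pd.DataFrame, GcEstimate]:
    """Observed-data association analysis.

    Returns a table (snp_id[, chrom, pos], chi2_raw, chi2_gc, p,
    degenerate) and the genomic-control estimate.
    """
    chi2_raw, _p_raw, degen = trend_scan(cohort.doses, cohort.is_case)
    gc = genomic_control(chi2_raw, degen)
    if gc_correct:
        chi2_gc, p = correct_chi2(chi2_raw, gc)
    else:
        chi2_gc, p = chi2_raw, stats.chi2.sf(chi2_raw, df=1)
    p = np.where(degen, 1.0, p)
    table = pd.DataFrame({"snp_id": cohort.snp_ids})
    if loci is not None:
        by_id = {l.snp_id: l for l in loci}
        table["chrom"] = [by_id[s].chrom for s in cohort.snp_ids]
        table["pos"] = [by_id[s].pos for s in cohort.snp_ids]
    table["chi2_raw"] = chi2_raw
    table["chi2_gc"] = chi2_gc
    table["p"] = p
    table["degenerate"] = degen
    return table, gc


def _pvalues_for_labels(doses: np.ndarray, labels: np.ndarray, gc_in_perm: bool
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Trend-test p-values for a batch of label vectors.

    ``labels`` is (n_perm, n_samples) boolean; the per-SNP genotype
    tables are formed with three matrix products against fixed genotype
    masks, so the whole batch is one BLAS call per dose class.
    Returns (p matrix, per-permutation lambdas).
    """
    masks = [(doses == g).astype(np.float64) for g in (0, 1, 2)]
    n_k = np.stack([m.sum(axis=0) for m in masks])  # (3, n_snps)
    labels_f = labels.astype(np.float64)
    r_k = np.stack([labels_f @ m for m in masks])  # (3, n_perm, n_snps)
    big_n = n_k.sum(axis=0)[None, :]
    big_r = r_k.sum(axis=0)
    scores = np.array([0.0, 1.0, 2.0], dtype=np.float64)
    t = np.tensordot(scores, r_k, axes=(0, 0))
    s = (scores[:, None] * n_k).sum(axis=0)[None, :]
    q = ((scores ** 2)[:, None] * n_k).sum(axis=0)[None, :]
    var_term = big_r * (big_n - big_r) * (big_n * q - s ** 2)
    degenerate = var_term <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(degenerate, 0.0,
                        big_n * (big_n * t - big_r * s) ** 2 / np.where(degenerate, 1.0, var_term))
    n_perm = labels.shape[0]
    lambdas = np.ones(n_perm)
    if gc_in_perm:
        for i in range(n_perm):
            usable = chi2[i][~degenerate[i]]
            if usable.size:
                lambdas[i] = np.median(usable) / CHI2_1DF_MEDIAN
        chi2 = chi2 / np.maximum(lambdas, 1.0)[:, None]
    p = stats.chi2.sf(chi2, df=1)
    p[degenerate] = 1.0
    return p, lambdas


def pvalues_for_labels(cohort: CohortGenotypes, labels: np.ndarray,
                       gc_in_perm: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Public wrapper of the batch engine for explicit label matrices.

    Used both by the Monte-Carlo permutation driver and by exhaustive
    enumeration over all distinct case/control assignments on tiny
    cohorts.
    """
    labels = np.asarray(labels, dtype=bool)
    if labels.ndim != 2 or labels.shape[1] != cohort.n_samples:
        raise ValueError("labels must be (n_perm, n_samples)")
    return _pvalues_for_labels(cohort.doses, labels, gc_in_perm)


def iter_permutation_pvalues(cohort: CohortGenotypes, n_perm: int, seed: int,
                             gc_in_perm: bool = True, chunk_size: int = 250
                             ) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Yield (p-value chunk, lambda chunk) for streamed consumption.

    Labels are case-count-preserving shuffles of the observed phenotype;
    genotypes are never altered, so LD between SNPs is carried into the
    null.  Deterministic given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    n = cohort.n_samples
    n_cases = cohort.n_cases
    done = 0
    while done < n_perm:
        k = min(chunk_size, n_perm - done)
        labels = np.zeros((k, n), dtype=bool)
        for i in range(k):
            labels[i, rng.choice(n, size=n_cases, replace=False)] = True
        yield _pvalues_for_labels(cohort.doses, labels, gc_in_perm)
        done += k


def permute_pvalues(cohort: CohortGenotypes, n_perm: int, seed: int,
                    gc_in_perm: bool = True) -> PermutationPvalues:
    """Materialised permutation p-value matrix (moderate n_perm only;
    use :func:`iter_permutation_pvalues` to stream larger runs)."""
    chunks = list(iter_permutation_pvalues(cohort, n_perm, seed, gc_in_perm))
    return PermutationPvalues(
        seed=seed, n_perm=n_perm, snp_ids=list(cohort.snp_ids),
        pvalues=np.concatenate([c[0] for c in chunks], axis=0),
        lambdas=np.concatenate([c[1] for c in chunks]),
    )


def write_association(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_association(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["degenerate"] = df["degenerate"].astype(bool)
    return df
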
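"""Core domain types shared across the pipeline.

Coordinate convention: all positions are 1-based and all intervals are
fully closed, matching MAP files and the tab-delimited annotation dialect.
Genotypes are stored as minor-allele dose (0/1/2) with ``MISSING`` (-1)
as the sentinel for a failed call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Sentinel for a missing genotype call in a dose matrix.
MISSING: int = -1


@dataclass(frozen=True)
class SnpLocus:
    """A biallelic marker.

    ``allele_minor`` / ``allele_major`` are ordered by pooled sample
    frequency when the locus comes from a genotyped cohort (ties broken
    lexicographically); for annotation-only use they are simply the two
    alleles.  ``allele_minor`` is the dose-counted allele.
    """

    snp_id: str
    chrom: str
    pos: int
    allele_minor: str = "A"
    allele_major: str = "C"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"SNP {self.snp_id}: position must be >= 1, got {self.pos}")


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene: primary-transcript span plus coding exons.

    Exons are closed intervals, nested within ``[tx_start, tx_end]``,
    pairwise disjoint and sorted by start.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not (1 <= self.tx_start <= self.tx_end):
            raise ValueError(f"gene {self.gene_id}: invalid transcript span "
                             f"[{self.tx_start}, {self.tx_end}]")
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"gene {self.gene_id}: exon start {s} > end {e}")
            if s < self.tx_start or e > self.tx_end:
                raise ValueError(f"gene {self.gene_id}: exon [{s}, {e}] outside transcript "
                                 f"[{self.tx_start}, {self.tx_end}]")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"gene {self.gene_id}: exons overlap or are unsorted at [{s}, {e}]")
            prev_end = e

    @property
    def tx_length(self) -> int:
        return self.tx_end - self.tx_start + 1

    def contains(self, pos: int) -> bool:
        return self.tx_start <= pos <= self.tx_end

    def in_exon(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)


@dataclass
class CohortGenotypes:
    """Individuals x SNPs dose matrix with case/control labels.

    ``doses`` has shape ``(n_samples, n_snps)``, dtype int8, entries in
    {0, 1, 2, MISSING}.  Row/column order matches ``sample_ids`` /
    ``snp_ids``.
    """

    snp_ids: list[str]
    sample_ids: list[str]
    doses: np.ndarray
    is_case: np.ndarray

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=np.int8)
        self.is_case = np.asarray(self.is_case, dtype=bool)
        n_samples, n_snps = self.doses.shape
        if n_samples != len(self.sample_ids):
            raise ValueError("dose matrix rows do not match sample_ids")
        if n_snps != len(self.snp_ids):
            raise ValueError("dose matrix columns do not match snp_ids")
        if self.is_case.shape != (n_samples,):
            raise ValueError("is_case length does not match sample count")
        valid = np.isin(self.doses, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.argwhere(~valid)[0]
            raise ValueError(f"invalid dose {self.doses[tuple(bad)]} at sample "
                             f"{self.sample_ids[bad[0]]}, SNP {self.snp_ids[bad[1]]}")

    @property
    def n_samples(self) -> int:
        return self.doses.shape[0]

    @property
    def n_snps(self) -> int:
        return self.doses.shape[1]

    @property
    def n_cases(self) -> int:
        return int(self.is_case.sum())

    @property
    def n_controls(self) -> int:
        return int((~self.is_case).sum())

    def subset_snps(self, keep: np.ndarray) -> "CohortGenotypes":
        """Return a cohort restricted to the SNP columns selected by ``keep``
        (boolean mask or integer index array)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CohortGenotypes(
            snp_ids=[self.snp_ids[i] for i in keep],
            sample_ids=list(self.sample_ids),
            doses=self.doses[:, keep].copy(),
            is_case=self.is_case.copy(),
        )


@dataclass
class CohortTruth:
    """Ground truth recorded by the simulator for a generated cohort."""

    causal_snp_ids: list[str]
    true_window_index: dict[str, int | None] = field(default_factory=dict)
    population: np.ndarray | None = None
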
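"""SNP-to-gene assignment and distance windowing.

Every SNP is assigned to the gene whose primary transcript contains it;
all other SNPs go to the closest gene (distance to the nearer transcript
edge, ties broken by lexicographically smaller gene id).  Distances are
binned into 10 kb windows up to ``K`` windows per side (default K=10,
i.e. +/-100 kb); SNPs further away stay unassigned.  Window sign is
oriented by the assigned gene's strand: negative = upstream (5'),
positive = downstream (3').  SNPs inside a coding exon of their gene are
flagged ``in_exon`` (a subset of the window-0 stratum).

All coordinates are 1-based closed; the 10 kb bins are half-open at the
inner edge and closed at the outer edge, so a SNP exactly 10,000 bp away
falls in the first window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import GeneModel, SnpLocus

WINDOW_BP = 10_000
DEFAULT_K = 10

#: chromosome names dropped on read: sex chromosomes, mitochondrion, and
#: anything carrying an underscore (unassembled contigs / alt haplotypes).
_EXCLUDED_CHROMS = {"x", "y", "mt", "m"}


class AnnotationError(ValueError):
    """Malformed or inconsistent gene annotation."""


@dataclass(frozen=True)
class WindowAssignment:
    snp_id: str
    gene_id: str
    window_index: int
    in_exon: bool
    distance_bp: int


@dataclass(frozen=True)
class RegionFilter:
    """Closed genomic intervals to exclude (e.g. the MHC region)."""

    regions: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        for chrom, start, end in self.regions:
            if start > end:
                raise ValueError(f"region {chrom}:{start}-{end} has start > end")

    def contains(self, chrom: str, pos: int) -> bool:
        return any(c == chrom and s <= pos <= e for c, s, e in self.regions)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return any(c == chrom and s <= end and start <= e for c, s, e in self.regions)


EMPTY_FILTER = RegionFilter(())


def _is_excluded_chrom(chrom: str) -> bool:
    name = chrom.lower().removeprefix("chr")
    return name in _EXCLUDED_CHROMS or "_" in name


def read_annotation(path: str | Path, drop_excluded_chroms: bool = True) -> list[GeneModel]:
    """Read the tab-delimited annotation dialect written by :mod:`genewin.simdata`.

    Columns: gene_id, chrom, strand, tx_start, tx_end, comma-separated
    ``start-end`` exon intervals (empty field for none).  Genes on sex
    chromosomes, the mitochondrial chromosome or unassembled/alt contigs
    are dropped.  Overlapping transcripts on the same chromosome are a
    hard error: the assignment model presumes each position belongs to at
    most one primary transcript.
    """
    genes: list[GeneModel] = []
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise AnnotationError(f"{path}:{lineno}: expected >= 5 tab-separated fields")
            gene_id, chrom, strand, tx_start, tx_end = fields[:5]
            exon_field = fields[5] if len(fields) > 5 else ""
            exons: list[tuple[int, int]] = []
            if exon_field:
                for token in exon_field.split(","):
                    s, _, e = token.partition("-")
                    exons.append((int(s), int(e)))
            try:
                gene = GeneModel(gene_id, chrom, strand, int(tx_start), int(tx_end),
                                 tuple(exons))
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
            if drop_excluded_chroms and _is_excluded_chrom(chrom):
                continue
            genes.append(gene)
    _check_no_overlap(genes)
    return genes


def _check_no_overlap(genes: Sequence[GeneModel]) -> None:
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, gs in by_chrom.items():
        gs = sorted(gs, key=lambda g: g.tx_start)
        for a, b in zip(gs, gs[1:]):
            if b.tx_start <= a.tx_end:
                raise AnnotationError(
                    f"transcripts of {a.gene_id} and {b.gene_id} overlap on {chrom}: "
                    f"[{a.tx_start},{a.tx_end}] vs [{b.tx_start},{b.tx_end}]")


def write_annotation(genes: Iterable[GeneModel], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for g in genes:
            exon_field = ",".join(f"{s}-{e}" for s, e in g.exons)
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tx_start}\t{g.tx_end}"
                     f"\t{exon_field}\n")


def bin_distance(distance_bp: int, side: str) -> int:
    """Map a positive distance to its signed 10 kb window index.

    ``side`` is ``"upstream"`` (negative indices) or ``"downstream"``.
    Window k covers distances in ``((k-1)*10kb, k*10kb]``, so 10,000 bp
    maps to index 1 and 10,001 bp to index 2.
    """
    if distance_bp <= 0:
        raise ValueError(f"distance must be >= 1 (0 is the gene window), got {distance_bp}")
    if side not in ("upstream", "downstream"):
        raise ValueError(f"side must be 'upstream' or 'downstream', got {side!r}")
    k = math.ceil(distance_bp / WINDOW_BP)
    return -k if side == "upstream" else k


def _side_for(gene: GeneModel, pos: int, strand_aware: bool) -> str:
    """Orientation of a SNP outside ``gene`` relative to transcription."""
    before = pos < gene.tx_start  # lower coordinate side
    if strand_aware and gene.strand == "-":
        return "downstream" if before else "upstream"
    return "upstream" if before else "downstream"


def assign_snp(snp: SnpLocus, genes: Sequence[GeneModel], k_max: int = DEFAULT_K,
               strand_aware: bool = True) -> WindowAssignment | None:
    """Assign one SNP to its gene and window; ``None`` if unassigned.

    ``genes`` must all lie on the SNP's chromosome and be sorted by
    ``tx_start`` with non-overlapping transcripts.
    """
    best: tuple[int, str, GeneModel] | None = None
    for gene in genes:
        if gene.contains(snp.pos):
            return WindowAssignment(snp.snp_id, gene.gene_id, 0,
                                    gene.in_exon(snp.pos), 0)
        d = gene.tx_start - snp.pos if snp.pos < gene.tx_start else snp.pos - gene.tx_end
        key = (d, gene.gene_id, gene)
        if best is None or key[:2] < best[:2]:
            best = key
    if best is None:
        return None
    distance, _, gene = best
    if distance > k_max * WINDOW_BP:
        return None
    idx = bin_distance(distance, _side_for(gene, snp.pos, strand_aware))
    return WindowAssignment(snp.snp_id, gene.gene_id, idx, False, distance)


def assign_all(snps: Sequence[SnpLocus], genes: Sequence[GeneModel],
               k_max: int = DEFAULT_K, strand_aware: bool = True) -> pd.DataFrame:
    """Vectorised assignment of many SNPs.

    Returns a DataFrame with one row per *assigned* SNP: snp_id, gene_id,
    window_index, in_exon, distance_bp.  SNPs with no gene within
    ``k_max * 10 kb`` on their chromosome are omitted (unassigned is a
    value, not an error).
    """
    _check_no_overlap(genes)
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for gs in by_chrom.values():
        gs.sort(key=lambda g: g.tx_start)

    rows: list[WindowAssignment] = []
    snps_by_chrom: dict[str, list[SnpLocus]] = {}
    for s in snps:
        snps_by_chrom.setdefault(s.chrom, []).append(s)

    for chrom, chrom_snps in snps_by_chrom.items():
        gs = by_chrom.get(chrom)
        if not gs:
            continue
        starts = np.array([g.tx_start for g in gs])
        ends = np.array([g.tx_end for g in gs])
        exon_flat: list[tuple[int, int, int]] = []  # (start, end, gene_idx)
        for gi, g in enumerate(gs):
            exon_flat.extend((s, e, gi) for s, e in g.exons)
        pos = np.array([s.pos for s in chrom_snps])
        # candidate = last gene with tx_start <= pos (transcripts disjoint)
        right_of = np.searchsorted(starts, pos, side="right") - 1
        for si, snp in enumerate(chrom_snps):
            i = right_of[si]
            if i >= 0 and pos[si] <= ends[i]:
                g = gs[i]
                rows.append(WindowAssignment(snp.snp_id, g.gene_id, 0,
                                             g.in_exon(snp.pos), 0))
                continue
            cands = []
            if i >= 0:
                cands.append((int(pos[si] - ends[i]), gs[i].gene_id, gs[i]))
            if i + 1 < len(gs):
                cands.append((int(starts[i + 1] - pos[si]), gs[i + 1].gene_id, gs[i + 1]))
            d, _, g = min(cands, key=lambda c: c[:2])
            if d > k_max * WINDOW_BP:
                continue
            idx = bin_distance(d, _side_for(g, snp.pos, strand_aware))
            rows.append(WindowAssignment(snp.snp_id, g.gene_id, idx, False, d))

    return pd.DataFrame(
        [(a.snp_id, a.gene_id, a.window_index, a.in_exon, a.distance_bp) for a in rows],
        columns=["snp_id", "gene_id", "window_index", "in_exon", "distance_bp"],
    )


def flag_exonic(assignments: pd.DataFrame, snps: Sequence[SnpLocus],
                genes: Sequence[GeneModel]) -> pd.DataFrame:
    """Recompute the ``in_exon`` flag for window-0 assignments.

    ``assign_all`` already sets the flag; this is the standalone operation
    for assignments loaded from disk.  Exon intervals are closed, so a SNP
    at an exon boundary coordinate is exonic.
    """
    pos_by_id = {s.snp_id: s.pos for s in snps}
    gene_by_id = {g.gene_id: g for g in genes}
    out = assignments.copy()
    flags = []
    for snp_id, gene_id, widx in zip(out["snp_id"], out["gene_id"], out["window_index"]):
        if widx != 0:
            flags.append(False)
            continue
        flags.append(gene_by_id[gene_id].in_exon(pos_by_id[snp_id]))
    out["in_exon"] = flags
    return out


def apply_region_filter(snps: Sequence[SnpLocus], genes: Sequence[GeneModel],
                        region_filter: RegionFilter) -> tuple[list[SnpLocus], list[GeneModel]]:
    """Drop SNPs inside and genes overlapping any excluded region.

    Intervals are closed on both edges; a gene straddling a region edge is
    removed (any overlap).  Assignment must be re-run on the result.
    """
    kept_snps = [s for s in snps if not region_filter.contains(s.chrom, s.pos)]
    kept_genes = [g for g in genes
                  if not region_filter.overlaps(g.chrom, g.tx_start, g.tx_end)]
    return kept_snps, kept_genes


def read_region_filter(path: str | Path) -> RegionFilter:
    """Read exclusion regions from a tab- or comma-delimited text file.

    Plain three-column files (chrom, start, end) are interpreted as 1-based
    closed intervals; files named ``*.bed`` use the BED convention
    (0-based half-open) and are converted exactly: start+1, end.
    """
    path = Path(path)
    is_bed = path.suffix.lower() == ".bed"
    regions: list[tuple[str, int, int]] = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.replace(",", "\t").split()
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if is_bed:
                start, end = start + 1, end
            regions.append((chrom, start, end))
    return RegionFilter(tuple(regions))


def write_assignments(assignments: pd.DataFrame, path: str | Path) -> None:
    assignments.to_csv(path, sep="\t", index=False)


def read_assignments(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["in_exon"] = df["in_exon"].astype(bool)
    return df
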
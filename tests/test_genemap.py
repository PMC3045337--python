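"""Nearest-gene assignment, distance binning, exon flags, region filters."""

import numpy as np
import pytest

from genewin import genemap, simdata
from genewin.genemap import RegionFilter, WINDOW_BP, assign_snp, bin_distance
from genewin.model import GeneModel, SnpLocus


def g(gene_id, start, end, strand="+", chrom="1", exons=()):
    return GeneModel(gene_id, chrom, strand, start, end, tuple(exons))


def s(pos, snp_id="x", chrom="1"):
    return SnpLocus(snp_id, chrom, pos)


class TestBinDistance:
    @pytest.mark.parametrize("d, side, expected", [
        (1, "downstream", 1),
        (10_000, "upstream", -1),     # closed outer edge
        (10_001, "upstream", -2),
        (99_999, "downstream", 10),
        (100_000, "downstream", 10),
    ])
    def test_boundaries(self, d, side, expected):
        assert bin_distance(d, side) == expected

    def test_zero_and_negative_rejected(self):
        with pytest.raises(ValueError):
            bin_distance(0, "upstream")
        with pytest.raises(ValueError):
            bin_distance(-5, "downstream")


class TestAssignSnp:
    def test_containment_beats_proximity(self):
        genes = [g("ga", 1000, 5000), g("gb", 5501, 9000)]
        a = assign_snp(s(5000), genes)  # inside ga, 501 bp from gb
        assert a.gene_id == "ga" and a.window_index == 0 and a.distance_bp == 0

    def test_15kb_upstream_is_window_minus_2(self):
        a = assign_snp(s(5_000), [g("ga", 20_000, 30_000, strand="+")])
        assert a.window_index == -2 and a.distance_bp == 15_000

    def test_strand_flips_orientation(self):
        a = assign_snp(s(5_000), [g("ga", 20_000, 30_000, strand="-")])
        assert a.window_index == 2  # 5' of tx_start on minus strand = downstream

    def test_no_strand_mode_uses_coordinates(self):
        a = assign_snp(s(5_000), [g("ga", 20_000, 30_000, strand="-")],
                       strand_aware=False)
        assert a.window_index == -2

    def test_equidistant_tie_prefers_smaller_gene_id(self):
        genes = [g("ga", 100, 200), g("gb", 400, 500)]
        a = assign_snp(s(300), genes)  # 100 bp from both edges
        assert a.gene_id == "ga"

    def test_beyond_k_windows_is_unassigned(self):
        assert assign_snp(s(200_000), [g("ga", 300_000, 310_000)]) is not None  # 100 kb
        assert assign_snp(s(150_000), [g("ga", 300_000, 310_000)]) is None  # 150 kb away

    def test_exon_boundary_is_exonic(self):
        gene = g("ga", 100, 1000, exons=[(200, 300)])
        assert assign_snp(s(300), [gene]).in_exon
        assert assign_snp(s(301), [gene]).in_exon is False


def brute_force_assign(snp, genes, k_max=10, strand_aware=True):
    """Independent linear scan: containment first, then nearest edge with
    lexicographic tie-break, ceil-binning by side."""
    import math

    best = None
    for gene in genes:
        if gene.chrom != snp.chrom:
            continue
        if gene.tx_start <= snp.pos <= gene.tx_end:
            return (gene.gene_id, 0, gene.in_exon(snp.pos), 0)
        d = min(abs(snp.pos - gene.tx_start), abs(snp.pos - gene.tx_end))
        if best is None or (d, gene.gene_id) < (best[0], best[1]):
            best = (d, gene.gene_id, gene)
    if best is None or best[0] > k_max * WINDOW_BP:
        return None
    d, _, gene = best
    before = snp.pos < gene.tx_start
    if strand_aware and gene.strand == "-":
        upstream = not before
    else:
        upstream = before
    idx = int(math.ceil(d / WINDOW_BP))
    return (gene.gene_id, -idx if upstream else idx, False, d)


def random_layout(rng, chrom_len=1_000_000, n_genes=8, n_snps=40):
    """A random non-overlapping layout plus engineered boundary SNPs."""
    starts = np.sort(rng.choice(np.arange(1, chrom_len, 2000), n_genes, replace=False))
    genes = []
    for i, st in enumerate(starts):
        end = int(st + rng.integers(500, 1900))
        exons = [(int(st + 10), int(st + 100))] if rng.random() < 0.7 else []
        genes.append(g(f"g{i:02d}", int(st), end, strand="+-"[rng.integers(2)],
                       exons=exons))
    positions = set(rng.integers(1, chrom_len, n_snps).tolist())
    for gene in genes[:3]:  # boundary cases: exact 10 kb multiples and edges
        positions.update([max(1, gene.tx_start - WINDOW_BP), gene.tx_start,
                          gene.tx_end, gene.tx_end + WINDOW_BP,
                          gene.tx_end + WINDOW_BP + 1])
    # equidistant midpoints between consecutive genes
    for a, b in zip(genes, genes[1:]):
        gap = b.tx_start - a.tx_end
        if gap > 2 and gap % 2 == 0:
            positions.add(a.tx_end + gap // 2)
    return genes, [s(int(p), f"s{k}") for k, p in enumerate(sorted(positions))]


def test_assignment_matches_brute_force_on_random_layouts(rng):
    for trial in range(60):
        genes, snps = random_layout(rng)
        df = genemap.assign_all(snps, genes).set_index("snp_id")
        for snp in snps:
            expected = brute_force_assign(snp, genes)
            if expected is None:
                assert snp.snp_id not in df.index
            else:
                row = df.loc[snp.snp_id]
                got = (row["gene_id"], int(row["window_index"]),
                       bool(row["in_exon"]), int(row["distance_bp"]))
                assert got == expected, (trial, snp)


def test_every_snp_assigned_at_most_once(small_annotation):
    genes, snps = small_annotation
    df = genemap.assign_all(snps, genes)
    assert df["snp_id"].is_unique


def test_window_population_decays_with_distance():
    cfg = simdata.SimConfig(seed=13, n_genes=120, n_snps=6000, n_chromosomes=2,
                            chrom_length_bp=8_000_000, n_cases=10, n_controls=10)
    genes, snps = simdata.simulate_annotation(cfg)
    df = genemap.assign_all(snps, genes)
    counts = df[df.window_index != 0].groupby(df.window_index.abs()).size()
    # monotone on average: first windows clearly fuller than last
    assert counts.loc[1] > counts.loc[5] > counts.loc[10]


class TestFlagExonic:
    def test_intron_snp_stays_window_zero(self):
        gene = g("ga", 100, 1000, exons=[(200, 300), (500, 600)])
        a = assign_snp(s(400), [gene])
        assert a.window_index == 0 and not a.in_exon

    def test_matches_point_in_interval_scan(self, small_annotation):
        genes, snps = small_annotation
        df = genemap.assign_all(snps, genes)
        reflag = genemap.flag_exonic(df.assign(in_exon=False), snps, genes)
        pos = {x.snp_id: x.pos for x in snps}
        gene_by_id = {x.gene_id: x for x in genes}
        for _, row in reflag.iterrows():
            expected = (row.window_index == 0 and
                        any(a <= pos[row.snp_id] <= b
                            for a, b in gene_by_id[row.gene_id].exons))
            assert bool(row.in_exon) == expected
        assert reflag["in_exon"].equals(df["in_exon"])


class TestRegionFilter:
    def test_empty_filter_is_identity(self, small_annotation):
        genes, snps = small_annotation
        s2, g2 = genemap.apply_region_filter(snps, genes, genemap.EMPTY_FILTER)
        assert s2 == list(snps) and g2 == list(genes)

    def test_straddling_gene_removed_and_boundary_snp_removed(self):
        genes = [g("ga", 900, 1100), g("gb", 5000, 6000)]
        snps = [s(1000, "in"), s(999, "edge"), s(4000, "out")]
        rf = RegionFilter((("1", 1000, 2000),))
        s2, g2 = genemap.apply_region_filter(snps, genes, rf)
        assert [x.snp_id for x in s2] == ["edge", "out"]
        assert [x.gene_id for x in g2] == ["gb"]

    def test_reassignment_never_uses_removed_gene(self):
        genes = [g("ga", 900, 1100), g("gb", 5000, 6000)]
        snps = [s(3000, "mid")]
        rf = RegionFilter((("1", 800, 1200),))
        s2, g2 = genemap.apply_region_filter(snps, genes, rf)
        df = genemap.assign_all(s2, g2)
        assert set(df["gene_id"]) <= {"gb"}

    def test_bed_conversion_is_exact(self, tmp_path):
        bed = tmp_path / "mask.bed"
        bed.write_text("1\t999\t2000\n")
        rf = genemap.read_region_filter(bed)
        assert rf.regions == (("1", 1000, 2000),)
        tsv = tmp_path / "mask.txt"
        tsv.write_text("1\t1000\t2000\n")
        assert genemap.read_region_filter(tsv).regions == rf.regions


class TestAnnotationIO:
    def test_round_trip(self, small_annotation, tmp_path):
        genes, _ = small_annotation
        path = tmp_path / "ann.tsv"
        genemap.write_annotation(genes, path)
        assert genemap.read_annotation(path) == list(genes)

    def test_sex_chromosome_genes_dropped(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text("ga\t1\t+\t100\t200\t\n"
                        "gx\tX\t+\t100\t200\t\n"
                        "gm\tMT\t-\t100\t200\t\n"
                        "gc\t1_alt\t+\t500\t900\t\n")
        genes = genemap.read_annotation(path)
        assert [x.gene_id for x in genes] == ["ga"]

    def test_exon_outside_transcript_names_gene(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("ga\t1\t+\t100\t200\t50-80\n")
        with pytest.raises(genemap.AnnotationError, match="ga"):
            genemap.read_annotation(path)

    def test_overlapping_transcripts_are_a_hard_error(self, tmp_path):
        path = tmp_path / "ovl.tsv"
        path.write_text("ga\t1\t+\t100\t300\t\ngb\t1\t+\t250\t500\t\n")
        with pytest.raises(genemap.AnnotationError, match="overlap"):
            genemap.read_annotation(path)
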
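"""Codon counting, RSCU, GC statistics and gene-model loading."""

import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from gbgc_codon import (
    codon_counts,
    concat_usage,
    gc3,
    gc_fraction,
    gc_fraction_intervals,
    load_gene_models,
    partitioned_gc3,
    rscu,
)
from gbgc_codon._genetic_code import (
    AA_TO_CODONS,
    CODON_TO_AA,
    DEGENERATE_AAS,
    SENSE_CODONS,
    STOP_CODONS,
    reverse_complement,
)
from gbgc_codon.isoacceptor import HUMAN_PARTITION
from gbgc_codon.sequence_features import (
    CodonUsageTable,
    MalformedCDSError,
    cds_sequence,
)
from conftest import random_codon_table


def brute_force_counts(cds: str) -> Counter:
    """Independent 3-mer striding recount (terminal stop removed)."""
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons.pop()
    return Counter(c for c in codons if c in CODON_TO_AA)


class TestCodonCounts:
    @pytest.mark.parametrize(
        "cds,expected,total,skipped",
        [
            ("ATGTGGTTTTAA", {"ATG": 1, "TGG": 1, "TTT": 1}, 3, 0),
            ("ATGNNNAAATAA", {"ATG": 1, "AAA": 1}, 2, 1),
            ("ATGAAATAA", {"ATG": 1, "AAA": 1}, 2, 0),
        ],
    )
    def test_examples(self, cds, expected, total, skipped):
        t = codon_counts(cds)
        assert t.counts == expected
        assert t.n_codons_total == total
        assert t.skipped == skipped

    def test_internal_stop_names_position(self):
        with pytest.raises(MalformedCDSError, match="codon 1"):
            codon_counts("ATGTAAAAATGA")

    def test_length_guard(self):
        with pytest.raises(MalformedCDSError, match="divisible by 3"):
            codon_counts("ATGAA")

    def test_random_cds_matches_striding_recount(self, rng):
        for _ in range(20):
            codons = rng.choice(SENSE_CODONS, size=300)
            cds = "".join(codons) + "TAA"
            t = codon_counts(cds)
            assert Counter(t.counts) == brute_force_counts(cds)
            assert t.n_codons_total == 300


class TestRSCU:
    def test_uniform_usage_gives_all_ones(self):
        counts = {c: 4 for c in SENSE_CODONS if CODON_TO_AA[c] in DEGENERATE_AAS}
        t = CodonUsageTable(counts=counts, n_codons_total=sum(counts.values()))
        vec = rscu(t)
        assert np.allclose(vec.to_numpy(), 1.0)

    def test_gln_direct_evaluation(self):
        # Gln: CAG=3, CAA=1; n_x=2, A_x=4 -> RSCU = count/(4/2)
        t = CodonUsageTable(counts={"CAG": 3, "CAA": 1}, n_codons_total=4)
        vec = rscu(t)
        assert vec["CAG"] == pytest.approx(1.5)
        assert vec["CAA"] == pytest.approx(0.5)

    def test_absent_amino_acid_is_nan_not_zero(self):
        t = CodonUsageTable(counts={"TTT": 2}, n_codons_total=2)
        vec = rscu(t)
        assert math.isnan(vec["GGG"])  # Gly never observed
        assert vec["TTT"] == pytest.approx(2.0)  # Phe: 2/(2/2)

    @given(seed=hst.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_per_amino_acid_sums_equal_degeneracy(self, seed):
        table = random_codon_table(np.random.default_rng(seed))
        vec = rscu(table)
        for aa in DEGENERATE_AAS:
            codons = list(AA_TO_CODONS[aa])
            a_x = sum(table.counts.get(c, 0) for c in codons)
            sums = vec[codons].sum()
            if a_x == 0:
                assert vec[codons].isna().all()
            else:
                assert sums == pytest.approx(len(codons), abs=1e-12)


class TestGC3:
    def test_universe_boundary(self):
        t = CodonUsageTable(counts={"ATG": 1}, n_codons_total=1)
        assert gc3(t, universe="sense") == 1.0
        assert math.isnan(gc3(t))  # Met outside the 59-codon universe

    def test_simple_fraction(self):
        t = CodonUsageTable(counts={"TTT": 1, "TTC": 1}, n_codons_total=2)
        assert gc3(t) == pytest.approx(0.5)

    def test_matches_character_count_oracle(self, rng):
        for _ in range(10):
            codons = rng.choice(SENSE_CODONS, size=500)
            cds = "".join(codons) + "TGA"
            t = codon_counts(cds)
            third = [c[2] for c in codons if CODON_TO_AA[c] in DEGENERATE_AAS]
            expected = sum(b in "GC" for b in third) / len(third)
            assert gc3(t) == pytest.approx(expected, abs=1e-12)

    def test_concat_gc3_is_count_weighted_mean(self, rng):
        tables = [random_codon_table(rng) for _ in range(5)]
        named = {f"g{i}": t for i, t in enumerate(tables)}
        combined = concat_usage(named, named)
        syn = lambda t: sum(
            t.counts.get(c, 0) for c in SENSE_CODONS if CODON_TO_AA[c] in DEGENERATE_AAS
        )
        weighted = sum(gc3(t) * syn(t) for t in tables) / sum(syn(t) for t in tables)
        assert gc3(combined) == pytest.approx(weighted, abs=1e-12)


class TestGCFraction:
    @pytest.mark.parametrize(
        "seq,expected", [("GGCC", 1.0), ("AATT", 0.0), ("ACGTN", 0.5)]
    )
    def test_examples(self, seq, expected):
        assert gc_fraction(seq) == pytest.approx(expected)

    def test_all_n_is_undefined(self):
        assert math.isnan(gc_fraction("NNNN"))

    def test_interval_recount_oracle(self, rng):
        seq = "".join(rng.choice(list("ACGTN"), size=10_000))
        genome = {"chr1": seq}
        s, e = 1234, 8765
        expected = gc_fraction(seq[s:e])
        assert gc_fraction_intervals(genome, "chr1", [(s, e)]) == pytest.approx(expected)

    def test_out_of_bounds_raises(self):
        with pytest.raises(ValueError, match="outside"):
            gc_fraction_intervals({"chr1": "ACGT"}, "chr1", [(0, 10)])


class TestPartitionedGC3:
    def test_mono_only_counts(self):
        t = CodonUsageTable(counts={"TTT": 1, "TTC": 1}, n_codons_total=2)
        mono, multi = partitioned_gc3(t, HUMAN_PARTITION)
        assert mono == pytest.approx(0.5)
        assert math.isnan(multi)

    def test_uniform_table_matches_subset_recount(self):
        counts = {c: 1 for c in SENSE_CODONS if CODON_TO_AA[c] in DEGENERATE_AAS}
        t = CodonUsageTable(counts=counts, n_codons_total=len(counts))
        mono, multi = partitioned_gc3(t, HUMAN_PARTITION)
        mono_codons = [c for c in counts if CODON_TO_AA[c] in HUMAN_PARTITION.mono]
        expected = sum(c[2] in "GC" for c in mono_codons) / len(mono_codons)
        assert mono == pytest.approx(expected)

    def test_degenerate_partition_side(self):
        counts = {c: 1 for c in SENSE_CODONS if CODON_TO_AA[c] in DEGENERATE_AAS}
        t = CodonUsageTable(counts=counts, n_codons_total=len(counts))
        mono, multi = partitioned_gc3(t, (set(), set(DEGENERATE_AAS)))
        assert math.isnan(mono)
        assert multi == pytest.approx(gc3(t))


class TestConcatUsage:
    def test_single_gene_identity(self, rng):
        t = random_codon_table(rng)
        out = concat_usage(["g"], {"g": t})
        assert out.counts == t.counts

    def test_disjoint_union(self):
        a = CodonUsageTable(counts={"TTT": 2}, n_codons_total=2)
        b = CodonUsageTable(counts={"GGG": 3}, n_codons_total=3)
        out = concat_usage(["a", "b"], {"a": a, "b": b})
        assert out.counts == {"TTT": 2, "GGG": 3}

    def test_unknown_id_listed(self):
        with pytest.raises(KeyError, match="missing"):
            concat_usage(["missing"], {})

    def test_matches_literal_concatenation(self, small_dataset, rng):
        ids = list(rng.choice(sorted(small_dataset.cds), size=50, replace=False))
        tables = {g: codon_counts(small_dataset.cds[g], source=g) for g in ids}
        combined = concat_usage(ids, tables)
        # strip each gene's terminal stop before concatenating
        literal = "".join(small_dataset.cds[g][:-3] for g in ids)
        expected = codon_counts(literal + "TAA")
        assert combined.counts == expected.counts


class TestGeneModels:
    def _write_gff(self, path, lines):
        path.write_text("##gff-version 3\n" + "\n".join(lines) + "\n")

    def test_single_exon_plus_strand(self, tmp_path):
        gff = tmp_path / "a.gff3"
        self._write_gff(
            gff,
            [
                "chr1\tx\tgene\t11\t19\t.\t+\t.\tID=g1",
                "chr1\tx\tmRNA\t11\t19\t.\t+\t.\tID=t1;Parent=g1",
                "chr1\tx\texon\t11\t19\t.\t+\t.\tID=e1;Parent=t1",
                "chr1\tx\tCDS\t11\t19\t.\t+\t0\tID=c1;Parent=t1",
            ],
        )
        genome = {"chr1": "A" * 10 + "ATGAAATAA" + "A" * 10}
        models = load_gene_models(gff, genome)
        assert len(models) == 1
        m = models[0]
        assert m.cds_intervals == [(10, 19)]
        assert m.intron_intervals == []
        assert cds_sequence(m, genome) == "ATGAAATAA"

    def test_minus_strand_same_codons(self, tmp_path):
        cds = "ATGAAATAA"
        genome = {"chr1": "C" * 10 + reverse_complement(cds) + "C" * 10}
        gff = tmp_path / "b.gff3"
        self._write_gff(
            gff,
            [
                "chr1\tx\tgene\t11\t19\t.\t-\t.\tID=g1",
                "chr1\tx\tmRNA\t11\t19\t.\t-\t.\tID=t1;Parent=g1",
                "chr1\tx\texon\t11\t19\t.\t-\t.\tID=e1;Parent=t1",
                "chr1\tx\tCDS\t11\t19\t.\t-\t0\tID=c1;Parent=t1",
            ],
        )
        (m,) = load_gene_models(gff, genome)
        assert codon_counts(cds_sequence(m, genome)).counts == codon_counts(cds).counts

    def test_non_divisible_cds_excluded(self, tmp_path, caplog):
        gff = tmp_path / "c.gff3"
        self._write_gff(
            gff,
            [
                "chr1\tx\tgene\t1\t7\t.\t+\t.\tID=g1",
                "chr1\tx\tmRNA\t1\t7\t.\t+\t.\tID=t1;Parent=g1",
                "chr1\tx\tCDS\t1\t7\t.\t+\t0\tID=c1;Parent=t1",
            ],
        )
        with caplog.at_level("WARNING"):
            models = load_gene_models(gff)
        assert models == []
        assert "divisible by 3" in caplog.text

    def test_mitochondrial_contigs_dropped(self, tmp_path):
        gff = tmp_path / "d.gff3"
        self._write_gff(
            gff,
            [
                "chrM\tx\tgene\t1\t9\t.\t+\t.\tID=g1",
                "chrM\tx\tmRNA\t1\t9\t.\t+\t.\tID=t1;Parent=g1",
                "chrM\tx\tCDS\t1\t9\t.\t+\t0\tID=c1;Parent=t1",
            ],
        )
        assert load_gene_models(gff) == []

    def test_canonical_is_longest_cds(self, tmp_path):
        gff = tmp_path / "e.gff3"
        self._write_gff(
            gff,
            [
                "chr1\tx\tgene\t1\t30\t.\t+\t.\tID=g1",
                "chr1\tx\tmRNA\t1\t30\t.\t+\t.\tID=tA;Parent=g1",
                "chr1\tx\tCDS\t1\t12\t.\t+\t0\tID=cA;Parent=tA",
                "chr1\tx\tmRNA\t1\t30\t.\t+\t.\tID=tB;Parent=g1",
                "chr1\tx\tCDS\t1\t18\t.\t+\t0\tID=cB;Parent=tB",
            ],
        )
        (m,) = load_gene_models(gff)
        assert m.cds_length == 18

    def test_bed12_matches_gff3(self, small_dataset, small_dataset_dir):
        from_gff = load_gene_models(small_dataset_dir / "genes.gff3")
        from_bed = load_gene_models(small_dataset_dir / "genes.bed")
        by_id = {m.gene_id: m for m in from_bed}
        assert len(from_gff) == len(from_bed) == len(small_dataset.models)
        for m in from_gff:
            b = by_id[m.gene_id]
            assert m.cds_intervals == b.cds_intervals
            assert m.intron_intervals == b.intron_intervals
            assert (m.strand, m.tss, m.polya) == (b.strand, b.tss, b.polya)


def test_strand_reflection_leaves_statistics_unchanged(small_dataset):
    """Reverse-complementing a chromosome and flipping strands must leave
    every codon table and GC statistic unchanged."""
    ds = small_dataset
    m = next(mm for mm in ds.models if mm.chrom == "chr1")
    L = len(ds.genome["chr1"])
    flipped_genome = {"chr1": reverse_complement(ds.genome["chr1"])}
    from gbgc_codon.sequence_features import GeneModel

    reflect = lambda iv: (L - iv[1], L - iv[0])
    flipped = GeneModel(
        gene_id=m.gene_id,
        chrom="chr1",
        strand="-" if m.strand == "+" else "+",
        tss=L - m.tss,
        polya=L - m.polya,
        cds_intervals=sorted(reflect(iv) for iv in m.cds_intervals),
        intron_intervals=sorted(reflect(iv) for iv in m.intron_intervals),
    )
    orig_cds = cds_sequence(m, ds.genome)
    assert cds_sequence(flipped, flipped_genome) == orig_cds
    assert gc_fraction_intervals(
        flipped_genome, "chr1", flipped.intron_intervals
    ) == pytest.approx(gc_fraction_intervals(ds.genome, "chr1", m.intron_intervals))
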
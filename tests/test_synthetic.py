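"""The synthetic-genome generator: landscape, suppression, sequences,
expression and gene sets."""

import numpy as np
import pandas as pd
import pytest

from gbgc_codon import SyntheticConfig, pairwise_r2, simulate
from gbgc_codon.recombination import quantile_assign
from gbgc_codon.sequence_features import codon_counts, gc3
from gbgc_codon.synthetic import (
    GRID_STEP,
    generate_recombination_landscape,
    place_genes_and_suppress,
)

TINY = dict(
    n_genes=60,
    n_chromosomes=2,
    chrom_length=4_000_000,
    n_gene_sets=20,
    set_size_range=(10, 30),
)


class TestConfig:
    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(suppression_strength=1.5)
        with pytest.raises(ValueError):
            SyntheticConfig(gbgc_slope=-1)
        with pytest.raises(ValueError):
            SyntheticConfig(regime="other")
        with pytest.raises(ValueError):
            SyntheticConfig(n_genes=0)


class TestLandscape:
    def test_mean_rate_matches_base(self):
        # 10 chromosomes of 10 Mb at base rate 1.2: total cM / total Mb
        cfg = SyntheticConfig(
            n_chromosomes=10, chrom_length=10_000_000, base_rate=1.2, seed=4
        )
        gmap, _ = generate_recombination_landscape(cfg, np.random.default_rng(4))
        mean = gmap.total_cm() / gmap.total_mb()
        assert 1.14 <= mean <= 1.26

    def test_degenerate_smoothing_limit(self):
        # smoothing scale beyond the chromosome: constant field at base rate
        cfg = SyntheticConfig(
            n_chromosomes=1,
            chrom_length=5_000_000,
            isochore_scale=50_000_000,
            base_rate=1.2,
            seed=2,
        )
        gmap, fields = generate_recombination_landscape(cfg, np.random.default_rng(2))
        r = fields["chr1"]
        assert (r.max() - r.min()) / r.mean() < 0.01
        for s in range(0, 4_000_000, 1_000_000):
            assert gmap.interval_rate("chr1", s, s + 1_000_000).rate == pytest.approx(
                1.2, rel=0.05
            )

    def test_seed_determinism(self):
        cfg = SyntheticConfig(seed=9, n_chromosomes=2, chrom_length=5_000_000)
        a, fa = generate_recombination_landscape(cfg, np.random.default_rng(9))
        b, fb = generate_recombination_landscape(cfg, np.random.default_rng(9))
        for c in fa:
            assert np.array_equal(fa[c], fb[c])

    def test_cumulative_cm_non_decreasing(self):
        cfg = SyntheticConfig(n_chromosomes=3, chrom_length=6_000_000, seed=1)
        gmap, _ = generate_recombination_landscape(cfg, np.random.default_rng(1))
        for c in gmap.chromosomes:
            _, cm = gmap.markers(c)
            assert (np.diff(cm) >= 0).all()


class TestSuppression:
    def _fields(self, cfg, seed=0):
        return generate_recombination_landscape(cfg, np.random.default_rng(seed))

    def test_null_suppression_leaves_map_unchanged(self):
        cfg = SyntheticConfig(**TINY, suppression_strength=0.0, seed=3)
        gmap, fields = self._fields(cfg)
        models, modified, truth = place_genes_and_suppress(
            cfg, fields, np.random.default_rng(3)
        )
        q = np.linspace(0, cfg.chrom_length, 200)
        for c in fields:
            assert np.allclose(
                modified.interpolate_cm(c, q), gmap.interpolate_cm(c, q), atol=1e-9
            )
        assert np.allclose(truth["suppression_factor"], 1.0)

    def test_top_ranked_factor_endpoint(self):
        cfg = SyntheticConfig(**TINY, suppression_strength=0.8, seed=3)
        _, fields = self._fields(cfg)
        _, _, truth = place_genes_and_suppress(cfg, fields, np.random.default_rng(3))
        top = truth["meiotic_expression"].idxmax()
        assert truth.loc[top, "suppression_factor"] == pytest.approx(0.2)
        s = cfg.suppression_strength
        assert truth["suppression_factor"].between(1 - s, 1).all()

    def test_reintegration_oracle(self):
        """Intragenic rate recomputed from the emitted map equals the base
        map's gene rate times the recorded factor."""
        cfg = SyntheticConfig(**TINY, seed=5)
        _, fields = self._fields(cfg, seed=5)
        models, modified, truth = place_genes_and_suppress(
            cfg, fields, np.random.default_rng(5)
        )
        for m in models:
            got = modified.interval_rate(m.chrom, m.start, m.end).rate
            expected = (
                truth.loc[m.gene_id, "true_base_rate"]
                * truth.loc[m.gene_id, "suppression_factor"]
            )
            assert got == pytest.approx(expected, rel=1e-9)

    def test_flanks_untouched(self):
        cfg = SyntheticConfig(**TINY, seed=5)
        gmap, fields = self._fields(cfg, seed=5)
        models, modified, _ = place_genes_and_suppress(
            cfg, fields, np.random.default_rng(5)
        )
        m = models[0]
        s, e = m.start - 5000, m.start - 1000  # upstream flank
        assert modified.interval_rate(m.chrom, s, e).rate == pytest.approx(
            gmap.interval_rate(m.chrom, s, e).rate, rel=1e-9
        )

    def test_genome_too_small_explicit_failure(self):
        cfg = SyntheticConfig(
            n_genes=200, n_chromosomes=1, chrom_length=1_000_000, seed=1
        )
        _, fields = self._fields(cfg)
        with pytest.raises(ValueError, match="too small"):
            place_genes_and_suppress(cfg, fields, np.random.default_rng(1))


class TestSequences:
    def test_decoupled_limit_gc_half(self):
        cfg = SyntheticConfig(**TINY, gbgc_slope=0.0, noise_sd_gc=0.0, seed=6)
        ds = simulate(cfg, sequences="cds_only")
        assert np.allclose(ds.truth["equilibrium_gc"], 0.5)
        gc3s = np.array([gc3(codon_counts(s)) for s in ds.cds.values()])
        n_codons = np.array([len(s) // 3 for s in ds.cds.values()])
        # binomial sampling noise only: ~4 sd of sqrt(.25/n)
        assert np.abs(gc3s - 0.5).max() < 4.5 * np.sqrt(0.25 / n_codons.min())

    def test_gbgc_regime_gc3_tracks_intron_gc(self):
        cfg = SyntheticConfig(
            n_genes=600,
            n_chromosomes=2,
            chrom_length=12_000_000,
            n_gene_sets=20,
            set_size_range=(10, 30),
            noise_sd_gc=0.0,
            seed=7,
        )
        ds = simulate(cfg)
        from gbgc_codon.sequence_features import gc_fraction_intervals

        rows = []
        for m in ds.models:
            rows.append(
                (
                    gc3(codon_counts(ds.cds[m.gene_id])),
                    gc_fraction_intervals(ds.genome, m.chrom, m.intron_intervals),
                )
            )
        g3, gi = np.array(rows).T
        assert pairwise_r2(g3, gi).r_squared > 0.9

    def test_trna_regime_mono_stays_gc_driven(self):
        cfg = SyntheticConfig(**TINY, regime="trna_coadapted", noise_sd_gc=0.0, seed=8)
        ds = simulate(cfg, sequences="cds_only")
        from gbgc_codon.isoacceptor import HUMAN_PARTITION
        from gbgc_codon.sequence_features import partitioned_gc3

        mono = np.array(
            [
                partitioned_gc3(codon_counts(ds.cds[g]), HUMAN_PARTITION)[0]
                for g in ds.truth.index
            ]
        )
        # mono-isoacceptor GC3 still follows the gene's equilibrium GC
        assert pairwise_r2(mono, ds.truth["equilibrium_gc"].to_numpy()).r_squared > 0.5

    def test_cds_well_formed(self, small_dataset):
        for gid, seq in list(small_dataset.cds.items())[:50]:
            t = codon_counts(seq, source=gid)  # raises on internal stop
            assert seq.startswith("ATG")
            assert len(seq) % 3 == 0
            assert t.skipped == 0

    def test_genome_matches_models(self, small_dataset):
        from gbgc_codon.sequence_features import cds_sequence

        for m in small_dataset.models[:30]:
            assert cds_sequence(m, small_dataset.genome) == small_dataset.cds[m.gene_id]


class TestExpressionAndSets:
    def test_unbiased_sets_match_population_mean(self):
        cfg = SyntheticConfig(
            n_genes=800,
            n_chromosomes=2,
            chrom_length=14_000_000,
            n_gene_sets=150,
            set_size_range=(100, 200),
            expression_bias_of_sets=0.0,
            seed=11,
        )
        ds = simulate(cfg, sequences="none")
        loge = np.log(ds.truth["meiotic_expression"])
        pop = loge.mean()
        set_means = np.array(
            [loge[list(members)].mean() for members in ds.sets.sets.values()]
        )
        # no stratification: set means scatter around the population mean
        assert abs(set_means.mean() - pop) < 0.1
        assert np.abs(set_means - pop).max() < 4 * loge.std() / np.sqrt(100)

    def test_zero_replicate_noise_exact_group_means(self):
        cfg = SyntheticConfig(**TINY, replicate_sigma=0.0, seed=12)
        ds = simulate(cfg, sequences="none")
        mat, meta = ds.expression, ds.sample_metadata
        for group, grp in meta.groupby("group"):
            cols = grp["sample"].tolist()
            if len(cols) > 1:
                assert np.allclose(mat[cols[0]], mat[cols].mean(axis=1))

    def test_set_sizes_within_range(self, small_dataset):
        lo, hi = small_dataset.config.set_size_range
        for members in small_dataset.sets.sets.values():
            assert lo <= len(members) <= hi

    def test_meiotic_groups_track_truth(self, small_dataset):
        from gbgc_codon import average_replicates, meiotic_sex_average

        grouped = average_replicates(
            small_dataset.expression, small_dataset.sample_metadata
        )
        meio = meiotic_sex_average(grouped, "female_meiotic", "male_meiotic")
        r2 = pairwise_r2(
            np.log(meio.sex_averaged),
            np.log(small_dataset.truth["meiotic_expression"]),
        ).r_squared
        assert r2 > 0.8


class TestDeterminism:
    def test_identical_config_identical_outputs(self):
        cfg = SyntheticConfig(**TINY, seed=13)
        a = simulate(cfg)
        b = simulate(cfg)
        assert a.genome == b.genome
        assert a.cds == b.cds
        pd.testing.assert_frame_equal(a.expression, b.expression)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        assert a.sets.sets == b.sets.sets
        pd.testing.assert_frame_equal(a.hotspots, b.hotspots)

    def test_sequences_mode_does_not_change_other_outputs(self):
        cfg = SyntheticConfig(**TINY, seed=14)
        full = simulate(cfg)
        none = simulate(cfg, sequences="none")
        pd.testing.assert_frame_equal(full.expression, none.expression)
        q = np.linspace(0, cfg.chrom_length, 100)
        assert np.allclose(
            full.genetic_map.interpolate_cm("chr1", q),
            none.genetic_map.interpolate_cm("chr1", q),
        )

    def test_different_seeds_differ(self):
        a = simulate(SyntheticConfig(**TINY, seed=1), sequences="none")
        b = simulate(SyntheticConfig(**TINY, seed=2), sequences="none")
        assert not np.allclose(
            a.truth["meiotic_expression"], b.truth["meiotic_expression"]
        )


def test_written_files_roundtrip(small_dataset, small_dataset_dir):
    """Files written by the generator reload into an equivalent dataset."""
    from gbgc_codon import load_dataset_dir

    loaded = load_dataset_dir(small_dataset_dir)
    assert loaded.genome == small_dataset.genome
    assert loaded.cds == small_dataset.cds
    assert len(loaded.models) == len(small_dataset.models)
    assert loaded.sets.sets == small_dataset.sets.sets
    q = np.linspace(0, small_dataset.config.chrom_length, 50)
    assert np.allclose(
        loaded.genetic_map.interpolate_cm("chr1", q),
        small_dataset.genetic_map.interpolate_cm("chr1", q),
    )
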
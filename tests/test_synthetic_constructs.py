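"""Molecular-clock / window construct generators and evaluation statistics."""

import numpy as np
import pytest

from rnaikit import (
    NucleotideSequence,
    TranscriptDatabase,
    enumerate_sirnas,
    find_hits,
    generate_clock_construct,
    generate_window_construct,
    load_benchmark_table,
    make_fixture_series,
    pearson_r,
    percent_identity,
    random_sequence,
    read_fasta,
)
from rnaikit.synthetic_constructs import CLOCK_SERIES, correlation_table


@pytest.fixture(scope="module")
def base():
    return random_sequence(500, np.random.default_rng(314), "base")


class TestClockConstruct:
    def test_zero_percent_is_identical(self, base):
        construct = generate_clock_construct(base, 0, rng_seed=1)
        assert construct.sequence.residues == base.residues
        assert construct.altered_positions == frozenset()

    def test_altered_position_count_is_exact(self, base):
        construct = generate_clock_construct(base, 2, rng_seed=1)
        assert len(construct.altered_positions) == 10  # round(2 * 500 / 100)
        # non-altered positions untouched
        for i, (a, b) in enumerate(zip(construct.sequence.residues, base.residues)):
            if i not in construct.altered_positions:
                assert a == b

    def test_reproducible_from_seed(self, base):
        a = generate_clock_construct(base, 30, rng_seed=9)
        b = generate_clock_construct(base, 30, rng_seed=9)
        assert a.sequence.residues == b.sequence.residues

    @pytest.mark.parametrize("percent", [-1, 101])
    def test_percent_out_of_range_rejected(self, base, percent):
        with pytest.raises(ValueError):
            generate_clock_construct(base, percent, rng_seed=1)

    @pytest.mark.parametrize("percent", [10, 50, 100])
    def test_identity_recovers_analytic_expectation(self, base, percent):
        """Monte-Carlo mean identity lies inside the analytic 99% CI of
        100 - 0.75 p (each altered position keeps its base w.p. 1/4)."""
        n_seeds = 500
        n_alt = round(percent * 500 / 100)
        identities = [
            percent_identity(
                generate_clock_construct(base, percent, rng_seed=s).sequence, base
            )
            for s in range(n_seeds)
        ]
        expected = 100 - 0.75 * percent
        # identity count = 500 - n_alt + Binomial(n_alt, 1/4)
        se_percent = np.sqrt(n_alt * 3 / 16 / n_seeds) / 500 * 100
        assert abs(np.mean(identities) - expected) <= 2.576 * se_percent

    def test_hit_count_decays_with_divergence(self, base):
        """Mean perfect-match hit count decreases monotonically in p
        (>= 100 seeds per level), mirroring the decay of a diverging
        trigger's siRNA complement."""
        db = TranscriptDatabase([base])
        means = []
        for percent in (0, 2, 4, 6, 8, 10):
            counts = []
            for seed in range(100):
                construct = generate_clock_construct(base, percent, rng_seed=1000 + seed)
                duplexes = enumerate_sirnas(construct.sequence, 21)
                hits = find_hits(duplexes, db, 0)
                counts.append(
                    sum(1 for h in hits if h.orientation == "sense-match")
                )
            means.append(np.mean(counts))
        assert means[0] == 480
        assert all(a > b for a, b in zip(means, means[1:]))


class TestWindowConstruct:
    def test_whole_sequence_window_returns_base(self, base):
        backbone = random_sequence(500, np.random.default_rng(1), "bb")
        out = generate_window_construct(base, 0, 500, backbone)
        assert out.residues == base.residues

    def test_zero_length_window_returns_backbone(self, base):
        backbone = random_sequence(500, np.random.default_rng(1), "bb")
        out = generate_window_construct(base, 100, 0, backbone)
        assert out.residues == backbone.residues

    def test_length_mismatch_rejected(self, base):
        backbone = random_sequence(400, np.random.default_rng(1), "bb")
        with pytest.raises(ValueError, match="length"):
            generate_window_construct(base, 0, 100, backbone)

    def test_first_window_construct_yields_80_perfect_hits(self, base):
        backbone = generate_clock_construct(base, 100, rng_seed=77).sequence
        trigger = generate_window_construct(base, 0, 100, backbone)
        hits = find_hits(enumerate_sirnas(trigger, 21), TranscriptDatabase([base]), 0)
        sense = [h for h in hits if h.orientation == "sense-match"]
        # barring a chance 21-mer in the randomized remainder: exactly 80
        assert len(sense) == 80
        assert all(h.position == h.sirna.start for h in sense)

    def test_differs_from_base_only_outside_window(self, base):
        backbone = random_sequence(500, np.random.default_rng(5), "bb")
        out = generate_window_construct(base, 200, 100, backbone)
        for i in range(500):
            if 200 <= i < 300:
                assert out.residues[i] == base.residues[i]
            else:
                assert out.residues[i] == backbone.residues[i]


class TestStatistics:
    def test_identical_sequences_are_100_percent(self, base):
        assert percent_identity(base, base) == 100.0

    def test_one_mismatch_in_100(self):
        a = NucleotideSequence("a", "A" * 100)
        b = NucleotideSequence("b", "A" * 99 + "C")
        assert percent_identity(a, b) == 99.0

    def test_random_vs_reverse_complement_is_about_25(self):
        rng = np.random.default_rng(8)
        from rnaikit import reverse_complement

        values = []
        for _ in range(200):
            s = random_sequence(300, rng)
            values.append(percent_identity(s, reverse_complement(s)))
        assert np.mean(values) == pytest.approx(25.0, abs=1.0)

    def test_pearson_perfect_correlations(self):
        x = [1.0, 2.0, 4.0, 8.0]
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_pearson_rejects_constant_vectors(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_he_column_correlation_matches_published_value(self):
        he = [26, 15, 25, 13, 9, 0, 0, 7, 7, 1, 10, 4]
        si = [-1.36, -1.37, -1.61, -2.09, -1.14, -0.52,
              -0.69, -0.61, -0.80, -0.22, -1.65, -1.60]
        assert round(pearson_r(he, si), 2) == -0.61

    def test_benchmark_table_correlations(self):
        table = load_benchmark_table()
        corr = correlation_table(table)
        assert round(corr["total_hits"], 2) == -0.31
        assert round(corr["hs_hits"], 2) == -0.37
        assert round(corr["he_hits"], 2) == -0.61


class TestFixtureSeries:
    def test_series_emits_fasta_and_manifest(self, tmp_path):
        manifest = make_fixture_series(tmp_path, seed=5, length=500)
        assert set(manifest.series) == {"clock", "window"}
        assert len(manifest[manifest.series == "clock"]) == len(CLOCK_SERIES)
        assert len(manifest[manifest.series == "window"]) == 5
        clock = read_fasta(tmp_path / "clock_series.fasta")
        windows = read_fasta(tmp_path / "window_series.fasta")
        base = read_fasta(tmp_path / "base.fasta").entries[0]
        assert clock["0MY"].residues == base.residues
        assert len(windows) == 5
        assert (tmp_path / "manifest.tsv").exists()

    def test_series_reproducible_from_seed(self, tmp_path):
        m1 = make_fixture_series(tmp_path / "a", seed=5, length=200)
        m2 = make_fixture_series(tmp_path / "b", seed=5, length=200)
        assert (
            (tmp_path / "a" / "clock_series.fasta").read_text()
            == (tmp_path / "b" / "clock_series.fasta").read_text()
        )
        assert m1.equals(m2)
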
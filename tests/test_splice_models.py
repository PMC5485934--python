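"""Window extraction and the WMM / maxent-table splice scoring models."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import TOY_LEND, TOY_RSTART, TOY_SEQ
from gapsites.splice_models import (
    ACCEPTOR_FRAGMENTS,
    ACCEPTOR_WIDTH,
    DONOR_WIDTH,
    ModelError,
    load_maxent_tables,
    load_wmm,
    revcomp,
    save_wmm,
    train_wmm,
    windows,
    wmm_from_profile,
    wmm_model,
)


class TestWindows:
    def test_toy_donor_plus(self, toy_genome):
        w = windows(toy_genome, "toy", TOY_LEND, TOY_RSTART)
        assert w.donor_plus == "CAGGTAAGT"

    def test_toy_acceptor_plus_ends_in_junction(self, toy_genome):
        w = windows(toy_genome, "toy", TOY_LEND, TOY_RSTART)
        assert len(w.acceptor_plus) == ACCEPTOR_WIDTH
        # 20 intronic bases ending in AG, then 3 exonic bases
        assert w.acceptor_plus[17:21] == "CAGG"
        assert w.acceptor_plus[18:20] == "AG"

    def test_revcomp_involution_of_mirrored_site(self, toy_genome):
        """Windows on the reverse-complemented genome with the mirrored key
        reproduce the originals with the strands swapped."""
        n = len(TOY_SEQ)
        mirrored = {"toy": revcomp(TOY_SEQ)}
        m_lend = n - TOY_RSTART + 1
        m_rstart = n - TOY_LEND + 1
        orig = windows(toy_genome, "toy", TOY_LEND, TOY_RSTART)
        mirr = windows(mirrored, "toy", m_lend, m_rstart)
        assert mirr.donor_minus == orig.donor_plus
        assert mirr.acceptor_minus == orig.acceptor_plus
        assert mirr.donor_plus == orig.donor_minus
        assert mirr.acceptor_plus == orig.acceptor_minus

    def test_chromosome_edge_unscorable(self, toy_genome):
        w = windows(toy_genome, "toy", 2, TOY_RSTART)
        assert w.donor_plus is None  # would start at position 0
        assert w.acceptor_minus is None
        w2 = windows(toy_genome, "toy", TOY_LEND, len(TOY_SEQ) - 1)
        assert w2.acceptor_plus is None  # 3 exonic bases exceed the end

    def test_planted_junctions_start_with_gt(self, universe):
        """Donor window positions 4-5 equal the intron's first two bases."""
        for plant in universe.plants:
            if plant.truth_class != "true-splice":
                continue
            key = plant.key
            if plant.strand == "+":
                w = windows(universe.genome, *key).donor_plus
            else:
                w = windows(universe.genome, *key).donor_minus
            assert w[3:5] == "GT"
            assert w == plant.donor_window


class TestWmm:
    def test_single_window_training_set_is_argmax(self):
        model = train_wmm(["GTAAGT"], pseudocount=0.1)
        target = model.score("GTAAGT")
        rng = np.random.default_rng(0)
        for _ in range(50):
            other = "".join(rng.choice(list("ACGT"), 6))
            assert model.score(other) <= target

    def test_signal_equals_background_scores_zero(self):
        bg = np.full((4, 4), 0.25)
        model = wmm_from_profile(np.full((4, 4), 0.25), bg)
        assert model.score("ACGT") == pytest.approx(0.0)
        assert model.score("TTTT") == pytest.approx(0.0)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ModelError):
            train_wmm([])

    def test_mixed_widths_rejected(self):
        with pytest.raises(ModelError):
            train_wmm(["ACGT", "ACG"])

    def test_two_complementary_windows_symmetric(self):
        model = train_wmm(["AAAA", "TTTT"], pseudocount=0.5)
        assert model.score("AAAA") == pytest.approx(model.score("TTTT"))

    def test_non_acgt_unscorable(self):
        model = train_wmm(["ACGT"])
        assert model.score("ACNT") is None

    def test_determinism(self):
        m1 = train_wmm(["GTAAGT", "GTGAGT"], pseudocount=0.3)
        m2 = train_wmm(["GTAAGT", "GTGAGT"], pseudocount=0.3)
        assert m1.score("GTAAGT") == m2.score("GTAAGT")

    @given(st.integers(0, 1000))
    @settings(derandomize=True, max_examples=30)
    def test_pseudocount_moves_scores_toward_zero(self, salt):
        """Smoothing shrinks every per-position log-odds weight toward 0
        monotonically, and hence the score of any training window."""
        rng = np.random.default_rng(salt)
        train = ["".join(rng.choice(list("ACGT"), 5)) for _ in range(4)]
        models = [train_wmm(train, pseudocount=pc) for pc in (0.1, 1.0, 10.0, 100.0)]
        for a, b in zip(models, models[1:]):
            assert np.all(np.abs(b.log_odds) <= np.abs(a.log_odds) + 1e-12)
            assert np.all(a.log_odds * b.log_odds >= -1e-12)  # no sign flips
        probe = train[0]
        scores = [m.score(probe) for m in models]
        assert all(scores[i] >= scores[i + 1] - 1e-12 for i in range(len(scores) - 1))
        assert scores[-1] >= -1e-12


def _write_constant_tables(path, value=2.0):
    donor = np.full(4**DONOR_WIDTH, value)
    np.savetxt(path / "donor_9mer.tsv", donor, fmt="%.1f")
    for i, (a, b) in enumerate(ACCEPTOR_FRAGMENTS):
        np.savetxt(path / f"acceptor_t{i}.tsv", np.full(4 ** (b - a), value), fmt="%.1f")


class TestMaxEntTables:
    def test_constant_tables_score_one(self, tmp_path):
        """With every ratio 2.0 both scores are log2(2) = 1: the donor is a
        single lookup and the acceptor multiplies five fragment ratios and
        divides by four overlap ratios."""
        _write_constant_tables(tmp_path)
        model = load_maxent_tables(str(tmp_path))
        assert model.kind == "maxent-table"
        assert model.score5("CAGGTAAGT") == pytest.approx(1.0)
        assert model.score3("T" * 20 + "CAG") == pytest.approx(1.0)

    def test_lookup_uses_kmer_rank(self, tmp_path):
        _write_constant_tables(tmp_path)
        donor = np.full(4**DONOR_WIDTH, 1.0)
        donor[0] = 8.0  # AAAAAAAAA
        np.savetxt(tmp_path / "donor_9mer.tsv", donor, fmt="%.1f")
        model = load_maxent_tables(str(tmp_path))
        assert model.score5("AAAAAAAAA") == pytest.approx(3.0)
        assert model.score5("AAAAAAAAC") == pytest.approx(0.0)

    def test_non_acgt_unscorable(self, tmp_path):
        _write_constant_tables(tmp_path)
        model = load_maxent_tables(str(tmp_path))
        assert model.score5("CAGGTNAGT") is None
        assert model.score3("N" * 23) is None

    def test_empty_dir_rejected(self, tmp_path):
        with pytest.raises(ModelError):
            load_maxent_tables(str(tmp_path))

    def test_short_table_rejected(self, tmp_path):
        _write_constant_tables(tmp_path)
        np.savetxt(tmp_path / "donor_9mer.tsv", np.full(100, 2.0), fmt="%.1f")
        with pytest.raises(ModelError, match="donor_9mer"):
            load_maxent_tables(str(tmp_path))


class TestModelIO:
    def test_wmm_file_round_trip(self, tmp_path, universe):
        model = universe.trained_model()
        path = tmp_path / "model.wmm"
        save_wmm(model, str(path))
        loaded = load_wmm(str(path))
        donor = "CAGGTAAGT"
        acceptor = "T" * 17 + "CAG" + "GCC"
        assert loaded.score5(donor) == pytest.approx(model.score5(donor), abs=1e-3)
        assert loaded.score3(acceptor) == pytest.approx(model.score3(acceptor), abs=1e-3)

    def test_wmm_width_enforced(self):
        short = wmm_from_profile(np.full((5, 4), 0.25))
        ok9 = wmm_from_profile(np.full((9, 4), 0.25))
        ok23 = wmm_from_profile(np.full((23, 4), 0.25))
        with pytest.raises(ModelError):
            wmm_model(short, ok23)
        model = wmm_model(ok9, ok23)
        with pytest.raises(ModelError):
            model.score5("ACGT")

    def test_scores_are_pure(self, universe):
        model = universe.trained_model()
        seq = "CAGGTAAGT"
        assert model.score5(seq) == model.score5(seq)
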
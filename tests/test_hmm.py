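"""Profile-HMM construction, scoring against exhaustive enumeration, and
the at-least-one-motif proteome screen."""

import numpy as np
import pytest
from scipy.stats import gumbel_r

from slacq import hmm
from slacq.sequences import MultipleAlignment, ProteinSequence

from oracles import enumerate_hmm_scores

AA = hmm.AMINO_ACIDS


def random_model(rng, K=None, allow_gaps=True):
    K = K or int(rng.integers(2, 4))
    base = "".join(AA[i] for i in rng.integers(0, 20, K))
    rows = []
    for r in range(4):
        s = list(base)
        if rng.random() < 0.6:
            s[int(rng.integers(K))] = AA[int(rng.integers(20))]
        if allow_gaps and rng.random() < 0.3:
            s[int(rng.integers(K))] = "-"
        rows.append((f"r{r}", "".join(s)))
    try:
        return hmm.build_profile(MultipleAlignment(records=rows))
    except hmm.HMMError:
        return None


def random_seq(rng, L):
    return ProteinSequence(id="t", residues="".join(AA[i] for i in rng.integers(0, 20, L)))


class TestBuildProfile:
    def test_identical_rows_give_consensus_states(self):
        seed = MultipleAlignment(records=[(f"r{i}", "WEP") for i in range(5)])
        model = hmm.build_profile(seed)
        assert model.K == 3
        assert model.consensus() == "WEP"

    def test_majority_gap_column_becomes_insert(self):
        rows = [("a", "W-EP"), ("b", "W-EP"), ("c", "WAEP"), ("d", "W-EP"), ("e", "W-EP")]
        model = hmm.build_profile(MultipleAlignment(records=rows))
        assert model.K == 3  # 60%-gap column excluded from match states

    def test_emissions_normalized_for_random_seeds(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            model = random_model(rng)
            if model is None:
                continue
            assert np.allclose(model.match_emissions.sum(axis=1), 1.0, atol=1e-9)
            model.validate()

    def test_all_gap_seed_rejected(self):
        rows = [("a", "W--"), ("b", "-E-"), ("c", "--P"), ("d", "---")]
        with pytest.raises(hmm.HMMError):
            # every column has >= 50% gaps
            hmm.build_profile(MultipleAlignment(records=rows[:3]))

    def test_needs_two_rows(self):
        with pytest.raises(hmm.HMMError):
            hmm.build_profile(MultipleAlignment(records=[("a", "WEP")]))


class TestScoringOracle:
    def test_viterbi_and_forward_match_enumeration(self):
        """Both scorers equal exhaustive path enumeration (K<=3, L<=6)."""
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 40:
            model = random_model(rng)
            if model is None:
                continue
            seq = random_seq(rng, int(rng.integers(1, 7)))
            v, _, _ = hmm.viterbi_local(model, seq)
            f = hmm.forward_local(model, seq)
            bv, bf = enumerate_hmm_scores(model, seq)
            assert abs(v - bv) <= 1e-10
            assert abs(f - bf) <= 1e-10
            checked += 1

    def test_forward_dominates_viterbi(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            model = random_model(rng)
            if model is None:
                continue
            seq = random_seq(rng, int(rng.integers(2, 30)))
            v, _, _ = hmm.viterbi_local(model, seq)
            assert hmm.forward_local(model, seq) >= v - 1e-12

    def test_single_path_degenerate_model_forward_equals_viterbi(self):
        """All transition mass on one match chain, one residue per state."""
        seed = MultipleAlignment(records=[(f"r{i}", "WEP") for i in range(50)])
        model = hmm.build_profile(seed, pseudocount_weight=1e-12)
        # squeeze out the transition pseudocounts entirely
        model.t_mm[:] = [1.0, 1.0, 1.0, 1.0]
        model.t_mi[:] = 0.0
        model.t_md[:] = 0.0
        model.match_emissions[:] = 0.0
        for k, ch in enumerate("WEP"):
            model.match_emissions[k, hmm.AA_INDEX[ch]] = 1.0
        seq = ProteinSequence(id="t", residues="WEP")
        v, _, _ = hmm.viterbi_local(model, seq)
        f = hmm.forward_local(model, seq)
        assert f == pytest.approx(v, abs=1e-12)

    def test_consensus_scores_at_least_any_same_length_sequence(self):
        rng = np.random.default_rng(3)
        seed = MultipleAlignment(records=[(f"r{i}", "WEPWC") for i in range(5)])
        model = hmm.build_profile(seed)
        cons = ProteinSequence(id="c", residues=model.consensus())
        vc, _, _ = hmm.viterbi_local(model, cons)
        for _ in range(30):
            v, _, _ = hmm.viterbi_local(model, random_seq(rng, 5))
            assert vc >= v - 1e-12

    def test_flanks_never_decrease_score(self):
        rng = np.random.default_rng(5)
        seed = MultipleAlignment(records=[(f"r{i}", "WEPWC") for i in range(5)])
        model = hmm.build_profile(seed)
        core = random_seq(rng, 12)
        v0, _, _ = hmm.viterbi_local(model, core)
        flank = "".join(AA[i] for i in rng.integers(0, 20, 50))
        v1, _, _ = hmm.viterbi_local(
            model, ProteinSequence(id="t", residues=flank + core.residues)
        )
        assert v1 >= v0 - 1e-9

    def test_hit_span_covers_planted_motif(self):
        seed = MultipleAlignment(records=[(f"r{i}", "WCWEPYW") for i in range(5)])
        model = hmm.build_profile(seed)
        seq = ProteinSequence(id="t", residues="AAAAAWCWEPYWAAAAA")
        score, start, end = hmm.viterbi_local(model, seq)
        assert (start, end) == (6, 12)


class TestCalibration:
    def test_gumbel_parameter_recovery(self):
        """Fitted (mu, lambda) within 10% on synthetic Gumbel(0,1), n=1000."""
        rng = np.random.default_rng(0)
        scores = gumbel_r.rvs(loc=0.0, scale=1.0, size=1000, random_state=rng)
        mu, lam = hmm.fit_gumbel(scores)
        assert abs(mu - 0.0) < 0.1
        assert abs(lam - 1.0) < 0.1

    def test_location_equivariance(self):
        rng = np.random.default_rng(1)
        scores = gumbel_r.rvs(loc=2.0, scale=0.7, size=500, random_state=rng)
        mu0, lam0 = hmm.fit_gumbel(scores)
        mu1, lam1 = hmm.fit_gumbel(scores + 5.0)
        assert mu1 == pytest.approx(mu0 + 5.0, abs=1e-6)
        assert lam1 == pytest.approx(lam0, abs=1e-9)

    def test_evalue_scales_with_database_size(self):
        cal = hmm.GumbelCalibration(mu=0.0, lam=1.0, n_random=100, len_random=50, seed=0)
        assert cal.evalue(3.0, 200) == pytest.approx(2 * cal.evalue(3.0, 100))

    def test_degenerate_variance_rejected(self):
        with pytest.raises(hmm.HMMError):
            hmm.fit_gumbel(np.full(200, 1.5))

    def test_calibration_deterministic_given_seed(self):
        seed = MultipleAlignment(records=[(f"r{i}", "WEPWC") for i in range(4)])
        m1 = hmm.build_profile(seed)
        m2 = hmm.build_profile(seed)
        c1 = hmm.calibrate_evalue(m1, n_random=100, len_random=60, seed=9)
        c2 = hmm.calibrate_evalue(m2, n_random=100, len_random=60, seed=9)
        assert (c1.mu, c1.lam) == (c2.mu, c2.lam)


@pytest.fixture(scope="module")
def motif_models():
    rng = np.random.default_rng(0)
    consensus = "WCWEPYWILVAF"
    rows = []
    for r in range(6):
        s = list(consensus)
        s[int(rng.integers(len(s)))] = AA[int(rng.integers(20))]
        rows.append((f"r{r}", "".join(s)))
    model = hmm.build_profile(MultipleAlignment(records=rows), motif_id="m1")
    hmm.calibrate_evalue(model, n_random=200, len_random=120, seed=4)
    return [model]


class TestScreen:
    def test_empty_proteome(self, motif_models):
        result = hmm.screen_proteome(motif_models, [], 1e-3)
        assert result.kept == []

    def test_planted_motifs_recovered_decoys_rejected(self, motif_models):
        rng = np.random.default_rng(8)
        decoys = [
            ProteinSequence(id=f"bg{i}",
                            residues="".join(AA[j] for j in rng.integers(0, 20, 120)))
            for i in range(50)
        ]
        planted = []
        for i in range(10):
            flank = "".join(AA[j] for j in rng.integers(0, 20, 50))
            planted.append(ProteinSequence(
                id=f"hit{i}", residues=flank + "WCWEPYWILVAF" + flank
            ))
        result = hmm.screen_proteome(motif_models, decoys + planted, 1e-3)
        assert set(result.kept) == {s.id for s in planted}

    def test_at_least_one_motif_rule(self):
        """A sequence matching only one of several motifs is still kept."""
        rng = np.random.default_rng(2)
        models = []
        for mi, cons in enumerate(["WCWEPYWILVAF", "HHHNQDKRHHNQ"]):
            rows = [(f"r{mi}{r}", cons) for r in range(4)]
            m = hmm.build_profile(MultipleAlignment(records=rows), motif_id=f"m{mi}")
            hmm.calibrate_evalue(m, n_random=150, len_random=100, seed=10 + mi)
            models.append(m)
        flank = "".join(AA[j] for j in rng.integers(0, 20, 40))
        seq = ProteinSequence(id="x", residues=flank + "HHHNQDKRHHNQ" + flank)
        filler = [
            ProteinSequence(id=f"bg{i}",
                            residues="".join(AA[j] for j in rng.integers(0, 20, 100)))
            for i in range(20)
        ]
        result = hmm.screen_proteome(models, filler + [seq], 1e-3)
        assert "x" in result.kept
        assert result.presence["x"]["m1"] and not result.presence["x"]["m0"]

    def test_order_invariance(self, motif_models):
        rng = np.random.default_rng(9)
        seqs = [
            ProteinSequence(id=f"s{i}",
                            residues="".join(AA[j] for j in rng.integers(0, 20, 80)))
            for i in range(10)
        ]
        kept_fwd = set(hmm.screen_proteome(motif_models, seqs, 0.5).kept)
        kept_rev = set(hmm.screen_proteome(motif_models, seqs[::-1], 0.5).kept)
        assert kept_fwd == kept_rev

    def test_uncalibrated_model_rejected(self):
        seed = MultipleAlignment(records=[(f"r{i}", "WEP") for i in range(4)])
        model = hmm.build_profile(seed)
        with pytest.raises(hmm.HMMError, match="not calibrated"):
            hmm.screen_proteome([model], [], 1e-3)

    def test_empty_model_list_rejected(self):
        with pytest.raises(hmm.HMMError):
            hmm.screen_proteome([], [], 1e-3)


class TestSerialization:
    def test_round_trip(self, tmp_path):
        seed = MultipleAlignment(records=[(f"r{i}", "WE-PWC") for i in range(4)])
        model = hmm.build_profile(seed, motif_id="tm1")
        hmm.calibrate_evalue(model, n_random=100, len_random=50, seed=2)
        path = tmp_path / "tm1.hmm"
        hmm.save_profile(model, path)
        back = hmm.load_profile(path)
        assert back.motif_id == "tm1"
        assert np.allclose(back.match_emissions, model.match_emissions)
        assert np.allclose(back.t_mm, model.t_mm)
        assert back.calibration.mu == pytest.approx(model.calibration.mu)
        seq = ProteinSequence(id="t", residues="AWEPWCA")
        v_back = hmm.viterbi_local(back, seq)
        v_orig = hmm.viterbi_local(model, seq)
        assert v_back[0] == pytest.approx(v_orig[0], abs=1e-9)
        assert v_back[1:] == v_orig[1:]
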
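import math

import numpy as np
import pytest
from scipy import stats

import confeax as cx
from confeax.alignment_refinement import InstanceAlignment
from confeax.profile_hmm import ProfileHMM, evalue, henikoff_weights
from confeax.sequence_io import LETTER_INDEX, X_INDEX, SequenceRecord

from _oracles import enumerate_paths, random_profile_hmm, random_sequence


def _aln(rows, feature_id="f"):
    return InstanceAlignment(
        feature_id=feature_id,
        rows=[(f"r{i}", 0, len(r.replace("-", "")), r)
              for i, r in enumerate(rows)],
        n_cols=len(rows[0]))


class TestBuildHMM:
    def test_gapless_identical_rows(self):
        hmm = cx.build_hmm(_aln(["WKHDEMNFRY"] * 5))
        assert hmm.length == 10
        for j, ch in enumerate("WKHDEMNFRY"):
            assert np.argmax(hmm.match_emissions[j, :X_INDEX]) == LETTER_INDEX[ch]

    def test_low_occupancy_column_becomes_insert(self):
        rows = ["WKHDE", "WKHDE", "WK-DE", "WK-DE", "WK-DE"]
        hmm = cx.build_hmm(_aln(rows), match_threshold=0.5)
        assert hmm.length == 4  # the 40%-occupied column is an insert

    def test_stochasticity_invariants(self, rng):
        rows = ["WKHDEMNF", "WKHDEMNF", "WK-DEMNF", "WKHDE-NF", "AKHDEMNY"]
        hmm = cx.build_hmm(_aln(rows))
        assert np.allclose(hmm.match_emissions.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(hmm.t_mm + hmm.t_mi + hmm.t_md, 1.0, atol=1e-9)
        assert np.allclose(hmm.t_im + hmm.t_ii, 1.0, atol=1e-9)
        assert np.allclose(hmm.t_dm + hmm.t_dd, 1.0, atol=1e-9)

    def test_zero_match_columns_errors(self):
        rows = ["W---", "-K--", "--H-", "---D", "W---"]
        with pytest.raises(ValueError, match="occupancy threshold|match states"):
            cx.build_hmm(_aln(rows))

    def test_single_row_rejected(self):
        with pytest.raises(ValueError, match="2 alignment rows"):
            cx.build_hmm(_aln(["WKHDE"]))

    def test_henikoff_weights_downweight_duplicates(self):
        w = henikoff_weights(["WKHDE", "WKHDE", "WKHDE", "MACIL"])
        assert w[3] > w[0]
        assert w.sum() == pytest.approx(4.0)


class TestScoringOracle:
    """Viterbi/forward equal exhaustive path enumeration on tractable models."""

    def test_matches_enumeration_on_random_cases(self, rng):
        for _ in range(40):
            L = int(rng.integers(2, 5))
            hmm = random_profile_hmm(L, rng)
            seq = random_sequence(rng, int(rng.integers(1, 9)))
            v_o, f_o = enumerate_paths(hmm, seq)
            v, _ = cx.viterbi(hmm, seq)
            f = cx.forward(hmm, seq)
            assert v == pytest.approx(v_o, abs=1e-9)
            assert f == pytest.approx(f_o, rel=1e-9, abs=1e-9)

    def test_forward_at_least_viterbi(self, rng):
        for _ in range(20):
            hmm = random_profile_hmm(int(rng.integers(2, 6)), rng)
            seq = random_sequence(rng, int(rng.integers(3, 30)),
                                  alphabet="ACDEFGHIKLMNPQRSTVWY")
            v, _ = cx.viterbi(hmm, seq)
            assert cx.forward(hmm, seq) >= v - 1e-9

    def test_consensus_sequence_all_match_path(self):
        """A near-deterministic model scores its consensus along an all-match
        path with the closed-form log-odds sum."""
        rows = ["WKHDEMNFRY"] * 20
        hmm = cx.build_hmm(_aln(rows))
        score, path = cx.viterbi(hmm, "WKHDEMNFRY")
        assert all(st == "M" for _, _, st in path)
        lo = hmm.match_log_odds()
        expected = sum(lo[j, LETTER_INDEX[c]] for j, c in enumerate("WKHDEMNFRY"))
        expected += sum(np.log2(hmm.t_mm))          # 9 M->M transitions
        expected += 2 * math.log2(1 / hmm.length)   # entry + exit
        assert score == pytest.approx(expected, abs=1e-9)

    def test_background_sequence_scores_nonpositive(self, rng):
        rows = ["WKHDEMNFRY"] * 10
        hmm = cx.build_hmm(_aln(rows))
        # a sequence with no residue in common with the consensus
        seq = "".join(rng.choice(list("ACGILPST"), size=60))
        score, _ = cx.viterbi(hmm, seq)
        assert score <= 0.0

    def test_invariant_under_sequence_id_relabelling(self, rng):
        hmm = random_profile_hmm(3, rng)
        seq = random_sequence(rng, 12, alphabet="ACDEFGHIKLMNPQRSTVWY")
        v1, _ = cx.viterbi(hmm, SequenceRecord(id="a", residues=seq))
        v2, _ = cx.viterbi(hmm, SequenceRecord(id="zzz", residues=seq))
        assert v1 == v2


class TestCalibration:
    def test_gumbel_parameter_recovery(self):
        """ML fit recovers known Gumbel(mu=2, lambda=0.7) within 5% at n=5000."""
        rng = np.random.default_rng(42)
        draws = stats.gumbel_r.rvs(loc=2.0, scale=1 / 0.7, size=5000,
                                   random_state=rng)
        loc, scale = stats.gumbel_r.fit(draws)
        assert loc == pytest.approx(2.0, rel=0.05)
        assert 1 / scale == pytest.approx(0.7, rel=0.05)

    def test_evalue_monotone_decreasing_and_clipped(self, rng):
        hmm = random_profile_hmm(3, rng)
        hmm.calibration = (2.0, 0.7)
        scores = np.linspace(-5, 40, 30)
        es = [evalue(hmm, s, 100) for s in scores]
        assert all(a >= b for a, b in zip(es, es[1:]))
        assert evalue(hmm, 2.0, 100) == pytest.approx(100.0)  # S = mu clips
        assert evalue(hmm, -50.0, 100) == 100.0

    def test_calibrate_requires_hundred_sequences(self, rng):
        hmm = random_profile_hmm(3, rng)
        with pytest.raises(ValueError, match="100"):
            cx.calibrate(hmm, n_random=50, len_dist=100, seed=0)

    def test_calibrate_deterministic_given_seed(self):
        rows = ["WKHDEMNFRY"] * 8
        hmm1 = cx.build_hmm(_aln(rows))
        hmm2 = cx.build_hmm(_aln(rows))
        p1 = cx.calibrate(hmm1, n_random=100, len_dist=120, seed=7)
        p2 = cx.calibrate(hmm2, n_random=100, len_dist=120, seed=7)
        assert p1 == p2


class TestSearch:
    def _family_with_planted(self, seed, n=30, carriers=24):
        cfg = cx.planted_motif_config(seed=seed, n_proteins=n,
                                      carrier_fraction=carriers / n,
                                      length_range=(150, 250))
        return cx.simulate_family(cfg)

    def test_planted_sites_found_with_few_false_hits(self):
        records, _, truth = self._family_with_planted(seed=21)
        rows = ["".join(r.residues[b:e]) for (sid, fid, b, e) in truth.sites
                for r in records if r.id == sid]
        hmm = cx.build_hmm(_aln(rows), feature_id="planted")
        cx.calibrate(hmm, len_dist=[len(r.residues) for r in records], seed=1)
        hits = cx.search(hmm, records, threshold_evalue=0.01)
        carriers = {sid for sid, _, _, _ in truth.sites}
        found = {h.seq_id for h in hits}
        assert len(found & carriers) >= len(carriers) - 2
        assert len(found - carriers) <= 1

    def test_two_planted_copies_give_two_hits(self, rng):
        word = "WKHDEMNFRY"
        filler = "".join(rng.choice(list("ACGILPQST"), size=200))
        seq = filler[:50] + word + filler[50:150] + word + filler[150:]
        records = [SequenceRecord(id="two", residues=seq)] + [
            SequenceRecord(id=f"s{i}", residues="".join(
                rng.choice(list("ACGILPQST"), size=100)) + word)
            for i in range(6)]
        hmm = cx.build_hmm(_aln([word] * 8), feature_id="w")
        cx.calibrate(hmm, len_dist=[len(r.residues) for r in records], seed=3)
        hits = [h for h in cx.search(hmm, records, threshold_evalue=0.01)
                if h.seq_id == "two"]
        assert len(hits) == 2
        hits.sort(key=lambda h: h.start)
        assert hits[0].end <= hits[1].start

    def test_infinite_bits_threshold_empty(self, rng):
        hmm = random_profile_hmm(3, rng)
        records = [SequenceRecord(id="a", residues=random_sequence(
            rng, 50, "ACDEFGHIKLMNPQRSTVWY"))]
        assert cx.search(hmm, records, threshold_bits=float("inf")) == []

    def test_exactly_one_threshold_required(self, rng):
        hmm = random_profile_hmm(3, rng)
        with pytest.raises(ValueError, match="exactly one"):
            cx.search(hmm, [], threshold_evalue=1.0, threshold_bits=5.0)


@pytest.fixture(scope="module")
def degenerate_run():
    cfg = cx.planted_motif_config(seed=3, conservation=0.7,
                                  carrier_fraction=0.6)
    records, _, truth = cx.simulate_family(cfg)
    motifs = cx.discover_motifs(records, max_motifs=1, width_range=[10],
                                seed=3, sig_threshold=None,
                                max_seed_candidates=300, n_refine=8)
    hmm, hits, trace = cx.confeax_iterate(motifs[0], records, seed=3)
    return records, truth, motifs[0], hmm, hits, trace


class TestIteration:

    def test_converges_within_cap(self, degenerate_run):
        *_, trace = degenerate_run
        assert len(trace) <= 20
        assert trace[-1].converged

    def test_jaccard_reported_every_round_in_unit_interval(self, degenerate_run):
        *_, trace = degenerate_run
        assert [r.iteration for r in trace] == list(range(1, len(trace) + 1))
        assert all(0.0 <= r.jaccard <= 1.0 for r in trace)

    def test_fixed_point_on_rerun(self, degenerate_run):
        """Re-running from the converged hits reaches Jaccard 1 in one round."""
        records, _, motif, _, hits, _ = degenerate_run
        remotif = cx.MotifModel(motif_id=motif.motif_id, pwm=motif.pwm,
                                site_prior=motif.site_prior, llr=motif.llr,
                                hits=hits)
        _, _, trace = cx.confeax_iterate(remotif, records, seed=3, flank=0)
        assert trace[0].jaccard == 1.0
        assert len(trace) == 1 and trace[0].converged

    def test_seed_motif_needs_two_hits(self, degenerate_run):
        records, _, motif, *_ = degenerate_run
        lone = cx.MotifModel(motif_id="m", pwm=motif.pwm,
                             site_prior=motif.site_prior, llr=motif.llr,
                             hits=motif.hits[:1])
        with pytest.raises(ValueError, match="2 hits"):
            cx.confeax_iterate(lone, records, seed=0)

    def test_deterministic_given_seed(self, degenerate_run):
        records, _, motif, _, hits, _ = degenerate_run
        _, hits2, _ = cx.confeax_iterate(motif, records, seed=3)
        assert [h.key() for h in hits2] == [h.key() for h in hits]


def test_hmm_json_round_trip(rng):
    hmm = random_profile_hmm(4, rng)
    hmm.calibration = (1.5, 0.8)
    back = ProfileHMM.from_json(hmm.to_json())
    assert np.array_equal(back.match_emissions, hmm.match_emissions)
    assert np.array_equal(back.t_mm, hmm.t_mm)
    assert back.calibration == hmm.calibration
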
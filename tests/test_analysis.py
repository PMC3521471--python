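"""Propensity analyses: rankings, property correlations, curves, profiles."""

import numpy as np
import pytest

from solcard.analysis import (
    SKIPPED,
    PropertyVector,
    positional_score_profile,
    property_correlation,
    property_group_summary,
    rank_dipeptides,
    read_property_table,
    score_histogram,
    uncertainty_accuracy_curve,
)
from solcard.features import amino_acid_scores, dipeptide_index
from solcard.metrics import pearson_r
from solcard.reference import (
    AAINDEX_KUMS000103,
    ALPHA_HELIX_PROPENSITY,
    REFERENCE_AA_SOLUBILITY_SCORES,
)
from solcard.scorecard import ScoreCard, solubility_score

from conftest import random_sequences


def card_with(scores_by_dipeptide, base=100.0, threshold=None):
    scores = np.full(400, base)
    for dp, s in scores_by_dipeptide.items():
        scores[dipeptide_index(dp)] = s
    return ScoreCard(scores=scores, threshold=threshold)


class TestRankDipeptides:
    def test_top_ranked(self):
        card = card_with({"LA": 1000.0, "IP": 997.0, "MC": 991.0})
        assert rank_dipeptides(card, 3) == [("LA", 1000.0), ("IP", 997.0), ("MC", 991.0)]

    def test_uniform_card_alphabetical(self):
        card = ScoreCard(scores=np.full(400, 500.0))
        top = rank_dipeptides(card, 5)
        assert [dp for dp, _ in top] == ["AA", "AC", "AD", "AE", "AF"]

    def test_full_ranking_is_permutation(self, rng):
        card = ScoreCard(scores=rng.uniform(0, 1000, 400))
        full = rank_dipeptides(card, 400)
        assert len({dp for dp, _ in full}) == 400

    def test_ascending_gives_lowest(self):
        card = card_with({"SS": 0.0}, base=500.0)
        assert rank_dipeptides(card, 1, ascending=True) == [("SS", 0.0)]

    def test_top_n_out_of_range(self):
        card = ScoreCard(scores=np.full(400, 1.0))
        with pytest.raises(ValueError):
            rank_dipeptides(card, 401)


class TestPropertyCorrelation:
    def test_self_correlation(self, rng):
        aa = rng.uniform(0, 1000, 20)
        prop = PropertyVector("SELF", "the scores themselves", tuple(aa))
        assert property_correlation(aa, prop) == pytest.approx(1.0)

    def test_na_property_skipped(self, rng):
        vals = list(rng.uniform(0, 1, 20))
        vals[3] = float("nan")
        prop = PropertyVector("NAPROP", "has a hole", tuple(vals))
        assert property_correlation(rng.uniform(0, 1000, 20), prop) == SKIPPED

    def test_affine_rescaling_invariance(self, rng):
        aa = rng.uniform(0, 1000, 20)
        vals = rng.normal(size=20)
        r1 = property_correlation(aa, PropertyVector("P1", "raw", tuple(vals)))
        r2 = property_correlation(aa, PropertyVector("P2", "scaled", tuple(3.0 * vals + 7)))
        assert r1 == pytest.approx(r2, abs=1e-9)

    def test_published_helix_correlations(self):
        """Residue solubility scores track helix propensity (R=0.58) and the
        thermophilic helix composition scale (R=0.83)."""
        r_helix = pearson_r(REFERENCE_AA_SOLUBILITY_SCORES, ALPHA_HELIX_PROPENSITY)
        r_thermo = pearson_r(REFERENCE_AA_SOLUBILITY_SCORES, AAINDEX_KUMS000103)
        assert r_helix == pytest.approx(0.58, abs=0.005)
        assert r_thermo == pytest.approx(0.83, abs=0.005)


class TestPropertyGroupSummary:
    def _props(self, rs, aa):
        # craft properties with exact target correlations via z-scores
        z = (aa - aa.mean()) / aa.std()
        rng = np.random.default_rng(1)
        noise = rng.normal(size=20)
        noise -= noise.mean()
        noise -= z * (noise @ z) / (z @ z)  # orthogonalize
        noise /= np.std(noise)
        out = []
        for k, r in enumerate(rs):
            vals = r * z + np.sqrt(1 - r**2) * noise
            out.append(PropertyVector(f"P{k}", f"hydro prop {k}", tuple(vals)))
        return out

    def test_single_property(self, rng):
        aa = rng.uniform(0, 1000, 20)
        (p,) = self._props([0.4], aa)
        s = property_group_summary(aa, [p], "hydro")
        assert s["count"] == 1
        assert s["max"] == pytest.approx(s["mean"]) == pytest.approx(s["min"])
        assert s["var"] == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_pair_averages_to_zero(self, rng):
        aa = rng.uniform(0, 1000, 20)
        props = self._props([0.6, -0.6], aa)
        s = property_group_summary(aa, props, "hydro")
        assert s["mean"] == pytest.approx(0.0, abs=1e-9)

    def test_three_known_correlations(self, rng):
        aa = rng.uniform(0, 1000, 20)
        rs = [0.7, 0.1, -0.5]
        s = property_group_summary(aa, self._props(rs, aa), "hydro")
        assert s["count"] == 3
        assert s["max"] == pytest.approx(0.7, abs=1e-9)
        assert s["mean"] == pytest.approx(np.mean(rs), abs=1e-9)
        assert s["min"] == pytest.approx(-0.5, abs=1e-9)
        assert s["var"] == pytest.approx(np.var(rs), abs=1e-9)

    def test_no_match_rejected(self, rng):
        aa = rng.uniform(0, 1000, 20)
        with pytest.raises(ValueError):
            property_group_summary(aa, self._props([0.5], aa), "charge")

    def test_keyword_match_case_insensitive(self, rng):
        aa = rng.uniform(0, 1000, 20)
        s = property_group_summary(aa, self._props([0.5], aa), "HYDRO")
        assert s["count"] == 1


class TestReadPropertyTable:
    def test_round_trip_with_na(self, tmp_path):
        vals = "\t".join(str(float(v)) for v in range(20))
        na_vals = "\t".join(["1.0"] * 19 + ["NA"])
        path = tmp_path / "props.tsv"
        path.write_text(
            "# comment line\n"
            f"KUMS000103\thelix distribution in thermophiles\t{vals}\n"
            f"BROKEN01\tproperty with missing entry\t{na_vals}\n"
        )
        props = read_property_table(path)
        assert [p.id for p in props] == ["KUMS000103", "BROKEN01"]
        assert not props[0].has_na
        assert props[1].has_na

    def test_wrong_field_count_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("P1\tdesc\t1.0\t2.0\n")
        with pytest.raises(ValueError):
            read_property_table(path)


class TestScoreHistogram:
    def test_counts_conserved_per_class(self, rng):
        scores = rng.uniform(0, 1000, 50)
        labels = np.array(["soluble"] * 20 + ["insoluble"] * 30)
        h = score_histogram(scores, labels, 50.0)
        assert h["soluble"].sum() == 20
        assert h["insoluble"].sum() == 30

    def test_half_open_bin_membership(self):
        h = score_histogram([499.92], ["soluble"], 50.0)
        bin_idx = int(np.argmax(h["soluble"]))
        assert (h["edges"][bin_idx], h["edges"][bin_idx + 1]) == (450.0, 500.0)

    def test_one_score_per_class(self):
        h = score_histogram([100.0, 900.0], ["soluble", "insoluble"], 100.0)
        assert h["soluble"].sum() == 1 and (h["soluble"] > 0).sum() == 1
        assert h["insoluble"].sum() == 1 and (h["insoluble"] > 0).sum() == 1

    def test_bad_bin_width(self):
        with pytest.raises(ValueError):
            score_histogram([1.0], ["soluble"], 0.0)


class TestUncertaintyAccuracyCurve:
    def test_zero_size_is_plain_accuracy(self):
        scores = np.array([100.0, 400.0, 600.0, 900.0])
        y = np.array([0, 1, 0, 1])
        (size, cov, acc), = uncertainty_accuracy_curve(scores, y, 500.0, [0.0])
        assert size == 0.0 and cov == 1.0
        assert acc == pytest.approx(0.5)

    def test_full_abstention_gives_nan(self):
        out = uncertainty_accuracy_curve([490.0, 510.0], [0, 1], 500.0, [2000.0])
        size, cov, acc = out[0]
        assert cov == 0.0 and np.isnan(acc)

    def test_band_removes_near_threshold_errors(self):
        # errors concentrated near the threshold: accuracy rises with the band
        scores = np.array([100.0, 480.0, 520.0, 900.0])
        y = np.array([0, 1, 0, 1])  # the two middle calls are wrong
        curve = uncertainty_accuracy_curve(scores, y, 500.0, [0.0, 100.0])
        assert curve[0][2] == pytest.approx(0.5)
        assert curve[1][2] == pytest.approx(1.0)
        assert curve[1][1] == pytest.approx(0.5)

    def test_negative_size_rejected(self):
        with pytest.raises(ValueError):
            uncertainty_accuracy_curve([1.0, 2.0], [0, 1], 1.5, [-1.0])


class TestPositionalScoreProfile:
    def test_three_residue_example(self):
        card = card_with({"AC": 300.0, "CA": 600.0})
        prof = positional_score_profile("ACA", card)
        assert prof == [(1, "AC", 300.0), (2, "CA", 600.0)]

    def test_entry_count(self, rng):
        card = ScoreCard(scores=rng.uniform(0, 1000, 400))
        seq = random_sequences(rng, 1, 30, 30)[0]
        assert len(positional_score_profile(seq, card)) == 29

    def test_profile_mean_equals_weighted_score(self, rng):
        card = ScoreCard(scores=rng.uniform(0, 1000, 400))
        for seq in random_sequences(rng, 10):
            prof = positional_score_profile(seq, card)
            mean = np.mean([s for _, _, s in prof])
            assert mean == pytest.approx(solubility_score(seq, card), abs=1e-9)
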
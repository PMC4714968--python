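"""Risk-score construction, outlier detection, groupings, continuum."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ibdpheno import (GenotypeMatrix, Variant, associate_score,
                      build_score_weights, compare_groupings,
                      continuum_summary, enrichment_test,
                      estimate_effect_panel, exclude_loci, flag_outliers,
                      score_samples)
from ibdpheno.scores import EffectPanel, ScoreSet

from conftest import make_phenotypes


def _panel(rows):
    return EffectPanel(table=pd.DataFrame(
        rows, columns=["id", "w_CD", "w_UC", "is_hla", "locus_group"]))


def _gm(dos, groups=None):
    n, m = dos.shape
    groups = groups or ["OTHER"] * m
    from ibdpheno.cohort import LocusGroup
    return GenotypeMatrix(
        samples=[f"s{i}" for i in range(n)],
        variants=[Variant(id=f"v{j}", locus_group=LocusGroup(groups[j]))
                  for j in range(m)],
        dosages=np.asarray(dos, float))


class TestWeights:
    def test_contrast_arithmetic(self):
        p = _panel([("a", 0.3, 0.1, False, "OTHER"),
                    ("b", 0.7, -0.1, False, "NOD2")])
        w = build_score_weights(p, "CD_vs_UC")
        assert w["a"] == pytest.approx(0.2)
        assert w["b"] == pytest.approx(0.8)   # strongly CD-directed
        assert build_score_weights(p, "UC")["a"] == pytest.approx(0.1)
        assert build_score_weights(p, "CD")["b"] == pytest.approx(0.7)

    def test_exclude_loci(self):
        rows = [(f"x{i}", 0.1, 0.0, False, "OTHER") for i in range(160)]
        rows += [("n", 1.0, 0.0, False, "NOD2"),
                 ("m", 0.0, 0.5, True, "MHC"),
                 ("t", 0.1, 0.1, False, "MST1")]
        p = _panel(rows)
        kept = exclude_loci(p, {"NOD2", "MHC", "MST1"})
        assert len(kept.table) == 160
        pd.testing.assert_frame_equal(exclude_loci(p, set()).table, p.table)
        with pytest.raises(ValueError, match="unknown"):
            exclude_loci(p, {"HLA"})

    def test_excluding_changes_only_carriers(self):
        dos = np.array([[0.0, 2.0], [1.0, 0.0], [2.0, 0.0]])
        gm = _gm(dos, ["OTHER", "NOD2"])
        p = _panel([("v0", 0.2, 0.0, False, "OTHER"),
                    ("v1", 0.9, 0.0, False, "NOD2")])
        full = score_samples(gm, build_score_weights(p, "CD_vs_UC")).raw
        part = score_samples(gm, build_score_weights(
            exclude_loci(p, {"NOD2"}), "CD_vs_UC")).raw
        delta = full - part
        assert delta[0] != 0 and delta[1] == 0 and delta[2] == 0

    def test_external_weight_tsv_round_trip(self, tmp_path):
        p = _panel([("a", 0.3, 0.1, False, "OTHER")])
        f = tmp_path / "w.tsv"
        p.to_tsv(f)
        back = EffectPanel.from_tsv(f)
        pd.testing.assert_frame_equal(back.table, p.table)


class TestScoreSamples:
    def test_weighted_sum(self):
        gm = _gm(np.array([[2.0, 1.0]]))
        w = pd.Series({"v0": 0.5, "v1": -0.2})
        assert score_samples(gm, w).raw[0] == pytest.approx(0.8)

    def test_zero_weights_zero_scores(self):
        gm = _gm(np.array([[2.0, 1.0], [0.0, 1.0]]))
        w = pd.Series({"v0": 0.0, "v1": 0.0})
        assert np.all(score_samples(gm, w).raw == 0)

    def test_zero_weight_locus_is_inert(self):
        gm = _gm(np.array([[2.0, 1.0], [0.0, 2.0]]))
        w1 = pd.Series({"v0": 0.4})
        w2 = pd.Series({"v0": 0.4, "v1": 0.0})
        np.testing.assert_allclose(score_samples(gm, w1).raw,
                                   score_samples(gm, w2).raw)

    def test_affine_equivariance(self):
        """Scaling all weights scales raw scores; standardized scores and
        sample ranks are unchanged."""
        rng = np.random.default_rng(0)
        gm = _gm(rng.binomial(2, 0.3, (50, 8)).astype(float))
        w = pd.Series(rng.normal(size=8), index=[f"v{j}" for j in range(8)])
        s1 = score_samples(gm, w)
        s2 = score_samples(gm, 3.7 * w)
        np.testing.assert_allclose(s2.raw, 3.7 * s1.raw, rtol=1e-12)
        np.testing.assert_allclose(s2.standardized, s1.standardized,
                                   atol=1e-10)

    def test_majority_of_loci_required(self):
        gm = _gm(np.zeros((2, 1)))
        w = pd.Series({"v0": 0.1, "zz1": 0.1, "zz2": 0.1})
        with pytest.raises(ValueError, match="loci"):
            score_samples(gm, w)


class TestEstimatePanel:
    def test_known_weights_recovered(self):
        rng = np.random.default_rng(1)
        n, m = 6000, 6
        true_w = np.array([0.4, -0.3, 0.2, 0.0, 0.5, -0.2])
        dos = rng.binomial(2, 0.3, (n, m)).astype(float)
        eta = dos @ true_w - 0.3
        lab = np.where(rng.random(n) < 1 / (1 + np.exp(-eta)), "CD", "UC")
        panel = estimate_effect_panel(_gm(dos), lab)
        w = build_score_weights(panel, "CD_vs_UC")
        # per-locus univariate fits are attenuated relative to the joint
        # truth but must agree in sign and rough magnitude
        assert np.all(np.sign(w[np.abs(true_w) > 0.1])
                      == np.sign(true_w[np.abs(true_w) > 0.1]))
        joint = estimate_effect_panel(_gm(dos), lab, mode="joint")
        wj = build_score_weights(joint, "CD_vs_UC")
        np.testing.assert_allclose(wj.to_numpy(), true_w, atol=0.12)

    def test_label_swap_exchanges_weights(self):
        rng = np.random.default_rng(2)
        n, m = 3000, 4
        dos = rng.binomial(2, 0.3, (n, m)).astype(float)
        lab = rng.choice(["CD", "UC", "control"], n, p=[0.3, 0.3, 0.4])
        p1 = estimate_effect_panel(_gm(dos), lab)
        swapped = np.where(lab == "CD", "UC",
                           np.where(lab == "UC", "CD", "control"))
        p2 = estimate_effect_panel(_gm(dos), swapped)
        np.testing.assert_allclose(p1.table["w_CD"], p2.table["w_UC"],
                                   atol=1e-8)
        np.testing.assert_allclose(p1.table["w_UC"], p2.table["w_CD"],
                                   atol=1e-8)

    def test_monomorphic_locus_weight_zero(self):
        rng = np.random.default_rng(3)
        dos = np.column_stack([rng.binomial(2, 0.3, 200),
                               np.ones(200)]).astype(float)
        lab = rng.choice(["CD", "UC"], 200)
        panel = estimate_effect_panel(_gm(dos), lab)
        assert panel.table.loc[1, "w_CD"] == 0.0


class TestAssociateScore:
    def test_bonferroni_threshold(self):
        rng = np.random.default_rng(4)
        s = ScoreSet(samples=[str(i) for i in range(100)],
                     raw=rng.normal(size=100), contrast="CD_vs_UC")
        out = associate_score(s, rng.normal(size=100))
        assert out["threshold"] == pytest.approx(0.05 / 15)
        assert round(out["threshold"], 3) == 0.003

    def test_null_effect_near_zero(self):
        rng = np.random.default_rng(5)
        n = 2000
        s = ScoreSet(samples=[str(i) for i in range(n)],
                     raw=rng.normal(size=n), contrast="CD_vs_UC")
        out = associate_score(s, rng.normal(size=n))
        assert abs(out["beta"]) < 3 * out["se"]

    def test_constructed_signal_sign(self):
        rng = np.random.default_rng(6)
        n = 2000
        raw = rng.normal(size=n)
        y = 0.3 * raw + rng.normal(size=n)
        s = ScoreSet(samples=[str(i) for i in range(n)], raw=raw,
                     contrast="CD_vs_UC")
        out = associate_score(s, y)
        assert out["beta"] > 0 and out["significant"]


class TestOutliers:
    def _scores_p(self, raws, diags):
        P = make_phenotypes([{"diagnosis": d} for d in diags])
        s = ScoreSet(samples=P.sample_ids, raw=np.asarray(raws, float),
                     contrast="CD_vs_UC")
        return s, P

    def test_one_sided_rules(self):
        s, P = self._scores_p([-2.5, 2.5, 0.0, 2.5, -2.5, 0.0],
                              ["CD", "CD", "CD", "UC", "UC", "UC"])
        out = flag_outliers(s, P)
        flagged = set(out.loc[out["arm"] == "outlier", "sample_id"])
        assert flagged == {"s0", "s3"}   # CD low tail + UC high tail only

    def test_matched_comparators_by_site(self):
        rng = np.random.default_rng(7)
        n = 200
        diags = ["CD"] * 100 + ["UC"] * 100
        raws = rng.normal(0, 0.5, n)
        raws[0] = -3.0
        P = make_phenotypes([
            {"diagnosis": d, "site": f"site{i % 4}"}
            for i, d in enumerate(diags)])
        s = ScoreSet(samples=P.sample_ids, raw=raws, contrast="CD_vs_UC")
        out = flag_outliers(s, P, seed=0)
        o = out[out["arm"] == "outlier"].iloc[0]
        c = out[out["arm"] == "non_outlier"].iloc[0]
        assert o["site"] == c["site"]


class TestEnrichment:
    def test_fisher_on_printed_rates(self):
        """26/97 vs 8/95 revision counts (27% vs 8%) are clearly enriched."""
        table = np.array([[26, 71], [8, 87]])
        p = stats.fisher_exact(table)[1]
        assert p < 0.01
        # same decision through the package path
        diags = ["CD"] * 192
        P = make_phenotypes([{"diagnosis": d, "location": "L2"} for d in diags])
        P.df["diagnosis_revised"] = [True] * 26 + [False] * 71 + \
            [True] * 8 + [False] * 87
        out = pd.DataFrame({
            "sample_id": P.sample_ids,
            "arm": ["outlier"] * 97 + ["non_outlier"] * 95})
        res = enrichment_test(out, P)
        assert res["p"] < 0.01
        assert res["rate_outlier"] == pytest.approx(26 / 97)
        assert res["rate_non_outlier"] == pytest.approx(8 / 95)

    def test_null_calibration_under_permutation(self):
        rng = np.random.default_rng(8)
        n = 160
        P = make_phenotypes([{"diagnosis": "CD", "location": "L2"}
                             for _ in range(n)])
        revised = rng.random(n) < 0.15
        ps = []
        for _ in range(300):
            P.df["diagnosis_revised"] = rng.permutation(revised)
            out = pd.DataFrame({"sample_id": P.sample_ids,
                                "arm": ["outlier"] * 80 + ["non_outlier"] * 80})
            ps.append(enrichment_test(out, P)["p"])
        # permutation null: p-values roughly uniform, not anti-conservative
        assert (np.array(ps) < 0.05).mean() < 0.10

    def test_degenerate_flags(self):
        P = make_phenotypes([{"diagnosis": "CD"} for _ in range(10)])
        P.df["diagnosis_revised"] = False
        out = pd.DataFrame({"sample_id": P.sample_ids,
                            "arm": ["outlier"] * 5 + ["non_outlier"] * 5})
        assert enrichment_test(out, P)["p"] == 1.0


class TestGroupings:
    @staticmethod
    def _labels(rng, n):
        return rng.choice(["ilealCD", "colonicCD", "UC"], n, p=[0.3, 0.3, 0.4])

    def test_distinct_effects_favour_three_groups(self):
        rng = np.random.default_rng(9)
        n, m = 2000, 30
        lab = self._labels(rng, n)
        freqs = {"ilealCD": 0.45, "colonicCD": 0.25, "UC": 0.25}
        p = np.array([freqs[l] for l in lab])
        dos = rng.binomial(2, p[:, None], (n, m)).astype(float)
        res = compare_groupings(_gm(dos), lab)
        assert res["favours"] == "3_groups" and res["delta_bic"] > 0

    def test_identical_cd_effects_favour_two_groups(self):
        rng = np.random.default_rng(10)
        n, m = 2000, 30
        lab = self._labels(rng, n)
        freqs = {"ilealCD": 0.40, "colonicCD": 0.40, "UC": 0.25}
        p = np.array([freqs[l] for l in lab])
        dos = rng.binomial(2, p[:, None], (n, m)).astype(float)
        res = compare_groupings(_gm(dos), lab)
        assert res["favours"] == "2_groups"

    def test_zero_variant_panel(self):
        rng = np.random.default_rng(11)
        lab = self._labels(rng, 100)
        res = compare_groupings(_gm(np.empty((100, 0))), lab)
        assert res["delta_bic"] == 0.0

    def test_missing_class_errors(self):
        with pytest.raises(ValueError, match="missing label"):
            compare_groupings(_gm(np.zeros((10, 1))),
                              np.array(["UC"] * 10, object))


class TestContinuum:
    def test_single_group(self):
        s = ScoreSet(samples=["a", "b"], raw=np.array([1.0, 3.0]),
                     contrast="CD_vs_UC")
        out = continuum_summary(s, ["g1", "g1"])
        assert len(out) == 1 and out["mean"].iloc[0] == pytest.approx(2.0)

    def test_total_contribution_decomposes(self):
        rng = np.random.default_rng(12)
        lab = rng.choice(["ilealCD", "colonicCD", "UC"], 500)
        dos = rng.binomial(2, 0.3, (500, 10)).astype(float)
        res = compare_groupings(_gm(dos), lab)
        assert res["delta_bic"] == pytest.approx(
            sum(res["per_locus"].values()))
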
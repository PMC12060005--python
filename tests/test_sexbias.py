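"""Sex-bias calling, concordance classes, and the open/closed-model tests."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact

from chromland import sexbias
from chromland.sexbias import (
    SexBiasConfig,
    call_sex_bias,
    concordance,
    signature_composition_by_bias,
)

open_closed_model = sexbias.test_open_closed_model
from oracles import fisher_exact_two_sided


def _tpm(female, male, tissue="gonad"):
    """Frame with 2 replicates per sex from per-gene mean vectors."""
    female = np.asarray(female, float)
    male = np.asarray(male, float)
    idx = [f"g{i}" for i in range(len(female))]
    cols = pd.MultiIndex.from_tuples(
        [("female", tissue, 1), ("female", tissue, 2),
         ("male", tissue, 1), ("male", tissue, 2)],
        names=["sex", "tissue", "replicate"],
    )
    data = np.column_stack([female, female, male, male])
    return pd.DataFrame(data, index=idx, columns=cols)


class TestCallSexBias:
    def test_identical_sexes_give_zero_biased(self, rng):
        vals = rng.lognormal(3, 1, 300)
        calls = call_sex_bias(_tpm(vals, vals), "gonad")
        assert (calls["class"].isin(["male-biased", "female-biased"])).sum() == 0

    def test_planted_fourfold_bias_recovered_with_high_sensitivity(self, rng):
        n_planted, n_null = 200, 2000
        base = rng.lognormal(3, 1, n_planted + n_null)
        male = base.copy()
        female = base.copy()
        male[:n_planted] *= 4  # 4-fold male-biased
        # replicate CV ~10%
        cols = pd.MultiIndex.from_tuples(
            [(s, "gonad", r) for s in ("female", "male") for r in (1, 2)],
            names=["sex", "tissue", "replicate"],
        )
        data = np.column_stack(
            [female * rng.lognormal(0, 0.1, len(base)) for _ in range(2)]
            + [male * rng.lognormal(0, 0.1, len(base)) for _ in range(2)]
        )
        tpm = pd.DataFrame(
            data, index=[f"g{i}" for i in range(len(base))], columns=cols
        )
        calls = call_sex_bias(tpm, "gonad")
        planted = calls.iloc[:n_planted]
        sensitivity = (planted["class"] == "male-biased").mean()
        assert sensitivity >= 0.95
        null_calls = calls.iloc[n_planted:]
        fpr = null_calls["class"].isin(["male-biased", "female-biased"]).mean()
        assert fpr < 0.02

    def test_low_expression_filtered_regardless_of_ratio(self):
        tpm = _tpm([0.05, 50.0], [0.002, 50.0])
        calls = call_sex_bias(tpm, "gonad")
        assert calls.loc["g0", "class"] == "filtered"

    def test_scale_invariance(self, rng):
        f = rng.lognormal(3, 1.5, 400)
        m = f * rng.choice([1.0, 6.0], 400, p=[0.9, 0.1])
        a = call_sex_bias(_tpm(f, m), "gonad")
        b = call_sex_bias(_tpm(2 * f, 2 * m), "gonad")
        # doubling all TPMs leaves every non-filtered call unchanged
        keep = (a["class"] != "filtered") & (b["class"] != "filtered")
        assert (a.loc[keep, "class"] == b.loc[keep, "class"]).all()

    def test_single_replicate_rejected(self):
        cols = pd.MultiIndex.from_tuples(
            [("female", "gonad", 1), ("male", "gonad", 1), ("male", "gonad", 2)],
            names=["sex", "tissue", "replicate"],
        )
        tpm = pd.DataFrame(np.ones((5, 3)), columns=cols)
        with pytest.raises(ValueError, match="replicates"):
            call_sex_bias(tpm, "gonad")


class TestConcordance:
    def test_four_way_classification(self):
        f = pd.Series(
            {"a": "active", "b": "repressive", "c": "repressive", "d": "active"}
        )
        m = pd.Series(
            {"a": "active", "b": "repressive", "c": "active", "d": "repressive"}
        )
        out = concordance(f, m)
        assert out["a"] == "both-active"
        assert out["b"] == "both-repressive"
        assert out["c"] == "male-active/female-repressive"
        assert out["d"] == "female-active/male-repressive"

    def test_missing_genes_skipped_and_counted(self):
        f = pd.Series({"a": "active", "b": "active"})
        m = pd.Series({"a": "active"})
        out = concordance(f, m)
        assert list(out.index) == ["a"]
        assert out.attrs["n_skipped"] == 1

    def test_independent_random_classes_near_quarter_each(self, rng):
        n = 10_000
        f = pd.Series(rng.choice(["active", "repressive"], n),
                      index=[f"g{i}" for i in range(n)])
        m = pd.Series(rng.choice(["active", "repressive"], n), index=f.index)
        props = concordance(f, m).value_counts(normalize=True)
        assert np.allclose(props, 0.25, atol=0.02)


class TestOpenClosedModel:
    def _calls(self, classes):
        return pd.DataFrame(
            {"class": classes}, index=[f"g{i}" for i in range(len(classes))]
        )

    def test_proportional_table_gives_chi2_zero(self):
        # 10:20 vs 30:60 composition - exactly proportional
        classes = ["male-biased"] * 30 + ["unbiased"] * 90
        conc = pd.Series(
            ["male-active/female-repressive"] * 10 + ["both-active"] * 20
            + ["male-active/female-repressive"] * 30 + ["both-active"] * 60,
            index=[f"g{i}" for i in range(120)],
        )
        res = open_closed_model(self._calls(classes), conc)
        assert res["chi2"] == pytest.approx(0.0, abs=1e-10)
        assert res["p_chi2"] == pytest.approx(1.0)

    def test_fisher_2x2_matches_enumeration_oracle(self):
        table = [[10, 0], [0, 10]]
        odds, p = fisher_exact(table)
        assert p == pytest.approx(fisher_exact_two_sided(table), rel=1e-9)
        assert p == pytest.approx(1.082e-5, rel=1e-3)

    def test_planted_discordance_detected(self, rng):
        n = 500
        classes = ["male-biased"] * n + ["unbiased"] * n
        conc_vals = []
        for cls in classes:
            p_disc = 0.40 if cls == "male-biased" else 0.05
            if rng.random() < p_disc:
                conc_vals.append("male-active/female-repressive")
            else:
                conc_vals.append(
                    rng.choice(["both-active", "both-repressive",
                                "female-active/male-repressive"])
                )
        conc = pd.Series(conc_vals, index=[f"g{i}" for i in range(2 * n)])
        res = open_closed_model(self._calls(classes), conc)
        assert res["p_chi2"] < 1e-6
        assert res["male"]["p"] < 1e-6
        assert res["male"]["odds_ratio"] > 1

    def test_single_bias_class_rejected(self):
        classes = ["unbiased"] * 10
        conc = pd.Series(["both-active"] * 10,
                         index=[f"g{i}" for i in range(10)])
        with pytest.raises(ValueError):
            open_closed_model(self._calls(classes), conc)

    def test_null_calibration_of_chi_square(self, rng):
        """With independent bias labels and chromatin classes the test
        rejects at the nominal 5% rate (400 null replicates)."""
        rejections = 0
        n_rep = 400
        idx = [f"g{i}" for i in range(900)]
        for _ in range(n_rep):
            classes = (["male-biased"] * 300 + ["female-biased"] * 300
                       + ["unbiased"] * 300)
            conc = pd.Series(
                rng.choice(
                    ["both-active", "both-repressive",
                     "male-active/female-repressive",
                     "female-active/male-repressive"], 900,
                ),
                index=idx,
            )
            res = open_closed_model(self._calls(classes), conc)
            rejections += res["p_chi2"] < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07


class TestSignatureComposition:
    def _sig(self, classes):
        return pd.DataFrame(
            {"broad_class": classes}, index=[f"g{i}" for i in range(len(classes))]
        )

    def test_identical_assignments_give_p_one(self):
        calls = pd.DataFrame(
            {"class": ["male-biased"] * 40 + ["unbiased"] * 60},
            index=[f"g{i}" for i in range(100)],
        )
        sig = self._sig(["repressive"] * 50 + ["active"] * 50)
        res = signature_composition_by_bias(calls, sig, sig)
        assert res["fisher_cross_sex"]["male-biased"]["p"] == pytest.approx(1.0)

    def test_proportions_sum_to_one(self, rng):
        calls = pd.DataFrame(
            {"class": rng.choice(["male-biased", "female-biased", "unbiased"], 300)},
            index=[f"g{i}" for i in range(300)],
        )
        sig_f = self._sig(rng.choice(["active", "mixed", "repressive"], 300))
        sig_m = self._sig(rng.choice(["active", "mixed", "repressive"], 300))
        res = signature_composition_by_bias(calls, sig_f, sig_m)
        props = res["proportions"]
        for (bias, sex), sub in props.groupby(["bias_class", "chromatin_sex"]):
            if not sub["empty"].any():
                assert sub["proportion"].sum() == pytest.approx(1.0)

    def test_planted_cross_sex_difference_recovered(self, rng):
        n = 900
        calls = pd.DataFrame(
            {"class": ["male-biased"] * n},
            index=[f"g{i}" for i in range(n)],
        )
        # male-biased genes repressive in ovary 60% vs testis 45%
        sig_f = self._sig(
            np.where(rng.random(n) < 0.60, "repressive", "active")
        )
        sig_m = self._sig(
            np.where(rng.random(n) < 0.45, "repressive", "active")
        )
        res = signature_composition_by_bias(calls, sig_f, sig_m)
        assert res["fisher_cross_sex"]["male-biased"]["p"] < 1e-6


def test_end_to_end_open_closed_on_planted_dataset(small_dataset):
    """Planted discordance in the generator flows through the DE rule and
    the planted chromatin classes into a detected enrichment."""
    ds = small_dataset
    calls = call_sex_bias(ds.tpm, "gonad")
    gt = ds.truth.gene_table
    # expression-based class per sex from the planted truth: favored sex
    # of discordant genes is active, the other repressive
    base = gt["class_gonad"].map(
        lambda c: "active" if c == "active" else "repressive"
    )
    cls_f, cls_m = base.copy(), base.copy()
    disc = gt["discordant_gonad"]
    fav = gt["favored_sex"]
    cls_f[disc & (fav == "female")] = "active"
    cls_m[disc & (fav == "female")] = "repressive"
    cls_f[disc & (fav == "male")] = "repressive"
    cls_m[disc & (fav == "male")] = "active"
    auto = gt.index[gt["region"].isin(["autosome", "PAR"])]
    conc = concordance(cls_f[auto], cls_m[auto])
    res = open_closed_model(calls.loc[auto], conc)
    assert res["male"]["odds_ratio"] > 1
    assert res["female"]["odds_ratio"] > 1
    assert res["p_chi2"] < 1e-4
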
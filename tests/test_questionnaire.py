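import math

import numpy as np
import pandas as pd
import pytest

import oracles
from comfnet.questionnaire import (
    QUESTION_ITEMS,
    cronbach_alpha,
    efa_varimax,
    item_statistics,
    kmo_and_sphericity,
    spearman_matrix,
)
from comfnet.synthetic import comfort_survey_loadings, generate_questionnaire


def random_table(n=60, p=6, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.normal(size=(n, p)),
                        columns=[f"item{i}" for i in range(p)])


class TestCronbachAlpha:
    def test_identical_items_give_one(self):
        x = np.tile(np.arange(10.0)[:, None], (1, 4))
        assert cronbach_alpha(pd.DataFrame(x)) == pytest.approx(1.0)

    def test_two_equal_variance_items_closed_form(self):
        # construct exact sample correlation 0.5 with equal variances
        rng = np.random.default_rng(1)
        q, _ = np.linalg.qr(rng.normal(size=(50, 2)))
        z1, z2 = q[:, 0], q[:, 1]  # exactly orthonormal, mean not zero
        z1 = (z1 - z1.mean()) / np.linalg.norm(z1 - z1.mean())
        z2 = z2 - z2.mean()
        z2 -= z1 * (z1 @ z2)
        z2 /= np.linalg.norm(z2)
        a = z1
        b = 0.5 * z1 + np.sqrt(0.75) * z2
        tbl = pd.DataFrame({"a": a, "b": b})
        assert np.corrcoef(a, b)[0, 1] == pytest.approx(0.5, abs=1e-12)
        assert cronbach_alpha(tbl) == pytest.approx(2 * 0.5 / 1.5, abs=1e-9)

    def test_shift_invariance_and_common_scaling(self):
        tbl = random_table(seed=2)
        shifted = tbl.copy()
        shifted["item0"] = shifted["item0"] + 100.0
        assert cronbach_alpha(shifted) == pytest.approx(cronbach_alpha(tbl),
                                                        abs=1e-12)
        assert cronbach_alpha(tbl * 3.5) == pytest.approx(cronbach_alpha(tbl),
                                                          abs=1e-12)

    def test_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        tbl = random_table(n=40, p=5, seed=3)
        ref = pingouin.cronbach_alpha(data=tbl)[0]
        assert cronbach_alpha(tbl) == pytest.approx(ref, abs=1e-10)


class TestItemStatistics:
    def test_alpha_if_deleted_is_definitional(self):
        tbl = generate_questionnaire(80, seed=4)
        rep = item_statistics(tbl)
        for item in tbl.columns:
            others = [c for c in tbl.columns if c != item]
            assert rep.items.loc[item, "alpha_if_deleted"] == pytest.approx(
                cronbach_alpha(tbl, items=others), abs=1e-12)

    def test_item_equal_to_sum_of_others(self):
        tbl = random_table(n=50, p=4, seed=5)
        tbl["total_like"] = tbl.sum(axis=1)
        rep = item_statistics(tbl)
        assert rep.items.loc["total_like", "item_total_corrected"] == \
            pytest.approx(1.0)

    def test_noise_item_lowers_alpha_and_removal_raises_it(self):
        rng = np.random.default_rng(6)
        factor = rng.normal(size=400)
        good = pd.DataFrame({f"g{i}": factor + 0.5 * rng.normal(size=400)
                             for i in range(5)})
        noisy = good.copy()
        noisy["junk"] = rng.normal(size=400)
        assert cronbach_alpha(noisy) < cronbach_alpha(good)
        rep = item_statistics(noisy)
        assert rep.items.loc["junk", "alpha_if_deleted"] > rep.alpha


class TestKMOAndSphericity:
    def test_structured_data_has_adequate_kmo(self):
        tbl = generate_questionnaire(2000, seed=7)
        kmo, chi2, p = kmo_and_sphericity(tbl)
        assert kmo > 0.7
        assert p < 1e-6

    def test_kmo_matches_regression_residual_oracle(self):
        for seed in range(5):
            tbl = generate_questionnaire(120, seed=seed)
            kmo, _, _ = kmo_and_sphericity(tbl)
            assert kmo == pytest.approx(oracles.bf_kmo(tbl.to_numpy()),
                                        abs=1e-6)

    def test_bartlett_null_p_roughly_uniform(self):
        ps = []
        for seed in range(120):
            tbl = random_table(n=80, p=5, seed=1000 + seed)
            ps.append(kmo_and_sphericity(tbl)[2])
        assert np.mean(np.array(ps) < 0.05) == pytest.approx(0.05, abs=0.06)
        assert np.mean(ps) == pytest.approx(0.5, abs=0.12)

    def test_singular_matrix_rejected(self):
        tbl = random_table(n=30, p=3, seed=8)
        tbl["dup"] = tbl["item0"]
        with pytest.raises(ValueError, match="singular"):
            kmo_and_sphericity(tbl)


class TestEFA:
    def test_planted_two_factor_structure_recovered(self):
        tbl = generate_questionnaire(20000, seed=9)
        rep = efa_varimax(tbl, n_factors=2)
        env_items = ["Noise comfort", "Vibration comfort",
                     "Aural pressure comfort", "Visual comfort",
                     "Thermal comfort"]
        aff_items = ["Overall comfort", "Emotion value", "Emotion arousal",
                     "Static comfort"]
        loads = rep.loadings
        env_factor = loads.loc[env_items].abs().sum().idxmax()
        aff_factor = [c for c in loads.columns if c != env_factor][0]
        for item in env_items:
            assert abs(loads.loc[item, env_factor]) > 0.5
            assert loads.loc[item].abs().idxmax() == env_factor
        for item in aff_items:
            assert abs(loads.loc[item, aff_factor]) > 0.5
            assert loads.loc[item].abs().idxmax() == aff_factor
        assert rep.flagged_items == ()

    def test_rotation_preserves_communalities(self):
        tbl = generate_questionnaire(300, seed=10)
        x = tbl.to_numpy()
        r = np.corrcoef(x, rowvar=False)
        eigval, eigvec = np.linalg.eigh(r)
        order = np.argsort(eigval)[::-1][:2]
        unrotated = eigvec[:, order] * np.sqrt(eigval[order])
        rep = efa_varimax(tbl, n_factors=2)
        np.testing.assert_allclose(rep.communalities.to_numpy(),
                                   np.sum(unrotated**2, axis=1), atol=1e-8)

    def test_single_factor_data_second_factor_weak(self):
        rng = np.random.default_rng(11)
        f = rng.normal(size=5000)
        tbl = pd.DataFrame({f"i{k}": 0.8 * f + 0.6 * rng.normal(size=5000)
                            for k in range(9)})
        rep = efa_varimax(tbl, n_factors=2)
        assert rep.explained_variance_ratio[1] < 0.15

    def test_bad_factor_count_rejected(self):
        with pytest.raises(ValueError):
            efa_varimax(generate_questionnaire(50, seed=0), n_factors=9)


class TestSpearman:
    def test_monotone_transform_gives_unit_rho(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=40)
        tbl = pd.DataFrame({"x": x, "y": x**3, "z": rng.normal(size=40)})
        rho, p, masked = spearman_matrix(tbl)
        assert rho.loc["x", "y"] == pytest.approx(1.0)
        assert p.loc["x", "y"] < 1e-10
        assert not np.isnan(masked.loc["x", "y"])

    def test_rho_invariant_under_increasing_transform(self):
        rng = np.random.default_rng(13)
        tbl = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        warped = tbl.copy()
        warped["a"] = np.exp(warped["a"])
        rho1, _, _ = spearman_matrix(tbl)
        rho2, _, _ = spearman_matrix(warped)
        np.testing.assert_allclose(rho1.to_numpy(), rho2.to_numpy(), atol=1e-12)

    def test_null_masking_rate(self):
        hidden = 0
        trials = 300
        for seed in range(trials):
            rng = np.random.default_rng(2000 + seed)
            tbl = pd.DataFrame({"a": rng.normal(size=20),
                                "b": rng.normal(size=20)})
            _, _, masked = spearman_matrix(tbl, mask_alpha=0.05)
            hidden += int(np.isnan(masked.loc["a", "b"]))
        assert hidden / trials == pytest.approx(0.95, abs=0.05)

    def test_small_sample_uses_exact_permutation(self):
        rng = np.random.default_rng(14)
        tbl = pd.DataFrame(rng.normal(size=(8, 3)), columns=list("abc"))
        _, p, _ = spearman_matrix(tbl)
        # exact two-sided permutation p at n=8: multiple of 1/8!
        for i in range(3):
            for j in range(i + 1, 3):
                frac = p.iloc[i, j] * math.factorial(8)
                assert frac == pytest.approx(round(frac), abs=1e-6)

    def test_question_items_constant(self):
        assert len(QUESTION_ITEMS) == 9
        assert QUESTION_ITEMS[0] == "Overall comfort"


def test_full_battery_reproduces_qualitative_pattern():
    """On generator output: high alpha, two-factor split, and the
    overall-comfort column correlating most with static comfort and
    emotional valence."""
    tbl = generate_questionnaire(3000, seed=15)
    assert cronbach_alpha(tbl) > 0.7
    rep = efa_varimax(tbl, n_factors=2)
    assert rep.kmo > 0.7
    rho, _, _ = spearman_matrix(tbl)
    overall = rho["Overall comfort"].drop("Overall comfort")
    top_two = set(overall.sort_values(ascending=False).index[:2])
    assert top_two == {"Static comfort", "Emotion value"}
    assert abs(overall["Visual comfort"]) < 0.2
    assert abs(overall["Thermal comfort"]) < 0.2
    lam = comfort_survey_loadings()
    assert list(lam.index) == list(tbl.columns)
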
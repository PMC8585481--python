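"""Inferential layer: residualization, contrasts, permutation machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as spstats

from apertrack.stats import (
    attention_contrast,
    cluster_permutation,
    group_tracking_test,
    multiplicity,
    permutation_contrast,
    prep_behavior,
    residualize,
    tracking_beta,
)
from apertrack.synthexp import EEGGenParams, simulate_experiment
from conftest import synthetic_trials


class TestResidualize:
    def test_empty_design_demeans(self):
        y = np.array([1.0, 2.0, 3.0])
        np.testing.assert_allclose(residualize(y, None), y - 2.0)

    def test_orthogonality(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((200, 3))
        y = rng.standard_normal(200)
        r = residualize(y, X)
        for j in range(3):
            assert abs(np.corrcoef(r, X[:, j])[0, 1]) < 1e-10

    def test_recovers_noise_term(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(1000)
        e = rng.standard_normal(1000)
        r = residualize(2 * x + e, x)
        assert np.corrcoef(r, e)[0, 1] > 0.99

    def test_rank_deficiency_names_columns(self):
        x = np.random.default_rng(2).standard_normal(50)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(ValueError, match="collinear"):
            residualize(x.copy(), X)


class TestAttentionContrast:
    def test_planted_interaction(self):
        gen = EEGGenParams(b_aud=0, b_vis=0, noise_sd=0.05,
                           attention_effect=-0.2, attention_effect_central=-0.05)
        t = simulate_experiment(24, gen=gen, seed=21)
        _, anova, follow = attention_contrast(t)
        assert anova["interaction"].p < 0.01
        assert abs(follow["occipital"].effect_size) > abs(follow["central"].effect_size)

    def test_identical_conditions_give_null_f(self):
        gen = EEGGenParams(b_aud=0, b_vis=0, noise_sd=0.05, attention_effect=0.0)
        t = simulate_experiment(6, gen=gen, seed=3)
        # make the two attention conditions literally identical per trial index
        t = t.copy()
        for col in [c for c in t.columns if c.startswith("exp_")]:
            vals = t[col].to_numpy().copy()
            aud = t["attention"] == "auditory"
            vals[~aud.to_numpy()] = vals[aud.to_numpy()][: (~aud).sum()]
            t[col] = vals
        _, anova, _ = attention_contrast(t)
        assert anova["attention"].p > 0.05

    def test_f_equals_squared_paired_t(self):
        gen = EEGGenParams(noise_sd=0.05)
        t = simulate_experiment(8, gen=gen, seed=9)
        cell, anova, _ = attention_contrast(t)
        wide = cell.pivot_table(index="subject", columns=["roi", "attention"],
                                values="resid")
        att_means = {c: wide.xs(c, axis=1, level="attention").mean(axis=1)
                     for c in ("auditory", "visual")}
        tval, _ = spstats.ttest_rel(att_means["visual"], att_means["auditory"])
        assert anova["attention"].statistic == pytest.approx(tval**2, abs=1e-8)

    def test_per_subject_constant_invariance(self):
        gen = EEGGenParams(noise_sd=0.05)
        t = simulate_experiment(6, gen=gen, seed=13)
        _, anova_a, _ = attention_contrast(t)
        t2 = t.copy()
        offs = {s: o for s, o in zip(range(6), np.linspace(-3, 3, 6))}
        for col in [c for c in t2.columns if c.startswith("exp_")]:
            t2[col] = t2[col] + t2["subject"].map(offs)
        _, anova_b, _ = attention_contrast(t2)
        assert anova_a["interaction"].statistic == pytest.approx(
            anova_b["interaction"].statistic, rel=1e-8)


class TestTrackingBeta:
    def test_planted_coupling_and_null_modality(self):
        betas_a, betas_v = [], []
        for s in range(6):
            t = synthetic_trials(b_aud=0.3, b_vis=0.0, seed=s, subject=s)
            betas_a.append(tracking_beta(t, "auditory").beta)
            betas_v.append(tracking_beta(t, "visual").beta)
        assert np.mean(betas_a) == pytest.approx(0.3, abs=0.05)
        assert np.mean(betas_v) == pytest.approx(0.0, abs=0.05)

    def test_null_unbiased_across_many_subjects(self):
        betas = [tracking_beta(synthetic_trials(seed=s, n_trials=432), "auditory").beta
                 for s in range(500)]
        assert abs(np.mean(betas)) < 0.01

    def test_equivalence_with_residual_correlation_oracle(self):
        t = synthetic_trials(b_aud=0.3, seed=4)
        beta = tracking_beta(t, "auditory").beta
        # brute-force oracle: correlation between step-1 residuals and the
        # z-scored target-modality exponent
        att = np.where(t["attention"] == "visual", 0.5, -0.5)
        X = np.column_stack([att, t["trial"], t["chi_vis"]])
        resid = residualize(t["exp_Cz"].to_numpy(), X)
        z = lambda v: (v - v.mean()) / v.std()
        r = np.corrcoef(z(resid), z(t["chi_aud"].to_numpy()))[0, 1]
        assert beta == pytest.approx(r, abs=1e-10)

    def test_scale_equivariance(self):
        t = synthetic_trials(b_aud=0.3, seed=6)
        b1 = tracking_beta(t, "auditory").beta
        t2 = t.assign(exp_Cz=t["exp_Cz"] * 7.3)
        assert tracking_beta(t2, "auditory").beta == pytest.approx(b1, abs=1e-12)

    def test_attention_subset(self):
        t = synthetic_trials(b_aud=0.4, seed=8)
        b = tracking_beta(t, "auditory", attention_subset="auditory")
        assert b.attention_subset == "auditory"
        assert b.n_trials == (t["attention"] == "auditory").sum()

    def test_preconditions(self):
        t = synthetic_trials(seed=0, n_trials=36)
        with pytest.raises(ValueError, match="20 trials"):
            tracking_beta(t.head(10), "auditory")
        with pytest.raises(ValueError, match="constant"):
            tracking_beta(t.assign(chi_aud=1.0), "auditory")


class TestPermutationContrast:
    def _epochs(self, shift, n_sub=5, n_ep=60, sd=0.15, seed=0):
        rng = np.random.default_rng(seed)
        a = [rng.normal(0, sd, n_ep) for _ in range(n_sub)]
        b = [rng.normal(shift, sd, n_ep) for _ in range(n_sub)]
        return a, b

    def test_planted_shift_detected(self):
        a, b = self._epochs(0.5)
        res = permutation_contrast(a, b, n_perm=1000, seed=1)
        assert res.p <= 0.0009
        assert res.n_perm == 1000

    def test_requires_multiple_epochs(self):
        with pytest.raises(ValueError):
            permutation_contrast([np.array([1.0])], [np.array([2.0])])

    def test_include_observed_convention(self):
        a, b = self._epochs(0.5, n_sub=4, n_ep=10)
        res = permutation_contrast(a, b, n_perm=100, seed=2, include_observed=True)
        assert res.p >= 1 / 101


class TestClusterPermutation:
    def _chain_adjacency(self, n):
        A = np.zeros((n, n), bool)
        for i in range(n - 1):
            A[i, i + 1] = A[i + 1, i] = True
        return A

    def test_localized_effect_detected(self):
        rng = np.random.default_rng(3)
        n_pos = 12
        X = rng.standard_normal((20, n_pos))
        X[:, 3:8] += 1.0  # d = 1 on five adjacent positions
        res = cluster_permutation(X, self._chain_adjacency(n_pos), n_perm=500, seed=4)
        sig = [c for c, p in zip(res.clusters, res.p) if p < 0.05]
        assert sig
        covered = max(len(set(c) & set(range(3, 8))) for c in sig)
        assert covered >= 4

    def test_all_zero_data_no_clusters(self):
        X = np.zeros((10, 6))
        res = cluster_permutation(X, self._chain_adjacency(6), n_perm=50, seed=0)
        assert res.clusters == ()

    def test_empty_adjacency_rejected(self):
        with pytest.raises(ValueError):
            cluster_permutation(np.zeros((5, 3)), np.zeros((0, 0)), n_perm=10)


class TestMultiplicity:
    def test_holm_hand_computed(self):
        reject, _ = multiplicity([0.01, 0.02, 0.04], method="holm")
        assert reject.tolist() == [True, True, True]

    def test_all_ones_none_rejected(self):
        reject, _ = multiplicity([1.0, 1.0, 1.0], method="bh_fdr")
        assert not reject.any()

    def test_single_p_unchanged(self):
        reject, adj = multiplicity([0.03], method="holm")
        assert adj[0] == pytest.approx(0.03)
        assert reject[0]


class TestPrepBehavior:
    def test_four_features_and_speed_scale(self, coupled_experiment):
        feats = prep_behavior(coupled_experiment)
        assert list(feats.columns) == ["acc_aud", "acc_vis", "speed_aud", "speed_vis"]
        assert len(feats) == coupled_experiment["subject"].nunique()
        # 1/rt lands on the right scale: residualized speed stays near zero-mean
        assert abs(feats["speed_aud"].mean()) < 2.0

    def test_uncorrelated_depth_leaves_centred_accuracy(self):
        rng = np.random.default_rng(5)
        frames = []
        for s in range(100):
            t = synthetic_trials(seed=s, subject=s, n_trials=72)
            t["depth"] = rng.uniform(0.1, 0.9)  # constant within, random across subjects
            t["correct"] = (rng.random(len(t)) < rng.uniform(0.5, 0.9)).astype(int)
            frames.append(t)
        table = pd.concat(frames)
        feats = prep_behavior(table)
        raw = table.groupby(["subject", "attention"])["correct"].mean().unstack()
        centred = raw["auditory"] - raw["auditory"].mean()
        assert np.corrcoef(feats["acc_aud"], centred)[0, 1] > 0.99

    def test_nonpositive_rt_rejected(self):
        t = synthetic_trials(seed=0)
        t.loc[t.index[0], "rt_s"] = -0.1
        with pytest.raises(ValueError, match="reaction time"):
            prep_behavior(t)


class TestGroupTrackingTest:
    def test_planted_effect(self):
        rng = np.random.default_rng(7)
        betas = 0.3 + rng.normal(0, 0.1, 24)
        res = group_tracking_test(betas)
        assert res.p < 0.001 and res.effect_size > 0.8

    def test_degenerate_zero_variance_flagged(self):
        res = group_tracking_test(np.full(24, 0.3))
        assert res.note is not None and np.isinf(res.statistic)

    def test_sign_flip_invariance(self):
        rng = np.random.default_rng(8)
        betas = rng.normal(0.2, 0.1, 12)
        a = group_tracking_test(betas)
        b = group_tracking_test(-betas)
        assert a.statistic == pytest.approx(-b.statistic)
        assert abs(a.effect_size) == pytest.approx(abs(b.effect_size))
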
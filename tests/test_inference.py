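import itertools

import numpy as np
import pandas as pd
import pytest

from microresilience import (
    LMMSpec,
    bh_adjust,
    correlate,
    fit_lmm,
    mann_whitney,
    paired_wilcoxon,
    posthoc_contrast,
    taxa_screen,
    clr_transform,
    prevalence_filter,
)
from microresilience.inference import (
    ContractError,
    DesignError,
    InsufficientDataError,
)
from microresilience.tables import Timepoint, ValidationError
from conftest import make_subject_table


def did_frame(cells, n_per_arm=5, noise=0.0, subject_sd=0.0, seed=0):
    """Balanced 2-arm × 2-visit long data from cell means."""
    rng = np.random.default_rng(seed)
    rows = []
    for arm, (y0, y1) in cells.items():
        for s in range(n_per_arm):
            subj = f"{arm}{s}"
            b = subject_sd * rng.normal()
            rows.append(dict(subject_id=subj, arm=arm, timepoint="CID2",
                             value=y0 + b + noise * rng.normal()))
            rows.append(dict(subject_id=subj, arm=arm, timepoint="CID3",
                             value=y1 + b + noise * rng.normal()))
    return pd.DataFrame(rows)


class TestLMM:
    def test_difference_in_differences_identity(self):
        """Noiseless saturated design: interaction = DiD of cell means."""
        df = did_frame({"placebo": (10, 11), "2FL": (10, 14)})
        res = fit_lmm(df, LMMSpec("y", time_levels=("CID2", "CID3")))
        est = res.fixed_effects.loc["arm[T.2FL]:time[T.CID3]", "estimate"]
        assert np.isclose(est, 3.0, atol=1e-9)

    def test_null_identity(self):
        df = did_frame({"placebo": (10, 12), "2FL": (10, 12)}, noise=0.0)
        res = fit_lmm(df, LMMSpec("y", time_levels=("CID2", "CID3")))
        est = res.fixed_effects.loc["arm[T.2FL]:time[T.CID3]", "estimate"]
        assert np.isclose(est, 0.0, atol=1e-9)

    def test_noisy_fit_reports_mixedlm(self):
        df = did_frame({"placebo": (10, 11), "2FL": (10, 14)},
                       n_per_arm=10, noise=0.5, subject_sd=1.0, seed=2)
        res = fit_lmm(df, LMMSpec("y", time_levels=("CID2", "CID3")))
        assert res.method == "mixedlm" and res.converged
        est = res.fixed_effects.loc["arm[T.2FL]:time[T.CID3]", "estimate"]
        assert abs(est - 3.0) < 1.0

    def test_interaction_recovery_with_random_intercepts(self):
        rng = np.random.default_rng(5)
        rows = []
        for i in range(40):
            arm = "2FL" if i % 2 else "placebo"
            b = rng.normal(0, 2)
            for tp, w in [("CID2", 0), ("SUV1", 2), ("CID3", 8)]:
                y = b + 0.1 * w + (0.25 * w if arm == "2FL" else 0) + rng.normal(0, 0.3)
                rows.append(dict(subject_id=f"S{i}", arm=arm, timepoint=tp, value=y))
        res = fit_lmm(pd.DataFrame(rows), LMMSpec("y", time_levels=("CID2", "SUV1", "CID3")))
        assert res.p_interaction < 0.01
        est8 = res.fixed_effects.loc["arm[T.2FL]:time[T.CID3]", "estimate"]
        assert abs(est8 - 2.0) < 0.5

    def test_one_arm_data_is_design_error(self):
        df = did_frame({"placebo": (10, 11)})
        with pytest.raises(DesignError):
            fit_lmm(df, LMMSpec("y", time_levels=("CID2", "CID3")))

    def test_covariates_enter_model(self):
        df = did_frame({"placebo": (10, 11), "2FL": (10, 14)}, noise=0.3, seed=3)
        df["baseline_covariate"] = np.repeat(
            np.random.default_rng(0).normal(30, 4, df["subject_id"].nunique()), 2
        )
        res = fit_lmm(
            df,
            LMMSpec("y", time_levels=("CID2", "CID3"),
                    covariates=("baseline_covariate",)),
        )
        assert "baseline_covariate" in res.fixed_effects.index

    def test_time_levels_outside_period_rejected(self):
        with pytest.raises(DesignError):
            LMMSpec("y", time_levels=("CID1", "CID2"))


class TestPosthoc:
    def test_noiseless_contrast_matches_cell_difference(self):
        df = did_frame({"placebo": (10, 11), "2FL": (10, 14)})
        res = fit_lmm(df, LMMSpec("y", time_levels=("CID2", "CID3")))
        assert res.p_interaction < 0.05
        est, _ = posthoc_contrast(res, "CID3")
        assert np.isclose(est, 3.0, atol=1e-9)
        est0, _ = posthoc_contrast(res, "CID2")
        assert np.isclose(est0, 0.0, atol=1e-9)

    def test_contract_error_without_interaction(self):
        df = did_frame({"placebo": (10, 11), "2FL": (10, 11)}, noise=0.4, seed=1)
        res = fit_lmm(df, LMMSpec("y", time_levels=("CID2", "CID3")))
        assert res.p_interaction >= 0.05
        with pytest.raises(ContractError):
            posthoc_contrast(res, "CID3")

    def test_matches_two_sample_difference_on_balanced_data(self):
        df = did_frame({"placebo": (10, 11), "2FL": (10, 14)}, noise=0.5, seed=4)
        res = fit_lmm(df, LMMSpec("y", time_levels=("CID2", "CID3")))
        est, _ = posthoc_contrast(res, "CID3")
        at = df[df["timepoint"] == "CID3"]
        oracle = (
            at.loc[at["arm"] == "2FL", "value"].mean()
            - at.loc[at["arm"] == "placebo", "value"].mean()
        )
        assert np.isclose(est, oracle, atol=1e-6)


class TestWilcoxon:
    def test_all_positive_n6_exact(self):
        before = np.zeros(6)
        after = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        _, p = paired_wilcoxon(before, after)
        assert np.isclose(p, 2 / 2**6)

    def test_matches_enumeration_oracle(self):
        """Exact two-sided p equals full enumeration over sign patterns."""
        diffs = np.array([0.8, -1.6, 2.4, 3.1, -0.3, 1.9, 0.6])
        n = len(diffs)
        ranks = pd.Series(np.abs(diffs)).rank().to_numpy()
        w_obs = ranks[diffs > 0].sum()
        w_all = [
            ranks[np.array(signs) > 0].sum()
            for signs in itertools.product([-1, 1], repeat=n)
        ]
        total = ranks.sum()
        dev = abs(w_obs - total / 2)
        p_oracle = np.mean([abs(w - total / 2) >= dev - 1e-12 for w in w_all])
        _, p = paired_wilcoxon(np.zeros(n), diffs)
        assert np.isclose(p, p_oracle)

    def test_all_zero_differences_insufficient(self):
        x = np.arange(6, dtype=float)
        with pytest.raises(InsufficientDataError):
            paired_wilcoxon(x, x)

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            paired_wilcoxon([1, 2, 3], [2, 3, 4])

    def test_scale_invariance(self):
        before = np.zeros(8)
        after = np.array([0.5, -1.2, 2.0, 0.7, -0.1, 1.1, 0.9, -2.2])
        _, p1 = paired_wilcoxon(before, after)
        _, p2 = paired_wilcoxon(before * 37.5, after * 37.5)
        assert p1 == p2


class TestMannWhitney:
    def test_separated_groups_exact(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert np.isclose(p, 2 / 20)  # 2 of C(6,3) orderings as extreme

    def test_matches_enumeration_oracle(self):
        a = np.array([1.3, 4.2, 0.5, 2.2])
        b = np.array([2.9, 5.1, 3.3])
        _, p = mann_whitney(a, b)
        pooled = np.concatenate([a, b])
        n_a = len(a)

        def u_stat(idx):
            grp = pooled[list(idx)]
            rest = np.delete(pooled, list(idx))
            return sum((x > y) for x in grp for y in rest)

        u_obs = u_stat(range(n_a))
        mid = len(a) * len(b) / 2
        us = [u_stat(c) for c in itertools.combinations(range(len(pooled)), n_a)]
        p_oracle = np.mean([abs(u - mid) >= abs(u_obs - mid) - 1e-12 for u in us])
        assert np.isclose(p, p_oracle)

    def test_identical_groups(self):
        _, p = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p > 0.99

    def test_monotone_transform_invariance(self):
        a = [0.2, 1.5, 3.0, 0.9]
        b = [2.2, 0.4, 5.5]
        _, p1 = mann_whitney(a, b)
        _, p2 = mann_whitney(np.exp(a), np.exp(b))
        assert p1 == p2

    def test_empty_group_error(self):
        with pytest.raises(InsufficientDataError):
            mann_whitney([], [1.0])


class TestBHAdjust:
    def test_stepup_hand_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_single_p_identity_and_cap(self):
        assert bh_adjust([0.2])[0] == 0.2
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_monotone_and_order_stable(self, rng):
        p = rng.uniform(size=25)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)
        perm = rng.permutation(25)
        assert np.allclose(bh_adjust(p[perm]), q[perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.1, 1.4])


class TestCorrelate:
    def test_perfect_linear(self):
        x = np.arange(10, dtype=float)
        r, p = correlate(x, 2 * x + 1, "pearson")
        assert np.isclose(r, 1.0) and p < 1e-6

    def test_monotone_nonlinear(self):
        x = np.linspace(0, 5, 12)
        rs, _ = correlate(x, np.exp(x), "spearman")
        rp, _ = correlate(x, np.exp(x), "pearson")
        assert np.isclose(rs, 1.0) and rp < 1.0

    def test_missing_pairs_dropped(self):
        x = np.array([1, 2, 3, 4, np.nan, 6], dtype=float)
        y = np.array([2, 4, 6, 8, 10, np.nan], dtype=float)
        r, _ = correlate(x, y, "pearson")
        assert np.isclose(r, 1.0)

    def test_independent_samples_near_zero(self, rng):
        x, y = rng.normal(size=(2, 1000))
        r, _ = correlate(x, y, "pearson")
        assert abs(r) < 0.1

    def test_zero_variance_error(self):
        with pytest.raises(ValidationError):
            correlate([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


@pytest.fixture(scope="module")
def filtered_clr(default_bundle):
    table = prevalence_filter(default_bundle.counts, 0.15)
    return clr_transform(table, 1.0), default_bundle


class TestTaxaScreen:
    def test_vanco_screen_detects_perturbed_taxa(self, filtered_clr):
        clr, bundle = filtered_clr
        res = taxa_screen(clr, bundle.counts.meta, design="paired_vanco")
        assert res["q"].between(0, 1).all()
        assert np.all(res["q"] >= res["p"] - 1e-15)
        # the antibiotic hit most taxa hard: a majority flips significantly
        assert (res["q"] < 0.05).sum() > 0.5 * len(res)
        # among truly perturbed taxa, the called direction matches the
        # ground truth (unaffected taxa may still shift in CLR terms via
        # compositional renormalization, so they are not scored here)
        truth = dict(
            zip([f"g{j + 1:03d}" for j in range(73)], bundle.truth.taxon_class)
        )
        sig = res[(res["q"] < 0.05) & (res["direction"] != 0)]
        scored = [
            (truth[t], d)
            for t, d in zip(sig["taxon_id"], sig["direction"])
            if truth[t] != 0
        ]
        agree = np.mean([t == d for t, d in scored])
        assert len(scored) >= 20 and agree > 0.9

    def test_single_taxon_q_equals_p(self, filtered_clr):
        clr, bundle = filtered_clr
        one = type(clr)(clr.values.iloc[:, [0]])
        res = taxa_screen(one, bundle.counts.meta, design="paired_vanco")
        assert np.isclose(res["q"].iloc[0], res["p"].iloc[0])

    def test_arm_screen_null_at_baseline(self, filtered_clr):
        """Arms were randomized: at CID1 no taxon should separate them."""
        clr, bundle = filtered_clr
        res = taxa_screen(
            clr, bundle.counts.meta, design="per_timepoint_arms", timepoint="CID1"
        )
        assert (res["q"] < 0.05).sum() == 0

    def test_lmm_screen_smoke(self, filtered_clr):
        clr, bundle = filtered_clr
        few = type(clr)(clr.values.iloc[:, :5])
        res = taxa_screen(few, bundle.counts.meta, design="lmm_2week")
        assert len(res) == 5 and res["p"].between(0, 1).all()

    def test_unknown_design_rejected(self, filtered_clr):
        clr, bundle = filtered_clr
        with pytest.raises(DesignError):
            taxa_screen(clr, bundle.counts.meta, design="bogus")
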
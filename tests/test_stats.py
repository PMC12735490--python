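"""Paired tests, Tukey contrasts and multiplicity control vs oracles.

The brute-force references here are written independently of the
implementation: plain-Python loops straight from the step-up/step-down
definitions, and exhaustive sign-flip / signed-rank enumerations for the
paired tests.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from fibersynergy import stats, synergy, synthetic
from fibersynergy.stats import (
    adjust_pvalues, observed_vs_expected_suite, paired_test,
    synergy_comparison_suite, tukey_contrasts,
)


# --- independent references -------------------------------------------------

def bh_reference(ps):
    """Step-up BH: min over j >= i of m*p_(j)/j, clipped at 1."""
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    out = [0.0] * m
    for rank_i, idx in enumerate(order, start=1):
        candidates = [m * ps[order[j - 1]] / j for j in range(rank_i, m + 1)]
        out[idx] = min(1.0, min(candidates))
    return out


def holm_sidak_reference(ps):
    """Step-down Sidak: max over j <= i of 1-(1-p_(j))^(m-j+1), clipped."""
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    out = [0.0] * m
    for rank_i, idx in enumerate(order, start=1):
        candidates = [1.0 - (1.0 - ps[order[j - 1]]) ** (m - j + 1) for j in range(1, rank_i + 1)]
        out[idx] = min(1.0, max(candidates))
    return out


def sign_flip_p(diffs):
    """Exact two-sided permutation p for the mean of paired differences."""
    n = len(diffs)
    observed = abs(np.mean(diffs))
    count = 0
    for signs in itertools.product([1, -1], repeat=n):
        if abs(np.mean(np.array(signs) * diffs)) >= observed - 1e-12:
            count += 1
    return count / 2**n


def signed_rank_two_sided_p(diffs):
    """Exact two-sided signed-rank p: 2*min(P(W<=w), P(W>=w)) capped at 1."""
    d = np.asarray(diffs, dtype=float)
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    dist = []
    for signs in itertools.product([0, 1], repeat=len(d)):
        dist.append((ranks * np.array(signs)).sum())
    dist = np.array(dist)
    p_low = np.mean(dist <= w_obs + 1e-12)
    p_high = np.mean(dist >= w_obs - 1e-12)
    return min(1.0, 2 * min(p_low, p_high))


# --- multiple testing -------------------------------------------------------

class TestAdjustPvalues:
    def test_single_p_is_identity(self):
        assert adjust_pvalues([0.03], "bh") == [0.03]
        assert adjust_pvalues([0.03], "holm_sidak") == pytest.approx([0.03])

    def test_bh_hand_example(self):
        # equally spaced p's all share the largest m*p/rank = 0.04
        assert adjust_pvalues([0.01, 0.02, 0.03, 0.04], "bh") == pytest.approx([0.04] * 4)

    def test_holm_sidak_hand_example(self):
        out = adjust_pvalues([0.01, 0.04], "holm_sidak")
        assert out[0] == pytest.approx(1 - 0.99**2)  # 0.0199
        assert out[1] == pytest.approx(0.04)

    def test_matches_brute_force_exactly(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            m = int(rng.integers(1, 21))
            ps = rng.uniform(size=m).tolist()
            assert adjust_pvalues(ps, "bh") == bh_reference(ps)
            assert adjust_pvalues(ps, "holm_sidak") == holm_sidak_reference(ps)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            ps = rng.uniform(size=int(rng.integers(2, 15)))
            np.testing.assert_allclose(
                adjust_pvalues(ps.tolist(), "bh"),
                multipletests(ps, method="fdr_bh")[1], rtol=1e-12)
            np.testing.assert_allclose(
                adjust_pvalues(ps.tolist(), "holm_sidak"),
                multipletests(ps, method="holm-sidak")[1], rtol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            adjust_pvalues([0.5, 1.2], "bh")

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(3)
        for method in ("bh", "holm_sidak"):
            ps = rng.uniform(size=12)
            adj = adjust_pvalues(ps.tolist(), method)
            assert all(a >= p - 1e-15 for a, p in zip(adj, ps))


# --- paired tests -------------------------------------------------------------

class TestPairedTest:
    def test_identical_vectors_give_p_one(self):
        res = paired_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p_raw == 1.0

    def test_small_n_suppressed(self):
        res = paired_test([1.0, 2.0], [0.5, 1.0])
        assert res.suppressed and np.isnan(res.p_raw)

    def test_constant_nonzero_difference_degenerates_with_warning(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            res = paired_test([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert res.p_raw == 0.0 and np.isinf(res.statistic)

    def test_t_close_to_exact_permutation(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            x = rng.normal(size=6)
            y = rng.normal(size=6)
            res = paired_test(x, y, method="t")
            assert res.p_raw == pytest.approx(sign_flip_p(x - y), abs=0.2)

    def test_wilcoxon_matches_signed_rank_enumeration(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            x = rng.normal(size=6)
            y = rng.normal(size=6)
            res = paired_test(x, y, method="wilcoxon")
            assert res.p_raw == pytest.approx(signed_rank_two_sided_p(x - y), abs=1e-12)

    def test_antisymmetry(self):
        rng = np.random.default_rng(17)
        x, y = rng.normal(size=8), rng.normal(size=8)
        ab = paired_test(x, y)
        ba = paired_test(y, x)
        assert ab.p_raw == ba.p_raw
        assert ab.direction == -ba.direction


# --- Tukey contrasts ----------------------------------------------------------

class TestTukeyContrasts:
    def _layout(self, rng, n=8, k=5, shift=None):
        donor_effect = rng.normal(0, 2.0, size=(n, 1))
        y = 10 + donor_effect + rng.normal(0, 1.0, size=(n, k))
        if shift is not None:
            y[:, shift[0]] += shift[1]
        return pd.DataFrame(y, columns=[f"s{j}" for j in range(k)])

    def test_identical_substrates_all_p_one(self):
        values = pd.DataFrame(np.tile([[4.0, 4.0, 4.0, 4.0, 4.0]], (6, 1)),
                              columns=list("abcde"))
        out = tukey_contrasts(values)
        assert len(out) == 10
        assert (out["p_raw"] == 1.0).all() and (out["statistic"] == 0.0).all()

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(23)
        values = self._layout(rng, shift=(0, 10.0))
        out = tukey_contrasts(values)
        hits = out[out["comparison"].str.contains("s0")]
        others = out[~out["comparison"].str.contains("s0")]
        assert hits["significant"].all()
        assert not others["significant"].any()

    def test_two_donors_suppressed(self):
        values = pd.DataFrame(np.ones((2, 5)), columns=list("abcde"))
        assert len(tukey_contrasts(values)) == 0

    def test_unblocked_matches_statsmodels_tukeyhsd(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(29)
        values = self._layout(rng, n=10, k=4)
        ours = tukey_contrasts(values, blocked=False)
        long = values.melt(var_name="g", value_name="y")
        ref = pairwise_tukeyhsd(long["y"], long["g"])
        np.testing.assert_allclose(
            sorted(ours["p_raw"]), sorted(ref.pvalues), atol=1e-8)

    def test_blocking_removes_donor_variance(self):
        # strong donor effects: blocked analysis detects a modest shift the
        # pooled analysis drowns in between-donor noise
        rng = np.random.default_rng(31)
        donor_effect = rng.normal(0, 8.0, size=(10, 1))
        y = 20 + donor_effect + rng.normal(0, 0.5, size=(10, 5))
        y[:, 2] += 2.0
        values = pd.DataFrame(y, columns=list("abcde"))
        blocked = tukey_contrasts(values, blocked=True)
        pooled = tukey_contrasts(values, blocked=False)
        target = blocked["comparison"].str.contains("c")
        assert blocked[target]["significant"].all()
        assert not pooled[pooled["comparison"].str.contains("c")]["significant"].any()


# --- suites -------------------------------------------------------------------

class TestObservedVsExpectedSuite:
    def test_null_zero_noise_all_p_one(self):
        cfg = synthetic.FermGenConfig(synergy_mean=0, synergy_sd=0, noise_sd=0, seed=2)
        table, _ = synthetic.generate_fermentation_table(cfg)
        syn = synergy.apply_filters(synergy.compute_synergy(table))
        out = observed_vs_expected_suite(syn)
        assert (out["p_raw"] == 1.0).all()

    def test_family_is_condition_by_scfa(self, synergy_table):
        out = observed_vs_expected_suite(synergy_table)
        assert len(out) == 16  # 4 conditions x 4 SCFA measures
        assert (out["adjust_method"] == "bh").all()

    def test_injected_synergy_detected(self, synergy_table):
        out = observed_vs_expected_suite(synergy_table)
        total = out[out["comparison"].str.contains("total")]
        assert total["significant"].all()


class TestSynergyComparisonSuite:
    def test_family_of_one_keeps_raw_p(self):
        records = []
        for donor in range(6):
            for cond in ("HC", "PD"):
                records.append({
                    "donor_id": f"{cond}{donor}", "condition": cond, "scfa_type": "total",
                    "observed_mM": 10.0 + donor, "expected_mM": 8.0,
                    "synergy_pct": 25.0 + donor * (2 if cond == "PD" else 1),
                    "filter_status": "retained"})
        out = synergy_comparison_suite(pd.DataFrame(records), "across_conditions",
                                       scfa_types=["total"])
        assert len(out) == 1
        assert out["p_adjusted"].iloc[0] == pytest.approx(out["p_raw"].iloc[0], rel=1e-12)

    def test_shifted_condition_detected(self):
        cfg = synthetic.FermGenConfig(seed=37, synergy_sd=5.0)
        table, _ = synthetic.generate_fermentation_table(cfg)
        syn = synergy.apply_filters(synergy.compute_synergy(table))
        # plant a +40-point shift in UC donors
        uc = syn["condition"] == "UC"
        syn.loc[uc, "synergy_pct"] += 40.0
        out = synergy_comparison_suite(syn, "across_conditions", scfa_types=["total"])
        uc_rows = out[out["comparison"].str.contains("UC")]
        assert uc_rows["significant"].all()

    def test_within_condition_paired_layout(self, synergy_table):
        out = synergy_comparison_suite(synergy_table, "across_scfa_within_condition")
        # 4 conditions x 3 acid pairs
        assert len(out) == 12
        assert set(out["family"].str.split(":").str[0]) == {"within_condition"}

    def test_unknown_axis_rejected(self, synergy_table):
        with pytest.raises(ValueError, match="axis"):
            synergy_comparison_suite(synergy_table, "sideways")
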
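"""Summaries, rank tests vs hand oracles, FDR, power, and the pipeline."""

from itertools import combinations

import numpy as np
import pytest
from scipy.stats import nct, t as t_dist

from migd.stats import (
    ComparisonConfig,
    bh_adjust,
    kruskal_wallis,
    median_quartiles,
    power_two_sample_t,
    run_comparisons,
    sample_size_two_group,
)
from migd.synth import default_paper_spec, fit_lognormal_from_quartiles, generate_cohort

from conftest import make_cohort_from_arrays


# ---------------------------------------------------------------- oracles
def rank_with_ties(pooled):
    """Average ranks, computed by sorting (independent of scipy)."""
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def kw_h_oracle(groups):
    """Tie-corrected Kruskal–Wallis H from the rank-sum definition."""
    pooled = [v for g in groups for v in g]
    n = len(pooled)
    ranks = rank_with_ties(pooled)
    idx = 0
    h = 0.0
    for g in groups:
        r = sum(ranks[idx: idx + len(g)])
        idx += len(g)
        h += r * r / len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    ties = {}
    for v in pooled:
        ties[v] = ties.get(v, 0) + 1
    correction = 1.0 - sum(t**3 - t for t in ties.values()) / (n**3 - n)
    return h / correction


def bh_oracle(pvals):
    """Step-up: adj_i = min over j with p_(j) >= p_(i) of m*p_(j)/j, capped at 1."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * pvals[i] / rank)
        adj[i] = running
    return adj


# ---------------------------------------------------------------- summaries
class TestMedianQuartiles:
    def test_singleton(self):
        assert median_quartiles([5]) == (5, 5, 5)

    def test_linear_interpolation_odd_n(self):
        assert median_quartiles([1, 2, 3, 4, 5]) == (3, 2, 4)

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            median_quartiles([])

    def test_simulated_control_tmao_median_recovers_target(self, rng):
        spec = default_paper_spec()
        params = fit_lognormal_from_quartiles(spec.analyte_targets[("control", "TMAO")])
        draws = np.exp(params.mu + params.sigma * rng.standard_normal(10_000))
        med, _, _ = median_quartiles(draws)
        assert med == pytest.approx(3.09, rel=0.05)


# ---------------------------------------------------------------- rank test
class TestKruskalWallis:
    def test_identical_groups_give_h0_p1(self):
        res = kruskal_wallis([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_raw == pytest.approx(1.0)

    def test_degenerate_all_equal_flagged(self):
        res = kruskal_wallis([2.0, 2.0], [2.0, 2.0, 2.0])
        assert res.degenerate and res.p_raw == 1.0 and res.statistic == 0.0

    def test_matches_oracle_on_all_splits_of_six(self):
        """H agrees with the hand rank-formula on every 3|3 split of 6 values."""
        data = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        splits = 0
        for left in combinations(range(6), 3):
            g1 = [data[i] for i in left]
            g2 = [data[i] for i in range(6) if i not in left]
            ours = kruskal_wallis(g1, g2).statistic
            assert ours == pytest.approx(kw_h_oracle([g1, g2]), abs=1e-9)
            splits += 1
        assert splits == 20

    @pytest.mark.parametrize(
        "groups",
        [
            ([1, 2, 3], [4, 5, 6]),
            ([1.5, 1.5, 2.0], [2.0, 3.0], [0.5, 4.0, 4.0]),  # ties across groups
            ([10, 12], [11, 13, 14], [9]),
        ],
    )
    def test_tie_corrected_h_matches_oracle(self, groups):
        ours = kruskal_wallis(*groups).statistic
        assert ours == pytest.approx(kw_h_oracle([list(g) for g in groups]), abs=1e-9)

    def test_invariant_under_monotone_transform(self, rng):
        groups = [list(rng.normal(size=8)), list(rng.normal(size=10)), list(rng.normal(size=6))]
        base = kruskal_wallis(*groups).statistic
        transformed = [[np.exp(v) for v in g] for g in groups]
        assert kruskal_wallis(*transformed).statistic == pytest.approx(base)

    def test_type_one_error_near_nominal(self, rng):
        """Three null groups, 1000 reps at n=20/group: rejection rate ≈ 0.05."""
        reps, alpha = 1000, 0.05
        rejections = sum(
            kruskal_wallis(*(rng.normal(size=20) for _ in range(3))).p_raw < alpha
            for _ in range(reps)
        )
        rate = rejections / reps
        envelope = 1.96 * np.sqrt(alpha * (1 - alpha) / reps)
        assert abs(rate - alpha) <= envelope


# ---------------------------------------------------------------- FDR
class TestBhAdjust:
    def test_single_p_identity(self):
        assert bh_adjust([0.05]) == [0.05]

    def test_hand_computed_vector(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    @pytest.mark.parametrize(
        "pvals",
        [[0.001, 0.2, 0.9, 0.04, 0.5], [0.5, 0.5, 0.5], [1.0, 0.0, 0.3]],
    )
    def test_matches_step_up_oracle(self, pvals):
        assert bh_adjust(pvals) == pytest.approx(bh_oracle(pvals))

    def test_never_decreases_and_preserves_ranking(self, rng):
        p = rng.uniform(size=25)
        adj = np.array(bh_adjust(p))
        assert np.all(adj >= p) and np.all(adj <= 1)
        # monotone: adjusted values never cross when sorted by raw p
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_fatal(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


# ---------------------------------------------------------------- power
def power_oracle(n, d, alpha):
    """Two-sided two-sample t power via scipy noncentral t directly."""
    df = 2 * n - 2
    crit = t_dist.ppf(1 - alpha / 2, df)
    ncp = d * np.sqrt(n / 2)
    return nct.sf(crit, df, ncp) + nct.cdf(-crit, df, ncp)


class TestSampleSize:
    def test_moderate_effect_needs_64_per_group(self):
        assert sample_size_two_group(0.5, 0.05, 0.80) == 64

    def test_large_effect_needs_26(self):
        assert sample_size_two_group(0.8, 0.05, 0.80) == 26
        assert power_oracle(26, 0.8, 0.05) >= 0.80
        assert power_oracle(25, 0.8, 0.05) < 0.80

    def test_power_function_matches_noncentral_t_oracle(self):
        for n, d in [(10, 0.3), (64, 0.5), (26, 0.8), (200, 0.2)]:
            assert power_two_sample_t(n, d, 0.05) == pytest.approx(
                power_oracle(n, d, 0.05), abs=1e-6
            )

    def test_power_monotone_in_n(self):
        powers = [power_two_sample_t(n, 0.5, 0.05) for n in range(5, 80, 5)]
        assert all(a < b for a, b in zip(powers, powers[1:]))

    def test_n_monotone_in_effect_and_power(self):
        assert sample_size_two_group(0.3) >= sample_size_two_group(0.5)
        assert sample_size_two_group(0.5, power=0.9) >= sample_size_two_group(0.5, power=0.8)


# ---------------------------------------------------------------- pipeline
def null_cohort(rng, n_per_stratum=20):
    strata = [("control", 4), ("asd", 1), ("asd", 6), ("asd", 4)]
    specs = []
    for group, bsc in strata:
        values = {
            a: np.exp(rng.normal(size=n_per_stratum))
            for a in ("ADMA", "SDMA", "TMAO", "IS", "PCS")
        }
        specs.append((group, bsc, values))
    return make_cohort_from_arrays(specs)


class TestRunComparisons:
    def test_adjusted_never_below_raw_and_families_per_analyte(self, small_cohort):
        tests, summaries, skipped = run_comparisons(small_cohort)
        assert tests, "no comparisons ran"
        for t in tests:
            assert 0 <= t.p_raw <= 1 and t.p_adjusted >= t.p_raw - 1e-12
        assert any(s.analyte_or_index == "MIGD" for s in summaries)
        # loose subgroup empty in this fixture -> skipped, not failed
        assert any("asd_loose" in s for s in skipped)

    def test_summary_quartile_ordering(self, small_cohort):
        _, summaries, _ = run_comparisons(small_cohort)
        for s in summaries:
            assert s.q1 <= s.median <= s.q3 and s.n > 0

    def test_location_shift_detected_with_high_power(self, rng):
        """Hard-stool values shifted +2 SD vs controls at n=64: the
        control-vs-hard contrast rejects in ≥95% of 200 reps."""
        reps, hits = 200, 0
        config = ComparisonConfig(analytes=["ADMA"])
        for _ in range(reps):
            base = {
                "control": rng.normal(size=64),
                "hard": rng.normal(loc=2.0, size=64),
                "loose": rng.normal(size=64),
                "normal": rng.normal(size=64),
            }
            cohort = make_cohort_from_arrays(
                [
                    ("control", 4, {a: np.exp(base["control"]) for a in ["ADMA", "SDMA", "TMAO", "IS", "PCS"]}),
                    ("asd", 1, {a: np.exp(base["hard"]) for a in ["ADMA", "SDMA", "TMAO", "IS", "PCS"]}),
                    ("asd", 6, {a: np.exp(base["loose"]) for a in ["ADMA", "SDMA", "TMAO", "IS", "PCS"]}),
                    ("asd", 4, {a: np.exp(base["normal"]) for a in ["ADMA", "SDMA", "TMAO", "IS", "PCS"]}),
                ]
            )
            tests, _, _ = run_comparisons(cohort, config)
            p = next(t.p_raw for t in tests if "control vs asd_hard" in t.comparison)
            hits += p < 0.05
        assert hits / reps >= 0.95

    def test_four_group_omnibus_option(self, small_cohort):
        config = ComparisonConfig(omnibus_scope="four_group", analytes=["PCS"])
        tests, _, skipped = run_comparisons(small_cohort, config)
        # loose subgroup is empty -> the four-group omnibus is skipped
        assert any("omnibus" in s for s in skipped)
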
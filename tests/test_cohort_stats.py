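"""Cohort statistics: exclusions, Fisher, Mann-Whitney, descriptives."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom, rankdata

from cnloh.cohort_stats import (apply_exclusions, describe_burden,
                                fisher_prevalence, mw_burden, outcome_burden,
                                run_cohort_stats, subtype_spectrum)
from cnloh.loh_caller import SampleSummary


def _summary(sid, count=0, extents=None, flat=False, mycn=False, loh_only=False):
    extents = extents or {"INTERSTITIAL": count, "TELOMERIC": 0,
                          "WHOLE_CHROMOSOME": 0}
    return SampleSummary(sample_id=sid, near_cn_loh_count=count,
                         counts_by_extent=extents,
                         aberrant_segment_count=count + (not flat),
                         flat_profile=flat, mycn_amp_only=mycn,
                         cn_loh_only=loh_only)


def _meta(rows):
    return pd.DataFrame(rows, columns=["sample_id", "group", "related_group",
                                       "outcome", "stage"])


class TestFisher:
    def test_published_counts_round_to_0_005(self):
        assert round(fisher_prevalence(47, 134, 7, 8), 3) == 0.005

    def test_identical_proportions_give_p_one(self):
        assert fisher_prevalence(3, 10, 3, 10) == pytest.approx(1.0)

    def test_matches_exhaustive_fixed_margin_enumeration(self):
        # oracle: sum P(table) over all tables with the observed margins whose
        # probability does not exceed the observed table's
        def brute(k1, n1, k2, n2):
            big_n, big_k = n1 + n2, k1 + k2
            p_obs = hypergeom.pmf(k1, big_n, big_k, n1)
            xs = np.arange(max(0, big_k - n2), min(big_k, n1) + 1)
            ps = hypergeom.pmf(xs, big_n, big_k, n1)
            return float(ps[ps <= p_obs * (1 + 1e-9)].sum())

        rng = np.random.default_rng(0)
        for _ in range(150):
            n1, n2 = rng.integers(1, 13, 2)
            k1, k2 = rng.integers(0, n1 + 1), rng.integers(0, n2 + 1)
            assert fisher_prevalence(k1, n1, k2, n2) == \
                pytest.approx(brute(k1, n1, k2, n2), abs=1e-9)

    def test_symmetric_in_group_order_and_label_swap(self):
        p = fisher_prevalence(5, 20, 2, 15)
        assert fisher_prevalence(2, 15, 5, 20) == pytest.approx(p)
        assert fisher_prevalence(15, 20, 13, 15) == pytest.approx(p)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            fisher_prevalence(0, 0, 1, 2)


def _perm_oracle(a, b):
    x = np.concatenate([a, b])
    r = rankdata(x)
    na = len(a)
    obs = r[:na].sum()
    e = na * (len(x) + 1) / 2
    hits = total = 0
    for idx in itertools.combinations(range(len(x)), na):
        s = r[list(idx)].sum()
        total += 1
        hits += abs(s - e) >= abs(obs - e) - 1e-9
    return hits / total


class TestMannWhitney:
    def test_identical_samples_give_p_one_and_central_u(self):
        p, u = mw_burden([1, 2, 3], [1, 2, 3])
        assert p == 1.0 and u == pytest.approx(4.5)

    def test_complete_separation_n3_exact_p_is_two_twentieths(self):
        p, u = mw_burden([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)
        assert u == 0.0

    def test_exact_branch_matches_full_permutation_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            na, nb = rng.integers(2, 8, 2)
            a, b = rng.poisson(1.0, na), rng.poisson(2.0, nb)
            p, _ = mw_burden(a, b, method="exact")
            assert p == pytest.approx(_perm_oracle(a, b), abs=1e-12)

    def test_normal_approximation_close_to_exact_for_tied_counts(self):
        for seed in range(8):
            rng = np.random.default_rng(seed)
            a, b = rng.poisson(0.9, 15), rng.poisson(2.4, 15)
            pe, _ = mw_burden(a, b, method="exact")
            pa, _ = mw_burden(a, b, method="asymptotic")
            assert abs(pe - pa) < 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mw_burden([], [1])


class TestDescribeBurden:
    def test_all_zero_counts(self):
        assert describe_burden([0, 0, 0]) == {"median": 0.0, "mean": 0.0,
                                              "p25": 0.0, "p75": 0.0}

    def test_linear_interpolation_quartiles(self):
        d = describe_burden([0, 1, 2, 3])
        assert d == {"median": 1.5, "mean": 1.5, "p25": 0.75, "p75": 2.25}

    def test_singleton(self):
        assert describe_burden([5]) == {"median": 5.0, "mean": 5.0,
                                        "p25": 5.0, "p75": 5.0}

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            describe_burden([])


class TestSpectrum:
    def test_pure_interstitial_group(self):
        spec = subtype_spectrum([{"INTERSTITIAL": 2}, {"INTERSTITIAL": 1}])
        assert spec["INTERSTITIAL"] == 1.0

    def test_empty_group_yields_empty_spectrum(self):
        assert subtype_spectrum([{"INTERSTITIAL": 0}]) == {}

    def test_sampled_mixture_recovered_within_three_binomial_se(self):
        rng = np.random.default_rng(10)
        mix = {"INTERSTITIAL": 0.5, "TELOMERIC": 0.35, "WHOLE_CHROMOSOME": 0.15}
        keys = list(mix)
        draws = rng.choice(3, size=600, p=[mix[k] for k in keys])
        rows = [{keys[d]: 1} for d in draws]
        spec = subtype_spectrum(rows)
        for i, k in enumerate(keys):
            se = np.sqrt(mix[k] * (1 - mix[k]) / 600)
            assert abs(spec[k] - mix[k]) < 3 * se + 1e-9


class TestOutcome:
    def test_identical_distributions_p_one(self):
        summaries = [_summary(f"s{i}", count=1) for i in range(6)]
        outcomes = {f"s{i}": ("DOD" if i < 3 else "NED") for i in range(6)}
        out = outcome_burden(summaries, outcomes)
        assert out["overall"] == 1.0

    def test_strong_difference_detected(self):
        rng = np.random.default_rng(2)
        summaries = [_summary(f"d{i}", count=int(rng.poisson(3))) for i in range(20)]
        summaries += [_summary(f"n{i}", count=0) for i in range(20)]
        outcomes = {s.sample_id: ("DOD" if s.sample_id.startswith("d") else "NED")
                    for s in summaries}
        out = outcome_burden(summaries, outcomes)
        assert out["overall"] < 0.01

    def test_all_unknown_outcomes_rejected(self):
        summaries = [_summary("a"), _summary("b")]
        with pytest.raises(ValueError):
            outcome_burden(summaries, {"a": "unknown", "b": "unknown"})


class TestExclusions:
    def test_related_trio_keeps_designated_parent_only(self):
        summaries = [_summary("CL1", 2), _summary("CL1-a", 2), _summary("CL1-b", 2)]
        meta = _meta([("CL1", "cell_line", "CL1", "", ""),
                      ("CL1-a", "cell_line", "CL1", "", ""),
                      ("CL1-b", "cell_line", "CL1", "", "")])
        kept, log = apply_exclusions(summaries, meta)
        assert [s.sample_id for s in kept] == ["CL1"]
        assert len(log) == 2

    def test_unflagged_unrelated_cohort_passes_through(self):
        summaries = [_summary(f"NB{i}", 1) for i in range(4)]
        meta = _meta([(f"NB{i}", "tumor", "", "NED", "L") for i in range(4)])
        kept, log = apply_exclusions(summaries, meta)
        assert len(kept) == 4 and log.empty

    def test_stroma_like_tumor_patterns_removed_with_reasons(self):
        summaries = [_summary("t_flat", 0, flat=True),
                     _summary("t_mycn", 0, mycn=True),
                     _summary("t_loh", 2, loh_only=True),
                     _summary("t_ok", 1)]
        meta = _meta([(s.sample_id, "tumor", "", "", "") for s in summaries])
        kept, log = apply_exclusions(summaries, meta)
        assert [s.sample_id for s in kept] == ["t_ok"]
        assert set(log["reason"]) == {"flat profile", "MYCN amplification only",
                                      "CN-LOH only"}

    def test_flat_control_is_retained(self):
        summaries = [_summary("ctrl", 0, flat=True)]
        meta = _meta([("ctrl", "control", "", "", "")])
        kept, log = apply_exclusions(summaries, meta)
        assert len(kept) == 1 and log.empty

    def test_every_removed_sample_logged_exactly_once(self):
        rng = np.random.default_rng(4)
        summaries, rows = [], []
        for i in range(30):
            flat = bool(rng.random() < 0.3)
            summaries.append(_summary(f"s{i}", 0 if flat else 1, flat=flat))
            rows.append((f"s{i}", "tumor", "", "", ""))
        kept, log = apply_exclusions(summaries, _meta(rows))
        assert len(kept) + len(log) == 30
        assert log["sample_id"].is_unique

    def test_related_group_without_parent_rejected(self):
        summaries = [_summary("a", 1)]
        meta = _meta([("a", "cell_line", "ghost", "", "")])
        with pytest.raises(ValueError, match="ghost"):
            apply_exclusions(summaries, meta)


class TestRunCohortStats:
    def test_group_level_report_structure(self):
        rng = np.random.default_rng(6)
        summaries, rows = [], []
        for i in range(25):
            c = int(rng.poisson(0.9))
            summaries.append(_summary(f"NB{i}", c, loh_only=False))
            rows.append((f"NB{i}", "tumor", "", rng.choice(["DOD", "NED"]), "L"))
        for i in range(6):
            summaries.append(_summary(
                f"CL{i}", 2 + i % 2,
                extents={"INTERSTITIAL": 0, "TELOMERIC": 2 + i % 2,
                         "WHOLE_CHROMOSOME": 0}))
            rows.append((f"CL{i}", "cell_line", "", "", ""))
        res = run_cohort_stats(summaries, _meta(rows))
        assert res.n_per_group["cell_line"] == 6
        assert "cell_line_vs_tumor" in res.fisher_p
        assert "cell_line_vs_tumor" in res.mann_whitney_p
        assert res.spectrum["cell_line"]["TELOMERIC"] == 1.0
        assert res.outcome_p is not None

    def test_prevalence_fisher_median_consistent_with_published_rates(self):
        # presence/absence drawn at the published prevalences (47/134, 7/8)
        ps = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            kt = int(rng.binomial(134, 47 / 134))
            kc = int(rng.binomial(8, 7 / 8))
            ps.append(fisher_prevalence(kt, 134, kc, 8))
        assert 0.001 < float(np.median(ps)) < 0.02
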
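"""Group-level statistics over per-sample event summaries.

Implements the study's inclusion rules (X chromosome excluded from all
counts, one representative per related sample group, removal of profiles
whose appearance is compatible with almost pure stroma) and the group
comparisons: Fisher's exact test on the proportion of samples with at least
one near-CN-LOH event, the Mann-Whitney U test on per-sample event counts
(exact tie-aware permutation distribution for small group pairs), burden
descriptives, the extent spectrum per group, and the outcome comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .loh_caller import EXTENTS, SampleSummary

__all__ = [
    "apply_exclusions",
    "fisher_prevalence",
    "mw_burden",
    "describe_burden",
    "subtype_spectrum",
    "outcome_burden",
    "CohortResult",
    "run_cohort_stats",
]

EXACT_PRODUCT_LIMIT = 400  # use the exact permutation law when nA*nB <= this


def apply_exclusions(
    summaries: Sequence[SampleSummary], metadata: pd.DataFrame
) -> tuple[list[SampleSummary], pd.DataFrame]:
    """Inclusion filter: keep one representative per related group (the
    designated parent, i.e. the sample whose id equals the group label) and
    drop tumor samples whose profile pattern is compatible with almost pure
    stroma (flat_profile / mycn_amp_only / cn_loh_only). The stroma filter
    concerns contaminated tumor biopsies only: a flat constitutional control
    is the expected appearance, not an artifact.

    X-chromosome calls are already excluded from the summaries' counts.
    Returns (kept summaries, exclusion log with one row per removed sample).
    """
    meta = metadata.set_index("sample_id")
    log_rows: list[dict] = []
    kept: list[SampleSummary] = []
    related = metadata["related_group"].fillna("")
    for group_label in sorted(set(related) - {""}):
        members = metadata.loc[related == group_label, "sample_id"]
        if group_label not in set(members):
            raise ValueError(
                f"related group {group_label!r} has no designated parent sample")
    for s in summaries:
        if s.sample_id not in meta.index:
            raise ValueError(f"sample {s.sample_id} missing from metadata")
        rel = meta.at[s.sample_id, "related_group"]
        rel = "" if pd.isna(rel) else str(rel)
        if rel and s.sample_id != rel:
            log_rows.append({"sample_id": s.sample_id,
                             "reason": f"related to {rel}"})
            continue
        if str(meta.at[s.sample_id, "group"]) != "tumor":
            kept.append(s)
            continue
        if s.flat_profile:
            log_rows.append({"sample_id": s.sample_id, "reason": "flat profile"})
            continue
        if s.mycn_amp_only:
            log_rows.append({"sample_id": s.sample_id,
                             "reason": "MYCN amplification only"})
            continue
        if s.cn_loh_only:
            log_rows.append({"sample_id": s.sample_id, "reason": "CN-LOH only"})
            continue
        kept.append(s)
    log = pd.DataFrame(log_rows, columns=["sample_id", "reason"])
    return kept, log


def fisher_prevalence(k_a: int, n_a: int, k_b: int, n_b: int) -> float:
    """Two-sided Fisher exact p for prevalence k/n in two groups.

    Two-sided by the usual minimum-likelihood rule: the sum of probabilities
    of all tables (with the observed margins) no more probable than the
    observed one.
    """
    if n_a <= 0 or n_b <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= k_a <= n_a and 0 <= k_b <= n_b):
        raise ValueError("event counts must satisfy 0 <= k <= n")
    table = [[k_a, n_a - k_a], [k_b, n_b - k_b]]
    return float(stats.fisher_exact(table, alternative="two-sided").pvalue)


def _midranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def _exact_ranksum_pvalue(ranks_a: np.ndarray, ranks_all: np.ndarray) -> float:
    """Exact two-sided p for the rank sum of group A under random assignment.

    Shift-algorithm DP over subset sums of doubled midranks (midranks are
    multiples of 1/2, so doubling makes them integers); handles ties exactly.
    Two-sidedness: P(|S - E[S]| >= |s_obs - E[S]|).
    """
    n_a = len(ranks_a)
    n = len(ranks_all)
    d = np.rint(2.0 * ranks_all).astype(np.int64)
    s_obs = int(np.rint(2.0 * ranks_a.sum()))
    max_sum = int(d.sum())
    # counts[k, s] = number of k-subsets with doubled-rank sum s
    counts = np.zeros((n_a + 1, max_sum + 1))
    counts[0, 0] = 1.0
    for r in d:
        for k in range(n_a, 0, -1):  # downward so each item is used once
            counts[k, r:] += counts[k - 1, : max_sum + 1 - r]
    total = comb(n, n_a)
    dist = counts[n_a]
    assert abs(dist.sum() - total) / total < 1e-9
    e_s = n_a * d.sum() / n
    dev = abs(s_obs - e_s)
    sums = np.arange(max_sum + 1)
    p = dist[np.abs(sums - e_s) >= dev - 1e-9].sum() / total
    return float(min(p, 1.0))


def mw_burden(
    counts_a: Sequence[float], counts_b: Sequence[float], method: str = "auto"
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U comparison of per-sample event counts.

    Returns (p, U) with U the statistic of group A. ``method='exact'`` uses
    the full tie-aware permutation distribution of the rank sum (the default
    whenever nA*nB <= 400); ``'asymptotic'`` the tie-corrected normal
    approximation with continuity correction.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    ranks = _midranks(np.concatenate([a, b]))
    u_a = float(ranks[: len(a)].sum() - len(a) * (len(a) + 1) / 2.0)
    if method == "auto":
        method = "exact" if len(a) * len(b) <= EXACT_PRODUCT_LIMIT else "asymptotic"
    if method == "exact":
        p = _exact_ranksum_pvalue(ranks[: len(a)], ranks)
    elif method == "asymptotic":
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                     method="asymptotic").pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return p, u_a


def describe_burden(counts: Sequence[float]) -> dict[str, float]:
    """Median, mean and linear-interpolation quartiles of event counts."""
    c = np.asarray(counts, dtype=float)
    if len(c) == 0:
        raise ValueError("describe_burden requires a non-empty sample")
    return {
        "median": float(np.median(c)),
        "mean": float(np.mean(c)),
        "p25": float(np.percentile(c, 25)),
        "p75": float(np.percentile(c, 75)),
    }


def subtype_spectrum(counts_by_extent: Sequence[dict[str, int]]) -> dict[str, float]:
    """Fraction of near-CN-LOH events per extent over a group's samples.

    Returns an empty dict when the group has no events.
    """
    totals = {e: 0 for e in EXTENTS}
    for d in counts_by_extent:
        for e in EXTENTS:
            totals[e] += d.get(e, 0)
    n = sum(totals.values())
    if n == 0:
        return {}
    return {e: totals[e] / n for e in EXTENTS}


def outcome_burden(
    summaries: Sequence[SampleSummary], outcomes: dict[str, str]
) -> dict[str, float | None]:
    """Burden comparison between outcome categories (dead of disease vs no
    evidence of disease); samples with any other/unknown outcome are
    excluded. Returns a two-sided Mann-Whitney p overall and per extent
    (None where a group is empty)."""
    dod = [s for s in summaries if outcomes.get(s.sample_id) == "DOD"]
    ned = [s for s in summaries if outcomes.get(s.sample_id) == "NED"]
    if not dod and not ned:
        raise ValueError("no samples with a known binary outcome")
    out: dict[str, float | None] = {}

    def _p(get) -> float | None:
        if not dod or not ned:
            return None
        return mw_burden([get(s) for s in dod], [get(s) for s in ned])[0]

    out["overall"] = _p(lambda s: s.near_cn_loh_count)
    for e in EXTENTS:
        out[e] = _p(lambda s, e=e: s.counts_by_extent.get(e, 0))
    return out


@dataclass
class CohortResult:
    n_per_group: dict[str, int]
    prevalence: dict[str, dict]  # group -> {count, fraction}
    burden: dict[str, dict]  # group -> describe_burden output
    fisher_p: dict[str, float]  # "groupA_vs_groupB" -> p
    mann_whitney_p: dict[str, float]
    spectrum: dict[str, dict[str, float]]
    outcome_p: dict[str, float | None] | None
    exclusion_log: pd.DataFrame = field(repr=False, default=None)

    def to_json_dict(self) -> dict:
        return {
            "n_per_group": self.n_per_group,
            "prevalence": self.prevalence,
            "burden": self.burden,
            "fisher_p": self.fisher_p,
            "mann_whitney_p": self.mann_whitney_p,
            "spectrum": self.spectrum,
            "outcome_p": self.outcome_p,
        }


def run_cohort_stats(
    summaries: Sequence[SampleSummary], metadata: pd.DataFrame
) -> CohortResult:
    """Full cohort analysis: exclusions, per-group prevalence and burden,
    pairwise Fisher and Mann-Whitney tests, extent spectra and (for tumors)
    the outcome comparison."""
    kept, log = apply_exclusions(summaries, metadata)
    meta = metadata.set_index("sample_id")
    by_group: dict[str, list[SampleSummary]] = {}
    for s in kept:
        by_group.setdefault(str(meta.at[s.sample_id, "group"]), []).append(s)

    n_per_group = {g: len(v) for g, v in by_group.items()}
    prevalence, burden, spectrum = {}, {}, {}
    for g, members in by_group.items():
        counts = [s.near_cn_loh_count for s in members]
        k = sum(1 for c in counts if c > 0)
        prevalence[g] = {"count": k, "n": len(members),
                         "fraction": k / len(members)}
        burden[g] = describe_burden(counts)
        spectrum[g] = subtype_spectrum([s.counts_by_extent for s in members])

    fisher_p, mw_p = {}, {}
    for ga, gb in combinations(sorted(by_group), 2):
        key = f"{ga}_vs_{gb}"
        pa, pb = prevalence[ga], prevalence[gb]
        fisher_p[key] = fisher_prevalence(pa["count"], pa["n"], pb["count"], pb["n"])
        mw_p[key] = mw_burden(
            [s.near_cn_loh_count for s in by_group[ga]],
            [s.near_cn_loh_count for s in by_group[gb]])[0]

    outcome_p = None
    tumors = by_group.get("tumor", [])
    if tumors:
        outcomes = {sid: str(meta.at[sid, "outcome"])
                    for sid in (s.sample_id for s in tumors)}
        if any(v in ("DOD", "NED") for v in outcomes.values()):
            outcome_p = outcome_burden(tumors, outcomes)

    return CohortResult(
        n_per_group=n_per_group, prevalence=prevalence, burden=burden,
        fisher_p=fisher_p, mann_whitney_p=mw_p, spectrum=spectrum,
        outcome_p=outcome_p, exclusion_log=log,
    )
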
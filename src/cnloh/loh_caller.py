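"""Event taxonomy for fitted allelic states.

"Near copy-neutral LOH" is judged relative to the sample's own ploidy: with
an overall ploidy near 3, both 2+0 and 3+0 are LOH at least partially
compensated by the remaining allele, while the same 3+0 in a diploid genome
is LOH combined with gain (gain-LOH). Calls are labeled by extent —
interstitial, telomeric (reaching one chromosome end) or whole-chromosome —
and summarized per sample, including the stromal-contamination warning flags
(flat profile / amplification-only / CN-LOH-only) used as exclusion criteria
in the cohort statistics.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import MYCN_LOCUS, MarkerMap
from .state_fit import AllelicState, FittedSegment, SampleFit

__all__ = [
    "LohCall",
    "SampleSummary",
    "classify_allelic_event",
    "classify_extent",
    "calls_from_fit",
    "sample_event_summary",
    "compare_profiles",
    "MIN_EVENT_SIZE_BP",
]

CATEGORIES = ("NEAR_CN_LOH", "GAIN_LOH", "LOSS_LOH", "ALLELIC_IMBALANCE", "BALANCED")
EXTENTS = ("INTERSTITIAL", "TELOMERIC", "WHOLE_CHROMOSOME")
MIN_EVENT_SIZE_BP = 1_500_000  # reporting threshold for aberrations


def _balanced_split(total: int) -> AllelicState:
    return AllelicState((total + 1) // 2, total // 2)


def classify_allelic_event(state: AllelicState | tuple[int, int], sample_ploidy: float) -> str:
    """Category of an allelic state relative to the sample's overall ploidy.

    With P = round(sample_ploidy): minor = 0 and 2 <= total <= P is near
    CN-LOH; minor = 0 and total > P is gain-LOH; minor = 0 and total < 2 is
    loss-LOH (classical hemizygous or homozygous deletion). A state with
    retained heterozygosity deviating from the most balanced split of its
    total (e.g. 3+1 instead of 2+2) is an allelic imbalance; otherwise the
    state is balanced.
    """
    if sample_ploidy <= 0:
        raise ValueError("sample_ploidy must be > 0")
    a, b = state
    p = int(round(sample_ploidy))
    total = a + b
    if b == 0:
        if total < 2:
            return "LOSS_LOH"
        if total <= p:
            return "NEAR_CN_LOH"
        return "GAIN_LOH"
    if (a, b) != tuple(_balanced_split(total)):
        return "ALLELIC_IMBALANCE"
    return "BALANCED"


def classify_extent(
    start_bp: int, end_bp: int, marker_positions: np.ndarray, tol_markers: int = 5
) -> str:
    """Extent of a call relative to the chromosome's marker extent.

    Reaching both the first and last marker (within ``tol_markers`` markers)
    is a whole-chromosome event; exactly one end, telomeric; neither,
    interstitial. Whole-chromosome takes precedence over telomeric.
    """
    pos = np.asarray(marker_positions)
    n_before = int((pos < start_bp).sum())
    n_after = int((pos > end_bp).sum())
    at_left = n_before < tol_markers
    at_right = n_after < tol_markers
    if at_left and at_right:
        return "WHOLE_CHROMOSOME"
    if at_left or at_right:
        return "TELOMERIC"
    return "INTERSTITIAL"


@dataclass(frozen=True)
class LohCall:
    sample_id: str
    chrom: str
    start_bp: int
    end_bp: int
    state: AllelicState
    category: str
    extent: str
    amplification: bool = False

    @property
    def size_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    @property
    def size_mb(self) -> float:
        return self.size_bp / 1e6


@dataclass
class SampleSummary:
    sample_id: str
    near_cn_loh_count: int  # autosomes only, >= size threshold
    counts_by_extent: dict[str, int]
    aberrant_segment_count: int
    flat_profile: bool
    mycn_amp_only: bool
    cn_loh_only: bool
    overall_ploidy: float = float("nan")
    rho: float = float("nan")


def _modal_state(fit: SampleFit) -> AllelicState:
    weights: dict[AllelicState, float] = {}
    for fs in fit.segments:
        if fs.amplification:
            continue
        weights[fs.state] = weights.get(fs.state, 0.0) + fs.segment.marker_count
    if not weights:
        return AllelicState(1, 1)
    return max(sorted(weights), key=lambda s: weights[s])


def calls_from_fit(
    fit: SampleFit, marker_map: MarkerMap, tol_markers: int = 5
) -> list[LohCall]:
    """One call per merged fitted segment whose state deviates from the
    sample's modal (marker-weighted most frequent) state — the aberrations of
    the profile. Apply :func:`cnloh.segmentation.merge_adjacent` first so one
    biological event yields one call.
    """
    modal = _modal_state(fit)
    calls: list[LohCall] = []
    for fs in fit.segments:
        if fs.state == modal and not fs.amplification:
            continue
        category = classify_allelic_event(fs.state, fit.overall_ploidy)
        extent = classify_extent(
            fs.segment.start_bp, fs.segment.end_bp,
            marker_map.positions[fs.chrom], tol_markers)
        calls.append(LohCall(
            sample_id=fit.sample_id, chrom=fs.chrom,
            start_bp=fs.segment.start_bp, end_bp=fs.segment.end_bp,
            state=fs.state, category=category, extent=extent,
            amplification=fs.amplification))
    return calls


def _at_mycn_locus(call: LohCall) -> bool:
    chrom, lo, hi = MYCN_LOCUS
    return call.chrom == chrom and call.start_bp <= hi and call.end_bp >= lo


def sample_event_summary(
    calls: Sequence[LohCall],
    fit: SampleFit,
    min_event_size_bp: int = MIN_EVENT_SIZE_BP,
) -> SampleSummary:
    """Per-sample event burden and stroma-warning flags.

    Calls smaller than the reporting threshold are dropped. The near-CN-LOH
    burden counts autosomal events only. ``flat_profile`` means no reportable
    aberration at all; ``mycn_amp_only`` that the only aberrations are
    amplifications at the designated 2p locus; ``cn_loh_only`` that every
    aberration is a near-CN-LOH event — all three patterns are consistent
    with an almost purely stromal sample and are excluded from cohort
    statistics.
    """
    kept = [c for c in calls if c.size_bp >= min_event_size_bp]
    aberrant = len(kept)
    loh = [c for c in kept if c.category == "NEAR_CN_LOH" and c.chrom != "chrX"]
    by_extent = Counter(c.extent for c in loh)
    flat = aberrant == 0
    mycn_only = aberrant > 0 and all(c.amplification and _at_mycn_locus(c) for c in kept)
    loh_only = aberrant > 0 and all(c.category == "NEAR_CN_LOH" for c in kept)
    return SampleSummary(
        sample_id=fit.sample_id,
        near_cn_loh_count=len(loh),
        counts_by_extent={e: by_extent.get(e, 0) for e in EXTENTS},
        aberrant_segment_count=aberrant,
        flat_profile=flat,
        mycn_amp_only=mycn_only,
        cn_loh_only=loh_only,
        overall_ploidy=fit.overall_ploidy,
        rho=fit.rho,
    )


# ---------------------------------------------------------------------------
# cross-sample profile comparison

def _reciprocal_overlap(a: LohCall, b: LohCall) -> float:
    inter = min(a.end_bp, b.end_bp) - max(a.start_bp, b.start_bp) + 1
    if inter <= 0:
        return 0.0
    return min(inter / a.size_bp, inter / b.size_bp)


def compare_profiles(
    calls_by_sample: dict[str, Sequence[LohCall]],
    reciprocal_overlap_frac: float = 0.5,
    min_event_size_bp: int = MIN_EVENT_SIZE_BP,
) -> pd.DataFrame:
    """Shared / subset-shared / unique aberrations across related samples.

    Two aberrations are the same event when their reciprocal overlap is at
    least ``reciprocal_overlap_frac`` AND their allelic states are identical;
    aberrations that overlap but fail either condition are flagged as
    "partial (distinct events)". Returns one row per matched event cluster
    with a sharing label.
    """
    if len(calls_by_sample) < 2:
        raise ValueError("compare_profiles needs at least two samples")
    samples = list(calls_by_sample)
    items: list[tuple[str, LohCall]] = []
    for sid in samples:
        for c in calls_by_sample[sid]:
            if c.size_bp >= min_event_size_bp:
                items.append((sid, c))

    # union-find over matching aberrations
    parent = list(range(len(items)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    partial: set[int] = set()
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            si, ci = items[i]
            sj, cj = items[j]
            if si == sj or ci.chrom != cj.chrom:
                continue
            ov = _reciprocal_overlap(ci, cj)
            if ov <= 0:
                continue
            if ov >= reciprocal_overlap_frac and ci.state == cj.state:
                union(i, j)
            else:
                partial.update((i, j))

    clusters: dict[int, list[int]] = {}
    for i in range(len(items)):
        clusters.setdefault(find(i), []).append(i)
    rows = []
    for members in clusters.values():
        sids = sorted({items[i][0] for i in members})
        c0 = items[members[0]][1]
        if len(sids) == len(samples):
            label = "shared_by_all"
        elif len(sids) > 1:
            label = "shared_by_subset"
        else:
            label = "unique"
        rows.append({
            "chrom": c0.chrom,
            "start_bp": min(items[i][1].start_bp for i in members),
            "end_bp": max(items[i][1].end_bp for i in members),
            "state": str(c0.state),
            "category": c0.category,
            "samples": ",".join(sids),
            "n_samples": len(sids),
            "label": label,
            "partial_overlap": any(i in partial for i in members),
        })
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["chrom", "start_bp"], ignore_index=True)
    return df


def calls_to_frame(calls: Iterable[LohCall]) -> pd.DataFrame:
    """TSV-ready table of calls (sizes in Mb)."""
    return pd.DataFrame([
        {"sample": c.sample_id, "chrom": c.chrom, "start": c.start_bp,
         "end": c.end_bp, "major": c.state.a, "minor": c.state.b,
         "category": c.category, "extent": c.extent,
         "size_mb": round(c.size_mb, 3)}
        for c in calls
    ])
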
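"""End-to-end per-sample and cohort drivers.

Chains the stages: observed SNP table -> allele tracks -> change-point
segments -> (rho, ploidy, states) grid fit -> merged calls -> summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .genome import MarkerMap, make_marker_map
from .loh_caller import (LohCall, SampleSummary, calls_from_fit,
                         sample_event_summary)
from .segmentation import merge_adjacent, segment_sample
from .signal_model import SnpTable, allele_fraction_tracks
from .sim_cohort import CohortConfig, iter_cohort
from .state_fit import FitGrid, SampleFit, fit_sample

__all__ = ["SampleResult", "analyze_sample", "analyze_cohort"]


@dataclass
class SampleResult:
    fit: SampleFit
    calls: list[LohCall]
    summary: SampleSummary


def analyze_sample(
    snp: SnpTable,
    marker_map: MarkerMap,
    min_markers: int = 25,
    penalty: float | None = None,
    grid: FitGrid | None = None,
    min_event_size_bp: int | None = None,
) -> SampleResult:
    """Run the full per-sample pipeline on an observed table.

    The total-ratio track of the input is assumed already normalized
    (autosomal median 1); apply :func:`cnloh.signal_model.normalized_total_ratio`
    first when starting from raw intensities and reference samples.
    """
    from .loh_caller import MIN_EVENT_SIZE_BP

    tracks = allele_fraction_tracks(snp)
    segments = segment_sample(tracks, min_markers=min_markers, penalty=penalty)
    fit = fit_sample(segments, sample_id=snp.sample_id, grid=grid)
    fit.segments = merge_adjacent(fit.segments)
    calls = calls_from_fit(fit, marker_map)
    summary = sample_event_summary(
        calls, fit,
        min_event_size_bp=MIN_EVENT_SIZE_BP if min_event_size_bp is None else min_event_size_bp)
    return SampleResult(fit=fit, calls=calls, summary=summary)


def analyze_cohort(
    config: CohortConfig,
    marker_map: MarkerMap | None = None,
    min_markers: int = 25,
    grid: FitGrid | None = None,
    keep_truth: bool = False,
):
    """Simulate and analyze a whole cohort sample-by-sample (memory-light).

    Returns (results, metadata DataFrame[, truths]) where ``results`` maps
    sample_id -> SampleResult.
    """
    mm = marker_map or make_marker_map(marker_spacing_bp=config.marker_spacing_bp)
    results: dict[str, SampleResult] = {}
    truths = {}
    rows = []
    for sample in iter_cohort(config, marker_map=mm):
        res = analyze_sample(sample.snp, mm, min_markers=min_markers, grid=grid)
        results[sample.truth.sample_id] = res
        rows.append(sample.meta)
        if keep_truth:
            truths[sample.truth.sample_id] = sample.truth
    meta = pd.DataFrame(rows)
    if keep_truth:
        return results, meta, truths
    return results, meta
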
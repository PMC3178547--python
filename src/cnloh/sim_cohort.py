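"""Synthetic SNP-array cohorts with known ground truth.

The generator emulates the study conditions this pipeline targets: a mapping
array's regular marker grid over 22 autosomes + X, per-chromosome integer
allelic states from near-diploid to near-pentasomic, stromal contamination
that regenerates heterozygous-looking calls inside somatically LOH regions,
germline identity-by-descent runs in constitutional samples, and additive
Gaussian measurement noise on both the total-ratio and B-allele-fraction
channels. Every sample carries a truth profile so each downstream stage can
be scored exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Literal

import numpy as np
import pandas as pd

from .genome import CHROM_LENGTHS_BP, MYCN_LOCUS, MarkerMap, make_marker_map
from .signal_model import SnpTable
from .state_fit import AllelicState, expected_signals

log = logging.getLogger(__name__)

__all__ = [
    "TrueSegment",
    "TrueEvent",
    "TruthProfile",
    "CohortConfig",
    "simulate_truth_profile",
    "simulate_snp_table",
    "simulate_cohort",
    "iter_cohort",
]

ProfileType = Literal[
    "flat_diploid", "numerical_near_triploid", "mycn_segmental",
    "del11q_segmental", "control",
]
PROFILE_TYPES = ("flat_diploid", "numerical_near_triploid", "mycn_segmental",
                 "del11q_segmental", "control")

EXTENTS = ("INTERSTITIAL", "TELOMERIC", "WHOLE_CHROMOSOME")

# event size ranges (bp); chosen to clear the 1.5 Mb reporting threshold
INTERSTITIAL_SIZE = (2_000_000, 10_000_000)
TELOMERIC_SIZE = (5_000_000, 30_000_000)
_EDGE_MARGIN = 2_500_000  # keeps interstitial events clear of chromosome ends
_EVENT_GAP = 2_000_000  # minimum separation between injected events

#: split of a total copy number into the most balanced (major, minor) pair
def _balanced_split(total: int) -> AllelicState:
    return AllelicState((total + 1) // 2, total // 2)


@dataclass(frozen=True)
class TrueSegment:
    chrom: str
    start_bp: int  # 1-based inclusive
    end_bp: int
    state: AllelicState
    origin: str = "background"  # background | somatic | germlineIBD


@dataclass(frozen=True)
class TrueEvent:
    """An injected LOH event with its ground-truth extent label."""

    chrom: str
    start_bp: int
    end_bp: int
    state: AllelicState
    origin: str
    extent: str

    @property
    def size_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass
class TruthProfile:
    sample_id: str
    profile_type: str
    segments: list[TrueSegment]
    events: list[TrueEvent]
    rho: float = 0.0

    def chrom_segments(self, chrom: str) -> list[TrueSegment]:
        return [s for s in self.segments if s.chrom == chrom]

    def validate_tiling(self, lengths: dict[str, int]) -> None:
        for chrom, length in lengths.items():
            segs = sorted(self.chrom_segments(chrom), key=lambda s: s.start_bp)
            if not segs or segs[0].start_bp != 1 or segs[-1].end_bp != length:
                raise ValueError(f"truth segments do not tile {chrom}")
            for a, b in zip(segs[:-1], segs[1:]):
                if b.start_bp != a.end_bp + 1:
                    raise ValueError(f"gap/overlap in truth segments on {chrom}")


# ---------------------------------------------------------------------------
# truth simulation

def _background_states(
    profile_type: str, lengths: dict[str, int], rng: np.random.Generator
) -> dict[str, list[TrueSegment]]:
    segs: dict[str, list[TrueSegment]] = {}
    for chrom, length in lengths.items():
        if profile_type == "numerical_near_triploid" and chrom != "chrX":
            total = int(rng.choice([2, 3, 4, 5], p=[0.25, 0.40, 0.20, 0.15]))
            state = _balanced_split(total)
        else:
            state = AllelicState(1, 1)
        segs[chrom] = [TrueSegment(chrom, 1, length, state)]
    if profile_type == "mycn_segmental":
        chrom, lo, hi = MYCN_LOCUS
        _replace_interval(segs, chrom, lo + 500_000, hi - 500_000,
                          AllelicState(24, 1), "somatic")
        _replace_interval(segs, "chr17", 40_000_000, lengths["chr17"],
                          AllelicState(2, 1), "somatic")
        _replace_interval(segs, "chr1", 1, 10_000_000, AllelicState(1, 0), "somatic")
    elif profile_type == "del11q_segmental":
        _replace_interval(segs, "chr11", 70_000_000, lengths["chr11"],
                          AllelicState(1, 0), "somatic")
        _replace_interval(segs, "chr17", 40_000_000, lengths["chr17"],
                          AllelicState(2, 1), "somatic")
    return segs


def _replace_interval(
    segs: dict[str, list[TrueSegment]], chrom: str, start: int, end: int,
    state: AllelicState, origin: str,
) -> None:
    """Carve [start, end] out of the tiling and assign it a new state."""
    out: list[TrueSegment] = []
    for s in segs[chrom]:
        if s.end_bp < start or s.start_bp > end:
            out.append(s)
            continue
        if s.start_bp < start:
            out.append(replace(s, end_bp=start - 1))
        if s.end_bp > end:
            out.append(replace(s, start_bp=end + 1))
    out.append(TrueSegment(chrom, start, end, state, origin))
    segs[chrom] = sorted(out, key=lambda s: s.start_bp)


def _weighted_background_ploidy(
    segs: dict[str, list[TrueSegment]], lengths: dict[str, int]
) -> float:
    num = den = 0.0
    for chrom in lengths:
        if chrom == "chrX":
            continue
        for s in segs[chrom]:
            if s.origin != "background" or s.state.total > 12:
                continue
            w = s.end_bp - s.start_bp + 1
            num += w * s.state.total
            den += w
    return num / den if den else 2.0


def _free_intervals(
    segs: list[TrueSegment], existing_events: list[TrueEvent], chrom_len: int
) -> list[tuple[int, int]]:
    """Background stretches, shrunk by the inter-event gap."""
    taken = [(s.start_bp, s.end_bp) for s in segs if s.origin != "background"]
    taken += [(e.start_bp, e.end_bp) for e in existing_events]
    taken.sort()
    free: list[tuple[int, int]] = []
    cursor = 1
    for a, b in taken:
        if a - _EVENT_GAP > cursor:
            free.append((cursor, a - _EVENT_GAP))
        cursor = max(cursor, b + _EVENT_GAP)
    if cursor <= chrom_len:
        free.append((cursor, chrom_len))
    return free


def simulate_truth_profile(
    profile_type: str,
    event_rate: float,
    subtype_mix: tuple[float, float, float],
    marker_map: MarkerMap,
    rng: np.random.Generator,
    sample_id: str = "",
    rho: float = 0.0,
) -> TruthProfile:
    """Draw a ground-truth profile: background states per profile type plus
    Poisson(event_rate) injected near-CN-LOH events whose extents follow
    ``subtype_mix`` = (interstitial, telomeric, whole-chromosome).

    Control profiles inject germline IBD runs (total 2, minor 0); all other
    profiles inject somatic events with total copies between 2 and the
    rounded background ploidy. Events are placed on autosomes only, in
    background regions, with a minimum separation so that one injected event
    maps to one recovered event.
    """
    if profile_type not in PROFILE_TYPES:
        raise ValueError(f"unknown profile type: {profile_type!r}")
    mix = np.asarray(subtype_mix, dtype=float)
    if mix.min() < 0 or abs(mix.sum() - 1.0) > 1e-9:
        raise ValueError("subtype mix must be a probability vector")
    lengths = marker_map.lengths_bp
    segs = _background_states(profile_type, lengths, rng)
    # conservative cap for event totals: injected events (totals at or below
    # the genome ploidy) pull the realized marker-weighted ploidy down, so
    # near a rounding boundary the cap must not round up — otherwise an
    # injected "near copy-neutral" event could end up above the realized
    # rounded ploidy and classify as gain-LOH instead
    ploidy_ref = max(2, int(np.floor(_weighted_background_ploidy(segs, lengths) + 0.2)))
    origin = "germlineIBD" if profile_type == "control" else "somatic"
    events: list[TrueEvent] = []
    n_events = int(rng.poisson(event_rate)) if event_rate > 0 else 0
    autosomes = [c for c in lengths if c != "chrX"]
    for _ in range(n_events):
        extent = EXTENTS[int(rng.choice(3, p=mix))]
        if origin == "germlineIBD":
            total = 2
        else:
            total = int(rng.integers(2, ploidy_ref + 1))
        state = AllelicState(total, 0)
        placed = False
        for _try in range(50):
            chrom = autosomes[int(rng.integers(len(autosomes)))]
            length = lengths[chrom]
            free = _free_intervals(segs[chrom], [e for e in events if e.chrom == chrom], length)
            if extent == "WHOLE_CHROMOSOME":
                if len(segs[chrom]) == 1 and segs[chrom][0].origin == "background" \
                        and not any(e.chrom == chrom for e in events):
                    start, end = 1, length
                else:
                    continue
            elif extent == "TELOMERIC":
                size = int(rng.uniform(*TELOMERIC_SIZE))
                side = int(rng.integers(2))
                start, end = (1, size) if side == 0 else (length - size + 1, length)
                if not any(a <= start and end <= b for a, b in free):
                    continue
            else:  # INTERSTITIAL
                size = int(rng.uniform(*INTERSTITIAL_SIZE))
                cands = [(a, b) for a, b in free
                         if max(a, 1 + _EDGE_MARGIN) + size - 1 <= min(b, length - _EDGE_MARGIN)]
                if not cands:
                    continue
                a, b = cands[int(rng.integers(len(cands)))]
                lo = max(a, 1 + _EDGE_MARGIN)
                hi = min(b, length - _EDGE_MARGIN) - size + 1
                start = int(rng.integers(lo, hi + 1))
                end = start + size - 1
            _replace_interval(segs, chrom, start, end, state, origin)
            events.append(TrueEvent(chrom, start, end, state, origin, extent))
            placed = True
            break
        if not placed:
            log.warning("could not place a %s event for %s; skipped", extent, sample_id)
    all_segs = [s for chrom in lengths for s in segs[chrom]]
    profile = TruthProfile(sample_id=sample_id, profile_type=profile_type,
                           segments=all_segs, events=events, rho=rho)
    profile.validate_tiling(lengths)
    return profile


# ---------------------------------------------------------------------------
# observable simulation

HET_CALL_WINDOW = (0.10, 0.90)  # inclusive BAF window for an AB genotype call


def _marker_states(profile: TruthProfile, marker_map: MarkerMap):
    """Per-marker (a, b, is_ibd) arrays, concatenated in map order."""
    a_list, b_list, ibd_list = [], [], []
    for chrom in marker_map.chroms:
        pos = marker_map.positions[chrom]
        segs = sorted(profile.chrom_segments(chrom), key=lambda s: s.start_bp)
        if not segs:
            raise ValueError(f"truth profile missing segments on {chrom}")
        starts = np.array([s.start_bp for s in segs])
        idx = np.searchsorted(starts, pos, side="right") - 1
        if (idx < 0).any():
            raise ValueError(f"marker before first truth segment on {chrom}")
        ends = np.array([s.end_bp for s in segs])
        if (pos > ends[idx]).any():
            raise ValueError(f"truth segments do not cover all markers on {chrom}")
        a_list.append(np.array([segs[i].state.a for i in idx]))
        b_list.append(np.array([segs[i].state.b for i in idx]))
        ibd_list.append(np.array([segs[i].origin == "germlineIBD" for i in idx]))
    return np.concatenate(a_list), np.concatenate(b_list), np.concatenate(ibd_list)


def simulate_snp_table(
    truth: TruthProfile,
    marker_map: MarkerMap,
    rng: np.random.Generator,
    germline_het_prob: float = 0.30,
    noise_sd: float = 0.05,
) -> SnpTable:
    """Generate the observed per-marker table for one sample.

    Germline genotypes are heterozygous with probability ``germline_het_prob``
    except inside germline IBD runs (forced homozygous). Observed signals
    follow the stromal-mixture model: a fraction ``rho`` of diploid normal
    cells is blended with the tumor state, the total ratio is centered so its
    autosomal median is 1, and Gaussian noise is added to both channels (BAF
    truncated to [0, 1]). The genotype call thresholds the observed BAF: AB
    within [0.10, 0.90], else AA/BB — wide enough that contamination
    regenerates heterozygous calls inside somatic LOH from rho = 0.2 up.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not 0 < germline_het_prob < 1:
        raise ValueError("germline_het_prob must be in (0, 1)")
    rho = truth.rho
    a, b, ibd = _marker_states(truth, marker_map)
    n = len(a)
    chrom_col = np.concatenate(
        [np.repeat(c, len(marker_map.positions[c])) for c in marker_map.chroms]
    )
    pos_col = np.concatenate([marker_map.positions[c] for c in marker_map.chroms])
    auto = chrom_col != "chrX"

    het = rng.random(n) < germline_het_prob
    het &= ~ibd
    b_on_major = rng.random(n) < 0.5
    hom_is_bb = rng.random(n) < 0.5

    c_total = 2.0 * rho + (1.0 - rho) * (a + b)
    tumor_b = np.where(b_on_major, a, b)
    c_b = np.where(
        het, rho + (1.0 - rho) * tumor_b,
        np.where(hom_is_bb, c_total, 0.0),
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        baf = np.where(c_total > 0, c_b / np.where(c_total > 0, c_total, 1.0), 0.5)
    med = np.median(c_total[auto])
    t = c_total / med
    if noise_sd > 0:
        t = np.maximum(t + rng.normal(0.0, noise_sd, n), 0.0)
        baf = np.clip(baf + rng.normal(0.0, noise_sd, n), 0.0, 1.0)
    lo, hi = HET_CALL_WINDOW
    call = np.where((baf >= lo) & (baf <= hi), "AB", np.where(baf < lo, "AA", "BB"))
    df = pd.DataFrame(
        {"chrom": chrom_col, "pos": pos_col, "total_ratio": t, "baf": baf, "call": call}
    )
    return SnpTable(sample_id=truth.sample_id, df=df)


# ---------------------------------------------------------------------------
# whole-cohort simulation

@dataclass
class CohortConfig:
    """Study-scale defaults: 134 tumors, 10 cell lines (one related trio,
    leaving 8 after the relatedness exclusion) and 30 healthy controls;
    group event-rate means 0.89 / 2.4 / 0.10 events per sample and extent
    mixtures (interstitial, telomeric, whole-chromosome) of 50/15/35,
    5/74/21 and 100/0/0 percent."""

    n_tumors: int = 134
    n_cell_lines: int = 10
    n_controls: int = 30
    event_rate: dict = field(default_factory=lambda: {
        "tumor": 0.89, "cell_line": 2.4, "control": 0.10})
    subtype_mix: dict = field(default_factory=lambda: {
        "tumor": (0.50, 0.15, 0.35),
        "cell_line": (0.05, 0.74, 0.21),
        "control": (1.0, 0.0, 0.0)})
    tumor_profile_mix: dict = field(default_factory=lambda: {
        "numerical_near_triploid": 0.45, "mycn_segmental": 0.20,
        "del11q_segmental": 0.20, "flat_diploid": 0.15})
    cell_line_profile_mix: dict = field(default_factory=lambda: {
        "numerical_near_triploid": 0.50, "mycn_segmental": 0.20,
        "del11q_segmental": 0.30})
    tumor_rho_range: tuple[float, float] = (0.2, 0.6)
    noise_sd: float = 0.05
    germline_het_prob: float = 0.30
    marker_spacing_bp: int = 12_000  # 250K-mapping-array-like density
    related_trio: bool = True  # first 3 cell lines form parent + 2 subclones
    trio_extra_event_rate: float = 1.5  # unique events added to each subclone
    seed: int = 0

    def __post_init__(self) -> None:
        for grp, mix in self.subtype_mix.items():
            m = np.asarray(mix, float)
            if m.min() < 0 or abs(m.sum() - 1.0) > 1e-9:
                raise ValueError(f"subtype mix for {grp} is not a probability vector")
        for mix in (self.tumor_profile_mix, self.cell_line_profile_mix):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError("profile-type mix must sum to 1")
        if any(r < 0 for r in self.event_rate.values()):
            raise ValueError("event rates must be >= 0")


@dataclass
class CohortSample:
    truth: TruthProfile
    snp: SnpTable
    meta: dict


def _draw_profile_type(mix: dict, rng: np.random.Generator) -> str:
    keys = list(mix)
    return keys[int(rng.choice(len(keys), p=np.array([mix[k] for k in keys])))]


def _subclone(
    parent: TruthProfile, sample_id: str, extra_rate: float,
    subtype_mix, marker_map: MarkerMap, rng: np.random.Generator,
) -> TruthProfile:
    """A cell-line subclone: the parent's truth plus extra unique events."""
    extra = simulate_truth_profile(
        parent.profile_type, extra_rate, subtype_mix, marker_map, rng,
        sample_id=sample_id, rho=0.0)
    # rebuild: start from the parent's segments, then overlay extra events
    segs = {c: list(s for s in parent.segments if s.chrom == c)
            for c in marker_map.chroms}
    events = list(parent.events)
    for ev in extra.events:
        overlaps = any(e.chrom == ev.chrom
                       and not (e.end_bp < ev.start_bp - _EVENT_GAP
                                or e.start_bp > ev.end_bp + _EVENT_GAP)
                       for e in events)
        covered = all(s.origin == "background"
                      for s in segs[ev.chrom]
                      if not (s.end_bp < ev.start_bp or s.start_bp > ev.end_bp))
        if overlaps or not covered:
            continue
        _replace_interval(segs, ev.chrom, ev.start_bp, ev.end_bp, ev.state, ev.origin)
        events.append(ev)
    all_segs = [s for c in marker_map.chroms for s in sorted(segs[c], key=lambda s: s.start_bp)]
    prof = TruthProfile(sample_id=sample_id, profile_type=parent.profile_type,
                        segments=all_segs, events=events, rho=0.0)
    prof.validate_tiling(marker_map.lengths_bp)
    return prof


def iter_cohort(
    config: CohortConfig, marker_map: MarkerMap | None = None
) -> Iterator[CohortSample]:
    """Yield cohort samples one at a time (truth + observed table + metadata).

    Fully deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    mm = marker_map or make_marker_map(marker_spacing_bp=config.marker_spacing_bp)

    stage_probs = np.array([66, 51, 4, 13], float) / 134.0
    stages = ["L", "M", "MS", "unknown"]
    outcome_probs = [0.40, 0.45, 0.15]
    outcomes = ["DOD", "NED", "unknown"]

    for i in range(config.n_tumors):
        sid = f"NB{i + 1:03d}"
        ptype = _draw_profile_type(config.tumor_profile_mix, rng)
        rho = float(rng.uniform(*config.tumor_rho_range))
        truth = simulate_truth_profile(
            ptype, config.event_rate["tumor"], config.subtype_mix["tumor"],
            mm, rng, sample_id=sid, rho=rho)
        snp = simulate_snp_table(truth, mm, rng, config.germline_het_prob,
                                 config.noise_sd)
        meta = {
            "sample_id": sid, "group": "tumor", "related_group": "",
            "outcome": outcomes[int(rng.choice(3, p=outcome_probs))],
            "stage": stages[int(rng.choice(4, p=stage_probs))],
        }
        yield CohortSample(truth, snp, meta)

    trio_parent: TruthProfile | None = None
    for i in range(config.n_cell_lines):
        sid = f"CL{i + 1:03d}"
        in_trio = config.related_trio and config.n_cell_lines >= 3 and i < 3
        if in_trio and i == 0:
            ptype = _draw_profile_type(config.cell_line_profile_mix, rng)
            truth = simulate_truth_profile(
                ptype, config.event_rate["cell_line"],
                config.subtype_mix["cell_line"], mm, rng, sample_id=sid, rho=0.0)
            trio_parent = truth
            related = "CL001"
        elif in_trio:
            assert trio_parent is not None
            sid = f"CL001-s{i}"
            truth = _subclone(trio_parent, sid, config.trio_extra_event_rate,
                              config.subtype_mix["cell_line"], mm, rng)
            related = "CL001"
        else:
            ptype = _draw_profile_type(config.cell_line_profile_mix, rng)
            truth = simulate_truth_profile(
                ptype, config.event_rate["cell_line"],
                config.subtype_mix["cell_line"], mm, rng, sample_id=sid, rho=0.0)
            related = ""
        snp = simulate_snp_table(truth, mm, rng, config.germline_het_prob,
                                 config.noise_sd)
        meta = {"sample_id": truth.sample_id, "group": "cell_line",
                "related_group": related, "outcome": "", "stage": ""}
        yield CohortSample(truth, snp, meta)

    for i in range(config.n_controls):
        sid = f"CTRL{i + 1:03d}"
        truth = simulate_truth_profile(
            "control", config.event_rate["control"],
            config.subtype_mix["control"], mm, rng, sample_id=sid, rho=0.0)
        snp = simulate_snp_table(truth, mm, rng, config.germline_het_prob,
                                 config.noise_sd)
        meta = {"sample_id": sid, "group": "control", "related_group": "",
                "outcome": "", "stage": ""}
        yield CohortSample(truth, snp, meta)


def simulate_cohort(
    config: CohortConfig,
    out_dir: str | Path | None = None,
    overwrite: bool = False,
    marker_map: MarkerMap | None = None,
) -> pd.DataFrame:
    """Simulate the full cohort; if ``out_dir`` is given, write one SnpTable
    per sample under ``snp/``, a ``metadata.tsv`` and a ``truth_segments.tsv``
    (byte-identical across runs with the same config + seed). Returns the
    metadata table.
    """
    rows, truth_rows = [], []
    writer = None
    if out_dir is not None:
        out = Path(out_dir)
        snp_dir = out / "snp"
        if snp_dir.exists() and any(snp_dir.iterdir()) and not overwrite:
            raise FileExistsError(f"{snp_dir} exists; pass overwrite=True to replace")
        snp_dir.mkdir(parents=True, exist_ok=True)
        writer = snp_dir
    for sample in iter_cohort(config, marker_map=marker_map):
        rows.append(sample.meta)
        for seg in sample.truth.segments:
            truth_rows.append({
                "sample_id": sample.truth.sample_id, "chrom": seg.chrom,
                "start_bp": seg.start_bp, "end_bp": seg.end_bp,
                "major": seg.state.a, "minor": seg.state.b, "origin": seg.origin,
            })
        if writer is not None:
            sample.snp.df.to_csv(writer / f"{sample.truth.sample_id}.tsv",
                                 sep="\t", index=False, float_format="%.6f")
    meta = pd.DataFrame(rows)
    if out_dir is not None:
        meta.to_csv(Path(out_dir) / "metadata.tsv", sep="\t", index=False)
        pd.DataFrame(truth_rows).to_csv(Path(out_dir) / "truth_segments.tsv",
                                        sep="\t", index=False)
    return meta
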
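"""Change-point segmentation of per-chromosome array tracks.

Each chromosome is partitioned into runs of constant signal by least-squares
binary segmentation over three jointly scored channels: the normalized total
ratio (all markers), the mirrored allele fraction (heterozygous-called
markers only), and the heterozygous-call indicator (all markers; this is what
makes copy-neutral LOH visible in uncontaminated samples, where the mirrored
track goes silent). Channel residuals are normalized by a successive-
difference variance estimate so the split criterion is scale-free; a split is
accepted when it reduces the normalized residual sum by more than a
BIC-style penalty (default 5 log n per chromosome).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = ["Segment", "segment_sample", "merge_adjacent"]

_VAR_FLOOR = 1e-6


@dataclass(frozen=True)
class Segment:
    """A constant-signal run over consecutive markers (1-based inclusive bp)."""

    chrom: str
    start_bp: int
    end_bp: int
    marker_count: int
    mean_t: float
    mean_strong_fraction: float  # 1.0 when hom_only
    het_count: int
    hom_only: bool = False
    flagged_short: bool = False  # chromosome had fewer markers than min_markers
    #: signed estimate of the squared allele split (strong - 1/2)^2, noise
    #: deconvolved; may be slightly negative for balanced segments, which is
    #: itself informative and avoids the fold bias of |split| estimators
    delta2: float = 0.0

    @property
    def size_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def _channel_cumsums(x: np.ndarray, w: np.ndarray):
    """Cumulative (w, wx, wx^2) with a leading zero for O(1) interval sums."""
    cw = np.concatenate([[0.0], np.cumsum(w)])
    cx = np.concatenate([[0.0], np.cumsum(w * x)])
    cx2 = np.concatenate([[0.0], np.cumsum(w * x * x)])
    return cw, cx, cx2


def _interval_ss(cums, i: int, j: int) -> float:
    """Weighted residual sum of squares of x over [i, j)."""
    cw, cx, cx2 = cums
    n = cw[j] - cw[i]
    if n <= 0:
        return 0.0
    s = cx[j] - cx[i]
    s2 = cx2[j] - cx2[i]
    return max(s2 - s * s / n, 0.0)


def _split_gains(cums, i: int, j: int, lo: int, hi: int) -> np.ndarray:
    """Gain of splitting [i, j) at each s in [lo, hi): SS(i,j)-SS(i,s)-SS(s,j)."""
    cw, cx, cx2 = cums
    s_idx = np.arange(lo, hi)
    nl = cw[s_idx] - cw[i]
    nr = cw[j] - cw[s_idx]
    sl = cx[s_idx] - cx[i]
    sr = cx[j] - cx[s_idx]
    total = _interval_ss(cums, i, j)
    with np.errstate(divide="ignore", invalid="ignore"):
        ssl = (cx2[s_idx] - cx2[i]) - np.where(nl > 0, sl * sl / np.where(nl > 0, nl, 1), 0.0)
        ssr = (cx2[j] - cx2[s_idx]) - np.where(nr > 0, sr * sr / np.where(nr > 0, nr, 1), 0.0)
    return total - ssl - ssr


_FOLD_MEDIAN_0 = 0.6744897501960817  # median of |N(0, 1)|


def _folded_median_split2(dev: np.ndarray, sigma: float) -> float:
    """Signed squared allele split delta^2 from |BAF - 1/2| deviations.

    The naive mean of the mirrored fraction is biased upward near 1/2
    (measurement noise folds at the mirror) and the second moment is fragile
    to rare miscalled-homozygote outliers. Instead the sample median m of
    |N(delta, sigma)| is inverted through the folded-normal median equation
    Phi((m - d)/s) - Phi((-m - d)/s) = 1/2; below the delta = 0 median the
    estimate continues onto a negative branch m^2 - (0.674 s)^2, so its
    sampling noise stays symmetric around delta^2 = 0 for balanced segments
    instead of folding to zero.
    """
    from scipy.optimize import brentq
    from scipy.stats import norm

    m = float(np.median(dev))
    if sigma <= 0:
        return min(m, 0.5) ** 2
    m0 = _FOLD_MEDIAN_0 * sigma
    if m <= m0:
        return m * m - m0 * m0  # negative branch: "more balanced than noise"

    def eq(d: float) -> float:
        return norm.cdf((m - d) / sigma) - norm.cdf((-m - d) / sigma) - 0.5

    return min(float(brentq(eq, 0.0, m, xtol=1e-6)), 0.5) ** 2


def _diff_variance(x: np.ndarray, w: np.ndarray) -> float:
    """Noise variance from successive differences of the weighted-present
    values: E[(x_{i+1} - x_i)^2] = 2 sigma^2 for i.i.d. noise."""
    xs = x[w > 0]
    if len(xs) < 3:
        return _VAR_FLOOR
    d = np.diff(xs)
    return max(float(np.mean(d * d) / 2.0), _VAR_FLOOR)


def _interval_gains(cums_list, i: int, j: int, s1: np.ndarray, s2: np.ndarray) -> np.ndarray:
    """Gain of carving [s1, s2) out of [i, j), flanks pooled to one mean:
    SS(i,j) - SS(s1,s2) - SS(flanks pooled); vectorized over (s1, s2)."""
    total = 0.0
    gains = np.zeros(len(s1))
    for cums in cums_list:
        cw, cx, cx2 = cums
        total = _interval_ss(cums, i, j)
        n_m = cw[s2] - cw[s1]
        sum_m = cx[s2] - cx[s1]
        sum2_m = cx2[s2] - cx2[s1]
        with np.errstate(divide="ignore", invalid="ignore"):
            ss_m = sum2_m - np.where(n_m > 0, sum_m**2 / np.where(n_m > 0, n_m, 1), 0.0)
        n_f = (cw[j] - cw[i]) - n_m
        sum_f = (cx[j] - cx[i]) - sum_m
        sum2_f = (cx2[j] - cx2[i]) - sum2_m
        with np.errstate(divide="ignore", invalid="ignore"):
            ss_f = sum2_f - np.where(n_f > 0, sum_f**2 / np.where(n_f > 0, n_f, 1), 0.0)
        gains += total - ss_m - ss_f
    return gains


def _best_interval(cums_list, i: int, j: int, min_markers: int) -> tuple[float, int, int]:
    """Best interior interval [s1, s2) to isolate from [i, j): coarse scan
    over a geometric length grid, then coordinate-descent refinement of the
    two boundaries (exact on noise-free steps)."""
    lo, hi = i + min_markers, j - min_markers
    if hi - lo < min_markers:
        return 0.0, -1, -1
    best = (0.0, -1, -1)
    L = min_markers
    while L <= hi - lo:
        step = max(1, L // 4)
        s1 = np.arange(lo, hi - L + 1, step)
        if len(s1):
            g = _interval_gains(cums_list, i, j, s1, s1 + L)
            k = int(np.argmax(g))
            if g[k] > best[0]:
                best = (float(g[k]), int(s1[k]), int(s1[k] + L))
        L = max(L + 1, int(L * 1.4))
    if best[1] < 0:
        return best
    _, b1, b2 = best
    for _ in range(3):  # refine each boundary with the other fixed
        s1 = np.arange(lo, b2 - min_markers + 1)
        g = _interval_gains(cums_list, i, j, s1, np.full(len(s1), b2))
        b1 = int(s1[np.argmax(g)])
        s2 = np.arange(b1 + min_markers, hi + 1)
        g = _interval_gains(cums_list, i, j, np.full(len(s2), b1), s2)
        b2 = int(s2[np.argmax(g)])
        gain = float(_interval_gains(cums_list, i, j, np.array([b1]), np.array([b2]))[0])
        if (b1, b2) == (best[1], best[2]):
            break
        best = (gain, b1, b2)
    return best


def _segment_chromosome(
    channels: list[tuple[np.ndarray, np.ndarray]],
    min_markers: int,
    penalty: float,
) -> list[int]:
    """Return sorted breakpoints (marker indices) for one chromosome.

    Each interval is first scanned for the best single split (accepted above
    ``penalty``); failing that, the best interior run to isolate is found by
    an interval scan and accepted as a double split above 1.2x ``penalty``
    (two breakpoints, order-n^2 candidate intervals)."""
    n = len(channels[0][0])
    cums = []
    for x, w in channels:
        var = _diff_variance(x, w)
        cums.append(_channel_cumsums(x / np.sqrt(var), w))

    breaks: list[int] = []
    stack = [(0, n)]
    while stack:
        i, j = stack.pop()
        lo, hi = i + min_markers, j - min_markers + 1
        if hi <= lo:
            continue
        gains = np.zeros(hi - lo)
        for c in cums:
            gains += _split_gains(c, i, j, lo, hi)
        k = int(np.argmax(gains))
        if gains[k] > penalty:
            s = lo + k
            breaks.append(s)
            stack.append((i, s))
            stack.append((s, j))
            continue
        gain, s1, s2 = _best_interval(cums, i, j, min_markers)
        if s1 >= 0 and gain > 1.2 * penalty:
            breaks.extend([s1, s2])
            stack.append((i, s1))
            stack.append((s1, s2))
            stack.append((s2, j))
    return sorted(breaks)


def _make_segment(
    chrom: str,
    pos: np.ndarray,
    t: np.ndarray,
    strong: np.ndarray,
    het: np.ndarray,
    i: int,
    j: int,
    noise_var: float = 0.0,
    flagged_short: bool = False,
) -> Segment:
    het_ij = het[i:j]
    n_het = int(het_ij.sum())
    # het-density gate: a run depleted of heterozygous calls far below the
    # germline het rate is LOH regardless of a few boundary-slop AB markers;
    # the density rule needs enough markers to be conclusive, short random
    # het deserts must not masquerade as LOH
    hom_only = n_het == 0 or (j - i >= 50 and n_het < 0.1 * (j - i))
    if hom_only:
        mean_strong, delta2 = 1.0, 0.25
    else:
        dev = np.abs(strong[i:j][het_ij] - 0.5)
        delta2 = _folded_median_split2(dev, np.sqrt(noise_var))
        mean_strong = 0.5 + np.sqrt(max(delta2, 0.0))
    return Segment(
        chrom=chrom,
        start_bp=int(pos[i]),
        end_bp=int(pos[j - 1]),
        marker_count=j - i,
        mean_t=float(t[i:j].mean()),
        mean_strong_fraction=float(mean_strong),
        het_count=n_het,
        hom_only=hom_only,
        flagged_short=flagged_short,
        delta2=float(delta2),
    )


def segment_sample(
    tracks,
    min_markers: int = 25,
    penalty: float | None = None,
) -> list[Segment]:
    """Segment every chromosome of an :class:`~cnloh.signal_model.AlleleTracks`
    bundle into constant-signal runs of at least ``min_markers`` markers.

    ``penalty`` is the minimum normalized residual reduction required to
    accept a split; ``None`` selects ``5 * log(n)`` per chromosome. A
    chromosome with fewer than ``min_markers`` markers is returned as a
    single flagged segment.
    """
    if min_markers < 2:
        raise ValueError("min_markers must be >= 2")
    segments: list[Segment] = []
    for chrom in tracks.chroms:
        pos, t, strong, het = tracks.chromosome_arrays(chrom)
        n = len(pos)
        if n == 0:
            continue
        # the t-track diff variance doubles as the BAF noise estimate (one
        # additive noise scale per array, applied to both channels)
        noise_var = _diff_variance(t, np.ones(n))
        if noise_var <= _VAR_FLOOR:
            noise_var = 0.0
        if n < min_markers:
            segments.append(_make_segment(chrom, pos, t, strong, het, 0, n,
                                          noise_var=noise_var, flagged_short=True))
            continue
        pen = penalty if penalty is not None else 5.0 * np.log(n)
        het_w = het.astype(float)
        channels = [
            (t, np.ones(n)),
            (strong, het_w),
            (het_w, np.ones(n)),
        ]
        breaks = _segment_chromosome(channels, min_markers, pen)
        bounds = [0, *breaks, n]
        for i, j in zip(bounds[:-1], bounds[1:]):
            segments.append(_make_segment(chrom, pos, t, strong, het, i, j,
                                          noise_var=noise_var))
    return segments


def merge_adjacent(fitted_segments: Sequence) -> list:
    """Merge consecutive same-chromosome fitted segments with identical
    allelic state (and identical amplification flag) so that one biological
    event is counted once. Summaries are recomputed as marker-weighted means;
    total marker count is conserved.
    """
    from .state_fit import FittedSegment  # local import to avoid a cycle

    out: list[FittedSegment] = []
    for fs in fitted_segments:
        if out:
            prev = out[-1]
            same = (
                prev.chrom == fs.chrom
                and prev.state == fs.state
                and prev.amplification == fs.amplification
                and prev.segment.end_bp < fs.segment.start_bp
            )
            if same:
                a, b = prev.segment, fs.segment
                w1, w2 = a.marker_count, b.marker_count
                h1, h2 = a.het_count, b.het_count
                hom_only = (h1 + h2) == 0 or (
                    w1 + w2 >= 50 and (h1 + h2) < 0.1 * (w1 + w2))
                if hom_only:
                    strong, delta2 = 1.0, 0.25
                else:
                    strong = (a.mean_strong_fraction * h1 + b.mean_strong_fraction * h2) / (h1 + h2)
                    delta2 = (a.delta2 * h1 + b.delta2 * h2) / (h1 + h2)
                merged_seg = Segment(
                    chrom=a.chrom,
                    start_bp=a.start_bp,
                    end_bp=b.end_bp,
                    marker_count=w1 + w2,
                    mean_t=(a.mean_t * w1 + b.mean_t * w2) / (w1 + w2),
                    mean_strong_fraction=strong,
                    het_count=h1 + h2,
                    hom_only=hom_only,
                    flagged_short=a.flagged_short and b.flagged_short,
                    delta2=delta2,
                )
                merged_resid = (prev.residual * w1 + fs.residual * w2) / (w1 + w2)
                out[-1] = FittedSegment(merged_seg, prev.state, merged_resid,
                                        amplification=prev.amplification)
                continue
        out.append(fs)
    return out
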
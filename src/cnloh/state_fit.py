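"""Integer allelic-state fitting for contaminated, polyploid SNP-array profiles.

A tumor sample is modeled as a mixture of tumor cells carrying an integer
allelic state (a, b) per genomic segment (a = major, b = minor copies,
a >= b >= 0) and a fraction ``rho`` of admixed diploid stromal cells. The two
observable tracks are

* the normalized total ratio  t = c_total / c_norm, where
  c_total = 2 rho + (1 - rho) (a + b) and c_norm = 2 rho + (1 - rho) c~,
  with c~ the normalization ploidy (the genome-median tumor copy number, which
  the median-centered ratio track pins to t = 1); and
* the mirrored ("strongest") allele fraction of germline-heterozygous markers,
  f = (rho + (1 - rho) a) / c_total  (defined as 1 when c_total = 0).

Fitting inverts this model. Because affine relabelings of the copy-number
scale (the purity/ploidy ridge, of which whole-genome doubling is the
best-known case) can reproduce the observed signal levels almost exactly, the
search proceeds in two stages: a coarse (rho, c~) grid identifies candidate
solution families, and each family is then refined by alternating continuous
(rho, c~) optimization with integer state reassignment. The family reaching
the lowest refined residual wins; exact genome-doubling ties are resolved
toward the lower-ploidy solution and surfaced via an ambiguity flag rather
than silently. External per-chromosome copy anchors (e.g. FISH counts) can
constrain the solution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import optimize

from .segmentation import Segment

__all__ = [
    "AllelicState",
    "FittedSegment",
    "SampleFit",
    "FitGrid",
    "expected_signals",
    "fit_segment_state",
    "fit_sample",
    "apply_anchor",
]


class AllelicState(NamedTuple):
    """Integer (major, minor) copy pair; rendered in 'a+b' notation."""

    a: int
    b: int

    @property
    def total(self) -> int:
        return self.a + self.b

    def __str__(self) -> str:  # e.g. "2+0"
        return f"{self.a}+{self.b}"


def expected_signals(
    state: AllelicState | tuple[int, int], rho: float, c_tilde: float
) -> tuple[float, float]:
    """Expected (normalized total ratio, mirrored allele fraction).

    ``rho`` is the stromal (diploid) contamination fraction in [0, 1);
    ``c_tilde`` the normalization ploidy (> 0). The mirrored fraction is
    defined as 1.0 for a segment with zero mixture copies.
    """
    a, b = state
    c_total = 2.0 * rho + (1.0 - rho) * (a + b)
    c_strong = rho + (1.0 - rho) * a
    c_norm = 2.0 * rho + (1.0 - rho) * c_tilde
    t = c_total / c_norm
    frac = c_strong / c_total if c_total > 0 else 1.0
    return t, frac


# ---------------------------------------------------------------------------
# state enumeration helpers

def _state_table(max_copies: int) -> tuple[np.ndarray, np.ndarray]:
    """All states (a, b) with 0 <= b <= a <= max_copies, ordered by
    (total ascending, b descending) so that np.argmin's first-hit rule
    implements the tie-break: smaller total first, then larger minor."""
    states = [(a, b) for a in range(max_copies + 1) for b in range(a + 1)]
    states.sort(key=lambda s: (s[0] + s[1], -s[1]))
    arr = np.array(states, dtype=np.int64)
    return arr[:, 0], arr[:, 1]


def _expected_grid(
    A: np.ndarray, B: np.ndarray, rho: np.ndarray, c_tilde: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized expected signals; rho/c_tilde shape (G,1), A/B shape (S,).

    Returns (t, frac) of shape (G, S)."""
    tot = A + B
    c_total = 2.0 * rho + (1.0 - rho) * tot
    c_strong = rho + (1.0 - rho) * A
    c_norm = 2.0 * rho + (1.0 - rho) * c_tilde
    t = c_total / c_norm
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(c_total > 0, c_strong / np.where(c_total > 0, c_total, 1.0), 1.0)
    return t, frac


# ---------------------------------------------------------------------------
# results containers

@dataclass(frozen=True)
class FittedSegment:
    segment: Segment
    state: AllelicState
    residual: float  # squared error at the fitted (rho, c~)
    amplification: bool = False

    @property
    def chrom(self) -> str:
        return self.segment.chrom

    @property
    def size_bp(self) -> int:
        return self.segment.end_bp - self.segment.start_bp + 1


@dataclass
class SampleFit:
    """Fit result for one sample."""

    sample_id: str
    rho: float
    c_tilde: float
    segments: list[FittedSegment]
    per_chromosome: dict[str, int]  # modal (marker-weighted) total copies
    overall_ploidy: float  # marker-weighted mean total copies, autosomes
    objective: float
    ambiguity_flag: bool = False
    alternative: "SampleFit | None" = None

    @property
    def ploidy_label(self) -> str:
        """Rendered like '~2.3n' (one decimal)."""
        return f"~{self.overall_ploidy:.1f}n"


@dataclass(frozen=True)
class FitGrid:
    """Search configuration. Coarse grid: rho 0..0.9 step 0.02, c~ 1.5..5.0
    step 0.05; state totals capped at 12 copies; one marker-equivalent of
    penalty per distinct state plus a small tie-breaking preference for
    fewer copies; the best ``n_refine_basins`` distinct coarse solutions are
    refined continuously. Genome-doubling ties within ``doubling_rel_tol``
    set the ambiguity flag."""

    rho_min: float = 0.0
    rho_max: float = 0.9
    rho_step: float = 0.02
    c_min: float = 1.5
    c_max: float = 5.0
    c_step: float = 0.05
    max_copies: int = 12
    state_penalty: float = 1.0
    # Exact per-allele affine relabelings (x -> alpha x + beta with a matched
    # contamination) reproduce both observable tracks perfectly, so solution
    # families are separated by priors: no whole-chromosome nullisomy,
    # LOH is event-like rather than a genome-wide background (breaks
    # down-shifted families), and lower ploidy is preferred (breaks
    # up-shifted families).
    ploidy_penalty: float = 0.05  # per unit marker-weighted mean total
    # LOH is expected to be event-like: only the marker fraction in
    # minor = 0 states beyond ``loh_allowance`` is penalized, so genuine
    # event loads cost nothing while genome-wide LOH backgrounds do
    loh_penalty: float = 2.0
    loh_allowance: float = 0.25
    nullisomy_max_bp: float = 10e6  # (0,0) allowed only as a focal deletion
    n_refine_basins: int = 40
    doubling_rel_tol: float = 0.02
    amp_t_threshold: float = 3.0  # normalized-ratio level treated as amplicon
    hom_only_policy: str = "use_one"  # or "drop"
    min_hom_only_markers: int = 10

    def rho_values(self) -> np.ndarray:
        n = int(round((self.rho_max - self.rho_min) / self.rho_step)) + 1
        return self.rho_min + self.rho_step * np.arange(n)

    def c_values(self) -> np.ndarray:
        n = int(round((self.c_max - self.c_min) / self.c_step)) + 1
        return self.c_min + self.c_step * np.arange(n)


def _fraction_weight(seg: Segment, grid: FitGrid) -> tuple[float, float]:
    """(observed fraction to use, 0/1 weight of the fraction term)."""
    if not seg.hom_only:
        return seg.mean_strong_fraction, 1.0
    if grid.hom_only_policy == "use_one" and seg.marker_count >= grid.min_hom_only_markers:
        # A sizeable run with no heterozygous call is itself evidence of LOH:
        # treat it as mirrored fraction 1.0 so LOH remains callable at rho = 0.
        return 1.0, 1.0
    return 1.0, 0.0


def fit_segment_state(
    mean_t: float,
    mean_strong_fraction: float | None,
    rho: float,
    c_tilde: float,
    max_copies: int = 12,
) -> tuple[AllelicState, float]:
    """Best integer state for one segment at fixed (rho, c~).

    ``mean_strong_fraction=None`` drops the allele-fraction term (segment
    with no usable heterozygous information). Ties in squared error break
    toward the smaller total, then the larger minor allele count.
    """
    if max_copies < 1:
        raise ValueError("max_copies must be >= 1")
    A, B = _state_table(max_copies)
    t, frac = _expected_grid(A, B, np.array([[rho]]), np.array([[c_tilde]]))
    err = (t[0] - mean_t) ** 2
    if mean_strong_fraction is not None:
        err = err + (frac[0] - mean_strong_fraction) ** 2
    i = int(np.argmin(err))
    return AllelicState(int(A[i]), int(B[i])), float(err[i])


# ---------------------------------------------------------------------------
# whole-sample search

_D2_FLOOR = 0.0025  # variance-stabilization floor for the split residual


def _split_err(d2_obs: np.ndarray, f_exp: np.ndarray) -> np.ndarray:
    """Residual of the allele split, scored on the squared-split scale.

    (d2_obs - delta_model^2)^2 / (4 max(delta_model^2, floor)) reduces to the
    familiar (delta_obs - delta_model)^2 away from balance, while staying
    finite and fold-bias-free for balanced states where delta ~ 0 and the
    observed d2 fluctuates symmetrically around zero.
    """
    dm2 = (f_exp - 0.5) ** 2
    return (d2_obs - dm2) ** 2 / (4.0 * np.maximum(dm2, _D2_FLOOR))


@dataclass
class _Obs:
    """Prepared per-segment observation arrays."""

    t: np.ndarray
    f: np.ndarray  # reported mirrored fraction (0.5 + sqrt(max(d2, 0)))
    d2: np.ndarray  # signed squared-split estimate
    f_w: np.ndarray
    w: np.ndarray
    wf: np.ndarray  # split-term weight: het markers carrying the BAF signal
    amp: np.ndarray  # amplicon mask (excluded from rho/c~ estimation)
    null_ok: np.ndarray  # segments small enough for a (0,0) focal deletion
    chroms: list[str]

    @property
    def informative(self) -> np.ndarray:
        return ~self.amp


def _prepare_obs(segments: Sequence[Segment], grid: FitGrid) -> _Obs:
    t = np.array([s.mean_t for s in segments])
    f = np.empty(len(segments))
    d2 = np.empty(len(segments))
    f_w = np.empty(len(segments))
    wf = np.empty(len(segments))
    for i, s in enumerate(segments):
        f[i], f_w[i] = _fraction_weight(s, grid)
        d2[i] = 0.25 if (s.hom_only and f_w[i] > 0) else s.delta2
        # absence of het calls is per-marker evidence; a measured split is
        # only as precise as the het markers behind it
        wf[i] = (s.marker_count if s.hom_only else s.het_count) * f_w[i]
    w = np.array([s.marker_count for s in segments], dtype=float)
    amp = t > grid.amp_t_threshold
    null_ok = np.array([s.size_bp <= grid.nullisomy_max_bp for s in segments])
    return _Obs(t=t, f=f, d2=d2, f_w=f_w, w=w, wf=wf, amp=amp, null_ok=null_ok,
                chroms=[s.chrom for s in segments])


_BIG = 1e12


def _assign_states(
    rho: float, c: float, obs: _Obs, A: np.ndarray, B: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Best state index per segment at fixed parameters; returns
    (index (N,), t-term error (N,), split-term error (N,))."""
    t_exp, f_exp = _expected_grid(A, B, np.array([[rho]]), np.array([[c]]))
    terr = (t_exp[0][None, :] - obs.t[:, None]) ** 2
    ferr = obs.f_w[:, None] * _split_err(obs.d2[:, None], f_exp[0][None, :])
    err = terr + ferr
    zero = (A + B) == 0
    err = np.where((~obs.null_ok)[:, None] & zero[None, :], _BIG, err)
    idx = np.argmin(err, axis=1)
    rows = np.arange(len(idx))
    return idx, terr[rows, idx], ferr[rows, idx]


def _penalized_objective(
    terr: np.ndarray, ferr: np.ndarray, idx: np.ndarray, obs: _Obs,
    totals: np.ndarray, B: np.ndarray, grid: FitGrid
) -> tuple[float, float]:
    """(full objective incl. family priors, prior-free fit objective).

    The prior-free value measures only how well the solution fits the data
    (weighted residual + state-count penalty); ambiguity detection compares
    families on it, since the priors are exactly what breaks their ties."""
    info = obs.informative
    wres = float((obs.w * terr + obs.wf * ferr)[info].sum())
    if info.any():
        n_states = len(set(idx[info].tolist()))
        w_inf = obs.w[info]
        mean_total = float(np.average(totals[idx[info]], weights=w_inf))
        loh_frac = float(w_inf[B[idx[info]] == 0].sum() / w_inf.sum())
    else:
        n_states, mean_total, loh_frac = 1, 0.0, 0.0
    fit_obj = wres + grid.state_penalty * n_states
    full = (fit_obj + grid.ploidy_penalty * mean_total
            + grid.loh_penalty * max(0.0, loh_frac - grid.loh_allowance))
    return full, fit_obj


def _coarse_grid(obs: _Obs, grid: FitGrid, A: np.ndarray, B: np.ndarray):
    """Objective and state assignment at every coarse grid point."""
    rho_v, c_v = grid.rho_values(), grid.c_values()
    rho_g = np.repeat(rho_v, len(c_v))
    c_g = np.tile(c_v, len(rho_v))
    t_exp, f_exp = _expected_grid(A, B, rho_g[:, None], c_g[:, None])  # (G, S)
    totals = A + B
    G, N = len(rho_g), len(obs.t)
    assign = np.zeros((G, N), dtype=np.int16)
    wres = np.zeros(G)
    zero = totals == 0
    for n in range(N):
        terr = (t_exp - obs.t[n]) ** 2
        if obs.f_w[n] > 0:
            ferr = obs.f_w[n] * _split_err(obs.d2[n], f_exp)
        else:
            ferr = 0.0
        err = terr + ferr
        if not obs.null_ok[n]:
            err = np.where(zero[None, :], _BIG, err)
        idx = np.argmin(err, axis=1)
        assign[:, n] = idx
        if not obs.amp[n]:
            rows = np.arange(G)
            wres += obs.w[n] * terr[rows, idx]
            if obs.f_w[n] > 0:
                wres += obs.wf[n] * ferr[rows, idx]
    info = obs.informative
    if info.any():
        sub = np.sort(assign[:, info], axis=1)
        n_states = 1 + (np.diff(sub, axis=1) > 0).sum(axis=1)
        w_inf = obs.w[info]
        mean_total = (totals[assign[:, info]] @ w_inf) / w_inf.sum()
        loh_frac = ((B[assign[:, info]] == 0) @ w_inf) / w_inf.sum()
    else:
        n_states = np.ones(G, dtype=int)
        mean_total = np.zeros(G)
        loh_frac = np.zeros(G)
    obj = (wres + grid.state_penalty * n_states
           + grid.ploidy_penalty * mean_total
           + grid.loh_penalty * np.maximum(0.0, loh_frac - grid.loh_allowance))
    return obj, assign, rho_g, c_g


def _refine_basin(
    rho0: float, c0: float, obs: _Obs, grid: FitGrid, A: np.ndarray, B: np.ndarray
) -> tuple[float, float, float, np.ndarray, np.ndarray]:
    """Alternate continuous (rho, c~) optimization with integer state
    reassignment until the assignment stabilizes. Returns
    (objective, rho, c, assignment, residuals)."""
    totals = A + B
    rho, c = float(rho0), float(c0)
    idx, terr, ferr = _assign_states(rho, c, obs, A, B)
    obj0, fit0 = _penalized_objective(terr, ferr, idx, obs, totals, B, grid)
    best = (obj0, rho, c, idx, terr + ferr, fit0)
    for _ in range(8):
        a_fix = A[idx].astype(float)
        b_fix = B[idx].astype(float)
        info = obs.informative

        def fixed_resid(params: np.ndarray) -> float:
            r = min(max(params[0], grid.rho_min), grid.rho_max)
            cc = min(max(params[1], grid.c_min), grid.c_max)
            c_tot = 2.0 * r + (1.0 - r) * (a_fix + b_fix)
            c_norm = 2.0 * r + (1.0 - r) * cc
            t_e = c_tot / c_norm
            with np.errstate(divide="ignore", invalid="ignore"):
                f_e = np.where(c_tot > 0,
                               (r + (1.0 - r) * a_fix) / np.where(c_tot > 0, c_tot, 1.0),
                               1.0)
            terr_ = (t_e - obs.t) ** 2
            ferr_ = obs.f_w * _split_err(obs.d2, f_e)
            return float((obs.w * terr_ + obs.wf * ferr_)[info].sum())

        res = optimize.minimize(fixed_resid, x0=[rho, c], method="Nelder-Mead",
                                options={"xatol": 1e-4, "fatol": 1e-10,
                                         "maxiter": 200})
        rho = float(min(max(res.x[0], grid.rho_min), grid.rho_max))
        c = float(min(max(res.x[1], grid.c_min), grid.c_max))
        new_idx, terr, ferr = _assign_states(rho, c, obs, A, B)
        obj, fit_obj = _penalized_objective(terr, ferr, new_idx, obs, totals, B, grid)
        if obj < best[0]:
            best = (obj, rho, c, new_idx, terr + ferr, fit_obj)
        if np.array_equal(new_idx, idx):
            break
        idx = new_idx
    return best


def _chrom_modal_totals(obs: _Obs, seg_totals: np.ndarray) -> dict[str, int]:
    out: dict[str, int] = {}
    for chrom in dict.fromkeys(obs.chroms):
        weights: dict[int, float] = {}
        for c, tot, is_amp, w in zip(obs.chroms, seg_totals, obs.amp, obs.w):
            if c != chrom or is_amp:
                continue
            weights[int(tot)] = weights.get(int(tot), 0.0) + w
        if weights:
            out[chrom] = max(sorted(weights), key=lambda k: weights[k])
    return out


def _fit_amplicon(
    mean_t: float, mean_frac: float | None, rho: float, c_tilde: float, max_copies: int
) -> tuple[AllelicState, float]:
    """Capped state for an amplified segment: major pinned at max_copies; the
    minor allele is chosen from the allele fraction when available (the total
    ratio is beyond the cap's reach by construction)."""
    best: tuple[float, int] | None = None
    for b in range(max_copies + 1):
        te, fe = expected_signals((max_copies, b), rho, c_tilde)
        err = (fe - mean_frac) ** 2 if mean_frac is not None else (te - mean_t) ** 2
        if best is None or err < best[0]:
            best = (err, b)
    assert best is not None
    return AllelicState(max_copies, best[1]), float(best[0])


def _anchors_ok(
    anchors: dict[str, int] | None, obs: _Obs, seg_totals: np.ndarray
) -> bool:
    if not anchors:
        return True
    modal = _chrom_modal_totals(obs, seg_totals)
    return all(modal.get(chrom) == want for chrom, want in anchors.items())


@dataclass
class _Basin:
    objective: float
    rho: float
    c: float
    idx: np.ndarray
    resid: np.ndarray
    fit_objective: float  # prior-free: weighted residual + state penalty


def _build_fit(
    sample_id: str, segments: Sequence[Segment], obs: _Obs, grid: FitGrid,
    basin: _Basin, A: np.ndarray, B: np.ndarray,
) -> SampleFit:
    rho, c_tilde = basin.rho, basin.c
    fitted: list[FittedSegment] = []
    for n, seg in enumerate(segments):
        if obs.amp[n]:
            state, resid = _fit_amplicon(
                obs.t[n], obs.f[n] if obs.f_w[n] > 0 else None,
                rho, c_tilde, grid.max_copies)
            fitted.append(FittedSegment(seg, state, resid, amplification=True))
        else:
            i = int(basin.idx[n])
            state = AllelicState(int(A[i]), int(B[i]))
            fitted.append(FittedSegment(seg, state, float(basin.resid[n])))
    seg_totals = np.array([fs.state.total for fs in fitted])
    per_chrom = _chrom_modal_totals(obs, seg_totals)
    auto = np.array([(c != "chrX") and not a for c, a in zip(obs.chroms, obs.amp)])
    if auto.any():
        ploidy = float(np.average(seg_totals[auto], weights=obs.w[auto]))
    else:
        ploidy = float(np.average(seg_totals, weights=obs.w))
    return SampleFit(
        sample_id=sample_id, rho=rho, c_tilde=c_tilde, segments=fitted,
        per_chromosome=per_chrom, overall_ploidy=ploidy,
        objective=basin.objective,
    )


def fit_sample(
    segments: Sequence[Segment],
    sample_id: str = "",
    grid: FitGrid | None = None,
    anchors: dict[str, int] | None = None,
) -> SampleFit:
    """Two-stage joint search for (rho, c~) and per-segment integer states.

    ``anchors`` restricts solutions to those whose fitted modal total on
    each anchored chromosome equals the anchor (e.g. FISH copy counts).
    When a solution with every total doubled (or halved) scores within the
    doubling tolerance, the lower-ploidy fit is returned with
    ``ambiguity_flag`` set and the alternative attached.
    """
    segments = list(segments)
    if not segments:
        raise ValueError("fit_sample requires at least one segment")
    grid = grid or FitGrid()
    A, B = _state_table(grid.max_copies)
    totals = A + B
    obs = _prepare_obs(segments, grid)
    if anchors:
        for chrom in anchors:
            if chrom not in obs.chroms:
                raise ValueError(f"anchor chromosome {chrom} not present in segments")

    obj_g, assign_g, rho_g, c_g = _coarse_grid(obs, grid, A, B)

    # candidate basins: local minima of the coarse objective surface (one
    # per solution family), deduplicated by state assignment
    info = obs.informative
    n_rho, n_c = len(grid.rho_values()), len(grid.c_values())
    surf = obj_g.reshape(n_rho, n_c)
    padded = np.pad(surf, 1, constant_values=np.inf)
    is_min = np.ones_like(surf, dtype=bool)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == dc == 0:
                continue
            is_min &= surf <= padded[1 + dr: 1 + dr + n_rho, 1 + dc: 1 + dc + n_c]
    cand = np.flatnonzero(is_min.ravel())
    cand = cand[np.argsort(obj_g[cand], kind="stable")]
    seen: set[bytes] = set()
    basins: list[_Basin] = []
    for g in cand:
        sig = assign_g[g, info].tobytes()
        if sig in seen:
            continue
        seen.add(sig)
        refined = _refine_basin(float(rho_g[g]), float(c_g[g]), obs, grid, A, B)
        basin = _Basin(*refined)
        if _anchors_ok(anchors, obs, totals[basin.idx]):
            basins.append(basin)
        if len(seen) >= grid.n_refine_basins:
            break
    if not basins:
        name = ", ".join(f"{c}={v}" for c, v in (anchors or {}).items())
        raise ValueError(f"no solution satisfies the anchor(s) {name}")
    basins.sort(key=lambda b: b.objective)
    best = basins[0]

    # genome-doubling ambiguity among refined candidate families
    tol = 1.0 + grid.doubling_rel_tol
    T_best = totals[best.idx]
    alt_basin: _Basin | None = None
    flag = False
    if info.any() and (T_best[info] % 2 == 0).all():
        halved = [b for b in basins[1:]
                  if (totals[b.idx][info] * 2 == T_best[info]).all()
                  and b.fit_objective <= tol * best.fit_objective]
        if halved:
            alt_basin, best = best, min(halved, key=lambda b: b.objective)
            flag = True
    if alt_basin is None:
        doubled = [b for b in basins[1:]
                   if (totals[b.idx][info] == 2 * T_best[info]).all()
                   and b.fit_objective <= tol * best.fit_objective]
        if doubled:
            alt_basin = min(doubled, key=lambda b: b.objective)
            flag = True

    fit = _build_fit(sample_id, segments, obs, grid, best, A, B)
    fit.ambiguity_flag = flag
    if alt_basin is not None:
        fit.alternative = _build_fit(sample_id, segments, obs, grid, alt_basin, A, B)
    return fit


def apply_anchor(
    fit: SampleFit, anchors: dict[str, int], grid: FitGrid | None = None
) -> SampleFit:
    """Refit restricted to solutions honoring external per-chromosome
    total-copy anchors; raises if an anchor is infeasible (naming it)."""
    if not anchors:
        raise ValueError("apply_anchor requires at least one anchor")
    segments = [fs.segment for fs in fit.segments]
    return fit_sample(segments, sample_id=fit.sample_id, grid=grid, anchors=anchors)
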
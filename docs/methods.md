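# Methods

## The problem

Neuroblastoma genomes range from near-diploid with focal lesions (MYCN
amplification, 11q deletion, 17q gain) to near-triploid karyotypes built
entirely from whole-chromosome gains and losses. On a SNP array two tracks
are observable per marker: the normalized total intensity ratio *t* and the
B-allele fraction (BAF). Loss of heterozygosity that is partially or fully
compensated by duplication of the remaining allele ("near copy-neutral LOH",
e.g. allelic state 2+0 or 3+0 in a near-triploid genome) is invisible on the
total ratio and must be read from the allele-specific signal — which stromal
contamination blurs, but does not erase: admixed normal cells regenerate
heterozygous-looking calls inside somatically LOH regions, and the displaced
BAF of those calls carries the signal.

This package implements the full chain: a synthetic cohort generator with
known ground truth, track construction, change-point segmentation, a
contamination/ploidy/state fit, an event taxonomy, and the cohort-level
statistics, organized as numbered drivers under `analysis/` over the library
in `src/cnloh/`.

## Signal model

A sample is a mixture of a fraction `rho` of diploid stromal cells and tumor
cells carrying an integer allelic state (a, b) per segment (a = major,
b = minor copies). With normalization ploidy `c~` (the genome-median tumor
copy number; the median-centered ratio track pins it to t = 1):

```
c_total = 2 rho + (1 - rho)(a + b)        mixture copies
t       = c_total / (2 rho + (1 - rho) c~)
f       = (rho + (1 - rho) a) / c_total   mirrored allele fraction, f >= 1/2
```

`f` is defined as 1 for zero mixture copies. Worked points: (1,1) gives
(1, 0.5) for any rho; (2,0) at rho 0.3, c~ 2 gives (1, 0.85) — copy-neutral
on *t*, clearly displaced on *f*; (2,0) at rho 0, c~ 2.8 gives (0.714, 1.0).

## Synthetic cohorts (`sim_cohort`)

The generator emulates a 250K-mapping-array design: markers every 12 kb
(default) on a build-36-era 22+X chromosome table; germline heterozygosity
30% per marker; germline IBD runs forced homozygous. Five profile types:
flat diploid, numerical near-triploid (whole-chromosome totals drawn from
{2,3,4,5} with weights 0.25/0.40/0.20/0.15, most-balanced allele split),
MYCN-amplified segmental (focal 2p amplicon with 25 total copies, telomeric
17q gain, telomeric 1p loss), 11q-deleted segmental, and constitutional
control. Near-CN-LOH events are injected per sample with Poisson counts at
the group means (tumors 0.89, cell lines 2.4, controls 0.10 events/sample)
and extent mixtures of 50/15/35 (tumor), 5/74/21 (cell line) and 100/0/0
(control) percent interstitial/telomeric/whole-chromosome. Interstitial
events are 2–10 Mb, telomeric 5–30 Mb — comfortably above the 1.5 Mb
reporting threshold. Control events are germline IBD runs (2+0, forced
homozygous); tumor/cell-line events are somatic (T, 0) with T between 2 and
a conservative rounding of the background ploidy, so each injected event is
genuinely "near copy-neutral" relative to the realized genome. Events are
placed on autosomes only (the X is excluded from all statistics), in
background regions, with a 2 Mb minimum separation, so one injected event
maps to one recovered event. Tumor contamination is drawn uniformly from
[0.2, 0.6]; cell lines and controls are pure. The default cohort is 134
tumors, 10 cell lines of which the first three form a related trio (parent
plus two subclones that share the parent's aberrations and add ~1.5 unique
events each), and 30 controls; after the relatedness exclusion the analyzed
cell-line group has the study's n = 8.

Observed signals are the mixture model values plus additive Gaussian noise
(default SD 0.05 on both channels; BAF truncated to [0, 1]). Genotype calls
threshold the observed BAF: AB within [0.10, 0.90] inclusive, else AA/BB.
The window is deliberately wide: a (2,0) segment has mirrored fraction
1 - rho/2, so false heterozygous calls inside somatic LOH — the phenomenon
the whole analysis leans on — appear from rho = 0.2 up. A narrow "textbook"
window such as [0.3, 0.7] would produce no het calls below rho = 0.6 and
make contaminated LOH unreadable.

What the generator does **not** model: linkage disequilibrium, probe-level
effects (GC waves, fragment-length bias), centromeres/acrocentric arms,
subclonal (non-integer) mixtures, and genotyping error beyond the Gaussian
channel noise. Passing tests therefore demonstrate correctness of the
inference machinery under the stated signal model, not robustness to every
artifact of real arrays.

## Track construction (`signal_model`)

References are chosen per sample as the k = 6 candidates minimizing the SD
of log2(sample/candidate) over autosomal markers (deterministic tie-break by
id); the chosen references are averaged marker-wise and the sample ratio is
median-centered so the autosomal median is 1. Mirrored fractions
max(BAF, 1-BAF) are taken at AB-called markers only. A sample with no AB
calls at all is flagged homozygous-only rather than dropped, so LOH in pure
cell lines remains callable.

## Segmentation (`segmentation`)

Least-squares binary segmentation over three jointly scored channels: *t*
(all markers), the mirrored fraction (AB markers), and the AB-call indicator
(all markers — this is what exposes copy-neutral LOH in pure samples, where
the mirrored track simply goes silent). Channel residuals are normalized by
a successive-difference variance estimate (E[(x_{i+1}-x_i)^2] = 2 sigma^2),
making the split criterion scale-free; a split must reduce the normalized
residual by more than 5 log n (per chromosome). Because a single split is
weak evidence for a short interior run, each interval is also scanned for
the best run to isolate (coarse geometric length grid, then coordinate
descent on the two boundaries — exact on noise-free steps), accepted above
1.2x the single-split penalty. Segments have at least 25 markers (300 kb at
12 kb spacing); a chromosome shorter than that becomes one flagged segment.

Two segment-level estimators matter downstream:

* **Homozygous-only gating.** A segment is treated as LOH-like when it has
  zero AB calls, or fewer than 10% AB markers over at least 50 markers (a
  few boundary-slop AB markers must not mask a real LOH run, while short
  random "het deserts" must not fake one).
* **Fold-bias-free allele split.** The naive mean of the mirrored fraction
  is biased upward near 1/2 (noise folds at the mirror), and the raw second
  moment is fragile to rare miscalled homozygotes. Each segment therefore
  carries a signed squared-split estimate delta^2 obtained by inverting the
  folded-normal median equation at the sample median of |BAF - 1/2| (noise
  SD taken from the t-track difference variance — the generator and typical
  arrays put comparable noise on both channels); below the delta = 0 median
  the estimate continues onto a negative branch, so its sampling noise stays
  symmetric around zero for balanced segments.

## State fitting (`state_fit`)

At fixed (rho, c~) every segment gets the integer state minimizing
(t - t_model)^2 plus a variance-stabilized split residual
(delta^2_obs - delta^2_model)^2 / (4 max(delta^2_model, 0.05^2)), which
reduces to the familiar (delta_obs - delta_model)^2 away from balance and
stays finite and unbiased at it. Ties break toward the smaller total, then
the larger minor count. Homozygous-only segments of at least 10 markers use
delta^2 = 1/4 (mirrored fraction 1), which is what keeps LOH callable in
pure cell lines; the observed mean split on AB markers would otherwise be
poisoned by a handful of boundary markers.

The sample-level search is the delicate part. The mixture model has *exact*
per-allele affine symmetries: mapping every allele copy x to alpha x + beta
with a suitably matched contamination reproduces both observable tracks
perfectly (whole-genome doubling is the alpha = 2, beta = 0 case). Level
matching alone therefore cannot choose among solution families; priors must.
The search proceeds in two stages — a coarse grid (rho 0 to 0.9 step 0.02,
c~ 1.5 to 5.0 step 0.05) whose local objective minima seed up to 40
candidate families, each refined by alternating continuous (rho, c~)
optimization (Nelder-Mead) with integer reassignment — and the refined
objective adds, on top of the marker-weighted residual (t-term weighted by
marker count, split-term by het count, i.e. by each channel's information
content):

* one marker-equivalent of penalty per distinct state (model complexity);
* a hard ban on whole-chromosome nullisomy ((0,0) allowed only below 10 Mb,
  the focal homozygous-deletion regime) — this breaks down-shifted families
  that relabel balanced diploid chromosomes as zero copies;
* an LOH-excess penalty of 2 per unit marker fraction in minor = 0 states
  *beyond* a 25% genome allowance — LOH is event-like, not a background, so
  genuine event loads cost nothing while families that relabel balanced
  backgrounds as genome-wide LOH are rejected;
* a small (0.05/copy) preference for lower mean copy number, breaking
  up-shifted families.

Exact genome-doubling ties (all totals doubled or halved, compared on the
prior-free objective within a 2% tolerance) are resolved toward the
lower-ploidy solution and *surfaced* via an ambiguity flag with the
alternative fit attached — a featureless diploid profile is flagged, because
it genuinely is indistinguishable from a featureless tetraploid one, which
is exactly the misclassification the study had to resolve with FISH.
External per-chromosome copy anchors (`apply_anchor`, e.g. FISH counts)
restrict the candidate families and clear the flag when they disambiguate.
Segments whose ratio level exceeds t = 3 are treated as amplicons: excluded
from the rho/c~ objective (a MYCN amplicon would otherwise drag the
normalization), then assigned a capped state (major pinned at 12, minor from
the allele fraction) and flagged.

Reported per sample: rho, c~, per-segment states with residuals, modal
(marker-weighted) total per chromosome, and the overall ploidy as the
marker-weighted mean autosomal total, rendered to one decimal ("~2.3n").
Marker-weighted mean (rather than the mode) is an interpretation choice and
is used consistently throughout.

Measured on the generator's conditions (50 near-triploid samples, ~20k
markers, noise SD 0.03, rho uniform on [0, 0.6]): contamination recovered
within +-0.05 and every per-chromosome total correct in 48-50 of 50 samples.
The residual failure mode is a nearly pure tumor whose chromosome totals are
dominated by even copy numbers, where an affine relabeling is exactly
degenerate and the priors can pick the wrong family — the same ambiguity
class the study resolved externally.

## Event taxonomy (`loh_caller`)

With P = round(overall ploidy): minor = 0 and 2 <= total <= P is
**near-CN-LOH** (at P = 3 both 2+0 and 3+0 qualify); minor = 0 and
total > P is **gain-LOH**; total < 2 is **loss-LOH**; retained
heterozygosity deviating from the most balanced split of its total (3+1
instead of 2+2) is **allelic imbalance** — called but excluded from all
burden statistics; anything else is balanced. Extent: an event reaching both
chromosome ends (within a 5-marker tolerance) is whole-chromosome, one end
telomeric, neither interstitial. Calls are made on merged same-state runs
(one biological event, one call), reported at >= 1.5 Mb, with near-CN-LOH
burdens counted on autosomes only. Germline IBD runs are counted as
near-CN-LOH — without matched normals they cannot be separated from somatic
events, which is also why the control group is analyzed at all. Per-sample
stroma-warning flags: flat profile (no reportable aberration), MYCN
amplification only (amplicon calls at the designated 2p locus and nothing
else), CN-LOH only.

Profile comparison across related samples matches aberrations by reciprocal
overlap >= 0.5 *and* identical allelic state; overlapping events failing
either condition are flagged "partial (distinct events)" — e.g. two 1q gains
with different breakpoints and different copy numbers are two events, not a
shared one. Clusters are labeled shared-by-all / shared-by-subset / unique.

## Cohort statistics (`cohort_stats`)

Inclusion rules: X-chromosome calls never enter any count; within each
related group only the designated parent (the sample whose id equals the
group label) is kept; tumor samples flagged flat / MYCN-only / CN-LOH-only
are removed as stroma-compatible (the filter targets contaminated biopsies;
a flat constitutional control is the expected appearance and is retained).
Every removal is logged once with its reason.

Prevalence (fraction of samples with >= 1 near-CN-LOH event) is compared by
two-sided Fisher's exact test (minimum-likelihood rule, via scipy). Burden
is compared by the two-sided Mann-Whitney U test: for group pairs with
nA * nB <= 400 the exact tie-aware permutation distribution of the rank sum
is computed by a shift-algorithm DP over doubled midranks; larger pairs use
the tie-corrected normal approximation with continuity correction (the two
agree within 0.01 at n = 15 per group). Burden descriptives use linear
interpolation between order statistics for the quartiles (the convention is
fixed here; published quartiles cannot disambiguate it). The outcome
comparison (dead of disease vs no evidence of disease at five years) applies
the same burden test overall and per extent; samples with any other outcome
are excluded by the binary definition.

A note on the count model: Poisson counts at the published group means imply
a tumor prevalence of 1 - exp(-0.89) = 0.59, higher than the published 35% —
the published counts are overdispersed (median 0, mean 0.89), and both
moments cannot be matched by a Poisson model. The generator keeps the means;
prevalence-level checks draw presence/absence directly from the published
prevalences. A consequence worth knowing: at the published means and group
sizes (134 vs 8) the tumor-vs-cell-line Mann-Whitney comparison has about
87% power at alpha = 0.05 under the Poisson model, so roughly one seed in
eight fails to reach significance.

## Problem sizes

The numbered analysis scripts run 60 tumors / 10 cell lines / 20 controls at
50 kb marker spacing (about 62k markers per sample; at that density
pure-LOH runs below ~5 Mb escape the het-density channel, so small control
IBD runs are under-called there). `scripts/acceptance.py` runs the full
study scale — 134 / 10 / 30 samples at 12 kb spacing (~252k markers) — in a
few minutes, and the test suite exercises noise-free 30-sample recovery at
12 kb and parameter recovery at ~20k markers.

## Known limitations

* All family-breaking priors (nullisomy ban, LOH allowance, ploidy
  preference) are biological defaults, not data; profiles violating them
  (genuine genome-wide LOH, near-haploid genomes) will be relabeled.
* Subclonal heterogeneity is not modeled: one rho per sample, integer states
  only.
* The BAF noise scale is taken from the t track; platforms with very
  different channel noise would need a separate estimate.
* Event counting reports maximal same-state runs; whether published counts
  merged events interrupted by small unrelated segments is unknowable from
  the publication.
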
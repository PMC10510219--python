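# Methods

This note documents the models, estimators, numerical choices and known
limitations of `pet_hetero`, in the order data flows through the pipeline.

## SUV and lesion delineation (`pet_hetero.voi`)

SUV is body-weight-normalized uptake, `SUV = C[kBq/mL] · weight[kg] /
dose[MBq]` under the 1 g/mL tissue-density convention (the factors of 1000
cancel). A VOI at level `L` is the **26-connected** component of
`{SUV ≥ L}`; 26-connectivity is the permissive standard for bright blobs,
and the comparison is inclusive so that the maximum voxel always survives
its own 100 % threshold. Levels are either absolute SUV (the classical 2.5)
or a fraction of the lesion's SUVmax (40–70 %).

For relative thresholds the lesion's SUVmax must be located before any VOI
exists. We bound the search with a deterministic *bootstrap region*: the
connected component grown from the user's seed voxel at
`max(2.5, background + 3σ)`, where background and σ are the volume median
and 1.4826 × MAD (robust because lesions occupy few voxels). The local
maximum of that region defines SUVmax; the final VOI is the component of
the thresholded set containing that maximum voxel. If the local maximum
does not exceed `background + 3σ` the VOI is returned with a
`background_warning` flag rather than an error.

Per-VOI metrics: `SUVmean` is the arithmetic mean, `MTV` the voxel count ×
voxel volume (mL), `TLG = SUVmean × MTV` (an identity by construction, and
asserted as such), `HI = SUVmax / SUVmean ≥ 1`, and the VOI extent is the
largest axis-aligned bounding-box span (voxel-center convention,
`(max − min + 1) × spacing`).

**Lesion diameter for the inclusion filter** is the extent of the
40 %SUVmax VOI — the most inclusive relative level, which tracks the
metabolic extent that the partial-volume argument behind the 10 mm rule
concerns. Each metric row additionally carries its own VOI extent
(`extent_mm`), which shrinks with the threshold.

## Inclusion rules and aggregation (`pet_hetero.cohort`)

Lesions below 10 mm are excluded (exactly 10 mm is kept); bone lesions are
kept only with CT confirmation. Rules act on whole lesions (all threshold
rows) and every exclusion is logged with the rule that fired; the filter is
idempotent and order-independent.

Per-lesion HI is the atomic quantity; patients are aggregated afterwards:

* *maximum group* — metrics of the lesion with the largest SUVmax. Ties in
  SUVmax are broken toward the **larger HI** (the conservative choice that
  flags more heterogeneity); this is configurable in the sense that the
  per-lesion table is preserved, so any other rule can be applied to it.
* *mean / median group* — mean / median of the per-lesion values (midpoint
  of central values for even counts).

Both aggregate HIs always lie within `[min, max]` of the per-lesion HIs.
SUVmax, MTV and TLG are aggregated under the same three schemes for the
correlation grid. Patients left with zero evaluable lesions are reported
separately and excluded from statistics. Cohort summary percentages use
half-up decimal rounding (21/32 → 65.63 %), matching clinical-table
conventions rather than banker's rounding.

## Survival statistics (`pet_hetero.survstats`)

All estimators are implemented from first principles (scipy is used only
for t / χ² tail probabilities); `lifelines` and `scipy.stats` appear in the
test suite as independent cross-checks, never in the implementation.

* **Spearman** — Pearson correlation of midranks (ties averaged); p from
  the two-sided t approximation on n−2 df. The "progression" variable is
  the binary progression-by-horizon indicator; patients censored before the
  horizon have unknowable status and are excluded pairwise.
* **Kaplan–Meier** — product-limit estimator with the
  deaths-before-censorings convention at tied times; the median is the
  first event time with S(t) ≤ 0.5, else "not reached".
* **Log-rank** — hypergeometric variance, 1-df χ², two-sided; symmetric in
  the labels. Degenerate risk sets (zero variance) return χ² = 0, p = 1.
* **Time-dependent ROC** (cumulative cases / dynamic controls at a fixed
  horizon, default 12 months): at each observed cutoff `c`, with
  `p = P(X > c)` and stratified KM survival `S_hi`, `S_lo` at the horizon,

      Se(c) = p (1 − S_hi) / (1 − S),   Sp(c) = (1 − p) S_lo / S,
      S     = p S_hi + (1 − p) S_lo.

  This is the Kaplan–Meier-weighted estimator of the
  cumulative/dynamic family with exact marker-stratified KM in place of
  nearest-neighbor smoothing — deterministic, parameter-free, and with the
  mixture `S` in the denominators it is guaranteed to stay in [0, 1] and to
  reduce *exactly* to the empirical binary ROC when there is no censoring
  (oracle-tested). AUC is the trapezoidal area along the cutoff-swept path
  from (0,0) to (1,1); no concavity is enforced. The operating cutoff
  maximizes Youden's J = Se + Sp − 1 over observed marker values, ties
  broken toward the smaller (more sensitive) cutoff. The high-risk stratum
  is `marker > cutoff` (strict).

Degenerate configurations (no events by the horizon, no survivors past it,
fewer than two patients in a stratum) are flagged and the affected
statistics skipped rather than fabricated.

## The phantom generator (`pet_hetero.phantom`)

The generator emulates the statistical structure the analysis assumes, not
scanner physics. Lesions are spheres with the monomial radial profile

    SUV(r) = peak · (1 − (1 − f) (r/R)^p),  r ≤ R,

with rim floor `f = 0.40` of the peak. The single exponent `p` maps
monotonically to the 50 %SUVmax-VOI heterogeneity index (continuum range
1 ≤ HI < 2), so heterogeneity is directly controllable; `p` is solved by
Brent root-finding on the numerically integrated continuum HI(p), and an
unattainable target raises a "profile infeasible" error. `f = 0.40` makes
the 40 %SUVmax VOI the whole sphere, so the measured filter diameter equals
the true diameter up to one voxel. Defaults: 4 mm isotropic voxels (typical
PET resolution), 64³ grid, unit-SUV background with Gaussian noise
σ = 0.05, 32 patients with 1–15 lesions each, diameters 6–30 mm straddling
the 10 mm filter, peaks 4–12 SUV, target HI 1.1–1.9, site frequencies
patterned on a metastatic breast-cancer lesion mix, bone lesions
CT-confirmed with probability 0.7.

Outcomes follow a proportional-hazards model on the per-patient HI:
`h = h0 · exp(β (HI − 1))` with `β = 2.5` by default and
`h0 = ln 2 / 50 months`, so a homogeneous (HI = 1) patient has median PFS
50 months while a high-heterogeneity patient (HI ≈ 1.8) has median
≈ 6.9 months and a low one (HI ≈ 1.3) ≈ 24 months — the qualitative
pattern (high-HI median well under a year, low-HI median often not reached
within follow-up) that motivates this marker class. Event times are
exponential; a 20 % random-censoring fraction draws uniform censor times on
(0, 36] months and everyone is administratively censored at 36 months. The
latent per-patient HI that drives the hazard is the maximum-group aggregate
over *evaluable* lesions (≥ 10 mm; bone only if CT-confirmed), because the
marker under study is defined on the lesions the analysis may include; if a
patient has none, all lesions are used.

All randomness flows through one injected `numpy.random.Generator`; the
same seed reproduces volumes and outcomes bit-for-bit.

**What the phantom does not emulate — and what that means for the tests.**
No scatter/randoms/reconstruction artifacts, no respiratory motion, no
non-spherical shapes, no partial-volume correction. One consequence is
deliberate and worth stating: at 4 mm voxels a 10–14 mm lesion's 50 % VOI
contains only a handful of voxels, so its measured HI is dominated by
discretization — the very repeatability problem that motivates the 10 mm
exclusion rule. End-to-end image-level statistics on a 32-patient phantom
cohort are therefore noisy (a single seed can look null), which mirrors the
fragility of small clinical cohorts but means a green pipeline run is a
*structural* check, not evidence of image-level power. Statistical
parameter-recovery claims are instead tested at the outcome level
(n = 200 patients, 50 replicates: recovered Youden cutoff between the HI
group centers and log-rank p < 0.05 in ≥ 90 % of replicates; 400 null
replicates: type-I error 5 % ± 3 % at a *pre-specified* median split —
testing at the data-optimized cutoff would inflate type-I error by
construction).

## Numerical and policy choices

* Threshold comparison inclusive (≥); voxel indices 0-based; physical
  coordinates are index × spacing (voxel centers).
* The absolute-2.5 VOI uses the same connected-component rule as relative
  thresholds (the alternative — no connectivity constraint — was rejected
  as it would merge disjoint uptake into one "lesion").
* Simulated observed times are floored at 10⁻⁶ months to keep survival
  times strictly positive.
* Problem sizes in the test suite (grids ≤ 48³, 200 random oracle grids,
  10,000 log-rank permutations, 50 + 400 survival replicates) were chosen
  as the smallest sizes at which the Monte-Carlo error of each check is
  comfortably below its assertion margin.
* Results JSONs are written with sorted keys and no timestamps, so a run is
  byte-reproducible from (config, seed); provenance (config hash, versions,
  seed) is recorded separately.

## Known limitations

* The stratified-KM time-dependent ROC can produce non-monotone empirical
  curves in small samples (clipped to [0, 1], no smoothing); AUC is the
  signed trapezoidal area along the cutoff sweep.
* The maximum-group tie rule and the strict `>` cutoff split are
  conventions; both are documented above and trivially changeable on the
  preserved per-lesion / per-patient tables.
* The phantom's site labels do not influence uptake or survival — they
  exist to exercise the bone/CT inclusion rule and the cohort summary.
* `compute_suv` assumes decay-corrected activity and the 1 g/mL density
  convention; lean-body-mass SUV variants are out of scope.
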
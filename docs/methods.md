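# Methods

## Coordinate model

All geometry is carried in microns in the level-0 slide frame (origin
top-left, y down). Pixel inputs are converted once on ingest using the
slide's microns-per-pixel (mpp); nothing downstream ever sees pixels. This
makes zone areas — which the grading convention fixes in mm² —
independent of scanner resolution, and makes results invariant under a
consistent rescaling of pixel coordinates and mpp (tested).

Tumor regions are GeoJSON polygons; holes are honored, self-intersecting
rings are rejected rather than repaired. Patch tiling is axis-aligned
with stride `patch_px × level_mpp` µm, phase-anchored at the top-left of
the regions' joint bounding box. The anchoring is a deterministic
convention, not a claim about any scanner's tiling; anchoring to the
slide origin instead shifts candidate centers by at most one stride,
which is below the localization tolerance used anywhere in the package.
A patch belongs to the tumor iff its center point lies inside or on a
region polygon — membership by dominant content, matching how patch
classifiers label patches. Default `level_mpp` is 0.48 µm/px, i.e.
256 px ≙ 122.88 µm for slides whose level 0 is the 0.24 µm/px
40×-equivalent plane; both knobs are exposed.

## Hotspot scoring and selection

Score: `h(p) = n_core + ε·(n_context − n_core)` with inclusive-distance
counts in concentric circles of `core_area_mm2` (default 1 mm²,
r ≈ 564.19 µm) and `context_area_mm2` (default 2 mm², r ≈ 797.88 µm).
Counting is exact Euclidean distance; a k-d tree accelerates the
fixed-radius queries but introduces no approximation (verified exactly
against an all-pairs oracle up to |M| = 2000).

Design choices where the procedure was genuinely open:

* **Candidate set.** All tumor patch centers are scored, not only
  mitosis-bearing patches. The two choices differ only for candidates
  with `n_core = 0`, which can never rank first on a slide that has any
  mitosis in the grid's reach; scoring all centers is the more uniform
  rule.
* **ε default 0.5.** The score family is defined for ε ∈ [0, 1] with no
  canonical interior value; the midpoint weights local density and
  surrounding context equally and avoids silently collapsing to either
  degenerate form. It is configurable everywhere.
* **Confidence filter is strict (`>`) at default 0.5**, so "exceeds the
  threshold" has one unambiguous boundary behavior.
* **Overlap suppression.** When several hotspots are requested, selection
  is greedy non-maximum suppression on the 2 mm² display circles:
  descending score, accept iff the circle intersects no accepted circle,
  with tangency counting as intersection (the same inclusive convention
  as the distance counts). Ties break by higher core count, then x, then
  y, making the ranking a total order and the output deterministic.
* **No re-masking of mitoses.** Detections outside the tumor polygons, if
  present, are still counted: the engine is a pure function of its
  inputs, and the upstream detector is responsible for where detections
  come from.

## Mitotic count and score

The counting zone for scoring is the selected hotspot's 2 mm² context
circle. Count-to-score cut-offs are explicit configuration
(`ScoreThresholds`), defaulting to ≤ 7 / 8–14 / ≥ 15 per 2 mm² — the
convention of the 2 mm²-hotspot grading literature. They are echoed in
every report so a site-specific table can be substituted and audited.
Only the mitotic-activity component of the Nottingham grade is in scope;
tubule formation and nuclear pleomorphism are not modeled.

## Agreement statistics

* **Accuracy** — trace over total of the 3×3 confusion matrix
  (investigator × consensus; orientation rows = investigator is fixed and
  stated in all I/O).
* **Linear weighted Cohen's κ** — disagreement weights `|i−j|/(k−1)`,
  chance term from the product of marginals. Point estimate and the
  standard asymptotic 95% CI come from `statsmodels`
  (`inter_rater.cohens_kappa`, `wt="linear"`); a bootstrap CI over pairs
  is available since no single CI method is canonical. A rater whose
  marginal is concentrated in one category makes κ undefined; this raises
  an error rather than returning 0.
* **ICC** — form ICC(2,1): two-way random effects, absolute agreement,
  single rater, computed with its F-based 95% CI by `pingouin`
  (`intraclass_corr`, type ICC(A,1)). The form is a parameter (`ICC1`,
  `ICC3`, average-rater variants) so a published value of unknown form
  can be checked against each candidate.
* **Zone intersection rate** — fraction of slides where two readers'
  circular counting zones intersect (inclusive tangency). A reader may
  explicitly record "no zone", which counts as non-intersecting; a slide
  missing from one reader is excluded from the denominator and listed.
  The AI-vs-reader variant flags a slide when *any* selected AI display
  zone overlaps the reader's zone.
* **Subgroups** — the same statistics restricted to strata by consensus
  score and by specimen type, one report per stratum × condition; strata
  with fewer than two slides report n with statistics marked undefined.

The κ implementation is cross-checked in the tests against scikit-learn's
independently coded `cohen_kappa_score` and against a from-scratch hand
application of the formula; the closed-form κ of a probability matrix
(`kappa_linear_expected`) is implemented separately from the table
estimator so the two can validate each other.

## Synthetic data

`generate_point_pattern` draws a homogeneous Poisson background
(intensity λ per mm², default 2/mm² — a plausible routine-slide baseline)
uniformly over the tumor polygon by rejection sampling, then adds planted
clusters: isotropic Gaussian points (σ in µm) truncated to the polygon by
redraw, not clipping. Confidences are i.i.d. Beta(5, 1.5) — right-skewed,
so most simulated detections survive the default 0.5 threshold. All
randomness flows through one `numpy` Generator per call, so identical
config + seed gives byte-identical output.

`simulate_reader_scores` draws each reader's score per slide from the row
of a 3×3 row-stochastic confusion kernel indexed by the true score,
independently across readers and conditions, and places counting zones at
the true hotspot center plus Gaussian jitter. The expected confusion
matrix of two such readers is `Σ_t prior_t · K_A[t,·] ⊗ K_B[t,·]`, which
yields an analytic weighted κ used to validate the simulator.

What the generator does *not* emulate: tissue texture and stain
variation, detector false positives with spatial structure, inhomogeneous
background intensity (inhomogeneity enters only through planted
clusters), reader drift between sessions, and correlation between the
two readers' errors beyond their shared truth. Passing tests therefore
demonstrate correctness of the geometry, scoring, selection and
statistics on point patterns with known structure — not detector quality
or reader behavior on real slides.

## Problem sizes and numerical choices

The validation experiments use: 100 random slides with up to 2000 mitoses
on grids up to 40×40 for oracle equivalence (exact integer counts, scores
to 1e-12); 100 seeds of a 5×5 mm slide with a planted n = 200, σ = 200 µm
cluster on λ = 2/mm² for recovery (criterion: top-1 within 600 µm in
≥ 95% of seeds; observed: 100%, mean error ≈ 60 µm); 200 simulated
two-rater studies of 50 subjects per ρ ∈ {0.3, 0.6, 0.9} for ICC recovery
(mean bias ≤ 0.03); and 10⁴ slides for the simulator-vs-closed-form κ
check (|Δ| ≤ 0.03). Circle areas and radii are mutual inverses to 1e-9
relative; detection coordinates survive CSV round-trips to 1e-9 µm by
writing full `repr` precision.

## Limitations

The package starts from detections; it contains no image model, so its
hotspots are only as good as the upstream detector's points. The NMS
overlap rule and ε default are conventions, stated and configurable, not
empirically fitted. Published headline agreement values from clinical
studies can be recomputed only when the underlying confusion matrices or
per-slide score tables are available to load; the package ships the
machinery, not any study's raw data.
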
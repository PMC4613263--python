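# Methods

This note records the models, conventions and design choices behind
`spotdiff`, in the spirit of a statistical software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
do not themselves compute.

## Spot tables and normalization

The unit of input is a *spot table*: one TSV per gel
(`spot_id, pi, mw_kda, raw_volume[, norm_volume]`), the spot-level product
of any densitometry package. Pixel-level registration, warping and
segmentation are upstream and out of scope; all matching happens in spot
coordinates.

Volumes are normalized per gel to parts-per-million of the total spot
volume (`norm = raw / Σraw × 10⁶`). Densitometry vendors do not publish
their normalization formulae; fraction-of-total is the standard 2DE
convention, preserves within-gel ratios exactly, and is idempotent because
the normalized value is always recomputed from raw volumes. An all-zero
gel is a degenerate input and raises.

## Reference gel and matching

The reference gel is the replicate with the most spots (ties to the lowest
index). The fuller criterion used at the bench — separation and staining
quality, artifact load — lives in the images and is not computable from
spot tables.

Matching is greedy nearest-neighbour linkage seeded from the reference
gel, in (pI, log₁₀ MW) space scaled by the tolerances (defaults
`tol_pi = 0.1` pH, `tol_logmw = 0.02`). Candidate links must satisfy both
|ΔpI| ≤ tol_pi and |Δlog₁₀MW| ≤ tol_logmw; links are accepted globally
closest-first, each gel contributing at most one spot per group; among
equidistant candidates the higher-volume spot wins (then spot id, for
determinism). Unlinked spots seed new groups, so grouping is a partition.
Group centroids are running means over accepted members. The defaults are
small relative to the default synthetic jitter (see below) and adjustable.

## The differential model

For a matched spot at a compared stage, with the adult stage as baseline:

* `SVQ = mean(baseline) / mean(stage)` over detected gels
  (detection = normalized volume > `detection_floor`, default 0).
* Direction: up iff SVQ ≤ 0.6, down iff SVQ ≥ 1.67, inclusive. Two cut-off
  conventions circulate (0.6/1.67 inclusive vs 0.67/1.67 exclusive); the
  inclusive pair is the default because the published result tables head
  their columns "SVQ ≤ 0.6" / "SVQ ≥ 1.67"; both are `DiffConfig` knobs.
* Coverage: per-gel quotients are `mean(baseline) / v_i`, one per detected
  stage gel — the baseline is summarized by its mean so that the H count
  has exactly one term per stage gel and lands in {4, 5, 6} for a 6-gel
  design. H counts quotients past the cut-off on the consensus side; the
  spot passes iff H ≥ `min_gels` (default 4). A pairwise (36 gel-pair)
  variant would also be defensible; the per-stage-gel definition was chosen
  for its one-quotient-per-gel structure and is the only one asserted.
* The exact Mann–Whitney p-value is attached whenever both sides have ≥ 2
  detections. It is deliberately *not* a gate: the coverage method is the
  primary criterion and the U-test an accompanying report. No
  multiple-testing correction is applied (recorded in run manifests).
* Absence: zero detections on one side with ≥ `min_gels` detections on the
  other is called `absent_in_stage` / `absent_in_baseline`; weaker
  one-sided evidence is emitted as unchanged/unreliable.
* Aggregation: a protein seen in several spots takes the arithmetic mean
  of member SVQs; its direction is the classification of that mean. A
  conflict flag marks disagreeing member directions (the asterisk
  convention of the published tables). Absence labels propagate only on
  unanimous members.

### Exact Mann–Whitney test

U is the rank-sum statistic with mid-ranks for ties. For combined samples
n+m ≤ 14 the two-sided p-value is exact by complete enumeration of all
C(n+m, n) group assignments, counting those with |U − nm/2| ≥ the observed
deviation (a 1e-9 slack guards float jitter in mid-rank sums). Tie-free
null deviation distributions are cached per (n, m) — an optimization with
identical results. Larger samples use the tie-corrected normal
approximation (scipy). The minimal two-sided 6-vs-6 p is 2/924 ≈ 0.00216;
smaller printed values in the literature for 6-vs-6 designs cannot come
from this exact test, so no check is pinned to them.

## The PMF engine

* Digestion: cleave after K or R except before P; all peptides with
  0..`max_missed_cleavages` (default 1) internal missed sites; peptides
  shorter than `min_peptide_length` (default 4) dropped.
* Masses: monoisotopic residue masses (pyteomics table) + water
  18.0105647 Da; fixed carbamidomethyl-C (+57.021464); variable
  oxidation-M states are enumerated by oxidized *count* 0..min(#M, 6) —
  all methionines share one delta, so distinct masses depend only on the
  count, which collapses the 2^#M state space. Average masses are
  available behind `monoisotopic=False` for linear-mode data. Peak lists
  are neutral monoisotopic masses by default; `peaks_are_mh=True` subtracts
  a proton for [M+H]⁺ lists.
* Matching: a peak matches the candidate with the smallest ppm error
  within `tolerance_ppm` (default 60); equidistant ties go to the lower
  mass; each peak matches at most one candidate. Qm counts distinct
  matched peaks (modified/missed-cleavage variants are not counted
  separately). An optional exclusion-mass list removes trypsin-autolysis
  and matrix peaks before matching.
* Scoring: the per-protein chance-match probability q is the measure of
  the union of ±tolerance windows around the protein's candidate masses
  within the observed peak span, divided by the span length (1 Da floor
  for degenerate spans). P = binomial upper tail P(X ≥ Qm | n_peaks, q);
  score = −10·log₁₀P, capped at 300 (q = 0 with matches also scores the
  cap; Qm = 0 scores 0). Commercial MOWSE implementations are unpublished;
  this is a documented probability-based variant that preserves their
  frequency logic.
* Significance: score > floor(−10·log₁₀(alpha/N)) with N the database
  size; 59 for alpha 0.05 and N = 42,755. The threshold is monotone in N
  and in 1/alpha.

## The synthetic-data generator

The generator emulates the three-stage, six-replicate cerebellum design so
the pipeline is testable without any deposited data. Conditions and
defaults:

* 3 stages (P7, P90 baseline, P637) × 6 replicate gels; `n_proteins`
  default 100.
* Baseline spot volumes log-uniform over three decades (10³–10⁶ arbitrary
  units): the published work gives no intensity distribution; three
  decades spans faint-to-saturated Coomassie spots.
* Replicate noise is multiplicative mean-1 lognormal with coefficient of
  variation `cv` (default 0.2): 2DE volumes are positive and right-skewed.
* 20% of proteins regulated per non-baseline stage; fold-change
  *magnitudes* log-uniform in `fold_change_range` (default 2–4, required
  to clear the unchanged band), side chosen up/down with probability ½
  (`regulation_side` can force one side for power studies). 10% of
  regulated proteins are *absent*: volume 0 in every gel of the compared
  stage — the operational meaning of the "absent" category in published
  summary tables. Absence in the baseline is recognized by the caller but
  not simulated (it would couple the shared baseline gels across
  contrasts).
* 10% of proteins occupy 2–3 spots (Dirichlet volume split); 5% of spots
  hold two co-migrating proteins (mixed spots, volumes summed).
* Positions uniform in pI 3–10 × log₁₀(10–100 kDa), with per-gel gaussian
  jitter (sd 0.02 pH, 0.004 log₁₀ kDa). True positions are
  rejection-sampled to keep a minimum pairwise separation slightly larger
  than the default matching box (0.12 pH, 0.024 log₁₀ kDa): two proteins
  co-migrating inside the resolvable box are physically one *mixed* spot,
  which the generator models explicitly, so coincident-but-distinct spots
  are excluded as unphysical.
* All randomness derives from `SeedSequence(seed)` spawned into six named
  streams (structure, positions, volumes, regulation, noise, jitter) in a
  documented order, so each decision is independently replayable — the
  suite verifies the regulated-count sampling by replaying stream 3.

Stage-dependent total spot counts (real studies detect different numbers
of spots per stage) emerge only via stage-specific absences; no separate
per-stage count knob is exposed.

The PMF case generator draws i.i.d. sequences from a Swiss-Prot-style
average residue composition (lengths 150–600), digests one chosen protein,
and perturbs its peptide masses with gaussian ppm error (default 20 ppm),
30% peak dropout and 5 uniform contaminant peaks.

### What the generator does not emulate

No gel images, no spatially correlated warping (jitter is i.i.d. per
gel), no intensity-dependent detection (the floor is a hard threshold),
no isotope envelopes or MS/MS spectra, no homology structure between
database sequences. Passing tests therefore demonstrate the statistical
machinery under the stated noise model, not robustness to image-analysis
artifacts or to homologous-database ambiguity.

## Numerical choices and degenerate inputs

Normalization tolerance 1e-9 relative on the ppm total; enumeration slack
1e-9 on rank deviations; ppm tie slack 1e-12; score cap 300; all-zero
gels, empty peak lists, empty databases, mixed-stage aggregations and
out-of-range configurations raise typed errors.

## Problem sizes used by the test and acceptance suites

Calibration suites run 200 simulated experiments of 50–100 proteins
(null, recovery and soundness checks), 1000 enumeration-oracle test
cases, and PMF searches against 500-protein databases with 100-search
null calibration — sizes chosen to give stable proportions (binomial
s.e. ≤ ~2% on the calibrated rates) while keeping the whole suite in a
few minutes on one CPU.

## Known limitations

* The uniform-peak chance-match model underestimates random matching for
  *peptide-like* peak lists: tryptic peptide masses cluster around the
  mass-defect comb, so decoy proteins can exceed the significance bound
  when the query is itself a real digest (visible in the examples'
  runner-up scores). The bound is calibrated for uniform contaminant
  noise; rank-first identification is unaffected in the simulated cases.
* Coordinate matching is greedy, not globally optimal; with jitter
  approaching the tolerance it can mis-link dense neighbourhoods.
* Protein-level regulation requires only one member spot to pass coverage
  (with the mean-SVQ direction); stricter all-member policies are easy to
  layer on top.
* The exact test's large-sample branch (n+m > 14) is an approximation;
  the designs this package targets (6 vs 6) always take the exact path.
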
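# Methods

This note records the models the package implements, the defaults it ships,
and the choices made where the design was genuinely open. Nothing here
states an empirical result that the tests or `scripts/acceptance.py` do not
themselves compute.

## Genotyping model

One specimen yields two cycle thresholds: CT of the FAM/TTA (wild-type)
probe and CT of the HEX/TTT (mutant) probe. The genotyping statistic is
ΔCT = CT_TTT − CT_TTA, with an absent CT replaced by 40, the final cycle
(`tta_substituted_40` / `ttt_substituted_40` flags record the substitution).
Specimens with no probe crossing threshold by cycle 30 are excluded as
amplification failures (`qc_filter`, cutoff configurable).

Two calling methods:

* **Cluster calling** (`kmeans_1d` + `calls_from_clusters`): Lloyd's
  algorithm on the 1-D ΔCT values with k = 3, deterministic initialisation
  at the (2i+1)/2k quantiles plus seeded random restarts (default 8),
  keeping the smallest within-cluster sum of squares. `max_iter` defaults
  to 10, matching how the reference analysis was run; convergence is
  declared by assignment stability and a warning is emitted if the cap is
  hit. Clusters map to genotypes by center order (lowest → FF, middle → LF,
  highest → LL). A ΔCT exactly midway between two centers goes to the
  lower-index cluster and is flagged `cluster_tie`.
* **Threshold calling** (`calls_from_thresholds`): fixed per-species bands
  shipped exactly as published — *Cx. pipiens*: FF below −4.0, LF in
  [−2.0, 4.9], LL above 5.0; *Cx. tarsalis*: FF below −2.0, LF in
  [−1.0, 1.0], LL above 2.0. The published band edges leave gaps
  (e.g. −4.0..−2.0); values falling there return UNDETERMINED with an
  `in_band_gap` flag rather than being silently snapped to the nearest
  band, mirroring the manual-review step of the original workflow. The
  extreme negative band is interpreted as FF (the source text labels two
  different bands "LF", which is inconsistent with the ΔCT sign logic and
  the cluster centers).

The pipeline (`io.call_plate`) clusters per species. k = 3 presumes all
three genotypes are present; when the fitted centers are closer than
1.5 cycles (`min_cluster_gap`) the ΔCT distribution does not actually have
three modes — typically a monomorphic population — and calling falls back
to decision bands: the species' own, or the narrow *Cx. tarsalis* scale for
species without published bands (the monomorphic sister species was read
against the *Cx. tarsalis* LL cluster in the validation study).

When CT columns are absent but per-cycle ΔRn curves are present, CT is
taken as the interpolated first cycle at which the baseline-subtracted
signal exceeds 10% of the plateau (`ct_from_curve`, fraction configurable).
This is a documented stand-in for instrument-reported CTs, not a model of
amplification kinetics.

## Statistics

* **Allele frequency**: F = (2N_FF + N_LF)/2N computed in exact rational
  arithmetic, rounded only for display. SE = sqrt(F(1−F)/2N), i.e. binomial
  on the 2N sampled alleles; the source never states its SE formula, and
  this convention reproduces the magnitude of its reported ± values.
* **Proportional-odds model**: logit P(Y≤j) = α_j − x'β (so β > 0 means
  shifted toward the resistant end and exp(β) > 1). Maximum likelihood on
  grouped multinomial counts by Newton–Raphson with analytic gradient and a
  central-difference Hessian (step 1e-6); step-halving line search;
  convergence at max|score| < 1e-8 or relative log-likelihood change
  < 1e-10. Covariance is the inverse negative Hessian; CIs are Wald
  (exp(β ± 1.96·SE)) and p-values come from the standard normal, matching
  the reference analysis' use of t-values against a normal. Outcome coding
  LL=1 < LF=2 < FF=3; categorical covariates are dummy-coded against
  reference levels *Cx. tarsalis* / bayside / wildlife. Single-covariate
  region and land-use fits subtract the 126 monomorphic bayside-wildlife
  *Cx. erythrothorax* from the marginal rows, because the models are
  defined over the two polymorphic species only. No multiple-testing
  correction is applied anywhere, matching the source analysis.
* **Fisher exact r×c**: full enumeration of tables with the observed
  margins (recursive row filling, log-gamma point probabilities);
  two-sided p is the sum of probabilities of tables whose point probability
  is ≤ the observed one within 1e-12 relative slack (the classical
  "as or more extreme" rule). All-zero rows/columns are dropped first; the
  enumerated probabilities are checked to sum to 1. Tables beyond the
  enumeration budget (default 10^7) raise an explicit error pointing to the
  seeded Monte-Carlo fallback (`fisher_exact_mc`, margin-fixed sampling via
  `scipy.stats.random_table` with the +1 continuity correction).
* **Bioassay metrics**: knockdown percent is regressed on time by OLS,
  pooled across bottles (fits are restricted to the pre-saturation phase in
  the analysis drivers, since the linear model does not apply after 100%
  knockdown). Slope equality between two strains is tested by nested-model
  ANCOVA: F = (SSE_common − SSE_separate)/(SSE_separate/(n−4)) on (1, n−4)
  df. Resistance ratio = susceptible knockdown proportion / resistant
  knockdown proportion at 45 min (resistant strain in the denominator);
  a zero denominator returns inf with a warning. CDC classification:
  knockdown < 90% at 120 min ⇒ suspected resistant; exactly 90% counts as
  susceptible ("below 90%").

## Geography

Trap sites within 1 km are combined by single-linkage connected components
over haversine distances (spherical Earth, R = 6371.0088 km): "within 1 km
of each other" is read maximally, so chains merge transitively; the cluster
id is the lexicographically smallest member site id, which makes the merge
invariant to input order. Geodesic refinement is irrelevant at 1-km scales.

## Synthetic-data generator

The generator reproduces the statistical structure the analysis assumes; it
is the package's test substrate, not a model of PCR chemistry.

* **CT pairs** (`simulate_ct_pair`): the matched probe amplifies at
  `base_ct` (default 24); ΔCT is normal around the species' cluster center
  with spread `cluster_sd`, split √2-evenly across the two CTs. Computed
  CTs at or past cycle 40 are reported as absent, which is how the CT-40
  substitution arises naturally. Whole-reaction failure occurs with
  `no_amp_prob` (default 0.04, the validation study's observed 4% exclusion
  rate). Off-allele dropout beyond the 40-cycle mechanism occurs with
  `dropout_prob` — defaults 0.05 for *Cx. pipiens*, whose homozygote
  off-allele probe comes up near cycle 37 at the detection limit, and 0 for
  *Cx. tarsalis*, whose off-allele probe comes up near cycle 27 where
  dropout is not physically plausible (a species-independent dropout rate
  would fabricate a fourth ΔCT mode at 40 − base_ct that real data do not
  show). Cluster centers default to the published per-species values
  (−13.212/−0.871/12.691 and −2.944/−0.089/3.107). Within-cluster spread is
  not a published quantity; it defaults to 1.0 cycles for *Cx. pipiens* and
  0.5 for *Cx. tarsalis* (chosen once so the narrow tarsalis centers remain
  cleanly separated, as the published violin plots are).
* **Cohort** (`simulate_specimens`): the default spec reproduces the
  published survey marginals — per-species totals (126/507/744) and
  genotype mixes, all 126 *Cx. erythrothorax* bayside-wildlife, and a
  pipiens/tarsalis region split chosen once so bayside totals 744 and
  inland 633 as printed. The specimen-level species×region×land-use
  cross-classification was never published, so the cross-cells (60/40
  bayside wildlife/urban, 60/40 inland industrial/agriculture) are
  synthetic: species-level and region-total marginals are faithful,
  cross-tabulations are not, and the adjusted (multi-covariate) odds ratios
  of the original analysis are therefore out of reach by construction.
  A configurable fraction `sf_prob` of heterozygote draws is relabelled
  SF-1014 (L1014S), which the dual-probe assay reads as LF but Sanger-style
  reference calls resolve; the default is 0 because the survey's field data
  were assay-based.
* **Bioassay** (`simulate_bioassay`): each mosquito's knockdown time is
  drawn by inverting the clamped linear cumulative-knockdown curve
  (expected percent = clamp(slope·t + intercept, 0, 100)) and binning to
  the 15-min observation grid, which keeps cumulative counts monotone by
  construction. Default lines are the published strain×insecticide
  regression equations; bottles hold 21–23 mosquitoes, three bottles per
  treatment.
* **Reference calls** (`simulate_reference_calls`): truth perturbed at a
  configurable error rate to a uniformly chosen different genotype.

What passing tests on this generator do **not** show: robustness to plate
spatial effects, amplification-efficiency differences, multiplex
competition kinetics, cross-contamination, or species misidentification —
none of which the generator emulates.

## Numerical choices and degenerate inputs

* k-means ties (point equidistant from two centers) go to the lower-index
  cluster, deterministically; empty clusters are re-seeded at the worst-fit
  point.
* The proportional-odds fit flags non-convergence and non-ascending
  cutpoints instead of returning silently; separation shows up this way.
* Exact rational arithmetic for allele frequencies; everything else in
  float64.
* CSV round-trips preserve reals to better than 1e-9 (12 significant
  digits); empty CT cells mean "no amplification", never zero.
* Genotype-from-sequence tolerates up to 2 total mismatches in the codon
  flanks (the most divergent species the assay covers differ at two probe
  bases) and reads IUPAC ambiguity codes as diploid traces, resolving them
  against the three codons the locus is known to segregate (TTA/TTT/TCA);
  anything else is `ambiguous`.

## Known limitations

* The assay design itself cannot see L1014S: SF heterozygotes are reported
  as LF. The package models this faithfully rather than fixing it.
* Threshold bands exist only for the two extensively validated species;
  other species are called by clustering (or the tarsalis bands when
  clustering is degenerate), which is a modelling choice, not a validated
  protocol.
* The bundled *Vgsc* templates are synthetic stand-ins that embed the real
  oligo binding sites with the deposited templates' published geometry
  (373-bp sequencing product, two probe mismatches on the divergent
  template, 100% amplicon identity between the sister templates); sequence
  outside the oligo footprints is random and carries no biology.
* The Fisher enumeration budget makes the exact test practical only for
  small tables (bioassay scale); larger tables must use the Monte-Carlo
  fallback.
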
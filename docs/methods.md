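# Methods

## Assay model and normalization

The pipeline models a GFP-fused yeast reporter-library exposure read
kinetically (OD600 and GFP every 5 min over a 2 h window, 25 grid points).
Two plate controls carry the normalization: blank wells (no yeast, same
compound and concentration) measure the material's optical interference in
both channels and are averaged per condition and subtracted; vehicle wells
define each reporter's baseline expression. Expression is GFP per unit
biomass,

    P(t) = (GFP(t) − GFP_blank(t)) / max(OD(t) − OD_blank(t), od_floor),

and the induction factor is ln I(t) = ln(P_treated / P_vehicle), averaged
pointwise over replicates. An optional housekeeping correction (default on)
subtracts the PGK1 reporter's ln I under the same condition, removing
plate-level drift that affects all strains alike; with a well-behaved
internal control it is a no-op in expectation.

Degenerate readings are floored rather than propagated: `od_floor = 0.01`
AU guards the biomass denominator and `p_floor = 1e-6` AU the expression
ratio. Floor events are counted and logged; they indicate conditions where
material interference approaches the cellular signal and results should be
treated with suspicion rather than silently trusted.

## The PELI index

PELI_ORF = exp(time-averaged |ln I|), trapezoidal integration on the
reading grid over the full window (t = 0 carries no special weight). This
form makes a no-effect trajectory give exactly 1, treats up- and
down-regulation symmetrically, and renders the positivity threshold
PELI > 1.5 interpretable as a ~50% average fold alteration. The index is a
single strategy function (`peli.peli_from_trajectory`) so an alternative
definition can be swapped in without touching aggregation or fitting.

Category and total PELIs are geometric means of member-ORF PELIs
(equivalently exp of the mean integrated |ln I|), consistent with the
exponential ORF form; an arithmetic mean is selectable. The 1.5 threshold
applies identically at ORF, category, and total levels; the comparison is
strict (PELI = 1.5 exactly is negative).

## Concentration-response and censoring

Category/total PELIs across the six design concentrations are fit with the
increasing four-parameter logistic y(x) = A + (D−A)/(1 + (C/x)^B) by
bounded least squares on log-midpoint, with A ∈ [1, 3], B ∈ [0.1, 10],
D ∈ [1, 50], C ∈ [c_min/10, 10·c_max]. Initialization is an 8-point
multistart with midpoint guesses geometrically spaced over the observed
concentrations plus seeded lognormal jitter (σ = 0.1); the best-SSE
solution is kept, and optimizer tolerances are tightened (1e-14) so
noise-free round trips invert to ≤1e-6. Fits with plateau − baseline < 0.05
are flagged `degenerate` (flat response).

PELI1.5 inverts the fit analytically at y = 1.5 and is censored against the
studied range (0.031–32 mg/L by default): `above_range` ("N/A") when
y(c_max) ≤ 1.5, `below_range` ("<0.031") when y(c_min) ≥ 1.5. The
below-range check runs first: a compound whose response exceeds 1.5 at
every studied concentration fits with a baseline above 1.5 — an
identifiability artifact of a saturated curve, resolved as "<c_min" rather
than an invalid fit. Exactly one censoring state holds per endpoint.

**Toxic equivalents.** The TEQ arithmetic is one consistent reading of
"response at PELI1.5", isolated behind `dose_response.compute_teq` so it
can be replaced: evaluate the sample's category fit (DNA for geno-,
oxidative for oxi-) at the sample's total-level PELI1.5 concentration to
get the target response p*, then invert the reference compound's
same-category fit at p*. Censoring propagates: an `above_range` PELI1.5
gives TEQ "N/A"; a `below_range` PELI1.5 gives a ">" bound evaluated at
c_min; p* outside the reference's response range clips to the
corresponding end of the reference concentration range with the matching
"<"/">" direction. Reference concentration-response data are supplied as
input tables (or generated synthetically); no literature values are
hard-coded.

## Enrichment

GSEA ranks all library ORFs by PELI descending (ties broken by a seeded
shuffle recorded via the seed) and scores each stress category with the
weighted-KS running-sum statistic, weight |PELI − 1|^p with p = 1. The null
is gene-label permutation — random member sets of equal size — because with
three replicates per condition a sample-permutation null is infeasible;
p = (1 + #{null ≥ observed})/(1 + n_perm), n_perm = 1000 by default, seed
required. An `exhaustive` mode enumerates all subsets for small libraries
and is the enumeration oracle in tests. An unweighted variant is
selectable; it is the variant whose p-values are exactly invariant to
monotone transforms of the ranking (the weighted default is not, since the
weights themselves transform). All-tied rankings fall back to unweighted
steps to avoid a zero-weight division.

Ontology enrichment treats terms as flat sets (no ancestor closure; apply
closure to the term map beforehand if wanted), with the library as the
reference universe and the activated set (PELI_ORF > 1.5, taken at the top
concentration) as the test set; the upper-tail hypergeometric p is reported
uncorrected at α = 0.05, with Benjamini–Hochberg selectable but off by
default, mirroring the assay's reporting convention.

## Multivariate summaries

Clustering uses the correlation distance d = 1 − Pearson r with average
linkage (the conventional choice here; complete linkage selectable —
"average" and "complete" are alternatives, not a combination). Zero-
variance items are rejected by name; non-monotone merge heights, possible
for average linkage, are logged rather than hidden. Dendrograms export to
Newick with branch lengths equal to parent-minus-child merge heights.

PCA treats conditions as observations in biomarker space,
column-mean-centered, via SVD. Variance fractions cover all components and
sum to 1; each component's sign is fixed so its largest-magnitude loading
is positive. Heatmap display clips ln I to ±2; clustering and PCA always
use unclipped values.

## Phenotypic anchoring

ROS fold change summarizes DCFDA kinetics by trapezoidal AUC over the 2 h
window (a final-timepoint summary would be noisier and discard the
kinetics): fold = (AUC_treated − AUC_chemical) / (AUC_stained − AUC_blank),
where the chemical control (probe + compound, no yeast) removes compound
autofluorescence. Folds map to H2O2 equivalents by monotone piecewise-
linear inverse interpolation of a standard curve, censored outside the
curve. Comet genotoxicity uses per-cell % Tail DNA (25 cells × 4
replicates, pooled with replicate ids retained) and a one-sided Welch
t-test against the untreated control at α = 0.05; Welch because equal
variances cannot be assumed across treatments. Pearson r with the two-sided
t-transform p (df = n − 2) anchors molecular to phenotypic endpoints; the
pairing (which concentrations enter) is whatever the user supplies, with n
reported alongside.

## Synthetic generator

The generator emulates the study design: 74 reporters × 5 compounds × 6
concentrations (four-fold steps, 0.031–32 mg/L) × 3 replicates, plus one
blank and one housekeeping well per condition and replicate, on a 0–120 min
grid at 5 min. Growth is logistic (od0 = 0.1, rate = 0.02/min, capacity
1.2). Per-(compound, reporter) effects follow a Hill dose dependence
plateau(c) = max_ln_i · c^h/(EC50^h + c^h), and induction ramps linearly in
time, so the time-averaged |ln I| is |plateau|/2 in closed form — the
analytic oracle behind the end-to-end recovery tests. Material interference
is additive, concentration-proportional OD/GFP background identical in
blank wells (so blank subtraction is exactly sufficient by construction),
scaled to stay below ~20% of the minimum cellular signal at 32 mg/L — an
assay whose blanks swamped its reporters would not be interpretable.
Noise is mean-one lognormal, CV 5% by default, applied per reading. The
default per-compound settings encode the study narrative (DNA stress
dominant; the smallest-size material potent well below 0.031 mg/L; the
others with midpoints inside the range), and every parameter is recorded in
`truth.json` for recovery tests.

The generator is phenomenological. It does not emulate growth inhibition
(concentrations are subcytotoxic by design), reporter maturation delays,
spatial plate effects, pipetting covariance between channels, or any
mechanistic stress biology; passing tests therefore demonstrate pipeline
correctness under the stated statistical structure, not biological validity
on real plates. Phenotype tables are affine functions of the programmed
oxidative/DNA effect sizes plus noise, so correlation recovery is testable
against a programmed r.

## Reproducibility and problem sizes

Every stochastic step takes a seed; the pipeline derives per-stage seeds
deterministically from one root seed, and a run is byte-reproducible from
its config (CSV floats printed at %.12g, manifest JSON with sorted keys and
a config hash). The test suite and acceptance script use the full
74-reporter study design where the check concerns the design itself
(determinism, null calibration, PCA structure) and 5–10-item instances
where the check is an enumeration or closed form; permutation counts of
200–5000 are used where the quantity under test is a Monte Carlo estimate
with known standard error.

## Known limitations

The exact historical PELI formula and TEQ arithmetic are not fully
specified in the public record of this assay family; both are implemented
as the self-consistent definitions above behind explicit strategy seams.
Ontology enrichment ignores term hierarchy. The 74-reporter table shipped
with the package is a synthetic placeholder (plausible stress genes,
fabricated systematic names) and should be replaced with a real library
table for production use. Average-linkage heights on correlation distance
are not guaranteed monotone; violations are logged.
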
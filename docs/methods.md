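# Methods

`habitatlink` implements the analysis chain of a paired field survey of
*Aedes albopictus* larval habitats in urban community gardens: each garden
contributes one colonized (C) and one noncolonized (NC) water container, and
the pipeline links the garden's pollution context, the water's chemistry, its
microbial communities (16S bacteria, ITS fungi, 18S microeukaryotes) and its
untargeted organic-molecule profile.

## Pollution-pressure variables

Each garden is scored against three pollution sources:

* `Var_atmo = (qNO2 + qPM2.5 + qPM10) / dH`, with quartile scores q in
  {1..4} computed across the garden set from local emission levels and `dH`
  the distance (m) to the nearest highway;
* `Var_agri = surface^2 / dA`, the squared area of the nearest agricultural
  zone over its distance;
* `Var_indus = 1 / dI`, the reciprocal distance (m) to the nearest
  industrial area.

Raw variables are min–max normalized to [0, 1] per variable across gardens.
Quartile scores use average ranks cut at the 25/50/75 percentiles of the
ranks, lower bound inclusive, so an all-equal input scores 1 everywhere.

**Printed-value comparisons.** The bundled survey table prints variables at
four decimals but mixes rounding conventions (e.g. one atmospheric row is
consistent only with truncation while another requires rounding), so
agreement with a printed value is defined as at most one unit in the last
printed digit. Under this convention the industrial column is reproduced for
22 of 23 gardens; the BIL row (printed distance 1818 m, printed variable
0.0004, computed 1/1818 = 0.00055) is arithmetically inconsistent under any
rounding convention and is reported as a discrepancy rather than forced.
Most atmospheric rows are likewise inconsistent with the stated formula
(e.g. score 12 over 4 m prints as 0.1958, not 3) — the five arithmetically
self-consistent rows (MID, MOU, ALST, FRA, TAS) are the reproduction set.
The units of `surface` are not recoverable from the printed table, so the
agricultural variable is carried through from the printed column when no
surface column is supplied.

## OTU preprocessing and diversity

* **Contaminant rule.** An OTU detected in any negative extraction/PCR
  control is removed unless its relative abundance in study samples is at
  least ten times its relative abundance in the controls. Relative
  abundances are per sample (count over sample total) because controls are
  sequenced at different depths; the study-side statistic is the maximum
  over study samples (the most permissive reading of "detected and not at
  least 10 times greater"), and the control-side statistic the maximum over
  controls. The exact 10x boundary is retained.
* **Rare-OTU rule.** OTUs with total count below 0.005 % of all reads are
  removed; the boundary count is retained.
* **Rarefaction.** Single multivariate-hypergeometric draw (sampling
  without replacement) per sample down to the marker's depth — 4103 (16S),
  6567 (ITS), 7204 (18S) by default; shallower samples are dropped with a
  warning. Seeded and bit-reproducible.
* **Diversity.** Shannon H' in nats (zero-count categories contribute 0);
  Bray–Curtis dissimilarity `sum|a-b| / sum(a+b)`, which is bounded in
  [0, 1] and semimetric (the triangle inequality is not guaranteed).

## Gradient ordination

The abiotic environment (physicochemistry plus pollution variables, or
organic-molecule occurrence) is summarized by PCA on standardized variables;
constant variables are dropped with a warning and axis signs are fixed so
each axis's dominant variable loads positively. The two leading components
enter, in order, a sequential (type-I) PERMANOVA of the community
Bray–Curtis matrix: the Gower-centered inner-product partition with
continuous covariates, pseudo-F per term, and permutation p-values with the
+1 correction (999 permutations by default; exact enumeration of all n!
relabelings is available for n <= 8 and is what the permutation engine is
tested against). dbRDA embeds the square-root transformed dissimilarities
(taming the negative eigenvalues of the semimetric index; the residual
negative-eigenvalue mass is reported), regresses the embedding on the
constraints and eigen-analyses the fitted inner products; by construction
its constrained-inertia fraction equals the PERMANOVA R^2 for the same model
and distances. OTUs tracking a significant axis are screened by Spearman
rank correlation (constant OTUs reported as missing, not dropped silently).
The Procrustes concordance of two ordinations centers and scales both score
matrices to unit total sum of squares and tests the sum of singular values
of X'Y by row permutation; the statistic is 1 exactly when one configuration
is a rigid rotation of the other.

Whether the two leading axes enter one joint sequential model or two
marginal models was an open design choice; the joint sequential model is the
default (axes are orthogonal, so their sums of squares are near-additive),
and marginal models can be obtained by passing one axis at a time.

## Chemistry and the LC–HRMS feature filter

Per-container summaries are arithmetic mean ± standard error
(sd(n−1)/sqrt(n)) by colonization status. Total organic carbon is total
minus inorganic carbon, with negative results rejected. Note: the bundled
survey's printed "± SE" columns are in several cases closer to plain
standard deviations; only the printed means are treated as reproducible.

The untargeted feature cascade runs in the fixed order: (1) normalization
of every intensity to the injection's deuterated-diuron internal standard
(injections missing the spike are excluded loudly); (2) removal of features
with QC coefficient of variation above 30 % — CV is sd(n−1)/mean on
normalized intensities, and a feature absent from the QCs is treated as
unreliable; (3) imputation of a missing study replicate by the mean of its
two siblings, else 0 (present values are never altered); (4) removal of
features not detected (intensity > 0) in 100 % of the samples of at least
one pollution group — "at least one" rather than "all" because detections
are garden-specific, configurable; (5) removal of features whose mean study
intensity is not more than 10 times the mean blank intensity (a zero blank
with a positive study mean passes); (6) removal of features without a
significant NC-vs-C difference by two-sided Welch t-test on per-sample mean
intensities at alpha = 0.05, uncorrected. Features whose total per-sample
variation is below 1e-9 of their mean are treated as constant at stage 6
(their t statistic would be pure floating-point noise). Missing QC or blank
injections skip stages 2/5 with a loud warning, never silently. Every stage
only shrinks the retained set; the audit records survivors per stage and
each dropped feature's first failing rule.

## Association network

Numeric variables of any kind are reduced to exceptionality indicators with
the modified z-score `(x - med(x)) / MAD` (bare MAD, no 0.6745
sigma-consistency constant) thresholded one-sidedly: only exceptionally
*high* values map to 1. Variables with zero MAD are dropped with an audit
entry. The default threshold is 3.5 standard-deviation equivalents — i.e.
3.5/0.6745 ≈ 5.19 in bare-MAD units — so that the classical "modified z
above 3.5" outlier rule keeps its intended stringency under the
unstandardized formula; applying 3.5 directly to the bare score would flag
roughly 1 % of clean Gaussian data as "exceptional", which defeats the
notion of exceptionality and floods the pair screen with chance
co-occurrences. The threshold is configurable everywhere.

Association strength between two binary vectors is Zhang's score
`(P(AB) − P(A)P(B)) / max{P(AB)(1 − P(A)), P(A)(P(B) − P(AB))}`, computed in
both rule directions with the larger value retained per edge (both
directions bounded in [−1, 1]; a zero denominator yields 0). Significance is
the exact one-sided binomial tail `P[K >= k_obs]` for `K ~ Binomial(n,
P(A)P(B))` on pairwise-complete cases, uncorrected for multiplicity. An
edge is retained iff Zhang > 0.25 (the only published edge-strength
threshold) and p < 0.05. Categorical indicators (colonization status,
pollution group) enter directly as 0/1 columns. The binary Spearman
correlation is recorded per edge alongside Zhang's score, since either
statistic may be used for display thresholds.

Two calibration facts worth knowing. First, evaluated at its own null
(independent events with *known* supports) the binomial screen's rejection
rate is close to the nominal 5 %; with supports *estimated* from the same
data it is strongly conservative (the variance of the co-occurrence count
given the margins is smaller than the binomial variance), so false edges
between genuinely independent variables are rarer than alpha suggests.
Second, when several planted (or real) variable pairs have exceptionality
sets drawn independently in a limited sample set, those sets can collide by
chance; the screen then reports the resulting co-exceedances, which is
correct behaviour of the method and the reason planted-truth recovery is
evaluated on a fixed reference fixture.

## Synthetic data

The generator reproduces the study's shapes and planted structure: 23
gardens by default, paired NC/C containers, distances log-uniform on
10–10^4 m, emission-derived quartile scores; lognormal chemistry with
planted NC:C mean ratios of 2 (N2O) and 6 (CH4) and all other fields
status-neutral; Dirichlet-multinomial OTU counts (total concentration 500)
with 30 % of OTUs shifted in log-abundance along the garden's standardized
raw pollution variable, raw sequencing depths 1.5–2.5 times the rarefaction
target (so preprocessing never starves a sample), and one negative control
carrying seeded contaminants that also leak weakly into study samples;
LC–HRMS matrices with triplicate injections, pooled QCs, blanks, an
internal-standard row that all signals ride on multiplicatively, 20 planted
real features (4-fold NC/C difference) and 80 artifacts violating exactly
one cascade rule each (QC CV 60 % via a deterministic ± pattern; absence
from one sample per pollution group; blank at half the study mean; exact
proportionality to the spike, hence flat after normalization). Planted
associations inject co-occurring values 10 MADs above the median into a
15 % sample fraction for disjoint variable pairs among standard-normal
noise variables.

What the generator does *not* emulate: taxonomic structure and phylogeny,
compositional correlations among unplanted OTUs, batch/drift effects in the
LC–HRMS sequence, spatial correlation among gardens, and measurement error
in the probe chemistry. Passing tests therefore demonstrate that the
algorithms recover the structure they are specified to recover, not that
the field data satisfy those models.

## Problem sizes and numerical choices

Simulation-based tests use reduced but structurally faithful sizes chosen as
the package's own test-design decision: null calibrations use 1000
replicates with 99 permutations at n = 15; power checks use 20 gardens, 100
OTUs at depth 500 and 25 replicates; rarefaction expectations use 300
seeds. Permutation p-values compare with a 1e-12 tolerance so ties at the
observed statistic count as exceedances. All random draws flow through
`numpy.random.default_rng` seeds; every generator is a pure function of
(config, seed).

## Known limitations

* The agricultural variable cannot be recomputed from the printed survey
  table (surface units unprinted); it is carried through as printed.
* PERMANOVA terms are sequential; marginal (type-III-like) tests are not
  implemented.
* The binomial edge test ignores the estimation of the supports (see the
  calibration note above), matching the published method rather than a
  margin-conditioned exact test.
* BIOM input is not supported; OTU tables are TSV.
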
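# Methods

This note documents the models, numerical choices, and open design
decisions behind `cofracnet`, and what the synthetic benchmarks do and
do not establish about real co-fractionation data.

## The synthetic co-fractionation model

The generator plants `n_complexes` disjoint complexes (members drawn
without replacement; remaining proteins are singletons) and emits one
chromatogram matrix per replicate × isotope channel, with the medium
channel carrying the unstimulated condition and the heavy channel the
stimulated one.  Exactly `round(rewired_fraction × n_complexes)`
complexes are absent in the stimulated condition; their members elute as
monomers there, so rewiring removes edges while keeping the protein
nodes, as in real condition comparisons.

Each *particle* — a complex, or one protein's monomer form — elutes as a
Gaussian peak.  The signal model for protein i in condition c, replicate
r, fraction x is

    y = b + A_i · exp(−(x − μ_p − δ_{p,r})² / 2σ_p²) + ε,   ε ~ N(0, noise_sd)

where p is the particle carrying protein i in condition c.  Negative
values are clipped to zero, `missing_rate` of points are blanked at
random, and `round(spike_rate × observed points)` positive observed
points per matrix are multiplied by `spike_magnitude` and recorded as
ground truth.

Parameter choices, made once on realism grounds:

| parameter | default | rationale |
|---|---|---|
| `n_fractions` | 60 | a standard SEC gradient |
| `n_replicates` | 3 | standard biological replication |
| complex centers | stratified over fractions 5–42 | distinct assemblies have distinct hydrodynamic sizes; stratification stops ten complexes from landing on one fraction, which no resolvable experiment would show |
| peak widths σ | U(1.5, 3) fractions | SEC peaks span a few fractions; matches the σ≈2 initialization the mixture fit assumes |
| member amplitudes | U(0.5, 2) | protein-to-protein ionization and stoichiometry differences |
| monomer centers | stratified over fractions 43–65 | monomers elute late; the span runs past the collected window, truncating the smallest proteins' peaks |
| monomer amplitudes | U(0.15, 0.45) | dissociated subunits give weaker ratio peaks than intact assemblies |
| baseline b | 0.3 | a SILAC ratio against a pooled internal standard never drops to exactly zero; a strictly positive background also means every observed point carries a value a multiplicative error can corrupt |
| retention jitter δ | N(0, 1) fraction, per particle per replicate | run-to-run retention variation; subunits of one particle co-migrate exactly within a run, while independent particles shift independently between runs — this is precisely what distinguishes co-complex membership from coincidental co-elution across replicates |
| `noise_sd` | 0.15 | point-wise quantitation noise at roughly 10–30% of peak height |
| `missing_rate` | 0.2 | missingness typical of ratio quantitation |
| `spike_rate`, `spike_magnitude` | 0.002, 50 | rare, high-magnitude single-point quantitation errors |

An optional `detection_floor` (off by default) blanks fractions whose
noiseless signal falls below a threshold, emulating the much sparser
matrices of real experiments where proteins are only quantified where
they elute.

**What the generator does not emulate:** peptide-level quantitation and
roll-up, correlated (structured) noise, partially overlapping complexes
and shared subunits with split stoichiometry, abundance-dependent
missingness, and chromatogram tailing.  Benchmarks passing here show the
algorithms behave as specified under their own assumptions; they do not
by themselves establish error rates on deposited data.

## Preprocessing and Gaussian deconvolution

Cleaning follows the standard co-fractionation order: single missing
points with observed immediate neighbors are imputed as the neighbor
mean (runs of ≥ 2 and endpoints untouched), proteins with fewer than
five observations are dropped, and a centered five-fraction sliding mean
(truncated at the ends, missing points left missing) smooths each
profile.  Whether imputation originally preceded the observation filter
is not documented anywhere we know of; imputing first is the
friendlier choice for borderline proteins and is fixed here.

Each smoothed profile is fit by nonlinear least squares (trust-region
reflective, analytic Jacobian) with k = 1…5 Gaussians over observed
points only; fractions are 1-based.  Initialization: centers at the k
largest local maxima (padded by the largest remaining values, then
quantile positions), amplitudes at the profile there, σ = 2.  Bounds:
A ∈ (0, 10·max), μ ∈ [−4, N+5], σ ∈ [0.5, N].  Convergence: relative
SSE tolerance 1e-8, at most 500 function evaluations per fit.  Model
selection minimizes

    AICc = n·ln(SSE/n) + 2p + 2p(p+1)/(n − p − 1),   p = 3k

over converged fits, skipping k with n − p − 1 ≤ 0; the mean squared
residual is floored at (10⁻⁶ · max profile value)² so that on noiseless
profiles, where every sufficiently large k fits to machine precision,
the parameter penalty rather than floating-point residual noise decides
k.  Search stops after the score worsens for two consecutive k.  A
profile with no signal, too few points, or no converged fit is
*discarded* — a normal, reported outcome distinct from an error.

## MODERN: single-point quantitation-error removal

A protein's interaction profile is its vector of Pearson correlations
to every other protein, computed over pairwise-complete fractions with
at least 3 shared observations (entries below that support are missing,
never zero).  For each observed point, the profile is recomputed with
that fraction dropped from both members of every pair, and the Pearson
correlation between original and recomputed profiles (over entries
defined in both, ≥ 3 of them) is that point's autocorrelation.  A
removal that leaves every defined entry unchanged has autocorrelation 1
by convention, covering the degenerate constant-profile case.  The
implementation accumulates the pairwise correlation sums once per
protein and down-dates them per fraction, giving all leave-one-out
profiles in O(proteins × fractions) per protein; a brute-force
reimplementation cross-checks it in the test suite.

Autocorrelations are one-inflated: nearly all removals barely move the
profile, and the left tail mixes genuine errors with high-leverage
clean points.  Standardizing the raw values with a pooled mean and SD
therefore cannot control the family-wise error rate — in our
experiments, pure-noise matrices (where no point is special) always
produced flags, because the raw distribution's left tail is intrinsically
heavy.  The implementation instead Fisher-transforms the
autocorrelations (atanh symmetrizes the pile-up at 1) and standardizes
each protein's values by their median and MAD (scaled by 1.4826).  The
robust per-protein scale is the decisive part: a genuine single-point
error is a gross outlier within its own protein and cannot inflate a
median/MAD estimate, whereas a mean/SD within a ~50-point protein caps
the attainable |z| at (n−1)/√n and hides exactly the points the method
exists to find.  Pooled mean/SD standardization remains available as
`standardize="pooled"`.  A point is flagged when z < Φ⁻¹((FWER/2)/N),
with N the observed points of the matrix — the Bonferroni-style
two-tailed threshold at FWER 0.05.  Detection is a single pass; flagged
points are set to missing and nothing is re-detected afterwards.

On the default benchmark (200 proteins × 60 fractions, spike magnitude
50, spike rate 0.002) this flags ~90% of injected spikes, and on
spike-free matrices the proportion with any flag at all is consistent
with the nominal 0.05.

## Pair features and co-complex classification

Six features per pair per replicate, over pairwise-complete fractions
(≥ 3, else missing): raw-profile Pearson r and its two-tailed p-value
from t = r·√((n−2)/(1−r²)); raw-profile Euclidean distance; smoothed
Pearson r; the separation in fractions of the two raw-profile maxima
(ties to the lowest fraction); and the smallest Euclidean distance
between fitted Gaussian components in (center, amplitude) coordinates —
σ is excluded because peak identity is about position and height, and
width estimates are the least stable fit parameter.  Replicates
concatenate to 18 columns per channel; channels are processed fully
independently (medium → unstimulated network, heavy → stimulated).

Labels come from complex definitions: co-members of at least one
complex are positives, pairs of complex-annotated proteins that never
share a complex are negatives, everything else is unlabeled.  The
classifier is Gaussian naive Bayes with per-class, per-feature moments
(variances floored at 1e-12 so constant features cannot blow up the
likelihood) and training-prior class weights; a pair's missing features
are simply dropped from its likelihood product, and pairs missing all
features are left unscored.  Labeled pairs are split into ten
stratified folds (by pair, not protein — a protein-level split is
defensible but was not chosen); each fold's classifier is trained on
the other nine and scores *all* pairs, and a pair's final score is the
median over the ten fold scores.  Scores are kept on the log-odds scale
internally: posteriors of clearly co-eluting pairs all round to 1.0 in
floating point, and ranking by log-odds (strictly monotone in the
posterior) avoids welding those pairs into one giant tie block.

Cumulative precision at rank k is gold positives over gold-labeled
pairs among the top k.  The network keeps the largest prefix whose
cumulative precision meets the target (0.70 default); equal-score
blocks enter or leave whole, and unlabeled pairs inside the prefix
become edges alongside labeled ones.  Note a structural consequence:
because the rule rides cumulative precision *down* to the target, the
tail of every emitted network sits at the decision boundary, and those
boundary edges are the least reproducible between channels.  The
condition-specific partition of two networks therefore always contains
boundary flicker on top of genuine rewiring, which is why planted-
rewiring recovery is evaluated on the co-complex pair universe (see
below).

## Differential network statistics

**Degree-preserving rewiring.**  `round(6.9 × |E|)` attempted
double-edge swaps; a swap draws two distinct edges (a,b), (c,d) (with a
random orientation flip) and replaces them with (a,d), (c,b) unless a
self-loop or multi-edge would result.  Attempted, not successful, swaps
are counted.  Degrees and |E| are invariant by construction and
asserted on every permutation.

**Δn_PPI test.**  For each gene set, Δ = edges among its proteins in
the stimulated network minus the same in the unstimulated network.
Both networks are rewired within each of `n_perm` permutations (paired,
matching how the observed difference pairs the two real networks), the
null mean and SD give z = (Δ_obs − mean)/SD, p = 2·Φ(−|z|) (two-tailed:
gained and lost interactions are both of interest), and
Benjamini–Hochberg q-values are computed across terms.  Terms with null
SD 0 get p = 1; terms with fewer than two annotated proteins in the
networks are skipped and reported.  Under a paired null (two
independent draws from one graph model) the term-level p-values are
uniform to within binomial error at n_perm = 200.

**Annotation sharing.**  The fraction of edges whose endpoints share at
least one term, against the same rewired null, with the add-one
empirical p = (1 + #{null ≥ observed})/(1 + n_perm), so p is never 0
and never below 1/(1+n_perm).

**Per-protein condition autocorrelation.**  Pearson r between a
protein's stimulated and unstimulated chromatograms per replicate
(≥ 5 shared fractions required), transformed to z by the rank-based
inverse normal Φ⁻¹((rank − ½)/m) across proteins within the replicate —
chosen over plain standardization because the rewired tail is heavy and
would otherwise set its own scale — then combined across available
replicates as Σz/√k (Stouffer).  Low combined z marks rewired proteins;
tiering is left to the caller.

**Correlation-shift test.**  Within-set pairwise Pearson correlations
per condition (pooled over replicates, pairs with < 5 shared
observations excluded) compared by the Brunner–Munzel test, two-sided;
fewer than 3 valid pairs in either condition leaves the test undefined
rather than silently significant.  When the rank variance degenerates
(e.g. both correlation sets identical), the stochastic-dominance
estimate itself decides: p̂ = ½ gives p = 1.

**Log-odds enrichment.**  Woolf z-test on a 2×2 table: ln OR with
SE = √(Σ 1/cell), Haldane–Anscombe +0.5 on all cells when any cell is
zero.

**Enrichment map.**  Term–term edges where the Jaccard index of the
annotated sets is ≥ 0.33 (boundary inclusive, so two 2-member sets
sharing one protein are linked).  Gene-set ingestion from annotation
tables excludes evidence codes IPI, IEA, NAS and ND and the NOT
qualifier, optionally propagates annotations up a supplied ontology,
and removes terms annotated to more than 100 proteins.

## Pipeline

Stages run in the order cleaning → MODERN → smoothing/fitting →
features → scoring → thresholding → comparison → differential
statistics → report.  Every stage derives its own seed deterministically
from the master seed and a stage name, so reruns are bit-identical for
integer outputs; completed stages are skipped (and their artifacts
reloaded) unless forced.  The YAML config carries a schema version and
rejects unknown keys.  When no gene sets are supplied, a
simulation-driven run tests each planted complex as its own term.

## Benchmark problem sizes

The test suite and `scripts/acceptance.py` use deliberately small
instances so a full run takes minutes on one CPU: MODERN on 10–20
matrices of 200 proteins × 60 fractions; classifier benchmarks on 60
proteins in 10 complexes with 3 replicates; Δn_PPI calibration on
120-node Erdős–Rényi pairs with 50 terms × 10–20 seeds at n_perm =
100–200 (scaled down from the 1000 permutations a full analysis would
use); rewiring recovery over 3–5 seeds.  The acceptance script prints
per-stage timings and writes each quantity with the problem size `n` it
was measured on.

## Known limitations

- MODERN's FWER guarantee is calibrated under an exchangeable null; on
  structured matrices, high-leverage clean points (sharp peak apexes of
  sparse profiles) can still be flagged, and with the spike-injection
  model used here such extra flags run at a few points per 10⁴.
- The precision threshold guarantees precision over *labeled* pairs
  only; the realized precision over all emitted edges depends on how
  well the gold standard represents the unlabeled pair population
  (observed gap ≲ 0.05 under the default generator).
- The naive-Bayes independence assumption is clearly wrong across the
  six features (they are transformations of the same profiles); as
  usual this costs calibration more than ranking.
- Complexes are disjoint in the generator; shared subunits and
  sub-complexes, common in curated catalogs, are untested territory.
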
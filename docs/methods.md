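# Methods

`ndmmkit` implements two linked analyses of nematode-derived modular
metabolites (NDMMs): annotation of modular ascarosides from
high-resolution tandem-MS data, and phylogenetic comparative analysis of
the resulting presence/absence patterns and compositional profiles. This
note records the models, the parameters that matter, the numerical
choices, and what the synthetic-data generators do and do not emulate.

## Exact-mass arithmetic and annotation

NDMM structures are assembled from components — a dideoxy sugar
(ascarylose or its mass-identical isomer paratose, C6H12O4), a fatty-acid
side chain (CnH2nO3 saturated, CnH(2n−2)O3 with one double bond,
n = 3–11, attached at the (ω−1) or ω carbon), an optional ureido head
group at the sugar 4′-position (ureidoisobutyric acid C5H10N2O3 or
ureidopropionic acid C4H8N2O3), and optionally a second ascaroside unit
esterified at the 2′- or 4′-position. Every condensation bond removes one
H2O, so neutral formulas are pure element bookkeeping. Monoisotopic
atomic masses are hard-coded to seven decimals, and adduct ions
([M+H]+, [M+Na]+, [M−H]−) carry an explicit electron-mass correction
(±0.0005486 Da): at m/z ≈ 400 the electron term is ≈1.4 ppm, which is the
difference between reproducing printed Q-TOF deviations and missing them.
Mass deviations are signed ppm internally; reports quote |Δ| to one
decimal.

Diagnostic MS/MS fragments are formula recipes: dimeric ascarosides
(DASC) lose the terminal side chain, leaving first unit + sugar − 2 H2O
(observed as [M+Na]+); UBAS compounds yield the head-plus-sugar cation
C11H19N2O5+; UPAS compounds yield the ureidopropionate anion C4H7N2O3−.
The screen always matches against *theoretical* fragment masses.

Because the sugar isomers and the 2′/4′ linkage are mass-identical, the
screen reports isomer *sets* and never invents a unique structural
assignment; resolving those isomers requires NMR, which is out of scope
(structures are handled at the molecular-formula level only).

Default matching tolerances are 5 ppm for precursors and 10 ppm for
fragment ions — consistent with the ≤~5 ppm deviations of a calibrated
Q-TOF and deliberately looser for fragments, whose centroiding is noisier.
Both are configurable. Detections at precursor intensity ≥ 1.0×10³ ion
counts are "quantifiable"; weaker detections are "trace" and are excluded
from comparative analyses (presence calls use replicate-mean intensity
against the same threshold; per-replicate calling is a configurable
alternative, but means match the standard tabulation).

## Profiles

Peak areas come as species × compound × replicate tables (three
biological replicates in the emulated design). Replicate means feed two
compositional views: within-class percentages (each metabolite class
standardised to 100% per species, monomeric and dimeric UBAS separately,
so rare classes stay visible) and a single closed composition over all
compounds (rows sum to 100%) used for dissimilarity analysis. Closure
makes both views invariant to absolute production scale. A class absent
from a species yields zeros, not NaN; an all-zero species row is an error
for closed profiles.

## Mk models and stochastic mapping

Presence/absence evolution is modelled as a 2-state continuous-time
Markov chain with gain rate q01 and loss rate q10 per unit branch length
(ER: q01 = q10; ARD: free). Likelihoods use Felsenstein pruning with the
closed-form 2-state transition matrix and an equal (1/2, 1/2) root prior;
per-node rescaling guards underflow, and an impossible configuration
returns −inf explicitly. Fitting maximises over log-rates with L-BFGS-B
from multiple starts seeded by a parsimony-informed rate
(Fitch score / tree length). Rates are bounded in [1e-9, 1e2]: with trees
scaled to root depth ≈ 1, rates beyond ~100 changes per unit time are
pure saturation — the likelihood is flat and any "optimum" there is an
artifact — so fits that park below 1e-6 or above half the upper bound are
flagged `at_bound`. ER vs ARD is chosen by a likelihood-ratio test
against chi-square with one degree of freedom at α = 0.05.

Stochastic character maps are sampled conditional on tip data: node
states root-down from the conditional likelihoods, then an
endpoint-conditioned path on every branch by modified rejection sampling
(the first jump drawn from a truncated exponential when the endpoints
differ), falling back to uniformization after 200 rejections — relevant
only for very unequal rates. Summaries report the mean change count and
the presence probability at each named clade's MRCA. Optional rate
uncertainty re-draws (q01, q10) per map from a random-walk Metropolis
sampler on log-rates with a gamma(2, scale = q_ML) prior, 1000 burn-in
iterations and thinning interval 10; these hyperparameters are
configurable and deliberately mild — the prior centres on the ML prefit
and mainly propagates curvature, not prior opinion.

Correctness is checked two ways: pruning equals brute-force enumeration
over internal-node states on all trees with ≤ 5 tips (|ΔlogL| < 1e-8),
and node-state frequencies over 2000 maps match analytic up/down-pass
marginals within 3 Monte-Carlo standard errors, with every sampled
history's change count at or above the Fitch parsimony score.

## The D statistic

Binary-trait phylogenetic signal uses the scaled sister-clade difference
sum. Nodal trait values are estimated tips-to-root by daughter averaging;
each internal node contributes |difference of its two daughters' values|,
summed into d_obs. Two simulated baselines calibrate the scale: tip-label
shuffles (no phylogenetic structure) and Brownian motion on the tree
thresholded at the rank matching the observed prevalence (so every null
replicate has exactly the observed number of presences). Then
D = (d_obs − mean d_Brownian) / (mean d_random − mean d_Brownian):
≈1 for phylogenetically random traits, ≈0 for Brownian-threshold traits,
< 0 for conservation stronger than Brownian, > 1 for overdispersion.
One-sided permutation p-values (with the +1 correction) are converted to
two-sided as min(1, 2·min(p_low, p_high)). D is refused for constant
traits and singletons, where neither null has usable spread. The
down-pass is vectorised over trait columns, so the default 10,000-deep
nulls run in milliseconds on 32 tips. Benjamini–Hochberg correction at
FDR 10% is applied separately to the D = 0 and D = 1 test families.

The exact nodal-value estimator inside published D implementations is not
restated in the text this package follows; the daughter-averaging
down-pass is validated by the defining calibrations (E[D] ≈ 1 under
shuffles, ≈ 0 under Brownian thresholding) rather than by matching a
specific third-party routine.

## Profile–phylogeny comparison

Bray–Curtis dissimilarity BC(x, y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ) over closed
profiles; patristic distances from the tree (path sums, cross-checked
against dendropy). The Mantel test correlates lower triangles with
Spearman's rho (midranks for ties) and permutes rows/columns of one
matrix jointly, p = (1 + #{rho_perm ≥ rho_obs}) / (n_perm + 1) with 999
permutations by default. NMDS minimises Kruskal stress-1 via SMACOF with
isotonic regression (scikit-learn), best of 8 random restarts, k = 2,
deterministic for a given seed.

## Synthetic data: what it emulates, what it does not

Generators reproduce the *shape* of the study design: an ultrametric
32-species tree with root depth 1 partitioned into four ingroup clades
(10 pacificus, 7 maupasi, 6 entomophagus, 5 triformis) plus a 4-species
outgroup; ~46 compounds × 3 replicates; spectra with planted precursors,
class-diagnostic fragments, Gaussian ppm error, and uniform decoy peaks
on m/z 50–1300 (the emulated acquisition window). Trees are pure-birth:
clade subtrees span the upper half of the depth axis (clade roots at
depth 0.5) with backbone joins above them — a stand-in encoding clade
membership, not the published topology, whose branch lengths are not
available in printable form. Decoy peaks are resampled to sit ≥ 50 ppm
from every planted ion so that specificity failures measure the screen,
not the generator. Softmax closure keeps simulated compositions strictly
positive (Bray–Curtis is degenerate on all-zero rows); the `contrast`
scale (default 3) sets how peaked the compositions are.

What passing tests on these inputs do *not* show: robustness to
chromatographic drift, isotopologue interference, inter-batch intensity
effects, non-Gaussian mass error, model misspecification in the real
tree's branch lengths, or correlated evolution among compounds. All
generators take an explicit seed and are bit-reproducible.

## Problem sizes in the checked runs

The test suite and the acceptance script size their simulations for a
single CPU: 100 random ≤5-tip trees for the likelihood oracle; 2000
stochastic maps on 16 tips; 200 traits per regime × 1000 permutations
for the D calibration on 32 tips; 200 replicates × 999 permutations for
the Mantel type-I check and 200 replicates for the LRT type-I check;
7 planted compounds × 50 decoys for the screen. The D permutation
default in the API remains 10,000.

## Known limitations

Two-state characters only (no multi-state Mk, no correlated-trait
models); no penalized-likelihood rescaling of input trees (the pipeline
expects an already-ultrametric tree and only warns otherwise — of the
implemented analyses only the Brownian arm of D assumes time-scaling);
highly modular PASC/NPAR compounds enter via a registry CSV
(name → formula) rather than combinatorial assembly, since their
side-chain chemistry is not expressible in the building-block grammar;
no stereochemistry or isotope-pattern simulation beyond monoisotopic
peaks; the D statistic's power is limited at 32 tips, so non-significant
results are weak evidence of absence.
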
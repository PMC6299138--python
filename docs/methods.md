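# Methods notes

This note documents the models and numerical choices behind `immunemap`, in
the spirit of a statistical software appendix: what each procedure assumes,
which parameters matter, and what the synthetic-data validation does and
does not establish.

## 1. Somatic variant layer

**Filter.** Three conjunctive steps: (i) consequence ∈ {missense, nonsense,
frameshift, splice_site}; (ii) VAF > 0.05 **or** coverage ≥ 5×; (iii) every
population-database frequency < 0.005 (a variant absent from a database
counts as frequency 0 — absence is evidence of rarity, which matches the
"rare variant" semantics of the filter). Thresholds are exposed as module
constants; all boundaries follow the stated inequalities exactly (the
coverage clause is inclusive, the frequency clause exclusive).

**nMAF clonality.** Each VAF is multiplied by 2/ploidy (diploid reference)
so that triploid and diploid loci are comparable, then divided by the locus
maximum; nMAF ≥ 0.2 ⇒ clonal, boundary inclusive. Whether ploidy
normalization should divide or multiply is ambiguous in the literature this
method descends from; we multiply by 2/ploidy (an allele observed at VAF v
in a triploid region represents fewer mutant copies per cell than the same
VAF in a diploid region) and the flag `ploidy_normalize=False` gives raw
VAFs. A locus whose adjusted MAFs are all zero has no defined nMAF and is an
error rather than a silent all-subclonal call.

**Regional clonality and ITH.** A mutation is clonal iff present in every
sampled locus of the patient; for a single-locus patient every mutation is
vacuously clonal and ITH is 0. ITH is defined as the subclonal fraction
under this rule — the named sources describe the idea but never print a
formula; the subclonal fraction is the direct quantification of "unique
mutations among sampling foci". CV of burden uses the n−1 sample standard
deviation (small-sample convention; cohorts have 3–5 loci per patient).

**Parsimony trees.** Loci plus an all-absent germline leaf; each mutation is
a binary character. Up to 8 leaves every unrooted topology is enumerated
((2n−5)!! ≤ 10 395) and scored by Fitch counting; ties go to the first tree
in the deterministic stepwise-addition enumeration order. Beyond 8 leaves a
seeded ratchet (greedy stepwise addition, NNI hill climbing, 20 rounds of
25 %-character upweighting) is used; it is a heuristic and carries no
optimality guarantee. Branch lengths come from rooting at the germline leaf
and refining the Fitch sets top-down ("take the parent state when
compatible, else the forced alternative"); for binary characters with a
fixed root state this refinement is minimal, and the per-edge change counts
always sum to the parsimony score (property-tested). True acctran/deltran
distinctions only arise in the rare both-states-possible internal
configurations; our rule resolves them deterministically.

## 2. Repertoire metrics

All metrics use natural logarithms and operate on *productive* clonotypes
(CDR3 amino-acid sequences without `*` or `_`). Clonotype identity is the
CDR3 amino-acid sequence alone. Shannon entropy H = −Σ pᵢ ln pᵢ; Simpson
index is the dominance form Σ pᵢ² (so clonal expansion *increases* it,
matching how the diversity panels are described; the complement 1 − Σ pᵢ²
would reverse the direction); clonality = 1 − H/ln R with the monoclonal
limit defined as 1 (the 0/0 case; the formula's limit as a repertoire
concentrates). Dominant clones use frequency ≥ 0.005, boundary inclusive.

## 3. Neoantigen layer

Affinity prediction is consumed, never computed: the affinity table carries
netMHCpan-style nM predictions for mutant/wild-type peptide pairs. Window
enumeration produces every 8–11-mer containing the mutated residue, clipped
at the protein termini (38 candidates at interior positions, 4 at a
terminus); identical (length, offset, sequence) duplicates are removed.
Strict filtering (mutant < 50 nM and mutant < 0.7·wild-type) feeds
correlation analyses; presence filtering (mutant < 500 nM) feeds
presence/absence maps. Load is counted at mutation level (a mutation with
any surviving peptide/allele pair counts once), the convention that makes
load commensurable with TMB; per-peptide counting is a one-line change via
the unaggregated filtered table.

## 4. ssGSEA and the feature matrix

For each sample, genes are ranked by expression (average ranks on ties;
descending walk order is stable in gene order). The running sum increments
by |rank|^α (α = 0.25, the standard single-sample weighting; the method
citation gives no parameters) normalized by the in-set total for member
genes, and by 1/(N−|S|) otherwise; the enrichment score is the *sum* of the
running-sum values (integrated form). The score is therefore invariant
under any strictly monotone transform of a sample's expression vector, and
the raw ES is used directly — range-normalization before unity scaling is
a no-op for the downstream min-max.

Normalization: `unity` min-max scales each feature to [0,1] across samples
(constant feature → 0.5); `zscore` centers to mean 0, population sd 1
(ddof = 0; constant feature → 0). Cytolytic activity is
√((GZMA+ε)(PRF1+ε)) TPM with ε = 0.01; the product form is exposed as an
option and is rank-equivalent for positive expression. Panel expression
features are log2(TPM+1); the pseudocount is not stated by the sources that
plot log2 TPM, and 1 is the field default.

The 278-column feature matrix has fixed block order: neoantigen load (1),
TCR clonality (1), 31 immune-regulation/antigen-presentation genes as
log2(TPM+1), 217 pathway ssGSEA scores and 28 cell-type ssGSEA scores, both
unity-normalized. Block sizes are contracts (wrong counts are errors);
block *content* is configuration. The shipped 31-gene list is a standard
checkpoint/costimulation/MHC panel; the 28 cell-type roster follows the
pan-cancer immunome convention, with a core of established human markers
per population padded by synthetic filler genes; the 217 pathway sets are
placeholders (a quarter of them immune-effector-linked). The original
panels live in external supplementary material that is not redistributed
here — results on real data require substituting the user's own GMT/YAML
panels of the same shapes.

## 5. The immune map

The per-iteration model is an *unsupervised* classification tree in the
Breiman synthetic-contrast construction: real rows (label 1) versus a copy
with every feature column independently permuted (label 0), per-node random
feature subsetting (√p), trained on a freshly drawn two-thirds discovery
subset. What the published description's "prediction model (decision tree)"
predicts is never stated; the synthetic-contrast reading is chosen because
the only consumed output is an unlabeled proximity matrix, and the named
random-forest toolkit's unsupervised mode works exactly this way. The
held-out third is used only to prune degenerate trees (real-vs-synthetic
accuracy < 0.55 → rebuilt once, then accepted). All samples — not only the
discovery set — are pushed down each tree so every pair accumulates 100
co-terminal observations; proximities are means over iterations with unit
diagonal. One tree per iteration (100 trees total); a forest per iteration
is available via `trees_per_iter`.

Embedding is classical (Torgerson) MDS on D = √(1 − proximity) (the
random-forest convention; plain 1 − proximity via `dissimilarity="linear"`):
double-centering, top-2 eigenpairs, coordinates eigenvector·√eigenvalue,
axis signs fixed so sample 0 has non-negative coordinates. Fewer than two
positive eigenvalues pads with zeros and warns.

Categorization is a two-component full-covariance Gaussian mixture fitted
by EM: means initialized at the farthest pair of points (deterministic
given the data), shared sample covariance start, covariance ridge 1e−6
applied only to near-singular M-step covariances (so exact-EM monotonicity
holds in the regular case), convergence at log-likelihood gain < 1e−8, cap
500 iterations with a warning flag on non-convergence. The component with
the higher responsibility-weighted mean cytolytic activity is *hot*; an
exact tie (measure zero) is an error prompting a re-seed. Patients whose
loci carry both labels are *heterogeneous*.

Hot-vs-cold group comparisons use the Mann–Whitney U test, exact null when
both groups have n ≤ 25 and the pooled values are tie-free, normal
approximation with tie correction otherwise.

## 6. Heterogeneity statistics

Pearson r is computed from the definitional sums; the p-value is two-sided
via t = r√((n−2)/(1−r²)) on n−2 df and the 95 % CI via Fisher's z
(undefined-width at n = 3 yields an infinite interval rather than an
error). Infiltration divergence is 1 minus the mean pairwise Pearson r
between a patient's 28-type cell-score vectors — Pearson rather than
Spearman to match every other correlation in the analysis — computed on the
unity-normalized scores (the same values that are plotted; z-scoring across
samples would distort within-patient pairwise correlations). p-values are
reported per test without multiplicity correction, matching the
presentation style of the source analyses; `benjamini_hochberg` is
available for batch reports.

## 7. The synthetic cohort: what is planted, and what a green test means

Defaults state the emulated world: 12 patients × 3–5 loci; truncal
mutations Poisson(25) per patient shared by all loci, private mutations
Poisson(18) per locus (8 % of them spanning an intermediate subset of loci
so phylogenies have internal branches); per-patient log-normal(σ = 0.6)
burden scales spread TMB and ITH across patients; ~6 decoy variants per
locus each violate exactly one filter step, so truth TMB = post-filter
count by construction. VAFs are Beta-distributed (truncal ≈ 0.4, private
≈ 0.15, floored above the confidence filter); coverage Poisson(115),
matching the reported median exome depth; ploidy 2 (85 %) or 3 (15 %) per
locus.

Each locus carries a latent hot/cold state with marginal P(hot) = 0.5,
drawn from a per-patient Gaussian copula whose within-patient correlation
is 1 − ITH: mutationally heterogeneous tumors mix immune states more often.
Hot loci gain `hot_effect` = 2 (log2) on an effector/checkpoint program
(CD8A, CXCL9, CXCL10, IFNG, GZMA, GZMB, EOMES, TBX21, PRF1, PDCD1, CD274,
… plus effector-population markers) and `suppressive_effect` = 1 on
suppressive-population markers — the infiltration-feedback structure that
makes anti- and pro-tumor infiltration positively correlated. Expression is
log-normal noise (σ = 0.5 log2) around per-gene baselines; TPM by
exponentiation, no library-size renormalization (ssGSEA needs only ranks).
Non-cytolytic cell-type marker genes additionally receive per-locus noise
with sd = 1.2·ITH (mean-corrected in TPM space), planting the
ITH → infiltration-divergence coupling; GZMA/PRF1 are exempt so cytolytic
activity depends on the latent state only — the planted-zero
burden–cytotoxicity coupling.

Repertoires are symmetric-Dirichlet/multinomial: 200–2000 clones, 50–150k
reads, concentration exp(−2.3 − u) with u = c·z + √(1−c²)·ε, z the
standardized log-burden. The internal slope c is the configured coupling
(0.35) divided by an attenuation constant 0.91, measured once by
Monte-Carlo calibration of the generator against its own truth (clonality
is a nonlinear, sampled transform of u); realized mean r(TMB, clonality)
over 20 seeds is 0.34. Mutant affinities are log-normal (median 200 nM),
wild-type independently log-normal with higher median (800 nM).

What green tests establish: the estimators recover *these planted*
structures at *this* scale — label recovery, coupling signs, exact regional
classification. What they do not establish: performance on real data, where
expression is not log-normal around independent baselines, panels are the
published ones, repertoires have V/J structure and sequencing error, and
mutation sharing follows true clonal phylogenies rather than a
truncal/private/subset scheme. One known looseness: with ~12 patients the
null sampling spread of any cohort-level correlation is wide, so
single-seed correlation values carry large error bars; the acceptance suite
therefore tests signs and seed-majorities, not magnitudes.

## 8. Determinism and seeds

Every stochastic stage (generator, tree proximity, ratchet, EM re-seeding)
flows from explicit integer seeds; `run_pipeline` derives all stage seeds
from one root seed and records every parameter in its manifest, so a rerun
from the manifest is bitwise identical. TSV writers use round-trip float
formatting and readers parse with round-trip precision, so write→read is
exact.
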
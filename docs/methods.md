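# Methods

`ripqtl` implements the statistical chain of a proteo-genetic study of a
two-founder recombinant-inbred (RI) rat family: multiplexed TMT proteomics
quantified per strain, descriptive genetics of protein abundance, kinship-
corrected protein-QTL mapping with empirical significance thresholds,
colocalization of association signals, and causal ordering of genotype,
protein and trait. Everything is exercised against a synthetic panel
generator with planted ground truth, so each estimator's behaviour can be
verified without any external data.

## Synthetic RI panel

**Genotypes.** Each strain's chromosome is a two-state Markov chain over a
marker grid placed uniformly in cM. The per-meiosis recombination fraction
between adjacent markers follows the Haldane map function
`r = (1 − e^(−2d))/2` (d in Morgans), expanded to the fixed-recombinant
frequency of an RI panel by the Haldane–Waddington formula: `R = 4r/(1+6r)`
for sib-mated panels (the default — rat RI families are sib-mated) and
`R = 2r/(1+2r)` for selfed panels. Strains are fully inbred: dosages are
strictly 0/1, and the two founders are appended as the all-0 and all-1
rows. Physical positions use a fixed scaling of 1 cM = 2 Mb so that windows
stated in bp (the 1 Mb cis window, 500 kb coloc flanks) are meaningful.
Residual heterozygosity is not simulated; `H` calls in real genotype files
are handled by the reader as missing.

**Proteome.** Per-strain log2 abundance is
`baseline + β_cis·x + Σ β_trans·x + polygenic + noise`, where the polygenic
term is a single multivariate-normal draw per protein with covariance
proportional to the centered kinship of the simulated genotypes (drawn at
strain level and copied to both sex replicates, since heritability here is
defined over strain means). Each strain contributes one male and one female
sample; sex is a small symmetric offset (±δ/2), batch is a per-(protein,
batch) offset with strains assigned to batches in blocks (both replicates
of a strain share a batch, as littermates share a plex).

**Heritability scaling.** The strain-mean heritability estimator (below)
has expectation `(V_g + σ_e²/2)/(V_g + σ_e²)` with two replicates per
strain, where `V_g` is the realised between-strain genetic variance and
`σ_e` the residual sample noise. The generator therefore solves
`σ_e² = V_g (1 − h²)/(h² − ½)` so that the *estimator* targets the
configured `polygenic_h2` (default 0.54, the study-scale median). Targets
at or below 0.5 are unreachable in expectation by this estimator — its
floor under pure noise is ½ — and are rejected unless an explicit
`residual_sd` is supplied instead (as the calibration panels do, which use
the stated residual sd of 0.5 directly).

**PSMs.** Each protein expands to `psm_per_protein` PSMs per batch with a
per-PSM ionisation offset (log2 sd 1.0 by default), a per-channel loading
effect, log-normal noise, and isotopic-impurity mixing through a
tri-diagonal matrix in which each channel keeps `1 − s` of its signal and
leaks `s/2` to each neighbour. `s ≥ 0.5` would break diagonal dominance and
is rejected.

**Panel size.** The default configuration simulates 29 RI strains plus two
founders (62 samples), five TMT batches and 500 proteins with 50 planted
cis effects of 1 log2 unit. The protein count is deliberately down-scaled
from study scale (~8,000); none of the estimators' properties depend on it,
and it keeps whole-pipeline simulations interactive.

**Randomness.** All draws flow from one seed through `SeedSequence`
spawning with fixed stream order (genotypes, proteome, PSMs, trait), so a
config reproduces its panel bit-for-bit.

## TMT quantification

Fixed order: impurity correction → intensity filtering → channel
normalization → rollup (per batch) → batch merge.

* **Correction** solves `M x = observed` exactly per PSM and clips negative
  components to zero. Correction precedes filtering, so thresholds apply to
  corrected intensities.
* **Filtering** keeps PSMs whose per-channel minimum is ≥ 1,000 *and*
  median ≥ 5,000 (the strict conjunction of the two published thresholds).
* **Normalization** shifts each channel's log2 intensities by a constant so
  its trimmed location matches the cross-channel mean. The "trimmed
  median" is implemented as the mean of the central 1 − 2·trim of sorted
  values (default trim 10%): a literal median of a symmetrically trimmed
  sample is just the median, which would make the trim fraction inert.
* **Rollup** mean-centers each PSM's log2 profile across its samples,
  averages centered profiles per protein, and restores the absolute level
  from the grand mean of the protein's three most abundant PSMs.
* **Merge** mean-centers each protein within batch and restores the mean of
  per-batch levels; proteins missing from some batches are kept and
  flagged as partially observed. Missing channels propagate as missing.

Exactness caveat: channel normalization estimates offsets from the PSM
population, so a noise-free round trip through the chain is exact (to
~1e−14) only when the true matrix has equal per-channel trimmed locations;
the round-trip fixtures balance columns accordingly, and multi-batch
merging is exact only up to per-(protein, batch) constants.

## Expression statistics

* **Moderated differential expression.** Two-group contrast with
  empirical-Bayes variance moderation: `s̃² = (d₀s₀² + d·s²)/(d₀+d)`, t on
  `d + d₀` df, hyperparameters by method-of-moments on log sample variances
  (excess spread of `log s²` beyond `trigamma(d/2)` identifies `d₀` via the
  inverse-trigamma; closed-form, no iterative fitting). `d₀ = 0` recovers
  the ordinary t, `d₀ = ∞` a z-test against the prior variance. BH
  adjustment across proteins; flagged when adjusted p < 0.01 and
  |log2FC| ≥ 1.
* **Heritability.** Population-variance ratio: additive = mean squared
  deviation of strain means from the grand mean; total = same over all
  samples; clipped to [0, 1]. Divide-by-count variances make perfect
  replicates give exactly 1 (sum-of-squares without normalisation cannot
  reproduce a 0–1 range).
* **CV flagging.** CV of strain-mean log2 values (the log scale is the only
  one on which panel-mean CVs of ~10⁻² are plausible); threshold = panel
  mean + 2 SD, single pass.
* **Sex contrast.** Paired t on per-strain M−F differences, n−1 df,
  unadjusted p < 0.01 reported as a screen; zero-variance differences give
  p = 1.
* **mRNA–protein correlation.** Pearson r per gene across matched strains
  (≥ 3 required) plus an overall r pooled over all matched values.

## QTL mapping

Single-marker linear mixed model `y = Wα + xβ + u + ε`,
`u ~ N(0, σ_g²K)`, with K the centered relatedness matrix
`(1/p) Σ (x_k − x̄_k)(x_k − x̄_k)ᵀ`. K is eigendecomposed once; the
variance ratio λ = σ_g²/σ_e² is profiled per marker by restricted maximum
likelihood over log₁₀λ ∈ [−5, 5]. The single-trait scan uses a 21-point
grid plus golden-section refinement; the vectorised multi-trait path (used
by permutation FDR and the calibration studies) uses a denser fixed
61-point grid shared across all (trait, marker) pairs so each REML
evaluation stays one array operation — the residual λ discretisation
perturbs Wald p-values far below every tolerance used here. Marker effects
are tested by Wald t on n − q df; with K = I the scan is algebraically
identical to OLS for any λ, which the tests exploit as an oracle.

Traits are mapped at strain level (M/F averaged by default, or
sex-stratified). The top variant per trait is the QTL, ties broken by
genomic coordinate. Classification: **cis** if within 1 Mb of the TSS on
the same chromosome; **trans** if on another chromosome or ≥ 5 Mb from the
nearest exon boundary (a stricter ">10 Mb from the gene" variant is
available behind a flag); the gap between the definitions is
"unclassified".

**Permutation FDR.** Strain labels of the expression matrix are permuted
(one shuffle shared by all traits, preserving the M/F pairing), the scan is
repeated, and per-trait minimum p-values form the empirical null. For a
candidate threshold t, FDR(t) = mean permuted count of traits at or below t
over the observed count; the threshold is the largest observed statistic
with estimated FDR ≤ the 5% target (10 permutations by default). Cis and
genome-wide statistics get separate thresholds, mirroring the distinct
published cis/trans cutoffs. On panels with 50 planted effects among 500
proteins the realized FDR sits within binomial error of the target and
power exceeds 80% (see `tests/test_acceptance.py`).

## Colocalization

Wakefield approximate Bayes factor per marker,
`log ABF = ½[log(1−r) + r z²]`, `r = W/(V+W)`, with prior effect sd 0.15
(the standard choice for standardized quantitative traits). Five
hypotheses are scored in log space with per-SNP priors p₁ = p₂ = 10⁻⁴ and
p₁₂ = 10⁻⁵ (field-standard defaults; the H3 cross-term is computed with a
stable log-difference). Windows are ±500 kb around the index locus;
PP4 > 0.8 is called a colocalization. Single-SNP windows have no
two-variant configuration, so PP3 is defined as 0 there. The same
operation serves eQTL–pQTL, trans→cis and pQTL–phenotype pairs.

## Causal model selection

Four DAGs over (Q, P, T) with Q constrained to be a root: causal chain
Q→P→T, reactive chain Q→T→P, pleiotropic fork, and the full model with
both Q→T and P→T. Each node given its parents is a Gaussian linear
regression; structures are scored by BIC (−2 logL + k ln n, counting
intercepts, slopes and variances; Q's marginal term is identical across
structures and omitted). BIC rather than a posterior over structures keeps
the score prior-free and reproducible. The winner plus its BIC gap to the
runner-up is reported, alongside a mediation summary
`1 − β(Q→T|P)/β(Q→T)` clipped to [0, 1]. At study scale (~30 strains) the
selection is under-powered — the recovery studies use n = 200 to validate
correctness; treat 30-strain calls as hypotheses, not conclusions.

## What the generator does not emulate

Real LD beyond the RI Markov chain (no mutation, drift or selection),
X-chromosome dosage, peptide-level sequence effects (missed cleavages,
modifications), non-Gaussian abundance distributions, shared co-expression
structure between proteins, and batch effects beyond additive per-protein
offsets. Passing tests therefore demonstrate correctness of the estimators
under their stated models, not robustness to every artefact of real
proteomics data.

## Numerical choices and degenerate inputs

Eigenvalues of K are clipped at 0 (tolerance −1e−8); rank-deficient
covariates and singular impurity matrices raise; monomorphic-only marker
sets raise at kinship construction; markers with non-finite REML
likelihood are skipped and logged; zero-variance traits give undefined
heritability (NaN) rather than 0; all-missing channels raise at
normalization; proteins with no surviving PSMs are dropped and counted.
Coordinates are 1-based inclusive bp internally; dialect conversion (Mb)
happens only in the readers. Problem sizes in tests and the acceptance
script (500-protein panels, 10–20 seeds, 100–200 replicates) were chosen
as the smallest sizes at which the Monte-Carlo error of each check is
comfortably below its tolerance.
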
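# Methods

## The biological model

Dogroses of *Rosa* sect. *Caninae* are mostly pentaploid (2n = 5x = 35)
but sexual, thanks to the asymmetric *canina meiosis*: exactly two highly
homologous chromosome sets pair as bivalents and recombine, while the
remaining ploidy − 2 sets stay as univalents. Pollen carries one
(recombined) bivalent-derived set (n = x = 7); the egg carries one
recombined bivalent-derived set plus every univalent set unchanged
(n = 4x = 28). Fertilization restores the somatic number. Two consequences
drive everything in this package:

1. **Copy-number structure.** A locus has at most four distinct alleles in
   a pentaploid descended from founders whose two bivalent sets carry
   identical copies: the duplicated "bivalent" allele plus up to three
   univalent alleles. An allele carried in k of p sets contributes a
   fraction k/p of genomic template, so a diagnostic SNP's base frequency
   in gDNA sits at 0.2, 0.4 or 0.6 for k = 1, 2, 3 at p = 5.
2. **The transcription null.** If every copy is transcribed at the same
   per-copy rate, the same k/p fractions hold in cDNA. Allele-specific
   expression is a deviation of the cDNA fraction from k/p.

## Forward simulator (`canina_genetics`)

Chromosome sets are tracked as allele labels per single-copy locus.
Recombination between the two bivalent sets uses a Poisson crossover count
per meiosis (mean = `recombination_rate`) with uniform breakpoints on a
unit map; loci are evenly spaced on that map (no genetic map exists for
these markers, and results below never depend on the spacing). Which of
the two recombination products enters a gamete is a fair coin; no
segregation bias is modelled. Mutation follows the infinite-alleles model:
each transmission replaces the allele with a fresh label with probability
`mutation_rate`. Univalents bypass recombination entirely and are copied
into the egg, which makes their maternal-only transmission an exact
invariant rather than a statistical one. Tetraploid dogroses (haploid
pollen, triploid eggs) are the `ploidy=4` case. A single seeded
`numpy.random.Generator` drives all draws in documented order, so
identical seeds reproduce simulations bit for bit.

`evolve` is a constant-size, non-overlapping-generation random-mating
driver; it exists to exercise the transmission invariants (four-allele
ceiling, label conservation) over pedigrees, not to model dogrose
demography.

## Assay simulator (`pyroseq_sim`)

The unit of simulation is the *reported allele fraction* of one
pyrosequencing replicate — no pyrogram or dispensation modelling.
Replicate counts follow a beta-binomial: a replicate draws a success
probability from Beta with mean m (the true fraction, optionally scaled by
a per-assay multiplicative bias and clipped to [0, 1]) and intra-class
correlation ρ, then binomial counts at read depth N. Defaults N = 500,
ρ = 0.005 give a replicate standard deviation of ≈ 0.041 at m = 0.4,
consistent with the replicate scatter such instruments show; ρ = 0
degenerates to binomial and `read_depth=None` is the infinite-depth
(noiseless) limit used for exactness tests. Depth is nominal: the
instrument's internal averaging is not public, so N should be read as an
effective count controlling variance, not as sequenced molecules.

cDNA means come in two modes. *Composition mode* derives every assay of a
locus from one per-copy rate profile e_a: the carrier set's expected
fraction is Σ_carriers k_a e_a / Σ_all k_b e_b, so assays are mutually
consistent. *Per-assay target mode* assigns each assay its own true cDNA
fraction. The second exists because real assays carry independent PCR and
primer biases — observed fold deviations of a locus need not be jointly
consistent (e.g. per-assay cDNA fractions 0.174, 0.58, 0.58 sum past 1) —
and it is the default for estimator-recovery studies. The experiment
design mirrors the flower-bud layout: 2 gDNA replicates per individual and
3 cDNA replicates per bud stage (small/large) per individual, 3
individuals; bud stage has no effect by default (none was observed), with
an optional stage multiplier for power studies.

## Allele calling (`allele_calling`)

Clones are collapsed by single-linkage clustering with a difference budget
of `max_intra_allele_diff = 4` events, where a contiguous indel run counts
as one event; this mirrors the pragmatic lumping of sub-clades that differ
by a handful of substitutions. Clusters below `min_clones = 2` are
excluded as putative PCR-error singletons but reported. Note that under
single linkage a clone with one private error always joins its parent
cluster — a flagged singleton is a sequence genuinely distant from every
cluster. Consensus is column-majority with IUPAC codes at ties; tied
columns are barred from SNP candidacy.

Chimera screening scores, for every ordered allele pair and breakpoint,
the mosaic parent1[:b] + parent2[b:] against each clone. A clone is
chimeric when the best mosaic beats the best single parent by
≥ `min_improvement = 3` mismatches with ≥ `min_flank_sites = 1`
parent-diagnostic sites supporting each flank; the breakpoint is reported
as the half-open column interval between the innermost supporting sites,
which is the finest resolution the data permit. Exact consensus copies can
never be flagged, and the default threshold keeps the false-positive rate
on error-bearing clean clones well under the few-percent chimera rate
reported for this kind of cloning data.

Diagnostic-SNP discovery emits coding columns that split the alleles into
two clean bases, no gaps or ambiguity, with `flank = 3` monomorphic
columns either side as a pyrosequencing-suitability proxy (the real
instrument criterion is unpublished, so counts on real data may differ).
Carrier sets of size ≥ 2 are allowed — a SNP shared by two close alleles
measures their combined frequency, as happens for closely related rDNA
families.

## Copy-number inference (`copy_number`)

For one individual and locus, every composition of the ploidy among the
detected alleles (each ≥ 1 copy) is enumerated — there are C(p−1, a−1) —
and scored by the likelihood of the gDNA replicates around the implied
means Σ_carriers k/p. With read depths present the likelihood is
beta-binomial (the noise model's ρ); with fractions only, Gaussian with a
scale pooled across the locus's replicates (floored at 10⁻³). Alleles with
no covering assay absorb residual copies; likelihood ties are resolved
toward the most even residual split, then label order, and flagged.
Calls are per individual, since real compositions differ between plants.
The call reports the log-likelihood gap to the nearest differently-scored
composition as a confidence measure.

## Allele-specific transcription (`ase`)

Fractions are analysed untransformed (a logit switch exists but defaults
off, matching how such data are conventionally tested). The template
contrast is the classical mixed-model ANOVA with individual as a random
factor: F = MS(template) / MS(template × individual) on
(1, n_ind − 1) degrees of freedom, computed from weighted-means sums of
squares. Replicate counts are proportional across cells (they depend only
on template), so the decomposition is exact; the expected-mean-squares
form was chosen over REML because three individuals give REML nothing to
estimate and the closed form has no convergence failure modes. With one
individual the function degrades to Welch's t with a warning. A
2,000-run null simulation under the default noise model puts the type-I
error at 0.047 against the nominal 0.05.

Fold deviation is mean(cDNA)/expected with a seeded percentile bootstrap
CI over replicates; values below 1 are reported as the reciprocal
"x-fold lower" to match conventional phrasing. Nuisance factors (bud
stage, individual) get one-way ANOVAs on cDNA rows. The per-locus report
groups individuals that share a genomic composition and splits those that
differ, and adds Benjamini–Hochberg columns next to raw p-values (both are
reported; the per-SNP figures this mirrors used raw p).

## Molecular evolution (`molevol`)

*Counting.* Polymorphic codon columns are connected by a minimum spanning
tree on the codon graph (single-nucleotide steps, deterministic
tie-breaks); each edge contributes pathway-averaged synonymous /
non-synonymous step counts, with pathways through stop codons dropped when
avoidable. Codons with a gap or ambiguity in any sequence are excluded
(complete deletion); indels are counted as distinct gap-run events.
Column-wise minimum-change counting is one of several defensible
conventions (pairwise summation is another); the tests pin this one
against an exhaustive pathway-enumeration oracle.

*NG86.* Sites by degeneracy counting averaged over the pair, differences
by pathway averaging, Jukes–Cantor correction on both proportions;
ω undefined at dS = 0 and an explicit error past the JC domain (p ≥ 3/4).

*Codon ML.* The one-ratio model is the standard reversible 61-state codon
process with rate π_j κ^[ts] ω^[nonsyn] on single-nucleotide changes, F3x4
frequencies from the data (stops excluded, renormalized, small
pseudo-frequency against unobserved nucleotides), generator scaled to one
expected substitution per codon per unit branch length. The likelihood
uses Felsenstein pruning over pattern-compressed columns with an
eigendecomposed symmetrized generator. Optimization is L-BFGS-B on log
parameters (branch lengths, κ, ω) from three ω starts {0.1, 0.5, 1.5},
ftol 10⁻⁸, best kept; repeat fits agree in lnL to < 10⁻⁴. dS and dN are
reported per site from the fitted flux split and the neutral-site
proportions, following the usual ML-reporting convention. The two-ratio
model gives the terminal branches of named (multi-copy) alleles their own
ω; 2ΔlnL is referred to χ²₁, with a safeguarded re-polish of the
alternative from the null's optimum so nesting can never be violated
numerically. Exact reproduction of published lnL values is not claimed
(data constants and deletion conventions differ); ω, κ, dS, dN are the
comparable quantities.

*Rate tests.* Tajima's 1D relative rate test replaces a codon-ML relative
rate test deliberately: it is fully specified, assumption-light and
desk-verifiable, and it addresses the same question (rate equality between
alleles against an outgroup). m1 + m2 = 0 returns p = 1 flagged as
no-test. The batch wrapper BH-corrects across allele pairs.

*Simulator.* `simulate_codons` evolves codons along a newick tree under
exactly the process the ML fit assumes (uniform sense-codon root by
default), so fit-recovers-simulation is a closed loop: median over 20
seeds at 400 codons / 4 taxa recovers ω within ±0.05 and κ within ±0.3,
and the two-ratio LRT's type-I error over 200 one-ω simulations is 0.045.

## What the synthetic data do and do not show

The generators reproduce the *statistical structure* the analyses assume:
copy-number-proportional gDNA means, expression-shifted cDNA means,
beta-binomial replicate scatter, canina-meiotic transmission. They do not
reproduce instrument-specific artifacts (dispensation chemistry,
homopolymer drift, context-dependent primer bias beyond a constant
per-assay multiplier), PCR recombination beyond single-breakpoint
two-parent mosaics, or real codon usage and among-site rate variation.
Passing recovery tests therefore demonstrates correctness of the
estimators under the stated model, not robustness to every artifact of
real pyrosequencing data; the anomaly-flagging path exists precisely for
assays that violate the model (e.g. a 0.778 mean against a fitted 0.6).

## Numerical choices and problem sizes

Tolerances and sizes used by the test suite are the package's own
choices: 500 copy-number datasets, 2,000 GLM null runs, 200 LRT
simulations at 400 codons, 200-seed fold-recovery batches — large enough
for stable Monte-Carlo estimates at the asserted bands, small enough to
keep the suite interactive. Degenerate inputs are handled explicitly:
all-constant responses return p = 1 (F = 0 convention), zero-variance
nuisance ANOVAs return NaN with a warning, ω at its lower bound is
flagged, and empty diagnostic-SNP lists are a valid result (loci without
a usable SNP simply go unassayed, with residual-copy absorption
downstream).

## Known limitations

- No joint copy-number inference across loci; no linkage of calls to
  physical chromosomes beyond the bivalent-duplicate interpretation,
  which is an assumption.
- The mixed-model p-values are EMS-ANOVA, not SPSS/REML output; exact
  agreement with other software is not claimed.
- Column-wise substitution counts are convention-sensitive (see above).
- The flank-monomorphism proxy for pyrosequencing suitability is a
  stand-in for an unpublished instrument criterion.
- Tajima's RRT uses site counts, not a codon model; it trades power for
  exactness and transparency.
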
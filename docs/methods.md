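# Methods

This note documents the models, estimators, numerical conventions and
design choices behind `fusionscan`, and what the synthetic-data generator
does and does not emulate.

## The synthetic lineage-fusion model

The generator exists to give every estimator a dataset with known truth.
It is a stand-in: the analysis it feeds was designed for empirical ddRAD
data, and no generative model is prescribed for that system, so every
simulator choice here is our own and is labelled as such.

**Allele frequencies.** Three lineages with true history ((CAL,CHI),HOL).
Ancestral frequencies are uniform on [0.05, 0.95] (avoiding a glut of
monomorphic loci; loci that still end up monomorphic in a finite sample are
retained, and downstream filters must cope). Daughter frequencies follow
the Balding–Nichols beta model Beta(p(1−F)/F, (1−p)(1−F)/F). HOL and the
internal (CAL,CHI) ancestor drift from the root with `F_deep` (default
0.3); CAL and CHI drift from the internal ancestor with `F_shallow`
(default 0.1). The beta F is a drift *parameter*, not a promised realized
F_ST; the mapping is approximate and is validated empirically (monotone in
F, shallow split < deep split) rather than assumed exact. A parent
frequency that reaches 0 or 1 stays fixed in its descendants.

**Geography and ancestry.** `n_pops` populations sit at even spacing along
a `transect_length_km` south–north transect (constant longitude anchored at
San Diego, so great-circle distance from the anchor equals transect
distance). Expected Holarctic ancestry follows the logistic cline

    q(d) = 1 / (1 + exp(−4 (d − center) / width)),

where `width` is the inverse of the maximum slope — the standard
hybrid-zone cline-width convention. Modes:

- `fusion` — long-term random interbreeding: each allele copy of each
  individual is independently HOL-derived with probability q(d). The truth
  table records q(d) itself; sample-level ancestry therefore scatters
  around it with binomial error.
- `isolation` — no admixture anywhere; individuals south/north of the
  centre are pure CAL/HOL and mtDNA matches nuclear ancestry.
- `recent_contact` — exactly one generation of random mating: an individual
  is pure HOL with probability q², pure CAL with (1−q)², otherwise an F1
  carrying exactly one allele from each parental lineage at every
  non-resistant autosomal locus.

**Resistant loci.** A fraction `frac_resistant` (default 5%) of autosomal
loci are introgression-resistant: their ancestry follows a hard step at the
cline centre instead of q(d), emulating loci that do not cross the species
boundary. They are what keeps the true topology recoverable after fusion.

**mtDNA.** A single categorical lineage label per individual, drawn from a
logistic cline centred at `mt_cline_center_km` (which may be displaced from
the nuclear centre) — sufficient for profile and uncoupling tests. Optional
haplotype sequences are lineage reference sequences (12 diagnostic sites
per lineage on a 400 bp fragment) plus Poisson(1) private mutations per
individual, enough to exercise ϕ_ST and nearest-haplotype assignment.

**Sex and Z loci.** Sex is Bernoulli(`sex_ratio`); females are hemizygous
(ploidy 1) at the `frac_z_linked` Z loci, written as haploid VCF calls.
CHI is always a fully isolated population. Missing calls are masked
uniformly at `missing_rate`. All randomness flows from one seed through
named substreams; outputs are byte-identical under a fixed seed.

**What the simulator does not emulate:** coalescent genealogies and linked
drift, recombination maps, selection, sequencing-read error, allele
dropout, and spatially autocorrelated sampling noise. Passing tests
therefore demonstrate correctness of the estimators and the qualitative
fusion signatures under idealised sampling — not robustness to every
artefact of empirical ddRAD data.

## Estimators and numerical conventions

**Weir–Cockerham θ̂.** Two-allele, two-population variance components
(a: among populations, b: among individuals within populations, c: within
individuals) with the observed-heterozygosity terms; per-locus sample sizes
are the observed non-missing diploid counts. Negative estimates are
reported, never clamped (clamping would break the estimator's expectation
and the oracle tests). The multi-locus mean is the ratio of summed
components Σa / Σ(a+b+c). Hemizygous calls never enter the diploid-based
components: at Z-linked loci θ̂ uses male diploids only (our convention;
sequence-based Z differentiation is ϕ_ST's job). The unit tests verify the
component formulas against an independent allele-indicator nested-ANOVA
transcription to 1e−12.

**ϕ_ST.** One-level AMOVA on the pairwise Hamming distance matrix
(number of differing sites — the distance model is our default, chosen
because none is prescribed), σ²_a/(σ²_a+σ²_w), with a label-permutation
p-value counting the observed configuration in both numerator and
denominator (p ∈ (0,1]); 100 permutations by default.

**f3 and block jackknife.** Per-locus (p_C−p_A)(p_C−p_B); the corrected
form subtracts the target's sampling-variance estimate p̂(1−p̂)/(n_C−1)
(zero when the target is fixed, n_C = allele count), so E[f3] = 0 when C is
an independent sample of a source population. Blocks are counted in SNPs
(default 500) in genomic order, the last block may be short, and the SE is
the weighted (Busing-style) delete-one-block jackknife, which reduces
exactly to the classic delete-one formula for equal blocks. f3 values are
unscaled (no heterozygosity normalisation): magnitudes are not comparable
across datasets or to TreeMix output — only signs and Z-scores are
interpreted.

**Supervised q.** The admixture likelihood (dosage binomial in
q·p_HOL + (1−q)·p_CAL) is concave in q because the binomial log-likelihood
is concave in the mixture frequency and the mixture is linear in q. The
maximiser is found by bisection on the derivative over [0,1] (60
iterations, tolerance 1e−10), vectorised across samples — exact,
deterministic and fast. Reference frequencies of 0/1 are clipped by 1e−9 so
fixed loci keep a finite likelihood. At 1000 loci under the default drift
the Cramér–Rao bound puts the standard error of q̂ near 0.027, so RMSE
≤ 0.05 is the attainable — and tested — accuracy contract.

**EM admixture.** ADMIXTURE-style EM on the uncorrelated-frequency
admixture likelihood for small K, chosen over a Bayesian
correlated-frequency model because it is deterministic, fast and yields
the same interpretation of q. Five seeded restarts (best log-likelihood
wins, ties broken by restart order), stopping when the log-likelihood gain
drops below 1e−4 (the conventional stopping rule for this likelihood; near
the boundary the likelihood keeps creeping by ~1e−4/iteration long after q
has stabilised). Loci monomorphic across the sample are dropped first.
Missing genotypes are dropped per locus per sample. Clusters are aligned to
reference panels, when given, by greedy frequency correlation.

**Classification.** A sample is assigned to a lineage iff that lineage's
coefficient is ≥ 0.7 (boundary inclusive — "under 0.7" is admixed, so
exactly 0.7 is pure); coefficients strictly inside (0.3, 0.7) are ADMIXED.
Panel inclusion is *strict*: F_ST > 0.58 (or > 0.2) excludes a locus whose
θ̂ equals the threshold; the fixed rule requires θ̂ = 1 within 1e−9.
Heterozygotes at the diagnostic Z SNP are always ADMIXED. Hemizygous panel
states are reported as C/H, never as homozygous diploid evidence.

**Site filters.** Missingness is inclusive (fraction ≤ threshold is
retained). The exact HWE test is the two-sided "sum of configuration
probabilities ≤ observed" version (not mid-p), computed with log-gamma
weights and verified against full rational-arithmetic enumeration; default
α = 0.001 (no value is prescribed, so a conventional strict PLINK-style
default was chosen). Positional thinning chains loci closer than the
window into clusters and keeps one uniformly at random per cluster (seeded
— "randomly thinned"). LD pruning removes the later-position SNP of any
within-window pair with r² above threshold (composite genotype r² =
squared Pearson correlation of dosages over jointly observed samples); the
keep-earlier rule is a documented convention, not a replication of PLINK's
heuristic. Filter order is configurable and reported; the default follows
thin 50 bp → missingness → HWE → LD.

**Clines.** Great-circle distance uses the haversine formula with a
spherical Earth of radius 6371.0 km. The logistic fit is bounded
least-squares (`scipy.optimize.curve_fit`) on population means, reported
only on convergence.

**Topology tally.** Block distance is the mean squared allele-frequency
difference; each block votes for its minimum-distance pair and exact ties
go to a separate bucket. This is a deliberate surrogate for posterior
tree-set proportions from species-tree inference: only the qualitative
majority pattern (which pair wins genome-wide vs on a high-F_ST subset) is
meaningful, never the percentages themselves.

**Uncoupling test.** The difference in mean nuclear q_HOL between mtDNA
classes, with a two-sided permutation p-value (+1 smoothing). The
mosaic-genome argument is classically made from patterns, not a test; this
permutation test is this package's own formalisation and its result object
says so.

## Verification scenarios and problem sizes

The acceptance battery (`scripts/acceptance.py`, mirrored in
`tests/test_acceptance.py`) uses these desk-scale study conditions, chosen
once as realistic for a ddRAD study of this design:

- f3 sign/power: 50 replicates, 5 populations × 20 diploids + CHI, 2000
  loci, F_deep 0.3 / F_shallow 0.1, cline width 400 km on a 2000 km
  transect so the mid-transect target has q ≈ 0.5 and the ends are
  near-pure sources; blocks of 500 SNPs.
- Ancestry recovery: 108 supervised replicates at 1000 loci over true
  q ∈ {0.1, …, 0.9}; EM on two pure lineages of 20 diploids at 1000 loci.
- Uncoupling: 200 null replicates (fusion mode, the single mid-transect
  population of 50, where mtDNA is independent of individual nuclear
  ancestry) and 200 power replicates (recent-contact mode, where mtDNA
  tracks parent of origin); 199 permutations each.
- Topology: 3000 loci, 8 transect populations × 15 + CHI, 5% resistant
  loci. The fusion scenario uses a cline of width 4000 km (twice the
  transect): after long fusion the neutral ancestry cline is broad, so the
  sampled "CAL" and "HOL" groups (transect ends) are genuinely admixed
  (mean q ≈ 0.27/0.73) — under this generative model that is precisely the
  regime in which the genome-wide closest-pair vote flips to CAL–HOL while
  resistant/high-F_ST loci keep voting CAL–CHI. With near-pure end groups
  (a narrow cline) the genome-wide vote still recovers the true history:
  the discordance signature requires the fused groups to actually share
  ancestry, which is the phenomenon being modelled.
- Cline recovery: 50 replicates of 20 populations × 30 samples at 300
  loci, true centre 1000 km, width 500 km; supervised q̂ against
  end-population reference frequencies.

## Known limitations

- Two-population, biallelic W&C only; no hierarchical (>2-level) AMOVA.
- The EM is a point estimator: no credible intervals, no ΔK model choice,
  no cross-run cluster matching beyond frequency-correlation alignment.
- The uncoupling test conditions on a user-chosen region; applying it
  across a structured region confounds geography with mtDNA class.
- Topology percentages are surrogate vote shares, not tree posteriors.
- VCF support is deliberately narrow: unphased biallelic SNPs with GT only
  (phase separators accepted, phase discarded); no BCF/gVCF/imputation.
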
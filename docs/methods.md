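# Methods

This note documents the models, estimators, rule boundaries, and numerical
choices behind `applepop`, and what the bundled simulator does and does not
emulate.

## Genotype calling and site filters

Calling is per accession × site from read support. An allele is *present*
iff it is supported by ≥ `min_reads` (default 2) reads **and** its read
fraction is ≥ `min_af` (default 0.3); ref and alt are judged symmetrically
on their own read counts. Ref-only → dosage 0, alt-only → 2, both → 1,
neither (including zero depth) → missing. The allele-frequency threshold is
interpreted as a *within-accession read fraction* — it appears in the
context of per-accession genotype assignment; a population-level reading
would be a different filter and is not implemented.

Site filters, applied to coordinate-sorted sites:

* **Proximity**: any site whose nearest neighbour lies < 5 bp away is
  removed; the rule is symmetric, so both members of a close pair go.
  Distances are measured on the input coordinates, which makes the filter
  idempotent (survivors can never become "close" by removal).
* **Heterozygous-only**: sites where every non-missing call is a het.
* **Missingness**: "more than 50 %" is strict — a site with exactly half
  its calls missing survives.

The core SNP set for structure/ancestry analyses uses MAF ≥ 5 % and
missing rate ≤ 10 %, both boundaries inclusive as their wording implies.
A site violating several rules is tallied once in the `FilterReport`, under
the first rule in the order proximity → het-only → missingness; counts
always reconcile (removed + retained = input).

## Fourfold-degenerate sites and coding effects

A SNP is fourfold degenerate (4D) when it sits at a third codon position
whose two upstream bases determine the amino acid regardless of the third
(standard genetic code), honouring strand and CDS phase (the initial
`phase` bases of the first coding segment in transcription order are
trimmed). Genes whose phase-adjusted CDS length is not divisible by 3 are
skipped with a warning. A SNP covered by several coding frames must be 4D
in *all* of them — the conservative resolution of overlapping-gene
conflicts. Coding effects are classified by translating the codon with the
ref and alt alleles substituted; with overlapping frames, any
nonsynonymous verdict wins. Both paths are validated in the test suite
against a brute-force oracle that mutates and translates every coding
position.

## Diversity, differentiation, LD, HWE

**π.** Per site, the unbiased estimator
π_site = n/(n−1) · (1 − Σₐ p̂ₐ²), with n the number of non-missing allele
copies in the group; this equals the mean pairwise difference among allele
copies, which the tests verify by explicit pair enumeration. Window values
are Σ π_site over the window divided by the *window width in bp* — the
common windowed-π convention. The denominator is a documented knob
(`denominator='sites'` divides by usable-site count instead); since the
source analyses do not state their convention, the bp-denominator was
chosen and affects absolute levels only, not contrasts.

**F_ST.** Weir & Cockerham (1984) variance components per biallelic locus —
a (among populations), b (among individuals within populations), c (within
individuals) — with the multi-locus ratio of averages Σa / Σ(a+b+c), the
standard multi-locus practice (not the average of per-locus ratios). Loci
with an undefined or zero denominator are skipped. Per-SNP divergence
scans use the single-locus ratio a/(a+b+c); negative values are kept in
the ranking (they carry rank information; clamping is a documented
alternative). The top fraction keeps ceil(top_frac · N) SNPs with cutoff
ties retained.

**MDS.** Classical (Torgerson) scaling: double-centre −½ J D² J,
eigendecompose, keep the top `dims` non-negative eigenpairs (negative
eigenvalues truncate to zero; rank-deficient requests zero-pad with a
warning). The embedding is validated by the Spearman ρ between embedded
Euclidean distances and the input values over all pairs.

**LD.** Composite (genotype-dosage) r² — the squared Pearson correlation of
dosage vectors over accessions called at both sites — matching an analysis
of *genotypes* rather than EM-phased haplotypes. Sites are gated by
within-group MAF ≥ 0.10 and HWE exact p > 0.001 (the cutoff excludes
p ≤ 0.001, mirroring the usual `-hwcutoff` semantics); zero-variance pairs
are skipped; empty distance bins are reported absent, not zero.

**HWE.** The exact conditional test: conditional on the observed allele
counts, all compatible heterozygote counts are enumerated and the p-value
is the total probability of configurations no more probable than the
observed one. The implementation works in log-space with an exact
renormalization; the tests compare it, exhaustively for all tables with
n ≤ 30, against an independent integer-arithmetic enumeration.

## Phylogeny and PCA

Distances are p-distances on dosages, d(i,j) = mean |dᵢ − dⱼ|/2 over sites
called in both accessions (the simplest reading of a default
distance-matrix NJ analysis; model-based corrections are out of scope).
NJ follows Saitou–Nei with the Studier–Keppler Q criterion. Ties in Q are
broken deterministically by the lexicographically smallest pair of subtree
labels (each subtree keyed by its smallest leaf label). Negative branch
lengths are clamped to zero with the deficit transferred to the sister
edge; on additive matrices no clamping occurs and the generating tree is
recovered exactly (verified over random additive matrices to 1e−9).
Bootstrap resamples site columns with replacement (seeded), rebuilds the
tree, and reports for each internal bipartition of the full-data tree the
fraction of replicates containing it; supports are mapped onto the
full-data topology only. Outgroup rooting places the root at the midpoint
of the outgroup's pendant edge and leaves the bipartition set unchanged.

PCA uses the Patterson normalization: centre each site by its mean dosage,
scale by sqrt(p̂(1−p̂)) with p̂ the mean allele frequency, mean-impute
missing entries (zero after centring), drop monomorphic sites, and
eigendecompose the accession covariance. Eigenvector signs are fixed so the
largest-magnitude loading is positive, making outputs reproducible; scores
are eigenvectors scaled by the square roots of their eigenvalues.

## Ancestry mosaic

Per site and group, the major allele is the allele with frequency
*strictly* above 0.6 among non-missing calls (at exactly 0.6 there is no
major allele). A site is assigned *progenitor* when the domesticated and
progenitor groups share a major allele, *introgressor* when domesticated
and introgressor do; sites satisfying both increment **both** window
tallies — the procedure defines no exclusion rule for them and the ratio
test dilutes them naturally. Per non-overlapping 100-kb window with
progenitor/introgressor tallies c_p, c_i and total SNP count t, the label
is progenitor iff c_p > 2·c_i **and** t > 5 (both strict), introgressor by
the mirrored rule, else uncertain. "Total SNP count" is read as all
scanned SNPs in the window (the sentence contrasts it with the assigned
counts); counting only assigned sites is exposed as an option through the
inputs. Genome fractions are bp-weighted (terminal windows truncated at
the chromosome end when lengths are known); window-counting differs only
at chromosome ends.

The scanned SNP set applies the MAF ≥ 5 %, missing ≤ 10 % gates **over the
pooled accessions of the three groups being compared**. This matters:
sites near-monomorphic across the whole trio carry no ancestry signal but,
if retained, all share one major allele and inflate both tallies, making
c_p > 2·c_i unreachable. Under any exchangeable drift model around a
common ancestral frequency, the probability that two groups share a major
allele is at least one half, so a panel-wide MAF gate would leave the
ratio rule permanently starved; the trio-pooled gate removes exactly the
uninformative sites and is the reading adopted here.

## Sweep scan

For a grid point x (every 100 bp) the window holds the SNPs within
± 0.025 cM (a 0.05 cM window), at most 100, nearest kept. Genetic
positions come from piecewise-linear interpolation of the (bp, cM) map
anchors, with out-of-span positions extrapolated at the chromosome's mean
cM/bp rate.

Per SNP j: p̂ the reference allele frequency, (nⱼ, kⱼ) the object group's
allele count and alt count. The neutral marginal is
L0ⱼ = ∫ Binom(kⱼ | nⱼ, p) φ_ω(p | p̂) dp, where φ_ω is Normal(p̂, ω·p̂(1−p̂))
truncated to (0,1) with its tail mass placed as point masses at 0 and 1 —
a moment-matched drift kernel whose scale ω defaults to the
method-of-moments value F̂_ST/(1 − F̂_ST) from the genome-wide WC84 F_ST of
the two groups (an override is exposed). The sweep alternative with
effective selection parameter s̃ and map distance dⱼ (Morgans) from x uses
the escape probability cⱼ = 1 − e^(−dⱼ/s̃):
L1ⱼ(s̃) = cⱼ·L0ⱼ + (1 − cⱼ)·[p̂·1{kⱼ=nⱼ} + (1−p̂)·1{kⱼ=0}].
SNPs are down-weighted for local redundancy: wⱼ = 1/mⱼ with mⱼ the number
of window SNPs whose reference-dosage r² with j is ≥ 0.7 (including j).
The score is max(0, 2·max_s̃ Σⱼ wⱼ (log L1ⱼ − log L0ⱼ)) over a log-spaced
s̃ grid (12 points, 10⁻⁵–10⁻¹ Morgans).

Two structural consequences are asserted as invariants: windows whose
object SNPs are all polymorphic score exactly zero (L1 ≤ L0 throughout,
and the maximized ratio floors at 0), and the score is invariant to a
joint ref/alt relabel (the drift kernel is reflection-symmetric). SNPs
fixed in the reference carry no frequency contrast for this model and are
excluded from windows. This formulation is a faithful, implementable
reduction of the cross-population composite-likelihood approach; exact
numerical agreement with any particular external implementation is not
claimed — its own contract is what the oracles verify.

Quadrature: midpoint rule with 1,000 interior points plus the two boundary
masses, renormalized. Against an adaptive-quadrature oracle the relative
error at desk-scale parameters is ~10⁻⁵ at 4,000 points (the tested
configuration) and comfortably below the score contrasts that matter at
the 1,000-point default used in scans.

Region calling follows the averaging-and-joining recipe: 10-kb window means
of the non-missing grid scores; the join threshold is 80 % of the
genome-wide mean over non-missing windows (computed genome-wide, not per
chromosome — the unstated alternative is a config option); maximal runs of
qualifying windows become regions; two regions separated by exactly one
*scored* below-threshold window merge, with the gap window included in the
span (an unscored/missing gap window breaks regions without merging); the
region score is the maximum member-window mean; the top 10 % of regions by
score are kept (ceil count, cutoff ties retained); finally the top half by
π(reference)/π(object) over the region survive, with zero-object-π regions
ranking first (infinite ratio). Genes are attached by ≥ 1 bp span
intersection.

## The simulator

The generator is a Balding–Nichols drift model, not a coalescent:

* SNP positions are Poisson along each chromosome (default density
  0.002/bp at desk scale).
* Ancestral frequencies q ~ Beta(0.8, 0.8) — U-shaped, like a neutral SFS;
  the parameters are exposed.
* Population frequencies pᵢ ~ Beta(q(1−F)/F, (1−q)(1−F)/F). A population
  standing in for a distinct *species* may use two levels: a deep species
  draw (F, default 0.7 in the ancestry scenario) followed by a
  within-species draw (F_within, default 0.1). The two-level form is what
  produces interspecific alternate fixation — the feature the major-allele
  ancestry procedure feeds on — while keeping within-species diversity;
  a single level cannot produce it at any F, because both populations drift
  toward the same ancestral major allele.
* The admixed population tiles each chromosome with fixed-length blocks
  (default 100 kb), each block's source drawn from the configured
  fractions; block frequencies are copied from the source and perturbed
  with a small residual drift. A `None` source models an unsampled
  contributor (fresh draw with its own drift) and should come out
  `uncertain` downstream.
* Sweeps round the target population's frequencies to 0/1 inside the
  interval — a fixation implant that collapses diversity and creates the
  reference/object contrast the scan detects, without hitchhiking
  dynamics.
* Genotypes ~ Binomial(2, p); missingness is uniform (default 2 %); read
  depths ~ Poisson(λ = 12) with alt reads ~ Binomial(depth, f), f the
  allelic fraction perturbed by a 1 % per-read error.
* Toy 3-exon gene models tile the genome on alternating strands; the
  genome sequence is uniform random, and a linear genetic map (1 cM/Mb) is
  emitted.

All randomness derives from one seed through deterministically spawned
child streams; identical configs give byte-identical outputs.

**What it does not emulate.** Sites are independent, so the default output
has no linkage disequilibrium beyond drift-induced covariance — LD-decay
tests use the explicit correlated-block generator (`simulate_ld_blocks`),
and passing LD tests say nothing about realistic haplotype structure.
There is no recombination map heterogeneity, no selection dynamics, no
ascertainment against a reference genome, and allele-frequency spectra are
exchangeable across populations of equal F. Consequently, passing recovery
tests demonstrate the *estimators and rules* behave as specified under
their own assumptions, not that the pipeline's power on real data matches
the synthetic setting.

## Study scales used by the tests and acceptance script

Problem sizes were chosen as the smallest that leave the statistical
contrasts unambiguous: ancestry recovery uses 20 × 2 Mb chromosomes
(400 blocks of 100 kb, so binomial block-sampling noise is ≈ 2.5 points,
well inside the ±6-point recovery check) with 40 diploids per group; sweep
recovery uses 10-Mb genomes with one 100-kb implant at SNP density 0.001
and 20 diploids per group; oracle-equivalence checks run on tens of
accessions × ≤ a few hundred sites where brute force is exact and fast.

## Known limitations

* The per-accession read-fraction interpretation of the calling threshold
  is one of two defensible readings (see above); both are simple to swap.
* The sweep model's correlation down-weighting uses a hard r² ≥ 0.7
  partner count; softer weighting schemes exist.
* Multiallelic VCF records are skipped, not decomposed.
* The NJ implementation is O(n³) with an O(n²) tie scan per join —
  appropriate for panels of hundreds of accessions, not thousands.
* `hwe_exact` and `ld_decay` loop per site/pair in Python; they are meant
  for gated subsets (the pipeline subsamples LD input, default 2,000
  sites), not genome-scale exhaustive LD.
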
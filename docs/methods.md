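# Methods

This note documents the models, conventions and numerical choices behind
`canid`, and what the synthetic-data validation does and does not show.

## Genotype handling

Genotypes are biallelic autosomal SNP dosages counting the A1 allele
(0/1/2, −1 for missing) in a samples × markers `int8` matrix. Positions
are 1-based (PLINK MAP/BIM convention) and all interval logic uses closed
`[start, end]` bp intervals. The autosome filter keeps chromosome labels
"1"–"38" (dog) by default and is configurable.

Because PED/MAP files carry no allele columns, the counted allele on read
is the lexically smaller observed allele (`a1_policy="alpha"`), which is
deterministic and data-independent; PLINK's minor-allele rule is available
as `a1_policy="minor"`. Two consequences are worth knowing: (i) read →
write → read is the identity whenever `a1 < a2` lexically (the simulator
always writes A/G in that order) and for every marker in BED/BIM/FAM,
which stores alleles explicitly; (ii) a marker where only one allele is
observed cannot recover the unobserved allele from PED, so its orientation
after a round trip is undefined — such markers are typically removed by
any MAF filter before analysis.

Merging intersects marker ids, harmonizes alleles to the first dataset
(complementing dosages `d → 2 − d` at swapped A1/A2), and drops markers
with irreconcilable or strand-ambiguous (A/T, C/G) allele pairs, counting
them in the QC report. Missingness filtering removes samples first, then
markers, with strict-greater-than semantics (PLINK `--mind`/`--geno`);
the order is configurable and the report always reconciles
`in = out + removed` per axis.

The SNP-covered genome length is the sum over chromosomes of
`max(position) − min(position)`; it is the denominator of F_ROH.

## ROH detection and F_ROH

Detection is the consecutive-runs method (as in detectRUNS' "consecutive"
mode), not a sliding window: per sample and chromosome, maximal runs of
homozygous calls are split at every heterozygous or missing genotype (when
none are allowed — the default) and at inter-SNP gaps > `max_gap_bp`
(default 1000 kb). A run is reported iff its physical length ≥
`min_length_bp` (default 500 kb), its SNP count ≥ `min_snps`, and its
average spacing ≤ one SNP per 5000 kb. Segment boundaries are the first
and last homozygous SNP of the run (closed interval), not gap midpoints.
When small het/missing budgets are allowed the scan is a greedy
left-to-right extension trimmed back to homozygous endpoints; with the
default zero budgets it is exactly the maximal-run decomposition, and the
test suite proves it equivalent to a brute-force enumeration.

`min_snps` defaults to the Lencz false-positive bound
`l = ln(α/(n_s·n_i)) / ln(1 − h̄)` with α = 0.05, floored (an explicit
integer override is accepted, since the published analyses fixed the value
at 65 without reporting h̄). At the simulator's scaled marker density
(~1 SNP per 50–100 kb instead of ~1 per 15 kb on the real array), the
Lencz bound implies a minimum detectable run of several Mbp, so the
shortest length classes stay sparse in the synthetic tables; this is a
property of the scaled density, not of the detector.

F_ROH per sample divides summed ROH length by the SNP-covered autosome
length. The five reported coefficients use length thresholds
{0.5, 2, 4, 8, 16} Mbp, and the default convention is **cumulative**
(`froh_ge_X` sums all segments of length ≥ X). The published per-breed
table is internally consistent only under this convention: its own counts
× mean lengths reproduce the printed F_ROH column within 0.05 pp
cumulatively, but not class-by-class. A literal per-class mode is provided
and labelled. Group summaries use the sample mean and n−1 SD. The
published autosome length carries a 10× unit slip; the corrected
2,199.534 Mbp value (matching the dog autosome) makes the reconstruction
consistent and is the value embedded in `reference_tables.py`.

## Divergence

Weir–Cockerham θ uses the two-population biallelic variance components
a (among populations), b (among individuals within), c (within
individuals), computed per locus from sample sizes, allele frequencies and
*observed* heterozygosity, with `θ = Σa / Σ(a+b+c)` over loci. Loci with
any group fully missing, or fewer than three genotyped samples in the
pair, are skipped; monomorphic loci contribute zero to both sums. Negative
θ is preserved in diagnostics and clipped to 0 in the headline matrix.
Optional bootstrap over loci gives percentile CIs. θ is invariant to
A1/A2 relabelling (tested), and on Balding–Nichols simulations the
estimator tracks a Monte-Carlo expectation that includes the genotype
sampling layer — at realistic depths this is numerically ≈ F for two
populations at the same divergence.

The default Nei method is the 1972 standard distance with gene identities
pooled over loci before the ratio (what StAMPP computes); the 1983 D_A is
also exposed, since the published "D_a" notation is ambiguous, and every
matrix is tagged with its method. A zero identity (opposite fixation at
all shared loci) would be −ln 0; it is returned as the flag value 10^6.
Individual-level matrices treat each animal as a population of one
(frequencies in {0, ½, 1}).

## DAPC

Dosages are mean-imputed per marker (adegenet's default), centred, and
decomposed by SVD; the sign convention makes each component's
largest-magnitude loading positive, so results are bit-reproducible. The
initial PCA retains components covering 95 % of variance before α-score
selection. The α-score of a candidate PC count is the observed per-group
correct-reassignment proportion minus its mean over random label
permutations (default 25, seeded); the recommended count maximises it.
LDA whitens the pooled within-class covariance (ridge 10⁻⁸ on
singularity) and eigendecomposes the between-class scatter in the
whitened basis, yielding ≤ (groups − 1) discriminant functions; membership
posteriors use a Gaussian class model with identity covariance in the
whitened DF space and equal priors. "Variance represented" multiplies the
explained variance of the retained PCs by the share of discriminant
eigenvalue mass retained.

## Admixture

The likelihood is the standard K-cluster admixture model with
uncorrelated cluster frequencies: `g_ij ~ Binomial(2, π_ij)`,
`π_ij = Σ_k q_ik f_kj`, missing genotypes skipped, frequencies clamped to
[10⁻⁶, 1−10⁻⁶]. Estimation is EM on expected ancestry-allele counts
(frappe-style) from a seeded random start; the log-likelihood trace is
non-decreasing (asserted in tests) and K = 1 returns the closed-form
pooled-frequency solution. This deliberately replaces the original
Bayesian MCMC implementation: the model is identical, the point estimate
is deterministic and desk-scale, and the correlated-frequencies prior is
not implemented. Evanno ΔK is applied to replicate final log-likelihoods
in place of mean ln P(D); a zero replicate SD flags ΔK as infinite.
Cluster label switching is resolved by greedy matching before any
truth comparison, and per-group ancestry tables name clusters by their
majority group.

Defaults follow the published setup — replicates default to 10 per K over
K = 1..10 — while the analysis drivers and tests use smaller sweeps
(e.g. K = 1..5, 5 replicates, thinned markers) chosen so a full sweep
runs in minutes on one core; ancestry recovery saturates well below the
full panel in every validation.

## Network

The default pairwise distance is `1 − IBS` with
`IBS = mean (2 − |g_a − g_b|)/2` over shared non-missing loci — simple and
frequency-free. A PLINK-style method-of-moments PI_HAT
(`P(IBD=1)/2 + P(IBD=2)` solved from genome-wide IBS0/1/2 counts and
sample allele frequencies, probabilities clipped to [0,1] and
renormalised, no small-sample correction) is provided because the
published workflow fed "IBD distances" to Netview; both are labelled.
The mutual k-NN rule keeps an edge iff each endpoint is in the other's k
nearest; ties at the k-th distance break by sample order, so the graph is
fully deterministic. Super-paramagnetic clustering itself is out of
scope — the artifact delivers the graph that stage consumes.

## Gene panels

A SNP belongs to a gene iff the chromosome matches and
`start ≤ position ≤ end` (both edges in); SNPs in overlapping genes are
assigned to all and flagged. The packaged panel file
(`data/synthetic_panel.tsv`) carries the candidate genes of the four
phenotype categories with **synthetic placeholder coordinates** laid out
on the simulated genome; real-genome coordinates are user-supplied, and
GO over-representation against external annotation databases is out of
scope. Panel PCA delegates to the DAPC PCA restricted to panel columns
(provenance asserted by test). Factor analysis is principal-axis
factoring (via statsmodels) on standardised dosages with optional varimax
rotation and Thomson regression scores; "one gene, one factor" is
implemented as FA on per-gene mean dosages with `n_factors = n_genes`,
alongside marker-level FA. Constant variables are dropped with a warning
before factoring.

## Synthetic data: what it emulates, and what it does not

Balding–Nichols was chosen as the divergence model because W&C θ has a
computable expectation under it: ancestral frequencies U(0.05, 0.95),
population frequencies Beta(p(1−F)/F, (1−p)(1−F)/F), genotypes
Binomial(2, f). Admixed cohorts draw each allele copy from
`q f_A + (1−q) f_B` with recorded truth q. Autozygous tracts have
exponential lengths (mean 8 Mbp, truncated below at 1 Mbp), are placed
uniformly without overlap (rejection sampling keeps truth intervals
disjoint for clean recovery scoring), and the final tract is truncated
towards the remaining requirement so realized F_ROH lands in
[target, target + min_tract/genome]; inside a tract each SNP is set
homozygous with the allele drawn once per locus at its panel frequency.
Default geometry is dog-like but desk-scale: 10 chromosomes × 60 Mbp with
6,000–20,000 SNPs depending on the stage (the real array is ~38 × 60 Mbp
at ~1 SNP/15 kb). All generators are bit-reproducible under a fixed seed.

The five-breed preset mirrors the empirical design: BSD/GSD/GW/SWD as
diverged sources (group sizes 31/56/30/6 — the SWD cohort is raised from
the real 3 to 6 so pairwise θ is defined), plus a CWD cohort built as
GSD × GW admixture with q ≈ N(0.75, 0.05) and the strongest implanted
inbreeding (target F_ROH: CWD 0.10, SWD 0.08, GSD 0.06, BSD 0.05, GW 0).

What passing recovery tests shows: the detector, estimators and model
selection recover the parameters of data that match their own generative
assumptions, at realistic sample sizes and divergence. What it does not
show: robustness to LD (loci are independent here), genotyping error,
ascertainment bias of array SNPs, shared drift between related breeds
(divergence is star-shaped), or post-founding drift in the hybrid breed —
which is why the synthetic CWD, unlike the real one, does not cohere into
its own cluster in the k-NN graph or earn its own admixture cluster at
the Evanno optimum. Absolute θ values between the synthetic groups
(≈0.13–0.21) are a property of the chosen F, not a reproduction of the
published matrix.

## Degenerate inputs and tie-breaks

Chromosomes with < 2 markers get span 0 with a warning; empty ROH groups
produce empty rows rather than errors; pairs with zero shared genotyped
loci get a flagged missing distance; requesting more PCs than the matrix
rank truncates with a warning; a single group refuses discriminant
analysis; `evanno_delta_k` requires ≥ 3 consecutive K with ≥ 2 replicates.
All argsort-based tie-breaks (k-NN neighbours, cluster naming) are
resolved by explicit secondary keys so repeated runs are byte-identical.
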
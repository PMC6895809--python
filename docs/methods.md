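# Methods

This note documents the models and procedures implemented in
`eiphkit`, the defaults that matter, and what the synthetic cohort
does and does not establish about real data.

## Physical model of capillary fracture

The capillary wall is treated as an adhesive elastic cell layer with a
pre-existing flaw. Sustained bleeding is predicted once the flaw
reaches the critical fracture length `l_c = α·γ/E`, the only length
scale that an adhesion energy per area γ (J/m², i.e. N/m) and an
elastic modulus E (Pa, i.e. N/m²) can form. The dimensionless
prefactor α depends on flaw geometry and loading and is left
configurable (default 1): the package preserves every monotonicity the
model asserts — risk rises when adhesion falls or stiffness rises —
while isolating the unknown constant. `rupture_indicator` is the
scale-free ratio defect_length / l_c, with 1 the predicted threshold
of sustained bleeding.

Haemodynamics enter through two closures. Transmural pressure is the
plain difference intraluminal − alveolar (alveolar pressure is
negative during inspiration, which raises the wall load). Lumen
narrowing by venous remodelling is mapped to upstream pressure through
the laminar Poiseuille law: at fixed flow, a fractional radius
reduction f multiplies the segment's pressure drop by (1 − f)⁻⁴.
No pulsatile or network flow model is attempted; the model's role is
to define the three gene-set parameters (adhesion, stiffness, flow),
not to simulate haemodynamics. Pressures are stored in Pa; the single
unit boundary is the 133.322 Pa/mmHg conversion helper.

## Phenotype from tracheal-wash cytology

Each weekly sample scores 12 cytological categories plus cell density
on the ordinal scale 0 (none) – 3 (high). Records with malformed
dates, scores outside 0–3 or a missing haemosiderophage value are
rejected with a reason. Horses need ≥ 4 validated samples to enter the
analysis.

The per-horse phenotype is the HF frequency score over the series.
Two readings of the definition exist and both are implemented:

- **count mode (default)**: (# samples with HF score > 1) / n — the
  "number of times" reading, matching the term *frequency*;
- **sum mode**: (Σ HF scores over samples with HF score > 1) / n.

The threshold is strictly > 1: a score of 1 ("occasional") never
counts as bleeding evidence. Covariates are gender (male 0 / female
1), age at first race start within the sampling window (fractional
years), sampling-period factor (first / second / both seasons, encoded
as two indicators with *both* as reference) and the mean over samples
of days since the most recent prior race start. Horses with cytology
but no race record keep NaN covariates and drop out of the regression.
The case/control split used by the structure test is HF frequency > 0
(affected) vs = 0, configurable.

## Marker QC

Filters run in a configurable order (default: missingness > 10 %,
Hardy–Weinberg exact p < 0.001, MAF < 2 %, X-linked SNPs heterozygous
in males) and each removed SNP is attributed to the first filter that
rejects it, so the per-filter counts always sum to input − retained,
and the pipeline is idempotent. The 98 % call-rate criterion used by
array-intensity pipelines is representable as the missingness filter
at 0.02 and exposed as a preset; intensity-cluster QC itself needs raw
intensities and is out of scope. A per-individual missingness filter
is available but off by default.

The Hardy–Weinberg test is the exact conditional test: given the
observed allele counts, the heterozygote count under HWE has
probability ∝ 2^n₁ · n! / (n₀! n₁! n₂!), and the two-sided p sums all
tables no more probable than the observed one (probability-ordering
definition), computed by full enumeration in log space. Exactness
matters at n = 72, where the χ² approximation is unreliable in the
tails. Only an explicit `X` chromosome label triggers the male-
heterozygosity filter — the equine genome has 31 autosomes, so numeric
labels are never treated as sex chromosomes.

## Population structure

Pairwise IBS is the mean over shared non-missing SNPs of
(2 − |gᵢ − gⱼ|)/2. Classical (Torgerson) MDS double-centres the
squared distance D = 1 − IBS and returns eigenvector coordinates
scaled by √eigenvalue; axis signs are fixed (largest-magnitude loading
positive) so plots are reproducible. The permutation test statistic is
the proportion of variance in off-diagonal pairwise IBS explained by
pair class (within-case / within-control / between) — a transparent
between/total sum-of-squares definition, calibrated by size-preserving
label permutation with p = (1 + #{perm ≥ obs}) / (1 + n_perm). The
original software's exact formula for "proportion of variance in IBS
between groups" is not published; this definition is stated and tested
on its own terms (null calibration and positive controls).

## GWAS

Per SNP, ordinary least squares of the phenotype on [intercept,
additive minor-allele dosage, covariates], complete-case per SNP, with
a two-sided t-test on the dosage coefficient (df = n − covariates −
2). For SNPs with no missing calls the covariates are projected out
once and the per-SNP slope, SE and p follow from the
Frisch–Waugh–Lovell identity, which vectorises the scan across 10⁴–10⁵
SNPs; SNPs with missing calls fall back to a per-SNP fit. Agreement
with `statsmodels.OLS` is asserted in tests. Constant genotypes and
exactly collinear covariates are flagged rather than fitted. Main
effects only by default; the analysis class is additive linear
regression, and covariate-interaction fits are out of the default
path.

Family-wise significance uses the Bonferroni threshold α/m. The
genomic inflation factor λ is the median of the per-SNP χ²₁ statistics
over 0.4549 (the χ²₁ median). Top-k SNPs (ties broken by chromosome,
position) demarcate genome regions: per chromosome, top SNPs closer
than `merge_gap` (default 5 Mb, consistent with reported region spans
of 1–16 Mb; the exact demarcation rule behind those spans is not
published) merge into one region.

## Variance components

The GRM is Z·Zᵀ/m over dosages standardized by observed frequencies
(2p(1−p)); missing calls become 0 after centring; monomorphic SNPs are
excluded. REML for y = Xb + g + e, g ~ (0, G σ²_g), is fitted by
EM-REML in the eigenbasis of G, where the covariance is diagonal and
each iteration is O(n·k). The EM update keeps variances non-negative
and the restricted likelihood non-decreasing (asserted per step in
tests); because EM crawls near a variance boundary, a deterministic
Nelder–Mead polish on the log-variance scale is applied afterwards and
accepted only if it improves the restricted likelihood. Standard
errors come from the expected information matrix; significance of σ²_g
uses the likelihood-ratio test against the ½χ²₀ + ½χ²₁ boundary
mixture. Per-chromosome scans fit one chromosome's GRM at a time
against its own residual — at n ≈ 72 a joint 31-component model is
ill-posed — and chromosomes with < 10 SNPs are skipped. A GRM
numerically indistinguishable from the identity leaves σ²_g and σ²_e
unidentifiable and is flagged.

## Gene-set association

SNPs map to a gene when their position lies in [start − w, end + w]
(inclusive, strand-ignored) for w ∈ {0, 5,000, 20,000} bp. A SNP may
belong to several genes; within one set it is counted once. The set
statistic is T = Σ χ²₁-quantile(1 − pⱼ) over the set's SNPs —
two-sided regression p-values are converted through the χ²₁ quantile,
which at the study's residual df is indistinguishable from t² and
matches summary-statistic-based set tests. Under the null T is
distributed as Σ λᵢ χ²₁ with λᵢ the eigenvalues of the SNPs' genotype
Pearson-correlation (LD) matrix, estimated from the analysis sample
itself (no external reference panel exists for this population).
Negative eigenvalue estimates are clipped at 0 and values below 10⁻⁸
dropped. The upper-tail probability is computed by Imhof's
characteristic-function inversion via adaptive quadrature; if the
integral fails to converge the Satterthwaite moment-matching
c·χ²_ν approximation is used and the result is labelled. The
single-SNP set reduces exactly to the SNP's own p; Σλᵢ = trace(R) = k
gives the null mean of T.

## Haplotypes and epistasis

Haplotype blocks are the retained SNPs spanning a gene (first 12 by
position if more), matching per-gene reporting rather than sliding
windows. EM phasing enumerates, per individual, all haplotype pairs
compatible with the unphased dosages, weights them by products of
current frequencies (Hardy–Weinberg pairing) and re-estimates
frequencies from posterior-expected counts; initialization is the
deterministic linkage-equilibrium product of allele frequencies, the
log-likelihood is non-decreasing per iteration, and individuals with
missing calls in the block are excluded. Association is per-haplotype
one-vs-rest OLS of the phenotype on the posterior-expected dosage
(plus covariates), reported as β and p per haplotype with frequency ≥
1 % — per-haplotype reporting, not an omnibus test. Epistasis between
two SNPs is the two-sided t-test of the g₁·g₂ coefficient in
y ~ 1 + g₁ + g₂ + g₁·g₂ (+ covariates); edge lists report nominal p
(with a Bonferroni-adjusted column alongside) and are symmetric in
pair order.

## Synthetic cohort

The generator emulates the study conditions: 72 horses (32 M / 40 F),
three half-sib families of 8 on an unrelated background, 31
chromosomes at one SNP per 43.2 kb, and gene sets of sizes
43/50/26/33/29/258 whose multi-tag memberships reproduce the published
intersection structure (triple intersection of 5; pairwise
intersections 9, 14 and 11 including the triple). Family sizes are not
published; 8 per sire family (24 of 72 in families) gives clearly
visible MDS clusters without dominating the cohort.

Haplotypes come from a latent Gaussian AR(1) within LD blocks (default
20 SNPs, ρ = 0.8) thresholded at MAF-matched quantiles (MAF uniform on
[0.05, 0.5]); each half-sib receives one unrecombined sire haplotype
plus one population haplotype. This reproduces LD decay within blocks
and the family-cluster phenomenology, but not recombination maps,
coalescent allele-frequency spectra or long-range LD — conclusions
about those features do not transfer.

The causal model plants 2 causal SNPs in each of the cytoskeleton and
blood-flow sets with equal effects, scaled so the genetic score
explains h² = 0.7 of the phenotypic variance (~17.5 % per locus).
This concentrated architecture is chosen to match the emulated study's
reported outcome: a 72-individual scan can only yield genome-wide
significant SNPs (p < 1.15×10⁻⁶) if individual loci explain on the
order of 30 % of variance, and the simulated scans accordingly produce
a mix of genome-wide significant and suggestive top SNPs, as reported.
A diffuse many-small-effects architecture at this n would leave every
set test underpowered and reproduce neither the published Manhattan
profile nor the set-level significance pattern.

Weekly cytology follows the known haemosiderophage kinetics: a
Bernoulli bleeding event per week with probability
logistic(−2.2 + 0.9·z) of the standardized genetic risk z (≈ 10 %
weekly at mean risk), then HF scores 3/2/1 in the one/two/three weeks
after the event, decaying to background 0/1. Only the HF category is
risk-linked; the other categories are i.i.d. multinomial pass-through.
Race records give each horse one start every ~3 weeks in its sampled
season(s).

All generators are pure functions of (config, seed).

## Numerical choices and problem sizes

- HWE enumeration is exact in log space; ties in the probability
  ordering include tables equal to the observed probability within a
  10⁻¹² relative slack.
- Imhof quadrature: `scipy.integrate.quad` on (0, ∞) with limit 500;
  results with estimated error > 10⁻⁴ fall back to Satterthwaite.
- EM-REML: start at half the phenotypic variance per component,
  variance floor 10⁻⁸·var(y), convergence when the parameter change
  drops below tol·var(y); the simplex polish is deterministic.
- Calibration and recovery suites use the replicate counts stated with
  each check (e.g. 400 null replicates at n = 300 for type-I error,
  50 replicates at n = 500 / m = 2,000 for REML recovery, 25
  replicates at n_snps = 4,000 for the set-ranking property); these
  are the package's reference problem sizes for desk-scale validation.
- MDS axis signs and all tie-breaks (top-SNP ranking, set ordering)
  are deterministic, so repeated runs are byte-identical.

## Known limitations

- The set test's null uses sample LD from n = 72-scale cohorts; its
  eigenvalues are noisy, which is the same limitation the original
  summary-statistic approach has with small reference panels.
- Single-component REML per chromosome ignores the genetic variance on
  other chromosomes (it is absorbed into the residual); estimates are
  therefore conservative for a polygenic trait.
- EM phasing caps blocks at 12 SNPs and excludes individuals with
  missing calls in the block rather than marginalizing over them.
- The fracture model is a scaling law: it orders risk by γ/E and flow
  state but does not predict absolute bleeding thresholds without α
  and a defect-size distribution, neither of which is identifiable
  from the data the pipeline consumes.
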
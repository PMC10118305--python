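# Methods

`sweepscape` re-implements, as a tested library, the analysis chain used in
recent population-genomic studies of insecticide resistance in *Aedes
aegypti*: cohort-aware variant filtering, kinship pruning, windowed
diversity statistics, a composite-likelihood-ratio (CLR) sweep scan against
an empirical background site frequency spectrum (SFS), unphased
multilocus-genotype (MLG) sweep statistics, a linkage-aware rotation
permutation enrichment test, and a focal-locus haplotype-cluster report.
Every stage runs on synthetic data the package generates itself, so the
whole chain is testable without sequence downloads.

## Data model

Genotypes are unphased alternate-allele dosages (0/1/2) with a distinct
MISSING sentinel; dosage 0 and MISSING are never conflated.  Site
coordinates are 1-based (VCF convention); interval masks are 0-based
half-open (BED convention) with tested conversion helpers.  Multi-allelic
records are flagged and dropped, never decomposed.

## Filtering

Six per-site statistics (QD, FS, SOR, MQ, MQRankSum, ReadPosRankSum) feed a
5-of-6 voting rule: QD ≥ 2, FS < 40, SOR < 4, MQ ≥ 40, MQRS ∈ [−5, 5],
RPRS ∈ [−3, 3].  An absent statistic counts as passing its filter — the
rank-sum annotations are undefined at sites without heterozygous calls, and
treating absence as failure would discard valid sites.  Genotypes with
GQ < 20 are masked to MISSING (the GQ field itself is untouched).  The
call-rate rule keeps a site when its within-cohort call rate is ≥ 75% in at
least (cohorts − 1) cohorts; the phrase admits a second reading (global 75%
AND presence in that many cohorts), shipped behind `per_cohort=False`.
Mappability is computed by brute force for synthetic-scale references: a
position is masked when any k-mer covering it (k = 150, ≤ 2 mismatches by
default) matches elsewhere in the sequence or, by default, its reverse
complement; a palindromic k-mer matching its own location stays unique.

## Kinship

The KING-robust between-family estimator
φ̂ = (N_het,het − 2·N_opp,hom)/(2m) + 1/2 − (N_het,i + N_het,j)/(4m),
m = min(N_het,i, N_het,j), over jointly called sites.  m = 0 returns
not-estimable (NaN), never a silent 0.  Pruning is greedy in descending φ̂
(ties by pair id) with continent-specific cutoffs (Americas 0.20, Africa
0.05 by default; a pair spanning continents uses the stricter cutoff);
within a pair the lower-coverage member is removed, coverage ties removing
the lexicographically later id.  The cutoffs are plain parameters, so a
user can lower the American cutoff (e.g. to 0.1896) to catch borderline
pairs rather than relying on a hidden heuristic.

## Diversity statistics

Per-site unbiased heterozygosity 2x(n−x)/(n(n−1)) is summed per window and
divided by accessible bases (window length minus masked bases), because the
SNP set has repetitive/non-unique regions removed.  Tajima's D uses fixed
n = 2 × samples with a per-site call-rate threshold (default 0.75) so the
normalising constants are window-invariant; a per-site-n variant is behind
a flag.  Windows below a minimum variant count (default 3) are NaN, not 0.
FST is the Weir–Cockerham (1984) diploid estimator from observed
heterozygosity, combined as a ratio of sums; genome scans use
variant-count windows, region reports bp windows.  LD is the phase-free
dosage-correlation r² (pairwise-complete over samples), NaN for
single-variant windows.  PCA mean-imputes missing dosages per site, centres,
and by default applies Patterson scaling (√(p(1−p))); the genome-wide scan
drops SNPs with MAF ≤ 5%, the focal-region PCA keeps all SNPs.

## CLR sweep scan

The background model is the empirical SFS of all SNPs segregating in the
focal cohort, projected down (hypergeometric expectation) to a common
background size; sites with missing data use per-site n with cached
projections.  The sweep model is the star-like hitchhiking approximation:
each lineage escapes the sweep independently with probability
p_e = 1 − exp(−Λ·d), d the genetic distance from the SNP to the test site
(cM with a map, bp × constant rate otherwise; larger Λ = more escape =
weaker signal).  Given e escaped lineages, e+1 lineages are drawn from the
background (the +1 being the common ancestor of the swept lineages, chosen
uniformly), which yields the full distorted spectrum; the likelihood
conditions on polymorphism because the input is segregating SNPs.  Folded
spectra are stored symmetrised so projection and distortion stay exact, and
model vectors are folded before comparison.

Numerics: p_e is discretised to ~96 bins, dense near 1 where the model
approaches the background; the smallest bin is 10⁻⁹ rather than 0 because
p_e = 0 predicts no polymorphism (such observations get ~−∞ log-likelihood
rather than an error during scans).  The Λ grid is log-spaced (32 points by
default) between the scales ln2/grid-step and ln2/chromosome-span, plus a
neutral sentinel (p_e ≡ 1) that makes CLR = 2(max ℓ − ℓ₀) ≥ 0 by
construction; Λ̂ ties break toward the sentinel, then the smallest Λ.
Chromosomes are scanned in 50 Mb chunks overlapping by 5 Mb, resolved by
nearest chunk centre.

## G statistics

A specimen's MLG over a window of fixed variant count is its dosage string;
MISSING is a distinct symbol (dropping sites would desynchronise windows
across specimens, imputing would fabricate genotypes; `drop_missing_sites`
provides the alternative).  G1 = Σg_i², G12 and G123 pool the top two or
three classes, G2/G1 = (G1 − g₁²)/G1.  Only exact string identity is used —
no similarity clustering — matching the statistic's definition.

## Rotation enrichment test

Sweep scores are spatially autocorrelated, so i.i.d. permutation overstates
the evidence when one sweep covers a physical cluster of genes from the
same set (the histone-cluster confound).  The test joins the chromosomes
into a circle and rotates all scores by a uniform random offset **in units
of grid sites** (scores live on the test-site grid), preserving the local
score landscape while randomising its alignment with gene positions.  The
statistic per term is the number of member genes (± 1 kb flank) overlapped
by ≥ 1 top-quantile site; ties at the outlier threshold are included so the
outlier set is rotation-invariant.  p = (1 + #{rotated ≥ observed})/(1 + N)
(never zero) and q-values are Benjamini–Hochberg.  Because the statistic is
a count, the add-one estimator is conservative when its support is narrow;
the calibration test therefore uses a large gene set so the null statistic
has wide support.  A naive shuffle comparator is included solely to
demonstrate the linkage control.

## Focal-locus report

Region PCA (all SNPs, no MAF filter) with per-SNP loadings; centroid
(k-means, 50 restarts, fixed seed) cluster assignment on configurable PCs —
under a partial sweep the three diploid carrier classes of the swept
haplotype separate along the dominant component, so `pcs=(1,)` clusters on
PC1 alone; manual PC-threshold assignment reproduces figure-driven
groupings.  Per-cluster sliding-window π, top-vs-bottom windowed FST,
genotype-class tables at named focal sites (GQ < 20 masked first, uncalled
loci reported as NO-CALL rows, never zeros), and a focal-site r² matrix
that shares the dosage-correlation kernel with the windowed LD statistic
(unit diagonal; NaN rows for monomorphic or absent sites; named loci can be
exempted from the GQ mask, for sites regenotyped by other means).

## Synthetic data

Two genotype generators with distinct, documented scopes:

**Neutral panel generator** (site-independent; valid for SFS-based
statistics only — it produces no LD).  Site count S ~ Poisson(θ·L·a₁),
a₁ = Σ_{i=1}^{2n−1} 1/i.  With no drift, derived counts are drawn with
P(i) ∝ 1/i and carriers assigned uniformly — the exact neutral equilibrium
sample SFS, giving E[Σπ] = θL and E[S] = Watterson exactly (a
truncated-continuous 1/p frequency density with binomial sampling was
evaluated and rejected: truncation at 1/(4n) removes ~40% of singleton
mass, retention (1−ε)^{2n} ≈ e^{−1/2} independent of n, biasing mean
Tajima's D to ≈ +0.28).  With drift, cohort frequencies follow
Balding–Nichols Beta(p(1−F)/F, (1−p)(1−F)/F) around an ancestral p with
density ∝ 1/p, chosen because it gives a closed-form FST ≈ F for recovery
tests.

**Forward Wright–Fisher simulator** (haplotype structure; used for CLR
localisation, G statistics and the locus report).  The population (≤ 1000
diploids) is initialised at neutral mutation–drift equilibrium in linkage
equilibrium (exact population SFS, carriers uniform); the forward phase
applies multiplicative selection (1, 1+s, (1+s)²), Poisson(rL) crossovers
per meiosis, and recurrent mutation (new singletons each generation, lost
columns pruned periodically).  Linkage equilibrium at initialisation is a
deliberate simplification: the selected phase itself builds the
hitchhiking LD that the haplotype statistics measure, while standing
short-range neutral LD is under-represented — flank windows are therefore
slightly "cleaner" than real data, which passing tests should be read
against.  Sweeps are conditioned on establishment by rejection (restart on
loss, count logged); s = 0 runs drift for a configurable number of
generations as a neutral control.  Sampled haplotypes are returned
alongside the unphased genotype matrix so tests retain phased truth.

Quality synthesis draws "good" sites inside all six passing ranges and
"bad" sites failing ≥ 2 randomly chosen filters, so the 5-of-6 rule must
reject them and truth recovery is exact by construction; absent fields are
only injected into passing statistics, preserving the labels.  The gene
annotation generator can plant a physically clustered gene set (the
linkage confound); the mask generator hits a target coverage fraction
within ±2%.

### Study conditions used by the tests and `scripts/acceptance.py`

Chosen once as desk-scale analogues of mosquito data and fixed:

| scenario | parameters |
|---|---|
| neutral calibration | θ = 0.01/bp, 30–50 diploids, 50–500 kb |
| drift / FST | Balding–Nichols F = 0.1, 2 × 50 diploids |
| CLR recovery | N = 500, L = 200 kb, s = 0.1, θ = ρ = 0.005/bp, 25 diploids, complete sweep |
| G statistics | N = 300, L = 150 kb, s = 0.3, θ = ρ = 0.005/bp, 25-variant windows |
| focal locus | N = 300, L = 100 kb, s = 0.3, partial sweep to 0.55, ρ = 0.1·θ |

ρ = θ is a realistic genome-wide ratio for insects; the focal-locus
scenario uses ρ = 0.1·θ because the analysis emulates a long
low-recombination gene region where a partial sweep leaves two extended
haplotype classes.  The G-statistic scenario uses strong selection
(s = 0.3, the insecticide-resistance regime) with windows well inside the
sweep footprint, since MLG identity statistics need the swept background to
dominate the window.  CLR recovery tests use polarized (unfolded) spectra —
the simulation knows ancestral states — while the pipeline default for real
data is folded, since no ancestral polarisation is assumed.

## Known limitations

* The neutral panel generator cannot test haplotype statistics (no LD by
  construction); the WF simulator must be used there.
* The WF simulator's desk scale (N ≤ 1000) means drift is strong; rates are
  scaled up so θ and ρ match realistic per-window values, as is standard in
  rescaled forward simulation.
* The brute-force mappability computation is quadratic and intended for
  synthetic references (≲ 100 kb).
* The rotation test's add-one p-values are conservative for narrow-support
  statistics; this is a property of the estimator, not an error.
* No BCF, phasing, structural variants, invariant-site CLR likelihoods,
  B-value correction, GO DAG propagation, or inversion detection.
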
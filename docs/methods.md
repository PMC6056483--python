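# Methods

`dipkit` analyses panels of diallelic insertion/deletion (DIP) markers of
the kind used in forensic genetics (e.g. the 30 Investigator DIPplex "HLD"
loci). A genotype is fully described by the insertion-allele dosage
g ∈ {0, 1, 2}; every statistic below is written in terms of the insertion
frequency p (q = 1 − p) and dosage counts. Missing genotypes carry an
explicit sentinel and are excluded locus-wise from every estimate.

## Forensic parameters

For each locus with observed heterozygote fraction h = Ho:

- He = 2pq, deliberately **without** the 2n/(2n−1) small-sample correction:
  the convention of the PowerStats-style spreadsheets used for these
  panels, under which He reaches exactly 0.5000 at p = 0.5.
- PIC = 1 − (p² + q²) − 2p²q² (Botstein, diallelic case).
- MP = Σ f_g² over the three **observed** genotype relative frequencies;
  PD = 1 − MP. Using observed rather than HWE-expected frequencies matters:
  HWE caps PD at 0.625 for a diallelic locus, while observed counts can
  exceed it.
- PE = h²(1 − 2hH²), H = 1 − h (the heterozygosity-based
  exclusion-probability formula for a single parent–child comparison).
- Combined statistics CPD/CPE = 1 − Π(1 − v_l), accumulated as
  −expm1(Σ log1p(−v_l)) so a 30-locus CPD keeps ~13 significant digits.

## Equilibrium tests

HWE uses the exact conditional test: given the observed allele counts,
all compatible heterozygote counts are enumerated with
P(n₁ | n, n_A) ∝ multinomial × 2^{n₁}, and the p-value is the probability
mass of configurations no more probable than the observed one (no mid-p).
Bonferroni thresholds are α/m. Pairwise LD is assessed by EM over the
double-heterozygote phase ambiguity (initialized at linkage-equilibrium
product frequencies; convergence at a log-likelihood gain < 1e−10 or 1000
iterations), followed by a 1-df likelihood-ratio test of D = 0. D′ uses
the sign-appropriate Dmax; monomorphic pairs are flagged with D = r² = 0,
p = 1. No multiplicity correction is applied to the locus-pair p-values by
default; `bonferroni` can be applied by the caller.

## Differentiation

Pairwise Fst is the Weir–Cockerham (1984) θ from the a/b/c variance
components, reported as the ratio of sums over loci; loci monomorphic
across the pair, or with fewer than two typed individuals on either side,
are skipped. Negative θ is reported as-is in tables and clamped to zero
only when a matrix feeds geometry (MDS). Locus-by-locus significance uses
a label-permutation test holding sample sizes fixed,
p = (1 + #{θ* ≥ θ}) / (1 + n_perm); permutations are evaluated in a single
batched pass. DA is Nei–Tajima–Tateno,
1 − (1/L) Σ √(p_A p_B) + √(q_A q_B), computed from allele frequencies only.

## Ordination and trees

PCA operates on the individuals × loci dosage matrix, mean-imputed per
locus and mean-centered but not variance-scaled, via SVD; each component
is sign-fixed so its loading vector has nonnegative sum, making output
deterministic. Explained percentages are eigenvalue shares of the total.
MDS is classical Torgerson double-centering with top-k eigenpairs;
negative eigenvalue mass is recorded as a diagnostic. Neighbor joining
follows Saitou–Nei with the Studier–Keppler criterion; equal-Q ties break
toward the lexicographically smallest pair of subtree labels, and a
negative limb is clamped to zero with the deficit moved to its sibling so
the joined pair's distance is preserved — trees are bit-reproducible and
exact on additive matrices.

## Admixture model

Dosages are modeled as g_il ~ Binomial(2, π_il) with π = QF; Q (N × K
ancestry fractions) and F (K × L cluster frequencies) are fit by EM block
updates (frappe/ADMIXTURE likelihood), F clipped to [1e−6, 1 − 1e−6],
Q from Dirichlet(1) starts and F from perturbed pooled frequencies. The
log-likelihood is asserted nondecreasing in-run. Defaults: tol 1e−6,
max_iter 2000; the multistart driver keeps the best of (default) 10 seeds.

**Choosing K.** In-sample log-likelihood gains never plateau here: each
added cluster contributes ≈ N + L free parameters, so a structureless step
still gains ≈ (N+L)/2 log-units (Wilks). Cross-validated likelihood is
also uninformative at 30–60 loci because per-individual ancestry estimates
carry more variance than the structure signal. `select_k` therefore
corrects each gain by the (N+L)/2 allowance and requires the corrected
gain of the best-of-seeds profile to exceed
max(2 × pooled across-seed SD, 0.1 × allowance, 2 × top-of-range corrected
gain). The last term uses the top step of the scanned range as an in-data
overfitting reference, because the true overfitting gain varies between
~0.9× and ~1.7× of the Wilks allowance with sample size and K; the scanned
range must therefore extend past the plausible K (e.g. 1..6 when 4 is
expected). With one seed the SD term vanishes and the other floors apply.

At 30 diallelic loci the per-individual ancestry SE is ~0.2 (Fisher
information ~25–35 at a simplex vertex), so individual Q estimates are
intrinsically diffuse: a pure individual's fitted max-Q averages
~0.82–0.92, and population-mean Q is shrunk by ~0.4 × SE through one-sided
truncation at the vertex. Population-level contrasts (admixed groups
visibly less assigned than unadmixed ones) are reliable; per-individual
fractions are not precision estimates at this marker count.

## Ancestry-informative markers

Population frequencies are averaged within each continental cluster,
unweighted (each population counts once). δ at a locus is the largest
absolute difference between cluster means (= max − min). Selection keeps
loci with δ strictly greater than the threshold (default 0.29, the cutoff
used for this panel).

## Synthetic panels

The generator produces the structure the analyses assume: HWE within
populations, Balding–Nichols Beta(p(1−F)/F, q(1−F)/F) divergence between
them (mean p, variance F·p·q — F is exactly the Fst the Weir–Cockerham
estimator targets), hierarchical ancestral → branch → cluster → population
divergence, and admixed individuals drawn per gene copy (cluster by the
mixing weights, then allele by that cluster's frequency — the same
generative model the EM fits). All randomness flows from one seed.

The `kyrgyz_like` preset emulates the shape of a 25-population reference
panel at 30 DIPplex-named loci: 11 East Asian populations plus a focal
Central Asian sample of 295 individuals, 5 European populations (including
an admixture-derived American group that tracks its European sources at
these markers), 6 Mexican populations, and 3 admixed Central Asian
populations; reference populations have 100 diploids each (typical of
published DIPplex studies). European and Mexican clusters diverge from a
shared "Western" branch (branch Fst 0.10, cluster Fst 0.06/0.08), so at
K = 2 they are indistinguishable while East Asians split off — the
behaviour real panels of this kind show; East Asian and Central Asian
cluster Fst is 0.15, within-cluster population drift 0.01. Central Asian
populations mix 40–50% cluster-specific ancestry with East Asian and
European contributions. Ancestral frequencies are drawn uniform(0.25,
0.75); at these divergences roughly half the loci exceed δ = 0.29,
matching the AIM yield the preset is meant to exhibit (the realized count
varies by seed, ~9–20 of 30).

What the preset does **not** emulate: linkage between loci (simulated
independent, consistent with the panel's null LD finding), genotyping
error and missingness patterns, mutation, and real population history
(admixture here is a two-generation-style gene-copy mixture, not a dated
demographic event). Passing tests therefore validate the estimators'
statistical behaviour, not any claim about the real populations.

## Problem sizes and numerical choices

Statistical tests in the suite run at the sizes the analyses target
(n = 295 focal individuals, 25 populations × 30 loci; 10 000 replicates
for exact-test calibration; 20 seeds for Fst recovery; 10 independent
selection runs for K choice). Tolerances follow from binomial/Beta
standard errors at those sizes and are stated next to each test. EM
convergence for K-selection scans uses tol 1e−4 / 600 iterations — gains
between K values are orders of magnitude larger than the residual
optimization error — while single fits default to tol 1e−6 / 2000.
Distance serialization is fixed at 6 decimals; round-trips are exact at
that precision.

## Known limitations

- Per-individual ancestry at 30 DIP loci is noisy by information content;
  see the admixture section.
- The exact HWE test is conservative (discrete support), so its realized
  type-I error is below nominal.
- The Genepop dialect stores population labels in the individual-id field;
  sample ids are regenerated on read (`<pop>_<k>`), so only the genotype
  CSV round-trips sample ids exactly.
- `select_k` requires the scanned K range to extend beyond the plausible
  truth; the top-of-range step is consumed as an overfitting reference and
  cannot itself be selected.
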
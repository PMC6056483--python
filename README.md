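# dipkit

Population-genetic and forensic analysis of diallelic insertion/deletion
(DIP / InDel) marker panels — the marker class typed by kits such as the
30-locus Investigator DIPplex. A DIP genotype is just the insertion-allele
dosage g ∈ {0, 1, 2}, and a complete panel study runs from per-locus
forensic efficiency through population structure:

- **Forensic parameters** per locus — allele frequency, MAF, Ho,
  He = 2pq, PIC = 1 − (p²+q²) − 2p²q², matching probability / power of
  discrimination from observed genotype frequencies, power of exclusion
  PE = h²(1 − 2hH²) — and the combined CPD/CPE = 1 − Π(1 − v_l).
- **Equilibrium tests** — exact conditional Hardy–Weinberg test with
  Bonferroni thresholds; pairwise LD via EM haplotype-frequency
  estimation (D, D′, r²) and a 1-df likelihood-ratio test.
- **Differentiation** — pairwise Weir–Cockerham θ (ratio of sums over
  loci) with batched permutation p-values, and Nei's D_A distance.
- **Ordination & phylogeny** — individual-level dosage PCA, classical
  (Torgerson) MDS, and a deterministic neighbor-joining tree with Newick
  export.
- **Admixture** — maximum-likelihood EM for the K-cluster admixture model
  (g ~ Binomial(2, QF)), label alignment across runs, and an
  overfitting-corrected likelihood-plateau rule for choosing K.
- **Ancestry-informative markers** — δ = max − min of cluster-averaged
  insertion frequencies, with strict-threshold selection (δ > 0.29 by
  default).
- **Synthetic panels** — Hardy–Weinberg sampling under hierarchical
  Balding–Nichols divergence with admixed populations, including a
  25-population, 4-cluster preset with a 295-individual focal sample,
  so every stage is testable end to end with known ground truth.

Intended users: forensic-genetics and population-genetics practitioners
validating a DIP panel, and method developers who need a small, fully
seeded reference implementation of this analysis stack.

## Worked example

```python
from dipkit import synthetic_data, forensic_stats, equilibrium

gm, true_q, cluster_freqs, cfg = synthetic_data.generate_kyrgyz_like(seed=0)
focal = gm.subset(populations=["Kyrgyz_study"])   # 295 individuals x 30 loci

summary = forensic_stats.summarize(focal)
print(summary.per_locus.head(5).round(4).to_string(index=False))
print("CPD", f"{summary.cpd:.13f}", " CPE", round(summary.cpe, 4))

hwe = equilibrium.hwe_all_loci(focal)
thr = equilibrium.bonferroni(0.05, focal.n_loci)
print("Bonferroni threshold", round(thr, 4),
      " significant loci:", int((hwe.p_value < thr).sum()))
```

prints

```
 locus      p    maf     ho     he    pic     mp     pd     pe
 HLD77 0.6847 0.3153 0.4068 0.4317 0.3385 0.4097 0.5903 0.1181
 HLD45 0.4898 0.4898 0.4780 0.4998 0.3749 0.3649 0.6351 0.1689
HLD131 0.1797 0.1797 0.2915 0.2948 0.2513 0.5412 0.4588 0.0601
 HLD70 0.2864 0.2864 0.4102 0.4088 0.3252 0.4334 0.5666 0.1202
  HLD6 0.4627 0.4627 0.4915 0.4972 0.3736 0.3737 0.6263 0.1802
CPD 0.9999999999818  CPE 0.9842
Bonferroni threshold 0.0017  significant loci: 0
```

Each row is one locus: `p` is the insertion-allele frequency, `pd` the
probability that two random individuals differ at that locus, `pe` its
single-locus exclusion power. The combined CPD near 1 − 10⁻¹¹ says the
30-locus panel individualizes essentially perfectly, while a CPE of ~0.98
is modest — the usual conclusion that DIP panels complement rather than
replace STRs for paternity work. No locus departs from Hardy–Weinberg
after Bonferroni correction, as expected for a generator that samples HWE
genotypes.

The same workflow runs from the shell:

```bash
dipkit simulate --seed 0 --out genotypes.csv
dipkit forensic genotypes.csv --population Kyrgyz_study --out forensic.csv
dipkit fst genotypes.csv --out fst.csv
dipkit mds fst.csv --out mds.csv
dipkit run --config run.yaml      # full pipeline with manifest
```

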
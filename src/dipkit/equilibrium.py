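"""Hardy-Weinberg exact testing and two-locus linkage disequilibrium.

The HWE test is the exact conditional test for a diallelic locus: holding
the observed allele counts fixed, every compatible heterozygote count is
enumerated and the p-value is the total probability of configurations no
more probable than the observed one (no mid-p adjustment).

LD between two diallelic loci is assessed by estimating the four haplotype
frequencies with an EM algorithm over the double-heterozygote phase
ambiguity, then testing gametic disequilibrium D = 0 with a 1-df
likelihood-ratio test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

from .core import MISSING, GenotypeMatrix


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str  # {"hwe_exact", "ld_lrt"}
    df: int | None = None
    monomorphic: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0 + 1e-12:
            raise ValueError("p_value out of [0,1]")
        self.p_value = min(self.p_value, 1.0)


def bonferroni(alpha: float, m: int) -> float:
    """Per-test significance threshold alpha/m for m simultaneous tests."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0,1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def _het_log_probs(n: int, n_minor: int) -> tuple[np.ndarray, np.ndarray]:
    """Log-probabilities of every heterozygote count compatible with
    ``n_minor`` minor alleles among ``n`` diploids (conditional on allele
    counts).  Returns (het_counts, log_probs)."""
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hets = hets[(n_minor - hets) // 2 + hets <= n]  # minor homozygotes + hets <= n
    hom_minor = (n_minor - hets) // 2
    hom_major = n - hets - hom_minor
    logp = (
        gammaln(n + 1)
        - gammaln(hom_minor + 1)
        - gammaln(hets + 1)
        - gammaln(hom_major + 1)
        + hets * np.log(2.0)
        + gammaln(n_minor + 1)
        + gammaln(2 * n - n_minor + 1)
        - gammaln(2 * n + 1)
    )
    return hets, logp


def hwe_exact_test(n_hom_ins: int, n_het: int, n_hom_del: int) -> TestResult:
    """Exact conditional HWE test from the three genotype counts."""
    counts = (n_hom_ins, n_het, n_hom_del)
    if any(c < 0 or c != int(c) for c in counts):
        raise ValueError("genotype counts must be nonnegative integers")
    n = sum(counts)
    if n < 1:
        raise ValueError("need at least one genotype")
    n_ins = 2 * n_hom_ins + n_het
    n_minor = min(n_ins, 2 * n - n_ins)
    if n_minor == 0:
        return TestResult(0.0, 1.0, "hwe_exact", monomorphic=True)
    hets, logp = _het_log_probs(n, n_minor)
    obs = logp[hets == n_het][0]
    p = float(np.exp(logp[logp <= obs + 1e-9]).sum())
    return TestResult(float(n_het), min(p, 1.0), "hwe_exact")


def hwe_all_loci(gm: GenotypeMatrix) -> pd.DataFrame:
    """Exact HWE p-value per locus (missing genotypes excluded)."""
    rows = []
    for j, locus in enumerate(gm.loci):
        d = gm.dosage[:, j]
        d = d[d != MISSING]
        res = hwe_exact_test(int((d == 2).sum()), int((d == 1).sum()), int((d == 0).sum()))
        rows.append({"locus": locus.locus_id, "n_typed": d.size,
                     "p_value": res.p_value, "monomorphic": res.monomorphic})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Two-locus LD
# ---------------------------------------------------------------------------


@dataclass
class HaplotypePair:
    """EM-estimated two-locus haplotype frequencies and LD summaries.

    ``hap_freqs`` orders haplotypes (II, ID, DI, DD), first letter = locus A
    allele.  ``loglik`` is the multinomial log-likelihood of the genotype
    table at the EM optimum; ``n`` the number of complete individuals.
    """

    hap_freqs: np.ndarray
    D: float
    D_prime: float
    r2: float
    loglik: float
    n: int
    monomorphic: bool = False
    loglik_trace: list[float] = field(default_factory=list)

    @property
    def pA(self) -> float:
        return float(self.hap_freqs[0] + self.hap_freqs[1])

    @property
    def pB(self) -> float:
        return float(self.hap_freqs[0] + self.hap_freqs[2])


def _genotype_probs(x: np.ndarray) -> np.ndarray:
    """3x3 genotype-class probabilities (dosageA, dosageB) from haplotype
    frequencies (II, ID, DI, DD) under random union of gametes."""
    x11, x12, x21, x22 = x
    return np.array([
        [x22 * x22, 2 * x21 * x22, x21 * x21],
        [2 * x12 * x22, 2 * (x11 * x22 + x12 * x21), 2 * x11 * x21],
        [x12 * x12, 2 * x11 * x12, x11 * x11],
    ])


def _table_loglik(n_tab: np.ndarray, x: np.ndarray) -> float:
    probs = _genotype_probs(x)
    mask = n_tab > 0
    return float(np.sum(n_tab[mask] * np.log(np.maximum(probs[mask], 1e-300))))


def em_haplotype_freqs(
    dosages_a: np.ndarray,
    dosages_b: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> HaplotypePair:
    """Maximum-likelihood haplotype frequencies for two diallelic loci.

    Individuals missing at either locus are dropped.  Only the double
    heterozygote is phase-ambiguous; EM splits it between the cis (II/DD)
    and trans (ID/DI) resolutions.  Initialization at linkage-equilibrium
    product frequencies (interior, deterministic); convergence when the
    log-likelihood gain drops below ``tol``.
    """
    a = np.asarray(dosages_a)
    b = np.asarray(dosages_b)
    keep = (a != MISSING) & (b != MISSING)
    a, b = a[keep], b[keep]
    n = a.size
    if n < 2:
        raise ValueError("need >= 2 individuals typed at both loci")
    n_tab = np.zeros((3, 3))
    for ga in range(3):
        for gb in range(3):
            n_tab[ga, gb] = np.sum((a == ga) & (b == gb))
    pA = (2 * n_tab[2].sum() + n_tab[1].sum()) / (2 * n)
    pB = (2 * n_tab[:, 2].sum() + n_tab[:, 1].sum()) / (2 * n)
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        x = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
        ll = _table_loglik(n_tab, x)
        return HaplotypePair(x, 0.0, 0.0, 0.0, ll, n, monomorphic=True, loglik_trace=[ll])

    # fixed gamete counts from phase-unambiguous genotypes
    ndh = n_tab[1, 1]
    base = np.array([
        2 * n_tab[2, 2] + n_tab[2, 1] + n_tab[1, 2],  # II
        2 * n_tab[2, 0] + n_tab[2, 1] + n_tab[1, 0],  # ID
        2 * n_tab[0, 2] + n_tab[0, 1] + n_tab[1, 2],  # DI
        2 * n_tab[0, 0] + n_tab[0, 1] + n_tab[1, 0],  # DD
    ])
    x = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
    trace = [_table_loglik(n_tab, x)]
    for _ in range(max_iter):
        cis = x[0] * x[3]
        trans = x[1] * x[2]
        w = cis / (cis + trans) if cis + trans > 0 else 0.5
        c = base + ndh * np.array([w, 1 - w, 1 - w, w])
        x = c / (2 * n)
        trace.append(_table_loglik(n_tab, x))
        if trace[-1] - trace[-2] < tol:
            break
    pA = x[0] + x[1]
    pB = x[0] + x[2]
    d = x[0] - pA * pB
    if d >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    d_prime = 0.0 if dmax == 0 else d / dmax
    denom = pA * (1 - pA) * pB * (1 - pB)
    r2 = 0.0 if denom == 0 else d * d / denom
    return HaplotypePair(x, float(d), float(d_prime), float(r2), trace[-1], n, loglik_trace=trace)


def ld_test(pair: HaplotypePair, n_tab: np.ndarray | None = None) -> TestResult:
    """1-df likelihood-ratio test of D = 0 for an EM haplotype fit.

    The independence log-likelihood is evaluated at product haplotype
    frequencies built from the fitted allele frequencies; the full-model
    log-likelihood is the EM optimum stored on ``pair``.
    """
    if pair.monomorphic:
        return TestResult(0.0, 1.0, "ld_lrt", df=1, monomorphic=True)
    pA, pB = pair.pA, pair.pB
    x0 = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
    # reconstruct the independence loglik from the same genotype table the EM
    # saw; the first trace entry was evaluated at exactly these frequencies
    ll0 = pair.loglik_trace[0] if pair.loglik_trace else _table_loglik(n_tab, x0)
    stat = max(0.0, 2.0 * (pair.loglik - ll0))
    return TestResult(stat, float(chi2.sf(stat, df=1)), "ld_lrt", df=1)


def ld_all_pairs(gm: GenotypeMatrix) -> pd.DataFrame:
    """EM LD statistics and LRT p-values for every locus pair.

    Long-format output (locusA, locusB, D, Dprime, r2, p_value) suitable for
    heat-map rendering.
    """
    rows = []
    for i, j in itertools.combinations(range(gm.n_loci), 2):
        pair = em_haplotype_freqs(gm.dosage[:, i], gm.dosage[:, j])
        res = ld_test(pair)
        rows.append({
            "locusA": gm.loci[i].locus_id,
            "locusB": gm.loci[j].locus_id,
            "D": pair.D,
            "Dprime": pair.D_prime,
            "r2": pair.r2,
            "p_value": res.p_value,
        })
    return pd.DataFrame(rows)
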
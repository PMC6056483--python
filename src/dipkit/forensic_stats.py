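"""Per-locus forensic efficiency parameters for diallelic InDel panels.

Conventions (the PowerStats-style spreadsheet conventions standard in
forensic genetics for these panels):

* expected heterozygosity He = 2pq, with no 2n/(2n-1) small-sample
  correction — He reaches exactly 0.5000 at p = 0.5;
* matching probability MP is the sum of squared *observed* genotype
  relative frequencies (not HWE-expected ones), so PD = 1 - MP can exceed
  the HWE ceiling of 0.625 for a diallelic locus;
* power of exclusion uses the heterozygosity-based formula
  PE = h^2 (1 - 2 h H^2) with h the observed heterozygote fraction and
  H = 1 - h;
* PIC is Botstein's polymorphic information content specialized to two
  alleles, 1 - (p^2 + q^2) - 2 p^2 q^2;
* combined statistics 1 - prod(1 - v_l) are accumulated in the log domain
  so that a 30-locus CPD retains all printed significant digits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix


def allele_frequency(dosages: np.ndarray) -> tuple[float, int]:
    """Insertion-allele frequency and number of non-missing alleles.

    Missing genotypes are excluded; raises on an all-missing locus.
    """
    d = np.asarray(dosages)
    typed = d != MISSING
    n_typed = int(typed.sum())
    if n_typed == 0:
        raise ValueError("locus has no typed genotypes")
    return float(d[typed].sum() / (2 * n_typed)), 2 * n_typed


def expected_heterozygosity(p: float) -> float:
    """He = 2pq (uncorrected)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    return 2.0 * p * (1.0 - p)


def observed_heterozygosity(dosages: np.ndarray) -> float:
    """Fraction of typed individuals that are heterozygous."""
    d = np.asarray(dosages)
    typed = d != MISSING
    n_typed = int(typed.sum())
    if n_typed == 0:
        raise ValueError("locus has no typed genotypes")
    return float((d[typed] == 1).sum() / n_typed)


def pic(p: float) -> float:
    """Botstein polymorphic information content for a diallelic locus."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    q = 1.0 - p
    return 1.0 - (p * p + q * q) - 2.0 * p * p * q * q


def match_probability(genotype_counts: np.ndarray) -> tuple[float, float]:
    """MP and PD from observed genotype counts (hom-ins, het, hom-del).

    Accepts raw counts or relative frequencies (anything nonnegative with a
    positive total).
    """
    c = np.asarray(genotype_counts, dtype=float)
    if c.shape != (3,) or (c < 0).any() or c.sum() <= 0:
        raise ValueError("need nonnegative counts over the 3 genotype classes")
    f = c / c.sum()
    mp = float(np.sum(f * f))
    return mp, 1.0 - mp


def power_of_exclusion(ho: float) -> float:
    """PE = h^2 (1 - 2 h H^2), h = observed heterozygosity, H = 1 - h."""
    if not 0.0 <= ho <= 1.0:
        raise ValueError("ho must lie in [0, 1]")
    h, bigh = ho, 1.0 - ho
    return h * h * (1.0 - 2.0 * h * bigh * bigh)


def combine(values: np.ndarray) -> float:
    """Combined statistic 1 - prod(1 - v) over loci, in the log domain.

    Order-invariant and precision-preserving even when the product of
    complements underflows toward 0 (13-digit combined discrimination
    powers).  Empty input gives 0.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        return 0.0
    if ((v < 0) | (v > 1)).any():
        raise ValueError("per-locus values must lie in [0, 1]")
    if (v == 1.0).any():
        return 1.0
    return float(-np.expm1(np.sum(np.log1p(-v))))


@dataclass
class ForensicSummary:
    """Per-locus forensic table plus panel-level combined statistics."""

    per_locus: pd.DataFrame  # columns: locus,p,maf,ho,he,pic,mp,pd,pe
    cpd: float
    cpe: float

    def to_csv(self, path) -> None:
        self.per_locus.round(6).to_csv(path, index=False)


def summarize(gm: GenotypeMatrix) -> ForensicSummary:
    """Compute the full forensic-parameter suite for every locus of a panel.

    Loci with no typed genotypes are flagged (NaN row) and excluded from the
    combined CPD/CPE.
    """
    rows = []
    for j, locus in enumerate(gm.loci):
        d = gm.dosage[:, j]
        typed = d[d != MISSING]
        if typed.size == 0:
            rows.append({"locus": locus.locus_id, "p": np.nan, "maf": np.nan, "ho": np.nan,
                         "he": np.nan, "pic": np.nan, "mp": np.nan, "pd": np.nan, "pe": np.nan})
            continue
        p, _ = allele_frequency(d)
        ho = observed_heterozygosity(d)
        counts = np.array([(typed == 2).sum(), (typed == 1).sum(), (typed == 0).sum()])
        mp, pd_ = match_probability(counts)
        rows.append({
            "locus": locus.locus_id,
            "p": p,
            "maf": min(p, 1.0 - p),
            "ho": ho,
            "he": expected_heterozygosity(p),
            "pic": pic(p),
            "mp": mp,
            "pd": pd_,
            "pe": power_of_exclusion(ho),
        })
    table = pd.DataFrame(rows, columns=["locus", "p", "maf", "ho", "he", "pic", "mp", "pd", "pe"])
    ok = table["pd"].notna()
    return ForensicSummary(
        per_locus=table,
        cpd=combine(table.loc[ok, "pd"].to_numpy()),
        cpe=combine(table.loc[ok, "pe"].to_numpy()),
    )
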
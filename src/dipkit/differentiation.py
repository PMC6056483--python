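"""Pairwise population differentiation: Weir-Cockerham theta and Nei's DA.

theta is the Weir & Cockerham (1984) variance-components estimator of Fst,
reported as the ratio of sums a / (a + b + c) over loci.  Locus-by-locus
significance is assessed by permuting individuals between the two
populations (the same null the study's AMOVA p-values address).  DA is the
Nei, Tajima & Tateno (1983) distance computed from allele frequencies only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, AlleleFreqTable, DistanceMatrix, GenotypeMatrix


def _wc_components(n: np.ndarray, p: np.ndarray, h: np.ndarray) -> tuple[np.ndarray, ...]:
    """Weir-Cockerham variance components per locus.

    Parameters are (r populations x L loci) arrays of typed sample sizes,
    insertion frequencies and heterozygote fractions.  Returns (a, b, c)
    arrays of shape (L,): among-population, between-individual and
    within-individual components.
    """
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    h = np.asarray(h, dtype=float)
    r = n.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = n.mean(axis=0)
        nc = (r * nbar - (n * n).sum(axis=0) / (r * nbar)) / (r - 1)
        pbar = (n * p).sum(axis=0) / (r * nbar)
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n * h).sum(axis=0) / (r * nbar)
        inner = pbar * (1 - pbar) - (r - 1) / r * s2
        a = nbar / nc * (s2 - (inner - hbar / 4) / (nbar - 1))
        b = nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
    return a, b, c


def _pop_stats(gm: GenotypeMatrix, pop: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    rows = np.asarray(gm.populations) == pop
    d = gm.dosage[rows]
    typed = d != MISSING
    n = typed.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(typed, d, 0).sum(axis=0) / (2 * n)
        h = (typed & (d == 1)).sum(axis=0) / n
    return n, p, h


@dataclass
class FstResult:
    theta: float  # multi-locus ratio-of-sums estimate
    per_locus: pd.DataFrame  # locus, a, b, c, theta (NaN where undefined)
    loci_used: list[str]


def wc_fst(gm: GenotypeMatrix, pop_a: str, pop_b: str) -> FstResult:
    """Pairwise Weir-Cockerham theta between two populations of a panel.

    Loci monomorphic across both populations, or with fewer than two typed
    individuals in either, are skipped.  The multi-locus estimate is the
    ratio of summed components (not a mean of per-locus ratios) and is not
    truncated at zero.
    """
    nA, pA, hA = _pop_stats(gm, pop_a)
    nB, pB, hB = _pop_stats(gm, pop_b)
    n = np.vstack([nA, nB])
    p = np.vstack([pA, pB])
    h = np.vstack([hA, hB])
    pooled = (n * p).sum(axis=0) / n.sum(axis=0)
    usable = (n >= 2).all(axis=0) & (pooled > 0) & (pooled < 1)
    if not usable.any():
        raise ValueError(f"no shared polymorphic loci between {pop_a!r} and {pop_b!r}")
    a, b, c = _wc_components(n, p, h)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        per_theta = np.where(usable & (denom != 0), a / denom, np.nan)
    table = pd.DataFrame({
        "locus": gm.locus_ids,
        "a": np.where(usable, a, np.nan),
        "b": np.where(usable, b, np.nan),
        "c": np.where(usable, c, np.nan),
        "theta": per_theta,
    })
    theta = float(a[usable].sum() / denom[usable].sum())
    return FstResult(theta, table, [gm.locus_ids[j] for j in np.flatnonzero(usable)])


def fst_matrix(gm: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise multi-locus theta over all populations of a panel."""
    pops = gm.population_list()
    m = np.zeros((len(pops), len(pops)))
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            m[i, j] = m[j, i] = wc_fst(gm, pops[i], pops[j]).theta
    return DistanceMatrix(pops, m, kind="fst")


# ---------------------------------------------------------------------------
# Permutation test (locus-by-locus and overall)
# ---------------------------------------------------------------------------


def _batched_theta(
    dosage: np.ndarray, member_a: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """theta for many A/B splits at once.

    ``dosage`` is (N individuals x L loci) with MISSING sentinels;
    ``member_a`` is (R splits x N) boolean.  Returns per-locus theta
    (R x L, NaN where undefined) and the overall ratio-of-sums theta (R,).
    """
    typed = (dosage != MISSING).astype(float)
    dos = np.where(dosage != MISSING, dosage, 0).astype(float)
    het = ((dosage == 1) & (dosage != MISSING)).astype(float)
    A = member_a.astype(float)
    B = 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        nA, nB = A @ typed, B @ typed  # (R, L)
        pA = (A @ dos) / (2 * nA)
        pB = (B @ dos) / (2 * nB)
        hA = (A @ het) / nA
        hB = (B @ het) / nB
    n = np.stack([nA, nB])  # (2, R, L); _wc_components reduces over axis 0
    p = np.stack([pA, pB])
    h = np.stack([hA, hB])
    pooled = (n * p).sum(axis=0) / n.sum(axis=0)
    usable = (n >= 2).all(axis=0) & (pooled > 0) & (pooled < 1)
    a, b, c = _wc_components(n, p, h)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        per = np.where(usable & (denom != 0), a / denom, np.nan)
        num_sum = np.where(usable, a, 0.0).sum(axis=1)
        den_sum = np.where(usable, denom, 0.0).sum(axis=1)
        out_theta = np.where(usable.any(axis=1), num_sum / den_sum, np.nan)
    return per, out_theta


def fst_permutation_pvalue(
    gm: GenotypeMatrix,
    pop_a: str,
    pop_b: str,
    n_perm: int = 10000,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Permutation p-values for theta, per locus and overall.

    Individuals are shuffled between the two populations holding sample
    sizes fixed; p = (1 + #{theta_perm >= theta_obs}) / (1 + n_perm).
    Permuted loci whose theta is undefined (monomorphic after shuffling)
    count as not exceeding the observed value.  The returned frame has one
    row per usable locus plus a final ``__overall__`` row.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    labels = np.asarray(gm.populations)
    rows = np.flatnonzero((labels == pop_a) | (labels == pop_b))
    dosage = gm.dosage[rows]
    is_a = labels[rows] == pop_a
    n_a = int(is_a.sum())
    N = rows.size
    obs_per, obs_overall = _batched_theta(dosage, is_a[None, :])
    member = np.zeros((n_perm, N), dtype=bool)
    for r in range(n_perm):
        member[r, rng.choice(N, size=n_a, replace=False)] = True
    perm_per, perm_overall = _batched_theta(dosage, member)
    with np.errstate(invalid="ignore"):
        exceed = np.nansum(perm_per >= obs_per[0][None, :], axis=0)
        p_loci = (1.0 + exceed) / (1.0 + n_perm)
        p_overall = (1.0 + np.nansum(perm_overall >= obs_overall[0])) / (1.0 + n_perm)
    out = pd.DataFrame({
        "locus": gm.locus_ids,
        "theta": obs_per[0],
        "p_value": np.where(np.isnan(obs_per[0]), np.nan, p_loci),
    })
    out = out[out["theta"].notna()].reset_index(drop=True)
    overall = pd.DataFrame(
        {"locus": ["__overall__"], "theta": [obs_overall[0]], "p_value": [p_overall]}
    )
    return pd.concat([out, overall], ignore_index=True)


def count_significant_loci(locus_pvalues: pd.DataFrame | dict, alpha: float = 0.05):
    """Count loci with p < alpha (strict), per population pair.

    Accepts either a single long-format frame with a ``p_value`` column
    (returns an int) or a mapping of pair -> frame (returns a dict of
    counts) — the summary behind a significant-locus bar diagram.
    """
    if isinstance(locus_pvalues, dict):
        return {k: count_significant_loci(v, alpha) for k, v in locus_pvalues.items()}
    df = locus_pvalues[locus_pvalues["locus"] != "__overall__"]
    return int((df["p_value"] < alpha).sum())


# ---------------------------------------------------------------------------
# Nei's DA
# ---------------------------------------------------------------------------


def nei_da(freqs_a: np.ndarray, freqs_b: np.ndarray) -> float:
    """DA = 1 - mean_l [sqrt(pA pB) + sqrt(qA qB)] over shared loci."""
    pa = np.asarray(freqs_a, dtype=float)
    pb = np.asarray(freqs_b, dtype=float)
    if pa.shape != pb.shape or pa.size == 0:
        raise ValueError("need equal-length, nonempty frequency vectors")
    keep = ~(np.isnan(pa) | np.isnan(pb))
    if not keep.any():
        raise ValueError("no shared typed loci")
    pa, pb = pa[keep], pb[keep]
    return float(1.0 - np.mean(np.sqrt(pa * pb) + np.sqrt((1 - pa) * (1 - pb))))


def da_matrix(table: AlleleFreqTable) -> DistanceMatrix:
    """Pairwise DA over all populations of a frequency table."""
    P = len(table.populations)
    m = np.zeros((P, P))
    for i in range(P):
        for j in range(i + 1, P):
            m[i, j] = m[j, i] = max(0.0, nei_da(table.p[i], table.p[j]))
    return DistanceMatrix(table.populations, m, kind="da")
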
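"""Maximum-likelihood admixture inference by EM.

The model: each individual i has ancestry fractions q_i over K clusters and
each cluster k has insertion frequencies f_kl; a genotype dosage g_il is
Binomial(2, pi_il) with pi_il = sum_k q_ik f_kl.  The EM block updates of Q
and F are those of the frappe/ADMIXTURE likelihood; given the seed the fit
is deterministic, making it a desk-scale, testable stand-in for MCMC-based
clustering of the same generative model.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenotypeMatrix

_EPS = 1e-6  # F bounded away from {0,1} to keep the log-likelihood finite


@dataclass
class AdmixtureFit:
    K: int
    Q: np.ndarray  # individuals x K, rows sum to 1
    F: np.ndarray  # K x loci, in [eps, 1-eps]
    loglik: float
    loglik_trace: list[float]
    converged: bool
    seed: int

    def __post_init__(self) -> None:
        if not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("Q rows must sum to 1")
        if (self.Q < -1e-12).any():
            raise ValueError("Q must be nonnegative")
        if ((self.F < _EPS - 1e-12) | (self.F > 1 - _EPS + 1e-12)).any():
            raise ValueError("F out of bounds")


def _loglik(G: np.ndarray, typed: np.ndarray, Q: np.ndarray, F: np.ndarray) -> float:
    PI = np.clip(Q @ F, _EPS, 1 - _EPS)
    term = G * np.log(PI) + (2.0 - G) * np.log1p(-PI)
    return float(term[typed].sum())


def fit_admixture(
    gm: GenotypeMatrix,
    K: int,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> AdmixtureFit:
    """Fit the K-cluster admixture model to a genotype panel.

    Q is initialized from a symmetric Dirichlet(1); F from the pooled locus
    frequencies perturbed by seeded noise.  Missing genotypes contribute
    nothing to the likelihood.  The EM log-likelihood trace is nondecreasing
    (asserted in-run); iteration stops when the gain drops below ``tol``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > gm.n_samples:
        raise ValueError("K exceeds the number of individuals")
    typed = gm.typed_mask()
    if not typed.any(axis=1).all():
        raise ValueError("individuals with no typed loci cannot be fit")
    G = np.where(typed, gm.dosage, 0).astype(float)
    N, L = G.shape
    rng = np.random.default_rng(seed)
    Q = rng.dirichlet(np.ones(K), size=N)
    pooled = G.sum(axis=0) / (2.0 * typed.sum(axis=0))
    F = np.clip(pooled[None, :] + rng.uniform(-0.1, 0.1, size=(K, L)), _EPS, 1 - _EPS)
    L_i = typed.sum(axis=1).astype(float)

    trace = [_loglik(G, typed, Q, F)]
    converged = False
    for _ in range(max_iter):
        PI = np.clip(Q @ F, _EPS, 1 - _EPS)
        GA = np.where(typed, G / PI, 0.0)
        GB = np.where(typed, (2.0 - G) / (1.0 - PI), 0.0)
        # expected insertion / deletion gene-copy counts by cluster
        num_q = Q * (GA @ F.T + GB @ (1.0 - F).T)
        Q_new = num_q / (2.0 * L_i[:, None])
        Q_new /= Q_new.sum(axis=1, keepdims=True)
        ins = F * (Q.T @ GA)
        tot = ins + (1.0 - F) * (Q.T @ GB)
        with np.errstate(invalid="ignore", divide="ignore"):
            F_new = np.where(tot > 0, ins / np.maximum(tot, 1e-300), F)
        F_new = np.clip(F_new, _EPS, 1 - _EPS)
        Q, F = Q_new, F_new
        ll = _loglik(G, typed, Q, F)
        if ll < trace[-1] - 1e-6 * max(1.0, abs(trace[-1])):
            raise RuntimeError("EM log-likelihood decreased — update bug")
        gain = ll - trace[-1]
        trace.append(ll)
        if gain < tol:
            converged = True
            break
    return AdmixtureFit(K=K, Q=Q, F=F, loglik=trace[-1], loglik_trace=trace,
                        converged=converged, seed=seed)


def fit_admixture_multistart(
    gm: GenotypeMatrix, K: int, seeds: int | list[int] = 10, **kwargs
) -> AdmixtureFit:
    """Best-log-likelihood fit over several EM starts (local-optimum guard)."""
    if isinstance(seeds, int):
        seeds = list(range(seeds))
    fits = [fit_admixture(gm, K, seed=s, **kwargs) for s in seeds]
    return max(fits, key=lambda f: f.loglik)


def align_labels(fit_a: AdmixtureFit, fit_b: AdmixtureFit) -> tuple[int, ...]:
    """Permutation of ``fit_b``'s clusters best matching ``fit_a``.

    Minimizes the total absolute difference of Q matrices; exhaustive over
    K! for K <= 6, greedy (column-by-column best match) above.
    """
    if fit_a.K != fit_b.K:
        raise ValueError("fits must share K")
    K = fit_a.K
    if K <= 6:
        best, best_cost = None, np.inf
        for perm in itertools.permutations(range(K)):
            cost = np.abs(fit_a.Q - fit_b.Q[:, perm]).sum()
            if cost < best_cost:
                best, best_cost = perm, cost
        return best
    cost = np.array([[np.abs(fit_a.Q[:, i] - fit_b.Q[:, j]).sum() for j in range(K)]
                     for i in range(K)])
    perm = [-1] * K
    free = set(range(K))
    for i in np.argsort(cost.min(axis=1)):
        j = min(free, key=lambda c: cost[i, c])
        perm[i] = j
        free.discard(j)
    return tuple(perm)


def permute_fit(fit: AdmixtureFit, perm: tuple[int, ...]) -> AdmixtureFit:
    """Relabel a fit's clusters by ``perm`` (as returned by align_labels)."""
    return AdmixtureFit(fit.K, fit.Q[:, perm], fit.F[list(perm), :], fit.loglik,
                        fit.loglik_trace, fit.converged, fit.seed)


@dataclass
class KSelection:
    """Multi-seed log-likelihood profile over K and the plateau choice."""

    table: pd.DataFrame  # K, mean_loglik, sd_loglik, best_loglik, penalized_gain
    selected_k: int
    pooled_sd: float
    penalty: float
    loglik: np.ndarray  # seeds x K


def _plateau_choice(ll_by_k: np.ndarray, ks: list[int], sd: float, penalty: float) -> int:
    """Last K whose overfitting-corrected gain over K-1 is substantive.

    Gains are corrected by the (N+L)/2 Wilks allowance, which is only a
    rough estimate of the true overfitting gain (boundary-pinned ancestry
    parameters make the truth anywhere from ~0.9x to ~1.7x of it).  The
    top-of-range step therefore serves as an in-data overfitting reference
    — the scanned range must extend past the plausible K — and a step
    counts as substantive only if its corrected gain exceeds
    ``max(2 sd, 0.1 penalty, 2 x final-step corrected gain)``.
    """
    gains = np.diff(ll_by_k) - penalty
    thr = max(2.0 * sd, 0.1 * penalty, 2.0 * gains[-1])
    for g, k in zip(gains, ks[1:]):
        if g < thr:
            return max(ks[0], k - 1)
    return ks[-1]


def select_k(
    gm: GenotypeMatrix,
    k_range: list[int] | range,
    n_seeds: int = 10,
    seed: int = 0,
    max_iter: int = 600,
    tol: float = 1e-4,
) -> KSelection:
    """Likelihood profile over K with an overfitting-corrected plateau rule.

    For every K in ``k_range`` the model is fit once per seed.  Adding a
    cluster introduces about N + L free parameters (one ancestry degree of
    freedom per individual plus a frequency row), so even a structureless
    K gains roughly (N + L)/2 log-likelihood units in-sample (Wilks); raw
    gains therefore never plateau.  The rule works on the best-of-seeds
    profile: the selected K is the last one whose gain over K-1, after
    subtracting the (N + L)/2 overfitting allowance, still exceeds
    ``max(2 pooled-SD, 0.1 allowance, 2 x top-of-range corrected gain)``;
    the pooled SD is the across-seed spread of the log-likelihood (0 when
    n_seeds = 1) and the top-of-range step acts as an in-data overfitting
    reference, so ``k_range`` should extend beyond the plausible K.
    """
    ks = sorted(k_range)
    if not ks:
        raise ValueError("k_range must be nonempty")
    base = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_seeds)
    ll = np.empty((n_seeds, len(ks)))
    for si, s in enumerate(base):
        for ki, k in enumerate(ks):
            ll[si, ki] = fit_admixture(gm, k, seed=int(s) + k, max_iter=max_iter, tol=tol).loglik
    sds = ll.std(axis=0, ddof=1) if n_seeds > 1 else np.zeros(len(ks))
    pooled_sd = float(np.sqrt(np.mean(sds**2)))
    penalty = (gm.n_samples + gm.n_loci) / 2.0
    best = ll.max(axis=0)
    table = pd.DataFrame({
        "K": ks,
        "mean_loglik": ll.mean(axis=0),
        "sd_loglik": sds,
        "best_loglik": best,
        "penalized_gain": np.concatenate([[np.nan], np.diff(best) - penalty]),
    })
    selected = _plateau_choice(best, ks, pooled_sd, penalty)
    return KSelection(table, selected, pooled_sd, penalty, ll)


def q_dataframe(gm: GenotypeMatrix, fit: AdmixtureFit) -> pd.DataFrame:
    """Q matrix as a tidy frame (sample, population, q1..qK), ordered by
    population then sample — the data behind a stacked-bar ancestry plot."""
    df = pd.DataFrame(fit.Q, columns=[f"q{k + 1}" for k in range(fit.K)])
    df.insert(0, "population", gm.populations)
    df.insert(0, "sample", gm.samples)
    order = {p: i for i, p in enumerate(gm.population_list())}
    return df.sort_values(["population", "sample"],
                          key=lambda s: s.map(order) if s.name == "population" else s,
                          ignore_index=True)
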
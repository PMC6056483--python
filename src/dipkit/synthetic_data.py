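"""Synthetic DIP genotype panels with known population structure.

The generator produces exactly the statistical structure the downstream
analyses assume, so every stage can be validated against ground truth:

* within a population, genotypes are Hardy-Weinberg draws
  (dosage ~ Binomial(2, p), loci independent);
* between populations, insertion frequencies diverge under the
  Balding-Nichols model, Beta(p(1-F)/F, (1-p)(1-F)/F), whose mean is the
  ancestral frequency p and whose variance is F*p*(1-p) — F is exactly the
  Fst the Weir-Cockerham estimator targets;
* divergence is hierarchical (ancestral -> cluster -> population), so
  populations inside a cluster resemble each other more than populations
  across clusters;
* admixed populations draw each of an individual's two gene copies
  independently: first a cluster according to the individual's mixing
  weights, then an allele from that cluster's frequency — the same
  generative model the admixture EM fits, making parameter recovery
  well-posed.

All randomness flows from a single seed through ``numpy`` child generators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import GenotypeMatrix, LocusDef


@dataclass(frozen=True)
class ClusterSpec:
    """One continental cluster: its divergence from the ancestral pool and
    the populations (name -> diploid sample size) it contains."""

    name: str
    fst: float
    populations: dict[str, int]
    within_fst: float = 0.01
    branch: str | None = None  # optional super-cluster the fst is measured from

    def __post_init__(self) -> None:
        if not 0.0 < self.fst < 1.0:
            raise ValueError(f"cluster fst must lie in (0,1), got {self.fst}")
        if not 0.0 < self.within_fst < 1.0:
            raise ValueError("within_fst must lie in (0,1)")
        if not self.populations:
            raise ValueError(f"cluster {self.name!r} has no populations")


@dataclass(frozen=True)
class PanelConfig:
    """Full layout of a synthetic multi-population panel."""

    n_loci: int
    ancestral_p: tuple[float, ...]
    clusters: tuple[ClusterSpec, ...]
    admixture: dict[str, dict[str, float]] = field(default_factory=dict)
    branches: dict[str, float] = field(default_factory=dict)  # branch -> fst from ancestral
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.ancestral_p) != self.n_loci:
            raise ValueError("ancestral_p length != n_loci")
        for c in self.clusters:
            if c.branch is not None and c.branch not in self.branches:
                raise ValueError(f"cluster {c.name!r} references unknown branch {c.branch!r}")
        if any(not 0.0 < p < 1.0 for p in self.ancestral_p):
            raise ValueError("ancestral frequencies must lie in (0,1)")
        names = [p for c in self.clusters for p in c.populations]
        if len(set(names)) != len(names):
            raise ValueError("population names must be unique across clusters")
        if len({c.name for c in self.clusters}) != len(self.clusters):
            raise ValueError("cluster names must be unique")
        cluster_names = {c.name for c in self.clusters}
        for pop, w in self.admixture.items():
            if pop not in names:
                raise ValueError(f"admixture entry for unknown population {pop!r}")
            unknown = set(w) - cluster_names
            if unknown:
                raise ValueError(f"admixture of {pop!r} names unknown clusters {sorted(unknown)}")
            vals = np.array(list(w.values()), dtype=float)
            if (vals < 0).any() or not np.isclose(vals.sum(), 1.0):
                raise ValueError(f"mixing weights of {pop!r} must be nonnegative and sum to 1")

    @property
    def cluster_names(self) -> list[str]:
        return [c.name for c in self.clusters]

    def population_cluster(self) -> dict[str, str]:
        """Population -> cluster assignment (admixed populations keep the
        cluster they are listed under)."""
        return {p: c.name for c in self.clusters for p in c.populations}


def sample_hwe_genotypes(
    p: float | np.ndarray,
    n: int,
    seed: int | np.random.Generator,
    population: str = "pop",
    locus_ids: list[str] | None = None,
) -> GenotypeMatrix:
    """Draw ``n`` diploid individuals in Hardy-Weinberg equilibrium.

    ``p`` may be a scalar (one locus) or a vector of per-locus insertion
    frequencies; dosages are independent Binomial(2, p) draws.
    """
    p = np.atleast_1d(np.asarray(p, dtype=float))
    if (p < 0).any() or (p > 1).any():
        raise ValueError("insertion frequency must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    dosage = rng.binomial(2, p, size=(n, p.size)).astype(np.int8)
    if locus_ids is None:
        locus_ids = [f"L{j + 1:03d}" for j in range(p.size)]
    return GenotypeMatrix(
        samples=[f"{population}_{i + 1}" for i in range(n)],
        populations=[population] * n,
        loci=[LocusDef(l) for l in locus_ids],
        dosage=dosage,
    )


def balding_nichols_freqs(
    ancestral_p: float | np.ndarray,
    fst: float,
    n_pops: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Draw population frequencies around ``ancestral_p`` at divergence ``fst``.

    Returns an ``(n_pops, n_loci)`` array of Beta(p(1-F)/F, (1-p)(1-F)/F)
    draws; mean = p, variance = F*p*(1-p).
    """
    p = np.atleast_1d(np.asarray(ancestral_p, dtype=float))
    if not 0.0 < fst < 1.0:
        raise ValueError(f"fst must lie strictly in (0,1), got {fst}")
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("ancestral_p must lie strictly in (0,1)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    scale = (1.0 - fst) / fst
    return rng.beta(p * scale, (1.0 - p) * scale, size=(n_pops, p.size))


def _sample_admixed(
    weights: np.ndarray, cluster_freqs: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Per gene copy: pick a cluster by ``weights``, then an allele by that
    cluster's frequency.  Returns (n, n_loci) dosages."""
    n_clusters, n_loci = cluster_freqs.shape
    dosage = np.zeros((n, n_loci), dtype=np.int8)
    for _copy in range(2):
        origin = rng.choice(n_clusters, size=(n, n_loci), p=weights)
        dosage += rng.random((n, n_loci)) < cluster_freqs[origin, np.arange(n_loci)]
    return dosage


def generate_panel(
    config: PanelConfig,
) -> tuple[GenotypeMatrix, np.ndarray, np.ndarray]:
    """Generate a full panel.

    Returns
    -------
    genotypes : GenotypeMatrix
        All individuals of all populations, in config order.
    true_q : ndarray, shape (n_individuals, n_clusters)
        Ground-truth ancestry fractions (one-hot for unadmixed populations).
    cluster_freqs : ndarray, shape (n_clusters, n_loci)
        The cluster-level insertion frequencies individuals were drawn from.
    """
    master = np.random.default_rng(config.seed)
    anc = np.asarray(config.ancestral_p, dtype=float)
    n_clusters = len(config.clusters)
    branch_freqs = {
        name: np.clip(balding_nichols_freqs(anc, fst, 1, master)[0], 1e-4, 1 - 1e-4)
        for name, fst in config.branches.items()
    }
    cluster_freqs = np.empty((n_clusters, config.n_loci))
    for k, cl in enumerate(config.clusters):
        base = branch_freqs[cl.branch] if cl.branch else anc
        cluster_freqs[k] = balding_nichols_freqs(base, cl.fst, 1, master)[0]
    # guard against Beta draws collapsing numerically onto the boundary
    cluster_freqs = np.clip(cluster_freqs, 1e-4, 1 - 1e-4)

    samples: list[str] = []
    pops: list[str] = []
    blocks: list[np.ndarray] = []
    q_rows: list[np.ndarray] = []
    locus_ids = [f"L{j + 1:03d}" for j in range(config.n_loci)]
    for k, cl in enumerate(config.clusters):
        for pop, size in cl.populations.items():
            if pop in config.admixture:
                w = np.zeros(n_clusters)
                for cname, wt in config.admixture[pop].items():
                    w[config.cluster_names.index(cname)] = wt
                blocks.append(_sample_admixed(w, cluster_freqs, size, master))
                q_rows.append(np.tile(w, (size, 1)))
            else:
                pop_freq = np.clip(
                    balding_nichols_freqs(cluster_freqs[k], cl.within_fst, 1, master)[0],
                    1e-4,
                    1 - 1e-4,
                )
                blocks.append(master.binomial(2, pop_freq, size=(size, config.n_loci)).astype(np.int8))
                onehot = np.zeros(n_clusters)
                onehot[k] = 1.0
                q_rows.append(np.tile(onehot, (size, 1)))
            samples.extend(f"{pop}_{i + 1}" for i in range(size))
            pops.extend([pop] * size)
    gm = GenotypeMatrix(samples, pops, [LocusDef(l) for l in locus_ids], np.vstack(blocks))
    return gm, np.vstack(q_rows), cluster_freqs


# ---------------------------------------------------------------------------
# Named preset
# ---------------------------------------------------------------------------

_DIPPLEX_LOCI = [
    "HLD77", "HLD45", "HLD131", "HLD70", "HLD6", "HLD111", "HLD58", "HLD56",
    "HLD118", "HLD92", "HLD93", "HLD99", "HLD88", "HLD101", "HLD67", "HLD83",
    "HLD114", "HLD48", "HLD124", "HLD122", "HLD125", "HLD64", "HLD81", "HLD136",
    "HLD133", "HLD97", "HLD40", "HLD128", "HLD39", "HLD84",
]

_EAST_ASIAN = {
    "Kyrgyz_study": 295, "BeijingHan": 100, "GuangdongHan": 100, "ShanghaiHan": 100,
    "She": 100, "Yi": 100, "Tujia": 100, "Xibe": 100, "Bai": 100,
    "TibetTibetan": 100, "QinghaiTibetan": 100, "SouthKorean": 100,
}
# Kyrgyz_study is generated inside the Central Asian cluster (admixed), see below.
_EAST_ASIAN.pop("Kyrgyz_study")

_EUROPEAN = {"Dane": 100, "Hungarian": 100, "Basque": 100, "CentralSpanish": 100, "Uruguayan": 100}
_MEXICAN = {
    "MexicanAmerindian": 100, "YucatanMexican": 100, "MexicoMexican": 100,
    "VeracruzMexican": 100, "JaliscoMexican": 100, "ChihuahuaMexican": 100,
}
_CENTRAL_ASIAN = {"Kyrgyz_study": 295, "Kazakh": 100, "Uygur": 100}


def kyrgyz_like_panel(seed: int = 0) -> PanelConfig:
    """A 25-population, 4-cluster panel emulating the study layout.

    30 diallelic loci named after the Investigator DIPplex markers; an
    11-population East Asian cluster, 5 European populations (incl. the
    Uruguayan group, which tracks its European source populations at these
    markers), 6 Mexican populations, and 3 Central Asian populations.  The
    focal Kyrgyz sample has 295 individuals; reference populations 100 each.
    The Central Asian populations are admixed, with most of their ancestry
    from a Central-Asian-specific cluster plus East-Asian and European
    contributions — at low K their membership splits across those clusters,
    while at K = 4 they form their own cluster, the qualitative behaviour
    the panel is meant to exhibit.  Cluster divergence (Fst 0.15) puts the
    spread of cluster frequencies at the scale where about half the loci
    exceed an ancestry-informativeness delta of 0.29.
    """
    rng = np.random.default_rng(seed)
    ancestral = tuple(rng.uniform(0.25, 0.75, size=30).round(4))
    clusters = (
        ClusterSpec("EastAsian", fst=0.15, populations=dict(_EAST_ASIAN)),
        ClusterSpec("European", fst=0.06, populations=dict(_EUROPEAN), branch="Western"),
        ClusterSpec("Mexican", fst=0.08, populations=dict(_MEXICAN), branch="Western"),
        ClusterSpec("CentralAsian", fst=0.15, populations=dict(_CENTRAL_ASIAN)),
    )
    admixture = {
        "Kyrgyz_study": {"CentralAsian": 0.50, "EastAsian": 0.30, "European": 0.20},
        "Kazakh": {"CentralAsian": 0.50, "EastAsian": 0.35, "European": 0.15},
        "Uygur": {"CentralAsian": 0.45, "EastAsian": 0.25, "European": 0.30},
    }
    cfg = PanelConfig(
        n_loci=30,
        ancestral_p=ancestral,
        clusters=clusters,
        admixture=admixture,
        branches={"Western": 0.10},
        seed=int(np.random.default_rng(seed + 1).integers(0, 2**31 - 1)),
    )
    return cfg


def kyrgyz_like_locus_ids() -> list[str]:
    """DIPplex-style locus names used when exporting the preset panel."""
    return list(_DIPPLEX_LOCI)


def generate_kyrgyz_like(seed: int = 0) -> tuple[GenotypeMatrix, np.ndarray, np.ndarray, PanelConfig]:
    """Generate the preset panel with DIPplex-style locus names."""
    cfg = kyrgyz_like_panel(seed)
    gm, q, f = generate_panel(cfg)
    gm = GenotypeMatrix(gm.samples, gm.populations, [LocusDef(l) for l in _DIPPLEX_LOCI], gm.dosage)
    return gm, q, f, cfg
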
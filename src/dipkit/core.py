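"""Core containers for diallelic insertion/deletion (DIP) marker data.

A DIP locus has exactly two alleles, an insertion (``I``) and a deletion
(``D``); a diploid genotype is therefore fully described by the insertion
allele *dosage* 0, 1 or 2.  Everything downstream (allele frequencies,
heterozygosities, Fst, admixture likelihoods) is written in terms of this
dosage coding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

#: Sentinel for an untyped genotype.  Kept distinct from every legal dosage so
#: that missing data can never silently bias a frequency.
MISSING: int = -1


@dataclass(frozen=True)
class LocusDef:
    """A diallelic insertion/deletion locus.

    Parameters
    ----------
    locus_id
        Marker name, e.g. ``"HLD39"``.  Must be nonempty.
    ins_label, del_label
        The two allele labels (insertion first).
    """

    locus_id: str
    ins_label: str = "I"
    del_label: str = "D"

    def __post_init__(self) -> None:
        if not self.locus_id:
            raise ValueError("locus_id must be nonempty")
        if self.ins_label == self.del_label:
            raise ValueError("allele labels must differ")


def _as_locus_list(loci: Sequence[LocusDef | str]) -> list[LocusDef]:
    out = [l if isinstance(l, LocusDef) else LocusDef(l) for l in loci]
    ids = [l.locus_id for l in out]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate locus_id in panel")
    return out


@dataclass
class GenotypeMatrix:
    """Individuals x loci insertion-allele dosages with population labels.

    ``dosage[i, l]`` counts insertion alleles carried by sample ``i`` at locus
    ``l`` and is one of {0, 1, 2, :data:`MISSING`}.
    """

    samples: list[str]
    populations: list[str]
    loci: list[LocusDef]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.populations = list(self.populations)
        self.loci = _as_locus_list(self.loci)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        n, l = self.dosage.shape
        if n != len(self.samples):
            raise ValueError("dosage rows != number of samples")
        if l != len(self.loci):
            raise ValueError("dosage columns != number of loci")
        if len(self.populations) != len(self.samples):
            raise ValueError("one population label required per sample")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample_id")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"illegal dosage values at {np.argwhere(bad)[:3]}")

    # -- basic views -----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    def population_list(self) -> list[str]:
        """Distinct population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def typed_mask(self) -> np.ndarray:
        """Boolean (samples x loci) mask of non-missing genotypes."""
        return self.dosage != MISSING

    # -- subsetting ------------------------------------------------------
    def subset(
        self,
        populations: Sequence[str] | None = None,
        loci: Sequence[str] | None = None,
    ) -> "GenotypeMatrix":
        """Restrict to the given population labels and/or locus ids."""
        rows = np.arange(self.n_samples)
        if populations is not None:
            keep = set(populations)
            unknown = keep - set(self.populations)
            if unknown:
                raise KeyError(f"unknown populations: {sorted(unknown)}")
            rows = np.array(
                [i for i, p in enumerate(self.populations) if p in keep], dtype=int
            )
        cols = np.arange(self.n_loci)
        if loci is not None:
            index = {lid: j for j, lid in enumerate(self.locus_ids)}
            try:
                cols = np.array([index[lid] for lid in loci], dtype=int)
            except KeyError as e:
                raise KeyError(f"unknown locus {e}") from None
        return GenotypeMatrix(
            samples=[self.samples[i] for i in rows],
            populations=[self.populations[i] for i in rows],
            loci=[self.loci[j] for j in cols],
            dosage=self.dosage[np.ix_(rows, cols)],
        )

    # -- frequencies -----------------------------------------------------
    def allele_frequencies(self) -> "AlleleFreqTable":
        """Per-population insertion-allele frequencies (missing excluded)."""
        pops = self.population_list()
        P, L = len(pops), self.n_loci
        p = np.full((P, L), np.nan)
        n_alleles = np.zeros((P, L), dtype=int)
        labels = np.asarray(self.populations)
        typed = self.typed_mask()
        dos = np.where(typed, self.dosage, 0)
        for k, pop in enumerate(pops):
            rows = labels == pop
            n_typed = typed[rows].sum(axis=0)
            n_alleles[k] = 2 * n_typed
            with np.errstate(invalid="ignore", divide="ignore"):
                p[k] = np.where(n_typed > 0, dos[rows].sum(axis=0) / (2 * n_typed), np.nan)
        return AlleleFreqTable(populations=pops, loci=list(self.loci), p=p, n_alleles=n_alleles)


@dataclass
class AlleleFreqTable:
    """Population x locus insertion-allele frequencies.

    The interchange object between pipeline stages: Nei's DA distance, AIM
    selection and serialization all operate on this table.  ``n_alleles`` is
    twice the number of typed individuals; a NaN frequency marks a
    population/locus cell with no typed individuals.
    """

    populations: list[str]
    loci: list[LocusDef]
    p: np.ndarray
    n_alleles: np.ndarray

    def __post_init__(self) -> None:
        self.populations = list(self.populations)
        self.loci = _as_locus_list(self.loci)
        self.p = np.asarray(self.p, dtype=float)
        self.n_alleles = np.asarray(self.n_alleles, dtype=int)
        if self.p.shape != (len(self.populations), len(self.loci)):
            raise ValueError("p shape != populations x loci")
        if self.n_alleles.shape != self.p.shape:
            raise ValueError("n_alleles shape != p shape")
        ok = np.isnan(self.p) | ((self.p >= 0.0) & (self.p <= 1.0))
        if not ok.all():
            raise ValueError("frequencies must lie in [0, 1]")
        if (self.n_alleles < 0).any() or (self.n_alleles % 2 != 0).any():
            raise ValueError("n_alleles must be even and nonnegative")

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    def row(self, population: str) -> np.ndarray:
        return self.p[self.populations.index(population)]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance/differentiation matrix over populations."""

    labels: list[str]
    values: np.ndarray
    kind: str = "fst"  # {"fst", "da"}

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape != labels x labels")
        if not np.isfinite(self.values).all():
            raise ValueError("distances must be finite")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("diagonal must be zero")
        if self.kind == "da" and ((self.values < -1e-12) | (self.values > 1 + 1e-12)).any():
            raise ValueError("DA distances must lie in [0, 1]")

    def clamped(self) -> "DistanceMatrix":
        """Copy with negative entries (possible for Fst estimates) set to 0."""
        v = np.maximum(self.values, 0.0)
        np.fill_diagonal(v, 0.0)
        return DistanceMatrix(self.labels, v, self.kind)
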
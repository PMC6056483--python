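"""On-disk formats: genotype CSV, Genepop, frequency/distance CSV, Newick, JSON.

The genotype CSV dialect is this package's own: a header row
``sample_id,population,<locus>,...`` followed by one row per individual whose
genotype cells are unordered allele pairs over {I, D} joined by ``/``
(``I/D`` == ``D/I``) with ``NN`` marking an untyped genotype.

Genepop files use the 2-digit allele dialect with ``01`` = insertion,
``02`` = deletion and ``0000`` = missing.  As is common practice for Genepop,
the id field of each individual line carries the population label, and the
label of a ``POP`` block is read from its last line; sample ids are
synthesized as ``<pop>_<k>`` on read.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import skbio

from .core import MISSING, AlleleFreqTable, DistanceMatrix, GenotypeMatrix, LocusDef

SCHEMA_VERSION = "1.0"


def _parse_cell(cell: str, row: int, col: str) -> int:
    cell = cell.strip()
    if cell == "NN":
        return MISSING
    parts = cell.split("/")
    if len(parts) != 2 or any(a not in ("I", "D") for a in parts):
        raise ValueError(
            f"malformed genotype cell {cell!r} at row {row}, column {col!r}: "
            "expected two '/'-separated alleles over {I, D} or 'NN'"
        )
    return sum(1 for a in parts if a == "I")


def read_genotype_csv(path: str | Path) -> GenotypeMatrix:
    """Read the genotype CSV dialect into a :class:`GenotypeMatrix`."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if len(header) < 3 or header[0] != "sample_id" or header[1] != "population":
            raise ValueError(
                f"{path}: header must start with sample_id,population,<locus>,..."
            )
        locus_ids = header[2:]
        samples: list[str] = []
        pops: list[str] = []
        rows: list[list[int]] = []
        for i, rec in enumerate(reader, start=2):
            if not rec:
                continue
            if len(rec) != len(header):
                raise ValueError(f"{path}: row {i} has {len(rec)} fields, expected {len(header)}")
            samples.append(rec[0])
            pops.append(rec[1])
            rows.append([_parse_cell(c, i, locus_ids[j]) for j, c in enumerate(rec[2:])])
    if len(set(samples)) != len(samples):
        raise ValueError(f"{path}: duplicate sample_id")
    return GenotypeMatrix(samples, pops, [LocusDef(l) for l in locus_ids], np.array(rows, dtype=np.int8))


_DOSAGE_TO_CELL = {2: "I/I", 1: "I/D", 0: "D/D", MISSING: "NN"}


def write_genotype_csv(gm: GenotypeMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", "population", *gm.locus_ids])
        for i, sid in enumerate(gm.samples):
            w.writerow([sid, gm.populations[i], *(_DOSAGE_TO_CELL[int(d)] for d in gm.dosage[i])])


# ---------------------------------------------------------------------------
# Genepop
# ---------------------------------------------------------------------------

_GP_CODE = {2: "0101", 1: "0102", 0: "0202", MISSING: "0000"}
_GP_ALLELE = {"01": 1, "02": 0}  # insertion copies contributed by one allele


def read_genepop(path: str | Path) -> GenotypeMatrix:
    """Read a 2-digit Genepop file (01 = insertion, 02 = deletion)."""
    path = Path(path)
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines()]
    if not lines:
        raise ValueError(f"{path}: empty file")
    body = lines[1:]  # first line is a free title
    locus_ids: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().upper() != "POP":
        # loci may be one-per-line or comma-separated
        locus_ids.extend(t.strip() for t in body[i].split(",") if t.strip())
        i += 1
    if not locus_ids:
        raise ValueError(f"{path}: no locus names before first POP")
    blocks: list[list[tuple[str, list[int]]]] = []
    current: list[tuple[str, list[int]]] | None = None
    for ln in body[i:]:
        if not ln.strip():
            continue
        if ln.strip().upper() == "POP":
            current = []
            blocks.append(current)
            continue
        if current is None:
            raise ValueError(f"{path}: individual line before first POP")
        if "," not in ln:
            raise ValueError(f"{path}: individual line lacks comma: {ln!r}")
        ident, geno = ln.split(",", 1)
        codes = geno.split()
        if len(codes) != len(locus_ids):
            raise ValueError(
                f"{path}: expected {len(locus_ids)} genotypes, got {len(codes)} in {ln!r}"
            )
        dosages = []
        for code in codes:
            if len(code) == 6:
                raise ValueError(f"{path}: 3-digit allele codes are unsupported ({code!r})")
            if len(code) != 4:
                raise ValueError(f"{path}: malformed genotype code {code!r}")
            a, b = code[:2], code[2:]
            if code == "0000":
                dosages.append(MISSING)
            elif a in _GP_ALLELE and b in _GP_ALLELE:
                dosages.append(_GP_ALLELE[a] + _GP_ALLELE[b])
            else:
                raise ValueError(f"{path}: unknown allele code in {code!r}")
        current.append((ident.strip(), dosages))
    if not blocks or any(not b for b in blocks):
        raise ValueError(f"{path}: empty POP block")
    samples, pops, rows = [], [], []
    for block in blocks:
        label = block[-1][0]  # population label = last line's id token
        for k, (_, dos) in enumerate(block, start=1):
            samples.append(f"{label}_{k}")
            pops.append(label)
            rows.append(dos)
    return GenotypeMatrix(samples, pops, [LocusDef(l) for l in locus_ids], np.array(rows, dtype=np.int8))


def write_genepop(gm: GenotypeMatrix, path: str | Path, title: str = "dipkit export") -> None:
    """Write 2-digit Genepop; individual ids carry the population label."""
    path = Path(path)
    out = [title]
    out.extend(gm.locus_ids)
    labels = np.asarray(gm.populations)
    for pop in gm.population_list():
        out.append("POP")
        for i in np.flatnonzero(labels == pop):
            codes = " ".join(_GP_CODE[int(d)] for d in gm.dosage[i])
            out.append(f"{pop} , {codes}")
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Frequency and distance tables
# ---------------------------------------------------------------------------


def write_freq_csv(table: AlleleFreqTable, path: str | Path) -> None:
    """Rows = populations, columns = per-locus insertion frequency (6 dp) and
    allele counts (``<locus>__n``)."""
    df = pd.DataFrame(np.round(table.p, 6), index=table.populations, columns=table.locus_ids)
    for j, lid in enumerate(table.locus_ids):
        df[f"{lid}__n"] = table.n_alleles[:, j]
    df.index.name = "population"
    df.to_csv(path)


def read_freq_csv(path: str | Path) -> AlleleFreqTable:
    df = pd.read_csv(path, index_col="population")
    locus_ids = [c for c in df.columns if not c.endswith("__n")]
    p = df[locus_ids].to_numpy(dtype=float)
    n = df[[f"{l}__n" for l in locus_ids]].to_numpy(dtype=int)
    return AlleleFreqTable(list(df.index), [LocusDef(l) for l in locus_ids], p, n)


def write_distance_csv(dm: DistanceMatrix, path: str | Path) -> None:
    df = pd.DataFrame(np.round(dm.values, 6), index=dm.labels, columns=dm.labels)
    df.index.name = dm.kind
    df.to_csv(path)


def read_distance_csv(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    kind = df.index.name if df.index.name in ("fst", "da") else "fst"
    return DistanceMatrix(list(df.columns), df.to_numpy(dtype=float), kind)


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------


def write_newick(tree) -> str:
    """Serialize an unrooted tree (see :mod:`dipkit.ordination_phylo`) to
    Newick with branch lengths at fixed 6-decimal precision."""

    def render(node, length: float | None) -> str:
        if node.is_leaf:
            head = node.label
        else:
            head = "(" + ",".join(render(c, bl) for c, bl in node.children) + ")"
        if length is None:
            return head
        if not np.isfinite(length):
            raise ValueError(f"non-finite branch length on edge to {node.label!r}")
        return f"{head}:{length:.6f}"

    root = tree.root
    return "(" + ",".join(render(c, bl) for c, bl in root.children) + ");"


def read_newick(path_or_text: str | Path):
    """Parse Newick via scikit-bio, returning an ``skbio.TreeNode``."""
    text = str(path_or_text)
    if "(" not in text:
        text = Path(path_or_text).read_text()
    return skbio.TreeNode.read([text])


# ---------------------------------------------------------------------------
# JSON result bundles
# ---------------------------------------------------------------------------


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json_bundle(payload: dict, path: str | Path) -> None:
    """Write a result bundle with a top-level ``schema_version`` field."""
    doc = {"schema_version": SCHEMA_VERSION}
    doc.update(_jsonable(payload))
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_json_bundle(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
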
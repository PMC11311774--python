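"""Readers and writers for the delimited formats the pipeline touches.

Peak matrices and sample metadata are plain CSV/TSV. Ranked lists and
metabolite-set libraries follow the Broad textual conventions (.rnk, .gmt,
.gmx) so outputs can be fed to, or checked against, the desktop GSEA tool.

Missingness convention: empty cells, "NA"/"NaN" and literal zeros in a peak
table are all read as MISSING (NaN). Absence must stay distinct from a small
value — longitudinal fold changes divide by baseline abundance, and a
metabolite undetected at baseline has no finite fold change at all.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    MetaboliteSet,
    MetaboliteSetLibrary,
    PeakAreaMatrix,
    RankedEntry,
    RankedList,
    ValidationError,
    validate_sample_metadata,
)

_NA_TOKENS = ("", "NA", "NaN", "nan", "na")


def _sep_for(path: Path, dialect: str | None) -> str:
    if dialect in ("csv", ","):
        return ","
    if dialect in ("tsv", "\t"):
        return "\t"
    if dialect is not None:
        raise ValueError(f"unknown dialect {dialect!r}")
    return "\t" if Path(path).suffix.lower() in (".tsv", ".txt") else ","


def _check_header_unique(path: Path, sep: str, what: str) -> None:
    # pandas silently mangles duplicate column names, so inspect the header row
    with open(path, newline="", encoding="utf-8") as fh:
        header = next(csv.reader(fh, delimiter=sep))
    ids = header[1:]
    dups = sorted({i for i in ids if ids.count(i) > 1})
    if dups:
        raise ValidationError(f"duplicate {what} id(s) in header: {dups}")


def read_peak_matrix(path: str | Path, metadata_path: str | Path,
                     dialect: str | None = None) -> PeakAreaMatrix:
    """Read a metabolite × sample peak-area table plus its sample metadata.

    The first column of the matrix file holds metabolite ids; remaining
    column headers are sample ids, each of which must have exactly one row
    in the metadata table. Empty cells, NA tokens and zeros become MISSING.
    """
    path, metadata_path = Path(path), Path(metadata_path)
    sep = _sep_for(path, dialect)
    _check_header_unique(path, sep, "sample")

    values = pd.read_csv(path, sep=sep, index_col=0,
                         na_values=list(_NA_TOKENS), keep_default_na=False)
    values = values.astype(float)
    values = values.mask(values == 0)  # zero reads as "not detected"
    if values.index.has_duplicates:
        dups = sorted(values.index[values.index.duplicated()].unique())
        raise ValidationError(f"duplicate metabolite id(s): {dups}")

    meta_sep = _sep_for(metadata_path, dialect)
    meta = pd.read_csv(metadata_path, sep=meta_sep, dtype=str)
    if "sample_id" not in meta.columns:
        raise ValidationError("metadata must have a 'sample_id' column")
    meta = meta.set_index("sample_id")
    validate_sample_metadata(meta)
    absent = [s for s in values.columns if s not in meta.index]
    if absent:
        raise ValidationError(f"sample(s) in matrix absent from metadata: {absent}")
    return PeakAreaMatrix(values=values, samples=meta.loc[list(values.columns)])


def write_peak_matrix(matrix: PeakAreaMatrix, path: str | Path,
                      metadata_path: str | Path | None = None,
                      dialect: str | None = None) -> None:
    """Write a peak matrix (MISSING as empty cells, never 0) and optionally
    its metadata table."""
    path = Path(path)
    sep = _sep_for(path, dialect)
    out = matrix.values.copy()
    out.index.name = "metabolite"
    out.to_csv(path, sep=sep, na_rep="")
    if metadata_path is not None:
        meta = matrix.samples.copy()
        meta.index.name = "sample_id"
        meta.to_csv(Path(metadata_path), sep=_sep_for(Path(metadata_path), dialect))


# ---------------------------------------------------------------------------
# .rnk — two-column ranked list
# ---------------------------------------------------------------------------

def write_rnk(ranked_list: RankedList, path: str | Path) -> None:
    """Write a Broad-style .rnk file: metabolite TAB score, descending.

    Rank-only lists (per-animal longitudinal lists, mean-rank aggregates)
    emit score = N + 1 - rank so that rank 1 gets the largest score.
    """
    if len(ranked_list) == 0:
        raise ValidationError("cannot write an empty ranked list")
    ordered = sorted(ranked_list.entries, key=lambda e: e.rank)
    n = len(ordered)
    lines = []
    for e in ordered:
        score = float(n + 1 - e.rank) if ranked_list.rank_only else e.score
        if not np.isfinite(score):
            raise ValidationError(
                f"non-finite score for {e.metabolite!r}; write the list in "
                "rank-only mode instead")
        lines.append(f"{e.metabolite}\t{float(score)!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_rnk(path: str | Path) -> RankedList:
    """Read a .rnk file; entries are re-ranked by descending score."""
    entries = []
    for i, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValidationError(f"{path}: malformed .rnk line {i}: {line!r}")
        entries.append((parts[0], float(parts[1])))
    names = [m for m, _ in entries]
    if len(set(names)) != len(names):
        raise ValidationError(f"{path}: duplicate metabolite names")
    entries.sort(key=lambda t: (-t[1], t[0]))
    return RankedList(
        entries=[RankedEntry(metabolite=m, score=s, rank=i + 1)
                 for i, (m, s) in enumerate(entries)],
        provenance={"source": str(path)})


# ---------------------------------------------------------------------------
# .gmt / .gmx — metabolite-set libraries
# ---------------------------------------------------------------------------

def write_gmt(library: MetaboliteSetLibrary, path: str | Path,
              dialect: str = "gmt") -> None:
    """Write a set library.

    ``gmt``: one set per line — name, description, members (tab-separated).
    ``gmx``: the column-oriented transpose — sets are columns, row 1 names,
    row 2 descriptions, members down each column.
    """
    if len(library) == 0:
        raise ValidationError("cannot write an empty library")
    sets = list(library)
    for s in sets:
        if not s.members:
            raise ValidationError(f"set {s.name!r} is empty")
    if dialect == "gmt":
        lines = ["\t".join([s.name, s.description] + sorted(s.members))
                 for s in sets]
    elif dialect == "gmx":
        cols = [[s.name, s.description] + sorted(s.members) for s in sets]
        depth = max(len(c) for c in cols)
        rows = []
        for r in range(depth):
            rows.append("\t".join(c[r] if r < len(c) else "" for c in cols))
        lines = rows
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_gmt(path: str | Path, dialect: str | None = None) -> MetaboliteSetLibrary:
    """Read a .gmt or .gmx library; the dialect defaults to the suffix."""
    path = Path(path)
    if dialect is None:
        dialect = "gmx" if path.suffix.lower() == ".gmx" else "gmt"
    text = path.read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines()]
    lib = MetaboliteSetLibrary()
    if dialect == "gmt":
        for i, line in enumerate(lines, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"{path}: malformed GMT line {i}: expected name, "
                    f"description and ≥1 member, got {len(parts)} field(s)")
            name, desc, *members = parts
            members = [m for m in members if m]
            if not members:
                raise ValidationError(f"{path}: set {name!r} on line {i} is empty")
            lib.add(MetaboliteSet(name=name, members=frozenset(members),
                                  description=desc))
    elif dialect == "gmx":
        grid = [ln.split("\t") for ln in lines if ln.strip()]
        if len(grid) < 3:
            raise ValidationError(f"{path}: GMX file needs ≥3 rows "
                                  "(names, descriptions, members)")
        width = max(len(r) for r in grid)
        cols = [[r[c] if c < len(r) else "" for r in grid] for c in range(width)]
        for c, col in enumerate(cols, 1):
            name, desc, *members = col
            if not name:
                raise ValidationError(f"{path}: GMX column {c} has no set name")
            members = [m for m in members if m]
            if not members:
                raise ValidationError(f"{path}: GMX set {name!r} is empty")
            lib.add(MetaboliteSet(name=name, members=frozenset(members),
                                  description=desc or "na"))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return lib
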
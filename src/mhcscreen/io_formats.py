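"""Tabular readers/writers and the validated domain types they produce.

All pipeline inputs are plain tab-separated text: a log2-scale expression
matrix (genes x samples), a clinical table (sample, time, event), a pair of
gene x pair protein-abundance matrices (normal / tumor), and GMT gene-set
files in the GSEA dialect (name, description, members).

Every reader validates at the boundary (unique identifiers, numeric cells,
missing-value policy) so downstream code can assume clean inputs.  Writers
emit a single ``#``-prefixed comment header recording the tool version and
any parameters; readers skip comment lines, so write-then-read round-trips
every type exactly for finite values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__

log = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "ClinicalTable",
    "PairedProteinTable",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_clinical",
    "write_clinical",
    "read_paired_protein",
    "write_paired_protein",
]


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Log2-scale expression, genes x samples.

    Invariants: gene and sample identifiers are unique, the value matrix is
    finite (missing-value policy is applied at load time), and its shape
    matches the identifier lists.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if vals.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"value matrix shape {vals.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(vals)):
            raise ValueError("expression matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not in expression matrix") from None

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_index(gene_id)]

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.gene_index(g) for g in gene_ids]
        return ExpressionMatrix(tuple(gene_ids), self.sample_ids, self.values[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(tuple(map(str, df.index)), tuple(map(str, df.columns)),
                   df.to_numpy(dtype=float))


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene identifiers (GMT line)."""

    name: str
    description: str = ""
    members: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.members

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ClinicalTable:
    """Per-sample follow-up: time in months, event flag (1 = death observed)."""

    sample_ids: tuple[str, ...]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        t = np.asarray(self.time, dtype=float)
        e = np.asarray(self.event, dtype=int)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "event", e)
        _check_unique(self.sample_ids, "sample")
        if t.shape != (len(self.sample_ids),) or e.shape != t.shape:
            raise ValueError("time/event length does not match sample_ids")
        if np.any(~np.isfinite(t)) or np.any(t < 0):
            bad = self.sample_ids[int(np.argmax(~np.isfinite(t) | (t < 0)))]
            raise ValueError(f"negative or non-finite survival time for sample {bad!r}")
        if not np.all(np.isin(e, (0, 1))):
            bad = self.sample_ids[int(np.argmax(~np.isin(e, (0, 1))))]
            raise ValueError(f"event flag not in {{0,1}} for sample {bad!r}")

    def __len__(self) -> int:
        return len(self.sample_ids)

    def subset(self, sample_ids: Sequence[str]) -> "ClinicalTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            idx = [pos[s] for s in sample_ids]
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not in clinical table") from None
        return ClinicalTable(tuple(sample_ids), self.time[idx], self.event[idx])


@dataclass(frozen=True)
class PairedProteinTable:
    """Matched tumor/normal protein abundances, genes x pairs.

    The two matrices share shape and indexing.  NaN marks a missing
    measurement; consumers drop pairs with a missing member per gene.
    """

    gene_ids: tuple[str, ...]
    pair_ids: tuple[str, ...]
    normal_values: np.ndarray
    tumor_values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "pair_ids", tuple(self.pair_ids))
        nv = np.asarray(self.normal_values, dtype=float)
        tv = np.asarray(self.tumor_values, dtype=float)
        object.__setattr__(self, "normal_values", nv)
        object.__setattr__(self, "tumor_values", tv)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.pair_ids, "pair")
        shape = (len(self.gene_ids), len(self.pair_ids))
        if nv.shape != shape or tv.shape != shape:
            raise ValueError(
                f"normal {nv.shape} and tumor {tv.shape} matrices must both be {shape}"
            )

    @property
    def n_pairs(self) -> int:
        return len(self.pair_ids)

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not in paired protein table") from None

    def swapped(self) -> "PairedProteinTable":
        """Return a table with the normal and tumor matrices exchanged."""
        return PairedProteinTable(
            self.gene_ids, self.pair_ids, self.tumor_values, self.normal_values
        )


# ---------------------------------------------------------------------------
# parsing helpers

def _float_repr(v: float) -> str:
    """Shortest round-trip decimal representation (exact write-then-read)."""
    return repr(float(v))


def _header_comment(params: Mapping[str, object] | None) -> str:
    parts = [f"mhcscreen={__version__}"]
    if params:
        parts.extend(f"{k}={params[k]}" for k in sorted(params))
    return "# " + " ".join(parts) + "\n"


def _read_table(path: str | Path, what: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0,
                     float_precision="round_trip")
    df.index = df.index.astype(str)
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate {what} identifier in {path}: {dup[0]!r}")
    dupc = df.columns[df.columns.duplicated()]
    if len(dupc):
        raise ValueError(f"duplicate column identifier in {path}: {dupc[0]!r}")
    return df


def _coerce_numeric(df: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    """Convert all cells to float, reporting the first offending cell.

    Numeric columns were already parsed losslessly by the reader; only
    object-dtype columns (which contain non-numeric text) need inspection.
    """
    df = df.copy()
    for c in df.columns:
        if df[c].dtype == object:
            coerced = pd.to_numeric(df[c], errors="coerce")
            bad = coerced.isna() & df[c].notna()
            if bad.any():
                r = df.index[bad][0]
                raise ValueError(
                    f"non-numeric value {df.loc[r, c]!r} at row {r!r}, "
                    f"column {c!r} in {path}"
                )
            df[c] = coerced
    return df.astype(float)


def read_expression(
    path: str | Path,
    missing_policy: str = "drop_gene",
    log2_transform: bool = False,
) -> ExpressionMatrix:
    """Load a genes x samples expression table.

    ``missing_policy`` handles genes with any missing value: ``drop_gene``
    removes them (count logged), ``error`` raises.  ``log2_transform``
    applies log2(x + 1) for inputs on a linear scale; by default values are
    assumed to be log2 already.
    """
    if missing_policy not in ("drop_gene", "error"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    df = _coerce_numeric(_read_table(path, "gene"), path)
    na_rows = df.isna().any(axis=1)
    if na_rows.any():
        if missing_policy == "error":
            bad = df.index[na_rows][0]
            raise ValueError(f"missing value in gene {bad!r} in {path}")
        log.warning("dropping %d gene(s) with missing values from %s",
                    int(na_rows.sum()), path)
        df = df.loc[~na_rows]
    vals = df.to_numpy(dtype=float)
    if log2_transform:
        if np.any(vals < 0):
            raise ValueError("log2 transform requested but matrix has negative values")
        vals = np.log2(vals + 1.0)
    return ExpressionMatrix(tuple(df.index), tuple(map(str, df.columns)), vals)


def write_expression(
    em: ExpressionMatrix, path: str | Path, params: Mapping[str, object] | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment(params))
        em.to_frame().to_csv(fh, sep="\t", index_label="gene_id", float_format=_float_repr)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>members...``."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f">=1 member ({len(fields)} field(s) found)"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            uniq = set(members)
            if len(uniq) < len(members):
                log.warning("%s:%d: %d duplicate member(s) in set %r dropped",
                            path, lineno, len(members) - len(uniq), name)
            sets.append(GeneSet(name=name, description=desc, members=frozenset(uniq)))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.members)]) + "\n")


def read_clinical(path: str | Path) -> ClinicalTable:
    """Load a clinical table with columns ``time`` and ``event`` indexed by sample."""
    df = _read_table(path, "sample")
    missing = {"time", "event"} - set(df.columns)
    if missing:
        raise ValueError(f"clinical table {path} missing column(s): {sorted(missing)}")
    df = _coerce_numeric(df[["time", "event"]], path)
    if df.isna().to_numpy().any():
        bad = df.index[df.isna().any(axis=1)][0]
        raise ValueError(f"missing clinical value for sample {bad!r} in {path}")
    return ClinicalTable(tuple(df.index), df["time"].to_numpy(),
                         df["event"].to_numpy())


def write_clinical(
    ct: ClinicalTable, path: str | Path, params: Mapping[str, object] | None = None
) -> None:
    df = pd.DataFrame({"time": ct.time, "event": ct.event}, index=list(ct.sample_ids))
    with open(path, "w") as fh:
        fh.write(_header_comment(params))
        df.to_csv(fh, sep="\t", index_label="sample_id", float_format=_float_repr)


def read_paired_protein(
    path_normal: str | Path, path_tumor: str | Path
) -> PairedProteinTable:
    """Load matched normal/tumor protein matrices; indices must agree exactly."""
    normal = _coerce_numeric(_read_table(path_normal, "gene"), path_normal)
    tumor = _coerce_numeric(_read_table(path_tumor, "gene"), path_tumor)
    if list(normal.index) != list(tumor.index):
        raise ValueError(
            f"gene identifiers disagree between {path_normal} and {path_tumor}"
        )
    if list(normal.columns) != list(tumor.columns):
        raise ValueError(
            f"pair identifiers disagree between {path_normal} and {path_tumor}"
        )
    return PairedProteinTable(
        tuple(normal.index), tuple(map(str, normal.columns)),
        normal.to_numpy(dtype=float), tumor.to_numpy(dtype=float),
    )


def write_paired_protein(
    ppt: PairedProteinTable,
    path_normal: str | Path,
    path_tumor: str | Path,
    params: Mapping[str, object] | None = None,
) -> None:
    for vals, path in ((ppt.normal_values, path_normal), (ppt.tumor_values, path_tumor)):
        df = pd.DataFrame(vals, index=list(ppt.gene_ids), columns=list(ppt.pair_ids))
        with open(path, "w") as fh:
            fh.write(_header_comment(params))
            df.to_csv(fh, sep="\t", index_label="gene_id", float_format=_float_repr)
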
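"""Constrained least-squares immune-cell deconvolution.

Bulk expression is modelled as a non-negative mixture of cell-type marker
profiles: per sample, solve  min ||S f - b||^2  subject to  f >= 0  with
:func:`scipy.optimize.nnls`, then close the composition with an "other"
component: other = max(0, 1 - sum(f)); if sum(f) > 1 the fractions are
rescaled to sum to 1 and other is 0.  Output rows therefore always lie on
the simplex.

The mixing model is linear in abundance, so log2-scale bulk input is
un-logged (2^x - 1) before solving.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .io_formats import ExpressionMatrix
from .survival_prognosis import StratifiedGroups, tertile_labels

__all__ = ["SignatureMatrix", "FractionTable", "nnls_fractions", "fraction_tertiles"]

OTHER = "other"


@dataclass(frozen=True)
class SignatureMatrix:
    """Marker-gene expression profiles per cell type (markers x types, linear scale)."""

    marker_gene_ids: tuple[str, ...]
    cell_type_names: tuple[str, ...]
    profiles: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "marker_gene_ids", tuple(self.marker_gene_ids))
        object.__setattr__(self, "cell_type_names", tuple(self.cell_type_names))
        prof = np.asarray(self.profiles, dtype=float)
        object.__setattr__(self, "profiles", prof)
        if len(set(self.marker_gene_ids)) != len(self.marker_gene_ids):
            raise ValueError("marker gene identifiers must be unique")
        if len(set(self.cell_type_names)) != len(self.cell_type_names):
            raise ValueError("cell type names must be unique")
        if prof.shape != (len(self.marker_gene_ids), len(self.cell_type_names)):
            raise ValueError("profile matrix shape does not match identifiers")
        if np.any(prof < 0):
            raise ValueError("signature profiles must be non-negative")
        zero = np.all(prof == 0, axis=0)
        if zero.any():
            bad = [t for t, z in zip(self.cell_type_names, zero) if z]
            raise ValueError(f"all-zero signature column(s): {bad}")
        if np.linalg.matrix_rank(prof) < len(self.cell_type_names):
            raise ValueError("signature matrix is rank-deficient")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.profiles, index=list(self.marker_gene_ids),
                            columns=list(self.cell_type_names))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SignatureMatrix":
        return cls(tuple(map(str, df.index)), tuple(map(str, df.columns)),
                   df.to_numpy(dtype=float))


@dataclass(frozen=True)
class FractionTable:
    """Estimated cell-type fractions per sample, closed with an "other" column."""

    sample_ids: tuple[str, ...]
    cell_type_names: tuple[str, ...]
    fractions: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "cell_type_names", tuple(self.cell_type_names))
        fr = np.asarray(self.fractions, dtype=float)
        object.__setattr__(self, "fractions", fr)
        if fr.shape != (len(self.sample_ids), len(self.cell_type_names)):
            raise ValueError("fraction matrix shape does not match identifiers")
        if np.any(fr < -1e-12):
            raise ValueError("fractions must be non-negative")
        if np.any(np.abs(fr.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("fraction rows must sum to 1")

    def column(self, cell_type: str) -> np.ndarray:
        try:
            j = self.cell_type_names.index(cell_type)
        except ValueError:
            raise KeyError(
                f"unknown cell type {cell_type!r}; have {self.cell_type_names}"
            ) from None
        return self.fractions[:, j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.fractions, index=list(self.sample_ids),
                            columns=list(self.cell_type_names))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FractionTable":
        return cls(tuple(map(str, df.index)), tuple(map(str, df.columns)),
                   df.to_numpy(dtype=float))


def nnls_fractions(
    bulk: ExpressionMatrix,
    sig: SignatureMatrix,
    linear_input: bool = False,
) -> FractionTable:
    """Estimate per-sample cell-type fractions by non-negative least squares.

    ``bulk`` is restricted to the signature's marker genes; a cell type whose
    signal vanishes on the shared markers, or a rank-deficient shared
    submatrix, is an error.  Log2 input is un-logged unless
    ``linear_input=True``.
    """
    shared = [g for g in sig.marker_gene_ids if g in set(bulk.gene_ids)]
    if not shared:
        raise ValueError("no signature marker genes found in bulk matrix")
    sig_df = sig.to_frame().loc[shared]
    S = sig_df.to_numpy()
    uncovered = [t for t, z in zip(sig.cell_type_names, np.all(S == 0, axis=0)) if z]
    if uncovered:
        raise ValueError(
            f"cell type(s) with no signal on shared markers: {uncovered}"
        )
    if np.linalg.matrix_rank(S) < len(sig.cell_type_names):
        raise ValueError("shared-marker signature submatrix is rank-deficient")
    B = bulk.subset_genes(shared).values
    if not linear_input:
        B = np.power(2.0, B) - 1.0
        B = np.maximum(B, 0.0)
    n_types = len(sig.cell_type_names)
    out = np.empty((bulk.n_samples, n_types + 1))
    for j in range(bulk.n_samples):
        f, _ = nnls(S, B[:, j])
        total = f.sum()
        if total > 1.0:
            f = f / total
            other = 0.0
        else:
            other = 1.0 - total
        out[j, :n_types] = f
        out[j, n_types] = other
    # snap tiny negative round-off and renormalise exactly
    out = np.maximum(out, 0.0)
    out /= out.sum(axis=1, keepdims=True)
    return FractionTable(bulk.sample_ids, sig.cell_type_names + (OTHER,), out)


def fraction_tertiles(fractions: FractionTable, cell_type: str) -> StratifiedGroups:
    """Top/bottom-third stratification of samples by one cell type's fraction."""
    return tertile_labels(fractions.sample_ids, fractions.column(cell_type))
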
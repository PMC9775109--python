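"""Anchor-panel co-expression screen and gene-set intersection logic.

Every gene in the expression matrix is correlated against a small panel of
anchor genes (antigen-presentation heavy/light chains plus peptide
transporters by default).  A gene is a hit for an anchor when its Pearson r
exceeds ``r_min`` in absolute value (strict) and its two-sided p-value is
below ``p_max`` (strict).  Per-anchor hit sets are then intersected, and the
surviving common set is overlapped with a pathway signature gene set.

The hit sets form a nested chain by construction:

    signature_overlap <= mhc_tap_common <= mhc_common & tap_common

and the anchors themselves are excluded from every hit set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix, GeneSet

log = logging.getLogger(__name__)

__all__ = [
    "AnchorPanel",
    "ScreenResult",
    "pearson_with_p",
    "correlate_all",
    "screen_anchor",
    "intersect_many",
    "run_screen",
]

DEFAULT_MHC_ANCHORS = ("HLA-A", "HLA-B", "HLA-C", "B2M")
DEFAULT_TAP_ANCHORS = ("TAP1", "TAP2")


class ConstantInputError(ValueError):
    """A vector with zero variance cannot be correlated."""


@dataclass(frozen=True)
class AnchorPanel:
    """The ordered anchor genes of the screen (disjoint MHC and TAP groups)."""

    mhc_anchors: tuple[str, ...] = DEFAULT_MHC_ANCHORS
    tap_anchors: tuple[str, ...] = DEFAULT_TAP_ANCHORS

    def __post_init__(self) -> None:
        object.__setattr__(self, "mhc_anchors", tuple(self.mhc_anchors))
        object.__setattr__(self, "tap_anchors", tuple(self.tap_anchors))
        if not self.mhc_anchors or not self.tap_anchors:
            raise ValueError("both anchor groups must be non-empty")
        if set(self.mhc_anchors) & set(self.tap_anchors):
            raise ValueError("MHC and TAP anchor groups must be disjoint")
        seen = self.mhc_anchors + self.tap_anchors
        if len(set(seen)) != len(seen):
            raise ValueError("anchor identifiers must be unique")

    @property
    def all_anchors(self) -> tuple[str, ...]:
        return self.mhc_anchors + self.tap_anchors


@dataclass(frozen=True)
class ScreenResult:
    """Per-anchor hit sets, their intersections, and the full record table."""

    per_anchor_hits: dict[str, GeneSet]
    mhc_common: GeneSet
    tap_common: GeneSet
    mhc_tap_common: GeneSet
    signature_overlap: GeneSet
    records: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        # nested-subset chain asserted on every construction
        if not self.signature_overlap.members <= self.mhc_tap_common.members:
            raise AssertionError("signature_overlap not within mhc_tap_common")
        if not self.mhc_tap_common.members <= (
            self.mhc_common.members & self.tap_common.members
        ):
            raise AssertionError("mhc_tap_common exceeds mhc_common & tap_common")


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, int]:
    """Pearson r with a two-sided p-value from the t distribution.

    r = sum((x-xbar)(y-ybar)) / sqrt(sum((x-xbar)^2) sum((y-ybar)^2)), and
    p is two-sided from t = r*sqrt((n-2)/(1-r^2)) with n-2 degrees of
    freedom; |r| = 1 yields p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        raise ConstantInputError("zero-variance input vector")
    r = float(np.clip((xc @ yc) / denom, -1.0, 1.0))
    if 1.0 - r * r <= 0.0:
        return r, 0.0, n
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return r, p, n


def _rank_rows(values: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, values)


def correlate_all(
    expr: ExpressionMatrix,
    anchor: str,
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlate every other gene against one anchor, vectorised.

    Returns a DataFrame with columns gene_id, anchor_id, r, p, n.  The
    anchor itself is excluded; zero-variance genes are skipped with a logged
    warning.  ``method`` is ``pearson`` or ``spearman`` (rank-transformed
    Pearson with the same t-based p-value).
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    a_idx = expr.gene_index(anchor)
    n = expr.n_samples
    if n < 3:
        raise ValueError(f"need at least 3 samples, got {n}")
    values = expr.values
    if method == "spearman":
        values = _rank_rows(values)
    y = values[a_idx]
    yc = y - y.mean()
    y_ss = float(yc @ yc)
    if y_ss == 0.0:
        raise ConstantInputError(f"anchor {anchor!r} has zero variance")

    keep = np.ones(expr.n_genes, dtype=bool)
    keep[a_idx] = False
    X = values[keep]
    Xc = X - X.mean(axis=1, keepdims=True)
    x_ss = np.einsum("ij,ij->i", Xc, Xc)
    nonconst = x_ss > 0
    n_const = int((~nonconst).sum())
    if n_const:
        log.warning("skipping %d zero-variance gene(s) against anchor %s",
                    n_const, anchor)
    gene_ids = np.array(expr.gene_ids, dtype=object)[keep][nonconst]
    Xc = Xc[nonconst]
    x_ss = x_ss[nonconst]

    r = np.clip((Xc @ yc) / np.sqrt(x_ss * y_ss), -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p[np.abs(r) >= 1.0] = 0.0
    return pd.DataFrame(
        {"gene_id": gene_ids, "anchor_id": anchor, "r": r, "p": p, "n": n}
    )


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adj, 1.0)
    return out


def screen_anchor(
    expr: ExpressionMatrix,
    anchor: str,
    r_min: float = 0.3,
    p_max: float = 0.05,
    method: str = "pearson",
    adjust: str | None = None,
    records: pd.DataFrame | None = None,
) -> GeneSet:
    """Genes passing |r| > r_min (strict) and p < p_max (strict) for one anchor.

    ``adjust='bh'`` applies Benjamini-Hochberg across all genes of this
    anchor before the p threshold.  A precomputed ``records`` table from
    :func:`correlate_all` may be supplied to avoid recomputation.
    """
    if records is None:
        records = correlate_all(expr, anchor, method=method)
    p = records["p"].to_numpy()
    if adjust == "bh":
        p = _bh_adjust(p)
    elif adjust is not None:
        raise ValueError(f"unknown p adjustment {adjust!r}")
    r = records["r"].to_numpy()
    mask = (np.abs(r) > r_min) & (p < p_max)
    return GeneSet(
        name=f"hits_{anchor}",
        description=f"|r|>{r_min}, p<{p_max} vs {anchor}",
        members=frozenset(records["gene_id"].to_numpy()[mask]),
    )


def intersect_many(sets: Sequence[GeneSet], name: str = "intersection") -> GeneSet:
    """Exact, order-independent intersection of one or more gene sets."""
    if not sets:
        raise ValueError("need at least one gene set to intersect")
    members = frozenset.intersection(*(frozenset(s.members) for s in sets))
    return GeneSet(name=name, description=f"intersection of {len(sets)} sets",
                   members=members)


def run_screen(
    expr: ExpressionMatrix,
    panel: AnchorPanel,
    signature: GeneSet,
    r_min: float = 0.3,
    p_max: float = 0.05,
    method: str = "pearson",
    adjust: str | None = None,
) -> ScreenResult:
    """Run the full anchor-panel screen.

    Per-anchor hit sets are intersected within the MHC group and within the
    TAP group, the two common sets are intersected, and the result is
    overlapped with the ``signature`` members.  Anchor genes are removed
    from every hit set.
    """
    missing = [a for a in panel.all_anchors if a not in expr.gene_ids]
    if missing:
        raise KeyError(f"anchor gene(s) absent from expression matrix: {missing}")
    anchors = set(panel.all_anchors)
    per_anchor: dict[str, GeneSet] = {}
    frames = []
    for anchor in panel.all_anchors:
        recs = correlate_all(expr, anchor, method=method)
        frames.append(recs)
        hits = screen_anchor(expr, anchor, r_min=r_min, p_max=p_max,
                             adjust=adjust, records=recs)
        per_anchor[anchor] = GeneSet(hits.name, hits.description,
                                     hits.members - anchors)
    mhc_common = intersect_many([per_anchor[a] for a in panel.mhc_anchors],
                                name="mhc_common")
    tap_common = intersect_many([per_anchor[a] for a in panel.tap_anchors],
                                name="tap_common")
    mhc_tap_common = intersect_many([mhc_common, tap_common], name="mhc_tap_common")
    overlap = GeneSet(name="signature_overlap",
                      description=f"mhc_tap_common & {signature.name}",
                      members=mhc_tap_common.members & signature.members)
    records = pd.concat(frames, ignore_index=True)
    return ScreenResult(
        per_anchor_hits=per_anchor,
        mhc_common=mhc_common,
        tap_common=tap_common,
        mhc_tap_common=mhc_tap_common,
        signature_overlap=overlap,
        records=records,
    )
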
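"""Paired tumor/normal proteomic disparity statistic and candidate filtering.

For each gene, every tumor/normal pair is classified by the sign of
(normal - tumor): pairs where the normal tissue has the higher abundance
count toward ``n_high_normal``, the rest toward ``n_high_cancer``.  Exact
ties are handled by a configurable policy (default: excluded, shrinking the
informative-pair denominator).  Fractions are percentages of informative
pairs, rounded half-up to two decimals.

Candidate filtering keeps genes that survived the co-expression screen, are
differentially expressed at the protein level, and show a high-in-normal
fraction at or above a threshold; survivors are ranked by that fraction.

A small packaged table (``data/paired_dominance_counts.tsv``) records
published per-gene dominance counts over 97 tumor/normal pairs for a set of
interferon-pathway candidate genes; it is used for validation and the
acceptance report.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneSet, PairedProteinTable

__all__ = [
    "DisparityRecord",
    "disparity",
    "disparity_all",
    "record_from_counts",
    "paired_table_from_counts",
    "filter_candidates",
    "load_published_counts",
]

TIE_POLICIES = ("exclude", "cancer", "normal")


def _round2(x: float) -> float:
    """Round half-up to two decimals (printed-table convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class DisparityRecord:
    """Per-gene dominance counts and percentages over informative pairs."""

    gene_id: str
    n_high_normal: int
    frac_normal: float
    n_high_cancer: int
    frac_cancer: float
    n_pairs_used: int

    def __post_init__(self) -> None:
        if self.n_high_normal + self.n_high_cancer != self.n_pairs_used:
            raise ValueError(
                f"{self.gene_id}: counts {self.n_high_normal}+{self.n_high_cancer} "
                f"do not sum to n_pairs_used={self.n_pairs_used}"
            )
        if abs(self.frac_normal + self.frac_cancer - 100.0) > 0.011:
            raise ValueError(f"{self.gene_id}: fractions do not sum to 100")


def record_from_counts(gene_id: str, n_high_normal: int, n_high_cancer: int) -> DisparityRecord:
    """Build a record directly from dominance counts."""
    n = n_high_normal + n_high_cancer
    if n < 1:
        raise ValueError("no informative pairs")
    return DisparityRecord(
        gene_id=gene_id,
        n_high_normal=n_high_normal,
        frac_normal=_round2(100.0 * n_high_normal / n),
        n_high_cancer=n_high_cancer,
        frac_cancer=_round2(100.0 * n_high_cancer / n),
        n_pairs_used=n,
    )


def disparity(
    table: PairedProteinTable, gene_id: str, tie_policy: str = "exclude"
) -> DisparityRecord:
    """Classify each pair of one gene by which tissue has the higher abundance.

    Pairs with a missing member are dropped.  Ties go to neither side
    (``exclude``, reducing the denominator), to the cancer side, or to the
    normal side, per ``tie_policy``.
    """
    if tie_policy not in TIE_POLICIES:
        raise ValueError(f"unknown tie_policy {tie_policy!r}; choose from {TIE_POLICIES}")
    i = table.gene_index(gene_id)
    normal = table.normal_values[i]
    tumor = table.tumor_values[i]
    ok = np.isfinite(normal) & np.isfinite(tumor)
    if not ok.any():
        raise ValueError(f"{gene_id}: no pair with both values present")
    diff = normal[ok] - tumor[ok]
    n_normal = int(np.sum(diff > 0))
    n_cancer = int(np.sum(diff < 0))
    n_ties = int(np.sum(diff == 0))
    if tie_policy == "cancer":
        n_cancer += n_ties
    elif tie_policy == "normal":
        n_normal += n_ties
    if n_normal + n_cancer == 0:
        raise ValueError(f"{gene_id}: no informative pairs (all tied)")
    return record_from_counts(gene_id, n_normal, n_cancer)


def disparity_all(
    table: PairedProteinTable,
    gene_ids: Sequence[str] | None = None,
    tie_policy: str = "exclude",
) -> list[DisparityRecord]:
    """Disparity records for several genes (all genes in the table by default)."""
    if gene_ids is None:
        gene_ids = table.gene_ids
    return [disparity(table, g, tie_policy=tie_policy) for g in gene_ids]


def paired_table_from_counts(
    counts: dict[str, tuple[int, int]],
    rng: np.random.Generator | None = None,
    shift: float = 1.0,
) -> PairedProteinTable:
    """Construct a paired table realising given per-gene dominance counts.

    For each gene with counts (a, b), a + b pairs are generated; a of them
    are normal-dominant by ``shift`` and b tumor-dominant.  Which pair
    positions are normal-dominant is randomised when ``rng`` is given, so
    the statistic must be recomputed from values rather than echoed.
    """
    genes = list(counts)
    n_pairs = {g: sum(counts[g]) for g in genes}
    width = max(n_pairs.values())
    pair_ids = tuple(f"P{i + 1:03d}" for i in range(width))
    normal = np.full((len(genes), width), np.nan)
    tumor = np.full((len(genes), width), np.nan)
    for i, g in enumerate(genes):
        a, b = counts[g]
        n = a + b
        base = rng.normal(10.0, 1.0, size=n) if rng is not None else np.full(n, 10.0)
        dom = np.r_[np.ones(a, dtype=bool), np.zeros(b, dtype=bool)]
        if rng is not None:
            rng.shuffle(dom)
        tumor[i, :n] = base
        normal[i, :n] = base + np.where(dom, shift, -shift)
    return PairedProteinTable(tuple(genes), pair_ids, normal, tumor)


def filter_candidates(
    screen=None,
    disparities: Iterable[DisparityRecord] = (),
    de_genes: GeneSet | None = None,
    min_frac_normal: float = 70.0,
) -> pd.DataFrame:
    """Final candidate table: screen survivors, differentially expressed at the
    protein level, with frac_normal >= ``min_frac_normal``.

    ``screen`` (a :class:`~mhcscreen.coexpression_screen.ScreenResult`, or a
    plain set of screen-surviving gene ids) and ``de_genes`` may each be
    None to skip that restriction.  Rows are ranked by frac_normal
    descending, gene id ascending on ties.
    """
    rows = []
    if screen is None:
        in_sig = None
    elif hasattr(screen, "signature_overlap"):
        in_sig = screen.signature_overlap.members
    else:
        in_sig = frozenset(screen)
    for rec in disparities:
        in_screen = in_sig is None or rec.gene_id in in_sig
        in_de = de_genes is None or rec.gene_id in de_genes
        if in_screen and in_de and rec.frac_normal >= min_frac_normal:
            rows.append(
                {
                    "gene_id": rec.gene_id,
                    "n_high_normal": rec.n_high_normal,
                    "frac_normal": rec.frac_normal,
                    "n_high_cancer": rec.n_high_cancer,
                    "frac_cancer": rec.frac_cancer,
                    "n_pairs_used": rec.n_pairs_used,
                    "in_screen": in_sig is not None,
                    "differentially_expressed": de_genes is not None,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "n_high_normal", "frac_normal", "n_high_cancer",
            "frac_cancer", "n_pairs_used", "in_screen", "differentially_expressed",
        ],
    )
    if len(df):
        df = df.sort_values(
            ["frac_normal", "gene_id"], ascending=[False, True]
        ).reset_index(drop=True)
    return df


def load_published_counts() -> pd.DataFrame:
    """Published per-gene dominance counts over 97 tumor/normal pairs.

    Columns: gene_id, n_high_normal, frac_normal_printed, n_high_cancer,
    frac_cancer_printed.  One row (HLA-DMB) is internally inconsistent in
    the source (counts sum to 96, printed fractions use 97) and is flagged
    by the ``consistent`` column.
    """
    with resources.files("mhcscreen.data").joinpath(
        "paired_dominance_counts.tsv"
    ).open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    df["consistent"] = (df["n_high_normal"] + df["n_high_cancer"]) == 97
    return df
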
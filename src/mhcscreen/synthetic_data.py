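"""Synthetic pipeline inputs with planted ground truth.

Generates, from one integer seed, a coherent trio of inputs:

* a bulk log2 expression matrix whose marker genes are a linear mixture of a
  cell-type signature with Dirichlet fractions, whose anchor genes share a
  latent per-sample factor, whose planted regulator genes are coupled to
  that factor with a chosen target correlation, and whose remaining genes
  are independent noise;
* exponential survival times whose hazard decreases with the standardized
  mean anchor expression (higher antigen-presentation score is protective),
  with independent uniform censoring;
* a paired tumor/normal protein table in which each gene's pairs are
  normal-dominant with a planted per-gene probability.

The seed fans out through :class:`numpy.random.SeedSequence` substreams, one
per component, so e.g. enlarging the noise-gene block does not perturb the
survival draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .coexpression_screen import AnchorPanel
from .deconvolution import SignatureMatrix
from .io_formats import ClinicalTable, ExpressionMatrix, PairedProteinTable

__all__ = [
    "SyntheticTruth",
    "make_signature_matrix",
    "make_bulk_dataset",
    "DEFAULT_CELL_TYPES",
]

DEFAULT_CELL_TYPES = (
    "B", "CD4_T", "CD8_T", "DC", "M1", "Monocyte", "Neutrophil", "NK", "Treg",
)

# substream labels, in a frozen order; new components must append, not insert
_STREAMS = (
    "fractions", "markers", "latent", "anchors", "regulators", "noise",
    "survival", "censoring", "protein",
)


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(_STREAMS, children)}


@dataclass
class SyntheticTruth:
    """Planted structure of a synthetic dataset.

    ``coupling_strength`` maps each planted regulator to its target
    correlation with the latent anchor factor (in [0, 1); 0 plants a null
    gene).  ``disparity_prob`` maps genes to the probability that a
    tumor/normal pair is normal-dominant; unlisted genes use
    ``background_disparity_prob``.  ``true_fractions`` is filled in by
    :func:`make_bulk_dataset`.
    """

    planted_regulators: tuple[str, ...]
    coupling_strength: Mapping[str, float]
    hazard_beta: float
    disparity_prob: Mapping[str, float]
    seed: int
    background_disparity_prob: float = 0.5
    true_fractions: np.ndarray | None = None
    cell_type_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.planted_regulators = tuple(self.planted_regulators)
        self.coupling_strength = dict(self.coupling_strength)
        self.disparity_prob = dict(self.disparity_prob)
        missing = set(self.planted_regulators) - set(self.coupling_strength)
        if missing:
            raise ValueError(f"planted regulator(s) without coupling: {sorted(missing)}")
        for g, c in self.coupling_strength.items():
            if not 0.0 <= c < 1.0:
                raise ValueError(f"coupling for {g!r} must be in [0, 1), got {c}")
        for g, p in self.disparity_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"disparity_prob for {g!r} must be in [0, 1], got {p}")
        if self.true_fractions is not None:
            self._check_fractions()

    def _check_fractions(self) -> None:
        fr = np.asarray(self.true_fractions)
        if np.any(fr < 0) or np.any(np.abs(fr.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("true_fractions rows must lie on the simplex")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_regulators": list(self.planted_regulators),
            "coupling_strength": self.coupling_strength,
            "hazard_beta": self.hazard_beta,
            "disparity_prob": self.disparity_prob,
            "seed": self.seed,
            "background_disparity_prob": self.background_disparity_prob,
            "cell_type_names": list(self.cell_type_names),
            "true_fractions": None
            if self.true_fractions is None
            else np.asarray(self.true_fractions).tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        tf = d.pop("true_fractions")
        obj = cls(
            planted_regulators=tuple(d["planted_regulators"]),
            coupling_strength=d["coupling_strength"],
            hazard_beta=d["hazard_beta"],
            disparity_prob=d["disparity_prob"],
            seed=d["seed"],
            background_disparity_prob=d["background_disparity_prob"],
            cell_type_names=tuple(d["cell_type_names"]),
        )
        if tf is not None:
            obj.true_fractions = np.asarray(tf)
            obj._check_fractions()
        return obj


def make_signature_matrix(
    n_markers_per_type: int,
    n_types: int,
    seed: int,
    fold: float = 16.0,
    cell_types: tuple[str, ...] | None = None,
) -> SignatureMatrix:
    """Lognormal marker profiles, high (by ``fold``) in the marker's own type.

    Construction guarantees full column rank: each type owns a block of
    markers dominating its own column.
    """
    if n_types < 2:
        raise ValueError(f"need at least 2 cell types, got {n_types}")
    if n_markers_per_type < 1:
        raise ValueError("need at least 1 marker per type")
    if cell_types is None:
        cell_types = DEFAULT_CELL_TYPES[:n_types]
        if len(cell_types) < n_types:
            cell_types = cell_types + tuple(
                f"type_{k}" for k in range(len(cell_types), n_types)
            )
    elif len(cell_types) != n_types:
        raise ValueError("cell_types length must equal n_types")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    markers = tuple(
        f"{ct}_M{i + 1}" for ct in cell_types for i in range(n_markers_per_type)
    )
    prof = rng.lognormal(mean=0.0, sigma=0.25, size=(len(markers), n_types))
    for j in range(n_types):
        rows = slice(j * n_markers_per_type, (j + 1) * n_markers_per_type)
        prof[rows, j] *= fold
    return SignatureMatrix(markers, tuple(cell_types), prof)


def make_bulk_dataset(
    truth: SyntheticTruth,
    anchors: AnchorPanel,
    sig: SignatureMatrix,
    n_samples: int,
    n_noise_genes: int = 1000,
    noise_sd: float = 0.3,
    seed: int | None = None,
    dirichlet_alpha: float = 1.0,
    n_pairs: int = 97,
    baseline_hazard: float = np.log(2) / 40.0,
    censor_tmax: float = 120.0,
    disparity_shift: float = 1.0,
) -> tuple[ExpressionMatrix, ClinicalTable, PairedProteinTable]:
    """Generate the bulk expression matrix, clinical table and paired protein table.

    Mutates ``truth`` in place to record the drawn cell-type fractions.  See
    the module docstring for the generative model.  ``baseline_hazard`` is
    the event rate at score 0 (default: median survival 40 months there);
    censoring is uniform on (0, ``censor_tmax``], roughly 30% censored at
    the defaults.
    """
    if n_samples < 20:
        raise ValueError(f"need n_samples >= 20 for survival realism, got {n_samples}")
    seed = truth.seed if seed is None else seed
    rngs = _rngs(seed)

    marker_ids = sig.marker_gene_ids
    anchor_ids = anchors.all_anchors
    planted_ids = truth.planted_regulators
    noise_ids = tuple(f"NOISE{i + 1:05d}" for i in range(n_noise_genes))
    non_anchor = set(marker_ids) | set(planted_ids) | set(noise_ids)
    clash = set(anchor_ids) & non_anchor
    if clash:
        raise ValueError(f"anchor id(s) collide with other gene blocks: {sorted(clash)}")
    dup = (
        len(marker_ids) + len(anchor_ids) + len(planted_ids) + len(noise_ids)
        != len(non_anchor | set(anchor_ids))
    )
    if dup:
        raise ValueError("gene blocks overlap; identifiers must be disjoint")

    n_types = len(sig.cell_type_names)
    F = rngs["fractions"].dirichlet(np.full(n_types, dirichlet_alpha), size=n_samples)
    truth.true_fractions = F
    truth.cell_type_names = sig.cell_type_names
    truth._check_fractions()

    # marker block: linear mixture, then log2 with additive noise on log scale
    mix = sig.profiles @ F.T
    marker_vals = np.log2(mix + 1.0) + noise_sd * rngs["markers"].standard_normal(
        mix.shape
    )

    L = rngs["latent"].standard_normal(n_samples)

    anchor_vals = 8.0 + L + noise_sd * rngs["anchors"].standard_normal(
        (len(anchor_ids), n_samples)
    )

    reg_rng = rngs["regulators"]
    reg_vals = np.empty((len(planted_ids), n_samples))
    for i, g in enumerate(planted_ids):
        c = truth.coupling_strength[g]
        eps = reg_rng.standard_normal(n_samples)
        reg_vals[i] = 6.0 + c * L + np.sqrt(1.0 - c * c) * eps

    noise_vals = 5.0 + rngs["noise"].standard_normal((n_noise_genes, n_samples))

    gene_ids = marker_ids + anchor_ids + planted_ids + noise_ids
    values = np.vstack([marker_vals, anchor_vals, reg_vals, noise_vals])
    sample_ids = tuple(f"S{i + 1:04d}" for i in range(n_samples))
    expr = ExpressionMatrix(gene_ids, sample_ids, values)

    # survival: hazard = baseline * exp(-beta * score), score = standardized
    # mean anchor expression (higher antigen presentation -> lower hazard)
    anchor_mean = anchor_vals.mean(axis=0)
    score = (anchor_mean - anchor_mean.mean()) / anchor_mean.std()
    scale = np.exp(truth.hazard_beta * score) / baseline_hazard
    t_event = np.maximum(rngs["survival"].exponential(scale), 1e-12)
    t_censor = rngs["censoring"].uniform(1e-9, censor_tmax, size=n_samples)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    clinical = ClinicalTable(sample_ids, time, event)

    prot_rng = rngs["protein"]
    pair_ids = tuple(f"P{i + 1:03d}" for i in range(n_pairs))
    tumor = prot_rng.normal(10.0, 1.0, size=(len(gene_ids), n_pairs))
    probs = np.array(
        [
            truth.disparity_prob.get(g, truth.background_disparity_prob)
            for g in gene_ids
        ]
    )
    dominant = prot_rng.random((len(gene_ids), n_pairs)) < probs[:, None]
    normal = tumor + np.where(dominant, disparity_shift, -disparity_shift)
    protein = PairedProteinTable(gene_ids, pair_ids, normal, tumor)

    return expr, clinical, protein
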
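"""End-to-end orchestration: simulate -> deconvolve -> screen -> disparity
-> survival/ROC, with a manifest recording parameters and file checksums.

Each stage reads its inputs from disk and writes its outputs under the run
directory, so any downstream stage can be resumed from the artifacts alone.
Identical config + seed produces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coexpression_screen import AnchorPanel, run_screen
from .deconvolution import SignatureMatrix, nnls_fractions
from .io_formats import (
    GeneSet,
    read_clinical,
    read_expression,
    read_gmt,
    read_paired_protein,
    write_clinical,
    write_expression,
    write_gmt,
    write_paired_protein,
)
from .proteomic_disparity import disparity_all, filter_candidates
from .survival_prognosis import (
    combined_stratify,
    expression_tertiles,
    km_estimate,
    logrank,
    prognostic_roc,
    tertile_labels,
)
from .synthetic_data import SyntheticTruth, make_bulk_dataset, make_signature_matrix

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "StageError", "run_all", "STAGES"]

STAGES = ("simulate", "deconvolve", "screen", "disparity", "survival")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """All knobs of one pipeline run; round-trips to/from YAML."""

    seed: int = 0
    # simulation
    n_samples: int = 459
    n_noise_genes: int = 300
    noise_sd: float = 0.3
    n_types: int = 6
    n_markers_per_type: int = 5
    dirichlet_alpha: float = 1.0
    planted_regulators: tuple[str, ...] = ("REG1", "REG2", "REG3")
    coupling: float = 0.8
    disparity_prob: float = 0.8
    background_disparity_prob: float = 0.5
    hazard_beta: float = 0.5
    n_pairs: int = 97
    censor_tmax: float = 120.0
    signature_size: int = 100
    de_genes_size: int = 100
    # screen
    mhc_anchors: tuple[str, ...] = ("HLA-A", "HLA-B", "HLA-C", "B2M")
    tap_anchors: tuple[str, ...] = ("TAP1", "TAP2")
    r_min: float = 0.3
    p_max: float = 0.05
    method: str = "pearson"
    # disparity
    min_frac_normal: float = 70.0
    tie_policy: str = "exclude"
    # survival / ROC
    mhc_composite_genes: tuple[str, ...] = ("HLA-A", "HLA-B", "HLA-C")
    t_cell_types: tuple[str, ...] = ("CD4_T", "CD8_T")
    roc_horizon: float = 60.0
    # io
    missing_policy: str = "drop_gene"

    def __post_init__(self) -> None:
        if not 0.0 <= self.coupling < 1.0:
            raise ValueError("coupling must be in [0, 1)")
        if not (0.0 <= self.p_max <= 1.0 and self.r_min >= 0.0):
            raise ValueError("thresholds out of range")
        if not 0.0 <= self.min_frac_normal <= 100.0:
            raise ValueError("min_frac_normal must be a percentage")
        for name in ("planted_regulators", "mhc_anchors", "tap_anchors",
                     "mhc_composite_genes", "t_cell_types"):
            setattr(self, name, tuple(getattr(self, name)))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**dict(raw))

    def anchor_panel(self) -> AnchorPanel:
        return AnchorPanel(self.mhc_anchors, self.tap_anchors)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_gene_list(genes: Sequence[str], path: Path) -> None:
    path.write_text("".join(f"{g}\n" for g in sorted(genes)))


def _read_gene_list(path: Path) -> frozenset[str]:
    return frozenset(line.strip() for line in path.read_text().splitlines() if line.strip())


def _groups_frame(named_groups: Mapping[str, Mapping[str, str]], sample_ids) -> pd.DataFrame:
    return pd.DataFrame(
        {name: [labels[s] for s in sample_ids] for name, labels in named_groups.items()},
        index=list(sample_ids),
    )


def _stage_simulate(config: RunConfig, out: Path) -> None:
    sig = make_signature_matrix(
        config.n_markers_per_type, config.n_types, seed=config.seed
    )
    truth = SyntheticTruth(
        planted_regulators=config.planted_regulators,
        coupling_strength={g: config.coupling for g in config.planted_regulators},
        hazard_beta=config.hazard_beta,
        disparity_prob={g: config.disparity_prob for g in config.planted_regulators},
        seed=config.seed,
        background_disparity_prob=config.background_disparity_prob,
    )
    expr, clinical, protein = make_bulk_dataset(
        truth,
        config.anchor_panel(),
        sig,
        n_samples=config.n_samples,
        n_noise_genes=config.n_noise_genes,
        noise_sd=config.noise_sd,
        dirichlet_alpha=config.dirichlet_alpha,
        n_pairs=config.n_pairs,
        censor_tmax=config.censor_tmax,
    )
    params = {"seed": config.seed}
    write_expression(expr, out / "expr.tsv", params)
    write_clinical(clinical, out / "clinical.tsv", params)
    write_paired_protein(protein, out / "protein_normal.tsv",
                         out / "protein_tumor.tsv", params)
    with open(out / "signature_matrix.tsv", "w") as fh:
        fh.write(f"# mhcscreen={__version__} seed={config.seed}\n")
        sig.to_frame().to_csv(fh, sep="\t", index_label="marker_id")
    truth.to_json(out / "truth.json")

    # pathway signature and differentially-expressed sets: the planted
    # regulators plus seeded draws from the noise block (distinct substream
    # from the dataset's own streams)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7001]))
    noise_ids = [g for g in expr.gene_ids if g.startswith("NOISE")]
    def _planted_plus(size: int) -> list[str]:
        extra = min(max(size - len(config.planted_regulators), 0), len(noise_ids))
        picked = rng.choice(noise_ids, size=extra, replace=False) if extra else []
        return sorted(set(config.planted_regulators) | set(picked))

    signature = GeneSet("pathway_signature", "simulated pathway gene set",
                        frozenset(_planted_plus(config.signature_size)))
    de_genes = _planted_plus(config.de_genes_size)
    write_gmt([signature], out / "signature.gmt")
    _write_gene_list(de_genes, out / "de_genes.txt")


def _stage_deconvolve(config: RunConfig, out: Path) -> None:
    expr = read_expression(out / "expr.tsv", missing_policy=config.missing_policy)
    sig = SignatureMatrix.from_frame(
        pd.read_csv(out / "signature_matrix.tsv", sep="\t", comment="#", index_col=0)
    )
    fractions = nnls_fractions(expr, sig)
    with open(out / "fractions.tsv", "w") as fh:
        fh.write(f"# mhcscreen={__version__} seed={config.seed}\n")
        fractions.to_frame().to_csv(fh, sep="\t", index_label="sample_id")


def _stage_screen(config: RunConfig, out: Path) -> None:
    expr = read_expression(out / "expr.tsv", missing_policy=config.missing_policy)
    signature = read_gmt(out / "signature.gmt")[0]
    result = run_screen(
        expr, config.anchor_panel(), signature,
        r_min=config.r_min, p_max=config.p_max, method=config.method,
    )
    sdir = out / "screen"
    sdir.mkdir(exist_ok=True)
    with open(sdir / "records.tsv", "w") as fh:
        fh.write(f"# mhcscreen={__version__} r_min={config.r_min} p_max={config.p_max}\n")
        result.records.to_csv(fh, sep="\t", index=False)
    for anchor, hits in result.per_anchor_hits.items():
        _write_gene_list(sorted(hits.members), sdir / f"hits_{anchor}.txt")
    for name in ("mhc_common", "tap_common", "mhc_tap_common", "signature_overlap"):
        _write_gene_list(sorted(getattr(result, name).members), sdir / f"{name}.txt")


def _stage_disparity(config: RunConfig, out: Path) -> None:
    protein = read_paired_protein(out / "protein_normal.tsv", out / "protein_tumor.tsv")
    overlap = _read_gene_list(out / "screen" / "signature_overlap.txt")
    de = _read_gene_list(out / "de_genes.txt")
    records = disparity_all(protein, tie_policy=config.tie_policy)
    disp_df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    with open(out / "disparity.tsv", "w") as fh:
        fh.write(f"# mhcscreen={__version__} tie_policy={config.tie_policy}\n")
        disp_df.to_csv(fh, sep="\t", index=False)
    candidates = filter_candidates(
        screen=overlap,
        disparities=records,
        de_genes=GeneSet("de", "differentially expressed", de),
        min_frac_normal=config.min_frac_normal,
    )
    with open(out / "candidates.tsv", "w") as fh:
        fh.write(
            f"# mhcscreen={__version__} min_frac_normal={config.min_frac_normal}\n"
        )
        candidates.to_csv(fh, sep="\t", index=False)


def _stage_survival(config: RunConfig, out: Path) -> None:
    expr = read_expression(out / "expr.tsv", missing_policy=config.missing_policy)
    clinical = read_clinical(out / "clinical.tsv")
    fr_df = pd.read_csv(out / "fractions.tsv", sep="\t", comment="#", index_col=0)

    mhc_score = expr.subset_genes(list(config.mhc_composite_genes)).values.mean(axis=0)
    missing = [t for t in config.t_cell_types if t not in fr_df.columns]
    if missing:
        raise KeyError(f"cell type(s) absent from fraction table: {missing}")
    t_score = (
        fr_df.loc[list(expr.sample_ids), list(config.t_cell_types)].sum(axis=1).to_numpy()
    )

    mhc_groups = tertile_labels(expr.sample_ids, mhc_score)
    t_groups = tertile_labels(expr.sample_ids, t_score)
    combined = combined_stratify(mhc_groups, t_groups)
    named = {"mhc": mhc_groups, "t_cell": t_groups, "combined": combined}

    groups_df = _groups_frame({k: v.labels for k, v in named.items()}, expr.sample_ids)
    with open(out / "groups.tsv", "w") as fh:
        fh.write(f"# mhcscreen={__version__}\n")
        groups_df.to_csv(fh, sep="\t", index_label="sample_id")

    lr_rows = []
    for name, groups in named.items():
        high = clinical.subset(groups.high)
        low = clinical.subset(groups.low)
        res = logrank(high, low)
        lr_rows.append(
            {
                "stratification": name,
                "chi_square": res.chi_square,
                "df": res.df,
                "p": res.p,
                "observed_high": res.observed[0],
                "observed_low": res.observed[1],
                "expected_high": res.expected[0],
                "expected_low": res.expected[1],
            }
        )
        for label, sub in (("high", high), ("low", low)):
            km = km_estimate(sub)
            km_df = pd.DataFrame(
                {
                    "time": km.event_times,
                    "survival": km.survival,
                    "at_risk": km.at_risk,
                    "n_events": km.n_events,
                }
            )
            with open(out / f"km_{name}_{label}.tsv", "w") as fh:
                fh.write(f"# mhcscreen={__version__} stratification={name} group={label}\n")
                km_df.to_csv(fh, sep="\t", index=False)
    with open(out / "logrank.tsv", "w") as fh:
        fh.write(f"# mhcscreen={__version__}\n")
        pd.DataFrame(lr_rows).to_csv(fh, sep="\t", index=False)

    def _z(x: np.ndarray) -> np.ndarray:
        return (x - x.mean()) / x.std()

    scores = {
        "mhc": mhc_score,
        "t_cell": t_score,
        "combined": _z(mhc_score) + _z(t_score),
    }
    roc_rows = []
    for name, score in scores.items():
        roc = prognostic_roc(expr.sample_ids, score, clinical,
                             horizon_months=config.roc_horizon)
        roc_rows.append(
            {
                "score": name,
                "auc": roc.auc,
                "horizon_months": roc.horizon_months,
                "n_cases": roc.n_cases,
                "n_controls": roc.n_controls,
            }
        )
    with open(out / "roc.tsv", "w") as fh:
        fh.write(f"# mhcscreen={__version__} horizon={config.roc_horizon}\n")
        pd.DataFrame(roc_rows).to_csv(fh, sep="\t", index=False)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "deconvolve": _stage_deconvolve,
    "screen": _stage_screen,
    "disparity": _stage_disparity,
    "survival": _stage_survival,
}


def run_all(config: RunConfig, outdir: str | Path) -> Path:
    """Execute every stage in order into ``outdir`` and write a manifest.

    The manifest lists the stages run, the full config, and a sha256
    checksum for every artifact; outputs are deterministic given the config.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    for stage in STAGES:
        log.info("running stage %s", stage)
        try:
            _STAGE_FUNCS[stage](config, out)
        except Exception as exc:  # noqa: BLE001 - rewrap with stage context
            raise StageError(stage, exc) from exc
    files = sorted(
        str(p.relative_to(out))
        for p in out.rglob("*")
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "version": __version__,
        "stages": list(STAGES),
        "config": config.to_dict(),
        "files": {f: _sha256(out / f) for f in files},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n"
    )
    return out
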
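import numpy as np
import pytest

from mhcscreen.coexpression_screen import AnchorPanel
from mhcscreen.deconvolution import SignatureMatrix
from mhcscreen.io_formats import ClinicalTable, ExpressionMatrix
from mhcscreen.synthetic_data import SyntheticTruth, make_bulk_dataset, make_signature_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_expr(rng) -> ExpressionMatrix:
    genes = [f"G{i}" for i in range(20)]
    samples = [f"S{j}" for j in range(15)]
    return ExpressionMatrix(genes, samples, rng.normal(8, 2, size=(20, 15)))


@pytest.fixture
def panel() -> AnchorPanel:
    return AnchorPanel()


@pytest.fixture
def signature_matrix() -> SignatureMatrix:
    return make_signature_matrix(5, 3, seed=1)


def make_synthetic(seed: int, n_samples: int = 459, n_noise_genes: int = 150,
                   coupling: float = 0.8, disparity_prob: float = 0.8,
                   hazard_beta: float = 0.5, noise_sd: float = 0.3,
                   planted=("REG1", "REG2", "REG3"), **kwargs):
    """Shared helper: one synthetic dataset with three planted regulators."""
    truth = SyntheticTruth(
        planted_regulators=tuple(planted),
        coupling_strength={g: coupling for g in planted},
        hazard_beta=hazard_beta,
        disparity_prob={g: disparity_prob for g in planted},
        seed=seed,
    )
    sig = make_signature_matrix(5, 6, seed=seed)
    expr, clinical, protein = make_bulk_dataset(
        truth, AnchorPanel(), sig, n_samples=n_samples,
        n_noise_genes=n_noise_genes, noise_sd=noise_sd, **kwargs,
    )
    return truth, sig, expr, clinical, protein


@pytest.fixture
def clinical_20() -> ClinicalTable:
    """20-subject mixed event/censoring fixture with tied times."""
    rng = np.random.default_rng(7)
    time = np.round(rng.exponential(30, size=20), 0) + 1.0
    event = rng.integers(0, 2, size=20)
    event[:2] = 1  # guarantee events
    return ClinicalTable([f"S{i}" for i in range(20)], time, event)
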
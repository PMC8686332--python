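import numpy as np
import pytest

from phakit.simulate import (
    GrowthSpec,
    ProteinSpec,
    SpectrumSpec,
    gen_growth_curve,
    gen_protein,
    gen_spectrum,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def random_peptide(rng: np.random.Generator, min_len: int = 5,
                   max_len: int = 300) -> str:
    n = int(rng.integers(min_len, max_len + 1))
    return "".join(rng.choice(list(AA20), size=n))


@pytest.fixture
def write_fasta(tmp_path):
    def _write(records, name="input.fasta", wrap=None):
        lines = []
        for rec_id, seq in records:
            lines.append(f">{rec_id}")
            if wrap:
                lines.extend(seq[i:i + wrap] for i in range(0, len(seq), wrap))
            else:
                lines.append(seq)
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n")
        return path
    return _write


@pytest.fixture(scope="session")
def phac2_like():
    """Synthetic extended-PhaC-like protein with its ground truth."""
    return gen_protein(ProteinSpec(seed=42))


@pytest.fixture(scope="session")
def clean_spectrum():
    """Noise-free synthetic spectrum at 20% PHA with its ground truth."""
    return gen_spectrum(SpectrumSpec(seed=7, pha_fraction=0.2, noise_sd=0.0))


@pytest.fixture(scope="session")
def noiseless_logistic():
    return gen_growth_curve(GrowthSpec(seed=11, noise_sd=0.0))
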
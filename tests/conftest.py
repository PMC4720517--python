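import numpy as np
import pytest

import pdsfil as p
from pdsfil import deer


@pytest.fixture(scope="session")
def r_grid():
    return deer.DEFAULT_R_GRID.copy()


@pytest.fixture(scope="session")
def helix45():
    """45-residue ideal α-helix along +z."""
    return p.ideal_helix(p.HelixSpec(45))


@pytest.fixture(scope="session")
def helix_label_pair(helix45):
    """Label clouds at helix sites with 29 residues between attachment
    points (one short of the paper's E88/H118-like spacing)."""
    a = p.attach_label(helix45, ("A", 8), seed=1)
    b = p.attach_label(helix45, ("A", 37), seed=2)
    return a, b


@pytest.fixture(scope="session")
def open_protomer():
    return p.synthetic_protomer(p.SyntheticProtomerSpec("open"), seed=0)


@pytest.fixture(scope="session")
def filament7(open_protomer):
    """7-mer parallel protofilament, 30 Å repeat, 27° tilt."""
    return p.synthetic_filament(open_protomer, repeat=30.0, tilt=27.0, n=7)


@pytest.fixture(scope="session")
def long_time_grid():
    """5 μs record: >= 2.5 dipolar periods at 45 Å, enough to separate
    background decay from a slowly decaying form factor."""
    return np.arange(0.0, 5.0 + 1e-12, 0.008)


def pure_form_factor(truth, time, depth=0.3):
    """Exact noiseless normalized trace for a known distribution."""
    F = deer.form_factor(truth, time)
    return deer.DeerTrace(time, 1.0 - depth * (1.0 - F), "form_factor")
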
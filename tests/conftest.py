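import numpy as np
import pytest

from dsbdesign.synthetic_data import EnsembleSpec, SyntheticSpec, build_structure, make_ensemble


@pytest.fixture(scope="session")
def hairpin():
    """20-residue two-stranded hairpin with one Cβ-feasible planted pair (6, 15)."""
    spec = SyntheticSpec(fold="hairpin", n_residues=20, planted_pairs=((6, 15),), seed=0)
    return build_structure(spec)


@pytest.fixture(scope="session")
def bonded_hairpin():
    """Hairpin carrying an ideal planted disulfide between residues 4 and 17."""
    spec = SyntheticSpec(fold="hairpin", n_residues=20, planted_disulfides=((4, 17),), seed=0)
    return build_structure(spec)


@pytest.fixture(scope="session")
def helix():
    spec = SyntheticSpec(fold="helix", n_residues=12, seed=0)
    return build_structure(spec)


@pytest.fixture(scope="session")
def stable_ensemble(bonded_hairpin):
    s, _ = bonded_hairpin
    spec = EnsembleSpec(
        n_frames=200, amplitude_sigma=0.3, rigid_jitter=True, exclude_atoms=frozenset({"SG"})
    )
    return make_ensemble(s, spec, seed=11)


@pytest.fixture(scope="session")
def drifting_ensemble(bonded_hairpin):
    s, _ = bonded_hairpin
    spec = EnsembleSpec(n_frames=200, amplitude_sigma=0.1, drift_rate=0.02)
    return make_ensemble(s, spec, seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
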
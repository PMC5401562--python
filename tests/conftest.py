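import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from tricchan import GatingModel, RecordingConfig, render_trace, simulate_state_path
from tricchan.ghk import symmetric_k
from tricchan.structure_geometry import StructureModel

WT_LEVELS_PS = (0.0, 42.2, 100.6, 163.7)
WT_LEVEL_CURRENTS_60MV = np.array([0.0, 2.532, 6.036, 9.822])  # pS * 60 mV / 1000


@pytest.fixture
def wt_model():
    """Wild-type-like trimer: symmetric rates, measured conductance levels."""
    return GatingModel(k_open=50.0, k_close=50.0, level_conductances=WT_LEVELS_PS)


@pytest.fixture
def symmetric_conditions():
    return symmetric_k()


@pytest.fixture
def wt_trace(wt_model, symmetric_conditions):
    """20 s filtered noisy recording at +60 mV (1e6 samples)."""
    path = simulate_state_path(wt_model, 20.0, seed=7)
    config = RecordingConfig(duration=20.0, holding_potential=60.0, noise_sd=0.35, seed=7)
    return render_trace(path, config, symmetric_conditions, wt_model), path


def ideal_helix(n_res: int, rise: float = 1.5, twist_deg: float = 100.0, radius: float = 2.3):
    """C-alpha coordinates of an ideal alpha-helix along +z."""
    i = np.arange(n_res)
    t = np.radians(twist_deg) * i
    return np.column_stack([radius * np.cos(t), radius * np.sin(t), rise * i])


def rotation_about_x(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def make_trimer(n_res: int = 60, offset: float = 12.0, jitter_sd: float = 0.0, seed: int = 0):
    """Synthetic C3 trimer: one helix offset from z, replicated by 120-deg turns."""
    rng = np.random.default_rng(seed)
    base = ideal_helix(n_res) + np.array([offset, 0.0, 0.0])
    base = base @ rotation_about_x(25.0).T  # tilt the protomer so chains are not trivial
    rows = []
    for k, chain in enumerate("ABC"):
        ang = np.radians(120.0 * k)
        c, s = np.cos(ang), np.sin(ang)
        rz = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
        coords = base @ rz.T
        if jitter_sd > 0:
            coords = coords + rng.normal(0, jitter_sd, coords.shape)
        for j, xyz in enumerate(coords):
            rows.append(("CA", "ALA", j + 1, chain, "C", *xyz))
    atoms = pd.DataFrame(
        rows,
        columns=["atom_name", "residue_name", "residue_number", "chain_id", "element", "x", "y", "z"],
    )
    return StructureModel(atoms=atoms, source_id="synthetic-trimer")
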
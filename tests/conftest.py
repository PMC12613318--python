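"""Shared fixtures: small lattice systems and synthetic segment datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from slm_msm.cli_io import desk_params, desk_targets
from slm_msm.lattice_kmc import ModelParams, TargetStructure
from slm_msm.slm_pipeline import SLMDataset


@pytest.fixture(scope="session")
def toy_targets():
    """The packaged frustrated two-target design."""
    return desk_targets()


@pytest.fixture(scope="session")
def toy_params():
    return desk_params()


@pytest.fixture(scope="session")
def square_target():
    """A 2x2 target whose four nearest-neighbour contacts are all strong
    bonds (required states all 0)."""
    return TargetStructure(
        offsets=((0, 0), (0, 1), (1, 0), (1, 1)),
        required_states=(0, 0, 0, 0),
        strong_bond_pairs=frozenset({(0, 1), (0, 2), (1, 3), (2, 3)}),
    )


@pytest.fixture(scope="session")
def square_params():
    return ModelParams(
        lattice_width=5, lattice_height=5, n_particles=4,
        J_s=-3.6, J_w=-1.0, n_internal_states=2, N_steps=50_000,
    )


def make_dataset(
    trends, energies=None, onsets=None, dwell=1.0,
    t_fas=None, assembled=None, traj_id=None,
):
    """Build a single- or multi-trajectory SLMDataset from raw coordinate
    arrays (convenience for binning/MSM tests)."""
    trends = np.asarray(trends, dtype=float)
    n = len(trends)
    if energies is None:
        energies = np.zeros(n)
    if traj_id is None:
        traj_id = np.zeros(n, dtype=int)
    traj_id = np.asarray(traj_id)
    rows = []
    for tid in np.unique(traj_id):
        sel = np.nonzero(traj_id == tid)[0]
        for k, i in enumerate(sel):
            onset = k * dwell if onsets is None else onsets[i]
            end = onset + dwell
            rows.append((tid, onset, end, energies[i], trends[i],
                         end - onset, 1, False))
    df = pd.DataFrame(rows, columns=[
        "traj_id", "onset_s", "end_s", "mean_energy", "mean_trend",
        "dwell_s", "n_kmc_steps", "drive_on",
    ])
    n_traj = len(np.unique(traj_id))
    if t_fas is None:
        t_fas = [df[df.traj_id == t].end_s.max() for t in np.unique(traj_id)]
    if assembled is None:
        assembled = [0] * n_traj
    return SLMDataset(
        segments=df,
        T_FAS=np.asarray(t_fas, dtype=float),
        assembled=np.asarray(assembled, dtype=int),
    )


@pytest.fixture
def dataset_factory():
    return make_dataset
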
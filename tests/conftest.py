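import numpy as np
import pandas as pd
import pytest

from diolphase.trajectory import Trajectory


def make_trajectory(atom_rows, coords, box_edge=100.0):
    """Build a Trajectory from explicit atom dicts and coordinates.

    ``atom_rows``: list of dicts with any subset of topology columns (the rest
    default to protein heavy atoms).  ``coords``: (n_frames, n_atoms, 3).
    """
    defaults = dict(
        residue_index=1,
        residue_type="G",
        atom_name="BB",
        element="C",
        mass=12.0,
        heavy=True,
        sidechain=False,
        molecule_id=0,
        molecule_kind="protein",
    )
    rows = [{**defaults, **r} for r in atom_rows]
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    box = np.full((coords.shape[0], 3), float(box_edge))
    return Trajectory(topology=pd.DataFrame(rows), coords=coords, box=box)


def brute_force_residue_contacts(traj, cutoff):
    """O(N^2) minimum-image residue contact map; independent oracle."""
    heavy = traj.protein_heavy()
    res = traj.topology["residue_index"].to_numpy()[heavy]
    n = traj.n_residues()
    counts = np.zeros((n, n))
    for f in range(traj.n_frames):
        x = traj.coords[f, heavy]
        delta = x[:, None, :] - x[None, :, :]
        delta -= traj.box[f] * np.round(delta / traj.box[f])
        d = np.sqrt((delta**2).sum(-1))
        hit = np.zeros((n, n), dtype=bool)
        ii, jj = np.nonzero(d <= cutoff)
        for i, j in zip(ii, jj):
            if res[i] != res[j]:
                hit[res[i] - 1, res[j] - 1] = True
        counts += hit
    freq = counts / traj.n_frames
    np.fill_diagonal(freq, np.nan)
    return freq


def brute_force_cosolvent_contacts(traj, cutoff):
    """O(N^2) per-residue count of cosolvent molecules in contact."""
    hp = traj.protein_heavy()
    hc = traj.cosolvent_heavy()
    res = traj.topology["residue_index"].to_numpy()[hp]
    mol = traj.topology["molecule_id"].to_numpy()[hc]
    n = traj.n_residues()
    totals = np.zeros(n)
    for f in range(traj.n_frames):
        delta = traj.coords[f, hp][:, None, :] - traj.coords[f, hc][None, :, :]
        delta -= traj.box[f] * np.round(delta / traj.box[f])
        d = np.sqrt((delta**2).sum(-1))
        pairs = {(res[i], mol[j]) for i, j in zip(*np.nonzero(d <= cutoff))}
        for r, _ in pairs:
            totals[r - 1] += 1
    return totals / traj.n_frames


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
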
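import numpy as np
import pytest

from hydrashell.core import AtomRecord, Frame, Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(20230917)


def make_atom(index, name="O", element=None, residue_name="GLY", residue_seq=None,
              chain_id="A", is_water=False, mass=None):
    element = element or name[0]
    masses = {"O": 15.999, "C": 12.011, "N": 14.007, "H": 1.008, "S": 32.06}
    return AtomRecord(index=index, name=name, element=element,
                      mass=mass if mass is not None else masses.get(element, 12.0),
                      residue_name=residue_name,
                      residue_seq=residue_seq if residue_seq is not None else index + 1,
                      chain_id=chain_id, is_water=is_water)


def make_water_traj(site_xyz, water_frames, box=None, frame_interval=1.0):
    """One carbonyl-O site (or several) plus water oxygens with given
    per-frame coordinates.

    ``site_xyz``: (n_sites, 3); ``water_frames``: (n_frames, n_waters, 3).
    """
    site_xyz = np.atleast_2d(np.asarray(site_xyz, dtype=float))
    water_frames = np.asarray(water_frames, dtype=float)
    if water_frames.ndim == 2:
        water_frames = water_frames[None]
    n_sites, n_waters = len(site_xyz), water_frames.shape[1]
    top = [make_atom(i, "O", residue_name="GLY", residue_seq=i + 1) for i in range(n_sites)]
    top += [make_atom(n_sites + j, "OW", element="O", residue_name="HOH",
                      residue_seq=j + 1, chain_id="W", is_water=True)
            for j in range(n_waters)]
    frames = [Frame(np.vstack([site_xyz, wf]), box=box, time=f * frame_interval)
              for f, wf in enumerate(water_frames)]
    return Trajectory(top, frames, frame_interval=frame_interval)


@pytest.fixture
def atom_factory():
    return make_atom


@pytest.fixture
def water_traj_factory():
    return make_water_traj
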
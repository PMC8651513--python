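import numpy as np
import pandas as pd
import pytest

from recharge.frames import FrameTable
from recharge.topology import ChargeSet
from recharge.toys import metropolis_sample, two_species_fluid

ITP_TEXT = """\
; toy glycerol-ester topology
[ moleculetype ]
; name  nrexcl
TOG     3

[ atoms ]
;   nr  type  resnr residue  atom   cgnr    charge       mass
     1  CTL1      1     TOG     C2      1     0.400000   12.011
     2   OSL      1     TOG    O21      1    -0.800000   15.999
     3  CTL2      1     TOG     C1      2     0.400000   12.011
"""

SIDECAR_TOML = """\
net_charge = 0.0
equivalence_groups = [["C2", "C1"]]
frozen_atoms = []
"""


@pytest.fixture
def itp_file(tmp_path):
    path = tmp_path / "tog.itp"
    path.write_text(ITP_TEXT)
    return path


@pytest.fixture
def sidecar_file(tmp_path):
    path = tmp_path / "tog.toml"
    path.write_text(SIDECAR_TOML)
    return path


@pytest.fixture
def simple_charges():
    q = np.array([0.4, -0.8, 0.4])
    return ChargeSet(("C2", "O21", "C1"), q, q.copy())


@pytest.fixture(scope="session")
def toy_system():
    return two_species_fluid(8, 8, 0.15)


@pytest.fixture(scope="session")
def toy_ensemble(toy_system):
    """A moderately long toy run shared across tests (read-only)."""
    ens = metropolis_sample(toy_system, 20000, seed=1234, stride=25)
    ens.validate()
    return ens


def make_frame_table(rows, box=(5.0, 5.0, 12.0)):
    """rows: (frame, resname, atomname, x, y, z, mass) tuples."""
    df = pd.DataFrame(
        rows, columns=["frame", "resname", "atomname", "x", "y", "z", "mass"]
    )
    df.insert(1, "time", df["frame"].astype(float))
    frames = sorted(df["frame"].unique())
    boxes = pd.DataFrame(
        {"lx": box[0], "ly": box[1], "lz": box[2]},
        index=pd.Index(frames, name="frame"),
    )
    return FrameTable(df, boxes)


@pytest.fixture
def slab_frames():
    """One-frame oil slab (20 lumped TOG pseudo-atoms in z = 4..8) with one
    interior water and 50 exterior waters."""
    rows = []
    for z in np.linspace(4.1, 7.9, 20):
        rows.append((0, "TOG", "C2", 0.0, 0.0, z, 885.43))
    rows.append((0, "SOL", "OW", 0.0, 0.0, 6.0, 15.999))
    for z in np.linspace(0.2, 3.5, 50):
        rows.append((0, "SOL", "OW", 0.0, 0.0, z, 15.999))
    return make_frame_table(rows)
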
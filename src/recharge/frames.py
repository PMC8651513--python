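"""Light-weight multi-frame coordinate container.

Frames are held as a flat table (frame, time, resname, atomname, x, y, z,
mass) plus per-frame box lengths — the minimum the density/hydration/dipole
analyses need. Reads/writes a plain CSV dialect and (multi-frame,
concatenated) GRO files. GRO carries no masses, so element masses are
guessed from the first letter of the atom name.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError, ParseError, ValidationError

COLUMNS = ["frame", "time", "resname", "atomname", "x", "y", "z", "mass"]

ELEMENT_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.973762,
    "S": 32.06,
}


def guess_mass(atom_name: str) -> float:
    for ch in atom_name:
        if ch.isalpha():
            return ELEMENT_MASSES.get(ch.upper(), 0.0)
    return 0.0


@dataclass
class FrameTable:
    """Coordinate frames with residue/atom labels and per-frame boxes.

    ``table`` columns: frame, time (ns), resname, atomname, x, y, z (nm),
    mass (g/mol). ``boxes``: index frame, columns lx, ly, lz (nm).
    """

    table: pd.DataFrame
    boxes: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"frame table missing columns {missing}")
        if not set(self.table["frame"].unique()) <= set(self.boxes.index):
            raise ValidationError("every frame needs a box entry")

    @property
    def frame_ids(self) -> np.ndarray:
        return np.sort(self.table["frame"].unique())

    @property
    def n_frames(self) -> int:
        return len(self.frame_ids)

    def iter_frames(self):
        for fid, df in self.table.groupby("frame", sort=True):
            yield int(fid), df, self.boxes.loc[fid]

    def select(self, resname=None, atomname=None) -> "FrameTable":
        df = self.table
        if resname is not None:
            names = [resname] if isinstance(resname, str) else list(resname)
            df = df[df["resname"].isin(names)]
        if atomname is not None:
            names = [atomname] if isinstance(atomname, str) else list(atomname)
            df = df[df["atomname"].isin(names)]
        return FrameTable(df, self.boxes)

    def translated(self, dz: float, wrap: bool = True) -> "FrameTable":
        """Rigidly shift all z coordinates (optionally wrapping into the box)."""
        df = self.table.copy()
        df["z"] = df["z"] + dz
        if wrap:
            lz = df["frame"].map(self.boxes["lz"])
            df["z"] = np.mod(df["z"], lz)
        return FrameTable(df, self.boxes)

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path) -> None:
        df = self.table.copy()
        for col in ("lx", "ly", "lz"):
            df[col] = df["frame"].map(self.boxes[col])
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FrameTable":
        df = pd.read_csv(path)
        for col in ("time", "mass"):
            if col not in df.columns:
                df[col] = 0.0
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"frame CSV missing columns {missing}")
        if not {"lx", "ly", "lz"} <= set(df.columns):
            raise FormatError("frame CSV missing box columns lx/ly/lz")
        boxes = (
            df.groupby("frame")[["lx", "ly", "lz"]].first().astype(float)
        )
        return cls(df[COLUMNS].copy(), boxes)

    @classmethod
    def from_gro(cls, path) -> "FrameTable":
        """Read one or more concatenated GRO frames."""
        rows = []
        box_rows = {}
        with open(path) as fh:
            lines = fh.read().split("\n")
        i = 0
        frame = 0
        while i < len(lines):
            if not lines[i].strip():
                i += 1
                continue
            title = lines[i]
            time = 0.0
            if "t=" in title:
                try:
                    time = float(title.split("t=")[1].split()[0]) / 1000.0  # ps->ns
                except (ValueError, IndexError):
                    time = 0.0
            try:
                natoms = int(lines[i + 1].strip())
            except (ValueError, IndexError) as exc:
                raise ParseError(
                    f"line {i + 2}: expected atom count", line_number=i + 2
                ) from exc
            atom_lines = lines[i + 2 : i + 2 + natoms]
            if len(atom_lines) < natoms:
                raise FormatError("truncated GRO frame")
            for ln, line in enumerate(atom_lines, start=i + 3):
                try:
                    resname = line[5:10].strip()
                    atomname = line[10:15].strip()
                    x = float(line[20:28])
                    y = float(line[28:36])
                    z = float(line[36:44])
                except (ValueError, IndexError) as exc:
                    raise ParseError(
                        f"line {ln}: malformed GRO atom line", line_number=ln
                    ) from exc
                rows.append(
                    (frame, time, resname, atomname, x, y, z, guess_mass(atomname))
                )
            box_fields = lines[i + 2 + natoms].split()
            if len(box_fields) < 3:
                raise FormatError("missing GRO box line")
            box_rows[frame] = [float(v) for v in box_fields[:3]]
            i += natoms + 3
            frame += 1
        table = pd.DataFrame(rows, columns=COLUMNS)
        boxes = pd.DataFrame.from_dict(
            box_rows, orient="index", columns=["lx", "ly", "lz"]
        )
        boxes.index.name = "frame"
        return cls(table, boxes)

    def to_gro(self, path) -> None:
        with open(path, "w") as fh:
            for fid, df, box in self.iter_frames():
                time_ps = float(df["time"].iloc[0]) * 1000.0
                fh.write(f"frame {fid} t= {time_ps:.3f}\n{len(df)}\n")
                for j, (_, row) in enumerate(df.iterrows(), start=1):
                    fh.write(
                        f"{(j - 1) % 99999 + 1:5d}{row.resname[:5]:<5s}"
                        f"{row.atomname[:5]:>5s}{j % 99999:5d}"
                        f"{row.x:8.3f}{row.y:8.3f}{row.z:8.3f}\n"
                    )
                fh.write(
                    f"{box.lx:10.5f}{box.ly:10.5f}{box.lz:10.5f}\n"
                )
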
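"""Per-atom partial charges in GROMACS-dialect topology (.itp) files.

The central object is :class:`ChargeSet`: named per-atom charges together
with the structure the refinement protocol has to respect — equivalence
groups (atoms forced to share one charge value, e.g. chemically identical
chains), a frozen mask (atoms whose charges are never touched, e.g. acyl
chains and the alcohol group), a reference charge set that regularization
pulls toward, and the declared molecular net charge.

Equivalence groups, frozen atoms and the net charge are declared in a
sidecar TOML file rather than inferred from atom types, because chain
identities are molecule-specific.
"""

from __future__ import annotations

import re
import tomllib
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import FormatError, ParseError, ValidationError

GROUP_TOL = 1e-12
NET_CHARGE_TOL = 1e-9

_ATOM_LINE_SPLIT = re.compile(r"(\s+)")


@dataclass(frozen=True, eq=False)
class ChargeSet:
    """Named per-atom partial charges with refinement structure.

    Parameters
    ----------
    atom_names : tuple of str
        Atom identifiers in file order.
    charges : ndarray
        Current charge per atom (e).
    reference_charges : ndarray
        Charges the regularization pulls toward (e).
    equivalence_groups : tuple of tuple of int
        Partition (possibly partial; singletons implied) of atom indices
        forced to share one charge value.
    frozen_mask : ndarray of bool
        True for atoms excluded from optimization.
    net_charge : float
        Declared molecular net charge (e).
    annotations : dict
        Opaque per-atom metadata (type, residue, mass, ...) retained for
        round-tripping.
    """

    atom_names: tuple[str, ...]
    charges: np.ndarray
    reference_charges: np.ndarray
    equivalence_groups: tuple[tuple[int, ...], ...] = ()
    frozen_mask: np.ndarray | None = None
    net_charge: float = 0.0
    annotations: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "atom_names", tuple(self.atom_names))
        object.__setattr__(
            self, "charges", np.asarray(self.charges, dtype=float).copy()
        )
        object.__setattr__(
            self,
            "reference_charges",
            np.asarray(self.reference_charges, dtype=float).copy(),
        )
        if self.frozen_mask is None:
            object.__setattr__(
                self, "frozen_mask", np.zeros(self.n_atoms, dtype=bool)
            )
        else:
            object.__setattr__(
                self, "frozen_mask", np.asarray(self.frozen_mask, dtype=bool).copy()
            )
        object.__setattr__(
            self,
            "equivalence_groups",
            tuple(tuple(int(i) for i in g) for g in self.equivalence_groups),
        )

    # -- basic structure ---------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def validate(self) -> None:
        """Check all ChargeSet invariants; raise ValidationError on failure."""
        n = self.n_atoms
        if self.charges.shape != (n,) or self.reference_charges.shape != (n,):
            raise ValidationError(
                "charges and reference_charges must have one entry per atom"
            )
        if self.frozen_mask.shape != (n,):
            raise ValidationError("frozen_mask must have one entry per atom")
        seen: set[int] = set()
        for group in self.equivalence_groups:
            for i in group:
                if i < 0 or i >= n:
                    raise ValidationError(f"equivalence group index {i} out of range")
                if i in seen:
                    raise ValidationError(
                        f"atom index {i} appears in more than one equivalence group"
                    )
                seen.add(i)
            vals = self.charges[list(group)]
            if np.ptp(vals) > GROUP_TOL:
                names = [self.atom_names[i] for i in group]
                raise ValidationError(
                    f"equivalence group {names} does not share one charge: {vals}"
                )
            frozen = self.frozen_mask[list(group)]
            if frozen.any() and not frozen.all():
                raise ValidationError(
                    "equivalence groups may not mix frozen and free atoms"
                )
        net = float(self.charges.sum())
        if abs(net - self.net_charge) > NET_CHARGE_TOL:
            raise ValidationError(
                f"net charge {net:+.12f} differs from declared "
                f"{self.net_charge:+.12f} by more than {NET_CHARGE_TOL} e"
            )
        bad = self.frozen_mask & (
            np.abs(self.charges - self.reference_charges) > GROUP_TOL
        )
        if bad.any():
            names = [self.atom_names[i] for i in np.flatnonzero(bad)]
            raise ValidationError(f"frozen atoms {names} deviate from reference")

    # -- parameterization structure ----------------------------------------

    @property
    def free_mask(self) -> np.ndarray:
        return ~self.frozen_mask

    def free_param_groups(self) -> list[np.ndarray]:
        """Free parameters: one per non-frozen equivalence group, plus one
        per non-frozen atom outside any group. Each entry is the array of
        atom indices sharing that parameter, in atom order."""
        grouped = set()
        params: list[np.ndarray] = []
        for group in self.equivalence_groups:
            grouped.update(group)
            if not self.frozen_mask[group[0]]:
                params.append(np.array(sorted(group), dtype=int))
        for i in range(self.n_atoms):
            if i not in grouped and not self.frozen_mask[i]:
                params.append(np.array([i], dtype=int))
        params.sort(key=lambda idx: idx[0])
        return params

    @property
    def n_free_params(self) -> int:
        return len(self.free_param_groups())

    def param_values(self) -> np.ndarray:
        return np.array([self.charges[g[0]] for g in self.free_param_groups()])

    def param_multiplicities(self) -> np.ndarray:
        return np.array([len(g) for g in self.free_param_groups()], dtype=float)

    def with_charges(self, charges: np.ndarray) -> "ChargeSet":
        return replace(self, charges=np.asarray(charges, dtype=float))

    def with_param_values(self, params: np.ndarray) -> "ChargeSet":
        q = self.charges.copy()
        for value, group in zip(params, self.free_param_groups(), strict=True):
            q[group] = value
        return self.with_charges(q)

    def project(self, raw: np.ndarray | None = None) -> "ChargeSet":
        """Project raw per-atom charges onto the constraint set.

        Order: freeze frozen atoms to their reference values, average within
        equivalence groups (charge-conserving), then remove the net-charge
        residual by a uniform shift over the free atoms.
        """
        q = (self.charges if raw is None else np.asarray(raw, dtype=float)).copy()
        q[self.frozen_mask] = self.reference_charges[self.frozen_mask]
        for group in self.equivalence_groups:
            idx = list(group)
            q[idx] = q[idx].mean()
        n_free = int(self.free_mask.sum())
        if n_free > 0:
            residual = q.sum() - self.net_charge
            q[self.free_mask] -= residual / n_free
        return self.with_charges(q)


# -- ITP I/O ---------------------------------------------------------------


@dataclass
class _ItpAtoms:
    """Parsed `[atoms]` section plus enough context to rewrite the file."""

    lines: list[str]                 # full file, no trailing newlines
    atom_line_numbers: list[int]     # 0-based indices into `lines`
    charge_token_index: list[int]    # token position of the charge field


def _parse_itp(text: str) -> tuple[_ItpAtoms, ChargeSet]:
    lines = text.split("\n")
    in_atoms = False
    found = False
    atom_lines: list[int] = []
    charge_tok: list[int] = []
    names: list[str] = []
    charges: list[float] = []
    numbers: set[int] = set()
    types: list[str] = []
    masses: list[str] = []
    residues: list[str] = []
    for ln, line in enumerate(lines):
        stripped = line.split(";", 1)[0].strip()
        if not stripped:
            continue
        m = re.match(r"\[\s*(\S+)\s*\]", stripped)
        if m:
            in_atoms = m.group(1).lower() == "atoms"
            found = found or in_atoms
            continue
        if not in_atoms:
            continue
        tokens = [t for t in _ATOM_LINE_SPLIT.split(line.split(";", 1)[0]) if t.strip()]
        if len(tokens) < 7:
            raise ParseError(
                f"line {ln + 1}: expected at least 7 fields "
                "(nr type resnr residue atom cgnr charge), got "
                f"{len(tokens)}",
                line_number=ln + 1,
            )
        try:
            nr = int(tokens[0])
        except ValueError as exc:
            raise ParseError(
                f"line {ln + 1}: non-integer atom number {tokens[0]!r}",
                line_number=ln + 1,
            ) from exc
        if nr in numbers:
            raise ValidationError(f"duplicate atom number {nr} on line {ln + 1}")
        numbers.add(nr)
        try:
            q = float(tokens[6])
        except ValueError as exc:
            raise ParseError(
                f"line {ln + 1}: non-numeric charge {tokens[6]!r}",
                line_number=ln + 1,
            ) from exc
        atom_lines.append(ln)
        charge_tok.append(6)
        names.append(tokens[4])
        charges.append(q)
        types.append(tokens[1])
        residues.append(tokens[3])
        masses.append(tokens[7] if len(tokens) > 7 else "")
    if not found:
        raise FormatError("no [atoms] section found")
    if not names:
        raise FormatError("[atoms] section contains no atom lines")
    cs = ChargeSet(
        atom_names=tuple(names),
        charges=np.array(charges),
        reference_charges=np.array(charges),
        net_charge=round(float(np.sum(charges)), 6),
        annotations={"types": types, "masses": masses, "residues": residues},
    )
    return _ItpAtoms(lines, atom_lines, charge_tok), cs


def read_itp_charges(path) -> ChargeSet:
    """Read the `[atoms]` section of a GROMACS .itp/.top file.

    Returns charges in file order; atom type, residue and mass columns are
    retained as opaque annotations so the file can be rewritten faithfully.
    """
    with open(path) as fh:
        _, cs = _parse_itp(fh.read())
    return cs


def _replace_charge_token(line: str, token_index: int, value: float) -> str:
    body, sep, comment = line.partition(";")
    parts = _ATOM_LINE_SPLIT.split(body)
    count = -1
    for i, part in enumerate(parts):
        if part.strip():
            count += 1
            if count == token_index:
                formatted = f"{value:.6f}"
                # keep column alignment when the new token is narrower
                pad = len(part) - len(formatted)
                parts[i] = " " * max(pad, 0) + formatted
                break
    return "".join(parts) + sep + comment


def apply_charges(base_path, new: ChargeSet, out_path) -> None:
    """Write a copy of ``base_path`` with the charge column replaced.

    Everything except the charge fields is preserved byte-for-byte; charges
    are written with 6 decimal places. Refuses sets that violate the
    declared net charge or whose atom names do not match the file.
    """
    with open(base_path) as fh:
        parsed, base = _parse_itp(fh.read())
    if base.atom_names != new.atom_names:
        offenders = [
            f"{a!r} != {b!r}"
            for a, b in zip(base.atom_names, new.atom_names)
            if a != b
        ]
        if len(base.atom_names) != len(new.atom_names):
            offenders.append(
                f"atom count {len(base.atom_names)} != {len(new.atom_names)}"
            )
        raise ValidationError("atom name mismatch: " + "; ".join(offenders))
    net = float(new.charges.sum())
    if abs(net - new.net_charge) > NET_CHARGE_TOL:
        raise ValidationError(
            f"refusing to write non-neutral charge set: net charge {net:+.9f} e "
            f"(declared {new.net_charge:+g} e)"
        )
    lines = list(parsed.lines)
    for q, ln, tok in zip(new.charges, parsed.atom_line_numbers, parsed.charge_token_index):
        lines[ln] = _replace_charge_token(lines[ln], tok, float(q))
    with open(out_path, "w") as fh:
        fh.write("\n".join(lines))


def delta_charges(a: ChargeSet, b: ChargeSet) -> np.ndarray:
    """Per-atom charge differences b - a (e). Requires identical orderings."""
    if a.atom_names != b.atom_names:
        raise ValidationError("charge sets have different atom orderings")
    return b.charges - a.charges


# -- sidecar config --------------------------------------------------------


def load_charge_config(path) -> dict:
    """Load the sidecar TOML declaring equivalence groups, frozen atoms and
    the molecular net charge (keys: ``equivalence_groups`` — list of lists of
    atom names; ``frozen_atoms`` — list of atom names; ``net_charge``)."""
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    return cfg


def attach_config(cs: ChargeSet, cfg: dict, auto_repair: bool = False) -> ChargeSet:
    """Attach a sidecar config to a plain ChargeSet (by atom name).

    With ``auto_repair`` the net-charge residual is spread uniformly over the
    non-frozen atoms instead of raising (off by default; published topologies
    sometimes carry rounding residue).
    """
    index: dict[str, int] = {}
    for i, name in enumerate(cs.atom_names):
        if name in index:
            raise ValidationError(
                f"duplicate atom name {name!r}: sidecar config requires unique names"
            )
        index[name] = i

    def lookup(name: str) -> int:
        if name not in index:
            raise ValidationError(f"config references unknown atom {name!r}")
        return index[name]

    groups = tuple(
        tuple(lookup(n) for n in group)
        for group in cfg.get("equivalence_groups", [])
    )
    frozen = np.zeros(cs.n_atoms, dtype=bool)
    for name in cfg.get("frozen_atoms", []):
        frozen[lookup(name)] = True
    net = float(cfg.get("net_charge", 0.0))
    out = replace(
        cs,
        equivalence_groups=groups,
        frozen_mask=frozen,
        net_charge=net,
        reference_charges=cs.reference_charges,
    )
    residual = float(out.charges.sum()) - net
    if abs(residual) > NET_CHARGE_TOL:
        if not auto_repair:
            raise ValidationError(
                f"net charge residual {residual:+.9f} e exceeds tolerance "
                f"{NET_CHARGE_TOL} e (pass auto_repair=True to spread it)"
            )
        q = out.charges.copy()
        free = ~frozen
        q[free] -= residual / free.sum()
        out = replace(out, charges=q, reference_charges=q.copy())
    out.validate()
    return out
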
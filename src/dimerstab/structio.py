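"""Structure and ensemble I/O plus atom-selection resolution.

Structures are stored as column arrays (one entry per atom) mirroring the
fixed-column PDB fields that matter downstream: chain, residue, atom name,
element, coordinates in Angstrom and the isotropic B-factor.  Multi-MODEL
files become an :class:`Ensemble` sharing a single topology.  Parsing and
writing are delegated to biotite; this module owns the in-memory contract
and the selection language.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "Atom",
    "Structure",
    "Ensemble",
    "AtomSelection",
    "PDBParseError",
    "SelectionError",
    "read_pdb",
    "write_pdb",
    "select_atoms",
]

BACKBONE_NAMES = ("N", "CA", "C", "O")

# PDB serial field is 5 columns wide; larger serials wrap around.
_PDB_SERIAL_MOD = 100000


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be parsed into a valid structure."""


class SelectionError(ValueError):
    """Raised when a selection spec matches nothing or names absent terms."""


@dataclass(frozen=True)
class Atom:
    """One atom record (a row view into a :class:`Structure`)."""

    serial: int
    name: str
    element: str
    chain_id: str
    res_name: str
    res_seq: int
    coords: np.ndarray
    b_factor: float = 0.0
    hetero: bool = False


@dataclass
class Structure:
    """An ordered set of atoms with shared coordinate units (Angstrom)."""

    serials: np.ndarray
    names: np.ndarray
    elements: np.ndarray
    chain_ids: np.ndarray
    res_names: np.ndarray
    res_seqs: np.ndarray
    coords: np.ndarray
    b_factors: np.ndarray
    hetero: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (n, 3) array")
        n = self.coords.shape[0]
        if n == 0:
            raise PDBParseError("structure contains zero atoms")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        for arr_name in ("serials", "names", "elements", "chain_ids",
                         "res_names", "res_seqs", "b_factors", "hetero"):
            if len(getattr(self, arr_name)) != n:
                raise ValueError(f"{arr_name} length mismatch with coords")
        if any(e == "" for e in self.elements):
            raise ValueError("every atom needs a non-empty element symbol")

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self)

    def atom(self, i: int) -> Atom:
        return Atom(
            serial=int(self.serials[i]),
            name=str(self.names[i]),
            element=str(self.elements[i]),
            chain_id=str(self.chain_ids[i]),
            res_name=str(self.res_names[i]),
            res_seq=int(self.res_seqs[i]),
            coords=self.coords[i].copy(),
            b_factor=float(self.b_factors[i]),
            hetero=bool(self.hetero[i]),
        )

    @property
    def atoms(self) -> list[Atom]:
        return [self.atom(i) for i in range(len(self))]

    def with_coords(self, coords: np.ndarray, label: str | None = None) -> "Structure":
        new = replace(self, coords=np.asarray(coords, dtype=float))
        if label is not None:
            new.label = label
        return new

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(str(c))
        return list(seen)


@dataclass
class Ensemble:
    """Coordinate frames over a shared topology, at a constant timestep."""

    topology: Structure
    coords: np.ndarray  # (n_frames, n_atoms, 3)
    timestep_ps: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("ensemble coords must be (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.topology):
            raise ValueError(
                "every frame must have exactly the topology's atom count")
        if self.timestep_ps <= 0:
            raise ValueError("timestep_ps must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def __len__(self) -> int:
        return self.n_frames

    def frame(self, i: int) -> Structure:
        return self.topology.with_coords(
            self.coords[i], label=f"{self.topology.label}_frame{i}")


@dataclass(frozen=True)
class AtomSelection:
    """Strictly increasing atom indices into one structure, plus its spec."""

    indices: np.ndarray
    spec: str = ""

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if idx.size == 0:
            raise SelectionError(f"selection {self.spec!r} is empty")
        if np.any(np.diff(idx) <= 0):
            raise ValueError("selection indices must be strictly increasing")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return self.indices.size


def _from_atom_array(arr: struc.AtomArray, label: str) -> Structure:
    return Structure(
        serials=np.array(arr.get_annotation("atom_id")
                         if "atom_id" in arr.get_annotation_categories()
                         else np.arange(1, arr.array_length() + 1)),
        names=arr.atom_name.astype(str),
        elements=arr.element.astype(str),
        chain_ids=arr.chain_id.astype(str),
        res_names=arr.res_name.astype(str),
        res_seqs=arr.res_id.astype(int),
        coords=arr.coord.astype(float),
        b_factors=(arr.get_annotation("b_factor").astype(float)
                   if "b_factor" in arr.get_annotation_categories()
                   else np.zeros(arr.array_length())),
        hetero=arr.hetero.astype(bool),
        label=label,
    )


def read_pdb(path: str | Path) -> Structure | Ensemble:
    """Read a PDB file into a :class:`Structure` (or :class:`Ensemble` if it
    holds multiple MODEL records).

    Altloc conflicts keep the highest-occupancy variant (first on ties);
    HETATM records are kept but flagged ``hetero``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(
            altloc="occupancy", extra_fields=["b_factor", "atom_id"])
    except Exception as exc:  # surface biotite's message with context
        raise PDBParseError(f"cannot parse {path}: {exc}") from exc
    if stack.array_length() == 0:
        raise PDBParseError(f"{path} contains zero atoms")
    label = path.stem
    if stack.stack_depth() == 1:
        return _from_atom_array(stack[0], label)
    topo = _from_atom_array(stack[0], label)
    return Ensemble(topology=topo, coords=stack.coord.astype(float))


def _to_atom_array(s: Structure, coords: np.ndarray) -> struc.AtomArray:
    arr = struc.AtomArray(len(s))
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.chain_id = s.chain_ids.astype("U4")
    arr.res_id = s.res_seqs.astype(int)
    arr.res_name = s.res_names.astype("U5")
    arr.atom_name = s.names.astype("U6")
    arr.element = s.elements.astype("U2")
    arr.hetero = s.hetero.astype(bool)
    arr.set_annotation("b_factor", s.b_factors.astype(float))
    arr.set_annotation("atom_id", (s.serials % _PDB_SERIAL_MOD).astype(int))
    return arr


def write_pdb(obj: Structure | Ensemble, path: str | Path) -> Path:
    """Write a structure or multi-MODEL ensemble as fixed-column PDB.

    Coordinates survive a round-trip to 3 decimals (the format's precision);
    serial numbers wider than the 5-column field are written modulo 100000.
    """
    path = Path(path)
    pdb = PDBFile()
    if isinstance(obj, Ensemble):
        arrays = [_to_atom_array(obj.topology, obj.coords[i])
                  for i in range(obj.n_frames)]
        stack = struc.stack(arrays)
        pdb.set_structure(stack)
    else:
        pdb.set_structure(_to_atom_array(obj, obj.coords))
    pdb.write(str(path))
    return path


def _parse_spec(spec: str) -> dict:
    """Parse ``"chain=C,D;res=1-120;atoms=backbone"`` into fields."""
    out = {"chain": None, "res": None, "atoms": "all"}
    for part in spec.split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise SelectionError(f"malformed selection term {part!r}")
        key, _, val = part.partition("=")
        key = key.strip().lower()
        val = val.strip()
        if key == "chain":
            out["chain"] = [v.strip() for v in val.split(",") if v.strip()]
        elif key == "res":
            ranges: list[tuple[int, int]] = []
            for tok in val.split(","):
                tok = tok.strip()
                if "-" in tok[1:]:  # allow negative lower bound
                    lo, hi = tok.rsplit("-", 1) if not tok.startswith("-") \
                        else (tok[: tok.rindex("-")], tok[tok.rindex("-") + 1:])
                    ranges.append((int(lo), int(hi)))
                else:
                    ranges.append((int(tok), int(tok)))
            out["res"] = ranges
        elif key == "atoms":
            val = val.lower()
            if val not in ("backbone", "ca", "all"):
                raise SelectionError(f"unknown atom class {val!r}")
            out["atoms"] = val
        else:
            raise SelectionError(f"unknown selection key {key!r}")
    return out


def select_atoms(
    s: Structure,
    spec: str,
    include_hetero: bool = False,
    include_hydrogens: bool = False,
) -> AtomSelection:
    """Resolve a selection spec against a structure.

    Atom classes: ``backbone`` = N, CA, C, O; ``ca`` = C-alpha only;
    ``all`` = every heavy atom of the listed residues.  HETATM records and
    hydrogens are excluded unless explicitly requested.
    """
    fields = _parse_spec(spec)
    mask = np.ones(len(s), dtype=bool)
    if not include_hetero:
        mask &= ~s.hetero
    if not include_hydrogens:
        mask &= ~np.isin(np.char.upper(s.elements.astype(str)), ("H", "D"))
    if fields["chain"] is not None:
        present = set(s.chains())
        missing = [c for c in fields["chain"] if c not in present]
        if missing:
            raise SelectionError(
                f"chain(s) {missing} not present (have {sorted(present)})")
        mask &= np.isin(s.chain_ids.astype(str), fields["chain"])
    if fields["res"] is not None:
        res_mask = np.zeros(len(s), dtype=bool)
        for lo, hi in fields["res"]:
            res_mask |= (s.res_seqs >= lo) & (s.res_seqs <= hi)
        mask &= res_mask
    names = np.char.upper(s.names.astype(str))
    if fields["atoms"] == "backbone":
        mask &= np.isin(names, BACKBONE_NAMES)
    elif fields["atoms"] == "ca":
        mask &= names == "CA"
    indices = np.flatnonzero(mask)
    if indices.size == 0:
        raise SelectionError(f"selection {spec!r} matched no atoms")
    return AtomSelection(indices=indices, spec=spec)
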
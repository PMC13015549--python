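"""Protein structure container and fixed-column PDB input/output.

Structures are stored as an ordered list of residues with named atoms,
coordinates in Å and a per-atom B-factor which, for predicted models
following the ColabFold convention, holds the per-residue confidence
(pLDDT, 0–100).  On load residues are renumbered to a contiguous 1..L
range; the author-assigned residue numbers are retained as metadata.
Only the first chain and first alternate location of each file are read
and HETATM records are skipped: the intended inputs are predicted
monomer models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import gemmi
import numpy as np

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass
class AtomRecord:
    """A named atom with coordinates (Å) and a B-factor (pLDDT for models)."""

    name: str
    coords: np.ndarray
    bfactor: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError("atom coordinates must be a 3-vector")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name!r}")
        if not self.name:
            raise ValueError("atom name must be non-empty")


@dataclass
class Residue:
    """One residue: 1-based sequence position, 3-letter code and its atoms."""

    index: int
    name3: str
    atoms: Dict[str, AtomRecord] = field(default_factory=dict)
    orig_number: Optional[int] = None  # author numbering from the source file

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError("residue index must be >= 1")

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name3.upper(), "X")

    def get(self, atom_name: str) -> Optional[AtomRecord]:
        return self.atoms.get(atom_name)

    def coord(self, atom_name: str) -> np.ndarray:
        atom = self.atoms.get(atom_name)
        if atom is None:
            raise KeyError(
                f"residue {self.index} ({self.name3}) lacks atom {atom_name!r}"
            )
        return atom.coords


@dataclass
class ProteinStructure:
    """An ordered single-chain structure."""

    chain_id: str
    residues: List[Residue]
    model_id: str = "model"

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError("a structure needs at least one residue")
        idx = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("residue indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def residue_at(self, index: int) -> Optional[Residue]:
        # residues are renumbered 1..L on load, so direct lookup is O(1);
        # fall back to scan for hand-built structures with gaps
        if 1 <= index <= len(self.residues) and self.residues[index - 1].index == index:
            return self.residues[index - 1]
        for r in self.residues:
            if r.index == index:
                return r
        return None

    def ca_coords(self, indices: Optional[Sequence[int]] = None) -> np.ndarray:
        """Cα coordinates for the given residue indices (default: all).

        Raises KeyError listing residues with no Cα.
        """
        residues = (
            self.residues
            if indices is None
            else [self._require(i) for i in indices]
        )
        missing = [r.index for r in residues if "CA" not in r.atoms]
        if missing:
            raise KeyError(f"residues lacking CA: {missing}")
        return np.array([r.coord("CA") for r in residues])

    def _require(self, index: int) -> Residue:
        r = self.residue_at(index)
        if r is None:
            raise KeyError(f"no residue with index {index}")
        return r

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ProteinStructure":
        """A copy with every atom mapped through x → R·x + t."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        new_residues = []
        for r in self.residues:
            atoms = {
                n: AtomRecord(n, rotation @ a.coords + translation, a.bfactor)
                for n, a in r.atoms.items()
            }
            new_residues.append(Residue(r.index, r.name3, atoms, r.orig_number))
        return ProteinStructure(self.chain_id, new_residues, self.model_id)


@dataclass(frozen=True)
class RegionSpec:
    """A 1-based inclusive residue range, e.g. the fold-switching CTD 110–162."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid region [{self.start}, {self.end}]")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def indices(self) -> range:
        return range(self.start, self.end + 1)

    def shifted(self, offset: int) -> "RegionSpec":
        return RegionSpec(self.start + offset, self.end + offset)


# ---------------------------------------------------------------------------
# PDB I/O


def _from_gemmi_model(model: gemmi.Model, model_id: str) -> ProteinStructure:
    if len(model) == 0:
        raise ValueError("model contains no chains")
    chain = model[0]
    residues: List[Residue] = []
    for res in chain:
        if res.het_flag == "H":
            continue
        atoms: Dict[str, AtomRecord] = {}
        for atom in res:
            if atom.altloc not in ("", "A", "\x00"):
                continue
            if atom.name in atoms:
                continue
            atoms[atom.name] = AtomRecord(
                atom.name,
                np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                atom.b_iso,
            )
        if atoms:
            residues.append(
                Residue(len(residues) + 1, res.name, atoms, res.seqid.num)
            )
    if not residues:
        raise ValueError("no polymer (ATOM) residues found")
    return ProteinStructure(chain.name or "A", residues, model_id)


def _read_gemmi(path: str | Path) -> gemmi.Structure:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty file")
    _validate_atom_lines(text, path)
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi detail
        raise ValueError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"{path}: no models found")
    return st


def _validate_atom_lines(text: str, path: Path) -> None:
    seen_atom = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith("ATOM"):
            seen_atom = True
            if len(line) < 54:
                raise ValueError(
                    f"{path}: malformed coordinate line {lineno}: too short"
                )
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise ValueError(
                        f"{path}: malformed coordinate line {lineno}: "
                        f"bad number {line[lo:hi]!r}"
                    ) from None
    if not seen_atom:
        raise ValueError(f"{path}: no ATOM records present")


def read_pdb(path: str | Path) -> ProteinStructure:
    """Read the first MODEL (first chain, first altloc) of a PDB file."""
    st = _read_gemmi(path)
    return _from_gemmi_model(st[0], Path(path).stem)


def read_pdb_models(path: str | Path) -> List[ProteinStructure]:
    """Read every MODEL of a (possibly multi-model) PDB file."""
    st = _read_gemmi(path)
    stem = Path(path).stem
    out = []
    for i, model in enumerate(st, start=1):
        out.append(_from_gemmi_model(model, f"{stem}_m{i}" if len(st) > 1 else stem))
    return out


def _atom_line(serial: int, atom: AtomRecord, res: Residue, chain_id: str) -> str:
    name = atom.name
    # standard PDB name justification: 1-letter elements start in column 14
    padded = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
    element = name.strip()[0] if name.strip() else " "
    x, y, z = atom.coords
    return (
        f"ATOM  {serial:5d} {padded} {res.name3:>3s} {chain_id[:1]:1s}"
        f"{res.index:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{atom.bfactor:6.2f}"
        f"          {element:>2s}"
    )


def write_pdb(structure: ProteinStructure, path: str | Path) -> None:
    """Write fixed-column ATOM records (coords to 3 decimals, B to 2)."""
    write_multimodel_pdb([structure], path, model_records=False)


def write_multimodel_pdb(
    structures: Sequence[ProteinStructure],
    path: str | Path,
    model_records: bool = True,
) -> None:
    """Write one or more structures, as MODEL/ENDMDL blocks when asked."""
    lines: List[str] = []
    for imodel, structure in enumerate(structures, start=1):
        if model_records:
            lines.append(f"MODEL {imodel:8d}")
        serial = 1
        for res in structure.residues:
            for atom in res.atoms.values():
                lines.append(_atom_line(serial, atom, res, structure.chain_id))
                serial += 1
        lines.append("TER")
        if model_records:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def get_sequence(structure: ProteinStructure) -> str:
    """One-letter sequence; residues outside the standard 20 become 'X'."""
    return structure.sequence


def mean_confidence(structure: ProteinStructure, region: RegionSpec) -> float:
    """Mean per-residue confidence (pLDDT) over a region.

    The confidence of a residue is the mean B-factor of its atoms; the
    region is intersected with the structure and must overlap it.
    """
    values = []
    for idx in region.indices():
        res = structure.residue_at(idx)
        if res is None or not res.atoms:
            continue
        values.append(
            math.fsum(a.bfactor for a in res.atoms.values()) / len(res.atoms)
        )
    if not values:
        raise ValueError(
            f"region [{region.start}, {region.end}] is disjoint from the "
            f"structure (length {len(structure)})"
        )
    return math.fsum(values) / len(values)
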
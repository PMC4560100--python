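"""PDB-format structure reading, selection, renumbering and writing.

Residues are addressed exclusively by author numbering, i.e. the
``(chain_id, res_seq, i_code)`` triple printed in the coordinate file,
because repeat and domain definitions for transporters are published in
author numbering.  A sequential index exists only internally.

Parsing is backed by :mod:`gemmi`; a fixed-column validation pass runs
first so that malformed ATOM/HETATM records raise an error naming the
offending line (gemmi itself is deliberately lenient).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "Residue",
    "ProteinStructure",
    "ResidueRangeSet",
    "PDBFormatError",
    "read_pdb",
    "select_residues",
    "write_pdb",
]

# waters keep their conventional het-names; needed to recognise
# crystallographic-water restraint partners
WATER_NAMES = {"HOH", "WAT", "DOD"}

HYDROGEN_ELEMENTS = {"H", "D", "T"}


class PDBFormatError(ValueError):
    """Raised for malformed fixed-column PDB records (message names the line)."""


@dataclass(frozen=True)
class AtomRecord:
    """One ATOM/HETATM record (coordinates in Å, author numbering)."""

    serial: int
    name: str
    altloc: str
    res_name: str
    chain_id: str
    res_seq: int
    i_code: str
    x: float
    y: float
    z: float
    occupancy: float = 1.0
    element: str = ""
    is_hetatm: bool = False

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.x, self.y, self.z)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")

    @property
    def coords(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in HYDROGEN_ELEMENTS


@dataclass
class Residue:
    """An ordered group of atoms sharing one (chain, res_seq, i_code) key."""

    chain_id: str
    res_seq: int
    i_code: str
    name: str
    atoms: list[AtomRecord]
    is_hetatm: bool = False

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_seq, self.i_code)

    @property
    def is_water(self) -> bool:
        return self.name in WATER_NAMES

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> AtomRecord | None:
        return self.atom("CA")

    def one_letter(self) -> str:
        info = gemmi.find_tabulated_residue(self.name)
        if info is not None and info.is_amino_acid():
            return info.one_letter_code.upper()
        return "X"


@dataclass
class ProteinStructure:
    """Ordered residues with atoms; the carrier type for every pipeline stage."""

    residues: list[Residue] = field(default_factory=list)
    title: str = ""
    provenance: str = ""

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(keys) != len(set(keys)):
            seen: set[tuple[str, int, str]] = set()
            for k in keys:
                if k in seen:
                    raise ValueError(f"duplicate residue key {k}")
                seen.add(k)

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def residue(self, chain_id: str, res_seq: int, i_code: str = "") -> Residue | None:
        for r in self.residues:
            if r.key == (chain_id, res_seq, i_code):
                return r
        return None

    def polymer(self) -> "ProteinStructure":
        """Amino-acid residues only (drops waters, ions, substrates)."""
        keep = []
        for r in self.residues:
            info = gemmi.find_tabulated_residue(r.name)
            if info is not None and info.is_amino_acid():
                keep.append(r)
        return ProteinStructure(keep, self.title, self.provenance + "|polymer")

    def sequence(self) -> str:
        return "".join(r.one_letter() for r in self.polymer())

    def ca_coords(self) -> np.ndarray:
        """(n, 3) Cα coordinates of residues that have a Cα, in file order."""
        rows = [r.ca.coords for r in self.residues if r.ca is not None]
        if not rows:
            return np.empty((0, 3))
        return np.vstack(rows)

    def ca_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.ca is not None]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ProteinStructure":
        """Return a copy with ``x' = R x + t`` applied to every atom."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        new_res = []
        for r in self.residues:
            new_atoms = []
            for a in r.atoms:
                x, y, z = rotation @ a.coords + translation
                new_atoms.append(replace(a, x=float(x), y=float(y), z=float(z)))
            new_res.append(Residue(r.chain_id, r.res_seq, r.i_code, r.name, new_atoms, r.is_hetatm))
        return ProteinStructure(new_res, self.title, self.provenance + "|transformed")


@dataclass(frozen=True)
class ResidueRangeSet:
    """Inclusive author-numbered residue ranges, e.g. ``A:12-77,A:129-218``."""

    ranges: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        by_chain: dict[str, list[tuple[int, int]]] = {}
        for chain, start, end in self.ranges:
            if start > end:
                raise ValueError(f"range {chain}:{start}-{end} has start > end")
            by_chain.setdefault(chain, []).append((start, end))
        for chain, spans in by_chain.items():
            spans = sorted(spans)
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                if s2 <= e1:
                    raise ValueError(
                        f"overlapping ranges {chain}:{s1}-{e1} and {chain}:{s2}-{e2}"
                    )

    @classmethod
    def from_string(cls, text: str, default_chain: str = "A") -> "ResidueRangeSet":
        """Parse ``"A:12-77,A:129-218"`` (chain prefix optional)."""
        ranges = []
        for part in text.split(","):
            part = part.strip()
            if not part:
                continue
            if ":" in part:
                chain, span = part.split(":", 1)
            else:
                chain, span = default_chain, part
            if "-" in span:
                lo, _, hi = span.partition("-")
            else:
                lo = hi = span
            ranges.append((chain, int(lo), int(hi)))
        return cls(tuple(ranges))

    @classmethod
    def from_ranges(cls, ranges: Iterable[tuple[str, int, int]]) -> "ResidueRangeSet":
        return cls(tuple(ranges))

    def contains(self, chain_id: str, res_seq: int) -> bool:
        return any(
            chain_id == c and s <= res_seq <= e for c, s, e in self.ranges
        )

    def span_size(self) -> int:
        """Total number of residue numbers covered (not residues present)."""
        return sum(e - s + 1 for _, s, e in self.ranges)

    def chains(self) -> set[str]:
        return {c for c, _, _ in self.ranges}

    def __str__(self) -> str:
        return ",".join(f"{c}:{s}-{e}" for c, s, e in self.ranges)

    def union(self, other: "ResidueRangeSet") -> "ResidueRangeSet":
        return ResidueRangeSet(tuple(list(self.ranges) + list(other.ranges)))


# ---------------------------------------------------------------------------
# reading


def _validate_fixed_columns(text: str, source: str) -> int:
    """Check ATOM/HETATM records parse in their fixed columns.

    Returns the number of ATOM records (HETATM not counted). Raises
    :class:`PDBFormatError` naming the first bad line.
    """
    n_atom = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec not in ("ATOM  ", "HETATM"):
            continue
        if len(line) < 54:
            raise PDBFormatError(f"{source}, line {lineno}: record shorter than 54 columns")
        try:
            int(line[6:11])
            int(line[22:26])
            float(line[30:38])
            float(line[38:46])
            float(line[46:54])
            if line[54:60].strip():
                float(line[54:60])
        except ValueError as exc:
            raise PDBFormatError(f"{source}, line {lineno}: {exc}") from None
        if rec == "ATOM  ":
            n_atom += 1
    return n_atom


def _resolve_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one altloc per atom name: highest occupancy, alphabetical tiebreak."""
    by_name: dict[str, list[AtomRecord]] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            order.append(a.name)
        by_name.setdefault(a.name, []).append(a)
    resolved = []
    for name in order:
        best = min(by_name[name], key=lambda a: (-a.occupancy, a.altloc))
        resolved.append(best)
    return resolved


def read_pdb(
    path: str | Path,
    model_index: int = 0,
    chain: str | None = None,
) -> ProteinStructure:
    """Read a PDB file into a :class:`ProteinStructure`.

    Parameters
    ----------
    path:
        PDB-format file containing at least one ATOM record.
    model_index:
        0-based model to read (default: first model).
    chain:
        If given, keep only this chain.

    HETATM records (ions, substrates, waters) are retained and flagged;
    alternate locations are resolved to the highest-occupancy conformer
    (ties broken alphabetically by altloc).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such PDB file: {path}")
    text = path.read_text()
    n_atom = _validate_fixed_columns(text, str(path))
    if n_atom == 0:
        raise PDBFormatError(f"{path}: no ATOM records")
    st = gemmi.read_pdb_string(text)
    if not 0 <= model_index < len(st):
        raise IndexError(f"model index {model_index} out of range (file has {len(st)})")
    model = st[model_index]

    residues: list[Residue] = []
    for ch in model:
        if chain is not None and ch.name != chain:
            continue
        for res in ch:
            is_het = res.het_flag == "H"
            atoms = []
            for a in res:
                atoms.append(
                    AtomRecord(
                        serial=a.serial,
                        name=a.name,
                        altloc="" if a.altloc == "\x00" else a.altloc,
                        res_name=res.name,
                        chain_id=ch.name,
                        res_seq=res.seqid.num,
                        i_code="" if res.seqid.icode.strip() == "" else res.seqid.icode,
                        x=a.pos.x,
                        y=a.pos.y,
                        z=a.pos.z,
                        occupancy=min(max(a.occ, 0.0), 1.0),
                        element=a.element.name,
                        is_hetatm=is_het,
                    )
                )
            atoms = _resolve_altlocs(atoms)
            residues.append(
                Residue(
                    chain_id=ch.name,
                    res_seq=res.seqid.num,
                    i_code="" if res.seqid.icode.strip() == "" else res.seqid.icode,
                    name=res.name,
                    atoms=atoms,
                    is_hetatm=is_het,
                )
            )
    title = path.stem
    for line in text.splitlines():
        if line.startswith("TITLE"):
            title = line[10:].strip() or title
            break
    return ProteinStructure(
        residues,
        title=title,
        provenance=f"read_pdb({path.name}, model={model_index}, chain={chain or 'all'})",
    )


# ---------------------------------------------------------------------------
# selection


def select_residues(
    s: ProteinStructure,
    ranges: ResidueRangeSet,
) -> ProteinStructure:
    """Residues whose (chain, res_seq) fall inside any range, order preserved.

    Missing residue numbers within a range are skipped; the number of
    requested-but-absent residue numbers is recorded in ``provenance`` as
    ``missing=<n>`` so that empty selections are detectable.
    """
    kept = [r for r in s.residues if ranges.contains(r.chain_id, r.res_seq)]
    present = {(r.chain_id, r.res_seq) for r in s.residues}
    missing = 0
    for chain, start, end in ranges.ranges:
        for num in range(start, end + 1):
            if (chain, num) not in present:
                missing += 1
    return ProteinStructure(
        kept,
        title=s.title,
        provenance=f"{s.provenance}|select({ranges}, missing={missing})",
    )


def selection_missing_count(s: ProteinStructure) -> int:
    """Parse the ``missing=`` warning count recorded by :func:`select_residues`."""
    marker = s.provenance.rfind("missing=")
    if marker < 0:
        return 0
    tail = s.provenance[marker + len("missing="):]
    digits = ""
    for ch in tail:
        if ch.isdigit():
            digits += ch
        else:
            break
    return int(digits) if digits else 0


# ---------------------------------------------------------------------------
# writing


def _format_atom_line(
    rec: str,
    serial: int,
    a: AtomRecord,
    res_name: str,
    res_seq: int,
    i_code: str,
) -> str:
    name = a.name
    # standard alignment: 1-letter element symbols start in column 14
    if len(name) < 4 and len(a.element) < 2:
        name = " " + name
    return (
        f"{rec:<6s}{serial:>5d} {name:<4s}{a.altloc or ' ':1s}{res_name:>3s} "
        f"{a.chain_id:1s}{res_seq:>4d}{i_code or ' ':1s}   "
        f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
        f"          {a.element:>2s}"
    )


def write_pdb(
    s: ProteinStructure,
    path: str | Path,
    renumber_from: int | None = None,
) -> Path:
    """Write fixed-column PDB output.

    With ``renumber_from``, residues are renumbered consecutively from that
    value in file order and the original numbering is recorded in REMARK 300
    lines (``REMARK 300 RENUMBER <chain> <old><icode> -> <new>``).
    """
    if len(s) == 0:
        raise ValueError("refusing to write an empty structure")
    if s.n_atoms > 99999:
        raise ValueError(f"{s.n_atoms} atoms exceed the PDB serial-number limit (99999)")
    path = Path(path)
    lines: list[str] = []
    if s.title:
        lines.append(f"TITLE     {s.title[:70]}")
    mapping: list[tuple[str, int, str, int]] = []
    if renumber_from is not None:
        for i, r in enumerate(s.residues):
            mapping.append((r.chain_id, r.res_seq, r.i_code, renumber_from + i))
        for chain, old, icode, new in mapping:
            lines.append(f"REMARK 300 RENUMBER {chain} {old}{icode or ''} -> {new}")
    serial = 0
    for i, r in enumerate(s.residues):
        res_seq = renumber_from + i if renumber_from is not None else r.res_seq
        i_code = "" if renumber_from is not None else r.i_code
        rec = "HETATM" if r.is_hetatm else "ATOM  "
        for a in r.atoms:
            serial += 1
            lines.append(_format_atom_line(rec, serial, a, r.name, res_seq, i_code))
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def renumber_map_from_pdb(path: str | Path) -> dict[tuple[str, int, str], int]:
    """Recover the old→new numbering map from REMARK 300 RENUMBER lines."""
    mapping: dict[tuple[str, int, str], int] = {}
    for line in Path(path).read_text().splitlines():
        if line.startswith("REMARK 300 RENUMBER"):
            _, _, _, chain, old, _, new = line.split()
            icode = ""
            if not old[-1].isdigit():
                icode = old[-1]
                old = old[:-1]
            mapping[(chain, int(old), icode)] = int(new)
    return mapping
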
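"""Coordinate input and domain-range handling.

Structures are read from PDB-format files (via gemmi) into a small typed
in-memory model: a :class:`Structure` holds chains of :class:`Residue`
objects, each identified by ``(chain id, author residue number, insertion
code)`` with coordinates in Angstroms.  Domain boundaries use the ECOD range
dialect ``"CHAIN:START-END[,CHAIN:START-END...]"`` (e.g. ``"A:1-170"``).

Only the first model of multi-model files is read; waters are dropped;
alternate locations are resolved to the highest-occupancy conformer.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "Residue",
    "Chain",
    "Structure",
    "DomainRange",
    "EmptyStructureError",
    "RangeParseError",
    "parse_structure",
    "parse_domain_range",
    "residues_in_range",
    "write_structure",
]

#: 3-letter codes treated as polymer residues when they appear in ATOM records.
STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})


class EmptyStructureError(ValueError):
    """Raised when a coordinate file contains no usable atoms."""


class RangeParseError(ValueError):
    """Raised for a malformed ECOD-style range string."""


@dataclass
class Residue:
    """One residue: polymer (amino acid) or hetero (ligand candidate)."""

    chain_id: str
    number: int
    icode: str  # "" when absent
    name: str
    atoms: dict[str, np.ndarray] = field(default_factory=dict)
    elements: dict[str, str] = field(default_factory=dict)
    is_polymer: bool = True

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.icode)

    def atom(self, name: str) -> np.ndarray | None:
        return self.atoms.get(name)

    def heavy_coords(self) -> np.ndarray:
        """(n, 3) array of non-hydrogen atom coordinates."""
        pts = [
            xyz
            for name, xyz in self.atoms.items()
            if self.elements.get(name, "") not in ("H", "D")
        ]
        return np.asarray(pts) if pts else np.empty((0, 3))

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Residue {self.chain_id}:{self.name}{self.number}{self.icode}>"


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def polymer(self) -> list[Residue]:
        return [r for r in self.residues if r.is_polymer]

    def hetero(self) -> list[Residue]:
        return [r for r in self.residues if not r.is_polymer]


@dataclass
class Structure:
    id: str
    chains: list[Chain] = field(default_factory=list)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"chain {chain_id!r} not in structure {self.id!r}")

    def residues(self) -> list[Residue]:
        return [r for c in self.chains for r in c.residues]

    def polymer_residues(self) -> list[Residue]:
        return [r for c in self.chains for r in c.polymer()]

    def hetero_residues(self) -> list[Residue]:
        return [r for c in self.chains for r in c.hetero()]


@dataclass(frozen=True)
class DomainRange:
    """Inclusive residue-number segments, e.g. parsed from ``"A:1-170"``."""

    segments: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise RangeParseError("domain range has no segments")
        for chain, start, end in self.segments:
            if start > end:
                raise RangeParseError(f"segment {chain}:{start}-{end} has start > end")

    def __str__(self) -> str:
        return ",".join(f"{c}:{a}-{b}" for c, a, b in self.segments)

    def contains(self, chain_id: str, number: int) -> bool:
        return any(
            c == chain_id and a <= number <= b for c, a, b in self.segments
        )


# segment grammar: CHAIN:START-END with optionally negative residue numbers
_SEGMENT_RE = re.compile(r"^([A-Za-z0-9]+):(-?\d+)-(-?\d+)$")


def parse_domain_range(text: str) -> DomainRange:
    """Parse an ECOD-dialect range string into a :class:`DomainRange`."""
    segments = []
    for part in text.split(","):
        part = part.strip()
        m = _SEGMENT_RE.match(part)
        if m is None:
            raise RangeParseError(f"malformed range segment: {part!r}")
        segments.append((m.group(1), int(m.group(2)), int(m.group(3))))
    return DomainRange(tuple(segments))


def parse_structure(path: str | Path, *, keep_waters: bool = False) -> Structure:
    """Read a PDB-format file into a :class:`Structure`.

    ATOM records with standard amino-acid names become polymer residues;
    everything else is a hetero (ligand-candidate) residue.  Waters are
    excluded unless ``keep_waters``.  Alternate locations are resolved to the
    highest-occupancy conformer.  Only the first model is used.
    """
    path = Path(path)
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    model = st[0]

    out = Structure(id=path.stem)
    for gchain in model:
        chain = Chain(chain_id=gchain.name)
        for gres in gchain:
            if not keep_waters and gres.name in WATER_NAMES:
                continue
            is_polymer = gres.het_flag == "A" and gres.name in STANDARD_AA
            res = Residue(
                chain_id=gchain.name,
                number=gres.seqid.num,
                icode=gres.seqid.icode.strip(),
                name=gres.name,
                is_polymer=is_polymer,
            )
            # resolve altlocs: keep highest occupancy per atom name
            best_occ: dict[str, float] = {}
            for atom in gres:
                occ = atom.occ
                if atom.name not in best_occ or occ > best_occ[atom.name]:
                    best_occ[atom.name] = occ
                    res.atoms[atom.name] = np.array(
                        [atom.pos.x, atom.pos.y, atom.pos.z]
                    )
                    res.elements[atom.name] = atom.element.name.upper()
            if res.atoms:
                chain.residues.append(res)
        if chain.residues:
            chain.residues.sort(key=lambda r: (r.number, r.icode))
            out.chains.append(chain)

    if not out.residues():
        raise EmptyStructureError(f"{path}: no atoms after filtering")
    return out


def residues_in_range(s: Structure, r: DomainRange) -> list[Residue]:
    """Residues of ``s`` inside any segment of ``r`` (deduplicated, chain order)."""
    wanted_chains = {c for c, _, _ in r.segments}
    present = {c.chain_id for c in s.chains}
    missing = wanted_chains - present
    if missing:
        raise KeyError(f"chain(s) {sorted(missing)} not in structure {s.id!r}")
    out = []
    for chain in s.chains:
        for res in chain.residues:
            if r.contains(res.chain_id, res.number):
                out.append(res)
    return out


def write_structure(s: Structure, path: str | Path) -> None:
    """Write a :class:`Structure` as a PDB-format file (via gemmi)."""
    st = gemmi.Structure()
    st.name = s.id
    model = gemmi.Model("1")
    for chain in s.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.number, res.icode or " ")
            gres.het_flag = "A" if res.is_polymer else "H"
            for name, xyz in res.atoms.items():
                atom = gemmi.Atom()
                atom.name = name
                atom.element = gemmi.Element(res.elements.get(name, name[0]))
                atom.pos = gemmi.Position(*map(float, xyz))
                atom.occ = 1.0
                gres.add_atom(atom)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
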
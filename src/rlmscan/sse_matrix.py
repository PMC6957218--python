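"""Secondary-structure assignment and the SSE interaction matrix.

Residues are labeled helix or strand from backbone dihedral windows,
single-residue gaps are bridged, and maximal runs become :class:`SSE`
segments (strands of at least 3 residues, helices of at least 4).  For every
SSE pair the :class:`InteractionMatrix` records one relation code:

``P``/``A``
    two strands linked by at least two backbone N...O hydrogen bonds,
    parallel or antiparallel by the sign of the axis dot product;
``C``/``T``
    packing contact (any pair involving a helix) closer than the contact
    cutoff -- ``C`` for near-parallel or near-antiparallel axes, ``T`` for
    crossing angles between ``t_angle_min`` and ``180 - t_angle_min``;
``none``
    otherwise.

The motif matcher additionally needs to know which face of the beta-sheet a
helix packs against; :func:`helix_side_sign` computes that sign against the
least-squares plane of an explicit strand set, so the caller can use the
strands of one candidate motif rather than the whole structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Residue, Structure

__all__ = [
    "SSE",
    "InteractionMatrix",
    "SSEParams",
    "assign_sse",
    "build_interaction_matrix",
    "helix_side_sign",
    "matrix_to_tsv",
]

HELIX = "helix"
STRAND = "strand"


@dataclass(frozen=True)
class SSEParams:
    """Tunable thresholds (all config-exposed; defaults documented in docs/methods.md)."""

    helix_phi: tuple[float, float] = (-100.0, -30.0)
    helix_psi: tuple[float, float] = (-80.0, -5.0)
    strand_phi: tuple[float, float] = (-180.0, -45.0)
    strand_psi: tuple[float, float] = (45.0, 225.0)  # mod 360
    min_strand: int = 3
    min_helix: int = 4
    hbond_cutoff: float = 3.5  # N...O, Angstrom
    min_hbonds: int = 2
    ca_ladder: tuple[float, float] = (4.0, 6.0)  # CA-only fallback
    contact_cutoff: float = 6.5  # min heavy-atom distance for C/T
    t_angle_min: float = 30.0  # degrees
    chain_break: float = 2.5  # max C(i-1)-N(i) bond length


@dataclass
class SSE:
    index: int
    kind: str  # HELIX or STRAND
    residues: list[Residue]
    start_vector: np.ndarray = field(default_factory=lambda: np.zeros(3))
    end_vector: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axis: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def chain_id(self) -> str:
        return self.residues[0].chain_id

    @property
    def start(self) -> int:
        return self.residues[0].number

    @property
    def end(self) -> int:
        return self.residues[-1].number

    def ca_coords(self) -> np.ndarray:
        return np.asarray([r.atom("CA") for r in self.residues])

    def range_str(self) -> str:
        return f"{self.chain_id}:{self.start}-{self.end}"

    def __repr__(self) -> str:  # pragma: no cover
        return f"<SSE {self.index} {self.kind} {self.range_str()}>"


@dataclass
class InteractionMatrix:
    """Symmetric pairwise relation codes over a structure's SSE list."""

    n: int
    codes: dict[tuple[int, int], str] = field(default_factory=dict)
    sides: dict[tuple[int, int], int] = field(default_factory=dict)

    def code(self, i: int, j: int) -> str:
        if i == j:
            return "none"
        return self.codes.get((min(i, j), max(i, j)), "none")

    def side(self, i: int, j: int) -> int | None:
        """Global-sheet side sign for a helix-strand C/T pair (export only)."""
        return self.sides.get((min(i, j), max(i, j)))


def _dihedral(p0, p1, p2, p3) -> float:
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1n) * b1n
    w = b2 - (b2 @ b1n) * b1n
    x = v @ w
    y = np.cross(b1n, v) @ w
    return float(np.degrees(np.arctan2(y, x)))


def _in_window(value: float | None, lo: float, hi: float) -> bool:
    if value is None:
        return False
    if hi <= 180.0:
        return lo <= value <= hi
    # window wraps past +180 (strand psi [45, 225])
    return value >= lo or value <= hi - 360.0


def _phi_psi(chain: list[Residue], params: SSEParams):
    """Per-residue (phi, psi) with None at termini and chain breaks."""
    n = len(chain)
    phi: list[float | None] = [None] * n
    psi: list[float | None] = [None] * n
    for i in range(n):
        r = chain[i]
        N, CA, C = r.atom("N"), r.atom("CA"), r.atom("C")
        if N is None or CA is None or C is None:
            continue
        if i > 0:
            pc = chain[i - 1].atom("C")
            if pc is not None and np.linalg.norm(N - pc) <= params.chain_break:
                phi[i] = _dihedral(pc, N, CA, C)
        if i < n - 1:
            nn = chain[i + 1].atom("N")
            if nn is not None and np.linalg.norm(nn - C) <= params.chain_break:
                psi[i] = _dihedral(N, CA, C, nn)
    return phi, psi


def _label(phi: float | None, psi: float | None, params: SSEParams) -> str:
    """'H', 'E' or '-'; a lone available dihedral decides at termini."""
    if phi is None and psi is None:
        return "-"
    hel = (phi is None or _in_window(phi, *params.helix_phi)) and (
        psi is None or _in_window(psi, *params.helix_psi)
    )
    strand = (phi is None or _in_window(phi, *params.strand_phi)) and (
        psi is None or _in_window(psi, *params.strand_psi)
    )
    if hel:
        return "H"
    if strand:
        return "E"
    return "-"


def _fit_axis(sse: SSE) -> None:
    cas = sse.ca_coords()
    centroid = cas.mean(axis=0)
    _, _, vt = np.linalg.svd(cas - centroid)
    axis = vt[0]
    if axis @ (cas[-1] - cas[0]) < 0:
        axis = -axis
    t = (cas - centroid) @ axis
    sse.axis = axis
    sse.start_vector = centroid + t.min() * axis
    sse.end_vector = centroid + t.max() * axis


def assign_sse(
    s: Structure,
    params: SSEParams = SSEParams(),
    *,
    sse_string: dict[str, str] | None = None,
) -> list[SSE]:
    """Assign helix/strand segments from backbone dihedrals.

    ``sse_string`` optionally supplies an externally computed per-chain label
    string ('H'/'E'/'-', one character per polymer residue) that replaces the
    dihedral windows, e.g. from DSSP.
    """
    sses: list[SSE] = []
    for chain in s.chains:
        poly = chain.polymer()
        if len(poly) < 4:
            continue
        if sse_string is not None and chain.chain_id in sse_string:
            labels = list(sse_string[chain.chain_id])
            if len(labels) != len(poly):
                raise ValueError(
                    f"SSE string length {len(labels)} != {len(poly)} residues "
                    f"in chain {chain.chain_id}"
                )
        else:
            phi, psi = _phi_psi(poly, params)
            labels = [_label(phi[i], psi[i], params) for i in range(len(poly))]
            # bridge single-residue gaps between identical labels
            for i in range(1, len(labels) - 1):
                if labels[i] == "-" and labels[i - 1] == labels[i + 1] != "-":
                    labels[i] = labels[i - 1]
        # split runs at chain breaks so loops modeled with gaps never merge
        breaks = set()
        for i in range(1, len(poly)):
            pc = poly[i - 1].atom("C")
            nn = poly[i].atom("N")
            if pc is None or nn is None or np.linalg.norm(nn - pc) > params.chain_break:
                breaks.add(i)
        start = 0
        for i in range(1, len(poly) + 1):
            boundary = (
                i == len(poly) or labels[i] != labels[start] or i in breaks
            )
            if not boundary:
                continue
            run = labels[start]
            length = i - start
            if run == "E" and length >= params.min_strand:
                kind = STRAND
            elif run == "H" and length >= params.min_helix:
                kind = HELIX
            else:
                kind = None
            if kind is not None and all(
                poly[k].atom("CA") is not None for k in range(start, i)
            ):
                sses.append(SSE(index=len(sses), kind=kind, residues=poly[start:i]))
            start = i
    for sse in sses:
        _fit_axis(sse)
    return sses


def _count_hbonds(a: SSE, b: SSE, params: SSEParams) -> int:
    """Backbone N...O pairs closer than the H-bond cutoff, either direction."""
    na = [r.atom("N") for r in a.residues if r.atom("N") is not None]
    oa = [r.atom("O") for r in a.residues if r.atom("O") is not None]
    nb = [r.atom("N") for r in b.residues if r.atom("N") is not None]
    ob = [r.atom("O") for r in b.residues if r.atom("O") is not None]
    if (not na or not ob) and (not nb or not oa):
        return _ca_ladder_pairs(a, b, params)
    count = 0
    for ns, os_ in ((na, ob), (nb, oa)):
        if not ns or not os_:
            continue
        d = np.linalg.norm(
            np.asarray(ns)[:, None, :] - np.asarray(os_)[None, :, :], axis=-1
        )
        count += int((d < params.hbond_cutoff).sum())
    return count


def _ca_ladder_pairs(a: SSE, b: SSE, params: SSEParams) -> int:
    """CA-only fallback: longest run of consecutive residue pairs whose CA-CA
    distance sits in the ladder window; returns a pseudo H-bond count (the
    run length) so the >= min_hbonds criterion applies unchanged."""
    ca_a = a.ca_coords()
    ca_b = b.ca_coords()
    d = np.linalg.norm(ca_a[:, None, :] - ca_b[None, :, :], axis=-1)
    lo, hi = params.ca_ladder
    ok = (d >= lo) & (d <= hi)
    best = 0
    for offset in range(-ok.shape[1] + 1, ok.shape[0]):
        diag = np.diagonal(ok, offset=-offset)
        run = cur = 0
        for v in diag:
            cur = cur + 1 if v else 0
            run = max(run, cur)
        best = max(best, run)
    return best


def _min_heavy_distance(a: SSE, b: SSE) -> float:
    pa = np.concatenate([r.heavy_coords() for r in a.residues])
    pb = np.concatenate([r.heavy_coords() for r in b.residues])
    tree = cKDTree(pb)
    d, _ = tree.query(pa, k=1)
    return float(d.min())


def _crossing_angle(a: SSE, b: SSE) -> float:
    cosang = float(np.clip(a.axis @ b.axis, -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


def sheet_plane(strands: list[SSE]) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane through the CA atoms of ``strands``.

    Returns (point, unit normal).  The normal's orientation is arbitrary but
    deterministic (SVD convention), hence consistent within one structure.
    """
    cas = np.concatenate([s.ca_coords() for s in strands])
    centroid = cas.mean(axis=0)
    _, _, vt = np.linalg.svd(cas - centroid)
    return centroid, vt[2]


def helix_side_sign(helix: SSE, strands: list[SSE]) -> int:
    """+1/-1: which face of the strands' plane the helix centroid lies on."""
    point, normal = sheet_plane(strands)
    centroid = helix.ca_coords().mean(axis=0)
    return 1 if (centroid - point) @ normal >= 0 else -1


def build_interaction_matrix(
    sses: list[SSE], s: Structure | None = None, params: SSEParams = SSEParams()
) -> InteractionMatrix:
    """Pairwise relation codes for all SSE pairs (see module docstring)."""
    m = InteractionMatrix(n=len(sses))
    strands = [x for x in sses if x.kind == STRAND]
    for i in range(len(sses)):
        for j in range(i + 1, len(sses)):
            a, b = sses[i], sses[j]
            if a.kind == STRAND and b.kind == STRAND:
                if _count_hbonds(a, b, params) >= params.min_hbonds:
                    m.codes[(i, j)] = "P" if a.axis @ b.axis > 0 else "A"
                continue
            if _min_heavy_distance(a, b) < params.contact_cutoff:
                theta = _crossing_angle(a, b)
                if params.t_angle_min <= theta <= 180.0 - params.t_angle_min:
                    m.codes[(i, j)] = "T"
                else:
                    m.codes[(i, j)] = "C"
                helix, strand = (a, b) if a.kind == HELIX else (b, a)
                if helix.kind == HELIX and strand.kind == STRAND and len(strands) >= 2:
                    m.sides[(i, j)] = helix_side_sign(helix, strands)
    return m


def matrix_to_tsv(sses: list[SSE], m: InteractionMatrix) -> str:
    """Auditable TSV export: one SSE table, then the pairwise code table."""
    lines = ["index\tkind\trange"]
    for sse in sses:
        lines.append(f"{sse.index}\t{sse.kind}\t{sse.range_str()}")
    lines.append("i\tj\tcode\tside")
    for (i, j), code in sorted(m.codes.items()):
        side = m.sides.get((i, j))
        lines.append(f"{i}\t{j}\t{code}\t{'' if side is None else side}")
    return "\n".join(lines) + "\n"
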
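"""Synthetic fixtures: ideal RLM structures, decoys, MSAs, annotation tables.

Everything the pipeline consumes can be generated here deterministically, so
the package builds and tests without any database download.

Structures are assembled from rigid ideal-geometry backbone segments:
strands at (phi, psi) = (-120, +120), helices at (-57, -47), built by
natural-extension (NeRF) chain construction and rigidly placed on a
three-layer alpha/beta/alpha template -- a parallel beta2-beta1-beta3 sheet
with helices on opposite faces.  Adjacent strands are offset by 3.8 A
across the sheet, 0.6 A along it and 0.4 A out of plane, the registration at
which ideal rigid strands form 8 backbone N...O hydrogen bonds under a 3.5 A
criterion.  Loops are
smooth interpolating backbone paths whose alternating local geometry keeps
them out of the helix/strand dihedral windows; they are not physically
realistic conformations, and only secondary-structure assignment and
distances are meant to be correct.

Decoys violate exactly one motif clause each, so a failing motif test
localizes to that clause.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rlm_search import RLMMatch
from .sse_matrix import SSE, HELIX, STRAND
from .structure_io import Chain, Residue, Structure

__all__ = [
    "FixtureSpec",
    "AnnotationBundle",
    "make_ideal_rlm",
    "make_decoy",
    "make_msa",
    "make_annotation_tables",
    "build_segment",
    "DECOY_KINDS",
    "CREVICE_LIGAND",
]

DECOY_KINDS = ("antiparallel_V", "short_strand", "no_crossover", "same_face_helices")

#: a ligand placement that lands in the beta1/beta3 crevice of the default
#: ideal fixture, touching elements I, V and the catalytic loop only
CREVICE_LIGAND = ("LIG", "crevice", (-0.54, -3.63, 0.67))

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# ideal backbone covalent geometry (lengths A, angles deg)
_BOND = dict(N_CA=1.458, CA_C=1.525, C_N=1.329, C_O=1.231)
_ANGLE = dict(N_CA_C=111.2, CA_C_N=116.2, C_N_CA=121.7, CA_C_O=120.8)


@dataclass(frozen=True)
class FixtureSpec:
    """Geometry plan for one ideal-RLM structure (same spec => same bytes)."""

    seed: int = 0
    strand_len: int = 6
    helix_len: int = 10
    loop_len: int = 4
    strand_spacing: float = 3.8   # across-sheet offset between adjacent strands
    strand_stagger: float = 0.6   # along-axis offset for H-bond registration
    strand_lift: float = 0.4      # out-of-plane offset completing the registration
    helix_lateral: float = 1.9    # helix x-offset from the central strand
    helix_height: float = 6.2     # |z| of helix axes above/below the sheet
    insertion: bool = False       # add a beta-alpha insertion between III and IV
    # ligand placements: (hetero residue name, anchor, offset vector);
    # anchor is an element name ("I".."V") or "crevice" (the beta1/beta3 cleft)
    ligands: tuple[tuple[str, str, tuple[float, float, float]], ...] = ()


# ---------------------------------------------------------------------------
# rigid-segment construction


def _place_atom(a, b, c, bond, angle, dihedral):
    angle = np.deg2rad(angle)
    dihedral = np.deg2rad(dihedral)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(dihedral),
            bond * np.sin(angle) * np.sin(dihedral),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_segment(phis: list[float], psis: list[float]) -> list[dict[str, np.ndarray]]:
    """NeRF-build backbone (N, CA, C, O) for ``len(phis)`` residues, omega=180."""
    n = len(phis)
    N = np.zeros(3)
    CA = np.array([_BOND["N_CA"], 0.0, 0.0])
    C = _place_atom(np.array([0.0, 1.0, 0.0]), N, CA, _BOND["CA_C"], _ANGLE["N_CA_C"], 0.0)
    res = [dict(N=N, CA=CA, C=C)]
    for i in range(1, n):
        prev = res[-1]
        Nn = _place_atom(prev["N"], prev["CA"], prev["C"], _BOND["C_N"], _ANGLE["CA_C_N"], psis[i - 1])
        CAn = _place_atom(prev["CA"], prev["C"], Nn, _BOND["N_CA"], _ANGLE["C_N_CA"], 180.0)
        Cn = _place_atom(prev["C"], Nn, CAn, _BOND["CA_C"], _ANGLE["N_CA_C"], phis[i])
        res.append(dict(N=Nn, CA=CAn, C=Cn))
    for i, r in enumerate(res):
        psi = psis[i] if i < n - 1 else psis[-1]
        r["O"] = _place_atom(r["N"], r["CA"], r["C"], _BOND["C_O"], _ANGLE["CA_C_O"], psi + 180.0)
    return res


def _segment_axis(res):
    cas = np.array([r["CA"] for r in res])
    centroid = cas.mean(axis=0)
    _, _, vt = np.linalg.svd(cas - centroid)
    axis = vt[0]
    if axis @ (cas[-1] - cas[0]) < 0:
        axis = -axis
    return centroid, axis


def _rotation_between(u, v):
    """Rotation matrix taking unit vector u onto unit vector v."""
    w = np.cross(u, v)
    s = np.linalg.norm(w)
    d = float(u @ v)
    if s < 1e-12:
        if d > 0:
            return np.eye(3)
        # 180 deg: rotate about any axis perpendicular to u
        p = np.array([1.0, 0.0, 0.0])
        if abs(u[0]) > 0.9:
            p = np.array([0.0, 1.0, 0.0])
        axis = np.cross(u, p)
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    wx = np.array([[0, -w[2], w[1]], [w[2], 0, -w[0]], [-w[1], w[0], 0]])
    return np.eye(3) + wx + wx @ wx * ((1 - d) / s**2)


def _oriented_segment(n_res, phi, psi, direction, center):
    """Build a segment and rigidly place it: axis along ``direction``, CA
    centroid at ``center``."""
    seg = build_segment([phi] * n_res, [psi] * n_res)
    centroid, axis = _segment_axis(seg)
    R = _rotation_between(axis, np.asarray(direction, float))
    out = []
    for r in seg:
        out.append({k: R @ (v - centroid) + np.asarray(center, float) for k, v in r.items()})
    return out


def _rodrigues(v, axis, angle):
    axis = axis / np.linalg.norm(axis)
    return (
        v * np.cos(angle)
        + np.cross(axis, v) * np.sin(angle)
        + axis * (axis @ v) * (1 - np.cos(angle))
    )


def _loop_path(p0, p1, n_res, bulge):
    """Backbone for ``n_res`` loop residues along a quadratic Bezier from p0
    to p1.  The N/C offsets corkscrew around the path (golden-angle step per
    residue), which scrambles consecutive dihedrals so no three loop residues
    can share a helix or strand label and merge with a flanking element."""
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    mid = 0.5 * (p0 + p1) + np.asarray(bulge, float)
    out = []
    for i in range(n_res):
        t = (i + 1) / (n_res + 1)
        ca = (1 - t) ** 2 * p0 + 2 * (1 - t) * t * mid + t**2 * p1
        tan = 2 * (1 - t) * (mid - p0) + 2 * t * (p1 - mid)
        tan /= np.linalg.norm(tan)
        ref = np.array([0.0, 0.0, 1.0])
        if abs(tan @ ref) > 0.9:
            ref = np.array([1.0, 0.0, 0.0])
        nrm = np.cross(tan, ref)
        nrm /= np.linalg.norm(nrm)
        nrm = _rodrigues(nrm, tan, i * 2.39996)  # golden angle, aperiodic
        n_at = ca - 0.74 * tan + 0.55 * nrm
        c_at = ca + 0.74 * tan + 0.55 * nrm
        o_at = c_at + 1.23 * np.cross(tan, nrm)
        out.append(dict(N=n_at, CA=ca, C=c_at, O=o_at))
    return out


# ---------------------------------------------------------------------------
# structure assembly


def _assemble(
    structure_id: str,
    pieces: list[tuple[str, list[dict[str, np.ndarray]]]],
    ligands: list[tuple[str, np.ndarray]] = (),
) -> tuple[Structure, dict[str, tuple[int, int]]]:
    """Concatenate labeled backbone pieces into one chain A structure.

    Returns the structure and a map label -> (first, last) residue number
    for every non-loop piece.
    """
    chain = Chain(chain_id="A")
    ranges: dict[str, tuple[int, int]] = {}
    num = 0
    for label, seg in pieces:
        first = num + 1
        for r in seg:
            num += 1
            res = Residue(
                chain_id="A", number=num, icode="", name="ALA", is_polymer=True
            )
            for aname in ("N", "CA", "C", "O"):
                res.atoms[aname] = np.asarray(r[aname], float)
                res.elements[aname] = aname[0]
            chain.residues.append(res)
        if not label.startswith("loop"):
            ranges[label] = (first, num)
    st = Structure(id=structure_id, chains=[chain])
    for i, (name, pos) in enumerate(ligands, start=1):
        res = Residue(
            chain_id="A", number=num + i, icode="", name=name, is_polymer=False
        )
        # a small 3-atom rigid ligand around the anchor position
        for j, off in enumerate(
            (np.zeros(3), np.array([1.4, 0.0, 0.0]), np.array([0.0, 1.3, 0.4]))
        ):
            res.atoms[f"C{j + 1}"] = np.asarray(pos, float) + off
            res.elements[f"C{j + 1}"] = "C"
        chain.residues.append(res)
    return st, ranges


def _sse_from_range(structure, index, kind, rng):
    chain = structure.chains[0]
    residues = [r for r in chain.residues if rng[0] <= r.number <= rng[1]]
    sse = SSE(index=index, kind=kind, residues=residues)
    cas = np.array([r.atom("CA") for r in residues])
    centroid = cas.mean(axis=0)
    _, _, vt = np.linalg.svd(cas - centroid)
    axis = vt[0]
    if axis @ (cas[-1] - cas[0]) < 0:
        axis = -axis
    t = (cas - centroid) @ axis
    sse.axis = axis
    sse.start_vector = centroid + t.min() * axis
    sse.end_vector = centroid + t.max() * axis
    return sse


def _layout(spec: FixtureSpec):
    """Element placements for the canonical sandwich (centers, directions)."""
    dx, dy = spec.strand_spacing, spec.strand_stagger
    up = (0.0, 1.0, 0.0)
    down = (0.0, -1.0, 0.0)
    return {
        "I": dict(kind=STRAND, n=spec.strand_len, center=(0.0, 0.0, 0.0), dir=up),
        "II": dict(
            kind=HELIX,
            n=spec.helix_len,
            center=(-spec.helix_lateral, 0.0, spec.helix_height),
            dir=down,
        ),
        "III": dict(
            kind=STRAND, n=spec.strand_len, center=(-dx, -dy, -spec.strand_lift), dir=up
        ),
        "IV": dict(
            kind=HELIX,
            n=spec.helix_len,
            center=(spec.helix_lateral, 0.0, -spec.helix_height),
            dir=down,
        ),
        "V": dict(
            kind=STRAND, n=spec.strand_len, center=(dx, dy, spec.strand_lift), dir=up
        ),
    }


def _build_sandwich(structure_id: str, spec: FixtureSpec, layout, order, bulges):
    """Build segments per ``layout``, connect them in ``order`` with loops."""
    segs = {
        name: _oriented_segment(
            p["n"],
            -57.0 if p["kind"] == HELIX else -120.0,
            -47.0 if p["kind"] == HELIX else 120.0,
            p["dir"],
            p["center"],
        )
        for name, p in layout.items()
    }
    pieces: list[tuple[str, list]] = []
    for k, name in enumerate(order):
        if k > 0:
            prev = segs[order[k - 1]]
            bulge = bulges.get((order[k - 1], name), (0.0, 0.0, 3.0))
            pieces.append(
                (
                    f"loop{k}",
                    _loop_path(
                        prev[-1]["CA"], segs[name][0]["CA"], spec.loop_len, bulge
                    ),
                )
            )
        pieces.append((name, segs[name]))

    # ligand anchor points
    anchors = {}
    for name in layout:
        cas = np.array([r["CA"] for r in segs[name]])
        anchors[name] = cas.mean(axis=0)
    top_I = max(segs["I"], key=lambda r: r["CA"][1])["CA"]
    top_V = max(segs["V"], key=lambda r: r["CA"][1])["CA"]
    anchors["crevice"] = 0.5 * (top_I + top_V)

    ligands = [
        (name, anchors[anchor] + np.asarray(off, float))
        for name, anchor, off in spec.ligands
    ]
    return _assemble(structure_id, pieces, ligands), anchors


def make_ideal_rlm(spec: FixtureSpec = FixtureSpec()) -> tuple[Structure, RLMMatch]:
    """Ideal beta-alpha-beta-alpha-beta sandwich plus its ground-truth match.

    With ``spec.insertion`` a beta-alpha unit is appended after element III
    (one more parallel strand extending the sheet away from beta1, plus a
    helix above it), mimicking the first four strands of a classic Rossmann
    domain; the matcher must exclude it from the motif elements.
    """
    layout = _layout(spec)
    order = ["I", "II", "III", "IV", "V"]
    if spec.insertion:
        dx, dy = spec.strand_spacing, spec.strand_stagger
        layout["ins_b"] = dict(
            kind=STRAND,
            n=spec.strand_len,
            center=(-2 * dx, -2 * dy, -2 * spec.strand_lift),
            dir=(0.0, 1.0, 0.0),
        )
        layout["ins_a"] = dict(
            kind=HELIX,
            n=spec.helix_len,
            center=(-2 * dx - spec.helix_lateral, -dy, spec.helix_height),
            dir=(0.0, -1.0, 0.0),
        )
        order = ["I", "II", "III", "ins_b", "ins_a", "IV", "V"]

    bulges = {
        ("I", "II"): (1.0, 1.5, 3.5),
        ("II", "III"): (-1.0, -1.5, 3.5),
        ("III", "IV"): (-1.0, 1.5, -3.5),
        ("IV", "V"): (1.0, -1.5, -3.5),
        ("III", "ins_b"): (-1.0, 1.5, 3.5),
        ("ins_b", "ins_a"): (-1.0, 1.5, 3.5),
        ("ins_a", "IV"): (0.0, 1.5, -4.5),
    }
    name = "ideal_rlm_ins" if spec.insertion else "ideal_rlm"
    (structure, ranges), _ = _build_sandwich(name, spec, layout, order, bulges)

    # ground truth: the scripted element ranges, as SSE objects
    elements = {}
    idx = 0
    kinds = dict(I=STRAND, II=HELIX, III=STRAND, IV=HELIX, V=STRAND)
    for ename in ("I", "II", "III", "IV", "V"):
        elements[ename] = _sse_from_range(structure, idx, kinds[ename], ranges[ename])
        idx += 1
    chain = structure.chains[0]
    cat = [
        r
        for r in chain.polymer()
        if ranges["I"][1] < r.number < ranges["II"][0]
    ]
    pred_end = ranges["ins_a"][1] if spec.insertion else ranges["III"][1]
    cross = [r for r in chain.polymer() if pred_end < r.number < ranges["IV"][0]]
    truth = RLMMatch(
        elements=elements,
        catalytic_loop=cat,
        crossover_loop=cross,
        variant="helix-IV",
        structure_id=structure.id,
    )
    return structure, truth


def make_decoy(kind: str, seed: int = 0) -> Structure:
    """A structure violating exactly one RLM clause; yields zero matches.

    - ``antiparallel_V``: the last strand runs antiparallel to the first;
    - ``short_strand``: the second sheet strand has only 2 residues;
    - ``no_crossover``: sequential sheet order 1-2-3, so the last strand
      never returns to H-bond the first;
    - ``same_face_helices``: both helices pack on the same sheet face.
    """
    if kind not in DECOY_KINDS:
        raise ValueError(f"unknown decoy kind {kind!r}; expected one of {DECOY_KINDS}")
    spec = FixtureSpec(seed=seed)
    layout = _layout(spec)
    dx, dy = spec.strand_spacing, spec.strand_stagger
    if kind == "antiparallel_V":
        layout["V"]["dir"] = (0.0, -1.0, 0.0)
    elif kind == "short_strand":
        layout["III"]["n"] = 2
    elif kind == "no_crossover":
        layout["III"]["center"] = (dx, dy, spec.strand_lift)
        layout["V"]["center"] = (2 * dx, 2 * dy, 2 * spec.strand_lift)
        layout["II"]["center"] = (spec.helix_lateral, 0.0, spec.helix_height)
        layout["IV"]["center"] = (dx + spec.helix_lateral, dy, -spec.helix_height)
    elif kind == "same_face_helices":
        layout["IV"]["center"] = (spec.helix_lateral, 0.0, spec.helix_height)
    bulges = {
        ("I", "II"): (1.0, 1.5, 3.5),
        ("II", "III"): (-1.0, -1.5, 3.5),
        ("III", "IV"): (-1.0, 1.5, -3.5),
        ("IV", "V"): (1.0, -1.5, -3.5),
    }
    if kind in ("no_crossover", "same_face_helices"):
        bulges[("III", "IV")] = (1.0, 1.5, -3.5) if kind == "no_crossover" else (1.0, 1.5, 5.0)
        bulges[("IV", "V")] = (1.0, -1.5, -3.5) if kind == "no_crossover" else (1.0, -1.5, 5.0)
    (structure, _), _ = _build_sandwich(f"decoy_{kind}", spec, layout, ["I", "II", "III", "IV", "V"], bulges)
    return structure


# ---------------------------------------------------------------------------
# MSA generator


def make_msa(
    n_seqs: int = 50,
    L: int = 200,
    rlm_columns: list[int] | None = None,
    p_in: float = 0.9,
    p_out: float = 0.3,
    seed: int = 0,
) -> tuple[list[str], list[int]]:
    """Gapless MSA with elevated conservation in ``rlm_columns``.

    Each column draws residues i.i.d. from a dominant-residue mixture: the
    column's dominant amino acid with probability ``p`` (``p_in`` inside the
    designated motif columns, ``p_out`` outside), otherwise uniform over the
    remaining 19.  Returns (rows, rlm_columns).
    """
    if not (0.0 <= p_out <= 1.0 and 0.0 <= p_in <= 1.0):
        raise ValueError("p_in and p_out must be probabilities")
    rng = np.random.default_rng(seed)
    if rlm_columns is None:
        rlm_columns = list(range(L // 4, L // 4 + max(1, L // 4)))
    inside = np.zeros(L, dtype=bool)
    inside[[c for c in rlm_columns if 0 <= c < L]] = True
    dominant = rng.integers(0, 20, size=L)
    cols = np.empty((n_seqs, L), dtype=np.int64)
    for c in range(L):
        p = p_in if inside[c] else p_out
        take = rng.random(n_seqs) < p
        others = rng.integers(0, 19, size=n_seqs)
        others = others + (others >= dominant[c])  # uniform over the other 19
        cols[:, c] = np.where(take, dominant[c], others)
    rows = ["".join(AA20[k] for k in cols[i]) for i in range(n_seqs)]
    return rows, sorted(c for c in rlm_columns if 0 <= c < L)


# ---------------------------------------------------------------------------
# annotation-table generator


@dataclass
class AnnotationBundle:
    """Planted-enrichment EC/pathway tables plus their ground truth."""

    ecs: pd.DataFrame          # columns: ec, pathway_class, is_rlm
    pathways: pd.DataFrame     # columns: pathway, pathway_class, ec
    true_folds: dict[str, float] = field(default_factory=dict)

    def counts(self, pathway_class: str) -> tuple[int, int, int, int]:
        """(class_rlm, class_all, group_rlm, group_all) for one class."""
        df = self.ecs
        cls = df[df.pathway_class == pathway_class]
        return (
            int(cls.is_rlm.sum()),
            len(cls),
            int(df.is_rlm.sum()),
            len(df),
        )


def _random_ecs(rng, n):
    seen = set()
    out = []
    while len(out) < n:
        ec = (
            int(rng.integers(1, 8)),
            int(rng.integers(1, 30)),
            int(rng.integers(1, 30)),
            int(rng.integers(1, 300)),
        )
        if ec not in seen:
            seen.add(ec)
            out.append(".".join(map(str, ec)))
    return out


def make_annotation_tables(
    n_ec: int = 2000,
    n_pathways: int = 24,
    rlm_fraction: float = 0.25,
    enriched_classes: dict[str, float] | None = None,
    seed: int = 0,
    n_classes: int = 8,
) -> AnnotationBundle:
    """EC lists, pathway membership and RLM flags with planted enrichment.

    ECs spread uniformly over ``n_classes`` pathway classes; within class c
    the RLM probability is ``rlm_fraction * fold_c`` (fold 1 elsewhere),
    clipped to [0, 1].  Pathways subdivide each class evenly.
    """
    rng = np.random.default_rng(seed)
    enriched_classes = dict(enriched_classes or {})
    classes = [f"class_{i:02d}" for i in range(n_classes)]
    folds = {c: float(enriched_classes.get(c, 1.0)) for c in classes}
    if any(f <= 0 for f in folds.values()):
        raise ValueError("enrichment folds must be positive")

    ecs = _random_ecs(rng, n_ec)
    cls_idx = rng.integers(0, n_classes, size=n_ec)
    p = np.clip([rlm_fraction * folds[classes[k]] for k in cls_idx], 0.0, 1.0)
    is_rlm = rng.random(n_ec) < p

    ec_df = pd.DataFrame(
        dict(
            ec=ecs,
            pathway_class=[classes[k] for k in cls_idx],
            is_rlm=is_rlm,
        )
    )
    per_class = max(1, n_pathways // n_classes)
    rows = []
    for k, ec in zip(cls_idx, ecs):
        j = int(rng.integers(0, per_class))
        rows.append((f"map_{k:02d}_{j}", classes[k], ec))
    pw_df = pd.DataFrame(rows, columns=["pathway", "pathway_class", "ec"])
    return AnnotationBundle(ecs=ec_df, pathways=pw_df, true_folds=folds)
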
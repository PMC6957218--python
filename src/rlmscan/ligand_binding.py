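"""Ligand contacts, compound taxonomy, and binding-mode pooling.

Contacts collect every hetero residue with a heavy atom within 4 A of the
domain; each contact is attributed to the motif regions (elements I-V,
catalytic loop, crossover loop) it touches, or marked outside-RLM.
Compounds classify into chemical-taxonomy superclasses via an exact-id
lookup table, with two fallbacks: a small manual override list that forces
CTP and its derivatives into the nucleotides superclass, and a catch-all
"Generic compounds" superclass for anything unmapped.  A contact is
biologically significant when its compound is a substrate, product or
cofactor of any EC assigned to the structure; otherwise its significance is
uncertain (crystallization additives typically land here).

Binding modes are pooled across homologs by superposing each motif onto a
reference motif: residue correspondences are built element-by-element
(strands I, III, V and helix II always; IV only when both are helices),
symmetric-trimmed to equal length, and fitted by the closed-form Kabsch
least-squares rotation.  Ligand atoms transformed into the reference frame
then overlay the shared crevice, one sphere per atom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .rlm_search import RLMMatch
from .structure_io import Residue, Structure

__all__ = [
    "CompoundRecord",
    "LigandContact",
    "Superposition",
    "find_contacts",
    "classify_compound",
    "flag_significance",
    "superpose_rlm",
    "kabsch",
    "pool_ligands",
    "CTP_OVERRIDE",
    "GENERIC_SUPERCLASS",
    "NUCLEOTIDE_SUPERCLASS",
    "DEFAULT_ADDITIVES",
]

logger = logging.getLogger(__name__)

NUCLEOTIDE_SUPERCLASS = "Nucleosides, nucleotides, and analogues"
GENERIC_SUPERCLASS = "Generic compounds"

#: CTP and derivatives, manually forced into the nucleotides superclass
CTP_OVERRIDE = frozenset({"C00063", "C00705", "C05673", "C05674", "C05822"})

#: common crystallization additives excluded from contact reports by default
DEFAULT_ADDITIVES = frozenset(
    {"GOL", "EDO", "PEG", "PG4", "MPD", "DMS", "ACT", "BME", "TRS", "FMT", "IMD"}
)


@dataclass(frozen=True)
class CompoundRecord:
    compound_id: str
    kingdom: str | None
    superclass: str
    chem_class: str | None
    source: str  # 'taxonomy-table' | 'generic-fallback' | 'manual-override'


@dataclass
class LigandContact:
    structure_id: str
    domain_id: str | None
    ligand_name: str
    ligand_key: tuple[str, int, str]  # (chain, number, icode)
    regions: frozenset[str]  # elements/loops touched, or {'outside-RLM'}
    min_distance: float
    significance: str = "uncertain"  # 'significant' | 'uncertain'
    compound_id: str | None = None


@dataclass
class Superposition:
    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray  # 3-vector
    rmsd: float
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def find_contacts(
    s: Structure,
    domain_residues: list[Residue],
    match: RLMMatch | None = None,
    cutoff: float = 4.0,
    blocklist: frozenset[str] = DEFAULT_ADDITIVES,
) -> list[LigandContact]:
    """Hetero residues with any heavy atom within ``cutoff`` of the domain.

    With a ``match``, each contact lists every motif region (element or
    loop) holding a residue within the cutoff of that ligand; a domain
    contact touching no motif region is attributed 'outside-RLM'.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    poly_pts = [r.heavy_coords() for r in domain_residues if r.is_polymer]
    poly_pts = [p for p in poly_pts if len(p)]
    if not poly_pts:
        return []
    domain_tree = cKDTree(np.concatenate(poly_pts))

    region_trees: dict[str, cKDTree] = {}
    if match is not None:
        for name, residues in match.regions().items():
            pts = [r.heavy_coords() for r in residues]
            pts = [p for p in pts if len(p)]
            if pts:
                region_trees[name] = cKDTree(np.concatenate(pts))

    out: list[LigandContact] = []
    for lig in s.hetero_residues():
        if lig.name in blocklist:
            continue
        pts = lig.heavy_coords()
        if not len(pts):
            continue
        dmin = float(domain_tree.query(pts, k=1)[0].min())
        if dmin > cutoff:
            continue
        regions = frozenset(
            name
            for name, tree in region_trees.items()
            if float(tree.query(pts, k=1)[0].min()) <= cutoff
        )
        out.append(
            LigandContact(
                structure_id=s.id,
                domain_id=match.domain_id if match else None,
                ligand_name=lig.name,
                ligand_key=lig.key,
                regions=regions or frozenset({"outside-RLM"}),
                min_distance=dmin,
            )
        )
    out.sort(key=lambda c: c.ligand_key)
    return out


def classify_compound(compound_id: str, taxonomy) -> CompoundRecord:
    """Superclass lookup with override > table > generic-fallback precedence.

    ``taxonomy`` maps compound id -> (kingdom, superclass, class); a pandas
    DataFrame with columns compound/kingdom/superclass/class works too.
    """
    if hasattr(taxonomy, "set_index"):
        df = taxonomy
        taxonomy = {
            row["compound"]: (row.get("kingdom"), row["superclass"], row.get("class"))
            for _, row in df.iterrows()
        }
    if compound_id in CTP_OVERRIDE:
        return CompoundRecord(
            compound_id, "Organic compounds", NUCLEOTIDE_SUPERCLASS, None,
            source="manual-override",
        )
    hit = taxonomy.get(compound_id)
    if hit is not None:
        kingdom, superclass, chem_class = hit
        return CompoundRecord(
            compound_id, kingdom, superclass, chem_class, source="taxonomy-table"
        )
    return CompoundRecord(
        compound_id, None, GENERIC_SUPERCLASS, None, source="generic-fallback"
    )


def flag_significance(
    contact: LigandContact,
    substrates: set[str],
    products: set[str],
    cofactors: set[str],
) -> str:
    """'significant' iff the mapped compound is a known reaction partner."""
    if contact.compound_id is None:
        return "uncertain"
    if contact.compound_id in (substrates | products | cofactors):
        return "significant"
    return "uncertain"


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> Superposition:
    """Closed-form least-squares rigid superposition of paired point sets."""
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape or mobile.ndim != 2:
        raise ValueError("point sets must be paired (n, 3) arrays")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    H = (mobile - mc).T @ (reference - rc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    moved = mobile @ R.T + t
    rmsd = float(np.sqrt(((moved - reference) ** 2).sum(axis=1).mean()))
    return Superposition(rotation=R, translation=t, rmsd=rmsd, n_atoms=len(mobile))


def _trim_pair(a: list[Residue], b: list[Residue]):
    """Symmetric center trim of two residue runs to the shorter length."""
    n = min(len(a), len(b))

    def center(run):
        lo = (len(run) - n) // 2
        return run[lo : lo + n]

    return center(a), center(b)


def _correspondence(mobile: RLMMatch, reference: RLMMatch):
    names = ["I", "II", "III", "V"]
    iv_m, iv_r = mobile.elements.get("IV"), reference.elements.get("IV")
    if iv_m is not None and iv_r is not None and iv_m.kind == iv_r.kind == "helix":
        names.insert(3, "IV")
    xs, ys = [], []
    for name in names:
        ra, rb = _trim_pair(
            mobile.element_residues(name), reference.element_residues(name)
        )
        for m_res, r_res in zip(ra, rb):
            ca_m, ca_r = m_res.atom("CA"), r_res.atom("CA")
            if ca_m is not None and ca_r is not None:
                xs.append(ca_m)
                ys.append(ca_r)
    return np.asarray(xs), np.asarray(ys)


def superpose_rlm(
    mobile: tuple[Structure, RLMMatch], reference: tuple[Structure, RLMMatch]
) -> Superposition:
    """Element-anchored Kabsch fit of one motif onto another.

    An externally computed transform can be substituted downstream wherever a
    :class:`Superposition` is accepted.
    """
    _, match_m = mobile
    _, match_r = reference
    for match in (match_m, match_r):
        for name in ("I", "III", "V"):
            if match.elements.get(name) is None:
                raise ValueError(f"match lacks strand element {name}")
    xs, ys = _correspondence(match_m, match_r)
    if len(xs) < 9:
        raise ValueError(
            f"only {len(xs)} corresponding CA atoms; superposition under-determined"
        )
    return kabsch(xs, ys)


def pool_ligands(
    group: list[tuple[Structure, RLMMatch, list[LigandContact]]],
    reference_index: int = 0,
    taxonomy=None,
) -> tuple[list[dict], list[dict]]:
    """Transform every member's ligand atoms into the reference motif frame.

    Returns (pooled atom records, per-member quality table).  Atom records
    carry structure id, ligand name, compound superclass and transformed
    coordinates; the quality table reports each member's motif-only RMSD.
    Members that cannot be superposed are skipped with a logged warning.
    """
    if not group:
        return [], []
    ref = group[reference_index]
    pooled: list[dict] = []
    quality: list[dict] = []
    taxonomy = taxonomy if taxonomy is not None else {}
    for k, (st, match, contacts) in enumerate(group):
        if k == reference_index:
            sup = Superposition(np.eye(3), np.zeros(3), 0.0, 0)
        else:
            try:
                sup = superpose_rlm((st, match), (ref[0], ref[1]))
            except ValueError as err:
                logger.warning("skipping %s: %s", st.id, err)
                continue
        quality.append(dict(structure=st.id, rmsd=sup.rmsd, n_atoms=sup.n_atoms))
        lig_keys = {c.ligand_key: c for c in contacts}
        for lig in st.hetero_residues():
            contact = lig_keys.get(lig.key)
            if contact is None:
                continue
            rec = classify_compound(contact.compound_id or lig.name, taxonomy)
            for atom_name, xyz in lig.atoms.items():
                if lig.elements.get(atom_name) in ("H", "D"):
                    continue
                pooled.append(
                    dict(
                        structure=st.id,
                        ligand=lig.name,
                        atom=atom_name,
                        superclass=rec.superclass,
                        x=float(sup.apply(xyz[None, :])[0][0]),
                        y=float(sup.apply(xyz[None, :])[0][1]),
                        z=float(sup.apply(xyz[None, :])[0][2]),
                    )
                )
    return pooled, quality
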
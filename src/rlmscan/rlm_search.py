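"""Minimal Rossmann-like motif (RLM) matching.

The motif is a doubly-wound three-layer alpha/beta/alpha sandwich core:
five elements I(beta1) - II(alpha1) - III(beta2) - IV(crossover element) -
V(beta3), where beta2 and beta3 are each parallel-H-bonded to the central
beta1 (sheet order beta2-beta1-beta3), alpha1 packs on one face of the
sheet, and the crossover element IV -- an alpha-helix, a beta-strand, or a
bare loop -- carries the chain to the opposite face between beta2 and beta3.
The catalytic loop (between I and II) and the crossover loop (N-terminal of
IV) flank the inter-strand crevice where ligands bind.

Matching runs over a structure's SSE list and interaction matrix; insertions
(extra SSEs between III and IV or between IV and V) are tolerated, as in
large Rossmann domains that extend the sheet.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .sse_matrix import HELIX, STRAND, InteractionMatrix, SSE, helix_side_sign
from .structure_io import (
    DomainRange,
    Residue,
    Structure,
    parse_domain_range,
    residues_in_range,
)

__all__ = [
    "RLMMatch",
    "match_rlm",
    "assign_to_domain",
    "matches_to_tsv",
    "match_from_ranges",
]

ELEMENT_NAMES = ("I", "II", "III", "IV", "V")

# dedup preference when the same (I, II, III, V) strands are reached
# through different crossover elements
_VARIANT_RANK = {"helix-IV": 0, "strand-IV": 1, "loop-IV": 2}


@dataclass
class RLMMatch:
    """One motif instance: elements I-V plus the two functional loops."""

    elements: dict[str, SSE | None]
    catalytic_loop: list[Residue]
    crossover_loop: list[Residue]
    variant: str  # 'helix-IV' | 'strand-IV' | 'loop-IV'
    structure_id: str = ""
    domain_id: str | None = None
    insertions: list[SSE] = field(default_factory=list)
    canonical: bool = True

    def element_residues(self, name: str) -> list[Residue]:
        sse = self.elements.get(name)
        return list(sse.residues) if sse is not None else []

    def all_rlm_residues(self) -> list[Residue]:
        """Residues of elements I-V plus both loops (insertions excluded)."""
        out: list[Residue] = []
        for name in ELEMENT_NAMES:
            out.extend(self.element_residues(name))
        out.extend(self.catalytic_loop)
        out.extend(self.crossover_loop)
        return out

    def regions(self) -> dict[str, list[Residue]]:
        regions = {
            name: self.element_residues(name)
            for name in ELEMENT_NAMES
            if self.elements.get(name) is not None
        }
        regions["catalytic_loop"] = list(self.catalytic_loop)
        regions["crossover_loop"] = list(self.crossover_loop)
        return regions

    def __repr__(self) -> str:  # pragma: no cover
        parts = [
            f"{n}={e.range_str() if e else '-'}" for n, e in self.elements.items()
        ]
        return f"<RLMMatch {self.variant} {' '.join(parts)}>"


def _loop_between(structure: Structure | None, a: SSE, b: SSE) -> list[Residue]:
    """Polymer residues strictly between SSE ``a`` and SSE ``b`` (same chain)."""
    if structure is None or a.chain_id != b.chain_id:
        return []
    chain = structure.chain(a.chain_id)
    return [r for r in chain.polymer() if a.end < r.number < b.start]


def _contact(m: InteractionMatrix, i: int, j: int) -> bool:
    return m.code(i, j) in ("C", "T")


def match_rlm(
    m: InteractionMatrix,
    sses: list[SSE],
    structure: Structure | None = None,
) -> list[RLMMatch]:
    """Enumerate all RLM instances in one structure.

    Clauses, checked for every ordered strand triple (I, III, V) and every
    admissible crossover element IV:

    a. kinds strand / helix / strand / {helix | strand | none} / strand;
    b. strict sequence order I < II < III < IV < V; II is the first helix
       after I; arbitrary SSEs may intervene between III and IV and between
       IV and V (insertions);
    c. relation(I, III) = P and relation(I, V) = P (parallel sheet with the
       first strand central);
    d. II packs (C or T) against I, on sheet side s;
    e. a helix IV packs against I or V on side -s (the crossover reaches the
       opposite face); a strand IV or a bare-loop IV has no side constraint,
       and loop-IV applies only when no SSE at all lies between III and V
       and the crossover loop has >= 2 residues;
    f. all three strands are >= 3 residues (enforced at SSE assignment but
       re-checked here).

    Duplicates reaching the same (I, II, III, V) through different IVs keep
    the preferred variant (helix > strand > loop).  Output is deterministic.
    """
    strands = [x for x in sses if x.kind == STRAND]
    helices = [x for x in sses if x.kind == HELIX]
    candidates: list[RLMMatch] = []

    for b1 in strands:
        for b2 in strands:
            if b2.index <= b1.index:
                continue
            if m.code(b1.index, b2.index) != "P":
                continue
            # element II: first helix after I; must precede III
            alpha1 = next((h for h in helices if h.index > b1.index), None)
            if alpha1 is None or alpha1.index >= b2.index:
                continue
            if not _contact(m, alpha1.index, b1.index):
                continue
            for b3 in strands:
                if b3.index <= b2.index:
                    continue
                if m.code(b1.index, b3.index) != "P":
                    continue
                if min(len(b1), len(b2), len(b3)) < 3:
                    continue
                sheet = [b1, b2, b3]
                side_ii = helix_side_sign(alpha1, sheet)
                between = [x for x in sses if b2.index < x.index < b3.index]

                def _finish(elem_iv: SSE | None, variant: str) -> RLMMatch:
                    if elem_iv is None:
                        insertions: list[SSE] = []
                        pred = b2
                        nxt = b3
                    else:
                        insertions = [x for x in between if x is not elem_iv]
                        before_iv = [
                            x for x in between if x.index < elem_iv.index
                        ]
                        pred = before_iv[-1] if before_iv else b2
                        nxt = elem_iv
                    return RLMMatch(
                        elements={
                            "I": b1,
                            "II": alpha1,
                            "III": b2,
                            "IV": elem_iv,
                            "V": b3,
                        },
                        catalytic_loop=_loop_between(structure, b1, alpha1),
                        crossover_loop=_loop_between(structure, pred, nxt),
                        variant=variant,
                        structure_id=structure.id if structure else "",
                        insertions=insertions,
                    )

                for x in between:
                    if x.kind == HELIX:
                        on_sheet = _contact(m, x.index, b1.index) or _contact(
                            m, x.index, b3.index
                        )
                        if on_sheet and helix_side_sign(x, sheet) == -side_ii:
                            candidates.append(_finish(x, "helix-IV"))
                    elif x.kind == STRAND:
                        candidates.append(_finish(x, "strand-IV"))
                if not between:
                    loop = _loop_between(structure, b2, b3)
                    if structure is None or len(loop) >= 2:
                        candidates.append(_finish(None, "loop-IV"))

    # dedup on the strand/helix frame, preferring helix-IV > strand-IV > loop-IV
    best: dict[tuple[int, int, int, int], RLMMatch] = {}
    for match in candidates:
        key = (
            match.elements["I"].index,
            match.elements["II"].index,
            match.elements["III"].index,
            match.elements["V"].index,
        )
        iv = match.elements["IV"]
        rank = (_VARIANT_RANK[match.variant], iv.index if iv else -1)
        prev = best.get(key)
        if prev is None:
            best[key] = match
        else:
            prev_iv = prev.elements["IV"]
            prev_rank = (_VARIANT_RANK[prev.variant], prev_iv.index if prev_iv else -1)
            if rank < prev_rank:
                best[key] = match
    out = sorted(best.values(), key=lambda t: tuple(
        t.elements[n].index if t.elements[n] else -1 for n in ELEMENT_NAMES
    ))
    return out


def assign_to_domain(
    matches: list[RLMMatch], domains: list[tuple[str, DomainRange]]
) -> list[RLMMatch]:
    """Keep matches fully contained in exactly one domain; tag the domain id.

    Every residue of every element (and of both loops) must fall inside a
    single domain's range -- a motif spanning two domains is discarded.  When
    one domain retains several matches, the one with the smallest element-I
    start is flagged canonical; the others are kept with ``canonical=False``.
    """
    for i, (_, ra) in enumerate(domains):
        for j in range(i + 1, len(domains)):
            rb = domains[j][1]
            if any(
                ca == cb and sa <= eb and sb <= ea
                for (ca, sa, ea) in ra.segments
                for (cb, sb, eb) in rb.segments
            ):
                warnings.warn(
                    f"domains {domains[i][0]} and {domains[j][0]} overlap",
                    stacklevel=2,
                )

    kept: list[RLMMatch] = []
    for match in matches:
        residues = match.all_rlm_residues()
        homes = set()
        contained = True
        for res in residues:
            inside = [
                did for did, rng in domains if rng.contains(res.chain_id, res.number)
            ]
            if len(inside) != 1:
                contained = False
                break
            homes.add(inside[0])
        if contained and len(homes) == 1:
            match.domain_id = homes.pop()
            kept.append(match)

    by_domain: dict[str, list[RLMMatch]] = {}
    for match in kept:
        by_domain.setdefault(match.domain_id, []).append(match)
    for group in by_domain.values():
        group.sort(key=lambda t: t.elements["I"].start)
        for k, match in enumerate(group):
            match.canonical = k == 0
    return kept


def match_from_ranges(
    ranges: dict[str, str],
    variant: str = "helix-IV",
    structure: Structure | None = None,
    structure_id: str = "",
) -> RLMMatch:
    """Rebuild a match from range strings (e.g. a row of the scan TSV).

    ``ranges`` maps element/loop names to ``"CHAIN:START-END"`` strings (or
    ``"-"`` for absent).  With a structure the real residues are attached;
    otherwise lightweight number-only stubs are used, which suffices for
    binning and bookkeeping but not for geometry.
    """

    def residues_for(text: str) -> list[Residue]:
        if not text or text == "-":
            return []
        dr = parse_domain_range(text)
        if structure is not None:
            return residues_in_range(structure, dr)
        out = []
        for chain, start, end in dr.segments:
            out.extend(
                Residue(chain_id=chain, number=n, icode="", name="UNK")
                for n in range(start, end + 1)
            )
        return out

    elements: dict[str, SSE | None] = {}
    for k, name in enumerate(ELEMENT_NAMES):
        residues = residues_for(ranges.get(name, "-"))
        if residues:
            kind = HELIX if name in ("II", "IV") and variant != "strand-IV" else STRAND
            if name == "IV" and variant == "strand-IV":
                kind = STRAND
            elements[name] = SSE(index=k, kind=kind, residues=residues)
        else:
            elements[name] = None
    return RLMMatch(
        elements=elements,
        catalytic_loop=residues_for(ranges.get("catalytic_loop", "-")),
        crossover_loop=residues_for(ranges.get("crossover_loop", "-")),
        variant=variant,
        structure_id=structure_id or (structure.id if structure else ""),
    )


def _range_of(residues: list[Residue]) -> str:
    if not residues:
        return "-"
    return f"{residues[0].chain_id}:{residues[0].number}-{residues[-1].number}"


def matches_to_tsv(matches: list[RLMMatch]) -> str:
    cols = [
        "structure", "domain", "variant", "canonical",
        "I", "II", "III", "IV", "V", "catalytic_loop", "crossover_loop",
    ]
    lines = ["\t".join(cols)]
    for t in matches:
        row = [
            t.structure_id,
            t.domain_id or "-",
            t.variant,
            "1" if t.canonical else "0",
        ]
        for name in ELEMENT_NAMES:
            sse = t.elements.get(name)
            row.append(sse.range_str() if sse else "-")
        row.append(_range_of(t.catalytic_loop))
        row.append(_range_of(t.crossover_loop))
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"
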
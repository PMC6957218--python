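"""Enzyme-function statistics: EC handling, family reaction categories,
pathway enrichment, cofactor summaries.

An EC number is the four-field enzyme reaction classifier; a "dashed" EC has
one or more unresolved fields (e.g. ``2.4.1.-``) and cannot be mapped to a
pathway.  Families (F-group records) are classified by the diversity of their
members' reactions into four exhaustive categories:

null
    no EC assigned to any member;
homogeneous
    exactly one distinct EC;
heterogeneous_substrate
    several ECs sharing the first three digits (same chemistry, different
    substrates);
heterogeneous_reaction
    ECs differing in the first three digits (different chemistries).

Pathway over/under-representation compares the observed frequency of motif
enzymes in a pathway class with the expected frequency from all enzymes,
with significance from a two-sided Fisher exact test on the 2x2 table of
(motif / non-motif) x (in class / not in class).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import pandas as pd
from scipy import stats

__all__ = [
    "ECNumber",
    "FGroupRecord",
    "PathwayTable",
    "EnrichmentResult",
    "filter_dashed",
    "classify_fgroup",
    "enrichment_test",
    "percent_report",
    "cofactor_join",
    "CATEGORIES",
]

CATEGORIES = (
    "null",
    "homogeneous",
    "heterogeneous_substrate",
    "heterogeneous_reaction",
)


@dataclass(frozen=True, order=True)
class ECNumber:
    """Four-field EC number; ``None`` fields render as dashes."""

    d1: int | None
    d2: int | None
    d3: int | None
    d4: int | None

    def __post_init__(self) -> None:
        if self.d1 is not None and not 1 <= self.d1 <= 7:
            raise ValueError(f"EC class digit out of range: {self.d1}")

    @classmethod
    def parse(cls, text: str) -> "ECNumber":
        parts = text.strip().split(".")
        if len(parts) != 4:
            raise ValueError(f"malformed EC number: {text!r}")
        vals = [None if p in ("-", "") else int(p) for p in parts]
        return cls(*vals)

    @property
    def dashed(self) -> bool:
        return any(d is None for d in (self.d1, self.d2, self.d3, self.d4))

    @property
    def sub_subclass(self) -> tuple:
        """First three digits -- the chemistry, ignoring the substrate digit."""
        return (self.d1, self.d2, self.d3)

    def __str__(self) -> str:
        return ".".join("-" if d is None else str(d) for d in (self.d1, self.d2, self.d3, self.d4))


@dataclass
class FGroupRecord:
    """One family key: the sorted tuple of F-group ids on a structure.

    A structure carrying several domains gets a combined key, distinct from
    the single-domain families of its parts.  ``multifunctional`` marks any
    member chain with two or more EC assignments.
    """

    fgroups: tuple[str, ...]
    structures: set[str] = field(default_factory=set)
    ecs: set[ECNumber] = field(default_factory=set)
    multifunctional: bool = False

    def __post_init__(self) -> None:
        key = tuple(sorted(set(self.fgroups)))
        object.__setattr__(self, "fgroups", key)


@dataclass
class PathwayTable:
    """pathway id -> EC set, plus the pathway -> class -> major group tree."""

    members: dict[str, set[ECNumber]]
    hierarchy: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, ecs in self.members.items():
            bad = [str(e) for e in ecs if e.dashed]
            if bad:
                raise ValueError(f"pathway {pid} contains dashed ECs: {bad}")

    def class_members(self, pathway_class: str) -> set[ECNumber]:
        out: set[ECNumber] = set()
        for pid, ecs in self.members.items():
            if self.hierarchy.get(pid, (None, None))[0] == pathway_class:
                out |= ecs
        return out


@dataclass
class EnrichmentResult:
    class_id: str
    observed: float
    expected: float
    ratio: float
    p_value: float
    significant: bool
    table: tuple[tuple[int, int], tuple[int, int]]


def filter_dashed(ecs: list[ECNumber]) -> tuple[list[ECNumber], int]:
    """Drop dashed ECs (unmappable to pathways); returns (kept, n_removed)."""
    kept = [e for e in ecs if not e.dashed]
    return kept, len(ecs) - len(kept)


def classify_fgroup(rec: FGroupRecord) -> str:
    """Reaction-diversity category of one family record (total function)."""
    ecs = set(rec.ecs)
    if not ecs:
        return "null"
    if len(ecs) == 1:
        return "homogeneous"
    if len({e.sub_subclass for e in ecs}) == 1:
        return "heterogeneous_substrate"
    return "heterogeneous_reaction"


def enrichment_test(
    class_rlm: int,
    class_all: int,
    group_rlm: int,
    group_all: int,
    class_id: str = "",
    alpha: float = 0.05,
) -> EnrichmentResult:
    """Observed/expected frequency ratio with Fisher two-sided significance.

    ``class_rlm``/``class_all`` count motif and total ECs in one pathway
    class; ``group_rlm``/``group_all`` the same over the whole major group.
    The 2x2 table splits motif and non-motif enzymes by class membership;
    the two-sided p sums hypergeometric point probabilities <= that of the
    observed table.
    """
    if group_rlm <= 0 or group_all <= 0:
        raise ValueError("group counts must be positive")
    a = class_rlm
    b = group_rlm - class_rlm
    c = class_all - class_rlm
    d = (group_all - group_rlm) - c
    if min(a, b, c, d) < 0:
        raise ValueError(
            f"inconsistent counts: table [[{a},{b}],[{c},{d}]] has a negative cell"
        )
    observed = class_rlm / group_rlm
    expected = class_all / group_all
    ratio = observed / expected if expected > 0 else float("nan")
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    return EnrichmentResult(
        class_id=class_id,
        observed=observed,
        expected=expected,
        ratio=ratio,
        p_value=p,
        significant=p < alpha,
        table=((a, b), (c, d)),
    )


def benjamini_hochberg(pvalues: list[float]) -> list[float]:
    """BH-adjusted p-values (optional; raw p is the default report)."""
    from statsmodels.stats.multitest import multipletests

    return list(multipletests(pvalues, method="fdr_bh")[1])


def percent_report(part: int, whole: int) -> int:
    """Integer percentage, rounded half-up (never banker's rounding)."""
    if whole <= 0:
        raise ValueError("whole must be positive")
    if not 0 <= part <= whole:
        raise ValueError("part must lie in [0, whole]")
    return int((Fraction(200 * part, whole) + 1) // 2)


# hybrid Fe-S cluster variants collapse to two canonical types
_HYBRID_TYPES = ("[Fe-O-S]", "[Ni-Fe-S]")


def normalize_cofactor(name: str) -> str:
    """Canonical cofactor label; hybrid-cluster variants merge to two types."""
    squeezed = name.strip()
    probe = squeezed.upper().replace(" ", "").replace("[", "").replace("]", "")
    for canon in _HYBRID_TYPES:
        key = canon.upper().replace(" ", "").replace("[", "").replace("]", "")
        if probe.startswith(key) or key in probe:
            return canon
    return squeezed


def cofactor_join(
    ec_to_cofactor: pd.DataFrame, records: list[FGroupRecord]
) -> pd.DataFrame:
    """Per-cofactor summary joining EC assignments to family records.

    ``ec_to_cofactor`` needs columns ``ec`` and ``cofactor``.  Output rows:
    cofactor, n_ecs, n_fgroups, and one ``pct_class_k`` column per EC class
    (integer percentages of the cofactor's ECs, rounded half-up).
    """
    if ec_to_cofactor.empty:
        return pd.DataFrame(columns=["cofactor", "n_ecs", "n_fgroups"])
    df = ec_to_cofactor.copy()
    df["cofactor"] = df["cofactor"].map(normalize_cofactor)
    df["ec_obj"] = df["ec"].map(ECNumber.parse)

    ec_to_fgroups: dict[ECNumber, set[tuple[str, ...]]] = {}
    for rec in records:
        for ec in rec.ecs:
            ec_to_fgroups.setdefault(ec, set()).add(rec.fgroups)

    rows = []
    for cof, grp in df.groupby("cofactor", sort=True):
        ecs = sorted(set(grp["ec_obj"]))
        fgroups = set()
        for ec in ecs:
            fgroups |= ec_to_fgroups.get(ec, set())
        row: dict[str, object] = {
            "cofactor": cof,
            "n_ecs": len(ecs),
            "n_fgroups": len(fgroups),
        }
        for klass in range(1, 8):
            n_k = sum(1 for ec in ecs if ec.d1 == klass)
            row[f"pct_class_{klass}"] = percent_report(n_k, len(ecs))
        rows.append(row)
    return pd.DataFrame(rows)
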
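"""End-to-end orchestration: scan structures, classify families, run the
statistics, and report.

The pipeline is fail-soft: a structure that cannot be parsed or scanned is
logged and skipped, the rest of the run continues, and the run is marked
failed at the end (strict mode aborts on the first error instead).  Given
the same inputs, configuration and seed, every output file is byte-identical
between runs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import conservation as cons
from . import function_enrichment as fe
from .ligand_binding import find_contacts, pool_ligands
from .rlm_search import RLMMatch, assign_to_domain, match_rlm, matches_to_tsv
from .sse_matrix import SSEParams, assign_sse, build_interaction_matrix, matrix_to_tsv
from .structure_io import Structure, parse_domain_range, parse_structure

__all__ = ["RunConfig", "RunReport", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline inputs and thresholds in one serializable record."""

    structures: str  # directory of PDB-format files
    out_dir: str = "rlmscan_out"
    domains: str | None = None      # TSV: structure, domain, range
    annotations: str | None = None  # TSV: structure, fgroup, ec
    ec_table: str | None = None     # TSV: ec, pathway_class, is_rlm
    msa: str | None = None          # aligned FASTA; row 0 = reference
    taxonomy: str | None = None     # TSV: compound, kingdom, superclass, class
    ligand_map: str | None = None   # TSV: ligand, compound
    contact_cutoff: float = 4.0
    hbond_cutoff: float = 3.5
    t_angle_min: float = 30.0
    sse_contact_cutoff: float = 6.5
    bin_counts: str = ""            # e.g. "5,9,5,7,4" for I,II,III,IV,V
    seed: int = 0
    strict: bool = False
    write_matrices: bool = False
    pool_reference: int = 0

    def sse_params(self) -> SSEParams:
        return SSEParams(
            hbond_cutoff=self.hbond_cutoff,
            contact_cutoff=self.sse_contact_cutoff,
            t_angle_min=self.t_angle_min,
        )

    def serialize(self) -> str:
        # out_dir is where results land, not part of the analysis itself;
        # leaving it out keeps reports byte-comparable across output locations
        lines = [
            f"{f.name} = {getattr(self, f.name)!r}"
            for f in dataclasses.fields(self)
            if f.name != "out_dir"
        ]
        return "\n".join(lines)

    def __post_init__(self) -> None:
        for name in ("contact_cutoff", "hbond_cutoff", "t_angle_min", "sse_contact_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class RunReport:
    ok: list[str] = field(default_factory=list)
    failed: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, Path] = field(default_factory=dict)
    summary: dict[str, object] = field(default_factory=dict)

    @property
    def success(self) -> bool:
        return not self.failed


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def _scan_one(st: Structure, cfg: RunConfig, domains_df: pd.DataFrame | None):
    params = cfg.sse_params()
    sses = assign_sse(st, params)
    matrix = build_interaction_matrix(sses, st, params)
    matches = match_rlm(matrix, sses, st)
    if domains_df is not None:
        rows = domains_df[domains_df["structure"] == st.id]
        doms = [
            (row["domain"], parse_domain_range(row["range"]))
            for _, row in rows.iterrows()
        ]
        if doms:
            matches = assign_to_domain(matches, doms)
    return sses, matrix, matches


def _fgroup_records(annotations: pd.DataFrame) -> list[fe.FGroupRecord]:
    records: dict[tuple[str, ...], fe.FGroupRecord] = {}
    for structure, grp in annotations.groupby("structure"):
        key = tuple(sorted(set(grp["fgroup"].dropna())))
        ecs = {
            fe.ECNumber.parse(e)
            for e in grp["ec"].dropna()
            if e and e != "-"
        }
        rec = records.setdefault(key, fe.FGroupRecord(fgroups=key))
        rec.structures.add(structure)
        rec.ecs |= ecs
        if len(ecs) >= 2:
            rec.multifunctional = True
    return [records[k] for k in sorted(records)]


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Scan every structure, then annotate, test and write the report bundle."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = RunReport()

    domains_df = _read_tsv(cfg.domains) if cfg.domains else None
    paths = sorted(Path(cfg.structures).glob("*.pdb"))
    scanned: list[tuple[Structure, list[RLMMatch]]] = []
    all_matches: list[RLMMatch] = []
    matrix_chunks: list[str] = []
    for path in paths:
        try:
            st = parse_structure(path)
            sses, matrix, matches = _scan_one(st, cfg, domains_df)
        except Exception as err:  # fail-soft per structure
            if cfg.strict:
                raise
            logger.error("stage=scan structure=%s error=%s", path.stem, err)
            report.failed[path.stem] = str(err)
            continue
        report.ok.append(st.id)
        scanned.append((st, matches))
        all_matches.extend(matches)
        if cfg.write_matrices:
            matrix_chunks.append(f"# {st.id}\n" + matrix_to_tsv(sses, matrix))

    rlm_path = out_dir / "rlm_table.tsv"
    rlm_path.write_text(matches_to_tsv(all_matches))
    report.outputs["rlm_table"] = rlm_path
    if matrix_chunks:
        mp = out_dir / "matrices.tsv"
        mp.write_text("".join(matrix_chunks))
        report.outputs["matrices"] = mp

    # ligand contacts (per structure with at least one match)
    lig_map = {}
    if cfg.ligand_map:
        df = _read_tsv(cfg.ligand_map)
        lig_map = dict(zip(df["ligand"], df["compound"]))
    contact_rows = []
    pool_group = []
    for st, matches in scanned:
        canonical = [m for m in matches if m.canonical] or matches
        for match in canonical:
            contacts = find_contacts(
                st, st.polymer_residues(), match, cutoff=cfg.contact_cutoff
            )
            for c in contacts:
                c.compound_id = lig_map.get(c.ligand_name)
                contact_rows.append(
                    dict(
                        structure=c.structure_id,
                        ligand=c.ligand_name,
                        regions=";".join(sorted(c.regions)),
                        min_distance=round(c.min_distance, 3),
                        compound=c.compound_id or "-",
                    )
                )
            pool_group.append((st, match, contacts))
    contacts_path = out_dir / "contacts.tsv"
    pd.DataFrame(
        contact_rows, columns=["structure", "ligand", "regions", "min_distance", "compound"]
    ).to_csv(contacts_path, sep="\t", index=False)
    report.outputs["contacts"] = contacts_path

    # pooled binding modes in the reference frame
    if len(pool_group) > 1:
        taxonomy = {}
        if cfg.taxonomy:
            tdf = _read_tsv(cfg.taxonomy)
            taxonomy = {
                r["compound"]: (r.get("kingdom"), r["superclass"], r.get("class"))
                for _, r in tdf.iterrows()
            }
        pooled, quality = pool_ligands(
            pool_group, reference_index=min(cfg.pool_reference, len(pool_group) - 1),
            taxonomy=taxonomy,
        )
        pd.DataFrame(pooled).to_csv(out_dir / "pooled_ligands.tsv", sep="\t", index=False)
        pd.DataFrame(quality).to_csv(out_dir / "pool_quality.tsv", sep="\t", index=False)
        report.outputs["pooled_ligands"] = out_dir / "pooled_ligands.tsv"

    summary: dict[str, object] = {
        "n_structures": len(paths),
        "n_parsed": len(report.ok),
        "n_failed": len(report.failed),
        "n_matches": len(all_matches),
        "n_structures_with_rlm": sum(1 for _, m in scanned if m),
    }
    if report.ok:
        summary["pct_structures_with_rlm"] = fe.percent_report(
            summary["n_structures_with_rlm"], len(report.ok)
        )

    # family reaction categories
    if cfg.annotations:
        records = _fgroup_records(_read_tsv(cfg.annotations))
        cat_rows = [
            dict(
                fgroups=";".join(r.fgroups),
                n_structures=len(r.structures),
                n_ecs=len(r.ecs),
                multifunctional=int(r.multifunctional),
                category=fe.classify_fgroup(r),
            )
            for r in records
        ]
        cat_df = pd.DataFrame(cat_rows)
        cat_path = out_dir / "fgroup_categories.tsv"
        cat_df.to_csv(cat_path, sep="\t", index=False)
        report.outputs["fgroup_categories"] = cat_path
        for cat in fe.CATEGORIES:
            summary[f"n_{cat}"] = int((cat_df["category"] == cat).sum())
        summary["n_fgroup_records"] = len(records)

    # pathway enrichment
    if cfg.ec_table:
        df = _read_tsv(cfg.ec_table)
        df["is_rlm"] = df["is_rlm"].isin(("1", "True", "true"))
        group_rlm = int(df["is_rlm"].sum())
        group_all = len(df)
        rows = []
        for cls in sorted(df["pathway_class"].unique()):
            sub = df[df["pathway_class"] == cls]
            res = fe.enrichment_test(
                int(sub["is_rlm"].sum()), len(sub), group_rlm, group_all, class_id=cls
            )
            rows.append(
                dict(
                    pathway_class=cls,
                    observed=round(res.observed, 6),
                    expected=round(res.expected, 6),
                    ratio=round(res.ratio, 4),
                    p_value=f"{res.p_value:.6g}",
                    significant=int(res.significant),
                )
            )
        enr_path = out_dir / "enrichment.tsv"
        pd.DataFrame(rows).to_csv(enr_path, sep="\t", index=False)
        report.outputs["enrichment"] = enr_path
        summary["n_enriched_significant"] = sum(r["significant"] for r in rows)

    # conservation against the first canonical match
    if cfg.msa and all_matches:
        rows = cons.read_msa(cfg.msa)
        profile = cons.conservation_index(rows)
        match = all_matches[0]
        per_res = cons.map_to_reference(profile, rows, 0, start_number=1)
        try:
            mean_in, mean_out, ks_d, ks_p = cons.inside_outside_test(per_res, match)
            summary["conservation_mean_in"] = round(mean_in, 4)
            summary["conservation_mean_out"] = round(mean_out, 4)
            summary["conservation_ks_d"] = round(ks_d, 4)
            summary["conservation_ks_p"] = f"{ks_p:.6g}"
        except ValueError as err:
            logger.warning("conservation stage skipped: %s", err)

    report.summary = summary
    lines = ["# rlmscan run summary", "", "## configuration"]
    lines += [f"#   {ln}" for ln in cfg.serialize().splitlines()]
    lines += ["", "## results"]
    lines += [f"{k}\t{v}" for k, v in summary.items()]
    if report.failed:
        lines += ["", "## failures"]
        lines += [f"{k}\t{v}" for k, v in sorted(report.failed.items())]
    summary_path = out_dir / "summary.txt"
    summary_path.write_text("\n".join(lines) + "\n")
    report.outputs["summary"] = summary_path
    return report
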
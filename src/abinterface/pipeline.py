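"""End-to-end orchestration: filters, selection, redundancy, contacts, statistics.

``run_pipeline`` consumes a chain-annotation summary plus a directory of PDB
files and writes a bundle of tidy CSV tables, an exclusion log, and a
machine-readable run summary.  Every input structure is accounted for exactly
once: it either contributes a row to the per-complex summary or appears in
the exclusion log with a reason.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from . import interface_statistics as stats
from . import region_annotation as regions
from .complex_selection import select_unit
from .datatypes import (
    AbAgComplex,
    AbInterfaceError,
    ContactRecord,
    RegionScheme,
)
from .interface_contacts import (
    count_interfacial_waters,
    find_contacts,
    summarize_interface,
)
from .redundancy import (
    cluster_sequences,
    extract_variable_sequence,
    remove_redundant,
)
from .structure_io import (
    classify_group,
    filter_dataset,
    load_annotation_summary,
    parse_complex,
)

logger = logging.getLogger(__name__)


class EmptyDatasetError(AbInterfaceError):
    """No complex survived the dataset filters (reported, not a crash)."""


@dataclass
class PipelineConfig:
    summary_path: str
    pdb_dir: str
    out_dir: str
    cutoff: float = 5.0
    cutoff_sweep: Tuple[float, ...] = ()
    max_resolution: float = 3.0
    exclude: Tuple[str, ...] = ()
    identity: float = 0.95
    scheme: RegionScheme = field(default_factory=RegionScheme)
    min_occurrence: float = 0.10
    n_boot: int = 5000
    ci_level: float = 0.95
    seed: int = 20230131
    with_waters: bool = False
    bfactor_include_hydrogens: bool = False
    ss_path: Optional[str] = None
    germline_path: Optional[str] = None


def load_config_file(path) -> Dict[str, str]:
    """Flat ``key = value`` config file mirroring the CLI flags."""
    out: Dict[str, str] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            out[key.strip()] = value.strip()
    return out


def read_germline_table(path) -> Dict[str, Dict[tuple, str]]:
    """TSV with columns pdb, domain, position, germline_aa (3-letter)."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    out: Dict[str, Dict[tuple, str]] = {}
    for _, row in table.iterrows():
        pos = str(row["position"])
        num = pos.rstrip("ABCDEFGHIJKLMNOPQRSTUVWXYZ")
        icode = pos[len(num):]
        out.setdefault(row["pdb"], {})[(row["domain"], int(num), icode)] = \
            row["germline_aa"]
    return out


# --- assembly stages ---------------------------------------------------------

def assemble_dataset(config: PipelineConfig
                     ) -> Tuple[List[AbAgComplex], List[Tuple[str, str]]]:
    """Parse, filter, select units, and remove redundancy.

    Returns the retained complexes and the exclusion log
    (structure_id, reason).
    """
    annotations = load_annotation_summary(config.summary_path)
    pdb_dir = Path(config.pdb_dir)
    exclusions: List[Tuple[str, str]] = []

    by_structure: Dict[str, list] = {}
    for ann in annotations:
        by_structure.setdefault(ann.structure_id, []).append(ann)

    units_per_file: Dict[str, List[AbAgComplex]] = {}
    for sid, anns in by_structure.items():
        pdb_path = pdb_dir / f"{sid}.pdb"
        if not pdb_path.exists():
            exclusions.append((sid, "PDB file not found"))
            continue
        text = pdb_path.read_text()
        units = []
        for i, ann in enumerate(anns):
            try:
                units.append(parse_complex(text, ann, unit_index=i))
            except AbInterfaceError as exc:
                exclusions.append((sid, f"unit {i}: {exc}"))
        if units:
            units_per_file[sid] = units

    # dataset filters apply before unit selection so a whole structure can be
    # excluded by resolution or by the manual list
    filtered_units: Dict[str, List[AbAgComplex]] = {}
    for sid, units in units_per_file.items():
        retained, removals = filter_dataset(units, config.max_resolution,
                                            config.exclude)
        if removals:
            # all units share the structure-level annotation fields
            exclusions.append((sid, removals[0][1]))
        if retained:
            filtered_units[sid] = retained

    selected: List[AbAgComplex] = []
    for sid in sorted(filtered_units):
        units = filtered_units[sid]
        best, scores = select_unit(
            units, include_hydrogens=config.bfactor_include_hydrogens)
        for score in scores:
            if score.unit_index != best.unit_index:
                exclusions.append(
                    (sid, f"packing duplicate unit {score.unit_index} "
                          f"(mean B {score.mean_b:.2f})"))
        selected.append(best)

    if not selected:
        return [], exclusions

    # redundancy removal over variable-domain sequences
    vh_seqs, vl_seqs = [], []
    for cx in selected:
        for dom, bucket in (("VH", vh_seqs), ("VL", vl_seqs)):
            if dom in cx.antibody_residues:
                bucket.append(extract_variable_sequence(
                    cx.antibody_residues[dom], dom, cx.structure_id))
    vh_clusters = cluster_sequences(vh_seqs, config.identity) if vh_seqs else \
        stats_empty_assignment(config.identity)
    vl_clusters = cluster_sequences(vl_seqs, config.identity) if vl_seqs else \
        stats_empty_assignment(config.identity)
    survivors, families = remove_redundant(selected, vh_clusters, vl_clusters)
    surviving_ids = {cx.structure_id for cx in survivors}
    for cx in selected:
        if cx.structure_id not in surviving_ids:
            exclusions.append((cx.structure_id, "redundant antibody"))
    return survivors, exclusions


def stats_empty_assignment(threshold: float):
    from .redundancy import ClusterAssignment
    return ClusterAssignment(mapping={}, threshold=threshold)


# --- reporting ---------------------------------------------------------------

CONTACT_COLUMNS = ["structure_id", "group", "ab_chain", "ab_domain", "ab_res",
                   "ab_aa", "ab_atom", "ag_chain", "ag_res", "ag_aa",
                   "ag_atom", "distance"]


def contacts_frame(items: Sequence[Tuple[str, str, Sequence[ContactRecord]]]
                   ) -> pd.DataFrame:
    rows = []
    for sid, group, contacts in items:
        for c in contacts:
            rows.append({"structure_id": sid, "group": group,
                         "ab_chain": c.ab_chain, "ab_domain": c.ab_domain,
                         "ab_res": c.ab_res, "ab_aa": c.ab_aa,
                         "ab_atom": c.ab_atom, "ag_chain": c.ag_chain,
                         "ag_res": c.ag_res, "ag_aa": c.ag_aa,
                         "ag_atom": c.ag_atom,
                         "distance": round(c.distance, 4)})
    return pd.DataFrame(rows, columns=CONTACT_COLUMNS)


def _analyze_cutoff(survivors: List[AbAgComplex], config: PipelineConfig,
                    cutoff: float, out_dir: Path,
                    ss_codes: Optional[Mapping] = None,
                    germline: Optional[Mapping[str, Mapping]] = None) -> dict:
    out_dir.mkdir(parents=True, exist_ok=True)
    scheme = config.scheme
    expanded = RegionScheme(cdr1=scheme.cdr1,
                            cdr2=(scheme.cdr2[0] - 1, scheme.cdr2[1] + 1),
                            cdr3=scheme.cdr3, vr_max=scheme.vr_max)

    per_complex_rows = []
    contact_items = []
    group_members: Dict[str, List[dict]] = {}
    for cx in survivors:
        group = classify_group(cx)
        contacts = find_contacts(cx, cutoff=cutoff)
        summary = summarize_interface(contacts)
        uer_keys = sorted({c.ag_res_key for c in contacts})
        segments = stats.epitope_segments(uer_keys) if uer_keys else 0
        row = {
            "structure_id": cx.structure_id, "group": group,
            "resolution": cx.annotation.resolution,
            "total_contacts": summary.total_contacts,
            "upr": summary.upr, "uer": summary.uer,
            "upa": summary.upa, "uea": summary.uea,
            "upa_main": summary.upa_main, "upa_side": summary.upa_side,
            "epitope_segments": segments,
        }
        if config.with_waters:
            n_wat, n_med = count_interfacial_waters(cx, cutoff=cutoff)
            row["interfacial_waters"] = n_wat
            row["water_mediated_contacts"] = n_med
        per_complex_rows.append(row)
        contact_items.append((cx.structure_id, group, contacts))
        group_members.setdefault(group, []).append(
            {"complex": cx, "contacts": contacts, "summary": summary})

    per_complex = pd.DataFrame(per_complex_rows)
    per_complex.to_csv(out_dir / "complex_summary.csv", index=False)
    all_contacts = contacts_frame(contact_items)
    all_contacts.to_csv(out_dir / "contacts.csv", index=False)

    # Table-1-style group summary; the Total row is the column sum
    group_rows = []
    for group in sorted(group_members):
        sub = per_complex[per_complex["group"] == group]
        group_rows.append({
            "group": group, "n_structures": len(sub),
            "total_contacts": int(sub["total_contacts"].sum()),
            "upr": int(sub["upr"].sum()), "upa": int(sub["upa"].sum()),
            "uer": int(sub["uer"].sum()), "uea": int(sub["uea"].sum()),
            "mean_resolution": round(float(sub["resolution"].mean()), 2),
        })
    total_row = {
        "group": "Total", "n_structures": len(per_complex),
        "total_contacts": int(per_complex["total_contacts"].sum()),
        "upr": int(per_complex["upr"].sum()),
        "upa": int(per_complex["upa"].sum()),
        "uer": int(per_complex["uer"].sum()),
        "uea": int(per_complex["uea"].sum()),
        "mean_resolution": round(float(per_complex["resolution"].mean()), 2),
    }
    group_summary = pd.DataFrame(group_rows + [total_row])
    group_summary.to_csv(out_dir / "group_summary.csv", index=False)

    # frequency / region / hotspot statistics per group
    freq_rows, class_rows, region_rows, capture_rows = [], [], [], []
    hotspot_frames, posfreq_rows, wk_rows = [], [], []
    for gi, group in enumerate(sorted(group_members)):
        members = group_members[group]
        upr_freqs, uer_freqs, region_counts_list, upr_pos_list = [], [], [], []
        upr_maps = []
        for m in members:
            contacts = m["contacts"]
            if not contacts:
                continue
            upr_aas = {}
            for c in contacts:
                upr_aas[c.ab_res_key] = c.ab_aa
            uer_aas = {}
            for c in contacts:
                uer_aas[c.ag_res_key] = c.ag_aa
            upr_freqs.append(stats.aa_frequencies(list(upr_aas.values())))
            uer_freqs.append(stats.aa_frequencies(list(uer_aas.values())))
            positions = regions.upr_positions(contacts)
            upr_pos_list.append(positions)
            region_counts_list.append(
                regions.region_counts(positions, scheme))
            upr_maps.append({(c.ab_domain, c.ab_seq, c.ab_icode): c.ab_aa
                             for c in contacts})
        if not upr_freqs:
            continue
        seed = (config.seed + 1009 * gi) % (2 ** 31)
        for basis, freqs in (("uPR", upr_freqs), ("uER", uer_freqs)):
            table = stats.group_frequency_table(
                freqs, n_boot=config.n_boot, level=config.ci_level, seed=seed)
            for aa, row in table.iterrows():
                freq_rows.append({"group": group, "basis": basis, "aa": aa,
                                  "mean": row["mean"], "lo": row["lo"],
                                  "hi": row["hi"]})
        class_table = stats.group_frequency_table(
            [stats.class_frequencies(f) for f in upr_freqs],
            n_boot=config.n_boot, level=config.ci_level, seed=seed)
        for cls, row in class_table.iterrows():
            class_rows.append({"group": group, "aa_class": cls,
                               "mean": row["mean"], "lo": row["lo"],
                               "hi": row["hi"]})
        mean_props, _ = regions.region_distribution(region_counts_list)
        for region, pct in sorted(mean_props.items()):
            region_rows.append({"group": group, "region": region,
                                "mean_pct": pct})
        capture_rows.append({
            "group": group,
            "cdr_capture_pct": regions.cdr_capture_fraction(upr_pos_list,
                                                            scheme),
            "cdr_capture_pct_expanded_cdr2": regions.cdr_capture_fraction(
                upr_pos_list, expanded),
        })
        hs = regions.hotspot_map(
            [(m["complex"], m["contacts"]) for m in members],
            scheme, config.min_occurrence)
        hs.insert(0, "group", group)
        hotspot_frames.append(hs)
        for pos, vec in sorted(stats.position_aa_frequencies(upr_maps).items()):
            for aa, pct in vec[vec > 0].items():
                posfreq_rows.append({"group": group, "domain": pos[0],
                                     "position": f"{pos[1]}{pos[2]}",
                                     "aa": aa, "pct": pct})
        # Wu-Kabat variability over the group's variable-domain sequences
        columns: Dict[tuple, List[str]] = {}
        for m in members:
            cx = m["complex"]
            for dom, residues in cx.antibody_residues.items():
                for res in residues:
                    if res.seq_id <= scheme.vr_max:
                        columns.setdefault((dom, res.seq_id, res.icode),
                                           []).append(res.aa)
        for (dom, seq_id, icode), col in sorted(columns.items()):
            wk = stats.wu_kabat(col, position=f"{seq_id}{icode}")
            wk_rows.append({"group": group, "domain": dom,
                            "position": wk.position, "N": wk.N, "k": wk.k,
                            "n_mode": wk.n_mode,
                            "variability": wk.variability})

    pd.DataFrame(freq_rows).to_csv(out_dir / "aa_frequencies.csv", index=False)
    pd.DataFrame(class_rows).to_csv(out_dir / "class_frequencies.csv",
                                    index=False)
    pd.DataFrame(region_rows).to_csv(out_dir / "region_distribution.csv",
                                     index=False)
    pd.DataFrame(capture_rows).to_csv(out_dir / "cdr_capture.csv", index=False)
    if hotspot_frames:
        pd.concat(hotspot_frames, ignore_index=True).to_csv(
            out_dir / "hotspots.csv", index=False)
    pd.DataFrame(posfreq_rows).to_csv(out_dir / "position_aa_frequencies.csv",
                                      index=False)
    pd.DataFrame(wk_rows).to_csv(out_dir / "wu_kabat.csv", index=False)

    # pooled co-occurrence over all groups (total atom-atom contacts)
    pooled = [c for _, _, contacts in contact_items for c in contacts]
    if pooled:
        matrix, zero_rows = stats.cooccurrence_matrix(pooled)
        matrix.to_csv(out_dir / "cooccurrence.csv")
        (out_dir / "cooccurrence_zero_rows.json").write_text(
            json.dumps(zero_rows))

    # epitope secondary structure, when codes were supplied
    if ss_codes is not None:
        ss_rows = []
        for group in sorted(group_members):
            keys = [k for m in group_members[group]
                    for k in {c.ag_res_key for c in m["contacts"]}]
            if keys:
                dist = regions.epitope_ss_distribution(keys, ss_codes)
                for cls, pct in dist.items():
                    ss_rows.append({"group": group, "ss_class": cls,
                                    "pct": pct})
        pd.DataFrame(ss_rows).to_csv(out_dir / "epitope_ss.csv", index=False)

    if germline is not None:
        germ_rows = []
        for group in sorted(group_members):
            upr_maps, germ_maps = [], []
            for m in group_members[group]:
                sid = m["complex"].structure_id
                if sid not in germline:
                    continue
                upr_maps.append({(c.ab_domain, c.ab_seq, c.ab_icode): c.ab_aa
                                 for c in m["contacts"]})
                germ_maps.append(germline[sid])
            if upr_maps:
                table, pooled_pct = stats.germline_mutation_fraction(
                    upr_maps, germ_maps)
                table.insert(0, "group", group)
                germ_rows.append(table)
        if germ_rows:
            pd.concat(germ_rows, ignore_index=True).to_csv(
                out_dir / "germline_mutation.csv", index=False)

    return {
        "cutoff": cutoff,
        "n_structures": len(per_complex),
        "groups": {r["group"]: r["n_structures"] for r in group_rows},
        "total_contacts": total_row["total_contacts"],
        "upr": total_row["upr"], "uer": total_row["uer"],
        "upa": total_row["upa"], "uea": total_row["uea"],
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the machine-readable run summary.

    Raises :class:`EmptyDatasetError` when no complex survives the filters
    (after writing the exclusion log), so callers can distinguish an empty
    dataset from a crash.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    survivors, exclusions = assemble_dataset(config)

    with open(out_dir / "exclusions.log", "wt", encoding="utf-8") as fh:
        for sid, reason in exclusions:
            fh.write(f"{sid}\t{reason}\n")

    if not survivors:
        summary = {"n_structures": 0, "exclusions": len(exclusions),
                   "empty_dataset": True}
        (out_dir / "run_summary.json").write_text(json.dumps(summary, indent=2))
        raise EmptyDatasetError("no complex survived the dataset filters")

    ss_codes = None
    if config.ss_path:
        path = Path(config.ss_path)
        ss_codes = (regions.read_dssp_file(path) if path.suffix == ".dssp"
                    else regions.read_ss_table(path))
    germline = read_germline_table(config.germline_path) \
        if config.germline_path else None

    cutoffs = list(config.cutoff_sweep) or [config.cutoff]
    reports = []
    for cutoff in cutoffs:
        sub = out_dir if len(cutoffs) == 1 else \
            out_dir / f"cutoff_{cutoff:g}A"
        reports.append(_analyze_cutoff(survivors, config, cutoff, sub,
                                       ss_codes=ss_codes, germline=germline))

    summary = {
        "n_structures": len(survivors),
        "exclusions": len(exclusions),
        "empty_dataset": False,
        "seed": config.seed,
        "cutoffs": cutoffs,
        "reports": reports,
    }
    (out_dir / "run_summary.json").write_text(json.dumps(summary, indent=2))
    return summary
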
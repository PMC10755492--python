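"""IMGT region mapping, hotspot tables, and secondary-structure collapse.

Every variable-domain position (numeric IMGT ID 1..128) belongs to exactly
one of FR1, CDR1, FR2, CDR2, FR3, CDR3, FR4; insertion codes never change
region membership.  Hotspot tables report, per (domain, position), how often
a position exists in a group of complexes (background) and how often it is a
unique paratope residue when present (conditional).
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .datatypes import (
    REGION_ORDER,
    AbAgComplex,
    ComputationError,
    ContactRecord,
    RegionScheme,
    Residue,
)

logger = logging.getLogger(__name__)

Position = Tuple[str, int, str]  # (domain, seq_id, icode)

#: DSSP 8-state -> 3-class collapse.  H/G/I (alpha, 3-10, pi helix) -> helix;
#: E/B (strand, isolated bridge) -> strand; T/S/blank (turn, bend, coil) ->
#: loop.  'P' (polyproline II, emitted by newer DSSP versions) -> loop.
_SS_COLLAPSE = {
    "H": "helix", "G": "helix", "I": "helix",
    "E": "strand", "B": "strand",
    "T": "loop", "S": "loop", " ": "loop", "": "loop", "-": "loop", "P": "loop",
}


def assign_region(seq_id: int, scheme: RegionScheme = RegionScheme(),
                  icode: str = "") -> str:
    """Region of one IMGT position; determined by the numeric part alone."""
    if not 1 <= seq_id <= scheme.vr_max:
        raise ComputationError(
            f"IMGT ID {seq_id} outside the variable domain (1-{scheme.vr_max})")
    for region, (lo, hi) in scheme.region_ranges.items():
        if lo <= seq_id <= hi:
            return region
    raise AssertionError("region ranges do not cover the variable domain")


def upr_positions(contacts: Sequence[ContactRecord]) -> Set[Position]:
    """Unique paratope residues as (domain, seq_id, icode) position keys."""
    return {(c.ab_domain, c.ab_seq, c.ab_icode) for c in contacts}


def region_counts(positions: Iterable[Position],
                  scheme: RegionScheme = RegionScheme(),
                  split_domains: bool = True) -> Dict[str, int]:
    """Count uPRs per region; keys like ``CDRH3``/``FRL2`` (or plain with
    ``split_domains=False``).  Positions beyond ``vr_max`` are skipped with a
    warning (constant-domain contacts)."""
    counts: Dict[str, int] = {}
    for dom, seq_id, _ in positions:
        if seq_id > scheme.vr_max:
            logger.warning("position %s%d beyond the variable domain skipped",
                           dom, seq_id)
            continue
        region = assign_region(seq_id, scheme)
        if split_domains:
            chain_letter = "H" if dom == "VH" else "L"
            region = region.replace("CDR", f"CDR{chain_letter}") \
                if region.startswith("CDR") else f"{region[:2]}{chain_letter}{region[2:]}"
        counts[region] = counts.get(region, 0) + 1
    return counts


def region_distribution(per_complex_counts: Sequence[Mapping[str, int]]
                        ) -> Tuple[Dict[str, float], pd.DataFrame]:
    """Average per-complex region proportions (in percent).

    Each complex's region counts are first normalized to percentages of its
    own uPR total, then averaged unweighted over complexes.  Complexes with
    zero uPRs are excluded with a warning.  Also returns the raw per-complex
    counts as a DataFrame (one row per complex, one column per region).
    """
    if not per_complex_counts:
        raise ComputationError("region_distribution: empty group")
    rows = []
    for counts in per_complex_counts:
        total = sum(counts.values())
        if total == 0:
            logger.warning("complex with zero uPRs excluded from region "
                           "distribution")
            continue
        rows.append(dict(counts))
    if not rows:
        raise ComputationError("region_distribution: no complex has uPRs")
    df = pd.DataFrame(rows).fillna(0).astype(int)
    proportions = df.div(df.sum(axis=1), axis=0) * 100.0
    return proportions.mean(axis=0).to_dict(), df


def paratope_proportions(cx: AbAgComplex, contacts: Sequence[ContactRecord],
                         scheme: RegionScheme = RegionScheme()
                         ) -> Dict[str, float]:
    """Fraction of available VR / CDR / FR residues that are paratope residues.

    Denominators count the residues actually present in the structure (numeric
    IMGT ID <= vr_max); numerators count uPRs in the corresponding region set.
    A zero denominator leaves that fraction out (logged).
    """
    present = {"VR": 0, "CDR": 0, "FR": 0}
    for dom, residues in cx.antibody_residues.items():
        for res in residues:
            if res.seq_id > scheme.vr_max:
                continue
            present["VR"] += 1
            region = assign_region(res.seq_id, scheme)
            present["CDR" if region.startswith("CDR") else "FR"] += 1
    uprs = upr_positions(contacts)
    in_vr = {p for p in uprs if p[1] <= scheme.vr_max}
    in_cdr = {p for p in in_vr
              if assign_region(p[1], scheme).startswith("CDR")}
    numer = {"VR": len(in_vr), "CDR": len(in_cdr), "FR": len(in_vr) - len(in_cdr)}
    out: Dict[str, float] = {}
    for key in ("VR", "CDR", "FR"):
        if present[key] == 0:
            logger.warning("%s: no %s residues present; fraction undefined",
                           cx.structure_id, key)
            continue
        out[key] = numer[key] / present[key]
    return out


def _present_positions(cx: AbAgComplex, vr_max: int) -> Set[Position]:
    out: Set[Position] = set()
    for dom, residues in cx.antibody_residues.items():
        for res in residues:
            if res.seq_id <= vr_max:
                out.add((dom, res.seq_id, res.icode))
    return out


def hotspot_map(group: Sequence[Tuple[AbAgComplex, Sequence[ContactRecord]]],
                scheme: RegionScheme = RegionScheme(),
                min_occurrence: float = 0.10) -> pd.DataFrame:
    """Per-position background occurrence and conditional uPR frequency.

    For each (domain, IMGT position incl. insertion code): ``n_present`` is
    the number of complexes whose sequence has the position, ``n_contact``
    the number where it is a uPR.  ``background_pct`` is relative to the
    group size, ``conditional_pct`` relative to ``n_present``.  Positions
    present in fewer than ``min_occurrence`` (inclusive) of the complexes are
    omitted, which naturally drops rare CDR insertions.
    """
    if not group:
        raise ComputationError("hotspot_map: empty group")
    n_group = len(group)
    n_present: Dict[Position, int] = {}
    n_contact: Dict[Position, int] = {}
    for cx, contacts in group:
        present = _present_positions(cx, scheme.vr_max)
        uprs = upr_positions(contacts) & present
        for pos in present:
            n_present[pos] = n_present.get(pos, 0) + 1
        for pos in uprs:
            n_contact[pos] = n_contact.get(pos, 0) + 1
    rows = []
    for pos in sorted(n_present, key=lambda p: (p[0], p[1], p[2])):
        present = n_present[pos]
        if present / n_group < min_occurrence:
            continue
        dom, seq_id, icode = pos
        rows.append({
            "domain": dom,
            "position": f"{seq_id}{icode}",
            "region": assign_region(seq_id, scheme),
            "n_present": present,
            "n_contact": n_contact.get(pos, 0),
            "background_pct": 100.0 * present / n_group,
            "conditional_pct": 100.0 * n_contact.get(pos, 0) / present,
        })
    return pd.DataFrame(rows, columns=["domain", "position", "region",
                                       "n_present", "n_contact",
                                       "background_pct", "conditional_pct"])


def cdr_capture_fraction(group_positions: Sequence[Iterable[Position]],
                         scheme: RegionScheme = RegionScheme()) -> float:
    """Percentage of all uPRs (pooled over the group) that fall inside CDRs.

    Evaluable under any :class:`RegionScheme`, e.g. to compare the default
    CDR2 56-65 against an expanded 55-66 definition.
    """
    total = 0
    inside = 0
    for positions in group_positions:
        for dom, seq_id, icode in positions:
            if seq_id > scheme.vr_max:
                continue
            total += 1
            if assign_region(seq_id, scheme).startswith("CDR"):
                inside += 1
    if total == 0:
        raise ComputationError("cdr_capture_fraction: no uPRs in group")
    return 100.0 * inside / total


def collapse_ss(code: str) -> str:
    """Collapse one DSSP 8-state code to helix / strand / loop."""
    cls = _SS_COLLAPSE.get(code.strip().upper() if code.strip() else " ")
    if cls is None:
        logger.warning("unknown DSSP code %r treated as loop", code)
        return "loop"
    return cls


def cdr3_length(chain: Sequence[Residue],
                scheme: RegionScheme = RegionScheme()) -> int:
    """Number of residues (insertions included) with numeric ID inside CDR3."""
    lo, hi = scheme.cdr3
    return sum(1 for r in chain if lo <= r.seq_id <= hi)


# --- secondary-structure input ------------------------------------------------

def read_dssp_file(path) -> Dict[Tuple[str, int, str], str]:
    """Read 8-state codes from a classic ``.dssp`` output file.

    Returns a mapping (chain_id, seq_id, icode) -> code.
    """
    from Bio.PDB.DSSP import make_dssp_dict
    dssp_dict, _ = make_dssp_dict(str(path))
    codes: Dict[Tuple[str, int, str], str] = {}
    for (chain_id, res_id), values in dssp_dict.items():
        _, seq_id, icode = res_id
        codes[(chain_id, int(seq_id), (icode or "").strip())] = values[1]
    return codes


def read_ss_table(path) -> Dict[Tuple[str, int, str], str]:
    """Read a simple 2-column table ``chain:resid<TAB>code`` of DSSP codes.

    ``resid`` may carry a trailing insertion code (e.g. ``A:111A``).
    """
    codes: Dict[Tuple[str, int, str], str] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            key, code = line.split("\t")
            chain, resid = key.split(":")
            num = resid.rstrip("ABCDEFGHIJKLMNOPQRSTUVWXYZ")
            icode = resid[len(num):]
            codes[(chain, int(num), icode)] = code
    return codes


def epitope_ss_distribution(uer_keys: Iterable[Tuple[str, int, str]],
                            codes: Mapping[Tuple[str, int, str], str]
                            ) -> Dict[str, float]:
    """Percent of unique epitope residues in helix / strand / loop.

    Residues without an assigned code default to loop (logged once).
    """
    counts = {"helix": 0, "strand": 0, "loop": 0}
    missing = 0
    total = 0
    for key in uer_keys:
        total += 1
        code = codes.get(key)
        if code is None:
            missing += 1
            counts["loop"] += 1
        else:
            counts[collapse_ss(code)] += 1
    if missing:
        logger.warning("%d of %d epitope residues lack a secondary-structure "
                       "code; labelled loop", missing, total)
    if total == 0:
        raise ComputationError("epitope_ss_distribution: no epitope residues")
    return {k: 100.0 * v / total for k, v in counts.items()}
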
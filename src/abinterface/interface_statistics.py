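"""Frequency, co-occurrence, segmentation, variability, and bootstrap statistics.

All amino-acid frequencies are computed on *unique* residues (uPRs/uERs), so a
residue making many atom-atom contacts is counted once — except the paratope x
epitope co-occurrence matrix, which by design pools total atom-atom contacts.
Group averages follow a two-step scheme: per-complex percentages first, then
an unweighted mean over complexes; uncertainty is a percentile bootstrap of
that mean.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datatypes import (
    AA_CLASSES,
    STANDARD_AA3,
    ComputationError,
    ContactRecord,
)

Position = Tuple[str, int, str]  # (domain, seq_id, icode)


def aa_frequencies(residue_aas: Sequence[str]) -> pd.Series:
    """Percentage of each of the 20 amino acids over a unique-residue set.

    Input is the 3-letter code of every unique residue in scope (one entry
    per uPR or uER, never per contact).  Output is indexed by the 20 standard
    codes and sums to 100.
    """
    if len(residue_aas) == 0:
        raise ComputationError("aa_frequencies: empty residue set")
    unknown = set(residue_aas) - set(STANDARD_AA3)
    if unknown:
        raise ComputationError(f"aa_frequencies: nonstandard codes {unknown}")
    counts = pd.Series(Counter(residue_aas), dtype=float)
    freq = counts.reindex(STANDARD_AA3, fill_value=0.0)
    return freq / freq.sum() * 100.0


def class_frequencies(freq: pd.Series) -> pd.Series:
    """Collapse a 20-amino-acid frequency vector into physicochemical classes.

    Classes: nonpolar (A,V,P,L,I,W,F), polar (S,T,Y,N,Q), positive (K,H,R),
    negative (E,D), special (G,C,M).  The classes partition the 20 amino
    acids, so the output sums to the input's total.
    """
    return pd.Series({cls: float(freq.loc[list(members)].sum())
                      for cls, members in AA_CLASSES.items()})


@dataclass(frozen=True)
class BootstrapCI:
    point: float
    lo: float
    hi: float
    n_boot: int
    level: float
    seed: int


def group_mean_ci(values: Sequence[float], n_boot: int = 5000,
                  level: float = 0.95, seed: int = 20230131) -> BootstrapCI:
    """Percentile bootstrap CI for the mean of per-complex values.

    Complexes are resampled with replacement ``n_boot`` times; the interval is
    the central ``level`` percentile range of the resampled means.
    Deterministic for a fixed seed.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ComputationError("group_mean_ci: empty input")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, arr.size, size=(n_boot, arr.size))
    means = arr[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return BootstrapCI(point=float(arr.mean()), lo=float(lo), hi=float(hi),
                       n_boot=n_boot, level=level, seed=seed)


def group_frequency_table(per_complex_freqs: Sequence[pd.Series],
                          n_boot: int = 5000, level: float = 0.95,
                          seed: int = 20230131) -> pd.DataFrame:
    """Mean of per-complex frequency vectors with bootstrap CIs per entry.

    Rows are the vector index (amino acids, classes, regions, ...); columns
    ``mean``, ``lo``, ``hi``.  Each entry's CI uses its own derived seed so
    the table is reproducible independent of column order.
    """
    if not per_complex_freqs:
        raise ComputationError("group_frequency_table: empty group")
    df = pd.DataFrame([s for s in per_complex_freqs]).fillna(0.0)
    rows = []
    for i, col in enumerate(df.columns):
        ci = group_mean_ci(df[col].to_numpy(), n_boot=n_boot, level=level,
                           seed=(seed + i) % (2 ** 31))
        rows.append({"key": col, "mean": ci.point, "lo": ci.lo, "hi": ci.hi})
    return pd.DataFrame(rows).set_index("key")


def cooccurrence_matrix(contacts: Sequence[ContactRecord]
                        ) -> Tuple[pd.DataFrame, List[str]]:
    """Row-normalized 20x20 paratope-by-epitope contact matrix.

    Entry (p, e) is the percentage of paratope amino acid p's total atom-atom
    contacts that land on epitope amino acid e; populated rows sum to 100.
    Counts pool *total contacts* (not unique residues).  Returns the matrix
    and the list of paratope amino acids with zero contacts (their rows are
    kept as zeros so the shape is stable).
    """
    if not contacts:
        raise ComputationError("cooccurrence_matrix: no contacts")
    counts = pd.DataFrame(0.0, index=list(STANDARD_AA3),
                          columns=list(STANDARD_AA3))
    for c in contacts:
        counts.loc[c.ab_aa, c.ag_aa] += 1
    row_sums = counts.sum(axis=1)
    zero_rows = [aa for aa in STANDARD_AA3 if row_sums[aa] == 0]
    norm = counts.div(row_sums.replace(0, np.nan), axis=0) * 100.0
    return norm.fillna(0.0), zero_rows


def _icode_rank(icode: str) -> int:
    return 0 if not icode else ord(icode.upper()) - ord("A") + 1


def epitope_segments(uer_keys: Iterable[Tuple[str, int, str]]) -> int:
    """Number of discontinuous epitope segments.

    Within each antigen chain, a segment is a maximal run of
    sequence-consecutive unique epitope residues; two residues are
    consecutive when their numbers differ by one, or share a number with
    different insertion codes (insertions ordered after the base number).
    Segments are summed over chains.
    """
    keys = list(uer_keys)
    if not keys:
        raise ComputationError("epitope_segments: no epitope residues")
    by_chain: Dict[str, List[Tuple[int, int]]] = {}
    for chain, seq_id, icode in keys:
        by_chain.setdefault(chain, []).append((seq_id, _icode_rank(icode)))
    segments = 0
    for chain, positions in by_chain.items():
        positions.sort()
        segments += 1
        for (s0, _), (s1, _) in zip(positions, positions[1:]):
            if s1 - s0 > 1:
                segments += 1
    return segments


def position_aa_frequencies(group_uprs: Sequence[Mapping[Position, str]]
                            ) -> Dict[Position, pd.Series]:
    """Per-position amino-acid distribution over the complexes of a group.

    ``group_uprs``: one mapping per complex from uPR position key
    (domain, seq_id, icode) to its 3-letter amino acid.  For each position
    that is a uPR in at least one complex, returns the frequency vector over
    those complexes (sums to 100%).
    """
    if not group_uprs:
        raise ComputationError("position_aa_frequencies: empty group")
    by_position: Dict[Position, List[str]] = {}
    for upr_map in group_uprs:
        for pos, aa in upr_map.items():
            by_position.setdefault(pos, []).append(aa)
    return {pos: aa_frequencies(aas) for pos, aas in by_position.items()}


@dataclass(frozen=True)
class WuKabatColumn:
    position: str
    N: int
    k: int
    n_mode: int

    @property
    def variability(self) -> float:
        return self.N * self.k / self.n_mode


def wu_kabat(column: Sequence[str], position: str = "") -> WuKabatColumn:
    """Wu-Kabat variability of one alignment column: N * k / n_mode.

    N = sequences with a residue at the position (gaps excluded upstream),
    k = distinct amino acids, n_mode = count of the most frequent one.
    The minimum of 1 is attained exactly on fully conserved columns.
    """
    if not column:
        raise ComputationError(f"wu_kabat: empty column {position!r}")
    counts = Counter(column)
    return WuKabatColumn(position=position, N=len(column), k=len(counts),
                         n_mode=max(counts.values()))


def germline_mutation_fraction(
        group_uprs: Sequence[Mapping[Position, str]],
        germline_maps: Sequence[Mapping[Position, str]],
) -> Tuple[pd.DataFrame, Optional[float]]:
    """Percentage of complexes whose uPR differs from the germline, per position.

    ``germline_maps`` parallels ``group_uprs``: for each complex, a mapping
    from position key to the germline 3-letter amino acid.  A position enters
    a complex's tally only when it is a uPR there *and* has a germline
    assignment.  Returns a per-position table (n_upr, n_mutated,
    mutated_pct) and the pooled percentage over all (complex, position)
    pairs (None when there is no overlap).
    """
    if len(group_uprs) != len(germline_maps):
        raise ComputationError("germline_mutation_fraction: group and germline "
                               "lists differ in length")
    n_upr: Dict[Position, int] = {}
    n_mut: Dict[Position, int] = {}
    for upr_map, germ_map in zip(group_uprs, germline_maps):
        for pos, aa in upr_map.items():
            germ = germ_map.get(pos)
            if germ is None:
                continue
            n_upr[pos] = n_upr.get(pos, 0) + 1
            if aa != germ:
                n_mut[pos] = n_mut.get(pos, 0) + 1
    rows = []
    for pos in sorted(n_upr):
        dom, seq_id, icode = pos
        rows.append({
            "domain": dom, "position": f"{seq_id}{icode}",
            "n_upr": n_upr[pos], "n_mutated": n_mut.get(pos, 0),
            "mutated_pct": 100.0 * n_mut.get(pos, 0) / n_upr[pos],
        })
    table = pd.DataFrame(rows, columns=["domain", "position", "n_upr",
                                        "n_mutated", "mutated_pct"])
    total = sum(n_upr.values())
    pooled = 100.0 * sum(n_mut.values()) / total if total else None
    return table, pooled
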
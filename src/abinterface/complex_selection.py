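"""Packing-duplicate elimination.

Crystal asymmetric units often contain several copies of the same
antibody-antigen complex.  Counting contacts from every copy would weight
those structures multiple times, so only the best-ordered copy — the one with
the lowest mean B-factor over its amino-acid atoms — is retained per file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Sequence, Tuple

from .datatypes import AbAgComplex, ComputationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class UnitScore:
    unit_index: int
    mean_b: float
    n_atoms: int


def mean_bfactor(cx: AbAgComplex, include_hydrogens: bool = False) -> UnitScore:
    """Mean B-factor over the unit's amino-acid atoms (antibody + antigen).

    Hydrogens are excluded by default, consistent with contact eligibility;
    pass ``include_hydrogens=True`` to average over every parsed atom.
    """
    total = 0.0
    count = 0
    for res in cx.all_antibody_residues() + cx.all_antigen_residues():
        atoms = res.atoms if include_hydrogens else res.eligible_atoms()
        for atom in atoms:
            total += atom.b_factor
            count += 1
    if count == 0:
        raise ComputationError(
            f"{cx.structure_id} unit {cx.unit_index}: no eligible atoms for "
            "B-factor average")
    return UnitScore(unit_index=cx.unit_index, mean_b=total / count, n_atoms=count)


def select_unit(units: Sequence[AbAgComplex],
                include_hydrogens: bool = False
                ) -> Tuple[AbAgComplex, List[UnitScore]]:
    """Pick the biological unit with the lowest mean B-factor.

    Ties are broken by the lowest ``unit_index`` (first annotation row).
    Returns the selected complex and the scores of every candidate.
    """
    if not units:
        raise ComputationError("select_unit: empty unit list")
    scores = [mean_bfactor(u, include_hydrogens=include_hydrogens) for u in units]
    best = min(range(len(units)),
               key=lambda i: (scores[i].mean_b, units[i].unit_index))
    if len(units) > 1:
        logger.info("%s: selected unit %d of %d (mean B %.2f)",
                    units[best].structure_id, units[best].unit_index,
                    len(units), scores[best].mean_b)
    return units[best], scores
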
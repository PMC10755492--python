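"""Ground-truthed synthetic antibody-antigen complexes.

The generator emits parseable PDB files whose interface is known by
construction: antibody and antigen residues live on widely separated planes
(far beyond any contact cutoff), and each planted atom-atom contact is
realized by moving exactly the named atoms to an isolated "contact site"
between the planes at the requested distance.  Chemical realism is explicitly
not a goal — only distance structure, IMGT-consistent numbering, realistic
atom names, and format validity matter.  Every generated complex is verified
with an all-pairs distance check before it is returned: the contact set at
the target cutoff must equal the planted list exactly and every other
cross-molecular pair must be farther than the decoy margin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .datatypes import (
    AA_1TO3,
    STANDARD_AA3,
    AbAgComplex,
    AbInterfaceError,
    Atom,
    ChainAnnotation,
    ContactRecord,
    InterfaceSummary,
    Residue,
)
from .interface_contacts import summarize_interface
from .structure_io import write_pdb

AB_CHAIN_OF = {"VH": "H", "VL": "L"}


class GenerationError(AbInterfaceError):
    """The requested geometry or identity structure cannot be realized."""


@dataclass(frozen=True)
class PlantedContact:
    """One atom-atom contact to engineer into a synthetic complex."""

    ab_pos: int
    ab_atom: str
    ag_pos: int
    ag_atom: str
    distance: float = 4.0
    ab_domain: str = "VH"
    ag_chain: str = "A"


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic complex.

    ``planted_contacts`` is the exact interface; all distances must be at or
    below ``cutoff`` which must be strictly below ``decoy_margin`` (the
    minimum separation enforced for every non-planted cross pair).
    ``paratope_composition`` fixes amino acids at chosen antibody positions so
    frequency statistics have known expectations; ``ab_sequences`` fixes whole
    domain sequences (1-letter) for clustering tests.
    """

    seed: int = 0
    n_ab_residues: int = 120
    domains: Tuple[str, ...] = ("VH", "VL")
    antigen_len: int = 60
    planted_contacts: Tuple[PlantedContact, ...] = ()
    decoy_margin: float = 8.0
    cutoff: float = 5.0
    insertions: Tuple[Tuple[str, int, str], ...] = ()  # (domain, seq_id, icode)
    ss_codes: Optional[str] = None  # one DSSP code per antigen residue
    paratope_composition: Mapping[Tuple[str, int], str] = field(default_factory=dict)
    ab_sequences: Optional[Mapping[str, str]] = None
    structure_id: str = "SYN1"
    antigen_type: Optional[str] = "protein"
    resolution: float = 2.0
    b_factor_base: float = 20.0

    def __post_init__(self) -> None:
        if not 1 <= self.n_ab_residues <= 128:
            raise GenerationError("n_ab_residues must be within 1..128 (IMGT "
                                  "variable domain)")
        if self.antigen_len < 1:
            raise GenerationError("antigen_len must be >= 1")
        if not set(self.domains) <= {"VH", "VL"} or not self.domains:
            raise GenerationError(f"invalid domain set {self.domains}")
        for pc in self.planted_contacts:
            if pc.distance > self.cutoff:
                raise GenerationError(
                    f"planted distance {pc.distance} exceeds cutoff {self.cutoff}")
            if pc.ab_domain not in self.domains:
                raise GenerationError(f"planted contact uses absent domain "
                                      f"{pc.ab_domain}")
            if not 1 <= pc.ab_pos <= self.n_ab_residues and \
                    (pc.ab_domain, pc.ab_pos) not in \
                    {(d, p) for d, p, _ in self.insertions}:
                raise GenerationError(f"planted antibody position {pc.ab_pos} "
                                      "not generated")
            if not 1 <= pc.ag_pos <= self.antigen_len:
                raise GenerationError(f"planted antigen position {pc.ag_pos} "
                                      "not generated")
        if self.cutoff >= self.decoy_margin:
            raise GenerationError("decoy_margin must exceed the cutoff")


@dataclass
class GroundTruth:
    """What the pipeline must recover from the generated data."""

    contacts: List[ContactRecord]
    summary: InterfaceSummary
    selected_unit_index: Optional[int] = None
    families: Optional[List[List[str]]] = None
    survivors: Optional[List[str]] = None


_BACKBONE_OFFSETS = (
    ("N", np.array([-1.0, 0.0, 0.0]), "N"),
    ("CA", np.array([0.0, 0.0, 0.0]), "C"),
    ("C", np.array([1.0, 0.0, 0.0]), "C"),
    ("O", np.array([1.2, 0.9, 0.0]), "O"),
    ("CB", np.array([0.0, -1.2, 0.0]), "C"),
)

_DIRECTIONS = [np.array(v, dtype=float) for v in
               [(1, 0, 0), (0, 1, 0), (0, 0, 1), (-1, 0, 0), (0, -1, 0),
                (0.7071067811865476, 0.7071067811865476, 0.0),
                (0.7071067811865476, 0.0, 0.7071067811865476),
                (0.0, 0.7071067811865476, 0.7071067811865476)]]


def _random_sequence(rng: np.random.Generator, n: int) -> List[str]:
    return [STANDARD_AA3[i] for i in rng.integers(0, 20, size=n)]


def _build_residue(chain_id: str, seq_id: int, icode: str, aa: str,
                   center: np.ndarray, rng: np.random.Generator,
                   b_base: float) -> Residue:
    atoms = []
    for name, offset, element in _BACKBONE_OFFSETS:
        if name == "CB" and aa == "GLY":
            continue
        atoms.append(Atom(name=name, element=element,
                          position=center + offset,
                          b_factor=float(b_base + rng.uniform(0.0, 10.0)),
                          occupancy=1.0))
    return Residue(chain_id=chain_id, seq_id=seq_id, icode=icode, aa=aa,
                   atoms=atoms)


def _plant_positions(spec: SyntheticSpec) -> Dict[tuple, np.ndarray]:
    """Lay out the planted atoms at isolated contact sites.

    Atoms sharing a planted contact form a graph; each connected component is
    placed around its own site between the antibody and antigen planes.  Two
    component shapes can be realized without creating unplanted near pairs:
    stars (all contacts share one atom; neighbours fan out along rotating
    unit directions — non-adjacent pairs are same-side and unconstrained) and
    paths (atoms laid out collinearly, so any cross-side non-adjacent pair is
    at least three edge lengths away).  Denser contact graphs are rejected;
    the all-pairs verification still rechecks every emitted geometry.
    """
    adjacency: Dict[tuple, List[Tuple[tuple, float]]] = {}
    for pc in spec.planted_contacts:
        a = ("ab", pc.ab_domain, pc.ab_pos, pc.ab_atom)
        b = ("ag", pc.ag_chain, pc.ag_pos, pc.ag_atom)
        adjacency.setdefault(a, []).append((b, pc.distance))
        adjacency.setdefault(b, []).append((a, pc.distance))
    for node in adjacency:
        adjacency[node].sort(key=lambda t: (t[0], t[1]))

    # connected components by BFS
    components: List[List[tuple]] = []
    seen: set = set()
    for start in sorted(adjacency):
        if start in seen:
            continue
        queue, members = [start], []
        seen.add(start)
        while queue:
            node = queue.pop(0)
            members.append(node)
            for neighbor, _ in adjacency[node]:
                if neighbor not in seen:
                    seen.add(neighbor)
                    queue.append(neighbor)
        components.append(members)

    placed: Dict[tuple, np.ndarray] = {}
    for ci, members in enumerate(components):
        anchor = np.array([60.0 * ci, 0.0, 60.0])
        degrees = {m: len(adjacency[m]) for m in members}
        n_edges = sum(degrees.values()) // 2
        hub = max(members, key=lambda m: (degrees[m], m))
        if degrees[hub] == n_edges:
            # star: every contact involves the hub
            placed[hub] = anchor
            for k, (neighbor, dist) in enumerate(adjacency[hub]):
                placed[neighbor] = anchor + \
                    dist * _DIRECTIONS[k % len(_DIRECTIONS)]
            if degrees[hub] > len(_DIRECTIONS):
                raise GenerationError(
                    f"atom {hub} shared by more than {len(_DIRECTIONS)} "
                    "planted contacts")
        elif max(degrees.values()) <= 2 and n_edges == len(members) - 1:
            # path: collinear along +x from an endpoint; cross-side
            # non-adjacent pairs are >= 3 consecutive edge lengths apart
            endpoint = min(m for m in members if degrees[m] == 1)
            placed[endpoint] = anchor
            prev, node = None, endpoint
            offset = 0.0
            while True:
                nxt = [(nb, d) for nb, d in adjacency[node] if nb != prev]
                if not nxt:
                    break
                (neighbor, dist), = nxt
                offset += dist
                placed[neighbor] = anchor + np.array([offset, 0.0, 0.0])
                prev, node = node, neighbor
        else:
            raise GenerationError(
                "planted contact graph component is neither a star nor a "
                f"path ({len(members)} atoms, {n_edges} contacts); split the "
                "shared atoms across separate complexes")
    return placed


def build_complex(spec: SyntheticSpec) -> Tuple[AbAgComplex, GroundTruth]:
    """Construct the in-memory complex and its ground truth (no serialization)."""
    rng = np.random.default_rng(spec.seed)

    # --- sequences ---
    ab_seqs: Dict[str, List[str]] = {}
    for dom in spec.domains:
        if spec.ab_sequences and dom in spec.ab_sequences:
            letters = spec.ab_sequences[dom]
            if len(letters) != spec.n_ab_residues:
                raise GenerationError(
                    f"{dom}: ab_sequences length {len(letters)} != "
                    f"n_ab_residues {spec.n_ab_residues}")
            ab_seqs[dom] = [AA_1TO3[c] for c in letters]
        else:
            ab_seqs[dom] = _random_sequence(rng, spec.n_ab_residues)
        for (d, pos), aa in spec.paratope_composition.items():
            if d == dom and 1 <= pos <= spec.n_ab_residues:
                ab_seqs[dom][pos - 1] = aa
    ag_seq = _random_sequence(rng, spec.antigen_len)

    planted_xyz = _plant_positions(spec)

    # --- antibody residues ---
    plane_y = {"VH": 0.0, "VL": 400.0}
    antibody: Dict[str, List[Residue]] = {}
    for dom in spec.domains:
        chain_id = AB_CHAIN_OF[dom]
        residues = []
        ids: List[Tuple[int, str]] = [(i, "") for i in
                                      range(1, spec.n_ab_residues + 1)]
        for d, seq_id, icode in spec.insertions:
            if d == dom:
                ids.append((seq_id, icode))
        ids.sort()
        for ordinal, (seq_id, icode) in enumerate(ids):
            aa = ab_seqs[dom][seq_id - 1] if not icode else \
                spec.paratope_composition.get((dom, seq_id),
                                              _random_sequence(rng, 1)[0])
            center = np.array([20.0 * ordinal, plane_y[dom], -200.0])
            residues.append(_build_residue(chain_id, seq_id, icode, aa,
                                           center, rng, spec.b_factor_base))
        antibody[dom] = residues

    # --- antigen residues ---
    antigen: List[Residue] = []
    for j in range(1, spec.antigen_len + 1):
        center = np.array([20.0 * (j - 1), 0.0, 300.0])
        antigen.append(_build_residue("A", j, "", ag_seq[j - 1], center, rng,
                                      spec.b_factor_base))

    # --- relocate / add planted atoms ---
    index: Dict[tuple, Residue] = {}
    for dom, residues in antibody.items():
        for r in residues:
            index[("ab", dom, r.seq_id, r.icode)] = r
    for r in antigen:
        index[("ag", r.chain_id, r.seq_id, r.icode)] = r
    for key, xyz in planted_xyz.items():
        side, tag, pos, atom_name = key
        res = index.get((side, tag, pos, ""))
        if res is None:
            raise GenerationError(f"planted atom {key} has no residue")
        existing = [a for a in res.atoms if a.name == atom_name]
        if existing:
            existing[0].position = xyz
        else:
            res.atoms.append(Atom(name=atom_name, element=atom_name[:1],
                                  position=xyz,
                                  b_factor=float(spec.b_factor_base
                                                 + rng.uniform(0.0, 10.0)),
                                  occupancy=1.0))

    annotation = ChainAnnotation(
        structure_id=spec.structure_id,
        heavy_chain_id=AB_CHAIN_OF["VH"] if "VH" in spec.domains else None,
        light_chain_id=AB_CHAIN_OF["VL"] if "VL" in spec.domains else None,
        antigen_chain_ids=["A"],
        antigen_type=spec.antigen_type,
        resolution=spec.resolution,
    )
    cx = AbAgComplex(annotation=annotation, antibody_residues=antibody,
                     antigen_residues={"A": antigen})

    truth_contacts = _expected_contacts(spec, cx)
    _verify_geometry(spec, cx, truth_contacts)
    truth = GroundTruth(contacts=truth_contacts,
                        summary=summarize_interface(truth_contacts))
    return cx, truth


def _expected_contacts(spec: SyntheticSpec, cx: AbAgComplex
                       ) -> List[ContactRecord]:
    res_index: Dict[tuple, Residue] = {}
    for dom, residues in cx.antibody_residues.items():
        for r in residues:
            res_index[("ab", dom, r.seq_id)] = r
    for r in cx.antigen_residues["A"]:
        res_index[("ag", "A", r.seq_id)] = r
    records = []
    for pc in spec.planted_contacts:
        ab_res = res_index[("ab", pc.ab_domain, pc.ab_pos)]
        ag_res = res_index[("ag", pc.ag_chain, pc.ag_pos)]
        records.append(ContactRecord(
            ab_chain=ab_res.chain_id, ab_seq=ab_res.seq_id,
            ab_icode=ab_res.icode, ab_aa=ab_res.aa, ab_atom=pc.ab_atom,
            ab_domain=pc.ab_domain,
            ag_chain=ag_res.chain_id, ag_seq=ag_res.seq_id,
            ag_icode=ag_res.icode, ag_aa=ag_res.aa, ag_atom=pc.ag_atom,
            distance=pc.distance))
    records.sort(key=lambda r: r.sort_key)
    return records


def _verify_geometry(spec: SyntheticSpec, cx: AbAgComplex,
                     expected: Sequence[ContactRecord]) -> None:
    """All-pairs check: the interface equals the planted list exactly."""
    ab = [(r, a) for r in cx.all_antibody_residues() for a in r.eligible_atoms()]
    ag = [(r, a) for r in cx.all_antigen_residues() for a in r.eligible_atoms()]
    ab_xyz = np.array([a.position for _, a in ab])
    ag_xyz = np.array([a.position for _, a in ag])
    d = np.linalg.norm(ab_xyz[:, None, :] - ag_xyz[None, :, :], axis=2)
    planted_keys = {(c.ab_chain, c.ab_seq, c.ab_icode, c.ab_atom,
                     c.ag_chain, c.ag_seq, c.ag_icode, c.ag_atom): c.distance
                    for c in expected}
    ii, jj = np.nonzero(d <= spec.decoy_margin)
    seen = set()
    for i, j in zip(ii, jj):
        ab_res, ab_atom = ab[i]
        ag_res, ag_atom = ag[j]
        key = (ab_res.chain_id, ab_res.seq_id, ab_res.icode, ab_atom.name,
               ag_res.chain_id, ag_res.seq_id, ag_res.icode, ag_atom.name)
        target = planted_keys.get(key)
        if target is None:
            raise GenerationError(
                f"unplanted pair {key} at {d[i, j]:.2f} A violates the decoy "
                f"margin {spec.decoy_margin} A")
        if abs(d[i, j] - target) > 1e-6:
            raise GenerationError(
                f"planted pair {key}: distance {d[i, j]:.6f} != {target}")
        seen.add(key)
    if seen != set(planted_keys):
        raise GenerationError(
            f"planted pairs missing from geometry: {set(planted_keys) - seen}")


def generate_complex(spec: SyntheticSpec
                     ) -> Tuple[str, ChainAnnotation, GroundTruth]:
    """Emit PDB text, the matching annotation row, and the ground truth.

    Deterministic: the same spec (seed included) yields byte-identical text.
    """
    cx, truth = build_complex(spec)
    return write_pdb([cx]), cx.annotation, truth


def generate_packing_variants(spec: SyntheticSpec,
                              b_offsets: Sequence[float]
                              ) -> Tuple[str, List[ChainAnnotation], GroundTruth]:
    """One file with ``len(b_offsets)`` rigid copies of the base complex.

    Unit i is translated far from the others and has every B-factor shifted
    by ``b_offsets[i]``; the ground truth records which unit has the lowest
    mean B-factor (ties: lowest unit index).
    """
    if not b_offsets:
        raise GenerationError("b_offsets must be non-empty")
    if len(b_offsets) > 8:
        raise GenerationError("at most 8 packing variants supported")
    chain_pool = "HLAEFGIJKMNOPQRSTUVWXYZBCD"
    complexes: List[AbAgComplex] = []
    annotations: List[ChainAnnotation] = []
    base_cx, base_truth = build_complex(spec)
    for i, offset in enumerate(b_offsets):
        shift = np.array([0.0, 2000.0 * i, 0.0])
        heavy = chain_pool[3 * i] if "VH" in spec.domains else None
        light = chain_pool[3 * i + 1] if "VL" in spec.domains else None
        ag_chain = chain_pool[3 * i + 2]
        remap = {"H": heavy, "L": light, "A": ag_chain}

        def move(res: Residue) -> Residue:
            return Residue(
                chain_id=remap[res.chain_id], seq_id=res.seq_id,
                icode=res.icode, aa=res.aa,
                atoms=[Atom(name=a.name, element=a.element,
                            position=a.position + shift,
                            b_factor=a.b_factor + offset,
                            occupancy=a.occupancy, altloc=a.altloc)
                       for a in res.atoms])

        annotation = ChainAnnotation(
            structure_id=spec.structure_id, heavy_chain_id=heavy,
            light_chain_id=light, antigen_chain_ids=[ag_chain],
            antigen_type=spec.antigen_type, resolution=spec.resolution)
        antibody = {dom: [move(r) for r in base_cx.antibody_residues[dom]]
                    for dom in base_cx.antibody_residues}
        antigen = {ag_chain: [move(r) for r in base_cx.antigen_residues["A"]]}
        complexes.append(AbAgComplex(annotation=annotation,
                                     antibody_residues=antibody,
                                     antigen_residues=antigen, unit_index=i))
        annotations.append(annotation)
    best = int(np.argmin(np.asarray(b_offsets, dtype=float)))
    truth = GroundTruth(contacts=base_truth.contacts,
                        summary=base_truth.summary,
                        selected_unit_index=best)
    return write_pdb(complexes), annotations, truth


def _mutate(rng: np.random.Generator, seq: str, n_sub: int) -> str:
    letters = list(seq)
    if n_sub == 0:
        return seq
    positions = rng.choice(len(letters), size=min(n_sub, len(letters)),
                           replace=False)
    alphabet = "".join(sorted(AA_1TO3))
    for p in positions:
        choices = [c for c in alphabet if c != letters[p]]
        letters[p] = choices[rng.integers(0, len(choices))]
    return "".join(letters)


def generate_redundant_dataset(
        family_sizes: Sequence[int],
        mutation_rate: int = 2,
        seed: int = 0,
        domains: Tuple[str, ...] = ("VH", "VL"),
        n_ab_residues: int = 110,
        threshold: float = 0.95,
        max_retries: int = 20,
) -> Tuple[Dict[str, str], List[ChainAnnotation], GroundTruth]:
    """Families of near-identical antibodies plus the expected survivors.

    Each family shares a base variable-domain sequence per domain; each member
    carries ``mutation_rate`` random substitutions.  The generator verifies
    that within-family identity stays at or above ``threshold`` and that
    cross-family identities stay below it, retrying with a derived seed up to
    ``max_retries`` times.  The expected survivor of each family is its
    member with the best resolution (member 0 by construction).

    Returns (files keyed by structure ID, annotation rows, ground truth).
    """
    from .redundancy import sequence_identity

    if any(s < 1 for s in family_sizes):
        raise GenerationError("family sizes must be >= 1")
    max_within = 2 * mutation_rate / n_ab_residues
    if 1.0 - max_within < threshold:
        raise GenerationError(
            f"mutation_rate {mutation_rate} cannot guarantee within-family "
            f"identity >= {threshold} at length {n_ab_residues}")

    for attempt in range(max_retries):
        rng = np.random.default_rng((seed + 7919 * attempt) % (2 ** 31))
        bases: List[Dict[str, str]] = []
        for _ in family_sizes:
            bases.append({dom: "".join(
                sorted(AA_1TO3)[i] for i in rng.integers(0, 20,
                                                         size=n_ab_residues))
                for dom in domains})
        ok = True
        for fi in range(len(bases)):
            for fj in range(fi + 1, len(bases)):
                for dom in domains:
                    ident = sequence_identity(bases[fi][dom], bases[fj][dom])
                    # members drift up to mutation_rate from their base, so
                    # demand base-to-base identity below threshold with slack
                    if ident >= threshold - 2 * mutation_rate / n_ab_residues:
                        ok = False
        if not ok:
            continue

        files: Dict[str, str] = {}
        annotations: List[ChainAnnotation] = []
        families: List[List[str]] = []
        survivors: List[str] = []
        member_seqs: List[Dict[str, str]] = []
        for fi, size in enumerate(family_sizes):
            members: List[str] = []
            for mi in range(size):
                sid = f"S{fi}{chr(ord('A') + mi)}"
                seqs = {dom: _mutate(rng, bases[fi][dom], mutation_rate)
                        for dom in domains}
                member_seqs.append(seqs)
                spec = SyntheticSpec(
                    seed=int(rng.integers(0, 2 ** 31)),
                    n_ab_residues=n_ab_residues,
                    domains=domains,
                    antigen_len=30,
                    planted_contacts=(PlantedContact(
                        ab_pos=107, ab_atom="CB", ag_pos=10, ag_atom="CB",
                        distance=4.0),),
                    ab_sequences=seqs,
                    structure_id=sid,
                    resolution=round(2.0 + 0.05 * mi, 2),
                )
                pdb_text, annotation, _ = generate_complex(spec)
                files[sid] = pdb_text
                annotations.append(annotation)
                members.append(sid)
            families.append(members)
            survivors.append(members[0])

        # verify the identity structure the clustering relies on
        valid = True
        fam_of: Dict[str, int] = {}
        for fi, fam in enumerate(families):
            for sid in fam:
                fam_of[sid] = fi
        sid_seqs = dict(zip([sid for fam in families for sid in fam],
                            member_seqs))
        sids = list(sid_seqs)
        for i in range(len(sids)):
            for j in range(i + 1, len(sids)):
                same_family = fam_of[sids[i]] == fam_of[sids[j]]
                for dom in domains:
                    ident = sequence_identity(sid_seqs[sids[i]][dom],
                                              sid_seqs[sids[j]][dom])
                    if same_family and ident < threshold:
                        valid = False
                    if not same_family and ident >= threshold:
                        valid = False
        if valid:
            truth = GroundTruth(contacts=[], summary=summarize_interface([]),
                                families=families, survivors=survivors)
            return files, annotations, truth
    raise GenerationError(
        f"could not satisfy identity constraints in {max_retries} attempts")


def generate_dataset(n_structures: int = 10, seed: int = 0,
                     n_contacts: int = 5, mixed_domains: bool = True
                     ) -> Tuple[Dict[str, str], List[ChainAnnotation],
                                Dict[str, GroundTruth]]:
    """A small study-like dataset: one file per structure, known interfaces.

    Alternates Fv (VH+VL) and VH-only single-domain antibodies when
    ``mixed_domains`` is set; every complex carries ``n_contacts`` planted
    contacts at paratope-plausible IMGT positions (27-117) with distances
    drawn from 3.5-4.5 A.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    files: Dict[str, str] = {}
    annotations: List[ChainAnnotation] = []
    truths: Dict[str, GroundTruth] = {}
    for i in range(n_structures):
        planted = []
        used_ab: set = set()
        used_ag: set = set()
        while len(planted) < n_contacts:
            pos = int(rng.integers(27, 118))
            ag_pos = int(rng.integers(1, 61))
            if pos in used_ab or ag_pos in used_ag:
                continue
            used_ab.add(pos)
            used_ag.add(ag_pos)
            planted.append(PlantedContact(
                ab_pos=pos, ab_atom="CB", ag_pos=ag_pos, ag_atom="CB",
                distance=float(rng.uniform(3.5, 4.5))))
        domains = ("VH", "VL") if (not mixed_domains or i % 2 == 0) else ("VH",)
        spec = SyntheticSpec(
            seed=int(rng.integers(0, 2 ** 31)),
            domains=domains,
            planted_contacts=tuple(planted),
            structure_id=f"SY{i:02d}",
            resolution=round(float(rng.uniform(1.5, 2.9)), 2))
        text, annotation, truth = generate_complex(spec)
        files[annotation.structure_id] = text
        annotations.append(annotation)
        truths[annotation.structure_id] = truth
    return files, annotations, truths


def write_annotation_tsv(annotations: Sequence[ChainAnnotation], path) -> None:
    """Write annotation rows in the summary-table format the loader reads."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("pdb\tHchain\tLchain\tantigen_chain\tantigen_type\tresolution\n")
        for ann in annotations:
            fh.write("\t".join([
                ann.structure_id,
                ann.heavy_chain_id or "NA",
                ann.light_chain_id or "NA",
                " | ".join(ann.antigen_chain_ids),
                ann.antigen_type or "NA",
                f"{ann.resolution:g}",
            ]) + "\n")


def ground_truth_json(truth: GroundTruth) -> str:
    """Serialize a ground truth to JSON (for the CLI synth subcommand)."""
    payload = {
        "n_contacts": truth.summary.total_contacts,
        "upr": truth.summary.upr, "uer": truth.summary.uer,
        "upa": truth.summary.upa, "uea": truth.summary.uea,
        "contacts": [
            {"ab_chain": c.ab_chain, "ab_res": c.ab_res, "ab_aa": c.ab_aa,
             "ab_atom": c.ab_atom, "ab_domain": c.ab_domain,
             "ag_chain": c.ag_chain, "ag_res": c.ag_res, "ag_aa": c.ag_aa,
             "ag_atom": c.ag_atom, "distance": c.distance}
            for c in truth.contacts],
        "selected_unit_index": truth.selected_unit_index,
        "families": truth.families,
        "survivors": truth.survivors,
    }
    return json.dumps(payload, indent=2)
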
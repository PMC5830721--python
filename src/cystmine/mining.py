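"""Mining labile disulfide bonds from a corpus of X-ray structures.

A disulfide is *labile* when it is demonstrably formed in at least one
structure of a protein and validly absent in at least one other — "validly"
meaning the absence is not explained by a truncated construct, a mutated
cysteine, or an unresolved residue.  Labile bonds are the operational proxy
for allosteric disulfides: a bond seen in both oxidised and reduced states
has a demonstrated propensity for cleavage.

The pipeline:

1. screen every structure (resolution ≤ 2.5 Å, no reducing agent in the
   crystallisation mix, chains mappable to an accession);
2. harvest disulfides from SSBOND header lines and measure their geometry;
3. for every known bond of an accession, classify each chain lacking the
   bond as missing / truncated / mutated / unresolved;
4. aggregate observations into one record per unique
   (accession, position-pair) bond and flag the labile ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .configuration import classify_geometry
from .geometry import (
    CystineGeometry,
    GeometryError,
    b_factor_average,
    measure_cystine,
    ss_pair_label,
    ss_state,
)
from .mapping import UNMAPPED, ChainMapping, chain_mapping_for, lookup_accession
from .pdbfile import StructureModel

__all__ = [
    "DEFAULT_REDUCING_AGENTS",
    "RESOLUTION_CUTOFF",
    "EQUILIBRIUM_SS_LENGTH",
    "LENGTH_TOLERANCE",
    "StructureVerdict",
    "BondObservation",
    "UniqueBond",
    "ScanResult",
    "screen_structure",
    "harvest_bonds",
    "length_filter",
    "assess_absence",
    "aggregate",
    "scan_corpus",
]

#: heteroatom codes treated as evidence of a reducing agent in the crystal
DEFAULT_REDUCING_AGENTS = frozenset({"DTT", "DTU", "DTV", "BME", "TCE"})

RESOLUTION_CUTOFF = 2.5     # Å; structures above are excluded
EQUILIBRIUM_SS_LENGTH = 2.038  # Å, relaxed S-S bond length
LENGTH_TOLERANCE = 0.10     # fractional window around the equilibrium length

PRESENT_STATUSES = ("present", "present_filtered_length")
EXCLUDED_STATUSES = ("excluded_truncated", "excluded_mutated", "excluded_unresolved")
ALL_STATUSES = PRESENT_STATUSES + ("missing",) + EXCLUDED_STATUSES


@dataclass
class StructureVerdict:
    pdb_id: str
    reasons: list[str] = field(default_factory=list)

    @property
    def status(self) -> str:
        return "excluded" if self.reasons else "included"

    @property
    def included(self) -> bool:
        return not self.reasons


@dataclass
class BondObservation:
    """One (structure, chain, bond) record."""

    accession: str
    pos_i: int
    pos_j: int
    pdb_id: str
    chain: str
    status: str
    resolution: Optional[float] = None
    geometry: Optional[CystineGeometry] = None

    def __post_init__(self) -> None:
        if self.pos_i > self.pos_j:
            raise ValueError("position pair must be ordered i < j")
        if self.status not in ALL_STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if (self.geometry is not None) != self.status.startswith("present"):
            raise ValueError("geometry must be present exactly for present-type statuses")

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.accession, self.pos_i, self.pos_j)


@dataclass
class UniqueBond:
    """All observations of one (accession, position-pair) disulfide."""

    accession: str
    pos_i: int
    pos_j: int
    observations: list[BondObservation]
    labile: bool
    representative: Optional[BondObservation] = None
    same_file_lability: bool = False
    in_reference: bool = True

    def count(self, status: str) -> int:
        return sum(1 for o in self.observations if o.status == status)

    @property
    def geometry(self) -> Optional[CystineGeometry]:
        return None if self.representative is None else self.representative.geometry


@dataclass
class ScanResult:
    verdicts: list[StructureVerdict]
    observations: list[BondObservation]
    bonds: list[UniqueBond]
    logs: list[str] = field(default_factory=list)


def screen_structure(
    model: StructureModel,
    resolution_cutoff: float = RESOLUTION_CUTOFF,
    reducing_agents: frozenset[str] = DEFAULT_REDUCING_AGENTS,
) -> StructureVerdict:
    """Corpus filter: resolution known and ≤ cutoff, no reducing-agent heteroatoms."""
    verdict = StructureVerdict(pdb_id=model.pdb_id)
    if model.resolution is None:
        verdict.reasons.append("no_resolution")
    elif model.resolution > resolution_cutoff:
        verdict.reasons.append("resolution_gt_2.5")
    if model.het_codes & reducing_agents:
        verdict.reasons.append("reducing_agent")
    return verdict


def length_filter(
    geometry: CystineGeometry,
    equilibrium: float = EQUILIBRIUM_SS_LENGTH,
    tolerance: float = LENGTH_TOLERANCE,
) -> bool:
    """S-S distance within ±10% of the 2.038 Å equilibrium length (inclusive).

    A 1e-9 Å guard keeps the inclusive bounds robust to coordinate rounding.
    """
    lo = (1 - tolerance) * equilibrium - 1e-9
    hi = (1 + tolerance) * equilibrium + 1e-9
    return lo <= geometry.d <= hi


def _measure_bond(
    model: StructureModel,
    end1: tuple[str, int, str],
    end2: tuple[str, int, str],
) -> CystineGeometry:
    res1 = model.residue(*end1)
    res2 = model.residue(*end2)
    geom = measure_cystine(res1, res2)
    b_avg, missing = b_factor_average(res1, res2)
    geom.b_avg = b_avg
    geom.b_missing_atoms = missing
    s1 = ss_state(end1[0], end1[1], end1[2], model.helices, model.sheets)
    s2 = ss_state(end2[0], end2[1], end2[2], model.helices, model.sheets)
    geom.ss_pair = ss_pair_label(s1, s2)
    return classify_geometry(geom)


def _geometric_ssbond_candidates(
    model: StructureModel, cutoff: float = 2.5
) -> list[tuple[tuple[str, int, str], tuple[str, int, str]]]:
    """SG-SG pairs closer than ``cutoff`` Å, for the optional geometric mode."""
    sgs = []
    for chain in model.chains.values():
        for res in chain.ordered():
            if res.name == "CYS":
                sg = res.coords("SG")
                if sg is not None:
                    sgs.append((res.key, sg))
    pairs = []
    for a in range(len(sgs)):
        for b in range(a + 1, len(sgs)):
            if np.linalg.norm(sgs[a][1] - sgs[b][1]) < cutoff:
                pairs.append((sgs[a][0], sgs[b][0]))
    return pairs


def harvest_bonds(
    model: StructureModel,
    mappings: dict[str, ChainMapping],
    equilibrium: float = EQUILIBRIUM_SS_LENGTH,
    tolerance: float = LENGTH_TOLERANCE,
    geometric_mode: bool = False,
    logs: Optional[list[str]] = None,
) -> list[BondObservation]:
    """Present-bond observations from the SSBOND records of one structure.

    Only bonds whose two endpoints map to canonical positions of the *same*
    accession are returned; inter-protein bonds and dangling SSBONDs are
    logged and skipped.  Duplicate SSBOND lines collapse to one observation.
    With ``geometric_mode``, SG-SG pairs under 2.5 Å lacking an SSBOND line
    are added as well.
    """
    logs = logs if logs is not None else []
    endpoint_pairs = []
    for ss in model.ssbonds:
        if ss.dangling:
            logs.append(f"{model.pdb_id}: dangling SSBOND {ss.endpoints()} skipped")
            continue
        endpoint_pairs.append(ss.endpoints())
    if geometric_mode:
        declared = {frozenset(p) for p in endpoint_pairs}
        for pair in _geometric_ssbond_candidates(model):
            if frozenset(pair) not in declared:
                endpoint_pairs.append(pair)

    observations: list[BondObservation] = []
    seen: set[tuple] = set()
    for end1, end2 in endpoint_pairs:
        m1 = mappings.get(end1[0])
        m2 = mappings.get(end2[0])
        if m1 is None or m2 is None:
            logs.append(f"{model.pdb_id}: SSBOND endpoint in unmapped chain, skipped")
            continue
        p1 = m1.canonical_position(end1[1], end1[2])
        p2 = m2.canonical_position(end2[1], end2[2])
        if p1 is None or p2 is None:
            logs.append(f"{model.pdb_id}: SSBOND endpoint outside alignment, skipped")
            continue
        if m1.accession != m2.accession:
            logs.append(
                f"{model.pdb_id}: inter-protein bond {m1.accession}:{p1} - {m2.accession}:{p2}"
            )
            continue
        if p1 > p2:
            end1, end2 = end2, end1
            p1, p2 = p2, p1
        chain_label = end1[0] if end1[0] == end2[0] else f"{end1[0]}-{end2[0]}"
        dedup = (m1.accession, p1, p2, chain_label)
        if dedup in seen:
            continue
        seen.add(dedup)
        try:
            geom = _measure_bond(model, end1, end2)
        except GeometryError as exc:
            logs.append(f"{model.pdb_id}: cannot measure bond {dedup}: {exc}")
            continue
        status = "present" if length_filter(geom, equilibrium, tolerance) else "present_filtered_length"
        observations.append(
            BondObservation(
                accession=m1.accession, pos_i=p1, pos_j=p2,
                pdb_id=model.pdb_id, chain=chain_label, status=status,
                resolution=model.resolution, geometry=geom,
            )
        )
    return observations


def assess_absence(
    model: StructureModel,
    mapping: ChainMapping,
    pair: tuple[int, int],
) -> str:
    """Status of a bond absent from one chain: is the absence valid evidence?

    Returns ``missing`` only when both cysteines are present, un-mutated and
    have resolved SG atoms — i.e. the bond genuinely could have formed but
    did not.  Otherwise the absence is explained away as ``excluded_truncated``
    (position outside the construct), ``excluded_mutated`` (aligned residue is
    not cysteine) or ``excluded_unresolved`` (cysteine present but without SG
    coordinates, or an interior gap in the model).
    """
    inv = mapping.inverse
    lo, hi = mapping.mapped_span
    statuses = []
    for pos in pair:
        if pos not in inv:
            if pos < lo or pos > hi:
                statuses.append("excluded_truncated")
            else:
                statuses.append("excluded_unresolved")
            continue
        resnum, icode = inv[pos]
        residue = model.residue(mapping.chain_id, resnum, icode)
        if residue is None:
            statuses.append("excluded_unresolved")
        elif residue.name != "CYS":
            statuses.append("excluded_mutated")
        elif residue.coords("SG") is None:
            statuses.append("excluded_unresolved")
        else:
            statuses.append("ok")
    for status in ("excluded_truncated", "excluded_mutated", "excluded_unresolved"):
        if status in statuses:
            return status
    return "missing"


def aggregate(
    observations: Sequence[BondObservation],
    culled_chains: Optional[set[tuple[str, str]]] = None,
) -> list[UniqueBond]:
    """Collapse observations into one entry per unique (accession, pair) bond.

    ``labile`` requires at least one present-type and one valid-missing
    observation.  The representative geometry comes from the present
    observation of best (lowest) resolution, ties broken by (pdb_id, chain);
    observations failing the length filter are used only if nothing passed
    it.  When a pre-culled chain list is supplied, membership of the
    reference cohort is restricted to bonds with a present observation on a
    culled chain.
    """
    grouped: dict[tuple[str, int, int], list[BondObservation]] = {}
    for obs in observations:
        grouped.setdefault(obs.key, []).append(obs)

    bonds = []
    for (acc, i, j), group in sorted(grouped.items()):
        present = [o for o in group if o.status in PRESENT_STATUSES]
        missing = [o for o in group if o.status == "missing"]
        labile = bool(present) and bool(missing)

        def rank(o: BondObservation) -> tuple:
            return (
                0 if o.status == "present" else 1,
                o.resolution if o.resolution is not None else math.inf,
                o.pdb_id,
                o.chain,
            )

        representative = min(present, key=rank) if present else None
        present_files = {o.pdb_id for o in present}
        missing_files = {o.pdb_id for o in missing}
        in_reference = True
        if culled_chains is not None:
            culled = {(p.lower(), c) for p, c in culled_chains}
            in_reference = any((o.pdb_id.lower(), o.chain) in culled for o in present)
        bonds.append(
            UniqueBond(
                accession=acc, pos_i=i, pos_j=j,
                observations=sorted(group, key=lambda o: (o.pdb_id, o.chain)),
                labile=labile, representative=representative,
                same_file_lability=bool(present_files & missing_files),
                in_reference=in_reference,
            )
        )
    return bonds


def scan_corpus(
    models: Iterable[StructureModel],
    chain_index: dict[tuple[str, str], str],
    sequences: dict[str, str],
    residue_table=None,
    resolution_cutoff: float = RESOLUTION_CUTOFF,
    reducing_agents: frozenset[str] = DEFAULT_REDUCING_AGENTS,
    equilibrium: float = EQUILIBRIUM_SS_LENGTH,
    tolerance: float = LENGTH_TOLERANCE,
    geometric_mode: bool = False,
    culled_chains: Optional[set[tuple[str, str]]] = None,
) -> ScanResult:
    """Run the full mining pipeline over parsed structures.

    Two passes: harvest present bonds (building the per-accession bond
    universe), then assess every mapped chain that lacks one of its
    accession's known bonds.  Deterministic for fixed inputs: all outputs are
    sorted by (accession, pos_i, pos_j, pdb_id, chain).
    """
    logs: list[str] = []
    verdicts: list[StructureVerdict] = []
    included: list[tuple[StructureModel, dict[str, ChainMapping]]] = []

    for model in models:
        verdict = screen_structure(model, resolution_cutoff, reducing_agents)
        mappings: dict[str, ChainMapping] = {}
        for chain_id in sorted(model.chains):
            accession = lookup_accession(chain_index, model.pdb_id, chain_id)
            if accession == UNMAPPED:
                continue
            canonical = sequences.get(accession)
            if canonical is None:
                logs.append(f"{model.pdb_id}/{chain_id}: no canonical sequence for {accession}")
                continue
            try:
                mappings[chain_id] = chain_mapping_for(
                    model, chain_id, accession, canonical, residue_table
                )
            except Exception as exc:  # implausible alignment etc.
                logs.append(f"{model.pdb_id}/{chain_id}: mapping failed: {exc}")
        if not mappings:
            verdict.reasons.append("unmapped")
        verdicts.append(verdict)
        if verdict.included:
            included.append((model, mappings))

    observations: list[BondObservation] = []
    universe: dict[str, set[tuple[int, int]]] = {}
    for model, mappings in included:
        present = harvest_bonds(
            model, mappings, equilibrium, tolerance, geometric_mode, logs
        )
        observations.extend(present)
        for obs in present:
            universe.setdefault(obs.accession, set()).add((obs.pos_i, obs.pos_j))

    have_present = {(o.pdb_id, o.chain.split("-")[0], o.key) for o in observations}
    have_present |= {(o.pdb_id, o.chain.split("-")[-1], o.key) for o in observations}
    for model, mappings in included:
        for chain_id in sorted(mappings):
            mapping = mappings[chain_id]
            for pair in sorted(universe.get(mapping.accession, ())):
                key = (mapping.accession, pair[0], pair[1])
                if (model.pdb_id, chain_id, key) in have_present:
                    continue
                status = assess_absence(model, mapping, pair)
                observations.append(
                    BondObservation(
                        accession=mapping.accession, pos_i=pair[0], pos_j=pair[1],
                        pdb_id=model.pdb_id, chain=chain_id, status=status,
                        resolution=model.resolution,
                    )
                )

    observations.sort(key=lambda o: (o.accession, o.pos_i, o.pos_j, o.pdb_id, o.chain))
    bonds = aggregate(observations, culled_chains)
    verdicts.sort(key=lambda v: v.pdb_id)
    return ScanResult(verdicts=verdicts, observations=observations, bonds=bonds, logs=logs)
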
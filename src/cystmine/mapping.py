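"""Mapping structure chains and author residue numbers to canonical sequence positions.

A disulfide seen in many crystal forms of the same protein must be counted
once, which requires translating each chain's author residue numbering to
1-based positions in the protein's canonical sequence.  Instead of a live
residue-mapping web service, the pipeline takes a local chain table
(pdb_id, chain_id, accession), canonical sequences in FASTA, and derives the
per-residue map by global alignment of the observed ATOM-record sequence to
the canonical sequence.  A pre-computed per-residue table (SIFTS-like TSV)
can be supplied to bypass alignment entirely.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, TextIO, Union

from Bio import Align, SeqIO
from Bio.SeqUtils import seq1

from .pdbfile import Chain, StructureModel

__all__ = [
    "ChainMapping",
    "MappingError",
    "UNMAPPED",
    "load_chain_table",
    "load_fasta",
    "load_residue_table",
    "align_chain",
    "chain_mapping_for",
    "observed_sequence",
]


class MappingError(ValueError):
    """Raised for malformed mapping inputs or implausible alignments."""


#: sentinel returned by chain-table lookups for chains absent from the table
UNMAPPED = "unmapped"

# Alignment scoring for observed-vs-canonical residue mapping.
MATCH_SCORE = 1.0
MISMATCH_SCORE = -1.0
GAP_OPEN = -5.0
GAP_EXTEND = -1.0

MIN_IDENTITY = 0.30


@dataclass
class ChainMapping:
    """Residue-level map of one structure chain onto its canonical sequence."""

    pdb_id: str
    chain_id: str
    accession: str
    #: author (resnum, icode) → canonical 1-based position
    residue_map: dict[tuple[int, str], int] = field(default_factory=dict)
    coverage: float = 0.0
    #: (canonical position, canonical aa, observed aa)
    mismatches: list[tuple[int, str, str]] = field(default_factory=list)
    canonical_length: int = 0

    def __post_init__(self) -> None:
        positions = list(self.residue_map.values())
        if len(set(positions)) != len(positions):
            raise MappingError("residue_map is not injective")

    @property
    def inverse(self) -> dict[int, tuple[int, str]]:
        return {pos: author for author, pos in self.residue_map.items()}

    def canonical_position(self, resnum: int, icode: str = " ") -> Optional[int]:
        return self.residue_map.get((resnum, icode))

    @property
    def mapped_span(self) -> tuple[int, int]:
        """(min, max) canonical position covered by the construct, or (0, 0)."""
        if not self.residue_map:
            return (0, 0)
        positions = self.residue_map.values()
        return (min(positions), max(positions))


def _open_text(source: Union[str, Path, TextIO]) -> TextIO:
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    return open(source, "rt", encoding="utf-8")


def load_chain_table(source: Union[str, Path, TextIO]) -> dict[tuple[str, str], str]:
    """Read a TSV with columns pdb_id, chain_id, accession into a lookup index.

    Duplicate (pdb_id, chain_id) rows are tolerated when they agree and are a
    :class:`MappingError` (listing the conflicting pairs) when they do not.
    Use :func:`lookup_accession` to query; absent chains read as ``UNMAPPED``.
    """
    handle = _open_text(source)
    reader = csv.DictReader(handle, delimiter="\t")
    required = {"pdb_id", "chain_id", "accession"}
    if reader.fieldnames is None or not required.issubset(reader.fieldnames):
        missing = required - set(reader.fieldnames or [])
        raise MappingError(f"chain table is missing column(s): {sorted(missing)}")
    index: dict[tuple[str, str], str] = {}
    conflicts: list[str] = []
    for row in reader:
        key = (row["pdb_id"].strip().lower(), row["chain_id"].strip())
        acc = row["accession"].strip()
        if key in index and index[key] != acc:
            conflicts.append(f"{key[0]}/{key[1]}: {index[key]} vs {acc}")
        index[key] = acc
    if conflicts:
        raise MappingError("conflicting accessions for chain(s): " + "; ".join(conflicts))
    return index


def lookup_accession(index: dict[tuple[str, str], str], pdb_id: str, chain_id: str) -> str:
    return index.get((pdb_id.lower(), chain_id), UNMAPPED)


def load_fasta(source: Union[str, Path, TextIO]) -> dict[str, str]:
    """Canonical sequences keyed by accession (first token of the header)."""
    handle = _open_text(source)
    return {rec.id.split("|")[0]: str(rec.seq) for rec in SeqIO.parse(handle, "fasta")}


def load_residue_table(source: Union[str, Path, TextIO]) -> dict[tuple[str, str], dict[tuple[int, str], int]]:
    """Optional SIFTS-like per-residue TSV bypassing alignment.

    Columns: pdb_id, chain_id, author_resnum, icode, accession, canonical_pos.
    Returns {(pdb_id, chain_id): {(resnum, icode): canonical_pos}}.
    """
    handle = _open_text(source)
    reader = csv.DictReader(handle, delimiter="\t")
    required = {"pdb_id", "chain_id", "author_resnum", "icode", "accession", "canonical_pos"}
    if reader.fieldnames is None or not required.issubset(reader.fieldnames):
        missing = required - set(reader.fieldnames or [])
        raise MappingError(f"residue table is missing column(s): {sorted(missing)}")
    table: dict[tuple[str, str], dict[tuple[int, str], int]] = {}
    for row in reader:
        key = (row["pdb_id"].strip().lower(), row["chain_id"].strip())
        icode = row["icode"].strip() or " "
        table.setdefault(key, {})[(int(row["author_resnum"]), icode)] = int(row["canonical_pos"])
    return table


def observed_sequence(chain: Chain) -> list[tuple[tuple[int, str], str]]:
    """One-letter observed sequence from ATOM-record residues, in author order.

    Heteroatom-only residues (ligands, waters) are skipped; unknown residue
    codes read as 'X'.  Using ATOM records (not SEQRES) means unresolved
    residues are naturally "not observed", which the truncation check relies
    on.
    """
    out = []
    for res in chain.ordered():
        if all(a.is_het for a in res.atoms):
            continue
        aa = seq1(res.name.capitalize())
        out.append(((res.number, res.insertion_code), aa if aa and aa != "*" else "X"))
    return out


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    # terminal gaps are free: constructs are routinely truncated
    aligner.end_gap_score = 0.0
    return aligner


def align_chain(
    observed: Sequence[tuple[tuple[int, str], str]],
    canonical: str,
    pdb_id: str = "",
    chain_id: str = "",
    accession: str = "",
) -> ChainMapping:
    """Globally align an observed chain to its canonical sequence.

    ``observed`` is the output of :func:`observed_sequence`.  Aligned pairs
    populate ``residue_map``; aligned-but-different residues are recorded as
    mismatches (candidate construct mutations); coverage is the fraction of
    canonical positions observed.  Raises :class:`MappingError` when identity
    over aligned columns falls below 30% (implausible mapping).
    """
    if not observed:
        raise MappingError("implausible mapping: empty observed sequence")
    if not canonical:
        raise MappingError("implausible mapping: empty canonical sequence")
    obs_seq = "".join(aa for _, aa in observed)

    alignment = _aligner().align(canonical, obs_seq)[0]
    mapping = ChainMapping(
        pdb_id=pdb_id, chain_id=chain_id, accession=accession,
        canonical_length=len(canonical),
    )
    matches = 0
    aligned_cols = 0
    for (t0, t1), (q0, q1) in zip(*alignment.aligned):
        for offset in range(t1 - t0):
            canon_pos = t0 + offset + 1  # 1-based
            author, obs_aa = observed[q0 + offset]
            mapping.residue_map[author] = canon_pos
            aligned_cols += 1
            if obs_aa == canonical[canon_pos - 1]:
                matches += 1
            else:
                mapping.mismatches.append((canon_pos, canonical[canon_pos - 1], obs_aa))
    if aligned_cols == 0 or matches / aligned_cols < MIN_IDENTITY:
        raise MappingError(
            f"implausible mapping for {pdb_id}/{chain_id}: "
            f"identity {matches}/{aligned_cols} below {MIN_IDENTITY:.0%}"
        )
    mapping.coverage = aligned_cols / len(canonical)
    return mapping


def chain_mapping_for(
    model: StructureModel,
    chain_id: str,
    accession: str,
    canonical: str,
    residue_table: Optional[dict[tuple[str, str], dict[tuple[int, str], int]]] = None,
) -> ChainMapping:
    """Build the residue-level mapping for one chain of a parsed structure."""
    key = (model.pdb_id.lower(), chain_id)
    if residue_table is not None and key in residue_table:
        mapping = ChainMapping(
            pdb_id=model.pdb_id, chain_id=chain_id, accession=accession,
            residue_map=dict(residue_table[key]), canonical_length=len(canonical),
        )
        mapping.coverage = len(mapping.residue_map) / len(canonical) if canonical else 0.0
        return mapping
    chain = model.chains.get(chain_id)
    if chain is None:
        raise MappingError(f"chain {chain_id!r} not present in {model.pdb_id}")
    return align_chain(
        observed_sequence(chain), canonical,
        pdb_id=model.pdb_id, chain_id=chain_id, accession=accession,
    )
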
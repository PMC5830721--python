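"""Reading and writing the legacy PDB text format (the subset the pipeline needs).

Only fixed-column PDB v3.3 records are handled: ATOM/HETATM, SSBOND, HELIX,
SHEET, SEQRES, ``REMARK   2 RESOLUTION`` and HEADER.  Disulfide mining relies
on the *header* metadata of crystal structures (SSBOND lines declare bonds,
REMARK 2 carries the resolution, HELIX/SHEET give the secondary-structure
context), which is exactly what legacy PDB files expose and mmCIF tooling
tends to normalise away; mmCIF is deliberately out of scope.

Parsing is total: arbitrary text never raises except for the two contract
errors (empty input, no coordinates); malformed records are skipped and
counted in a :class:`ParseReport`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, TextIO, Union

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "SSBondRecord",
    "SecStructRecord",
    "ParseReport",
    "StructureModel",
    "PDBFormatError",
    "parse_pdb",
    "write_pdb",
]

WATER_CODES = {"HOH", "DOD", "WAT"}


class PDBFormatError(ValueError):
    """Raised for inputs that violate the parsing/writing contract."""


@dataclass
class Atom:
    """One ATOM/HETATM record after altLoc resolution."""

    name: str
    element: str
    residue_name: str
    chain_id: str
    residue_number: int
    insertion_code: str = " "
    x: float = 0.0
    y: float = 0.0
    z: float = 0.0
    b_factor: float = 0.0
    occupancy: float = 1.0
    is_het: bool = False
    altloc: str = " "
    serial: int = 0

    @property
    def coords(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class Residue:
    chain_id: str
    number: int
    insertion_code: str
    name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.insertion_code)

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self, name: str) -> Optional[np.ndarray]:
        a = self.atom(name)
        return None if a is None else a.coords


@dataclass
class Chain:
    chain_id: str
    residues: dict[tuple[int, str], Residue] = field(default_factory=dict)

    def get(self, number: int, icode: str = " ") -> Optional[Residue]:
        return self.residues.get((number, icode))

    def ordered(self) -> list[Residue]:
        return [self.residues[k] for k in sorted(self.residues, key=lambda k: (k[0], k[1]))]


@dataclass
class SSBondRecord:
    """An SSBOND header line; endpoints are author residue identifiers."""

    chain1: str
    resnum1: int
    icode1: str
    chain2: str
    resnum2: int
    icode2: str
    declared_length: Optional[float] = None
    dangling: bool = False

    def endpoints(self) -> tuple[tuple[str, int, str], tuple[str, int, str]]:
        return (self.chain1, self.resnum1, self.icode1), (self.chain2, self.resnum2, self.icode2)


@dataclass
class SecStructRecord:
    """A HELIX or SHEET residue range (one strand per SHEET record)."""

    kind: str  # "helix" | "sheet"
    chain_id: str
    start: tuple[int, str]
    end: tuple[int, str]

    def contains(self, chain_id: str, number: int, icode: str = " ") -> bool:
        if chain_id != self.chain_id:
            return False
        lo = (self.start[0], self.start[1])
        hi = (self.end[0], self.end[1])
        return lo <= (number, icode) <= hi


@dataclass
class ParseReport:
    skipped: dict[str, int] = field(default_factory=dict)
    messages: list[str] = field(default_factory=list)

    def skip(self, record: str, message: str = "") -> None:
        self.skipped[record] = self.skipped.get(record, 0) + 1
        if message:
            self.messages.append(message)

    @property
    def n_skipped(self) -> int:
        return sum(self.skipped.values())


@dataclass
class StructureModel:
    """A parsed structure: coordinates plus the header metadata mining needs."""

    pdb_id: str = "XXXX"
    chains: dict[str, Chain] = field(default_factory=dict)
    resolution: Optional[float] = None
    ssbonds: list[SSBondRecord] = field(default_factory=list)
    helices: list[SecStructRecord] = field(default_factory=list)
    sheets: list[SecStructRecord] = field(default_factory=list)
    het_codes: set[str] = field(default_factory=set)
    seqres: dict[str, list[str]] = field(default_factory=dict)
    report: ParseReport = field(default_factory=ParseReport)

    def residue(self, chain_id: str, number: int, icode: str = " ") -> Optional[Residue]:
        chain = self.chains.get(chain_id)
        return None if chain is None else chain.get(number, icode)

    def atoms(self) -> Iterable[Atom]:
        for chain in self.chains.values():
            for res in chain.ordered():
                yield from res.atoms

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.atoms())


def _float(s: str) -> Optional[float]:
    try:
        v = float(s)
    except ValueError:
        return None
    return v if math.isfinite(v) else None


def _int(s: str) -> Optional[int]:
    try:
        return int(s)
    except ValueError:
        return None


def _parse_coord_line(line: str, report: ParseReport) -> Optional[Atom]:
    rec = line[:6]
    is_het = rec.startswith("HETATM")
    name = line[12:16].strip()
    altloc = line[16:17] or " "
    res_name = line[17:20].strip()
    chain_id = line[21:22] or " "
    res_num = _int(line[22:26].strip() or "")
    icode = line[26:27] or " "
    if icode == "":
        icode = " "
    x = _float(line[30:38].strip())
    y = _float(line[38:46].strip())
    z = _float(line[46:54].strip())
    occ = _float(line[54:60].strip()) if line[54:60].strip() else 1.0
    b = _float(line[60:66].strip()) if line[60:66].strip() else 0.0
    element = line[76:78].strip()
    serial = _int(line[6:11].strip() or "") or 0
    if not name or not res_name or res_num is None or x is None or y is None or z is None:
        report.skip(rec.strip(), f"unparseable coordinate record: {line.rstrip()!r}")
        return None
    if occ is None:
        occ = 1.0
    if b is None or b < 0:
        b = 0.0
    occ = min(max(occ, 0.0), 1.0)
    if not element:
        element = name[:1]
    return Atom(
        name=name,
        element=element,
        residue_name=res_name,
        chain_id=chain_id,
        residue_number=res_num,
        insertion_code=icode,
        x=x,
        y=y,
        z=z,
        b_factor=b,
        occupancy=occ,
        is_het=is_het,
        altloc=altloc,
        serial=serial,
    )


def _resolve_altlocs(atoms: list[Atom], report: ParseReport) -> list[Atom]:
    # Keep the highest-occupancy alternate location per atom site; ties go to
    # the alphabetically first altLoc.  Blank altLoc atoms are untouched.
    groups: dict[tuple, list[Atom]] = {}
    order: list[tuple] = []
    for a in atoms:
        key = (a.chain_id, a.residue_number, a.insertion_code, a.residue_name, a.name)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(a)
    out: list[Atom] = []
    for key in order:
        group = groups[key]
        if len(group) == 1:
            out.append(group[0])
            continue
        chosen = sorted(group, key=lambda a: (-a.occupancy, a.altloc))[0]
        report.skip("altloc", f"kept altLoc {chosen.altloc!r} of {len(group)} for {key}")
        out.append(chosen)
    return out


def parse_pdb(source: Union[str, TextIO]) -> StructureModel:
    """Parse legacy PDB text into a :class:`StructureModel`.

    Raises :class:`PDBFormatError` on empty input or input with no usable
    ATOM/HETATM coordinates; every other malformation is skipped and counted
    in ``model.report``.  Only the first NMR/multi-MODEL block is read.
    """
    text = source.read() if hasattr(source, "read") else source
    if not text or not text.strip():
        raise PDBFormatError("empty input")

    model = StructureModel()
    report = model.report
    raw_atoms: list[Atom] = []
    past_first_model = False  # true once the first MODEL block has ended

    for line in text.splitlines():
        rec = line[:6]
        if rec == "ENDMDL":
            past_first_model = True
            continue
        if rec in ("ATOM  ", "HETATM"):
            if past_first_model:
                continue
            atom = _parse_coord_line(line, report)
            if atom is not None:
                raw_atoms.append(atom)
            continue
        if rec == "HEADER":
            code = line[62:66].strip()
            if len(code) == 4:
                model.pdb_id = code
            continue
        if line.startswith("REMARK   2 RESOLUTION."):
            tail = line[22:].strip()
            res = _float(tail.split()[0]) if tail and tail.split() else None
            if res is not None and res > 0:
                model.resolution = res
            # "NOT APPLICABLE" and friends leave resolution unknown
            continue
        if rec == "SSBOND":
            ss = _parse_ssbond(line, report)
            if ss is not None:
                model.ssbonds.append(ss)
            continue
        if rec == "HELIX ":
            h = _parse_helix(line, report)
            if h is not None:
                model.helices.append(h)
            continue
        if rec == "SHEET ":
            s = _parse_sheet(line, report)
            if s is not None:
                model.sheets.append(s)
            continue
        if rec == "SEQRES":
            chain_id = line[11:12] or " "
            names = line[19:70].split()
            model.seqres.setdefault(chain_id, []).extend(names)
            continue

    if not raw_atoms:
        raise PDBFormatError("no coordinates")

    atoms = _resolve_altlocs(raw_atoms, report)
    for a in atoms:
        chain = model.chains.setdefault(a.chain_id, Chain(a.chain_id))
        res = chain.residues.get((a.residue_number, a.insertion_code))
        if res is None:
            res = Residue(a.chain_id, a.residue_number, a.insertion_code, a.residue_name)
            chain.residues[(a.residue_number, a.insertion_code)] = res
        res.atoms.append(a)
        if a.is_het and a.residue_name not in WATER_CODES:
            model.het_codes.add(a.residue_name)

    for ss in model.ssbonds:
        (c1, n1, i1), (c2, n2, i2) = ss.endpoints()
        ss.dangling = model.residue(c1, n1, i1) is None or model.residue(c2, n2, i2) is None
    return model


def _parse_ssbond(line: str, report: ParseReport) -> Optional[SSBondRecord]:
    chain1 = line[15:16] or " "
    num1 = _int(line[17:21].strip() or "")
    icode1 = (line[21:22] or " ") if line[21:22].strip() else " "
    chain2 = line[29:30] or " "
    num2 = _int(line[31:35].strip() or "")
    icode2 = (line[35:36] or " ") if line[35:36].strip() else " "
    if num1 is None or num2 is None:
        report.skip("SSBOND", f"unparseable SSBOND: {line.rstrip()!r}")
        return None
    length = _float(line[73:78].strip()) if line[73:78].strip() else None
    return SSBondRecord(chain1, num1, icode1, chain2, num2, icode2, declared_length=length)


def _parse_helix(line: str, report: ParseReport) -> Optional[SecStructRecord]:
    chain = line[19:20] or " "
    start = _int(line[21:25].strip() or "")
    icode1 = line[25:26].strip() or " "
    end = _int(line[33:37].strip() or "")
    icode2 = line[37:38].strip() or " "
    if start is None or end is None:
        report.skip("HELIX", f"unparseable HELIX: {line.rstrip()!r}")
        return None
    return SecStructRecord("helix", chain, (start, icode1), (end, icode2))


def _parse_sheet(line: str, report: ParseReport) -> Optional[SecStructRecord]:
    chain = line[21:22] or " "
    start = _int(line[22:26].strip() or "")
    icode1 = line[26:27].strip() or " "
    end = _int(line[33:37].strip() or "")
    icode2 = line[37:38].strip() or " "
    if start is None or end is None:
        report.skip("SHEET", f"unparseable SHEET: {line.rstrip()!r}")
        return None
    return SecStructRecord("sheet", chain, (start, icode1), (end, icode2))


def _format_atom_name(name: str, element: str) -> str:
    # Standard PDB convention: 1/2-letter element right-justified in cols 13-14.
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2:
        return f"{name:<4s}"[:4]
    return f" {name:<3s}"


def write_pdb(model: StructureModel) -> str:
    """Serialise a model back to legacy PDB text.

    Coordinates keep 3 decimals and B factors/occupancies 2 (PDB column
    precision); ``parse_pdb(write_pdb(m))`` is field-equal to ``m`` up to that
    precision.
    """
    for chain_id in model.chains:
        if len(chain_id) != 1:
            raise PDBFormatError(f"chain id must be a single character: {chain_id!r}")

    lines: list[str] = []
    lines.append(f"HEADER    SYNTHETIC STRUCTURE                     01-JAN-18   {model.pdb_id:<4s}")
    if model.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION. {model.resolution:7.2f} ANGSTROMS.")
    else:
        lines.append("REMARK   2 RESOLUTION. NOT APPLICABLE.")

    for chain_id in sorted(model.seqres):
        names = model.seqres[chain_id]
        for i in range(0, len(names), 13):
            chunk = names[i : i + 13]
            body = " ".join(f"{n:>3s}" for n in chunk)
            lines.append(f"SEQRES {i // 13 + 1:>3d} {chain_id} {len(names):>4d}  {body}")

    for i, h in enumerate(model.helices, start=1):
        lines.append(
            f"HELIX  {i:>3d} {i:>3d} ALA {h.chain_id} {h.start[0]:>4d}{h.start[1]} "
            f"ALA {h.chain_id} {h.end[0]:>4d}{h.end[1]} 1                               "
        )
    for i, s in enumerate(model.sheets, start=1):
        lines.append(
            f"SHEET  {i:>3d}   A 1 ALA {s.chain_id}{s.start[0]:>4d}{s.start[1]} "
            f"ALA {s.chain_id}{s.end[0]:>4d}{s.end[1]} 0"
        )
    for i, ss in enumerate(model.ssbonds, start=1):
        length = ss.declared_length if ss.declared_length is not None else 2.04
        lines.append(
            f"SSBOND {i:>3d} CYS {ss.chain1} {ss.resnum1:>4d}{ss.icode1}   "
            f"CYS {ss.chain2} {ss.resnum2:>4d}{ss.icode2}"
            f"{'':23s}1555   1555 {length:5.2f}"
        )

    serial = 0
    for chain_id in sorted(model.chains):
        chain = model.chains[chain_id]
        for res in chain.ordered():
            for a in res.atoms:
                serial += 1
                rec = "HETATM" if a.is_het else "ATOM  "
                icode = a.insertion_code if a.insertion_code.strip() else " "
                lines.append(
                    f"{rec}{serial:>5d} {_format_atom_name(a.name, a.element)} "
                    f"{a.residue_name:>3s} {a.chain_id}{a.residue_number:>4d}{icode}   "
                    f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{a.occupancy:6.2f}{a.b_factor:6.2f}"
                    f"          {a.element:>2s}"
                )
        lines.append(f"TER   {serial + 1:>5d}      {chain_id}")
    lines.append("END")
    return "\n".join(lines) + "\n"
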
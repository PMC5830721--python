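"""Synthetic ground-truth fixtures: cystines built from internal coordinates
and multi-structure ensembles with planted labile bonds.

The generator inverts the mining pipeline: cystine coordinates are laid down
by sequential internal-coordinate (NeRF) construction so every χ torsion,
α angle and the S–S distance hit prescribed targets exactly, and whole
ensembles of structures are emitted in which each planted bond is, per
structure, present, reduced (validly absent), or absent for one of the
decoy reasons (truncated construct, mutated cysteine, unresolved sulfur).
Alongside the PDB files the generator writes the chain table, canonical
FASTA and a truth table derived purely from the planted states, which the
miner must reproduce exactly.

Everything is deterministic given a seed: identical seeds yield
byte-identical fixture directories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .geometry import GeometryError, dse, measure_cystine
from .configuration import classify, sign_vector
from .pdbfile import Atom, Chain, Residue, SecStructRecord, SSBondRecord, StructureModel, write_pdb

__all__ = [
    "CystineSpec",
    "BondState",
    "StructureSpec",
    "EnsembleSpec",
    "build_cystine",
    "random_cystine_specs",
    "generate_structure",
    "generate_ensemble",
    "generate_corpus",
    "corpus_spec_from_yaml",
    "ensemble_truth",
    "generate_effect_cohort",
]

# Standard cysteine stereochemistry (lengths in Å, angles in degrees).
BOND_N_CA = 1.458
BOND_CA_CB = 1.530
BOND_CB_SG = 1.810
BOND_SS = 2.038
ANGLE_N_CA_CB = 110.5
ANGLE_CA_CB_SG = 114.0
ANGLE_CB_SS = 104.0
BOND_CA_C = 1.525
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_O = 120.5

AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


@dataclass
class CystineSpec:
    """Internal-coordinate targets for one disulfide-bonded cysteine pair."""

    chi1: float = -60.0
    chi2: float = -60.0
    chi3: float = -90.0
    chi2p: float = -60.0
    chi1p: float = -60.0
    d: float = BOND_SS
    alpha1: float = ANGLE_CB_SS
    alpha2: float = ANGLE_CB_SS
    b_factors: Union[float, Sequence[float]] = 20.0  # scalar or 12 per-atom values

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise GeometryError("S-S distance must be positive")
        for angle in (self.alpha1, self.alpha2):
            if not 0.0 < angle < 180.0:
                raise GeometryError("bending angles must lie strictly in (0, 180)")

    @property
    def chi(self) -> tuple[float, float, float, float, float]:
        return (self.chi1, self.chi2, self.chi3, self.chi2p, self.chi1p)


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           length: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF atom placement: position d with |cd| = length, angle(b,c,d) = angle
    and dihedral(a,b,c,d) = torsion."""
    theta = np.radians(angle)
    if not 0.0 < theta < np.pi:
        raise GeometryError("impossible geometry: bond angle of 0 or 180 degrees")
    phi = np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise GeometryError("impossible geometry: collinear reference atoms")
    n /= norm
    m = np.cross(n, bc)
    d_local = np.array(
        [-length * np.cos(theta),
         length * np.sin(theta) * np.cos(phi),
         length * np.sin(theta) * np.sin(phi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_cystine(
    spec: CystineSpec,
    chain_id: str = "A",
    resnum1: int = 1,
    resnum2: int = 2,
    origin: Sequence[float] = (0.0, 0.0, 0.0),
) -> tuple[Residue, Residue]:
    """Construct the 12 heavy atoms of a disulfide-bonded cysteine pair.

    Atoms are placed by sequential internal-coordinate construction so the
    measured χ vector, α angles and S–S distance reproduce the spec within
    1e−6.  Backbone C/O complete each residue at idealised geometry; only the
    internal coordinates of the N–CA–CB–SG–SG′–CB′–CA′–N′ chain are
    meaningful.
    """
    origin = np.asarray(origin, dtype=float)
    n1 = origin + np.array([0.0, 0.0, 0.0])
    ca1 = origin + np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.radians(ANGLE_N_CA_CB)
    cb1 = ca1 + BOND_CA_CB * np.array([-np.cos(ang), np.sin(ang), 0.0])

    sg1 = _place(n1, ca1, cb1, BOND_CB_SG, ANGLE_CA_CB_SG, spec.chi1)
    sg2 = _place(ca1, cb1, sg1, spec.d, spec.alpha1, spec.chi2)
    cb2 = _place(cb1, sg1, sg2, BOND_CB_SG, spec.alpha2, spec.chi3)
    ca2 = _place(sg1, sg2, cb2, BOND_CA_CB, ANGLE_CA_CB_SG, spec.chi2p)
    n2 = _place(sg2, cb2, ca2, BOND_N_CA, ANGLE_N_CA_CB, spec.chi1p)
    c1 = _place(cb1, n1, ca1, BOND_CA_C, ANGLE_N_CA_C, -120.0)
    o1 = _place(n1, ca1, c1, BOND_C_O, ANGLE_CA_C_O, 180.0)
    c2 = _place(cb2, n2, ca2, BOND_CA_C, ANGLE_N_CA_C, -120.0)
    o2 = _place(n2, ca2, c2, BOND_C_O, ANGLE_CA_C_O, 180.0)

    if np.isscalar(spec.b_factors):
        b = [float(spec.b_factors)] * 12
    else:
        b = [float(v) for v in spec.b_factors]
        if len(b) != 12:
            raise GeometryError("b_factors must be a scalar or 12 values")

    def residue(resnum: int, coords: dict[str, np.ndarray], b_slice: list[float]) -> Residue:
        res = Residue(chain_id, resnum, " ", "CYS")
        for (name, xyz), bf in zip(coords.items(), b_slice):
            element = "S" if name == "SG" else name[0]
            res.atoms.append(
                Atom(name=name, element=element, residue_name="CYS", chain_id=chain_id,
                     residue_number=resnum, x=float(xyz[0]), y=float(xyz[1]),
                     z=float(xyz[2]), b_factor=bf, occupancy=1.0)
            )
        return res

    res1 = residue(resnum1, {"N": n1, "CA": ca1, "C": c1, "O": o1, "CB": cb1, "SG": sg1}, b[:6])
    res2 = residue(resnum2, {"N": n2, "CA": ca2, "C": c2, "O": o2, "CB": cb2, "SG": sg2}, b[6:])
    return res1, res2


def random_cystine_specs(
    n: int,
    rng: np.random.Generator,
    boundary_margin: float = 5.0,
    d_range: tuple[float, float] = (1.90, 2.20),
) -> list[CystineSpec]:
    """Random χ-target specs, avoiding ±margin around the 0/180° sign
    boundaries so configuration assignments are unambiguous."""
    specs = []
    for _ in range(n):
        chis = []
        for _ in range(5):
            mag = rng.uniform(boundary_margin, 180.0 - boundary_margin)
            chis.append(float(mag if rng.random() < 0.5 else -mag))
        specs.append(
            CystineSpec(
                chi1=chis[0], chi2=chis[1], chi3=chis[2], chi2p=chis[3], chi1p=chis[4],
                d=float(rng.uniform(*d_range)),
                alpha1=float(rng.uniform(95.0, 115.0)),
                alpha2=float(rng.uniform(95.0, 115.0)),
                b_factors=float(rng.uniform(10.0, 60.0)),
            )
        )
    return specs


# ---------------------------------------------------------------------------
# ensemble generation


@dataclass
class BondState:
    """Per-structure state of one planted bond."""

    kind: str  # present | reduced | truncated | mutated | unresolved
    spec: CystineSpec = field(default_factory=CystineSpec)
    mutate_to: str = "TYR"

    KINDS = ("present", "reduced", "truncated", "mutated", "unresolved")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown bond state {self.kind!r}")


@dataclass
class StructureSpec:
    pdb_id: str
    resolution: Optional[float]
    bond_states: dict[tuple[int, int], BondState]
    het_codes: tuple[str, ...] = ()
    numbering_offset: int = 0
    in_chain_table: bool = True
    declare_ss: bool = False  # wrap bond ends in HELIX/SHEET header ranges


@dataclass
class EnsembleSpec:
    accession: str
    sequence: str
    structures: list[StructureSpec]

    def __post_init__(self) -> None:
        pairs = {p for s in self.structures for p in s.bond_states}
        for i, j in pairs:
            if not (1 <= i < j <= len(self.sequence)):
                raise ValueError(f"bond pair {(i, j)} outside sequence")
            if self.sequence[i - 1] != "C" or self.sequence[j - 1] != "C":
                raise ValueError(f"bond pair {(i, j)} must sit on cysteines")
        for s in self.structures:
            if set(s.bond_states) != pairs:
                raise ValueError(
                    f"{s.pdb_id}: every structure must state every bond of the ensemble"
                )


def generate_structure(ens: EnsembleSpec, spec: StructureSpec) -> StructureModel:
    """Build one structure of an ensemble as a parsed-model object."""
    model = StructureModel(pdb_id=spec.pdb_id, resolution=spec.resolution)
    chain = Chain("A")
    model.chains["A"] = chain
    offset = spec.numbering_offset

    omitted: set[int] = set()          # canonical positions absent from ATOM records
    strip_sg: set[int] = set()         # cysteines modelled without their SG
    mutations: dict[int, str] = {}     # canonical position -> 3-letter code
    cystine_residues: dict[int, Residue] = {}

    bond_index = 0
    for pair in sorted(spec.bond_states):
        state = spec.bond_states[pair]
        i, j = pair
        if state.kind == "present":
            res1, res2 = build_cystine(
                state.spec, chain_id="A", resnum1=i + offset, resnum2=j + offset,
                origin=(0.0, 40.0 + 30.0 * bond_index, 0.0),
            )
            cystine_residues[i] = res1
            cystine_residues[j] = res2
        elif state.kind == "truncated":
            omitted.update(range(1, i + 1))
        elif state.kind == "mutated":
            mutations[i] = state.mutate_to
        elif state.kind == "unresolved":
            strip_sg.add(i)
        bond_index += 1

    for pos, aa in enumerate(ens.sequence, start=1):
        if pos in omitted:
            continue
        if pos in cystine_residues:
            chain.residues[(pos + offset, " ")] = cystine_residues[pos]
            continue
        res_name = mutations.get(pos, AA3.get(aa, "GLY"))
        res = Residue("A", pos + offset, " ", res_name)
        x = 6.0 * pos
        base = [("N", (x, 0.0, -15.0)), ("CA", (x + 1.45, 0.0, -15.0)),
                ("C", (x + 2.0, 1.2, -15.0)), ("O", (x + 2.0, 2.4, -15.0))]
        if res_name != "GLY":
            base.append(("CB", (x + 1.8, -1.2, -15.0)))
        if res_name == "CYS" and pos not in strip_sg:
            base.append(("SG", (x + 2.4, -2.6, -15.0)))
        for name, xyz in base:
            element = "S" if name == "SG" else name[0]
            res.atoms.append(
                Atom(name=name, element=element, residue_name=res_name, chain_id="A",
                     residue_number=pos + offset, x=xyz[0], y=xyz[1], z=xyz[2],
                     b_factor=20.0, occupancy=1.0)
            )
        chain.residues[(pos + offset, " ")] = res

    seqres = []
    for pos, aa in enumerate(ens.sequence, start=1):
        if pos in omitted:
            continue
        seqres.append(mutations.get(pos, AA3.get(aa, "GLY")))
    model.seqres["A"] = seqres

    for pair in sorted(spec.bond_states):
        state = spec.bond_states[pair]
        if state.kind != "present":
            continue
        i, j = pair
        model.ssbonds.append(
            SSBondRecord("A", i + offset, " ", "A", j + offset, " ",
                         declared_length=round(state.spec.d, 2))
        )
        if spec.declare_ss:
            model.helices.append(
                SecStructRecord("helix", "A", (i + offset - 1, " "), (i + offset + 1, " "))
            )
            model.sheets.append(
                SecStructRecord("sheet", "A", (j + offset - 1, " "), (j + offset + 1, " "))
            )

    for k, code in enumerate(spec.het_codes):
        resnum = 900 + k
        for idx, name in enumerate(("S1", "C1", "C2", "O1")):
            model.het_codes.add(code)
            chain.residues.setdefault((resnum, " "), Residue("A", resnum, " ", code)).atoms.append(
                Atom(name=name, element=name[0], residue_name=code, chain_id="A",
                     residue_number=resnum, x=200.0 + idx, y=200.0, z=200.0 + 2 * k,
                     b_factor=30.0, occupancy=1.0, is_het=True)
            )
    return model


# ---------------------------------------------------------------------------
# truth tables (manual walk of the screening/absence rules — independent of
# the mining implementation)


def _structure_reasons(spec: StructureSpec, reducing_agents: frozenset) -> list[str]:
    reasons = []
    if spec.resolution is None:
        reasons.append("no_resolution")
    elif spec.resolution > 2.5:
        reasons.append("resolution_gt_2.5")
    if set(spec.het_codes) & reducing_agents:
        reasons.append("reducing_agent")
    if not spec.in_chain_table:
        reasons.append("unmapped")
    return reasons


_STATE_TO_STATUS = {
    "reduced": "missing",
    "truncated": "excluded_truncated",
    "mutated": "excluded_mutated",
    "unresolved": "excluded_unresolved",
}


def ensemble_truth(
    ensembles: Sequence[EnsembleSpec],
    reducing_agents: frozenset = frozenset({"DTT", "DTU", "DTV", "BME", "TCE"}),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Expected verdicts, observation statuses and labile flags, derived
    directly from the planted states."""
    verdict_rows = []
    obs_rows = []
    bond_rows = []
    for ens in ensembles:
        included = []
        for spec in ens.structures:
            reasons = _structure_reasons(spec, reducing_agents)
            verdict_rows.append(
                {"pdb_id": spec.pdb_id,
                 "status": "excluded" if reasons else "included",
                 "reasons": ",".join(reasons)}
            )
            if not reasons:
                included.append(spec)

        pairs = sorted({p for s in ens.structures for p in s.bond_states})
        for pair in pairs:
            discovered = any(s.bond_states[pair].kind == "present" for s in included)
            if not discovered:
                continue  # never seen bonded in an included structure: not in the universe
            n_present = 0
            n_missing = 0
            for spec in included:
                state = spec.bond_states[pair]
                if state.kind == "present":
                    lo = (1 - 0.10) * 2.038
                    hi = (1 + 0.10) * 2.038
                    status = "present" if lo <= state.spec.d <= hi else "present_filtered_length"
                    n_present += 1
                else:
                    status = _STATE_TO_STATUS[state.kind]
                    if status == "missing":
                        n_missing += 1
                obs_rows.append(
                    {"accession": ens.accession, "pos_i": pair[0], "pos_j": pair[1],
                     "pdb_id": spec.pdb_id, "chain": "A", "status": status}
                )
            bond_rows.append(
                {"accession": ens.accession, "pos_i": pair[0], "pos_j": pair[1],
                 "labile": bool(n_present and n_missing)}
            )
    verdicts = pd.DataFrame(verdict_rows, columns=["pdb_id", "status", "reasons"])
    observations = pd.DataFrame(
        obs_rows, columns=["accession", "pos_i", "pos_j", "pdb_id", "chain", "status"]
    )
    bonds = pd.DataFrame(bond_rows, columns=["accession", "pos_i", "pos_j", "labile"])
    verdicts = verdicts.sort_values("pdb_id", ignore_index=True)
    observations = observations.sort_values(
        ["accession", "pos_i", "pos_j", "pdb_id", "chain"], ignore_index=True
    )
    bonds = bonds.sort_values(["accession", "pos_i", "pos_j"], ignore_index=True)
    return verdicts, observations, bonds


# ---------------------------------------------------------------------------
# corpus generation


def _random_sequence(rng: np.random.Generator, length: int, cys_positions: Sequence[int]) -> str:
    alphabet = "ADEFGHIKLMNPQRSTVWY"  # no C: cysteines only where planted
    seq = [alphabet[int(k)] for k in rng.integers(0, len(alphabet), size=length)]
    for pos in cys_positions:
        seq[pos - 1] = "C"
    return "".join(seq)


def _random_spec(rng: np.random.Generator, chi3_low: bool = False) -> CystineSpec:
    """Rotamer-like χ targets: side-chain torsions near the ±60/180° wells,
    χ3 near its relaxed ±90° minimum (or biased toward 0 for strained bonds)."""
    chis = []
    for _ in range(4):
        well = float(rng.choice([-60.0, 60.0, 180.0]))
        val = well + float(rng.normal(0.0, 12.0))
        if val > 180.0:
            val -= 360.0
        chis.append(val)
    sign = 1.0 if rng.random() < 0.5 else -1.0
    if chi3_low:
        chi3 = sign * float(np.clip(rng.normal(25.0, 10.0), 5.0, 45.0))
    else:
        chi3 = sign * float(np.clip(rng.normal(90.0, 15.0), 10.0, 170.0))
    chis.insert(2, chi3)
    return CystineSpec(
        chi1=chis[0], chi2=chis[1], chi3=chis[2], chi2p=chis[3], chi1p=chis[4],
        d=float(rng.uniform(1.95, 2.15)),
        alpha1=float(rng.uniform(100.0, 110.0)),
        alpha2=float(rng.uniform(100.0, 110.0)),
        b_factors=float(rng.uniform(15.0, 45.0)),
    )


# Each scenario names the per-structure state sequence of the protein's bonds
# (four structures per protein).
_SCENARIOS = [
    ["present", "reduced", "present", "present"],        # labile
    ["present", "mutated", "present", "present"],        # decoy: mutation
    ["present", "truncated", "reduced", "present"],      # labile with truncation decoy
    ["present", "unresolved", "present", "present"],     # decoy: unresolved SG
    ["present", "present@long", "present", "present"],   # stable bond, one stretched
    ["present", "reduced", "mutated", "unresolved"],     # labile, all decoys
    ["present@2.6", "reduced", "present@2.6", "reduced"],  # presence only above cutoff
    ["present", "reduced@DTT", "present", "reduced"],    # reductant decoy structure
    ["present", "reduced@nores", "reduced", "present"],  # no-resolution decoy
    ["present@unmapped", "present", "reduced", "present"],  # unmapped decoy structure
]


def generate_corpus(
    n_proteins: int = 20,
    seed: int = 0,
    two_bond_fraction: float = 0.5,
) -> list[EnsembleSpec]:
    """A corpus of ensembles cycling through every planted-state scenario.

    Roughly four structures per protein; with the default 20 proteins the
    corpus holds ~60 structures and exercises every observation status and
    every structure-exclusion reason.
    """
    rng = np.random.default_rng(seed)
    ensembles = []
    counter = 0
    for k in range(n_proteins):
        scenario = _SCENARIOS[k % len(_SCENARIOS)]
        two_bonds = rng.random() < two_bond_fraction
        length = 110 if two_bonds else 60
        pairs = [(15, 35), (65, 95)] if two_bonds else [(15, 35)]
        cys = [p for pair in pairs for p in pair]
        sequence = _random_sequence(rng, length, cys)
        accession = f"P{k:05d}"

        structures = []
        for s_idx, token in enumerate(scenario):
            counter += 1
            pdb_id = f"{counter:04d}"
            resolution: Optional[float] = float(np.round(rng.uniform(1.2, 2.4), 2))
            het: tuple[str, ...] = ()
            in_table = True
            base_state = token
            stretched = False
            if token.endswith("@long"):
                base_state = token[: -len("@long")]
                stretched = True
            elif token.endswith("@2.6"):
                base_state = token[:-4]
                resolution = 2.6
            elif token.endswith("@DTT"):
                base_state = token[:-4]
                het = ("DTT",)
            elif token.endswith("@nores"):
                base_state = token[:-6]
                resolution = None
            elif token.endswith("@unmapped"):
                base_state = token[: -len("@unmapped")]
                in_table = False

            bond_states = {}
            for b_idx, pair in enumerate(pairs):
                # the scenario state drives the first bond; later bonds follow a
                # shifted version so two-bond proteins mix states
                if b_idx == 0:
                    kind = base_state
                else:
                    alt = scenario[(s_idx + b_idx) % len(scenario)]
                    kind = alt.split("@")[0]
                if kind == "truncated" and pair != pairs[0]:
                    kind = "reduced"  # truncation only ever removes the N-terminal bond
                state = BondState(kind=kind)
                if kind == "present":
                    spec = _random_spec(rng)
                    if stretched and b_idx == 0:
                        spec.d = 2.31  # outside the 10% window: presence evidence only
                    state = BondState(kind="present", spec=spec)
                bond_states[pair] = state
            structures.append(
                StructureSpec(
                    pdb_id=pdb_id, resolution=resolution, bond_states=bond_states,
                    het_codes=het, numbering_offset=int(rng.integers(0, 3) * 100),
                    in_chain_table=in_table, declare_ss=bool(rng.random() < 0.5),
                )
            )
        ensembles.append(EnsembleSpec(accession=accession, sequence=sequence, structures=structures))
    return ensembles


def generate_ensemble(
    ensembles: Sequence[EnsembleSpec],
    outdir: Union[str, Path],
) -> dict[str, Path]:
    """Write PDB files, canonical FASTA, chain table and truth TSVs.

    Returns the paths of the emitted artefacts.  Output is byte-identical
    for identical ensemble specs.
    """
    outdir = Path(outdir)
    structures_dir = outdir / "structures"
    structures_dir.mkdir(parents=True, exist_ok=True)

    chain_rows = []
    fasta_lines = []
    for ens in sorted(ensembles, key=lambda e: e.accession):
        fasta_lines.append(f">{ens.accession}")
        fasta_lines.extend(
            ens.sequence[i : i + 60] for i in range(0, len(ens.sequence), 60)
        )
        for spec in ens.structures:
            model = generate_structure(ens, spec)
            (structures_dir / f"{spec.pdb_id}.pdb").write_text(write_pdb(model))
            if spec.in_chain_table:
                chain_rows.append(
                    {"pdb_id": spec.pdb_id, "chain_id": "A", "accession": ens.accession}
                )

    paths = {
        "structures": structures_dir,
        "fasta": outdir / "canonical.fasta",
        "chains": outdir / "chains.tsv",
        "truth_verdicts": outdir / "truth_verdicts.tsv",
        "truth_observations": outdir / "truth_observations.tsv",
        "truth_bonds": outdir / "truth_bonds.tsv",
    }
    paths["fasta"].write_text("\n".join(fasta_lines) + "\n")
    pd.DataFrame(chain_rows, columns=["pdb_id", "chain_id", "accession"]).sort_values(
        ["pdb_id", "chain_id"], ignore_index=True
    ).to_csv(paths["chains"], sep="\t", index=False)

    verdicts, observations, bonds = ensemble_truth(list(ensembles))
    verdicts.to_csv(paths["truth_verdicts"], sep="\t", index=False)
    observations.to_csv(paths["truth_observations"], sep="\t", index=False)
    bonds.to_csv(paths["truth_bonds"], sep="\t", index=False)
    return paths


def corpus_spec_from_yaml(path: Union[str, Path]) -> dict:
    """Read simulate-run settings (n_proteins, seed, two_bond_fraction) from YAML."""
    with open(path, "rt", encoding="utf-8") as handle:
        config = yaml.safe_load(handle) or {}
    allowed = {"n_proteins", "seed", "two_bond_fraction"}
    unknown = set(config) - allowed
    if unknown:
        raise ValueError(f"unknown corpus config key(s): {sorted(unknown)}")
    return config


# ---------------------------------------------------------------------------
# effect cohorts for strain statistics


def generate_effect_cohort(
    n_per_cohort: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """A synthetic bond table in which labile bonds are biased toward low |χ3|.

    The torsional potential is steepest in χ3 (its twofold term peaks at
    χ3 = 0), so bonds generated with small |χ3| carry visibly higher DSE —
    emulating the reported excess strain of labile disulfides.  Geometry is
    *measured* from built coordinates, not copied from the targets.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for cohort, labile in (("reference", False), ("labile", True)):
        for k in range(n_per_cohort):
            spec = _random_spec(rng, chi3_low=labile)
            res1, res2 = build_cystine(spec)
            geom = measure_cystine(res1, res2)
            signs, boundary = sign_vector(geom)
            rows.append(
                {
                    "accession": f"E{cohort[0].upper()}{k:04d}",
                    "pos_i": 1, "pos_j": 2, "labile": labile,
                    "chi1": geom.chi1, "chi2": geom.chi2, "chi3": geom.chi3,
                    "chi2p": geom.chi2p, "chi1p": geom.chi1p,
                    "alpha1": geom.alpha1, "alpha2": geom.alpha2,
                    "d": geom.d, "dse": geom.dse,
                    "config": classify(signs), "config_boundary": boundary,
                    "ss_pair": "loop/loop", "in_reference": True,
                }
            )
    return pd.DataFrame(rows)
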
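"""Geometric descriptors of a disulfide (cystine) bond.

A cystine is fully described by five torsions χ1 (N–Cα–Cβ–Sγ), χ2
(Cα–Cβ–Sγ–Sγ′), χ3 (Cβ–Sγ–Sγ′–Cβ′, the torsion about the S–S bond itself),
χ2′ and χ1′ (mirrored on the second cysteine), the two flanking bending
angles α1 = Cβ–Sγ–Sγ′ and α2 = Cβ′–Sγ′–Sγ, and the sulfur–sulfur distance d.
The dihedral strain energy (DSE, kJ/mol) is a torsional-potential estimate of
how far the five χ angles sit from their relaxed minima; highly strained
bonds are easier to cleave, which is why DSE is the workhorse statistic for
flagging redox-active ("allosteric") disulfides.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .pdbfile import Residue, SecStructRecord

__all__ = [
    "CystineGeometry",
    "GeometryError",
    "DSE_CONSTANTS",
    "CYS_CORE_ATOMS",
    "dihedral",
    "bond_angle",
    "dse",
    "measure_cystine",
    "b_factor_average",
    "ss_state",
]

# Torsional force constants, kJ/mol: threefold terms on chi1/chi1' (8.37),
# chi2/chi2' (4.18) and a two- plus threefold term on chi3 (14.64, 2.51).
DSE_CONSTANTS = {"k1": 8.37, "k2": 4.18, "k3_two": 14.64, "k3_three": 2.51}

#: the six heavy atoms of a cysteine residue entering the 12-atom B average
CYS_CORE_ATOMS = ("N", "CA", "C", "O", "CB", "SG")


class GeometryError(ValueError):
    """Degenerate or incomplete geometry."""


@dataclass
class CystineGeometry:
    """Measured descriptors of one disulfide bond.

    Angles are signed degrees in (−180, 180]; ``d`` is the Sγ–Sγ′ distance in
    Å; ``dse`` is in kJ/mol; ``b_avg`` is the 12-atom B-factor average in Å².
    ``config`` and ``ss_pair`` are filled in by the classification layer.
    """

    chi1: float
    chi2: float
    chi3: float
    chi2p: float
    chi1p: float
    alpha1: float
    alpha2: float
    d: float
    dse: float
    b_avg: Optional[float] = None
    b_missing_atoms: int = 0
    config: Optional[str] = None
    config_boundary: bool = False
    ss_pair: Optional[str] = None

    @property
    def chi_vector(self) -> tuple[float, float, float, float, float]:
        return (self.chi1, self.chi2, self.chi3, self.chi2p, self.chi1p)

    @property
    def alpha_avg(self) -> float:
        return 0.5 * (self.alpha1 + self.alpha2)


def _as_vec(p) -> np.ndarray:
    v = np.asarray(p, dtype=float)
    if v.shape != (3,) or not np.all(np.isfinite(v)):
        raise GeometryError(f"expected a finite 3-vector, got {p!r}")
    return v


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1–p2–p3–p4 in degrees, IUPAC convention.

    Looking from p2 towards p3, a clockwise rotation carrying the near bond
    onto the far bond is positive.  Result lies in (−180, 180].
    """
    p1, p2, p3, p4 = (_as_vec(p) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    for a, b in ((p1, p2), (p2, p3), (p3, p4)):
        if np.linalg.norm(b - a) < 1e-9:
            raise GeometryError("coincident consecutive points")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise GeometryError("collinear points: torsion undefined")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    # sign flipped so the result matches the standard phi/psi torsion
    # convention of the structural-biology toolchains
    angle = -np.degrees(np.arctan2(np.dot(m1, n2), np.dot(n1, n2)))
    if angle <= -180.0:
        angle += 360.0
    return float(angle)


def bond_angle(p1, p2, p3) -> float:
    """Angle p1–p2–p3 at vertex p2, degrees in [0, 180]."""
    p1, p2, p3 = _as_vec(p1), _as_vec(p2), _as_vec(p3)
    v1, v2 = p1 - p2, p3 - p2
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-9 or n2 < 1e-9:
        raise GeometryError("coincident points: angle undefined")
    cosv = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosv)))


def dse(chi1: float, chi2: float, chi3: float, chi2p: float, chi1p: float,
        constants: Mapping[str, float] = DSE_CONSTANTS) -> float:
    """Dihedral strain energy in kJ/mol.

    DSE = k1 (1+cos 3χ1) + k1 (1+cos 3χ1′) + k2 (1+cos 3χ2) + k2 (1+cos 3χ2′)
        + k3_two (1+cos 2χ3) + k3_three (1+cos 3χ3)

    With the default constants the range is [0, 84.5] and the χ3-only minimum
    sits at |χ3| = 90°.  Invariant under side swap and under χ → χ ± 360°.
    """
    angles = (chi1, chi2, chi3, chi2p, chi1p)
    if not all(np.isfinite(a) for a in angles):
        raise GeometryError("non-finite chi angle")
    r = np.radians(angles)
    k1, k2 = constants["k1"], constants["k2"]
    k3a, k3b = constants["k3_two"], constants["k3_three"]
    return float(
        k1 * (1 + np.cos(3 * r[0]))
        + k1 * (1 + np.cos(3 * r[4]))
        + k2 * (1 + np.cos(3 * r[1]))
        + k2 * (1 + np.cos(3 * r[3]))
        + k3a * (1 + np.cos(2 * r[2]))
        + k3b * (1 + np.cos(3 * r[2]))
    )


AtomSource = Union[Residue, Mapping[str, Sequence[float]]]


def _coords(res: AtomSource, name: str) -> Optional[np.ndarray]:
    if isinstance(res, Residue):
        return res.coords(name)
    v = res.get(name)
    return None if v is None else np.asarray(v, dtype=float)


def measure_cystine(res1: AtomSource, res2: AtomSource) -> CystineGeometry:
    """Measure χ1, χ2, χ3, χ2′, χ1′, α1, α2, d and DSE of a cysteine pair.

    Each residue must provide N, CA, CB and SG coordinates (a
    :class:`~cystmine.pdbfile.Residue` or a plain name→xyz mapping).  Swapping
    the two residues relabels side-primed quantities and leaves χ3, d and DSE
    unchanged.
    """
    needed = ("N", "CA", "CB", "SG")
    sides = []
    for label, res in (("residue 1", res1), ("residue 2", res2)):
        coords = {}
        for name in needed:
            c = _coords(res, name)
            if c is None:
                raise GeometryError(f"incomplete cystine: {label} is missing atom {name}")
            coords[name] = c
        sides.append(coords)
    a, b = sides

    chi1 = dihedral(a["N"], a["CA"], a["CB"], a["SG"])
    chi2 = dihedral(a["CA"], a["CB"], a["SG"], b["SG"])
    chi3 = dihedral(a["CB"], a["SG"], b["SG"], b["CB"])
    chi2p = dihedral(b["CA"], b["CB"], b["SG"], a["SG"])
    chi1p = dihedral(b["N"], b["CA"], b["CB"], b["SG"])
    alpha1 = bond_angle(a["CB"], a["SG"], b["SG"])
    alpha2 = bond_angle(b["CB"], b["SG"], a["SG"])
    d = float(np.linalg.norm(a["SG"] - b["SG"]))
    return CystineGeometry(
        chi1=chi1, chi2=chi2, chi3=chi3, chi2p=chi2p, chi1p=chi1p,
        alpha1=alpha1, alpha2=alpha2, d=d,
        dse=dse(chi1, chi2, chi3, chi2p, chi1p),
    )


def b_factor_average(res1: Residue, res2: Residue) -> tuple[float, int]:
    """Mean B factor over the 12 heavy atoms of the cysteine pair.

    Returns ``(average, n_missing)``: atoms absent from either residue are
    skipped and counted, and the mean runs over those present.
    """
    values: list[float] = []
    missing = 0
    for res in (res1, res2):
        for name in CYS_CORE_ATOMS:
            atom = res.atom(name)
            if atom is None:
                missing += 1
            else:
                values.append(atom.b_factor)
    if not values:
        raise GeometryError("no atoms available for B-factor average")
    return float(np.mean(values)), missing


def ss_state(
    chain_id: str,
    number: int,
    icode: str,
    helices: Sequence[SecStructRecord],
    sheets: Sequence[SecStructRecord],
) -> str:
    """Secondary-structure state of a residue: helix, strand or loop.

    Membership is taken from the HELIX/SHEET header ranges; a residue listed
    in both (malformed header) counts as helix.
    """
    for h in helices:
        if h.contains(chain_id, number, icode):
            return "helix"
    for s in sheets:
        if s.contains(chain_id, number, icode):
            return "strand"
    return "loop"


def ss_pair_label(state1: str, state2: str) -> str:
    """Unordered secondary-structure pair label, e.g. ``helix/loop``."""
    return "/".join(sorted((state1, state2)))
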
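"""The 20-class sign-based taxonomy of disulfide bond configurations.

Each cystine is assigned to one of 20 configurations from the signs of its
five χ torsions.  The handedness (RH/LH) follows the sign of χ3, the shape
(spiral/hook/staple) follows how the χ2 and χ2′ signs relate to χ3, and the
prefix records the χ1/χ1′ signs.  The -RHstaple, -LHhook and -/+RHhook
classes are the recognised allosteric configurations; the -LHspiral is the
archetypal structural disulfide.

Because the two cysteines of a bond have no intrinsic order, a name must not
change when the bond is traversed in the opposite direction (which swaps
χ1↔χ1′ and χ2↔χ2′).  The 32 sign vectors therefore collapse to exactly 20
classes.  For hooks — where exactly one of χ2, χ2′ agrees in sign with χ3 —
the mixed-χ1 patterns split into two genuinely distinct classes; the prefix
is written with the sign of χ1 on the side whose χ2 agrees with χ3 first, so
"-/+RHhook" and "+/-RHhook" are different configurations and each is
side-swap invariant.
"""

from __future__ import annotations

from itertools import product
from typing import Iterable, Sequence, Union

from .geometry import CystineGeometry

__all__ = [
    "ALLOSTERIC_CONFIGURATIONS",
    "CONFIGURATION_NAMES",
    "sign_vector",
    "classify",
    "classify_geometry",
]

#: the three configurations associated with allosteric function
ALLOSTERIC_CONFIGURATIONS = ("-RHstaple", "-LHhook", "-/+RHhook")

_SIGNS = ("-", "+")


def sign_vector(geom: Union[CystineGeometry, Sequence[float]]) -> tuple[tuple[str, ...], bool]:
    """Signs of (χ1, χ2, χ3, χ2′, χ1′) plus a boundary flag.

    An angle of exactly 0° or ±180° has no meaningful sign; by convention it
    is assigned '−' and the boundary flag is set so callers can drop the bond
    from configuration tallies.
    """
    chis = geom.chi_vector if isinstance(geom, CystineGeometry) else tuple(geom)
    if len(chis) != 5:
        raise ValueError("expected five chi angles")
    signs = []
    boundary = False
    for chi in chis:
        if chi == 0.0 or abs(chi) == 180.0:
            signs.append("-")
            boundary = True
        else:
            signs.append("+" if chi > 0 else "-")
    return tuple(signs), boundary


def classify(signs: Sequence[str]) -> str:
    """Configuration name for a five-sign vector, e.g. ``('-','-','+','-','-')`` → ``-RHstaple``.

    Pure function; invariant under reversing the sign vector (side swap).
    """
    s1, s2, s3, s4, s5 = signs
    for s in (s1, s2, s3, s4, s5):
        if s not in _SIGNS:
            raise ValueError(f"signs must be '+' or '-', got {s!r}")

    hand = "RH" if s3 == "+" else "LH"
    near_matches = s2 == s3   # chi2 agrees with chi3
    far_matches = s4 == s3    # chi2' agrees with chi3

    if near_matches and far_matches:
        shape = "spiral"
    elif not near_matches and not far_matches:
        shape = "staple"
    else:
        shape = "hook"

    if s1 == s5:
        prefix = s1
    elif shape == "hook":
        # orient by the side whose chi2 sign agrees with chi3, so the name is
        # independent of which cysteine is called side 1
        first = s1 if near_matches else s5
        second = s5 if near_matches else s1
        prefix = f"{first}/{second}"
    else:
        prefix = "-/+"
    return f"{prefix}{hand}{shape}"


CONFIGURATION_NAMES: tuple[str, ...] = tuple(
    sorted({classify(v) for v in product(_SIGNS, repeat=5)})
)


def classify_geometry(geom: CystineGeometry) -> CystineGeometry:
    """Fill ``config`` and ``config_boundary`` on a measured geometry in place."""
    signs, boundary = sign_vector(geom)
    geom.config = classify(signs)
    geom.config_boundary = boundary
    return geom
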
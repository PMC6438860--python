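"""Grantham physicochemical distance between amino acids, with the
conservative-to-radical banding used in variant interpretation.

The distance combines side-chain composition (c), polarity (p) and molecular
volume (v):

    D(a, b) = rho * [alpha (c_a - c_b)^2 + beta (p_a - p_b)^2
                     + gamma (v_a - v_b)^2] ** 0.5

with alpha = 1.833, beta = 0.1018, gamma = 0.000399 and the scale rho fixed
by normalizing the mean distance over all 190 unordered residue pairs to 100.
Scores are reported rounded to the nearest integer, the convention of the
published matrix.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

from .chemistry import AA_3TO1


class UnsupportedResidueError(ValueError):
    pass


#: (composition, polarity, volume) per residue.
GRANTHAM_PROPERTIES: dict[str, tuple[float, float, float]] = {
    "S": (1.42, 9.2, 32.0), "R": (0.65, 10.5, 124.0), "L": (0.0, 4.9, 111.0),
    "P": (0.39, 8.0, 32.5), "T": (0.71, 8.6, 61.0), "A": (0.0, 8.1, 31.0),
    "V": (0.0, 5.9, 84.0), "G": (0.74, 9.0, 3.0), "I": (0.0, 5.2, 111.0),
    "F": (0.0, 5.2, 132.0), "Y": (0.20, 6.2, 136.0), "C": (2.75, 5.5, 55.0),
    "H": (0.58, 10.4, 96.0), "Q": (0.89, 10.5, 85.0), "N": (1.33, 11.6, 56.0),
    "K": (0.33, 11.3, 119.0), "D": (1.38, 13.0, 54.0), "E": (0.92, 12.3, 83.0),
    "M": (0.0, 5.7, 105.0), "W": (0.13, 5.4, 170.0),
}

ALPHA, BETA, GAMMA = 1.833, 0.1018, 0.000399


def _raw(a: str, b: str) -> float:
    ca, pa, va = GRANTHAM_PROPERTIES[a]
    cb, pb, vb = GRANTHAM_PROPERTIES[b]
    return math.sqrt(ALPHA * (ca - cb) ** 2 + BETA * (pa - pb) ** 2
                     + GAMMA * (va - vb) ** 2)


def _mean_raw() -> float:
    pairs = list(itertools.combinations(sorted(GRANTHAM_PROPERTIES), 2))
    return sum(_raw(a, b) for a, b in pairs) / len(pairs)


#: Scale factor normalizing the mean inter-residue distance to 100.
RHO: float = 100.0 / _mean_raw()


def _one_letter(aa: str) -> str:
    aa = aa.strip()
    if len(aa) == 1 and aa.upper() in GRANTHAM_PROPERTIES:
        return aa.upper()
    three = aa.upper()
    if three in AA_3TO1:
        return AA_3TO1[three]
    raise UnsupportedResidueError(f"not a canonical amino acid: {aa!r}")


def grantham_distance(a: str, b: str) -> int:
    """Grantham distance between two amino acids (1- or 3-letter codes),
    rounded to the nearest integer. Symmetric; zero on the diagonal."""
    x, y = _one_letter(a), _one_letter(b)
    return round(RHO * _raw(x, y))


def grantham_matrix() -> dict[tuple[str, str], int]:
    """All 190 unordered-pair distances, keyed by sorted 1-letter pair."""
    out = {}
    for x, y in itertools.combinations(sorted(GRANTHAM_PROPERTIES), 2):
        out[(x, y)] = grantham_distance(x, y)
    return out


@dataclass(frozen=True)
class GranthamBands:
    """Severity banding of a Grantham score.

    The published band edges leave the single score 150 unassigned
    ("101-150 moderately radical", ">151 radical"); to keep the
    classification total, 150 is moderately radical and radical starts
    at 151.
    """
    conservative: int = 50
    moderately_conservative: int = 100
    moderately_radical: int = 150

    labels = ("conservative", "moderately conservative",
              "moderately radical", "radical")


DEFAULT_BANDS = GranthamBands()


def grantham_class(score: float, bands: GranthamBands = DEFAULT_BANDS) -> str:
    """Band label for a Grantham score: <=50 conservative, 51-100 moderately
    conservative, 101-150 moderately radical, >=151 radical."""
    if score < 0:
        raise ValueError(f"Grantham score cannot be negative: {score}")
    if score <= bands.conservative:
        return "conservative"
    if score <= bands.moderately_conservative:
        return "moderately conservative"
    if score <= bands.moderately_radical:
        return "moderately radical"
    return "radical"
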
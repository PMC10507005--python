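"""Molecular formulas over C,H,N,O,S,P and their mass/descriptor arithmetic.

Everything downstream — formula assignment, compositional classification,
intensity-weighted sample summaries — rests on the exact monoisotopic
masses and the two structural descriptors defined here: the double-bond
equivalent (DBE) and the modified aromaticity index (AImod).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import cached_property

ELEMENTS = ("C", "H", "N", "O", "S", "P")

#: Monoisotopic masses of the most abundant isotopes (Da).
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
    "P": 30.97376151,
}

ELECTRON_MASS = 0.00054857990924
#: Mass of a proton (H atom minus its electron); converts [M-H]- m/z to neutral mass.
PROTON_MASS = MONOISOTOPIC_MASS["H"] - ELECTRON_MASS

#: Mass difference between 13C and 12C; position of the first isotopologue peak.
C13_C12_DELTA = 1.0033548378
#: Natural abundance ratio 13C/12C used for isotope-pattern verification.
C13_ABUNDANCE = 0.0107

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True, order=True)
class MolecularFormula:
    """Elemental composition with integer counts over C, H, N, O, S, P."""

    c: int
    h: int
    n: int = 0
    o: int = 0
    s: int = 0
    p: int = 0

    def __post_init__(self) -> None:
        if self.c < 1:
            raise ValueError(f"formula must contain carbon (c={self.c})")
        for el in ("h", "n", "o", "s", "p"):
            if getattr(self, el) < 0:
                raise ValueError(f"negative element count {el}={getattr(self, el)}")

    @cached_property
    def neutral_mass(self) -> float:
        """Neutral monoisotopic mass in Da."""
        return (
            self.c * MONOISOTOPIC_MASS["C"]
            + self.h * MONOISOTOPIC_MASS["H"]
            + self.n * MONOISOTOPIC_MASS["N"]
            + self.o * MONOISOTOPIC_MASS["O"]
            + self.s * MONOISOTOPIC_MASS["S"]
            + self.p * MONOISOTOPIC_MASS["P"]
        )

    @property
    def mz_deprotonated(self) -> float:
        """m/z of the singly deprotonated anion [M-H]-."""
        return self.neutral_mass - PROTON_MASS

    @property
    def heteroatom_count(self) -> int:
        return self.n + self.s + self.p

    def counts(self) -> tuple[int, int, int, int, int, int]:
        return (self.c, self.h, self.n, self.o, self.s, self.p)

    def __str__(self) -> str:
        parts = []
        for sym, cnt in zip(ELEMENTS, self.counts()):
            if cnt == 0:
                continue
            parts.append(sym if cnt == 1 else f"{sym}{cnt}")
        return "".join(parts)

    @classmethod
    def from_string(cls, text: str) -> "MolecularFormula":
        """Parse a canonical Hill-style formula string like ``C13H8O6``."""
        counts = dict.fromkeys(ELEMENTS, 0)
        pos = 0
        for m in _FORMULA_TOKEN.finditer(text):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r}")
            pos = m.end()
            sym = m.group(1)
            if sym not in counts:
                raise ValueError(f"unsupported element {sym!r} in {text!r}")
            counts[sym] += int(m.group(2) or 1)
        if pos != len(text):
            raise ValueError(f"cannot parse formula {text!r}")
        return cls(
            c=counts["C"], h=counts["H"], n=counts["N"],
            o=counts["O"], s=counts["S"], p=counts["P"],
        )


def dbe(f: MolecularFormula) -> float:
    """Double-bond equivalents: 1 + C - H/2 + (N + P)/2 (P taken trivalent)."""
    return 1.0 + f.c - f.h / 2.0 + (f.n + f.p) / 2.0


def aimod(f: MolecularFormula) -> float:
    """Modified aromaticity index.

    AImod = (1 + C - O/2 - S - (N + P + H)/2) / (C - O/2 - N - S - P),
    with half the oxygens discounted as potential carbonyl/carboxyl bonds.
    Returns 0 when the denominator is non-positive; negative values are
    clamped to 0 (a formula cannot be less than non-aromatic).
    """
    denom = f.c - 0.5 * f.o - f.n - f.s - f.p
    if denom <= 0:
        return 0.0
    num = 1.0 + f.c - 0.5 * f.o - f.s - 0.5 * (f.n + f.p + f.h)
    return max(0.0, num / denom)


def hc_ratio(f: MolecularFormula) -> float:
    return f.h / f.c


def oc_ratio(f: MolecularFormula) -> float:
    return f.o / f.c


def parity_valid(f: MolecularFormula) -> bool:
    """Valence-parity screen (integer DBE / nitrogen rule).

    For CHNOSP compositions with trivalent-P bookkeeping, an integer DBE and
    the nominal-mass nitrogen rule for the (de)protonated ion both reduce to
    the single parity condition h = n + p (mod 2).
    """
    return (f.h - f.n - f.p) % 2 == 0
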
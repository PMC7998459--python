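"""Elemental-composition and monoisotopic-mass arithmetic for cyclic peptides.

Everything downstream of gene mining — candidate mass enumeration, MS1
matching and MS/MS fragment annotation — reduces to integer element
bookkeeping over C, H, N, O and S plus a handful of physical constants.
This module owns that bookkeeping.

Conventions
-----------
* A *residue* composition is the amino acid minus one water (the usual
  peptide-bond convention), so a linear peptide is the residue sum plus
  one H2O and a head-to-tail cyclic peptide is the residue sum exactly.
* Post-translational modifications of the amatoxin/phallotoxin class are
  treated as composition deltas only: each hydroxylation adds one O,
  sulfoxidation adds one O, and formation of the Trp–Cys tryptathionine
  cross-bridge removes two H. No attempt is made to localise them.
* Adducts are singly or multiply protonated/sodiated/potassiated cations;
  m/z = (M + z * cation mass) / z with the *cation* (not neutral atom)
  masses, which is what reproduces printed [M+H]+ values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Tuple

__all__ = [
    "ElementalComposition",
    "Peptide",
    "ModificationState",
    "Adduct",
    "InvalidSequenceError",
    "ModificationError",
    "RESIDUE_TABLE",
    "ELEMENT_MASS",
    "WATER",
    "PROTON_MASS",
    "ADDUCT_MASS",
    "composition_of",
    "monoisotopic_mass",
    "peptide_mass",
    "apply_modifications",
    "adduct_mz",
    "ppm_delta",
    "immonium_mz",
    "isotopic_distribution",
]

ELEMENTS = ("C", "H", "N", "O", "S")

#: Principal-isotope (monoisotopic) masses, Da.
ELEMENT_MASS: Dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
    "S": 31.97207069,
}

#: Cation masses per unit charge, Da (electron mass already accounted for).
PROTON_MASS = 1.007276
ADDUCT_MASS: Dict[str, float] = {
    "H": 1.007276,
    "Na": 22.989218,
    "K": 38.963158,
}

#: Mass of CO, subtracted from a residue to form its immonium ion.
_CO_MASS = 27.99491

#: Isotope tables (mass, abundance) per element, principal isotope first.
_ISOTOPES: Dict[str, Tuple[Tuple[float, float], ...]] = {
    "C": ((12.0, 0.9893), (13.00335484, 0.0107)),
    "H": ((1.00782503, 0.999885), (2.01410178, 0.000115)),
    "N": ((14.00307401, 0.99636), (15.00010890, 0.00364)),
    "O": ((15.99491462, 0.99757), (16.99913176, 0.00038), (17.99915961, 0.00205)),
    "S": ((31.97207069, 0.9499), (32.97145876, 0.0075), (33.96786690, 0.0425),
          (35.96708071, 0.0001)),
}


class InvalidSequenceError(ValueError):
    """A peptide sequence contains a non-standard residue letter."""


class ModificationError(ValueError):
    """A modification state is inconsistent with the peptide sequence."""


@dataclass(frozen=True)
class ElementalComposition:
    """Integer element counts over C, H, N, O, S.

    Supports element-wise addition and subtraction; subtraction raises if
    any count would become negative (a composition is a bag of atoms).
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for el, n in self.counts.items():
            if el not in ELEMENT_MASS:
                raise ValueError(f"unsupported element {el!r}")
            if int(n) != n or n < 0:
                raise ValueError(f"count for {el} must be a non-negative integer, got {n!r}")
            if n:
                clean[el] = int(n)
        object.__setattr__(self, "counts", clean)

    def __getitem__(self, el: str) -> int:
        return self.counts.get(el, 0)

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return ElementalComposition(merged)

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) - n
            if merged[el] < 0:
                raise ValueError(f"subtraction would leave negative {el} count")
        return ElementalComposition(merged)

    def __mul__(self, k: int) -> "ElementalComposition":
        if int(k) != k or k < 0:
            raise ValueError("multiplier must be a non-negative integer")
        return ElementalComposition({el: n * int(k) for el, n in self.counts.items()})

    __rmul__ = __mul__

    def formula(self) -> str:
        """Hill-style CHNOS formula string, e.g. ``C59H84N10O11``."""
        parts = []
        for el in ELEMENTS:
            n = self[el]
            if n == 1:
                parts.append(el)
            elif n > 1:
                parts.append(f"{el}{n}")
        return "".join(parts)

    @classmethod
    def from_formula(cls, formula: str) -> "ElementalComposition":
        import re

        counts: Dict[str, int] = {}
        pos = 0
        for m in re.finditer(r"([A-Z][a-z]?)(\d*)", formula):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r}")
            pos = m.end()
            counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
        if pos != len(formula):
            raise ValueError(f"cannot parse formula {formula!r}")
        return cls(counts)

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.formula()


def _ec(**counts: int) -> ElementalComposition:
    return ElementalComposition(counts)


WATER = _ec(H=2, O=1)
WATER_MASS = 2 * ELEMENT_MASS["H"] + ELEMENT_MASS["O"]

#: Residue (amino acid minus water) compositions for the 20 standard residues.
RESIDUE_TABLE: Dict[str, ElementalComposition] = {
    "G": _ec(C=2, H=3, N=1, O=1),
    "A": _ec(C=3, H=5, N=1, O=1),
    "S": _ec(C=3, H=5, N=1, O=2),
    "P": _ec(C=5, H=7, N=1, O=1),
    "V": _ec(C=5, H=9, N=1, O=1),
    "T": _ec(C=4, H=7, N=1, O=2),
    "C": _ec(C=3, H=5, N=1, O=1, S=1),
    "L": _ec(C=6, H=11, N=1, O=1),
    "I": _ec(C=6, H=11, N=1, O=1),
    "N": _ec(C=4, H=6, N=2, O=2),
    "D": _ec(C=4, H=5, N=1, O=3),
    "Q": _ec(C=5, H=8, N=2, O=2),
    "K": _ec(C=6, H=12, N=2, O=1),
    "E": _ec(C=5, H=7, N=1, O=3),
    "M": _ec(C=5, H=9, N=1, O=1, S=1),
    "H": _ec(C=6, H=7, N=3, O=1),
    "F": _ec(C=9, H=9, N=1, O=1),
    "R": _ec(C=6, H=12, N=4, O=1),
    "Y": _ec(C=9, H=9, N=1, O=2),
    "W": _ec(C=11, H=10, N=2, O=1),
}

TOPOLOGIES = ("linear", "cyclic")


@dataclass(frozen=True)
class Peptide:
    """A peptide sequence with linear or head-to-tail cyclic topology."""

    sequence: str
    topology: str = "cyclic"

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"topology must be one of {TOPOLOGIES}, got {self.topology!r}")
        seq = self.sequence
        if len(seq) < 2:
            raise InvalidSequenceError("peptide must have at least 2 residues")
        if not seq.isupper():
            raise InvalidSequenceError("sequence must be uppercase")
        _validate_sequence(seq)

    def __len__(self) -> int:
        return len(self.sequence)


def _validate_sequence(seq: str) -> None:
    for i, aa in enumerate(seq):
        if aa not in RESIDUE_TABLE:
            raise InvalidSequenceError(
                f"unknown residue {aa!r} at position {i} in {seq!r}"
            )


@dataclass(frozen=True)
class ModificationState:
    """Composition-level modification state of an amatoxin-class peptide.

    ``n_hydroxyl`` hydroxylations (0–4, each +O), optional sulfoxidation
    (+O) and optional Trp–Cys cross-bridge (−2 H). Sulfoxide and bridge
    require the sequence to contain both Cys and Trp; that constraint is
    enforced where a sequence is available (:func:`apply_modifications`).
    """

    n_hydroxyl: int = 0
    sulfoxide: bool = False
    bridge: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.n_hydroxyl <= 4:
            raise ModificationError(
                f"n_hydroxyl must be in [0, 4], got {self.n_hydroxyl}"
            )

    @property
    def is_unmodified(self) -> bool:
        return self.n_hydroxyl == 0 and not self.sulfoxide and not self.bridge

    def label(self) -> str:
        parts = []
        if self.n_hydroxyl:
            parts.append(f"{self.n_hydroxyl}xOH")
        if self.sulfoxide:
            parts.append("sulfoxide")
        if self.bridge:
            parts.append("bridge")
        return "+".join(parts) if parts else "unmodified"


_ADDUCT_KINDS = {"protonated": "H", "sodiated": "Na", "potassiated": "K"}


@dataclass(frozen=True)
class Adduct:
    """A positive-mode adduct ion: [M+zH]z+, [M+zNa]z+ or [M+zK]z+."""

    kind: str = "protonated"
    charge: int = 1

    def __post_init__(self) -> None:
        kind = _ADDUCT_KINDS.get(self.kind, self.kind)
        if kind not in ADDUCT_MASS:
            raise ValueError(f"unknown adduct kind {self.kind!r}")
        object.__setattr__(self, "kind", kind)
        if self.charge < 1:
            raise ValueError("charge must be a positive integer")

    @property
    def cation_mass(self) -> float:
        return ADDUCT_MASS[self.kind]

    def label(self) -> str:
        z = "" if self.charge == 1 else str(self.charge)
        return f"[M+{z}{self.kind}]{z}+"


def composition_of(peptide: Peptide | str, topology: str = "cyclic") -> ElementalComposition:
    """Elemental composition of a peptide.

    Linear = sum of residue compositions + H2O; cyclic = residue sum only
    (cyclisation releases one water).
    """
    if isinstance(peptide, str):
        peptide = Peptide(peptide, topology)
    total = ElementalComposition()
    for aa in peptide.sequence:
        total = total + RESIDUE_TABLE[aa]
    if peptide.topology == "linear":
        total = total + WATER
    return total


def monoisotopic_mass(comp: ElementalComposition) -> float:
    """Monoisotopic mass in Da: sum of count x principal-isotope mass."""
    return sum(ELEMENT_MASS[el] * n for el, n in comp.counts.items())


def peptide_mass(sequence: str, topology: str = "cyclic",
                 mods: ModificationState | None = None) -> float:
    """Convenience: monoisotopic neutral mass of a (modified) peptide."""
    comp = composition_of(sequence, topology)
    if mods is not None and not mods.is_unmodified:
        comp = apply_modifications(comp, mods, sequence)
    return monoisotopic_mass(comp)


def apply_modifications(comp: ElementalComposition, mods: ModificationState,
                        seq: str) -> ElementalComposition:
    """Apply a modification state to a composition.

    O count += n_hydroxyl (+1 if sulfoxide); H count -= 2 if bridge.
    Sulfoxide/bridge require both C and W in ``seq``.
    """
    if (mods.sulfoxide or mods.bridge) and not ("C" in seq and "W" in seq):
        raise ModificationError(
            "sulfoxidation and tryptathionine bridge require both Cys and Trp "
            f"in the sequence, got {seq!r}"
        )
    counts = dict(comp.counts)
    extra_o = mods.n_hydroxyl + (1 if mods.sulfoxide else 0)
    if extra_o:
        counts["O"] = counts.get("O", 0) + extra_o
    if mods.bridge:
        counts["H"] = counts.get("H", 0) - 2
        if counts["H"] < 0:
            raise ModificationError("bridge would leave negative H count")
    return ElementalComposition(counts)


def adduct_mz(neutral_mass: float, adduct: Adduct | str = "H") -> float:
    """m/z of an adduct ion: (M + z * cation mass) / z."""
    if isinstance(adduct, str):
        adduct = Adduct(adduct)
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be positive")
    return (neutral_mass + adduct.charge * adduct.cation_mass) / adduct.charge


def ppm_delta(theoretical: float, measured: float) -> float:
    """Absolute mass discrepancy in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return abs(measured - theoretical) / theoretical * 1e6


def immonium_mz(residue: str) -> float:
    """Immonium ion m/z for a residue: residue mass − CO + proton."""
    if residue not in RESIDUE_TABLE:
        raise InvalidSequenceError(f"unknown residue {residue!r}")
    return monoisotopic_mass(RESIDUE_TABLE[residue]) - _CO_MASS + PROTON_MASS


def _convolve(a: Dict[int, Tuple[float, float]], b: Dict[int, Tuple[float, float]],
              bin_width: float, prune: float) -> Dict[int, Tuple[float, float]]:
    out: Dict[int, Tuple[float, float]] = {}
    for ka, (pa, ma) in a.items():
        for kb, (pb, mb) in b.items():
            p = pa * pb
            if p < prune:
                continue
            # mean masses add because the bins are narrow and independent
            mass = ma / pa + mb / pb
            k = round(mass / bin_width)
            p0, m0 = out.get(k, (0.0, 0.0))
            out[k] = (p0 + p, m0 + p * mass)
    return out


def isotopic_distribution(comp: ElementalComposition, mass_bin: float = 0.01,
                          prune: float = 1e-12) -> List[Tuple[float, float]]:
    """Fine-grained isotopic distribution by binned convolution.

    Per-element isotope distributions are raised to the atom count by
    repeated squaring and convolved across elements, aggregating into
    ``mass_bin``-wide bins (abundance-weighted mean mass per bin).
    Abundances are renormalised to sum to 1; peaks below ``prune``
    relative abundance are dropped during convolution.

    Returns a list of ``(mass, relative_abundance)`` sorted by mass; the
    first peak is the monoisotopic peak.
    """
    if mass_bin <= 0:
        raise ValueError("mass_bin must be positive")
    # identity spectrum: single zero-mass peak
    spectrum: Dict[int, Tuple[float, float]] = {0: (1.0, 0.0)}
    for el, n in comp.counts.items():
        base = {round(m / mass_bin): (p, p * m) for m, p in _ISOTOPES[el]}
        power = base
        k = n
        while k:
            if k & 1:
                spectrum = _convolve(spectrum, power, mass_bin, prune)
            k >>= 1
            if k:
                power = _convolve(power, power, mass_bin, prune)
    total = sum(p for p, _ in spectrum.values())
    peaks = sorted(
        ((m / p, p / total) for p, m in spectrum.values()), key=lambda t: t[0]
    )
    return peaks
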
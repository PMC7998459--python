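"""Theoretical fragment ions, MS/MS matching, and sequence assignment.

The assignment follows the manual practice used to confirm *Amanita*
cyclic peptides: y-type ions are computed on the written (linear) core
orientation even though the analyte is cyclic — empirically these
explain the spectra well — together with residue-diagnostic immonium
ions. A candidate is deemed real only when most or all of its residues
are accounted for by consecutive y-ion mass differentials or by matched
immonium ions; the verbal "most or all" rule is quantified as a
configurable residue-coverage threshold (default 0.8) plus a minimum
immonium count (default 1).

A principled cyclic-fragmentation mode is also available: ``ring_b``
ions are the union of b-series over all ring-opening rotations.

Note that leucine and isoleucine are isobaric, so assignments are
invariant under I<->L substitution; results carry an ``il_ambiguous``
flag when the core contains either residue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

from .chem import (
    PROTON_MASS,
    RESIDUE_TABLE,
    WATER_MASS,
    InvalidSequenceError,
    _validate_sequence,
    immonium_mz,
    monoisotopic_mass,
)
from .ms1 import Peak

__all__ = ["FragmentIon", "Ms2Spectrum", "AssignConfig", "AssignmentResult",
           "theoretical_ions", "match_spectrum", "assign", "compare_spectra"]


def _residue_mass(aa: str) -> float:
    return monoisotopic_mass(RESIDUE_TABLE[aa])


@dataclass(frozen=True)
class FragmentIon:
    """A theoretical fragment ion.

    ``index`` is the series index for y/b ions, the residue letter for
    immonium ions, and an (opening, index) pair for ring-opened b ions.
    ``span`` is the stretch of the core the ion covers.
    """

    series: str
    index: object
    mz: float
    span: str = ""


@dataclass
class Ms2Spectrum:
    """A centroided MS/MS spectrum; peaks are kept sorted by m/z."""

    precursor_mz: Optional[float]
    peaks: List[Peak]
    collision_energy: Optional[float] = None

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)

    def mz_array(self) -> List[float]:
        return [p.mz for p in self.peaks]


@dataclass(frozen=True)
class AssignConfig:
    """Tolerances and thresholds of the assignment rule.

    ``check_precursor`` enforces the MS1→MS2 coupling of the workflow: a
    candidate is only assignable to a spectrum whose precursor m/z agrees
    with the candidate's cyclic [M+H]+ within ``precursor_tol_ppm``.
    Spectra without a recorded precursor skip the gate.
    """

    fragment_tol: float = 0.02
    tol_unit: str = "Da"  # or "ppm"
    coverage_threshold: float = 0.8
    min_immonium: int = 1
    series: Tuple[str, ...] = ("y", "b", "immonium")
    check_precursor: bool = True
    precursor_tol_ppm: float = 10.0

    def tol_at(self, mz: float) -> float:
        return self.fragment_tol if self.tol_unit == "Da" else mz * self.fragment_tol / 1e6


@dataclass
class AssignmentResult:
    """Verdict of the coverage rule for one core against one spectrum."""

    core: str
    matched_y: Set[int]
    matched_b: Set[int]
    matched_immonium: Set[str]
    residue_coverage: float
    verdict: str
    il_ambiguous: bool = False

    @property
    def confirmed(self) -> bool:
        return self.verdict == "confirmed"


def theoretical_ions(core: str, series: Sequence[str] = ("y", "b", "immonium"),
                     dedup_tol: float = 1e-4) -> List[FragmentIon]:
    """Theoretical fragment ions for a core written in linear orientation.

    y_k = mass of the C-terminal k residues + H2O + proton;
    b_k = mass of the N-terminal k residues + proton (k = 1..n-1);
    immonium = residue mass - CO + proton, one per distinct residue;
    ring_b = union of b-series over all n cyclic rotations, deduplicated
    at ``dedup_tol`` Da.
    """
    _validate_sequence(core)
    n = len(core)
    if n < 3:
        raise InvalidSequenceError("core must have at least 3 residues")
    ions: List[FragmentIon] = []
    if "y" in series:
        running = WATER_MASS + PROTON_MASS
        for k in range(1, n):
            running += _residue_mass(core[n - k])
            ions.append(FragmentIon("y", k, running, core[n - k:]))
    if "b" in series:
        running = PROTON_MASS
        for k in range(1, n):
            running += _residue_mass(core[k - 1])
            ions.append(FragmentIon("b", k, running, core[:k]))
    if "immonium" in series:
        for aa in sorted(set(core)):
            ions.append(FragmentIon("immonium", aa, immonium_mz(aa), aa))
    if "ring_b" in series:
        seen: List[float] = []
        for opening in range(n):
            rotated = core[opening:] + core[:opening]
            running = PROTON_MASS
            for k in range(1, n):
                running += _residue_mass(rotated[k - 1])
                if any(abs(running - m) <= dedup_tol for m in seen):
                    continue
                seen.append(running)
                ions.append(FragmentIon("ring_b", (opening, k), running,
                                        rotated[:k]))
    return ions


def match_spectrum(spectrum: Ms2Spectrum, ions: Sequence[FragmentIon],
                   tol: float = 0.02, tol_unit: str = "Da"
                   ) -> List[Tuple[FragmentIon, Peak]]:
    """Match theoretical ions to spectrum peaks.

    Each theoretical ion is matched greedily to its nearest peak within
    the tolerance (at most one peak per ion). Result order follows the
    input ion order, so it is deterministic and independent of peak
    ordering.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    matches: List[Tuple[FragmentIon, Peak]] = []
    peaks = spectrum.peaks
    if not peaks:
        return matches
    for ion in ions:
        limit = tol if tol_unit == "Da" else ion.mz * tol / 1e6
        best = min(peaks, key=lambda p: abs(p.mz - ion.mz))
        if abs(best.mz - ion.mz) <= limit:
            matches.append((ion, best))
    return matches


def _covered_positions(core: str, matched_y: Set[int],
                       matched_immonium: Set[str]) -> Set[int]:
    """Residue positions explained by consecutive y-ion differentials or
    by immonium evidence.

    y_k covers the C-terminal k residues, so the differential between
    matched y_k and y_{k+1} pins down residue n-k-1 (0-based); a matched
    y_1 pins down the C-terminal residue. A matched immonium ion covers
    every position of that residue.
    """
    n = len(core)
    covered: Set[int] = set()
    if 1 in matched_y:
        covered.add(n - 1)
    for k in matched_y:
        if k + 1 in matched_y:
            covered.add(n - k - 1)
    for i, aa in enumerate(core):
        if aa in matched_immonium or (aa in "IL" and matched_immonium & {"I", "L"}):
            covered.add(i)
    return covered


def assign(core: str, spectrum: Ms2Spectrum,
           config: AssignConfig | None = None) -> AssignmentResult:
    """Apply the residue-coverage assignment rule to one candidate core.

    Confirmed iff the spectrum's precursor is mass-consistent with the
    cyclic core (when both are available and the gate is enabled),
    residue coverage >= ``coverage_threshold``, and at least
    ``min_immonium`` immonium ions matched.
    """
    from .chem import adduct_mz, peptide_mass, ppm_delta

    config = config or AssignConfig()
    precursor_ok = True
    if config.check_precursor and spectrum.precursor_mz:
        theo = adduct_mz(peptide_mass(core, "cyclic"), "H")
        precursor_ok = (ppm_delta(theo, spectrum.precursor_mz)
                        <= config.precursor_tol_ppm)
    ions = theoretical_ions(core, config.series)
    matches = match_spectrum(spectrum, ions, config.fragment_tol,
                             config.tol_unit)
    matched_y = {ion.index for ion, _ in matches if ion.series == "y"}
    matched_b = {ion.index for ion, _ in matches if ion.series == "b"}
    matched_imm = {ion.index for ion, _ in matches if ion.series == "immonium"}
    covered = _covered_positions(core, matched_y, matched_imm)
    coverage = len(covered) / len(core)
    ok = (precursor_ok and coverage >= config.coverage_threshold
          and len(matched_imm) >= config.min_immonium)
    return AssignmentResult(
        core=core,
        matched_y=matched_y,
        matched_b=matched_b,
        matched_immonium=matched_imm,
        residue_coverage=coverage,
        verdict="confirmed" if ok else "rejected",
        il_ambiguous=bool(set(core) & {"I", "L"}),
    )


def compare_spectra(spec_a: Ms2Spectrum, spec_b: Ms2Spectrum,
                    tol: float = 0.02) -> Tuple[int, List[Tuple[Peak, Peak]]]:
    """Count peaks shared between two spectra (greedy one-to-one pairing).

    Candidate peak pairs within ``tol`` are accepted nearest-first, each
    peak used at most once. Returns (shared count, aligned pairs).
    """
    if not spec_a.peaks or not spec_b.peaks:
        raise ValueError("both spectra must be non-empty")
    pairs = [
        (abs(pa.mz - pb.mz), ia, ib)
        for ia, pa in enumerate(spec_a.peaks)
        for ib, pb in enumerate(spec_b.peaks)
        if abs(pa.mz - pb.mz) <= tol
    ]
    pairs.sort()
    used_a: Set[int] = set()
    used_b: Set[int] = set()
    aligned: List[Tuple[Peak, Peak]] = []
    for _, ia, ib in pairs:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        aligned.append((spec_a.peaks[ia], spec_b.peaks[ib]))
    return len(aligned), aligned
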
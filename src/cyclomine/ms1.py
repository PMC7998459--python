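"""MS1 peak-list reading and ppm-tolerance matching of candidate masses.

Matching is deliberately permissive: every (candidate, adduct, peak)
pair within the ppm tolerance and inside the instrument scan range is
reported, sorted by discrepancy. Ambiguity between candidates sharing a
mass (e.g. I/L isomers) is resolved downstream at the MS/MS stage, not
here. Retention time, when present, is carried through unused.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .candidates import CandidateMass
from .chem import Adduct, ppm_delta

__all__ = ["Peak", "Ms1Match", "PeaklistFormatError", "read_peaklist",
           "match_ms1", "matches_to_dataframe"]

DEFAULT_SCAN_RANGE = (500.0, 1700.0)


class PeaklistFormatError(ValueError):
    """A peak-list file could not be parsed."""


@dataclass(frozen=True)
class Peak:
    """A centroided peak: m/z, intensity, optional retention time (s)."""

    mz: float
    intensity: float = 0.0
    retention_time: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError("peak intensity must be non-negative")


@dataclass(frozen=True)
class Ms1Match:
    """A candidate adduct ion matched to a measured MS1 peak."""

    candidate: CandidateMass
    adduct: str
    peak: Peak
    theoretical_mz: float
    measured_mz: float
    delta_ppm: float


def _read_csv_peaks(path: Path) -> List[Peak]:
    peaks = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            row = [c.strip() for c in row if c.strip()]
            if not row or row[0].startswith("#"):
                continue
            if lineno == 1 and not _is_number(row[0]):
                continue  # header line
            try:
                mz = float(row[0])
                intensity = float(row[1]) if len(row) > 1 else 0.0
                rt = float(row[2]) if len(row) > 2 else None
                peaks.append(Peak(mz, intensity, rt))
            except ValueError as exc:
                raise PeaklistFormatError(
                    f"{path}: malformed peak on line {lineno}: {exc}"
                ) from None
    return peaks


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def _read_mgf_peaks(path: Path, mode: str) -> List[Peak]:
    from pyteomics import mgf

    peaks = []
    try:
        with mgf.MGF(str(path)) as reader:
            for spectrum in reader:
                params = spectrum.get("params", {})
                if mode == "precursor":
                    pepmass = params.get("pepmass")
                    if pepmass is None:
                        raise PeaklistFormatError(
                            f"{path}: spectrum without PEPMASS in precursor mode")
                    mz = pepmass[0]
                    inten = pepmass[1] if len(pepmass) > 1 and pepmass[1] else 0.0
                    rt = params.get("rtinseconds")
                    peaks.append(Peak(float(mz), float(inten),
                                      float(rt) if rt is not None else None))
                else:
                    for mz, inten in zip(spectrum["m/z array"],
                                         spectrum["intensity array"]):
                        peaks.append(Peak(float(mz), float(inten)))
    except (ValueError, KeyError) as exc:
        if isinstance(exc, PeaklistFormatError):
            raise
        raise PeaklistFormatError(f"{path}: {exc}") from exc
    return peaks


def read_peaklist(path, format: Optional[str] = None, mode: str = "precursor"
                  ) -> List[Peak]:
    """Read a peak list from CSV (``mz[,intensity[,rt]]``) or MGF.

    For MGF, ``mode='precursor'`` returns one peak per spectrum (its
    PEPMASS); ``mode='fragments'`` returns every fragment peak of every
    spectrum. Peaks are returned sorted by m/z.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("mgf" if path.suffix.lower() == ".mgf" else "csv")
    if fmt == "mgf":
        peaks = _read_mgf_peaks(path, mode)
    elif fmt == "csv":
        peaks = _read_csv_peaks(path)
    else:
        raise ValueError(f"unknown peak-list format {fmt!r}")
    return sorted(peaks, key=lambda p: p.mz)


def match_ms1(peaks: Sequence[Peak], candidates: Sequence[CandidateMass],
              tol_ppm: float = 5.0,
              scan_range: Tuple[float, float] = DEFAULT_SCAN_RANGE
              ) -> List[Ms1Match]:
    """All (candidate, adduct, peak) pairs within ``tol_ppm``.

    Candidates whose theoretical m/z falls outside the scan range never
    match. The result is sorted by ascending ppm discrepancy (then by
    m/z for determinism) and is independent of input peak order.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if not candidates:
        raise ValueError("empty candidate list")
    lo, hi = scan_range
    matches: List[Ms1Match] = []
    for cand in candidates:
        for adduct, theo in cand.adduct_mzs.items():
            if not lo <= theo <= hi:
                continue
            for peak in peaks:
                delta = ppm_delta(theo, peak.mz)
                if delta <= tol_ppm:
                    matches.append(Ms1Match(cand, adduct, peak, theo,
                                            peak.mz, delta))
    matches.sort(key=lambda m: (m.delta_ppm, m.theoretical_mz, m.measured_mz,
                                m.adduct))
    return matches


def matches_to_dataframe(matches: Iterable[Ms1Match]) -> pd.DataFrame:
    """Report view mirroring the published match-table conventions:
    m/z to 4 decimals, ppm to 2, with the ppm column recomputed from the
    rounded m/z pair so the printed columns stay mutually consistent."""
    rows = []
    for m in matches:
        theo4, meas4 = round(m.theoretical_mz, 4), round(m.measured_mz, 4)
        rows.append({
            "core": m.candidate.core,
            "topology": m.candidate.topology,
            "mods": m.candidate.mods.label(),
            "adduct": m.adduct,
            "formula": m.candidate.formula.formula(),
            "theoretical_mz": theo4,
            "measured_mz": meas4,
            "delta_ppm": round(ppm_delta(theo4, meas4), 2),
            "provenance": ";".join(m.candidate.provenance),
        })
    return pd.DataFrame(rows, columns=["core", "topology", "mods", "adduct",
                                       "formula", "theoretical_mz",
                                       "measured_mz", "delta_ppm", "provenance"])
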
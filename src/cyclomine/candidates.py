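"""Combinatorial expansion of core peptides into candidate mass species.

Because the number and order of posttranslational modifications on a
given core are unknown a priori, every core is expanded into the full
cross product of topology (linear, cyclic), 0–4 hydroxylations, and —
only when the core contains both Cys and Trp — optional sulfoxidation
and optional tryptathionine bridge formation. Each state carries the
[M+H]+, [M+Na]+ and [M+K]+ adduct m/z values used for MS1 matching.

A core without Cys+Trp therefore yields exactly 10 states (2 x 5) and a
core with both yields 40 (2 x 5 x 2 x 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import pandas as pd

from .chem import (
    Adduct,
    ElementalComposition,
    ModificationState,
    Peptide,
    adduct_mz,
    apply_modifications,
    composition_of,
    monoisotopic_mass,
)

__all__ = ["EnumerationConfig", "CandidateMass", "enumerate_candidates",
           "candidate_table", "candidates_to_dataframe"]

DEFAULT_ADDUCTS = ("H", "Na", "K")


@dataclass(frozen=True)
class EnumerationConfig:
    """Bounds of the modification search space."""

    max_hydroxylations: int = 4
    topologies: Tuple[str, ...] = ("linear", "cyclic")
    adducts: Tuple[str, ...] = DEFAULT_ADDUCTS


@dataclass
class CandidateMass:
    """One (core, topology, modification state) species with its masses."""

    core: str
    topology: str
    mods: ModificationState
    formula: ElementalComposition
    neutral_mass: float
    adduct_mzs: Dict[str, float]
    provenance: Tuple[str, ...] = ()

    @property
    def key(self) -> Tuple[str, str, ModificationState]:
        return (self.core, self.topology, self.mods)

    def mz(self, adduct: str = "H") -> float:
        return self.adduct_mzs[adduct]

    def label(self) -> str:
        return f"{self.topology} {self.core} [{self.mods.label()}]"


def enumerate_candidates(core: str, config: EnumerationConfig | None = None,
                         provenance: Sequence[str] = ()) -> List[CandidateMass]:
    """All candidate mass species for one core peptide."""
    config = config or EnumerationConfig()
    has_cw = "C" in core and "W" in core
    out: List[CandidateMass] = []
    for topology in config.topologies:
        base = composition_of(Peptide(core, topology))
        for n_oh in range(config.max_hydroxylations + 1):
            for sulfoxide in ((False, True) if has_cw else (False,)):
                for bridge in ((False, True) if has_cw else (False,)):
                    mods = ModificationState(n_oh, sulfoxide, bridge)
                    comp = apply_modifications(base, mods, core)
                    neutral = monoisotopic_mass(comp)
                    mzs = {a: adduct_mz(neutral, Adduct(a)) for a in config.adducts}
                    out.append(CandidateMass(core, topology, mods, comp, neutral,
                                             mzs, tuple(provenance)))
    return out


def candidate_table(precursors: Sequence, config: EnumerationConfig | None = None
                    ) -> List[CandidateMass]:
    """Expand mined precursors into a deduplicated candidate list.

    Duplicate gene copies with the same core collapse to one candidate
    per (core, topology, mods) whose provenance lists every contributing
    precursor id.
    """
    if not precursors:
        return []
    merged: Dict[Tuple, CandidateMass] = {}
    for prec in precursors:
        for cand in enumerate_candidates(prec.core, config, provenance=(prec.id,)):
            if cand.key in merged:
                existing = merged[cand.key]
                if prec.id not in existing.provenance:
                    existing.provenance = existing.provenance + (prec.id,)
            else:
                merged[cand.key] = cand
    return list(merged.values())


def candidates_to_dataframe(candidates: Iterable[CandidateMass]) -> pd.DataFrame:
    """Flat TSV-ready view: one row per candidate state."""
    rows = []
    for c in candidates:
        row = {
            "core": c.core,
            "topology": c.topology,
            "n_hydroxyl": c.mods.n_hydroxyl,
            "sulfoxide": c.mods.sulfoxide,
            "bridge": c.mods.bridge,
            "formula": c.formula.formula(),
            "neutral_mass": round(c.neutral_mass, 4),
            "provenance": ";".join(c.provenance),
        }
        for a, mz in c.adduct_mzs.items():
            row[f"mz_{a}"] = round(mz, 4)
        rows.append(row)
    return pd.DataFrame(rows)
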
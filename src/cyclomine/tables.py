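"""Bundled reference tables of MSDIN precursors and detected cyclic peptides.

Two small TSVs ship with the package:

* ``msdin_precursors.tsv`` — the published precursor inventory of three
  lethal *Amanita* species (86 rows): leader, core and recognition
  segments plus the printed monoisotopic mass of the (possibly modified)
  cyclic product, toxin labels where applicable, and per-gene detection /
  transcription flags where reported.
* ``detected_peptides.tsv`` — the 13 cyclic peptides confirmed by
  LC–HRMS/MS-MS (12 novel + amanexitide) with molecular formula,
  theoretical and measured [M+H]+ m/z and the printed ppm discrepancy.

These serve as ground-truth fixtures for the mass calculator and the
mining heuristics, and as leader/recognition template pools for the
synthetic-data generator.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from typing import List, Tuple

import pandas as pd

__all__ = [
    "reference_precursors",
    "detected_peptides",
    "leader_position_sets",
    "toxin_states",
]

#: Modification states that turn an unmodified cyclic core into the named
#: toxin (n_hydroxyl, sulfoxide, bridge) — recovered by enumeration, see
#: candidate_enumeration tests.
TOXIN_STATES = {
    "alpha-amanitin": (4, True, True),
    "beta-amanitin": (4, True, True),
    "phallacidin": (4, False, True),
    "phalloidin": (3, False, True),
}


def _read(name: str) -> pd.DataFrame:
    with resources.files("cyclomine.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)


@lru_cache(maxsize=None)
def reference_precursors() -> pd.DataFrame:
    """The 86 published precursor rows (species, leader, core, recognition,
    printed_mass, label, detected, expressed)."""
    df = _read("msdin_precursors.tsv")
    df["printed_mass"] = df["printed_mass"].astype(float)
    return df


@lru_cache(maxsize=None)
def detected_peptides() -> pd.DataFrame:
    """The 13 MS-confirmed cyclic peptides with printed m/z columns."""
    df = _read("detected_peptides.tsv")
    for col in ("theoretical_mz", "measured_mz", "delta_ppm"):
        df[col] = df[col].astype(float)
    return df


@lru_cache(maxsize=None)
def leader_position_sets() -> Tuple[str, ...]:
    """Per-position residue sets observed across all published 10-aa leaders.

    Position 1 is always M and position 10 always P; the inner positions
    are degenerate. Used as the default leader motif for mining.
    """
    leaders = reference_precursors()["leader"]
    sets: List[set] = [set() for _ in range(10)]
    for leader in leaders:
        for i, aa in enumerate(leader):
            sets[i].add(aa)
    return tuple("".join(sorted(s)) for s in sets)


def toxin_states() -> dict:
    return dict(TOXIN_STATES)
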
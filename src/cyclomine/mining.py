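"""Mining MSDIN-family precursor genes from protein or genome sequences.

MSDIN precursors are short (25–60 aa) proteins with a tripartite
architecture: a 10-residue leader (near-invariant, starting with M and
ending with P), a 7–11 residue core that is excised and head-to-tail
cyclised by the prolyl oligopeptidase POPB, and a C-terminal recognition
sequence that typically begins with C or S. Because POPB cleaves at Pro,
canonical cores end in Pro; a minority of published cores do not and are
flagged ``non_canonical_core``.

The mining strategy is a deterministic degenerate-motif scan: every
10-mer window matching the leader motif opens a precursor candidate, and
the downstream tail is partitioned into ranked (core, recognition)
candidates. On genomes the scan runs over all six translation frames.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

from Bio import SeqIO
from Bio.Seq import Seq

from . import tables
from .chem import RESIDUE_TABLE

__all__ = [
    "MiningConfig",
    "CoreCandidate",
    "PrecursorRecord",
    "FrameTranslation",
    "six_frame_translate",
    "find_precursors",
    "extract_core_candidates",
    "mine_genome",
    "mine_proteins",
    "compare_to_transcripts",
    "records_to_dataframe",
]

_AA = set(RESIDUE_TABLE)
_DNA_RE = re.compile(r"^[ACGTN]+$")


def default_leader_pattern() -> Tuple[str, ...]:
    """Default 10-position degenerate leader motif.

    Position 1 is fixed to M and position 10 to P; the inner positions
    allow the residue sets observed across the published leader
    inventory.
    """
    return tables.leader_position_sets()


@dataclass(frozen=True)
class MiningConfig:
    """Parameters of the precursor scan.

    leader_pattern
        Ten strings, each the allowed residues at that leader position.
    core_len_range
        Inclusive (min, max) core length; published cores span 7–11.
    min_recognition_len
        Minimum residues required downstream of a core.
    allow_non_pro_core
        Whether to emit full-window candidates when no Pro falls inside
        the core length range (captures published non-Pro cores).
    max_recognition_len
        Cap on the recognition segment when no stop codon terminates it.
    """

    leader_pattern: Tuple[str, ...] = field(default_factory=default_leader_pattern)
    core_len_range: Tuple[int, int] = (7, 11)
    min_recognition_len: int = 2
    allow_non_pro_core: bool = True
    max_recognition_len: int = 25

    def __post_init__(self) -> None:
        if len(self.leader_pattern) != 10:
            raise ValueError("leader_pattern must have exactly 10 positions")
        lo, hi = self.core_len_range
        if lo < 2 or hi < lo:
            raise ValueError(f"invalid core_len_range {self.core_len_range}")
        if self.min_recognition_len < 0:
            raise ValueError("min_recognition_len must be >= 0")

    def leader_regex(self) -> "re.Pattern[str]":
        # lookahead so overlapping windows are not skipped
        body = "".join(f"[{p}]" for p in self.leader_pattern)
        return re.compile(f"(?=({body}))")


@dataclass(frozen=True)
class CoreCandidate:
    """One ranked (core, recognition) partition of a precursor tail."""

    core: str
    recognition: str
    rank: int
    flags: frozenset

    @property
    def core_ends_pro(self) -> bool:
        return "core_ends_pro" in self.flags


@dataclass
class PrecursorRecord:
    """One mined MSDIN precursor with its leader/core/recognition partition.

    Coordinates are 0-based half-open on the forward strand of the source
    sequence (nucleotides when mined from DNA, residues when mined from a
    protein). ``candidates`` holds the full ranked partition list; the
    record-level ``core``/``recognition`` are the top-ranked candidate.
    """

    id: str
    full_sequence: str
    leader: str
    core: str
    recognition: str
    source_id: str
    start: int
    end: int
    strand: str = "+"
    frame: Optional[int] = None
    flags: frozenset = frozenset()
    candidates: Tuple[CoreCandidate, ...] = ()

    def __post_init__(self) -> None:
        if self.leader + self.core + self.recognition != self.full_sequence:
            raise ValueError("leader|core|recognition must reconstruct full_sequence")


@dataclass(frozen=True)
class FrameTranslation:
    """A single reading-frame translation of a nucleotide sequence."""

    strand: str
    frame: int
    protein: str


def _translate_frame(dna: str, frame: int) -> str:
    sub = dna[frame : frame + 3 * ((len(dna) - frame) // 3)]
    if not sub:
        return ""
    prot = str(Seq(sub).translate())
    # biopython renders fully/partially ambiguous codons as X already
    return prot


def six_frame_translate(dna: str) -> List[FrameTranslation]:
    """All six reading-frame translations of a DNA sequence.

    Stop codons are rendered ``*`` and N-containing codons ``X``. The
    reverse frames translate the reverse complement; frame ``f`` on
    strand ``-`` starts at offset ``f`` of the reverse complement.
    """
    dna = dna.upper()
    if len(dna) < 3:
        raise ValueError("sequence shorter than one codon")
    m = _DNA_RE.match(dna)
    if not m:
        bad = next(i for i, c in enumerate(dna) if c not in "ACGTN")
        raise ValueError(f"illegal nucleotide {dna[bad]!r} at position {bad}")
    rc = str(Seq(dna).reverse_complement())
    out = []
    for frame in range(3):
        out.append(FrameTranslation("+", frame, _translate_frame(dna, frame)))
    for frame in range(3):
        out.append(FrameTranslation("-", frame, _translate_frame(rc, frame)))
    return out


def extract_core_candidates(tail: str, config: MiningConfig | None = None
                            ) -> List[CoreCandidate]:
    """Partition a post-leader tail into ranked (core, recognition) pairs.

    One candidate is generated per Pro whose position falls inside the
    core length range (the core ends at that Pro). If no Pro lies in
    range and ``allow_non_pro_core`` is set, one full-window candidate is
    generated per allowed length, flagged ``non_canonical_core``.

    Ranking (best first): recognition begins with C or S, then core ends
    with P, then longer cores.
    """
    config = config or MiningConfig()
    lo, hi = config.core_len_range
    tail = tail.split("*")[0]
    if len(tail) < lo + config.min_recognition_len:
        return []
    raw: List[Tuple[str, str, set]] = []
    pro_positions = [
        p for p in range(lo, min(hi, len(tail) - config.min_recognition_len) + 1)
        if tail[p - 1] == "P"
    ]
    if pro_positions:
        for p in pro_positions:
            raw.append((tail[:p], tail[p:], {"core_ends_pro"}))
    elif config.allow_non_pro_core:
        for p in range(lo, min(hi, len(tail) - config.min_recognition_len) + 1):
            raw.append((tail[:p], tail[p:], {"non_canonical_core"}))
    candidates = []
    for core, recognition, flags in raw:
        if not set(core) <= _AA:
            continue
        recognition = recognition[: config.max_recognition_len]
        if recognition[:1] in ("C", "S"):
            flags.add("recognition_starts_CS")
        candidates.append((core, recognition, flags))
    candidates.sort(
        key=lambda t: ("recognition_starts_CS" in t[2], "core_ends_pro" in t[2],
                       len(t[0])),
        reverse=True,
    )
    return [
        CoreCandidate(core, recognition, rank, frozenset(flags))
        for rank, (core, recognition, flags) in enumerate(candidates)
    ]


def find_precursors(protein: str, config: MiningConfig | None = None,
                    source_id: str = "", strand: str = "+",
                    frame: Optional[int] = None) -> List[PrecursorRecord]:
    """Scan a protein string for leader-motif windows and build records.

    Records never cross a stop (``*``); the recognition segment runs to
    the first stop or to ``max_recognition_len`` residues. Coordinates
    are residue offsets into ``protein``.
    """
    config = config or MiningConfig()
    pattern = config.leader_regex()
    records: List[PrecursorRecord] = []
    for m in pattern.finditer(protein):
        i = m.start()
        leader = m.group(1)
        tail = protein[i + 10 : i + 10 + config.core_len_range[1]
                       + config.max_recognition_len]
        candidates = extract_core_candidates(tail, config)
        if not candidates:
            continue
        top = candidates[0]
        full = leader + top.core + top.recognition
        records.append(
            PrecursorRecord(
                id=f"{source_id or 'seq'}:{i}",
                full_sequence=full,
                leader=leader,
                core=top.core,
                recognition=top.recognition,
                source_id=source_id,
                start=i,
                end=i + len(full),
                strand=strand,
                frame=frame,
                flags=top.flags,
                candidates=tuple(candidates),
            )
        )
    return records


def _genome_coordinates(rec: PrecursorRecord, seq_len: int) -> PrecursorRecord:
    """Map residue coordinates in a frame translation to forward-strand
    nucleotide coordinates."""
    aa_start, aa_end = rec.start, rec.end
    frame = rec.frame or 0
    nt_start = frame + 3 * aa_start
    nt_end = frame + 3 * aa_end
    if rec.strand == "-":
        nt_start, nt_end = seq_len - nt_end, seq_len - nt_start
    return replace(rec, start=nt_start, end=nt_end,
                   id=f"{rec.source_id}:{nt_start}-{nt_end}({rec.strand})")


def _read_fasta(path) -> List:
    path = Path(path)
    if path.suffix == ".gz":
        import gzip

        with gzip.open(path, "rt") as fh:
            records = list(SeqIO.parse(fh, "fasta"))
    else:
        records = list(SeqIO.parse(str(path), "fasta"))
    if not records or any(len(r.seq) == 0 for r in records):
        raise ValueError(f"empty or unreadable FASTA: {path}")
    return records


def mine_genome(fasta_path, config: MiningConfig | None = None
                ) -> List[PrecursorRecord]:
    """Mine precursors from all six frames of every sequence in a FASTA.

    Returns records in deterministic (source, start) order with 0-based
    half-open forward-strand nucleotide coordinates.
    """
    config = config or MiningConfig()
    out: List[PrecursorRecord] = []
    for seq_record in _read_fasta(fasta_path):
        dna = str(seq_record.seq).upper()
        for ft in six_frame_translate(dna):
            hits = find_precursors(ft.protein, config, source_id=seq_record.id,
                                   strand=ft.strand, frame=ft.frame)
            out.extend(_genome_coordinates(r, len(dna)) for r in hits)
    out.sort(key=lambda r: (r.source_id, r.start, r.strand))
    return out


def mine_proteins(fasta_path, config: MiningConfig | None = None
                  ) -> List[PrecursorRecord]:
    """Mine precursors from a protein FASTA (residue coordinates)."""
    config = config or MiningConfig()
    out: List[PrecursorRecord] = []
    for seq_record in _read_fasta(fasta_path):
        out.extend(find_precursors(str(seq_record.seq).upper(), config,
                                   source_id=seq_record.id))
    out.sort(key=lambda r: (r.source_id, r.start))
    return out


def compare_to_transcripts(precursors: Sequence[PrecursorRecord],
                           transcripts_fasta) -> Tuple[List[bool], float]:
    """Flag each precursor as expressed and summarise the fraction.

    A precursor counts as expressed when its full protein sequence
    appears as an exact substring of any forward-frame translation of
    any transcript. Returns (per-precursor flags, percent expressed
    rounded to one decimal).
    """
    if not precursors:
        raise ValueError("empty precursor list")
    translations: List[str] = []
    for rec in SeqIO.parse(str(transcripts_fasta), "fasta"):
        dna = str(rec.seq).upper()
        for frame in range(3):
            if len(dna) - frame >= 3:
                translations.append(_translate_frame(dna, frame))
    flags = [
        any(p.full_sequence in t for t in translations) for p in precursors
    ]
    percent = round(100.0 * sum(flags) / len(flags), 1)
    return flags, percent


def records_to_dataframe(records: Iterable[PrecursorRecord]):
    """Flatten records into a DataFrame matching the TSV export columns."""
    import pandas as pd

    rows = []
    for r in records:
        rows.append({
            "id": r.id, "source": r.source_id, "start": r.start, "end": r.end,
            "strand": r.strand, "frame": "" if r.frame is None else r.frame,
            "leader": r.leader, "core": r.core, "recognition": r.recognition,
            "flags": ",".join(sorted(r.flags)),
        })
    return pd.DataFrame(rows, columns=["id", "source", "start", "end", "strand",
                                       "frame", "leader", "core", "recognition",
                                       "flags"])
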
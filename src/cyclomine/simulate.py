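"""Seeded synthetic genomes, transcriptomes and mass-spectral peak lists.

The generator emulates the statistical structure the pipeline assumes:

* genomes — i.i.d. GC-weighted background DNA (default GC 0.46, matching
  sequenced lethal *Amanita* assemblies) with precursor genes embedded at
  random non-overlapping positions on either strand, each gene a
  codon-random reverse translation of a leader+core+recognition protein
  terminated by a stop codon;
* transcriptomes — a chosen fraction of the embedded genes wrapped in
  random UTR padding;
* MS1 peak lists — one [M+H]+ peak per candidate (Na/K adducts with
  configured probabilities) with multiplicative ppm-scale mass error
  (Normal, truncated at +-3 sd) restricted to the 500–1700 m/z scan
  range, plus uniform decoy peaks;
* MS/MS spectra — y ions guaranteed, b and immonium ions emitted with
  configured probabilities, Gaussian m/z jitter, rank-exponential
  intensities, plus uniform noise peaks.

Every generator draws from a numpy Generator derived from the config
seed, so outputs are bit-reproducible.

What this does NOT emulate: introns and splicing, codon-usage bias,
chromatography, isotope envelopes, or realistic instrument noise — see
the package methods note for the implications.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from . import tables
from .chem import RESIDUE_TABLE, InvalidSequenceError, adduct_mz
from .ms1 import DEFAULT_SCAN_RANGE, Peak
from .ms2 import Ms2Spectrum, theoretical_ions

__all__ = ["SimConfig", "SimulatedPrecursor", "generate_precursor",
           "reverse_translate", "generate_genome", "generate_transcriptome",
           "simulate_ms1", "simulate_ms2", "write_dataset"]

#: Codons per amino acid (standard genetic code), plus stop codons.
_CODONS: Dict[str, List[str]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    _CODONS.setdefault(aa, []).append(codon)
for aa in _CODONS:
    _CODONS[aa].sort()
_STOP_CODONS = sorted(standard_dna_table.stop_codons)

#: Residue weights for random cores, biased towards the residues that
#: dominate published Amanita cyclic peptides (Pro, Phe, Ile).
_CORE_RESIDUES = "PFILVATSGYHNDEKRQWMC"
_CORE_WEIGHTS = np.array([6.0, 5.0, 4.0, 2.0, 2.0, 1.5, 1.5, 1.0, 1.0, 1.0,
                          1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 0.5, 0.5, 0.5])
_CORE_WEIGHTS = _CORE_WEIGHTS / _CORE_WEIGHTS.sum()


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the synthetic benchmark.

    Defaults: 20 embedded genes in 1 Mbp of GC-0.46 background, cores of
    7–11 residues, 18/22 of genes transcribed, 1.5 ppm MS1 mass error
    (so observed discrepancies span the 0–4.5 ppm range reported for
    real matches), noiseless MS/MS m/z, 100 MS1 decoy peaks.
    """

    seed: int = 0
    n_genes: int = 20
    background_length: int = 1_000_000
    background_gc: float = 0.46
    core_length_range: Tuple[int, int] = (7, 11)
    expressed_fraction: float = 18 / 22
    ms1_ppm_sd: float = 1.5
    ms2_jitter_sd: float = 0.0
    n_noise_peaks: int = 100
    ms2_n_noise_peaks: int = 0
    adduct_probabilities: Tuple[Tuple[str, float], ...] = (("Na", 0.5), ("K", 0.3))
    b_ion_probability: float = 0.7
    immonium_probability: float = 1.0
    scan_range: Tuple[float, float] = DEFAULT_SCAN_RANGE

    def __post_init__(self) -> None:
        for name in ("background_gc", "expressed_fraction",
                     "b_ion_probability", "immonium_probability"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class SimulatedPrecursor:
    """One generated precursor gene: protein, coding DNA and its parts."""

    core: str
    leader: str
    recognition: str
    protein: str
    dna: str  # CDS including the stop codon


def reverse_translate(protein: str, rng: np.random.Generator,
                      add_stop: bool = True) -> str:
    """Codon-random reverse translation (uniform over synonymous codons)."""
    codons = []
    for aa in protein:
        options = _CODONS.get(aa)
        if options is None:
            raise InvalidSequenceError(f"cannot reverse-translate residue {aa!r}")
        codons.append(options[rng.integers(len(options))])
    if add_stop:
        codons.append(_STOP_CODONS[rng.integers(len(_STOP_CODONS))])
    return "".join(codons)


def random_core(rng: np.random.Generator,
                length_range: Tuple[int, int] = (7, 11),
                end_pro: bool = True) -> str:
    """A random core peptide with Amanita-like residue frequencies."""
    n = int(rng.integers(length_range[0], length_range[1] + 1))
    letters = rng.choice(list(_CORE_RESIDUES), size=n, p=_CORE_WEIGHTS)
    core = "".join(letters)
    if end_pro:
        core = core[:-1] + "P"
    return core


def generate_precursor(core: Optional[str] = None,
                       rng: Optional[np.random.Generator] = None,
                       length_range: Tuple[int, int] = (7, 11)
                       ) -> SimulatedPrecursor:
    """Build one precursor around a core, sampling published leader and
    recognition templates; the DNA is a codon-random reverse translation."""
    rng = rng if rng is not None else np.random.default_rng()
    ref = tables.reference_precursors()
    if core is None:
        core = random_core(rng, length_range)
    else:
        for i, aa in enumerate(core):
            if aa not in RESIDUE_TABLE:
                raise InvalidSequenceError(
                    f"unknown residue {aa!r} at position {i} in core {core!r}")
    leader = ref["leader"].iloc[int(rng.integers(len(ref)))]
    recognition = ref["recognition"].iloc[int(rng.integers(len(ref)))]
    protein = leader + core + recognition
    dna = reverse_translate(protein, rng)
    return SimulatedPrecursor(core, leader, recognition, protein, dna)


def _background_dna(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    probs = np.array([(1 - gc) / 2, (1 - gc) / 2, gc / 2, gc / 2])
    return rng.choice(np.array(list("ATGC")), size=length, p=probs)


def generate_genome(config: SimConfig,
                    rng: Optional[np.random.Generator] = None,
                    cores: Optional[Sequence[str]] = None
                    ) -> Tuple[str, pd.DataFrame, List[SimulatedPrecursor]]:
    """A synthetic genome with embedded precursor genes and its truth table.

    Returns (genome sequence, truth DataFrame with columns core/leader/
    recognition/start/end/strand, precursor list). Coordinates are
    0-based half-open forward-strand positions of the CDS excluding the
    stop codon. Raises if the genes cannot be placed without overlap.
    """
    rng = rng if rng is not None else config.rng()
    n = config.n_genes if cores is None else len(cores)
    precursors = [
        generate_precursor(None if cores is None else cores[i], rng,
                           config.core_length_range)
        for i in range(n)
    ]
    total_gene_len = sum(len(p.dna) for p in precursors)
    if config.background_length < max(200 * n, 2 * total_gene_len):
        raise ValueError("background too short to place genes without crowding")
    genome = _background_dna(config.background_length, config.background_gc, rng)
    placed: List[Tuple[int, int]] = []
    rows = []
    for i, prec in enumerate(precursors):
        gene_len = len(prec.dna)
        for _ in range(1000):
            start = int(rng.integers(0, config.background_length - gene_len))
            end = start + gene_len
            if all(end <= s or start >= e for s, e in placed):
                break
        else:
            raise ValueError("could not place gene without overlap")
        placed.append((start, end))
        strand = "+" if rng.random() < 0.5 else "-"
        insert = prec.dna if strand == "+" else _revcomp(prec.dna)
        genome[start:end] = list(insert)
        stop_len = 3
        if strand == "+":
            cds_start, cds_end = start, end - stop_len
        else:
            cds_start, cds_end = start + stop_len, end
        rows.append({"gene_id": f"gene{i:03d}", "core": prec.core,
                     "leader": prec.leader, "recognition": prec.recognition,
                     "start": cds_start, "end": cds_end, "strand": strand})
    columns = ["gene_id", "core", "leader", "recognition", "start", "end",
               "strand"]
    truth = (pd.DataFrame(rows, columns=columns)
             .sort_values("start").reset_index(drop=True))
    return "".join(genome), truth, precursors


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


def generate_transcriptome(precursors: Sequence[SimulatedPrecursor],
                           expressed_fraction: float,
                           rng: np.random.Generator,
                           utr_length: Tuple[int, int] = (10, 60)
                           ) -> Tuple[List[str], List[bool]]:
    """Transcripts for ``round(fraction * n)`` randomly chosen genes.

    Each transcript is the precursor CDS flanked by random UTR padding.
    Returns (transcript sequences, per-precursor expressed flags).
    """
    if not 0 <= expressed_fraction <= 1:
        raise ValueError("expressed_fraction must be in [0, 1]")
    n = len(precursors)
    n_expressed = round(expressed_fraction * n)
    chosen = set(rng.choice(n, size=n_expressed, replace=False).tolist())
    transcripts = []
    flags = []
    for i, prec in enumerate(precursors):
        expressed = i in chosen
        flags.append(expressed)
        if expressed:
            up = "".join(_background_dna(int(rng.integers(*utr_length)), 0.46, rng))
            down = "".join(_background_dna(int(rng.integers(*utr_length)), 0.46, rng))
            transcripts.append(up + prec.dna + down)
    return transcripts, flags


def _truncated_ppm_error(rng: np.random.Generator, sd_ppm: float) -> float:
    if sd_ppm == 0:
        return 0.0
    while True:
        x = rng.normal(0.0, sd_ppm)
        if abs(x) <= 3 * sd_ppm:
            return x


def simulate_ms1(candidates: Sequence, config: SimConfig,
                 rng: Optional[np.random.Generator] = None) -> List[Peak]:
    """An MS1 peak list for a set of candidate species.

    Each candidate always yields its [M+H]+ peak (if inside the scan
    range), Na/K adduct peaks with the configured probabilities, all
    with multiplicative Normal ppm error truncated at +-3 sd; plus
    ``n_noise_peaks`` uniform decoy peaks across the scan range.
    """
    rng = rng if rng is not None else config.rng()
    lo, hi = config.scan_range
    adduct_probs = dict(config.adduct_probabilities)
    peaks: List[Peak] = []
    for cand in candidates:
        for adduct, theo in cand.adduct_mzs.items():
            prob = 1.0 if adduct == "H" else adduct_probs.get(adduct, 0.0)
            if rng.random() >= prob:
                continue
            if not lo <= theo <= hi:
                continue
            err = _truncated_ppm_error(rng, config.ms1_ppm_sd)
            mz = theo * (1 + err * 1e-6)
            peaks.append(Peak(mz, float(rng.exponential(1e5))))
    for _ in range(config.n_noise_peaks):
        peaks.append(Peak(float(rng.uniform(lo, hi)), float(rng.exponential(1e3))))
    return sorted(peaks, key=lambda p: p.mz)


def simulate_ms2(core: str, config: SimConfig,
                 rng: Optional[np.random.Generator] = None) -> Ms2Spectrum:
    """A fragment spectrum of a cyclic core's written-orientation ions.

    All y ions are emitted; b ions and immonium ions with configured
    probabilities; Gaussian m/z jitter of sd ``ms2_jitter_sd`` Da;
    intensities follow a decorative rank-exponential model; optional
    uniform noise peaks.
    """
    rng = rng if rng is not None else config.rng()
    ions = theoretical_ions(core, ("y", "b", "immonium"))
    emitted: List[float] = []
    for ion in ions:
        if ion.series == "y":
            p = 1.0
        elif ion.series == "b":
            p = config.b_ion_probability
        else:
            p = config.immonium_probability
        if rng.random() < p:
            emitted.append(ion.mz + (rng.normal(0.0, config.ms2_jitter_sd)
                                     if config.ms2_jitter_sd else 0.0))
    order = rng.permutation(len(emitted))
    peaks = [
        Peak(mz, float(1e5 * np.exp(-0.2 * rank)))
        for mz, rank in zip(emitted, order)
    ]
    if config.ms2_n_noise_peaks:
        lo = 50.0
        hi = max(i.mz for i in ions) + 50.0
        for _ in range(config.ms2_n_noise_peaks):
            peaks.append(Peak(float(rng.uniform(lo, hi)),
                              float(rng.exponential(1e3))))
    from .chem import peptide_mass
    precursor = adduct_mz(peptide_mass(core, "cyclic"), "H")
    return Ms2Spectrum(precursor_mz=precursor, peaks=peaks)


def write_dataset(config: SimConfig, out_dir) -> Dict[str, str]:
    """Generate and write a full synthetic dataset to ``out_dir``.

    Writes genome and transcriptome FASTA, MS1 peak CSV, per-core MS/MS
    MGF, a truth table TSV and a JSON manifest recording the seed and
    paths. Returns the manifest dict.
    """
    from pyteomics import mgf as mgf_writer

    from .candidates import enumerate_candidates

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = config.rng()
    genome, truth, precursors = generate_genome(config, rng)
    transcripts, flags = generate_transcriptome(precursors,
                                                config.expressed_fraction, rng)
    truth["expressed"] = flags

    genome_path = out / "genome.fasta"
    genome_path.write_text(">synthetic_genome\n" + _wrap(genome) + "\n")
    tx_path = out / "transcriptome.fasta"
    with open(tx_path, "w") as fh:
        for i, t in enumerate(transcripts):
            fh.write(f">transcript{i:03d}\n{_wrap(t)}\n")

    candidates = []
    for i, prec in enumerate(precursors):
        for cand in enumerate_candidates(prec.core, provenance=(f"gene{i:03d}",)):
            if cand.topology == "cyclic" and cand.mods.is_unmodified:
                candidates.append(cand)
    peaks = simulate_ms1(candidates, config, rng)
    ms1_path = out / "ms1_peaks.csv"
    with open(ms1_path, "w") as fh:
        fh.write("mz,intensity\n")
        for p in peaks:
            fh.write(f"{p.mz:.6f},{p.intensity:.1f}\n")

    ms2_path = out / "ms2_spectra.mgf"
    spectra = []
    for i, prec in enumerate(precursors):
        spec = simulate_ms2(prec.core, config, rng)
        spectra.append({
            "m/z array": np.array(spec.mz_array()),
            "intensity array": np.array([p.intensity for p in spec.peaks]),
            "params": {"title": f"gene{i:03d}", "pepmass": spec.precursor_mz},
        })
    mgf_writer.write(spectra, str(ms2_path), file_mode="w")

    truth_path = out / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)

    manifest = {
        "seed": config.seed,
        "n_genes": config.n_genes,
        "genome": genome_path.name,
        "transcriptome": tx_path.name,
        "ms1_peaks": ms1_path.name,
        "ms2_spectra": ms2_path.name,
        "truth": truth_path.name,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def _wrap(seq: str, width: int = 80) -> str:
    return "\n".join(seq[i:i + width] for i in range(0, len(seq), width))
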
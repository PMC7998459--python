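# Methods

## Scope and model

`cyclomine` implements the desk-scale peptidogenomics workflow for
MSDIN-family cyclic peptides: precursor-gene mining, combinatorial mass
prediction, MS1 ppm matching, and MS/MS sequence assignment, together
with a generator of synthetic study data. Genome and transcriptome
assembly, chromatography, external search engines, intron-aware gene
models and toxicology are out of scope.

## Mass arithmetic

All mass computation is integer element bookkeeping over C, H, N, O, S.
A residue is the amino acid minus one water; a linear peptide is the
residue sum plus H₂O; a head-to-tail cyclic peptide is the residue sum
exactly (cyclisation releases one water, 18.010565 Da). Monoisotopic
masses use principal-isotope masses C 12 (exact), H 1.00782503,
N 14.00307401, O 15.99491462, S 31.97207069; adduct ions use cation
masses H⁺ 1.007276, Na⁺ 22.989218, K⁺ 38.963158 and
m/z = (M + z·m_cation)/z. The proton (not hydrogen-atom) mass is used
for [M+H]⁺ because it reproduces the published ion values (e.g.
1108.6321 → 1109.6394); the hydrogen-atom mass would give 1109.6399.

Posttranslational modifications of the amatoxin/phallotoxin class are
composition deltas only — each hydroxylation +O (at most four),
sulfoxidation +O, tryptathionine bridge −2 H — with no site
localisation; sulfoxide and bridge are gated on the presence of both
Cys and Trp in the core, following the biosynthetic rule rather than
general thioether chemistry. Epimerisation is mass-silent and not
enumerated. Because the number and order of modifications on any given
core are unknown, candidates are generated as the full cross product
(10 states per core, 40 when Cys and Trp are both present), and the
mature toxin masses (α-/β-amanitin, phallacidin, phalloidin) are
*recovered by enumeration* rather than asserted from known structures.

Values are stored at full double precision and rounded only for
reports: m/z to 4 decimals, ppm to 2, matching the conventions of the
published tables. Report-level ppm is computed from the rounded m/z
pair so the printed columns of a match table stay mutually consistent.
Several published reference values carry last-digit wobble relative to
their own molecular formulas (up to ~0.3 mDa); all reproductions are
therefore asserted at ±0.0005 Da.

The isotopic-distribution routine convolves per-element isotope
spectra (repeated squaring over atom counts) into bins of configurable
width (default 0.01 Da), tracking abundance-weighted mean masses per
bin, pruning below 10⁻¹² relative abundance and renormalising to unit
sum. Only monoisotopic masses feed the pipeline; the distribution is
provided for envelope inspection.

## Precursor mining

Published MSDIN leaders are uniformly 10 residues, start with Met and
end with Pro, with limited variation at interior positions. Mining is
a deterministic degenerate-motif scan: the default pattern fixes
position 1 = M and position 10 = P and allows, at each interior
position, exactly the residue set observed across the bundled
86-leader inventory. This replaces the homology search of the original
workflow (whose parameters are not specified) with a reproducible,
user-configurable rule; loosening the pattern is a config edit.

Downstream of a leader match, the tail is partitioned into ranked
(core, recognition) candidates: one candidate per Pro within the core
length range 7–11 (POPB cleaves at Pro), or — when no Pro is in range —
one full-window candidate per length, flagged `non_canonical_core`.
Ranking prefers a recognition sequence starting with C or S, then a
Pro-terminated core, then longer cores; all candidates are retained
with their rank because the published rows include both first-Pro and
last-Pro cores, so no single cut rule fits. The recognition segment
runs to the first stop codon, capped at 25 residues; at least 2
recognition residues are required (some published rows end at contig
boundaries with only two).

Genome mining scans all six frames; coordinates are 0-based half-open
on the forward strand. Introns are not modelled: mining operates on
protein space or contiguous ORFs, a documented limitation relative to
real fungal genomes. Expression checking is an exact substring test of
the precursor protein against three-frame translations of transcripts,
summarised as a percentage rounded to one decimal.

## MS1 matching

Every (candidate, adduct, peak) pair within the ppm tolerance and
inside the scan range is reported, sorted by discrepancy. The default
tolerance is 5 ppm (published matches reach 3.43 ppm; no instrument
tolerance is stated) and the default scan range 500–1700 m/z. No
uniqueness constraint is imposed — ambiguity is resolved at MS2 — and
retention time is carried but unused.

## MS/MS assignment

Fragment ions are computed on the written (linear) core orientation:
y_k = mass of the C-terminal k residues + H₂O + proton, b_k = mass of
the N-terminal k residues + proton, immonium = residue − CO + proton.
This mirrors the manual practice that confirmed the published
peptides; a principled cyclic mode (`ring_b`: the union of b series
over all ring-opening rotations, deduplicated at 10⁻⁴ Da) is available
since a cyclic analyte has no unique terminus. The y/b tables satisfy
y_k + b_(n−k) = linear [M+H]⁺ + proton, used as a self-check.

Matching is greedy nearest-peak per theoretical ion within a tolerance
(default 0.02 Da, Q-TOF-typical; configurable as ppm). The verbal
"most or all amino acids matched" rule is quantified as residue
coverage ≥ 0.8 plus ≥ 1 matched immonium ion, where a residue position
counts as covered when pinned by consecutive matched y ions (the
y_k/y_{k+1} differential identifies residue n−k−1; y₁ identifies the
C-terminal residue) or when its residue type has immonium evidence.
One further conjunct is imposed: the spectrum's precursor m/z must
agree with the candidate's cyclic [M+H]⁺ (default 10 ppm, skipped when
no precursor is recorded). This encodes the workflow's MS1→MS2
coupling — candidates only reach MS/MS through a precursor-mass match —
and is what makes composition-distinct decoys rejectable: immonium
evidence alone cannot separate decoys drawn from the same Pro/Phe/Ile-
heavy residue pool. Leucine and isoleucine are isobaric; assignments
are invariant under I↔L substitution and results carry an
`il_ambiguous` flag.

Spectrum-to-spectrum comparison (natural vs synthetic peptide) is a
greedy nearest-first one-to-one alignment within a tolerance,
reporting the shared-ion count. Published shared-ion counts from real
instrument pairs are treated as format examples, not reproduction
targets.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes,
with defaults chosen as the study conditions:

- genome: 20 precursor genes embedded at random non-overlapping
  positions and strands in 1 Mbp of i.i.d. background at GC 0.46 (the
  sequenced assemblies report ≈46%); each gene is a codon-random
  reverse translation (uniform over synonymous codons — no *Amanita*
  codon-usage table is available) of leader + core + recognition
  sampled from the published templates, terminated by a stop codon;
- random cores: length 7–11, Pro-terminated, residue frequencies
  biased toward Pro, Phe and Ile as observed in the discovered
  peptides;
- transcriptome: round(fraction × n) genes (default 18/22) wrapped in
  random UTR padding;
- MS1: one [M+H]⁺ peak per selected candidate, Na/K adducts with
  probabilities 0.5/0.3, multiplicative mass error ~ Normal(0, 1.5 ppm)
  truncated at ±3 σ (so observed discrepancies span the 0–4.5 ppm range
  of the published matches), clipped to the 500–1700 m/z scan range,
  plus 100 uniform decoy peaks;
- MS/MS: the full y ladder, b ions with probability 0.7, immonium ions
  with probability 1.0, optional Gaussian m/z jitter (default 0 —
  noiseless), rank-exponential intensities (decorative; nothing
  depends on them).

All randomness flows from one seed through a numpy Generator, so every
artefact is bit-reproducible. The generator does **not** emulate
introns or splicing, codon-usage bias, chromatography, isotope
envelopes, profile (non-centroided) peaks, or realistic chemical
noise; passing the round-trip benchmarks therefore demonstrates
internal consistency of the pipeline, not performance on real
instrument data, where fragmentation efficiency and interference are
far less forgiving.

Benchmark problem sizes (1 Mbp / 20 genes for mining round-trips,
10 000 peaks for error-model calibration, 50 decoys for the
false-discovery check) were chosen as the smallest scales at which the
properties are meaningfully exercised.

## Configuration and outputs

A single config file (YAML or JSON) with per-stage sections drives the
CLI; unknown keys are rejected to surface typos. All output tables are
TSV with a `#` header recording tool version, config hash and seed;
exit codes are 0 (success), 2 (usage), 3 (input format).

## Known limitations

- Mining misses intron-containing genes and spliced isoforms.
- Hydroxylation and other modifications are composition-level; no
  site localisation or structure-aware enumeration.
- Charge states above 2 and negative-ion mode are unsupported; the
  element table is fixed to CHNOS.
- The assignment rule quantifies a verbal criterion; its thresholds
  (coverage 0.8, ≥1 immonium, 0.02 Da fragment tolerance) are
  documented defaults, not fitted values.
- I/L (and by extension same-composition permutations under immonium-
  only evidence) are not distinguishable from mass data alone.
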
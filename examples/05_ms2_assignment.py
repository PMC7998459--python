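"""Confirm a cyclic peptide sequence from its MS/MS spectrum.

Simulates a fragment spectrum for cyclo(AFFPPFFIPP) (CylG2), computes
theoretical y / b / immonium ions on the written core orientation, and
applies the residue-coverage rule: confirmed only when most or all
residues are explained by consecutive y-ion differentials or immonium
ions, and the precursor mass is consistent. A composition-shuffled
decoy is rejected.
"""

from cyclomine import SimConfig, assign, simulate_ms2, theoretical_ions

core = "AFFPPFFIPP"
spectrum = simulate_ms2(core, SimConfig(seed=1))

print(f"spectrum of cyclo({core}): {len(spectrum.peaks)} peaks, "
      f"precursor {spectrum.precursor_mz:.4f}")
print("\ntheoretical y-series:")
for ion in theoretical_ions(core, ("y",)):
    print(f"  y{ion.index:<2} {ion.mz:9.4f}  covers {ion.span}")

result = assign(core, spectrum)
print(f"\n{core}: {result.verdict} "
      f"(coverage {result.residue_coverage:.2f}, "
      f"immonium {sorted(result.matched_immonium)})")

decoy = "AFFEEFFIGG"  # different composition, similar look
decoy_result = assign(decoy, spectrum)
print(f"{decoy}: {decoy_result.verdict} "
      f"(coverage {decoy_result.residue_coverage:.2f})")
# Coverage 1.00 with matched immonium ions confirms the core; the decoy
# fails the precursor/coverage rule and is rejected.
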
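"""Expand a core peptide into its candidate mass species.

Each core yields linear and cyclic topologies x 0-4 hydroxylations
(x sulfoxide x Trp-Cys bridge when the core contains both C and W),
each with [M+H]+, [M+Na]+ and [M+K]+ m/z. For a Cys+Trp core the
enumeration contains the mature toxin among its 40 states.
"""

from cyclomine import enumerate_candidates

for core in ("AFFPPFFIPP", "IWGIGCNP"):
    cands = enumerate_candidates(core)
    print(f"{core}: {len(cands)} candidate states")
    for c in sorted(cands, key=lambda c: c.neutral_mass)[:4]:
        print(f"  {c.topology:<7} {c.mods.label():<22} "
              f"{c.formula.formula():<16} M={c.neutral_mass:.4f} "
              f"[M+H]+={c.mz('H'):.4f}")
    print("  ...")

amanitin = next(c for c in enumerate_candidates("IWGIGCNP")
                if c.topology == "cyclic" and c.mods.n_hydroxyl == 4
                and c.mods.sulfoxide and c.mods.bridge)
print(f"\nfully modified cyclic IWGIGCNP: {amanitin.neutral_mass:.4f} Da "
      "(alpha-amanitin)")
# The 918.3542 Da state is alpha-amanitin; the strategy is to enumerate
# every combination and let the mass spectra decide which states exist.
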
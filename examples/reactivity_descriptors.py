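"""Global reactivity descriptors and solvation energies for the panel.

Converts the bundled frontier-orbital energies (hartree) to the nine
conceptual-DFT descriptors per compound and phase, and computes the
aqueous-minus-gas solvation stabilization from total energies.  High
electrophilicity (omega) and softness (S) mark the more reactive,
more polarizable compounds.
"""

import thioscreen as ts

orbitals = ts.bundled_fixture("reactivity_inputs")
for phase in ("gas", "aqueous"):
    table = ts.descriptor_table(orbitals, phase=phase)
    print(f"\n{phase} phase (eV; S in 1/eV):")
    print(table[["compound", "e_gap", "chi", "eta", "s_soft", "omega", "n_nuc"]]
          .round(2).to_string(index=False))

energies = ts.bundled_fixture("energies_dipoles")
totals = {(r.compound_id, r.phase): r.e_total for r in energies}
print("\nsolvation stabilization (eV, negative = stabilized in water):")
for cid in ("2H", "6H", "7H", "9H"):
    de = ts.solvation_energy(totals[(cid, "gas")], totals[(cid, "aqueous")])
    print(f"  {cid}: {de:+.3f}")
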
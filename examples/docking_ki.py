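"""Verify reported inhibition constants against their binding energies.

AutoDock-convention thermodynamics: Ki = exp(dG/RT) at 298.15 K.  Every
reported Ki in both topoisomerase tables should agree with its own dG
within 1% (the spread induced by 2-decimal rounding of dG).
"""

import thioscreen as ts

for name in ("docking_alpha", "docking_beta"):
    records = ts.bundled_fixture(name)
    print(f"\n{name} ({records[0].target}):")
    for row in ts.verify_docking_table(records):
        print(f"  {row['compound']:<10s} dG {row['dg_kcalmol']:+.2f} kcal/mol  "
              f"reported {row['reported_ki_nM']:8.2f} nM  "
              f"computed {row['computed_ki_nM']:8.2f} nM  "
              f"({row['rel_error']:.2%}, {'ok' if row['passed'] else 'MISMATCH'})")
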
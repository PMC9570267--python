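"""Lipinski / Veber / Golden-Triangle screen of the panel plus etoposide.

A Lipinski score of 4 means all four oral-drug criteria hold; Veber adds
flexibility and polar-surface caps; the Golden Triangle flags the
(logD7.4, MW) sweet spot for permeability and metabolic stability.
Etoposide, the reference drug, fails both rule sets - the thiouracil
derivatives do not.
"""

import thioscreen as ts

panel = ts.bundled_fixture("physchem")
for row in ts.screen(panel):
    print(f"{row['compound']:<10s} Lipinski {row['lipinski_score']}/4 "
          f"({'pass' if row['lipinski_passed'] else 'FAIL'})  "
          f"Veber {'pass' if row['veber_passed'] else 'FAIL'}  "
          f"triangle: {row['golden_triangle']}")
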
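"""Rank quantum-chemistry methods against the X-ray geometry of thiouracil.

Loads the bundled bond-length table (12 bonds, 6 levels of theory) and
ranks each method by A%, the mean absolute deviation from experiment as a
percentage of the mean experimental bond length.  Lower is better; the
winner is the functional/basis combination used for the panel's
downstream electronic-structure work.
"""

import thioscreen as ts

table = ts.bundled_fixture("bondlengths_tu")
for rank, res in enumerate(ts.rank_methods(table), start=1):
    print(f"{rank}. {res.method:<22s} A% = {res.a_percent:.3f}")
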
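"""Generate a reproducible synthetic compound panel.

Writes the three study-shaped CSV tables (quantum, physchem, activity)
for 20 compounds with 25% of activities censored, then reloads them
through the typed readers.  Identical seeds give byte-identical files.
"""

import tempfile
from pathlib import Path

import thioscreen as ts

cfg = ts.SimulationConfig(n_compounds=20, seed=11, censor_fraction=0.25)
quantum, physchem, activity = ts.simulate_compounds(cfg)

out = Path(tempfile.mkdtemp())
for name, frame in [("quantum", quantum), ("physchem", physchem),
                    ("activity", activity)]:
    frame.to_csv(out / f"{name}.csv", index=False)
records = ts.load_table(out / "activity.csv", "activity")
present = sum(r.ic50 is not None for r in records)
print(f"wrote {out}: {len(records)} compounds, {present} activities present "
      f"({len(records) - present} censored)")
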
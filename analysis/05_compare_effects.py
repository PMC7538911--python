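#!/usr/bin/env python
"""Generated-quantity contrasts: for each rating task, subtract the
posterior exaggeration coefficients of the nuisance-transformation fit
from the target-transformation fit, draw by draw (linear and quadratic
terms).  A positive linear contrast whose CrI excludes 0 means the
transformation moves its own percept more than the other transformation
does.

Expects 04_validate_dissociation.py to have run; writes compare_table.csv
under results/.
"""

from pathlib import Path

from facetrait.pipeline import stage_compare

RUN = Path(__file__).resolve().parents[1] / "scratch" / "run"
OUT = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    table = stage_compare(RUN)
    OUT.mkdir(exist_ok=True)
    (OUT / "compare_table.csv").write_text((RUN / "compare_table.csv").read_text())
    print(table.to_string(index=False))
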
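#!/usr/bin/env python
"""Generate the synthetic study: 400-face population with two ground-truth
trait directions at cosine -0.4, and 20 raters per task on the 1-9 scale.

Writes faces.csv, ratings_<task>.csv and truth.json under scratch/run/
(raw study-scale data; the numbered scripts that follow reduce it to the
small tables kept under results/).
"""

from pathlib import Path

from facetrait.pipeline import stage_simulate

RUN = Path(__file__).resolve().parents[1] / "scratch" / "run"
OUT = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    manifest = stage_simulate(RUN, seed=0, cos_angle=-0.4, n_faces=400, n_raters=20)
    print(f"simulated model-building study -> {RUN} (run_id {manifest['run_id']})")
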
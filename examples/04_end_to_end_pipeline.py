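"""The full pipeline: simulate -> analyze -> report, on real signals.

A small cohort (12 subjects, 2 exergames) is synthesized with monotone
demand effects on mean RR, every recording is preprocessed and scored,
and the reliability grid plus validity verdicts are printed.
"""

import tempfile
from pathlib import Path

from vmhrv import CohortConfig, analyze_cohort, generate_cohort, render_report

cfg = CohortConfig(
    n_subjects=12,
    games=("Simple", "Targets"),
    true_icc=0.9,
    artifact_rate=0.01,
    seed=8,
)
table, truth, series = generate_cohort(cfg, signals=True)
print(f"generated {len(series)} recordings")

with tempfile.TemporaryDirectory() as out:
    res = analyze_cohort(table=table, series_map=series, out_dir=out)
    print(f"exclusions (failed gate or too short): {len(res['exclusions'])}")
    print()
    print(render_report(Path(out)))

# mrr_ms should come out eligible (ICC >= 0.5 at all levels) with a
# significant level effect and large pairwise effect sizes: the generator
# shortens mean RR by 60 and 120 ms as demand rises, a strong vagal-
# withdrawal signature relative to the occasion noise.
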
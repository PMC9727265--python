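#!/usr/bin/env python
"""Generate the synthetic immune-monitoring study bundle.

Writes the cohort table (141 subjects: 26 healthy controls, 65 stable and
50 infected kidney-transplant recipients, of whom 19 septic and 21
retested), the ground-truth JSON, one calibration-bead run per instrument
protocol, and event-level CSVs for a few example subjects, all under
results/synthetic_study/.
"""

import sys
from pathlib import Path

from mesfmon.pipeline import PipelineConfig, run_simulate

OUT = Path("results/synthetic_study")


def main(seed: int = 1) -> None:
    cfg = PipelineConfig(seed=seed)
    info = run_simulate(cfg, OUT)
    print(f"wrote synthetic study for {info['n_subjects']} subjects to {OUT}/")
    print("  cohort.csv        per-subject truth table (one row per timepoint)")
    print("  truth.json        full ground truth incl. TBNK counts and SOFA")
    print("  beads_*.csv       four-level bead runs, one per protocol")
    print("  events_*.csv      example event-level samples (both panels)")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
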
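#!/usr/bin/env python
"""Run the event-level standardization pipeline and report reliability.

Simulates the default four-protocol study, gates each sample, extracts
population MFIs, fits the per-protocol bead calibration, converts to
MESF, and quantifies cross-protocol agreement: the headline result is
that the intraclass correlation of the bead-calibrated MESFs is near 1
for both markers while the raw MFIs (which mix in the instrument
gain/offset) agree poorly.  Writes results/reliability.json and
results/full_report.json.
"""

import json
import sys
import warnings
from pathlib import Path

from mesfmon.pipeline import PipelineConfig, run_full_pipeline

OUT = Path("results")


def main(seed: int = 1) -> None:
    cfg = PipelineConfig(seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = run_full_pipeline(cfg)

    OUT.mkdir(exist_ok=True)
    (OUT / "full_report.json").write_text(json.dumps(report, indent=2))
    (OUT / "reliability.json").write_text(json.dumps(report["reliability"], indent=2))

    print("calibration curves (fitted slope/intercept vs generating gain/offset):")
    for pid, c in report["calibration"].items():
        print(f"  {pid:13s} slope {c['slope']:.4f}  intercept {c['intercept']:+.4f}"
              f"  R^2 {c['r_squared']:.6f}")
    print("\ncross-protocol reliability (ICC, two-way random absolute agreement):")
    for marker in ("nCD64", "mHLA-DR"):
        r = report["reliability"][marker]
        print(f"  {marker:8s} calibrated MESF ICC = {r['icc']:.3f}   "
              f"raw MFI ICC = {r['icc_raw_mfi']:.3f}")
    print(f"\nfull report -> {OUT/'full_report.json'}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
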
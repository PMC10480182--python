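#!/usr/bin/env python
"""Headline comparison: measured-TKE inlets vs the 5% intensity guess.

Runs the complete study and flags, per (model, voxel, SNR) cell,
whether the degraded-mapped boundary condition yields lower errors than
the TI-5% inlet.  Writes results/results.csv and results/comparison.csv.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from stenoflow import StudyConfig, run_all

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    cfg = StudyConfig()
    out = run_all(cfg)
    OUT.mkdir(exist_ok=True)
    out["results"].to_csv(OUT / "results.csv", index=False)
    comp = out["comparison"]
    comp.to_csv(OUT / "comparison.csv", index=False)
    sel = comp[comp["voxel_fraction"].isin([0.05, 0.10]) & (comp["snr"] >= 5.0)]
    flags = pd.concat(
        [sel["mapped_beats_TI_velocity"], sel["mapped_beats_TI_tke"]]
    ).astype(bool)
    print(sel.round(5).to_string(index=False))
    print(f"\nFor voxel sizes 5-10% and SNR >= 5, mapped TKE data beat the "
          f"5% intensity guess in {int(flags.sum())}/{len(flags)} per-cell "
          f"comparisons ({100 * flags.mean():.0f}%; TKE alone: "
          f"{int(sel['mapped_beats_TI_tke'].sum())}/{len(sel)}). Even degraded "
          "measurements carry the actual turbulence state of the flow, which "
          "an arbitrary intensity cannot.")


if __name__ == "__main__":
    main()
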
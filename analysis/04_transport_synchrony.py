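#!/usr/bin/env python
"""Synchrony of food transport with cranial expansion, per phase.

Common-lag cross-correlograms between the food's rostrocaudal velocity
and each cranial degree-of-freedom velocity, per phase and per
individual, on spacer-concatenated z-scored series. The question: does
food motion in the esophagus track cranial expansion, and at what lag?
"""

from pathlib import Path

from gulpflow.io import load_study_config
from gulpflow.pipeline import correlogram_table, run_pipeline

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cfg = load_study_config(ROOT / "scratch" / "study" / "study.yaml")
    summary = run_pipeline(cfg)
    table = correlogram_table(summary)
    # full per-individual correlograms are bulky; keep them in scratch and
    # publish the pooled-study table
    table.to_csv(ROOT / "scratch" / "correlograms_full.csv", index=False,
                 float_format="%.6g")
    out = ROOT / "results" / "correlograms.csv"
    table[table["group"] == "all"].to_csv(out, index=False, float_format="%.6g")

    for phase in ("capture", "handling", "swallowing"):
        groups = summary.synchrony.get(phase)
        if not groups:
            continue
        print(f"{phase}:")
        for dof, cc in sorted(groups["all"].items()):
            print(
                f"  {dof:<22} best lag {cc.best_lag:+3d} frames "
                f"({cc.best_lag_ms:+6.1f} ms), R^2 = {cc.best_r2:.3f}"
            )
    if "swallowing" in summary.synchrony:
        cc = summary.synchrony["swallowing"]["all"]["hyoid_retraction"]
        print(
            f"\nesophageal food transport lags hyoid retraction by "
            f"{cc.best_lag_ms:.1f} ms (R^2 {cc.best_r2:.2f}) — the generator's "
            f"configured lag is 25 ms (8 frames at 300 frames/s)"
        )
    print(f"table -> {out}")


if __name__ == "__main__":
    main()
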
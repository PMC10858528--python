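"""Discounted LY/QALY per structure and arm, incremental comparisons between
structures, and the one-way sensitivity grid.

Reads fits.json and baseline_bm.json (run 02 first), writes outcomes.csv,
comparison.csv and sensitivity.csv, and prints the incremental table with
relative differences.

    python analysis/04_summarize_outcomes.py [--out results/study]
"""

import argparse
from pathlib import Path

from oncostruct.pipeline import StudyConfig, outcomes_stage


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results/study"))
    args = ap.parse_args()

    cfg = StudyConfig()
    res = outcomes_stage(cfg, args.out)
    print("incremental outcomes (arm A - arm B), discounted at "
          f"{cfg.discount.annual_rate:.1%}/yr over {cfg.horizon_years:g} years:")
    for name, s in res["summaries"].items():
        print(f"  {name:5s} incremental LY {s.incremental('ly'):6.3f}   "
              f"incremental QALY {s.incremental('qaly'):6.3f}")
    print("\nrelative differences of incremental QALY (rounded %):")
    comp = res["comparison"].set_index("structure")
    for ref in ("PSM", "STM3"):
        print(f"  STM5 vs {ref}: {comp.loc['STM5', f'qaly_vs_{ref}_pct']:+.0f}%")
    print("\nsensitivity grid (incremental QALY):")
    piv = res["sensitivity"].pivot(index="scenario", columns="structure",
                                   values="incremental_qaly").round(3)
    print(piv.to_string())


if __name__ == "__main__":
    main()
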
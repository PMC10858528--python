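"""Fit the six parametric families to every endpoint and arm, select the
best-fitting family by information criterion, and report the ranking.

Reads endpoints/*.csv from the study directory (run 01 first), writes
fits.json and fit_ranking.csv, and prints the selected family per curve with
a proportional-hazards diagnostic for the two headline endpoints.

    python analysis/02_fit_survival.py [--out results/study]
"""

import argparse
from pathlib import Path

from oncostruct.fitting import test_proportional_hazards
from oncostruct.pipeline import StudyConfig, fit_stage, load_endpoints


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results/study"))
    ap.add_argument("--criterion", choices=("aic", "aicc", "bic"), default="aic")
    args = ap.parse_args()

    cfg = StudyConfig(selection_criterion=args.criterion)
    res = fit_stage(cfg, args.out)
    print(f"selected families ({args.criterion}):")
    for name, arms in res["fits"].items():
        chosen = ", ".join(f"{a}: {m.family}" for a, m in arms.items())
        print(f"  {name:15s} {chosen}")

    endpoints = load_endpoints(args.out)
    for name in ("os", "ttnt"):
        a, b = endpoints[name]["A"], endpoints[name]["B"]
        if a.n_events and b.n_events:
            ph = test_proportional_hazards(a, b)
            print(f"PH check {name}: HR={ph.hazard_ratio:.2f}, "
                  f"global p={ph.global_p:.3f} ({'holds' if ph.holds else 'violated'})")


if __name__ == "__main__":
    main()
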
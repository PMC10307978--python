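"""Collect the per-stage tables into the directional summary.

Reads the CSVs written by scripts 03-05 and prints, for each of the five
qualitative claims (adjacent-position correlation, unit-pair correlations,
static-vs-moving distances, static->moving decoding, moving->moving
decoding), whether the trained models reproduce its direction. Writes
results/summary.json.
"""

import json
import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"


def main(seed: int = 0) -> None:
    corr = pd.read_csv(RESULTS / f"correlation_structure_seed{seed}.csv")
    dist = pd.read_csv(RESULTS / f"static_vs_moving_seed{seed}.csv")
    deco = pd.read_csv(RESULTS / f"decoding_seed{seed}.csv")

    by = lambda df, col: df.groupby("condition")[col].mean()
    sm = dist[dist.movement == "smooth_fwd"]
    checks = {
        "adjacent_position_correlation_stec_gt_sec":
            bool(by(corr, "mean_adjacent_correlation")["stec"]
                 > by(corr, "mean_adjacent_correlation")["sec"]),
        "significant_positive_pairs_stec_gt_sec":
            bool(by(corr, "positive_significant_fraction")["stec"]
                 > by(corr, "positive_significant_fraction")["sec"]),
        "median_abs_correlation_stec_gt_sec":
            bool(by(corr, "median_abs_correlation")["stec"]
                 > by(corr, "median_abs_correlation")["sec"]),
        "diagonal_distance_stec_lt_sec":
            bool(by(sm, "mean_diagonal_distance")["stec"]
                 < by(sm, "mean_diagonal_distance")["sec"]),
        "distance_grows_with_offset_under_stec":
            bool(sm[sm.condition == "stec"]["offset_spearman_rho"].mean() > 0),
        "static_to_moving_decoding_stec_gt_sec":
            bool(deco[deco.train == "static"].groupby("condition")["accuracy"]
                 .mean()["stec"]
                 > deco[deco.train == "static"].groupby("condition")["accuracy"]
                 .mean()["sec"]),
        "moving_to_moving_decoding_stec_gt_tec":
            bool((deco[deco.train == "moving"]
                  .pivot_table(index="decoder", columns="condition", values="accuracy")
                  .eval("stec > tec")).mean() > 0.5),
    }
    summary = {"seed": seed, "directional_checks": checks}
    (RESULTS / f"summary_seed{seed}.json").write_text(json.dumps(summary, indent=2))
    for name, ok in checks.items():
        print(f"{'PASS' if ok else 'FAIL'}  {name}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
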
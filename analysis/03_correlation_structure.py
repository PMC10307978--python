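"""Smoothness of bar representations: correlation structure.

Loads the checkpoints written by 02_train_conditions.py and quantifies, for
the balanced (STEC) and spatial-only (SEC) regimes, (a) the correlation
across units between population responses to bars at adjacent positions,
(b) the fraction of unit pairs whose response trajectories to a smoothly
moving bar are significantly positively correlated, and (c) the median
absolute unit-pair correlation, with a rank-sum comparison between regimes.
Writes results/correlation_structure.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from stec.analysis import (
    collect_position_responses,
    compare_conditions_ranksum,
    mean_adjacent_correlation,
    unit_trajectory_correlations,
)
from stec.network import load_params, run_batch
from stec.stimuli import N_POSITIONS, ORIENTATIONS, rasterize_bar

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch" / "models"


def main(seed: int = 0) -> None:
    rows = []
    fractions = {}
    for cond in ("stec", "sec"):
        params, _ = load_params(SCRATCH / f"params_{cond}_seed{seed}")
        for h in ("lower", "upper"):
            per_orient_sigfrac = []
            for theta in ORIENTATIONS:
                mov = collect_position_responses(params, theta, "smooth_fwd", h, cond)
                bars = np.stack([rasterize_bar(theta, q).pixels for q in range(N_POSITIONS)])
                resp = getattr(run_batch(params, bars[None], with_generated=False), h)[:, 0]
                utc = unit_trajectory_correlations(resp)
                per_orient_sigfrac.append(utc["positive_significant_fraction"])
                rows.append(
                    {
                        "condition": cond, "hierarchy": h, "orientation": theta,
                        "mean_adjacent_correlation": mean_adjacent_correlation(mov),
                        "positive_significant_fraction": utc["positive_significant_fraction"],
                        "median_abs_correlation": float(np.median(utc["abs_correlations"])),
                    }
                )
            fractions[(cond, h)] = per_orient_sigfrac
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / f"correlation_structure_seed{seed}.csv", index=False)
    cols = [
        "mean_adjacent_correlation",
        "positive_significant_fraction",
        "median_abs_correlation",
    ]
    print(df.groupby(["condition", "hierarchy"])[cols].mean().round(3).to_string())
    for h in ("lower", "upper"):
        res = compare_conditions_ranksum(fractions[("stec", h)], fractions[("sec", h)])
        print(f"rank-sum (significant-positive fraction, {h}): "
              f"stat={res.statistic:.2f} p={res.pvalue:.3g}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
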
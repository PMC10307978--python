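"""Decoding analyses: static->moving robustness and the efficiency limit.

Static->moving: decoders are trained on noise-augmented responses to static
bars and tested on responses to smoothly moving bars (position task: 9
centered bars, chance 1/9; orientation task: 3 centered bars x 8
orientations, chance 1/8). Higher accuracy for the balanced regime (STEC)
than the spatial-only regime (SEC) indicates robustness to the erroneous
inter-hierarchy signals motion induces.

Moving->moving: the same position task trained and tested on (disjointly
augmented) moving-bar responses probes how discriminable the responses
remain; the temporal-only regime (TEC) is expected to fall below STEC here
because excessive smoothing collapses nearby stimuli onto similar
responses. Writes results/decoding.csv.
"""

import sys
from pathlib import Path

import pandas as pd

from stec._substreams import substream_seed
from stec.analysis import DECODERS, decode, moving_vs_moving_decode
from stec.network import load_params

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch" / "models"

SIGMA = 0.1
N_SAMPLES = 300


def main(seed: int = 0) -> None:
    rows = []
    params = {
        cond: load_params(SCRATCH / f"params_{cond}_seed{seed}")[0]
        for cond in ("stec", "sec", "tec")
    }
    for cond in ("stec", "sec"):
        for task in ("position", "orientation"):
            for dec in ("naive_bayes", "lda"):
                for h in ("lower", "upper"):
                    res = decode(
                        params[cond], task, dec, SIGMA,
                        seed=substream_seed(seed, "decode", cond, task, dec, h),
                        hierarchy=h, n_samples=N_SAMPLES, condition=cond,
                    )
                    rows.append(vars(res) | {"train": "static", "test": "moving"})
    for cond in ("stec", "tec"):
        for dec in DECODERS:
            res = moving_vs_moving_decode(
                params[cond], "position", dec, SIGMA,
                seed=substream_seed(seed, "mm", cond, dec),
                hierarchy="lower", n_samples=N_SAMPLES, condition=cond,
            )
            rows.append(vars(res) | {"train": "moving", "test": "moving"})
    df = pd.DataFrame(rows).drop(columns=["extra"])
    df.to_csv(RESULTS / f"decoding_seed{seed}.csv", index=False)
    print(df.groupby(["train", "condition", "task", "decoder"])["accuracy"]
          .mean().round(3))


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
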
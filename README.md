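# stec — spatio-temporally efficient coding of dynamic visual stimuli

Efficient coding holds that sensory neurons minimize informational
redundancy, but a maximally efficient code is fragile: noise in one unit
corrupts information no other unit carries, and in a *bidirectional
hierarchy* a moving stimulus adds a second, systematic error — by the time
a signal crosses levels it describes where the stimulus *was*, so top-down
and bottom-up pathways keep injecting stale information. This package
implements and analyzes a coding scheme that buys robustness against both
error sources by temporally smoothing neural responses, and studies the
resulting efficiency–robustness trade-off in simulation.

The model is a three-level hierarchy (4096-pixel input, two 64-unit
hidden hierarchies, bidirectionally fully connected, sigmoid units updated
synchronously). Its weights minimize

    L = L_Temporal + λ · L_Spatial

where `L_Temporal` penalizes step-to-step change of each level's population
response (smoothness → robustness) and `L_Spatial` is the divergence of
each unit's response distribution from a reference density over [0, 1]
(entropy maximization → efficiency; the upper hierarchy's reference is
concentrated near zero, making it sparse). The balance parameter defines
three regimes that the analyses contrast:

| λ | regime |
|---|--------|
| 5 | balanced spatio-temporal coding (STEC) |
| 1000 | spatial-only / pure efficient coding (SEC) |
| 0.01 | temporal-only / pure smoothing (TEC) |

Training material is procedurally generated: 1/f-correlated grayscale
scenes (128×192) scanned by 9-step constant-velocity gaze windows (64×64,
L∞ speed ≤ 4 px/step). Probes are binary bars (8 orientations × 41
positions, 4 px wide) presented smoothly, randomly, or statically, and
robustness is quantified by (i) correlation structure of bar responses,
(ii) Euclidean distances between static- and moving-bar responses, and
(iii) cross-condition decoding (train on static, test on moving) with six
classifier families under Gaussian stimulus noise.

## Worked example

Train the three regimes at desk scale and run the analyses (about 20
minutes on one CPU; artifacts under `results/` and `scratch/`):

```
python analysis/02_train_conditions.py 0
python analysis/03_correlation_structure.py 0
```

The training summary prints the regime trade-off (seed 0, 3000 iterations,
64 hidden units):

```
stec: final temporal=0.7671 spatial=0.0989
sec: final temporal=7.3444 spatial=0.0334
tec: final temporal=0.3860 spatial=3.1571
```

The spatial-only regime (SEC) reaches the lowest spatial term — the most
entropy-efficient code — but pays for it with a ten-fold larger temporal
term: its population responses jump between adjacent time steps. The
balanced regime keeps the temporal term an order of magnitude smaller while
staying near SEC's spatial optimum; the temporal-only regime smooths
hardest and gives up spatial efficiency entirely. The correlation analysis
then quantifies what this means for bar representations (means over 8
orientations):

```
                     mean_adjacent_correlation  positive_significant_fraction  median_abs_correlation
condition hierarchy
sec       lower                          0.751                          0.315                   0.420
          upper                          0.450                          0.550                   0.519
stec      lower                          0.973                          0.416                   0.702
          upper                          0.934                          0.631                   0.887
rank-sum (significant-positive fraction, lower): stat=3.36 p=0.000778
rank-sum (significant-positive fraction, upper): stat=1.58 p=0.115
```

Responses to bars at adjacent positions are far more similar under balanced
coding (0.97 vs 0.75 in the lower hierarchy, 0.93 vs 0.45 in the upper):
the representation changes smoothly with the stimulus — the property that
makes moving-bar responses resemble static ones and keeps decoding robust
to motion-induced stale signals. Unit pairs are also more often
significantly positively correlated under balanced coding, the signature
of redundancy that buys robustness. `04_static_vs_moving.py` and
`05_decoding.py` run the distance and decoding stages, and `06_report.py`
collects every directional claim into `results/summary.json` — at this
scale all seven report checks pass.

The same pipeline is scriptable end to end with the console entry point:

```
stec run --profile smoke          # tiny end-to-end run
stec analyze --stage distances --profile smoke
stec report --outdir scratch/run
```

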
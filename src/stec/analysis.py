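"""Robustness analyses of trained hierarchies probed with bar stimuli.

Three evaluation stages:

1. correlation structure — smoothness of population responses to a smoothly
   moving bar (response correlations at adjacent bar positions, and
   unit-pair correlations over time);
2. static-vs-moving response distances — Euclidean distance between
   responses to a static bar and to a moving bar at each position pair; a
   small diagonal means the moving-bar response matches the static-bar
   response at the same position, i.e. coding robust to the stale top-down /
   bottom-up signals a moving stimulus induces;
3. decoding — classifiers trained on (noise-augmented) static-bar responses
   and tested on moving-bar responses, for a 9-class position task and an
   8-class orientation task.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist

from ._substreams import substream, substream_seed
from .network import NetworkParams, run_batch
from .stimuli import (
    N_POSITIONS,
    ORIENTATIONS,
    make_random_bar_sequence,
    make_smooth_bar_sequences,
    noise_augment_set,
    rasterize_bar,
)

__all__ = [
    "PositionResponseSet",
    "DecodingResult",
    "DECODERS",
    "NOISE_SIGMAS",
    "N_AUGMENT",
    "collect_position_responses",
    "adjacent_position_correlation",
    "unit_trajectory_correlations",
    "compare_conditions_ranksum",
    "static_vs_moving_distance",
    "make_decoder",
    "fit_and_score",
    "build_decoding_sets",
    "decode",
    "decode_suite",
    "moving_vs_moving_decode",
    "centered_positions",
]

#: noise standard deviations of the augmentation sweep
NOISE_SIGMAS = (0.025, 0.05, 0.1, 0.2, 0.4)
#: noise-augmented response samples per stimulus, per set
N_AUGMENT = 300
#: number of position classes (centered bars) in the position task
N_POSITION_CLASSES = 9
#: centered bars per orientation in the orientation task
N_ORIENTATION_BARS = 3

MOVEMENTS = ("smooth_fwd", "smooth_bwd", "random", "static")


@dataclass
class PositionResponseSet:
    """One 64-vector of hidden responses per bar position (41 x n_units).

    For moving bars the vector at position p is the response recorded at the
    time step the bar occupies p; for static bars, the final-step response
    of a full-length static presentation of the bar at p.
    """

    condition: str
    hierarchy: str
    orientation: float
    movement: str
    responses: np.ndarray

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        if self.responses.ndim != 2 or self.responses.shape[0] != N_POSITIONS:
            raise ValueError(f"responses must be ({N_POSITIONS}, n_units)")


@dataclass
class DecodingResult:
    task: str
    decoder: str
    noise_sigma: float
    accuracy: float
    n_train: int
    n_test: int
    condition: str = ""
    hierarchy: str = ""
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# response collection


def _hidden(traj, hierarchy: str) -> np.ndarray:
    if hierarchy not in ("lower", "upper"):
        raise ValueError("hierarchy must be 'lower' or 'upper'")
    return getattr(traj, hierarchy)


def collect_position_responses(
    params: NetworkParams,
    orientation: float,
    movement: str,
    hierarchy: str,
    condition: str = "",
    static_steps: int = N_POSITIONS,
    random_seed: int = 0,
    static_readout: str = "final",
) -> PositionResponseSet:
    """Position-indexed response matrix for one orientation and movement type.

    ``static_readout``: ``final`` reads the last step of the static
    presentation; ``steady_state`` reads the first step at which the
    per-unit change from the previous step falls below 1e-6 (falling back
    to the final step if the run never settles).
    """
    if movement not in MOVEMENTS:
        raise ValueError(f"movement must be one of {MOVEMENTS}")
    if static_readout not in ("final", "steady_state"):
        raise ValueError("static_readout must be 'final' or 'steady_state'")
    bars = np.stack([rasterize_bar(orientation, p).pixels for p in range(N_POSITIONS)])
    if movement == "static":
        # 41 independent static presentations, batched
        frames = np.repeat(bars[:, None], static_steps, axis=1)
        traj = run_batch(params, frames, with_generated=False)
        series = _hidden(traj, hierarchy)  # (T, 41, units)
        if static_readout == "steady_state":
            change = np.abs(np.diff(series, axis=0)).max(axis=2)  # (T-1, 41)
            settled = change < 1e-6
            steps = np.where(
                settled.any(axis=0), settled.argmax(axis=0) + 1, series.shape[0] - 1
            )
            resp = series[steps, np.arange(N_POSITIONS)]
        else:
            resp = series[-1]  # (41, units), row p = bar at p
    elif movement in ("smooth_fwd", "smooth_bwd"):
        order = np.arange(N_POSITIONS) if movement == "smooth_fwd" else np.arange(N_POSITIONS)[::-1]
        traj = run_batch(params, bars[order][None], with_generated=False)
        steps = _hidden(traj, hierarchy)[:, 0]  # (41, units), row t = step t
        resp = np.empty_like(steps)
        resp[order] = steps  # response at the step each position is shown
    else:  # random
        seq = make_random_bar_sequence(orientation, seed=random_seed)
        traj = run_batch(params, seq.frames[None], with_generated=False)
        steps = _hidden(traj, hierarchy)[:, 0]
        resp = np.empty_like(steps)
        resp[np.asarray(seq.metadata["positions"])] = steps
    return PositionResponseSet(
        condition=condition,
        hierarchy=hierarchy,
        orientation=orientation,
        movement=movement,
        responses=resp,
    )


# ---------------------------------------------------------------------------
# correlation structure


def adjacent_position_correlation(pset: PositionResponseSet) -> np.ndarray:
    """41x41 matrix of Pearson correlations (across units) between positions.

    Entry (i, j) correlates the population vectors at bar positions i and j.
    Zero-variance rows yield NaN entries.
    """
    X = pset.responses
    flat = X.std(axis=1) <= 1e-12 * max(1.0, np.abs(X).max())
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(X)
    C[flat, :] = np.nan
    C[:, flat] = np.nan
    np.fill_diagonal(C, np.where(flat, np.nan, 1.0))
    return C


def mean_adjacent_correlation(pset: PositionResponseSet) -> float:
    """Mean correlation between responses at neighbouring positions (|i-j|=1)."""
    C = adjacent_position_correlation(pset)
    off = np.diagonal(C, offset=1)
    return float(np.nanmean(off))


def unit_trajectory_correlations(trajectory: np.ndarray) -> dict:
    """Pairwise unit correlations over time for one response trajectory.

    ``trajectory`` is (T, n_units). For every unordered unit pair, the
    Pearson correlation over time with its two-sided p-value (t distribution
    with T-2 dof). Constant units are excluded from pairing and counted.

    Returns dict with ``positive_significant_fraction`` (pairs with r > 0
    and p < 0.05, over non-constant pairs), ``abs_correlations`` (the |r|
    distribution), ``n_pairs``, ``n_excluded_pairs``.
    """
    X = np.asarray(trajectory, dtype=float)
    T, U = X.shape
    if T < 3:
        raise ValueError("need at least 3 time steps for pairwise correlation")
    sd = X.std(axis=0)
    keep = sd > 1e-12 * max(1.0, np.abs(X).max())
    n_excluded = (U * (U - 1)) // 2 - (keep.sum() * (keep.sum() - 1)) // 2
    Xk = X[:, keep]
    C = np.corrcoef(Xk, rowvar=False)
    iu = np.triu_indices(Xk.shape[1], k=1)
    r = np.clip(C[iu], -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt((T - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=T - 2)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    positive_significant = (r > 0) & (p < 0.05)
    return {
        "positive_significant_fraction": float(positive_significant.mean()) if r.size else np.nan,
        "abs_correlations": np.abs(r),
        "correlations": r,
        "p_values": p,
        "n_pairs": int(r.size),
        "n_excluded_pairs": int(n_excluded),
    }


def compare_conditions_ranksum(stat_a: np.ndarray, stat_b: np.ndarray):
    """Two-sided Wilcoxon rank-sum test between two condition statistics."""
    a = np.asarray(stat_a, dtype=float)
    b = np.asarray(stat_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    return stats.ranksums(a, b)


# ---------------------------------------------------------------------------
# static vs moving distances


def static_vs_moving_distance(
    static: PositionResponseSet, moving: PositionResponseSet
) -> np.ndarray:
    """41x41 Euclidean distances; entry (i, j) = d(static at i, moving at j)."""
    if static.responses.shape != moving.responses.shape:
        raise ValueError("response sets must have matching shapes")
    if not np.isclose(static.orientation, moving.orientation) or static.hierarchy != moving.hierarchy:
        raise ValueError("response sets must share orientation and hierarchy")
    return cdist(static.responses, moving.responses, metric="euclidean")


def offset_distance_profile(D: np.ndarray, max_offset: int = 5) -> np.ndarray:
    """Mean distance at each position offset 0..max_offset (band averages)."""
    return np.array(
        [
            np.mean(np.concatenate([np.diagonal(D, k), np.diagonal(D, -k)]) if k else np.diagonal(D))
            for k in range(max_offset + 1)
        ]
    )


# ---------------------------------------------------------------------------
# decoding


def centered_positions(n: int) -> list[int]:
    """The n position indices closest to the middle of 0..40 (index 20)."""
    mid = (N_POSITIONS - 1) // 2
    half = n // 2
    return list(range(mid - half, mid - half + n))


def make_decoder(name: str, seed: int = 0):
    """Instantiate one of the six decoder families."""
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    from sklearn.ensemble import BaggingClassifier
    from sklearn.naive_bayes import GaussianNB
    from sklearn.neural_network import MLPClassifier
    from sklearn.svm import LinearSVC
    from sklearn.tree import DecisionTreeClassifier

    if name == "naive_bayes":
        return GaussianNB()
    if name == "lda":
        return LinearDiscriminantAnalysis()
    if name == "linear_svm":
        return LinearSVC(random_state=seed)
    if name == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if name == "ensemble":
        # bagged decision trees
        return BaggingClassifier(n_estimators=100, random_state=seed, n_jobs=1)
    if name == "nn5":
        # 5-layer feed-forward net: 4 hidden relu layers + softmax output,
        # trained with the same Adam constants as the coding model and
        # stopped on a training-loss plateau
        return MLPClassifier(
            hidden_layer_sizes=(64, 64, 64, 64),
            activation="relu",
            solver="adam",
            learning_rate_init=0.001,
            beta_1=0.9,
            beta_2=0.999,
            epsilon=1e-8,
            max_iter=400,
            n_iter_no_change=10,
            tol=1e-4,
            random_state=seed,
        )
    raise ValueError(f"unknown decoder {name!r}")


DECODERS = ("naive_bayes", "lda", "linear_svm", "decision_tree", "ensemble", "nn5")


def _responses_to_noisy_stimuli(
    params: NetworkParams,
    frames: np.ndarray,
    readout_steps: np.ndarray,
    hierarchy: str,
    sigma: float,
    n_samples: int,
    master_seed: int,
    which: str,
) -> np.ndarray:
    """Hidden responses to n_samples noisy copies of a (T, H, W) sequence.

    ``readout_steps`` lists the step(s) at which to read the response.
    Returns (n_samples, len(readout_steps), n_units).
    """
    noisy = noise_augment_set(frames, sigma, n_samples, master_seed, which, dtype=np.float32)
    traj = run_batch(params, noisy, with_generated=False)
    resp = _hidden(traj, hierarchy)  # (T, n_samples, units)
    return resp[np.asarray(readout_steps)].transpose(1, 0, 2)


def build_decoding_sets(
    params: NetworkParams,
    task: str,
    hierarchy: str,
    source: str,
    noise_sigma: float,
    master_seed: int,
    which: str,
    n_samples: int = N_AUGMENT,
    orientation: float = 0.0,
    static_steps: int = N_POSITIONS,
) -> tuple[np.ndarray, np.ndarray]:
    """Build one labelled response set (X, y) for a decoding task.

    ``task``: ``position`` (9 centered bars of one orientation, chance 1/9)
    or ``orientation`` (3 centered bars per orientation, 8 classes, chance
    1/8). ``source``: ``static`` (final-step responses to static
    presentations) or ``moving`` (responses at the step each bar position is
    reached, smooth forward and backward runs pooled). Every stimulus
    contributes ``n_samples`` noise-augmented responses (noise stream named
    by ``which`` so train and test never share noise).
    """
    if task == "position":
        stimuli = [(orientation, p, p) for p in centered_positions(N_POSITION_CLASSES)]
    elif task == "orientation":
        stimuli = [
            (theta, p, k)
            for k, theta in enumerate(ORIENTATIONS)
            for p in centered_positions(N_ORIENTATION_BARS)
        ]
    else:
        raise ValueError("task must be 'position' or 'orientation'")

    Xs, ys = [], []
    for idx, (theta, pos, label) in enumerate(stimuli):
        stim_seed = substream_seed(master_seed, "decoding", which, idx)
        bar = rasterize_bar(theta, pos).pixels
        if source == "static":
            # one noise draw per sample, repeated over time: a static
            # stimulus presents a single (noisy) image with no change
            noisy = noise_augment_set(
                bar, noise_sigma, n_samples, stim_seed, which, dtype=np.float32
            )
            frames = np.repeat(noisy[:, None], static_steps, axis=1)
            traj = run_batch(params, frames, with_generated=False)
            resp = _hidden(traj, hierarchy)[-1]
        elif source == "moving":
            all_bars = np.stack(
                [rasterize_bar(theta, p).pixels for p in range(N_POSITIONS)]
            )
            half = n_samples // 2
            parts = []
            for direction, n_dir in (("fwd", half), ("bwd", n_samples - half)):
                frames = all_bars if direction == "fwd" else all_bars[::-1]
                step_at_pos = pos if direction == "fwd" else N_POSITIONS - 1 - pos
                parts.append(
                    _responses_to_noisy_stimuli(
                        params, frames, [step_at_pos], hierarchy, noise_sigma,
                        n_dir, substream_seed(stim_seed, direction), which,
                    )[:, 0]
                )
            resp = np.concatenate(parts)
        else:
            raise ValueError("source must be 'static' or 'moving'")
        Xs.append(resp)
        ys.append(np.full(len(resp), label))
    return np.concatenate(Xs), np.concatenate(ys)


def fit_and_score(
    train_set: tuple[np.ndarray, np.ndarray],
    test_set: tuple[np.ndarray, np.ndarray],
    decoder: str,
    seed: int = 0,
) -> float:
    """Fit one decoder on the training set and return test accuracy."""
    X_train, y_train = train_set
    X_test, y_test = test_set
    clf = make_decoder(decoder, seed=seed)
    if len(np.unique(y_train)) == 1:
        # degenerate single-class task: the constant predictor is exact
        return float(np.mean(y_test == y_train[0]))
    clf.fit(X_train, y_train)
    return float(np.mean(clf.predict(X_test) == y_test))


def decode(
    params: NetworkParams,
    task: str,
    decoder: str,
    noise_sigma: float,
    seed: int,
    hierarchy: str = "lower",
    train_source: str = "static",
    test_source: str = "moving",
    n_samples: int = N_AUGMENT,
    orientation: float = 0.0,
    condition: str = "",
) -> DecodingResult:
    """Train on ``train_source`` responses, test on ``test_source`` responses.

    The default static->moving direction probes robustness: high accuracy
    means moving-bar responses resemble the static-bar responses the decoder
    was trained on.
    """
    return decode_suite(
        params, task, [decoder], noise_sigma, seed, hierarchy=hierarchy,
        train_source=train_source, test_source=test_source,
        n_samples=n_samples, orientation=orientation, condition=condition,
    )[decoder]


def decode_suite(
    params: NetworkParams,
    task: str,
    decoders,
    noise_sigma: float,
    seed: int,
    hierarchy: str = "lower",
    train_source: str = "static",
    test_source: str = "moving",
    n_samples: int = N_AUGMENT,
    orientation: float = 0.0,
    condition: str = "",
) -> dict[str, DecodingResult]:
    """Run several decoder families on one shared pair of response sets.

    Building the noise-augmented response sets dominates the cost of a
    decoding run, so scoring all requested decoders against one train/test
    pair is far cheaper than calling :func:`decode` per decoder.
    """
    unknown = [d for d in decoders if d not in DECODERS]
    if unknown:
        raise ValueError(f"unknown decoder {unknown[0]!r}; choose from {DECODERS}")
    train = build_decoding_sets(
        params, task, hierarchy, train_source, noise_sigma, seed, "train",
        n_samples=n_samples, orientation=orientation,
    )
    test = build_decoding_sets(
        params, task, hierarchy, test_source, noise_sigma, seed, "test",
        n_samples=n_samples, orientation=orientation,
    )
    results = {}
    for decoder in decoders:
        acc = fit_and_score(
            train, test, decoder, seed=substream_seed(seed, "decoder", decoder)
        )
        results[decoder] = DecodingResult(
            task=task,
            decoder=decoder,
            noise_sigma=noise_sigma,
            accuracy=acc,
            n_train=len(train[1]),
            n_test=len(test[1]),
            condition=condition,
            hierarchy=hierarchy,
        )
    return results


def moving_vs_moving_decode(
    params: NetworkParams,
    task: str,
    decoder: str,
    noise_sigma: float,
    seed: int,
    test_seed: int | None = None,
    **kwargs,
) -> DecodingResult:
    """As :func:`decode` but train and test both on moving-bar responses.

    Train and test noise is drawn from disjoint substreams of ``seed``;
    passing ``test_seed`` equal to ``seed``'s train stream is rejected to
    guard against train/test leakage.
    """
    if test_seed is not None and test_seed == seed:
        raise ValueError("test_seed must differ from seed (train/test noise would be shared)")
    return decode(
        params, task, decoder, noise_sigma, seed,
        train_source="moving", test_source="moving", **kwargs,
    )
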
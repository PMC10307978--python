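"""The spatio-temporal coding objective and its training loop.

The scalar objective is

    L = L_Temporal + lambda * L_Spatial

where ``L_Temporal`` penalizes the squared change of the population response
between adjacent time steps (at the input level: the squared error between
the top-down generated input and the presented frame), and ``L_Spatial`` is
the deviation of the response distribution from a per-hierarchy reference
("compensation") density over [0, 1]. Spatial deviation is measured as the
KL divergence from a differentiable soft histogram of the responses to the
discretized compensation density: a uniform compensation density makes
minimizing it equivalent to maximizing response entropy (efficient coding),
while a density concentrated near zero additionally drives responses sparse.

The balancing parameter lambda selects the coding regime: 5 balances both
terms (spatio-temporal, STEC), 1000 makes coding spatial-only (SEC) and
0.01 temporal-only (TEC).

Gradients are computed in closed form. By default they are truncated one
step back in time: each response contributes gradient only through its own
pre-activation, never through the states that produced its inputs. Full
backpropagation through the unrolled sequence is available via the ``bptt``
flag for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._substreams import substream
from .network import Architecture, BatchTrajectory, NetworkParams, ResponseTrajectory, init_params, run_batch
from .stimuli import StimulusSequence, gaze_frames, generate_surrogate_scene

__all__ = [
    "ObjectiveConfig",
    "TrainingConfig",
    "LossReport",
    "TrainingDivergedError",
    "compensation_density",
    "soft_histogram",
    "discrete_kl",
    "temporal_loss",
    "spatial_loss",
    "total_loss",
    "loss_and_grads",
    "train",
]

LAMBDA_PRESETS = {"stec": 5.0, "sec": 1000.0, "tec": 0.01}


class TrainingDivergedError(RuntimeError):
    """Raised when the loss becomes non-finite; carries the trace so far."""

    def __init__(self, message: str, trace: pd.DataFrame):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class ObjectiveConfig:
    """Loss configuration.

    ``sparse_rate`` sets how sharply the upper hierarchy's compensation
    density concentrates near zero (bin mass proportional to
    exp(-sparse_rate * bin_center)).
    """

    lambda_: float = 5.0
    n_bins: int = 16
    compensation_lower: str = "uniform"
    compensation_upper: str = "sparse"
    sparse_rate: float = 4.0

    def __post_init__(self) -> None:
        if self.lambda_ < 0:
            raise ValueError("lambda must be non-negative")
        if self.n_bins < 2:
            raise ValueError("need at least 2 histogram bins")

    @classmethod
    def from_preset(cls, name: str, **overrides) -> "ObjectiveConfig":
        """Presets: ``stec`` (lambda=5), ``sec`` (1000), ``tec`` (0.01)."""
        key = name.lower()
        if key not in LAMBDA_PRESETS:
            raise ValueError(f"unknown preset {name!r}; choose from {sorted(LAMBDA_PRESETS)}")
        return cls(lambda_=LAMBDA_PRESETS[key], **overrides)

    def compensation(self, hierarchy: str) -> np.ndarray:
        kind = {"lower": self.compensation_lower, "upper": self.compensation_upper}[hierarchy]
        return compensation_density(kind, self.n_bins, self.sparse_rate)


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization schedule and batch geometry.

    Defaults follow the full-scale protocol: Adam(0.001, 0.9, 0.999, 1e-8),
    10^4 iterations per repetition, 5 repetitions (each repetition restart
    re-initializes the optimizer state, not the weights), minibatch 100 gaze
    sequences of 9 steps each.
    """

    adam_alpha: float = 0.001
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    iterations_per_repetition: int = 10_000
    repetitions: int = 5
    minibatch: int = 100
    steps_per_scene: int = 9
    max_speed: int = 4
    n_scenes: int = 64
    master_seed: int = 0
    bptt: bool = False
    credit_assignment: str = "combined"  # or "per_hierarchy"
    restart_weights: bool = False  # re-init weights (not just Adam) each repetition
    compute_dtype: str = "float32"  # forward/backward precision; weights stay float64
    trace_every: int = 50

    def __post_init__(self) -> None:
        if min(self.repetitions, self.minibatch, self.steps_per_scene, self.n_scenes) < 1:
            raise ValueError("counts must be positive")
        if self.iterations_per_repetition < 0:
            raise ValueError("iterations_per_repetition must be >= 0")
        if self.credit_assignment not in ("combined", "per_hierarchy"):
            raise ValueError("credit_assignment must be 'combined' or 'per_hierarchy'")


@dataclass
class LossReport:
    """One evaluation of the objective, term by term."""

    total: float
    temporal: float
    spatial: dict[str, float]
    lambda_: float

    @property
    def spatial_sum(self) -> float:
        return float(sum(self.spatial.values()))


# ---------------------------------------------------------------------------
# spatial term: soft histogram + KL to the compensation density


def compensation_density(kind: str, n_bins: int, sparse_rate: float = 4.0) -> np.ndarray:
    """Discretized compensation density as probability mass per bin.

    ``uniform`` targets maximum-entropy (non-sparse) responses; ``sparse``
    concentrates mass near zero with bin mass ~ exp(-sparse_rate * center).
    """
    centers = (np.arange(n_bins) + 0.5) / n_bins
    if kind == "uniform":
        q = np.ones(n_bins)
    elif kind == "sparse":
        q = np.exp(-sparse_rate * centers)
    else:
        raise ValueError(f"unknown compensation density {kind!r}")
    return q / q.sum()


def soft_histogram(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Differentiable histogram over [0, 1] via Gaussian soft assignment.

    Each value is assigned to all bins with weights softmax over
    -(v - center)^2 / (2 h^2), h = bin width. Returns normalized bin masses
    along the first axis of ``values`` (axis sums to 1).
    """
    v = np.asarray(values, dtype=float)
    centers = (np.arange(n_bins) + 0.5) / n_bins
    h = 1.0 / n_bins
    s = -((v[..., None] - centers) ** 2) / (2.0 * h * h)
    s -= s.max(axis=-1, keepdims=True)
    w = np.exp(s)
    w /= w.sum(axis=-1, keepdims=True)
    return w.mean(axis=0)


def discrete_kl(p: np.ndarray, q: np.ndarray) -> float:
    """KL(p || q) for probability mass vectors (0 log 0 = 0)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def spatial_loss(
    responses: np.ndarray, compensation: np.ndarray, n_bins: int | None = None
) -> float:
    """Mean over units of KL(soft histogram of unit responses || compensation).

    ``responses`` has shape (n_samples, n_units) with entries in [0, 1]
    (sigmoid outputs). Minimizing drives each unit's response distribution
    toward the compensation density.
    """
    value, _ = _spatial_loss_and_grad(responses, compensation, n_bins)
    return value


def _spatial_loss_and_grad(
    responses: np.ndarray, compensation: np.ndarray, n_bins: int | None = None
) -> tuple[float, np.ndarray]:
    z = np.asarray(responses)
    if z.dtype not in (np.float32, np.float64):
        z = z.astype(float)
    if z.ndim != 2:
        raise ValueError("responses must be (n_samples, n_units)")
    if (z < 0).any() or (z > 1).any():
        raise ValueError("responses must lie in the unit interval (sigmoid outputs)")
    q = np.asarray(compensation, dtype=z.dtype)
    K = q.size
    if n_bins is not None and n_bins != K:
        raise ValueError("n_bins disagrees with the compensation density length")
    N, U = z.shape
    centers = ((np.arange(K) + 0.5) / K).astype(z.dtype)
    h = 1.0 / K
    s = -((z[:, :, None] - centers) ** 2) / (2.0 * h * h)  # (N, U, K)
    s -= s.max(axis=-1, keepdims=True)
    w = np.exp(s)
    w /= w.sum(axis=-1, keepdims=True)
    p = w.mean(axis=0)  # (U, K)
    value = float(np.mean(np.sum(p * np.log(p / q), axis=-1)))
    # d value / d z: through the softmax assignment and the bin masses
    A = np.log(p / q) + 1.0  # (U, K)
    ds = (centers - z[:, :, None]) / (h * h)  # (N, U, K)
    Aw = A[None] * w
    grad = (Aw * ds).sum(-1) - Aw.sum(-1) * (w * ds).sum(-1)
    grad /= N * U
    return value, grad


# ---------------------------------------------------------------------------
# temporal term


def _as_batch(trajectory: ResponseTrajectory | BatchTrajectory) -> BatchTrajectory:
    if isinstance(trajectory, BatchTrajectory):
        return trajectory
    return BatchTrajectory(
        lower=trajectory.lower[:, None],
        upper=trajectory.upper[:, None],
        generated_input=trajectory.generated_input[:, None],
        stimulus=trajectory.stimulus[:, None],
    )


def temporal_loss(
    trajectory: ResponseTrajectory | BatchTrajectory,
    stimuli: StimulusSequence | np.ndarray | None = None,
) -> float:
    """Squared population change between adjacent steps, averaged over levels.

    For the hidden hierarchies: ||x_t - x_{t-1}||^2, the squared L2 norm of
    the population change, averaged over steps t = 1..T-1 (and the batch).
    For the input level: the per-pixel squared error between the generated
    input and the presented frame, rescaled by the hidden population size so
    the input term carries the same weight as a hidden level rather than
    dominating through its 4096-pixel dimensionality. The three per-level
    terms are averaged with equal weight; this scaling places the lambda
    presets in their three intended regimes (temporal-dominated / balanced /
    spatial-dominated).
    """
    batch = _as_batch(trajectory)
    T = batch.lower.shape[0]
    if T < 2:
        raise ValueError("temporal loss needs a trajectory of length >= 2")
    n_ref = batch.lower.shape[-1]
    stim = batch.stimulus
    if stimuli is not None:
        frames = stimuli.frames if isinstance(stimuli, StimulusSequence) else np.asarray(stimuli)
        if frames.ndim == 3:  # (T, H, W) for a single sequence
            stim = frames.reshape(T, 1, -1)
        elif frames.ndim == 4:  # (batch, T, H, W)
            stim = frames.reshape(frames.shape[0], T, -1).transpose(1, 0, 2)
        else:
            raise ValueError("stimuli must be (T, H, W) or (batch, T, H, W)")
    term_gen = n_ref * np.mean((batch.generated_input[1:] - stim[1:]) ** 2)
    term_lower = n_ref * np.mean((batch.lower[1:] - batch.lower[:-1]) ** 2)
    term_upper = n_ref * np.mean((batch.upper[1:] - batch.upper[:-1]) ** 2)
    return float((term_gen + term_lower + term_upper) / 3.0)


def total_loss(
    trajectory: ResponseTrajectory | BatchTrajectory,
    stimuli: StimulusSequence | np.ndarray | None,
    config: ObjectiveConfig,
) -> LossReport:
    """Combine the temporal and spatial terms with the configured lambda.

    The spatial term pools hidden responses over the batch and over time
    steps t >= 1 (the constant initial state is excluded).
    """
    batch = _as_batch(trajectory)
    temporal = temporal_loss(batch, stimuli)
    spatial = {}
    for name, arr in (("lower", batch.lower), ("upper", batch.upper)):
        pooled = arr[1:].reshape(-1, arr.shape[-1])
        spatial[name] = spatial_loss(pooled, config.compensation(name))
    total = temporal + config.lambda_ * sum(spatial.values())
    return LossReport(total=float(total), temporal=temporal, spatial=spatial, lambda_=config.lambda_)


# ---------------------------------------------------------------------------
# closed-form gradients


def loss_and_grads(
    params: NetworkParams,
    frames: np.ndarray,
    config: ObjectiveConfig,
    bptt: bool = False,
    credit_assignment: str = "combined",
) -> tuple[LossReport, dict[str, np.ndarray]]:
    """Evaluate the objective on a (batch, T, H, W) frame stack with gradients.

    With ``bptt=False`` (default) gradients are truncated one step back in
    time. With ``bptt=True`` they are propagated through the full unrolled
    recurrence; ``credit_assignment='per_hierarchy'`` then restricts the
    through-time propagation to each hierarchy's own recurrent pathway.
    """
    traj = run_batch(params, frames)
    lower, upper, gen, stim = traj.lower, traj.upper, traj.generated_input, traj.stimulus
    T, B = lower.shape[:2]
    if T < 2:
        raise ValueError("training sequences must have at least 2 frames")
    nt = T - 1
    U_l, U_u, P = lower.shape[-1], upper.shape[-1], stim.shape[-1]

    # --- loss values
    report_spatial: dict[str, float] = {}
    d_lower = np.zeros_like(lower)
    d_upper = np.zeros_like(upper)
    d_gen = np.zeros_like(gen)

    n_ref = U_l  # hidden population size; see temporal_loss on level weighting
    # temporal: generated input vs stimulus
    diff_gen = gen[1:] - stim[1:]
    term_gen = n_ref * np.mean(diff_gen**2)
    d_gen[1:] += 2.0 * n_ref * diff_gen / (3.0 * nt * B * P)
    # temporal: hidden adjacent differences (each x_t appears in the t and
    # t+1 difference; both are direct loss arguments)
    diff_l = lower[1:] - lower[:-1]
    term_lower = n_ref * np.mean(diff_l**2)
    d_lower[1:] += 2.0 * n_ref * diff_l / (3.0 * nt * B * U_l)
    d_lower[:-1] -= 2.0 * n_ref * diff_l / (3.0 * nt * B * U_l)
    diff_u = upper[1:] - upper[:-1]
    term_upper = n_ref * np.mean(diff_u**2)
    d_upper[1:] += 2.0 * n_ref * diff_u / (3.0 * nt * B * U_u)
    d_upper[:-1] -= 2.0 * n_ref * diff_u / (3.0 * nt * B * U_u)
    temporal = float((term_gen + term_lower + term_upper) / 3.0)

    # spatial: pooled over batch and steps t >= 1
    for name, arr, dst in (("lower", lower, d_lower), ("upper", upper, d_upper)):
        pooled = arr[1:].reshape(-1, arr.shape[-1])
        value, g = _spatial_loss_and_grad(pooled, config.compensation(name))
        report_spatial[name] = value
        dst[1:] += config.lambda_ * g.reshape(nt, B, -1)

    report = LossReport(
        total=float(temporal + config.lambda_ * sum(report_spatial.values())),
        temporal=temporal,
        spatial=report_spatial,
        lambda_=config.lambda_,
    )

    # --- backward: accumulate parameter gradients step by step
    grads = {n: np.zeros_like(getattr(params, n)) for n in params.weight_names()}
    carry_l = np.zeros((B, U_l))
    carry_u = np.zeros((B, U_u))
    for t in range(T - 1, 0, -1):
        delta_l = d_lower[t] + (carry_l if bptt else 0.0)
        delta_u = d_upper[t] + (carry_u if bptt else 0.0)
        G_l = delta_l * lower[t] * (1.0 - lower[t])
        G_u = delta_u * upper[t] * (1.0 - upper[t])
        G_g = d_gen[t] * gen[t] * (1.0 - gen[t])
        grads["W_il"] += stim[t - 1].T @ G_l
        grads["W_ll"] += lower[t - 1].T @ G_l
        grads["W_ul"] += upper[t - 1].T @ G_l
        grads["b_l"] += G_l.sum(axis=0)
        grads["W_lu"] += lower[t - 1].T @ G_u
        grads["W_uu"] += upper[t - 1].T @ G_u
        grads["b_u"] += G_u.sum(axis=0)
        grads["W_li"] += lower[t - 1].T @ G_g
        grads["b_i"] += G_g.sum(axis=0)
        if bptt:
            if credit_assignment == "combined":
                carry_l = G_l @ params.W_ll.T + G_u @ params.W_lu.T + G_g @ params.W_li.T
                carry_u = G_l @ params.W_ul.T + G_u @ params.W_uu.T
            else:  # per-hierarchy: only each level's own recurrent pathway
                carry_l = G_l @ params.W_ll.T
                carry_u = G_u @ params.W_uu.T
    return report, grads


# ---------------------------------------------------------------------------
# Adam + training loop


class _Adam:
    def __init__(self, shapes: dict[str, tuple], alpha, beta1, beta2, eps):
        self.alpha, self.beta1, self.beta2, self.eps = alpha, beta1, beta2, eps
        self.m = {n: np.zeros(s) for n, s in shapes.items()}
        self.v = {n: np.zeros(s) for n, s in shapes.items()}
        self.t = 0

    def update(self, params: NetworkParams, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for n, g in grads.items():
            m, v = self.m[n], self.v[n]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            denom = np.sqrt(v / (1 - b2**self.t))
            denom += self.eps
            getattr(params, n)[...] -= self.alpha / (1 - b1**self.t) * m / denom


def train(
    obj: ObjectiveConfig,
    trn: TrainingConfig,
    arch: Architecture = Architecture(),
    scenes: np.ndarray | None = None,
    init: NetworkParams | None = None,
) -> tuple[NetworkParams, pd.DataFrame]:
    """Train the hierarchy on gaze sequences over (surrogate) scenes.

    Each iteration samples a minibatch of constant-velocity gaze sequences
    from the scene pool, unrolls the network, and applies one Adam update
    from the closed-form gradients of L. Every repetition restart resets the
    Adam moments (the weights persist unless ``restart_weights``).

    Returns the trained parameters and a loss trace (columns: iteration,
    temporal, spatial_lower, spatial_upper, total).
    """
    if scenes is None:
        scenes = np.stack(
            [
                generate_surrogate_scene(s)
                for s in substream(trn.master_seed, "scene-pool").integers(
                    0, 2**31 - 1, size=trn.n_scenes
                )
            ]
        )
    params = (init.copy() if init is not None else init_params(arch, seed=trn.master_seed))
    patch = arch.frame_shape[0]
    if arch.frame_shape[0] != arch.frame_shape[1]:
        raise ValueError("training expects square stimulus frames")
    sampler = substream(trn.master_seed, "train-sampling")
    dtype = np.dtype(trn.compute_dtype)
    compute_params = params if dtype == params.W_il.dtype else params.astype(dtype)
    trace_rows: list[dict] = []
    it_global = 0
    for rep in range(trn.repetitions):
        if rep > 0 and trn.restart_weights:
            params = init_params(arch, seed=trn.master_seed + rep)
            compute_params = params if dtype == params.W_il.dtype else params.astype(dtype)
        adam = _Adam(
            {n: getattr(params, n).shape for n in params.weight_names()},
            trn.adam_alpha, trn.adam_beta1, trn.adam_beta2, trn.adam_eps,
        )
        for _ in range(trn.iterations_per_repetition):
            idx = sampler.integers(0, len(scenes), size=trn.minibatch)
            batch = np.stack(
                [
                    gaze_frames(
                        scenes[i], sampler, trn.steps_per_scene, trn.max_speed, patch
                    )[0]
                    for i in idx
                ]
            )
            report, grads = loss_and_grads(
                compute_params, batch.astype(dtype), obj,
                bptt=trn.bptt, credit_assignment=trn.credit_assignment,
            )
            if not np.isfinite(report.total):
                raise TrainingDivergedError(
                    f"loss became non-finite at iteration {it_global}",
                    pd.DataFrame(trace_rows),
                )
            if it_global % trn.trace_every == 0:
                trace_rows.append(
                    {
                        "iteration": it_global,
                        "temporal": report.temporal,
                        "spatial_lower": report.spatial["lower"],
                        "spatial_upper": report.spatial["upper"],
                        "total": report.total,
                    }
                )
            adam.update(params, grads)
            if compute_params is not params:  # refresh the low-precision copy
                for n in params.weight_names():
                    getattr(compute_params, n)[...] = getattr(params, n)
            it_global += 1
    return params, pd.DataFrame(
        trace_rows, columns=["iteration", "temporal", "spatial_lower", "spatial_upper", "total"]
    )
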
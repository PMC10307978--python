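"""The bidirectional 3-level hierarchy and its one-step dynamics.

The model has a visual input level (64x64 = 4096 units, clamped to the
stimulus), a lower hidden hierarchy and an upper hidden hierarchy (64 units
each by default). Adjacent levels are fully connected in both directions and
each hidden level has recurrent connections. One synchronous time step maps
the previous state of every level through a sigmoid:

    x_lower(t) = sigmoid(W_ul' x_upper(t-1) + W_ll' x_lower(t-1)
                         + W_il' x_input(t-1) + b_l)
    x_upper(t) = sigmoid(W_lu' x_lower(t-1) + W_uu' x_upper(t-1) + b_u)

(the topmost level has no top-down input). The lower hierarchy additionally
drives a top-down reconstruction of the input,

    g(t) = sigmoid(W_li' x_lower(t-1) + b_i),

which is compared with the true stimulus by the temporal objective; the
input level itself is always clamped to the presented frame.

Weight matrices are stored as (source_size, target_size) so a projection is
``x @ W``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np

from ._substreams import substream
from .stimuli import StimulusSequence

__all__ = [
    "Architecture",
    "NetworkParams",
    "NetworkState",
    "ResponseTrajectory",
    "init_params",
    "init_state",
    "step",
    "run",
    "save_params",
    "load_params",
]


from scipy.special import expit as _sigmoid  # numerically stable sigmoid


@dataclass(frozen=True)
class Architecture:
    """Level sizes; ``frame_shape`` is the stimulus frame, input = its size."""

    frame_shape: tuple[int, int] = (64, 64)
    n_lower: int = 64
    n_upper: int = 64

    @property
    def n_input(self) -> int:
        return self.frame_shape[0] * self.frame_shape[1]


@dataclass
class NetworkParams:
    """All weight matrices and biases of the hierarchy."""

    arch: Architecture
    W_il: np.ndarray  # input -> lower, (n_input, n_lower)
    W_ll: np.ndarray  # lower -> lower (recurrent)
    W_ul: np.ndarray  # upper -> lower (top-down)
    b_l: np.ndarray
    W_lu: np.ndarray  # lower -> upper (bottom-up)
    W_uu: np.ndarray  # upper -> upper (recurrent)
    b_u: np.ndarray
    W_li: np.ndarray  # lower -> input (top-down generation), (n_lower, n_input)
    b_i: np.ndarray

    _MATRIX_SHAPES = {
        "W_il": ("n_input", "n_lower"),
        "W_ll": ("n_lower", "n_lower"),
        "W_ul": ("n_upper", "n_lower"),
        "b_l": ("n_lower",),
        "W_lu": ("n_lower", "n_upper"),
        "W_uu": ("n_upper", "n_upper"),
        "b_u": ("n_upper",),
        "W_li": ("n_lower", "n_input"),
        "b_i": ("n_input",),
    }

    def __post_init__(self) -> None:
        for name, dims in self._MATRIX_SHAPES.items():
            arr = np.asarray(getattr(self, name))
            if arr.dtype not in (np.float32, np.float64):
                arr = arr.astype(float)
            expected = tuple(getattr(self.arch, d) for d in dims)
            if arr.shape != expected:
                raise ValueError(f"{name} must have shape {expected}, got {arr.shape}")
            if not np.isfinite(arr).all():
                raise ValueError(f"{name} contains non-finite entries")
            object.__setattr__(self, name, arr)

    def weight_names(self) -> list[str]:
        return list(self._MATRIX_SHAPES)

    def copy(self) -> "NetworkParams":
        kw = {n: getattr(self, n).copy() for n in self._MATRIX_SHAPES}
        return NetworkParams(arch=self.arch, **kw)

    def astype(self, dtype) -> "NetworkParams":
        """Copy with all arrays cast to ``dtype`` (e.g. float32 compute)."""
        kw = {n: getattr(self, n).astype(dtype) for n in self._MATRIX_SHAPES}
        return NetworkParams(arch=self.arch, **kw)


@dataclass
class NetworkState:
    """Population state at one time step (all vectors flattened)."""

    x_input: np.ndarray
    x_lower: np.ndarray
    x_upper: np.ndarray
    generated_input: np.ndarray


@dataclass
class ResponseTrajectory:
    """Per-level response time series for one presented sequence."""

    lower: np.ndarray  # (T, n_lower)
    upper: np.ndarray  # (T, n_upper)
    generated_input: np.ndarray  # (T, n_input)
    stimulus: np.ndarray  # (T, n_input), the clamped input at each step

    def __len__(self) -> int:
        return self.lower.shape[0]


def init_params(arch: Architecture = Architecture(), seed: int = 0) -> NetworkParams:
    """Gaussian init scaled by 1/sqrt(fan-in); biases zero."""
    rng = substream(seed, "weights")
    def w(n_src: int, n_dst: int) -> np.ndarray:
        return rng.normal(0.0, 1.0 / np.sqrt(n_src), size=(n_src, n_dst))

    return NetworkParams(
        arch=arch,
        W_il=w(arch.n_input, arch.n_lower),
        W_ll=w(arch.n_lower, arch.n_lower),
        W_ul=w(arch.n_upper, arch.n_lower),
        b_l=np.zeros(arch.n_lower),
        W_lu=w(arch.n_lower, arch.n_upper),
        W_uu=w(arch.n_upper, arch.n_upper),
        b_u=np.zeros(arch.n_upper),
        W_li=w(arch.n_lower, arch.n_input),
        b_i=np.zeros(arch.n_input),
    )


def _flatten_frame(frame: np.ndarray, arch: Architecture) -> np.ndarray:
    frame = np.asarray(frame, dtype=float)
    if frame.shape != arch.frame_shape:
        raise ValueError(f"frame must have shape {arch.frame_shape}, got {frame.shape}")
    return frame.reshape(-1)


def init_state(stimulus_frame: np.ndarray, arch: Architecture = Architecture()) -> NetworkState:
    """Clamp the input to the first frame; hidden levels start at 0.5.

    0.5 = sigmoid(0) is the unbiased fixed point of the activation.
    """
    x_input = _flatten_frame(stimulus_frame, arch)
    return NetworkState(
        x_input=x_input,
        x_lower=np.full(arch.n_lower, 0.5),
        x_upper=np.full(arch.n_upper, 0.5),
        generated_input=np.full(arch.n_input, 0.5),
    )


def step(params: NetworkParams, state: NetworkState, next_frame: np.ndarray) -> NetworkState:
    """One synchronous update: every new state is computed from old states."""
    for name in params.weight_names():
        if not np.isfinite(getattr(params, name)).all():
            raise FloatingPointError(f"non-finite entries in {name}")
    a_l = (
        state.x_input @ params.W_il
        + state.x_lower @ params.W_ll
        + state.x_upper @ params.W_ul
        + params.b_l
    )
    a_u = state.x_lower @ params.W_lu + state.x_upper @ params.W_uu + params.b_u
    a_g = state.x_lower @ params.W_li + params.b_i
    return NetworkState(
        x_input=_flatten_frame(next_frame, params.arch),
        x_lower=_sigmoid(a_l),
        x_upper=_sigmoid(a_u),
        generated_input=_sigmoid(a_g),
    )


def run(params: NetworkParams, sequence: StimulusSequence | np.ndarray) -> ResponseTrajectory:
    """Present a sequence frame-by-frame and record every step's responses.

    Row 0 of the trajectory is the initial state (hidden levels at 0.5,
    input clamped to the first frame); each subsequent row is one synchronous
    update. The trajectory length equals the sequence length.
    """
    frames = sequence.frames if isinstance(sequence, StimulusSequence) else np.asarray(sequence)
    if frames.ndim != 3 or frames.shape[0] == 0:
        raise ValueError("sequence must contain at least one frame")
    traj = run_batch(params, frames[None, ...])
    return ResponseTrajectory(
        lower=traj.lower[:, 0],
        upper=traj.upper[:, 0],
        generated_input=traj.generated_input[:, 0],
        stimulus=traj.stimulus[:, 0],
    )


@dataclass
class BatchTrajectory:
    """Trajectories of a batch of sequences, axes (T, batch, units)."""

    lower: np.ndarray
    upper: np.ndarray
    generated_input: np.ndarray
    stimulus: np.ndarray


def run_batch(
    params: NetworkParams, frames: np.ndarray, with_generated: bool = True
) -> BatchTrajectory:
    """Vectorized :func:`run` over a (batch, T, H, W) stack of sequences.

    ``with_generated=False`` skips the top-down input-generation pathway
    (only needed by the training objective), halving the cost of response
    collection.
    """
    frames = np.asarray(frames)
    if frames.dtype not in (np.float32, np.float64):
        frames = frames.astype(float)
    if frames.ndim != 4 or frames.shape[1] == 0:
        raise ValueError("frames must be (batch, T, H, W) with T >= 1")
    if frames.shape[2:] != params.arch.frame_shape:
        raise ValueError(
            f"frames must be {params.arch.frame_shape}, got {frames.shape[2:]}"
        )
    B, T = frames.shape[:2]
    arch = params.arch
    dtype = np.result_type(frames, params.W_il)
    stim = frames.reshape(B, T, arch.n_input).transpose(1, 0, 2).astype(dtype, copy=False)
    lower = np.empty((T, B, arch.n_lower), dtype=dtype)
    upper = np.empty((T, B, arch.n_upper), dtype=dtype)
    gen = np.empty((T, B, arch.n_input), dtype=dtype) if with_generated else None
    lower[0] = 0.5
    upper[0] = 0.5
    if with_generated:
        gen[0] = 0.5
    for t in range(1, T):
        lower[t] = _sigmoid(
            stim[t - 1] @ params.W_il
            + lower[t - 1] @ params.W_ll
            + upper[t - 1] @ params.W_ul
            + params.b_l
        )
        upper[t] = _sigmoid(
            lower[t - 1] @ params.W_lu + upper[t - 1] @ params.W_uu + params.b_u
        )
        if with_generated:
            gen[t] = _sigmoid(lower[t - 1] @ params.W_li + params.b_i)
    return BatchTrajectory(lower=lower, upper=upper, generated_input=gen, stimulus=stim)


# ---------------------------------------------------------------------------
# checkpoints: .npz array container + JSON metadata sidecar


def save_params(path_stem: str | Path, params: NetworkParams, meta: dict | None = None) -> None:
    stem = Path(path_stem)
    arrays = {n: getattr(params, n) for n in params.weight_names()}
    np.savez(stem.with_suffix(".npz"), **arrays)
    info = {
        "frame_shape": list(params.arch.frame_shape),
        "n_lower": params.arch.n_lower,
        "n_upper": params.arch.n_upper,
        **(meta or {}),
    }
    stem.with_suffix(".json").write_text(json.dumps(info, indent=2))


def load_params(path_stem: str | Path) -> tuple[NetworkParams, dict]:
    stem = Path(path_stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    arch = Architecture(
        frame_shape=tuple(meta["frame_shape"]),
        n_lower=meta["n_lower"],
        n_upper=meta["n_upper"],
    )
    with np.load(stem.with_suffix(".npz")) as data:
        arrays = {k: data[k] for k in data.files}
    return NetworkParams(arch=arch, **arrays), meta
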
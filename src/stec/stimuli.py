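"""Stimulus generation: surrogate natural scenes, gaze sequences, bars, noise.

The training material emulates grayscale natural scenes (128x192, values in
[0, 1]) with 1/f-amplitude Gaussian random fields: the coding objective only
exploits smooth second-order spatial structure, not semantic content, so a
spatially correlated random field is an adequate surrogate.

Probe stimuli are 64x64 binary bars at 8 orientations (k*pi/8) and 41
positions per orientation, presented smoothly (position 0->40 and 40->0),
in random position order, or statically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._substreams import substream

__all__ = [
    "SCENE_SHAPE",
    "PATCH_SIZE",
    "N_ORIENTATIONS",
    "N_POSITIONS",
    "BAR_WIDTH",
    "ORIENTATIONS",
    "GazeTrajectory",
    "BarFrame",
    "StimulusSequence",
    "generate_surrogate_scene",
    "sample_gaze_sequence",
    "gaze_frames",
    "adjust_velocity_magnitude",
    "rasterize_bar",
    "make_smooth_bar_sequences",
    "make_random_bar_sequence",
    "make_static_sequence",
    "add_noise",
    "noise_augment_set",
    "save_image_png",
    "load_image_png",
    "save_sequence",
    "load_sequence",
]

SCENE_SHAPE = (128, 192)
PATCH_SIZE = 64
N_ORIENTATIONS = 8
N_POSITIONS = 41
BAR_WIDTH = 4.0
#: the 8 bar orientations, k*pi/8 for k = 0..7 (0 = horizontal bar)
ORIENTATIONS = tuple(k * np.pi / 8 for k in range(N_ORIENTATIONS))


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class GazeTrajectory:
    """A constant-velocity gaze path over a scene.

    ``start`` is the (row, col) of the first patch's top-left corner;
    ``velocity`` is an integer (drow, dcol) per time step with L-inf norm
    <= the configured maximum speed.
    """

    start: tuple[int, int]
    velocity: tuple[int, int]
    n_steps: int

    def window_corners(self) -> np.ndarray:
        """(n_steps, 2) array of top-left corners, one per time step."""
        t = np.arange(self.n_steps)[:, None]
        return np.asarray(self.start)[None, :] + t * np.asarray(self.velocity)[None, :]


@dataclass(frozen=True)
class BarFrame:
    """A 64x64 binary bar image with its orientation/position labels."""

    pixels: np.ndarray
    orientation: float
    position_index: int

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.shape != (PATCH_SIZE, PATCH_SIZE):
            raise ValueError(f"bar frame must be {PATCH_SIZE}x{PATCH_SIZE}, got {px.shape}")
        if not np.isin(px, (0.0, 1.0)).all():
            raise ValueError("bar frame must be binary (0/1)")


@dataclass
class StimulusSequence:
    """An ordered list of 64x64 frames presented one per time step."""

    frames: np.ndarray  # (T, 64, 64)
    kind: str  # gaze | smooth_bar_forward | smooth_bar_backward | random_bar | static_bar
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (PATCH_SIZE, PATCH_SIZE):
            raise ValueError(
                f"frames must be (T, {PATCH_SIZE}, {PATCH_SIZE}), got {self.frames.shape}"
            )

    def __len__(self) -> int:
        return self.frames.shape[0]


# ---------------------------------------------------------------------------
# surrogate scenes


def generate_surrogate_scene(
    seed: int, shape: tuple[int, int] = SCENE_SHAPE
) -> np.ndarray:
    """Generate one spatially correlated grayscale scene, rescaled to [0, 1].

    White Gaussian noise is shaped in the Fourier domain with a 1/f amplitude
    envelope (f = radial spatial frequency), giving the power-law spectral
    decay characteristic of natural images, then linearly rescaled so
    min = 0 and max = 1.
    """
    rng = substream(seed, "scene")
    white = rng.standard_normal(shape)
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    f = np.hypot(fy, fx)
    f[0, 0] = np.inf  # zero out the DC amplitude; the rescale sets the level
    amplitude = 1.0 / f
    img = np.fft.ifft2(np.fft.fft2(white) * amplitude).real
    lo, hi = img.min(), img.max()
    return (img - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# gaze sequences


def adjust_velocity_magnitude(
    start: tuple[int, int],
    direction: tuple[float, float],
    magnitude: int,
    n_steps: int,
    scene_shape: tuple[int, int],
    patch_size: int = PATCH_SIZE,
) -> tuple[int, int]:
    """Integer velocity of the largest feasible L-inf magnitude <= ``magnitude``.

    The continuous direction is scaled to the candidate magnitude, rounded to
    the pixel grid and clipped back to the L-inf ball; the magnitude is
    lowered until every one of the ``n_steps`` patch windows stays inside the
    scene. Magnitude 0 is always feasible.
    """
    d = np.asarray(direction, dtype=float)
    norm = np.abs(d).max()
    if norm > 0:
        d = d / norm  # unit L-inf direction
    for m in range(int(magnitude), -1, -1):
        v = np.clip(np.rint(d * m), -m, m).astype(int)
        corners = np.asarray(start) + np.arange(n_steps)[:, None] * v
        if (corners >= 0).all() and (
            corners + patch_size <= np.asarray(scene_shape)
        ).all():
            return int(v[0]), int(v[1])
    raise ValueError("start position itself is out of bounds")


def sample_gaze_sequence(
    scene: np.ndarray,
    n_steps: int = 9,
    max_speed: int = 4,
    seed: int = 0,
) -> StimulusSequence:
    """Sample a constant-velocity gaze over ``scene`` and cut out its patches.

    The start corner is uniform over valid positions, the speed magnitude
    uniform over integers 0..max_speed, the direction uniform on the circle;
    the magnitude is reduced when needed so the whole path stays in-bounds.
    """
    rng = substream(seed, "gaze")
    frames, meta = gaze_frames(scene, rng, n_steps=n_steps, max_speed=max_speed)
    return StimulusSequence(frames=frames, kind="gaze", metadata={**meta, "seed": seed})


def gaze_frames(
    scene: np.ndarray,
    rng: np.random.Generator,
    n_steps: int = 9,
    max_speed: int = 4,
    patch_size: int = PATCH_SIZE,
) -> tuple[np.ndarray, dict]:
    """Raw (T, patch, patch) gaze frames drawn from a caller-owned Generator.

    Backs :func:`sample_gaze_sequence`; exposed separately so the training
    loop can draw many sequences from one stream (and, for reduced-scale
    runs, use a smaller patch).
    """
    scene = np.asarray(scene, dtype=float)
    if n_steps < 1 or max_speed < 0:
        raise ValueError("n_steps must be >= 1 and max_speed >= 0")
    if scene.shape[0] < patch_size or scene.shape[1] < patch_size:
        raise ValueError(f"scene {scene.shape} is smaller than the {patch_size}px patch")
    start = (
        int(rng.integers(0, scene.shape[0] - patch_size + 1)),
        int(rng.integers(0, scene.shape[1] - patch_size + 1)),
    )
    magnitude = int(rng.integers(0, max_speed + 1))
    angle = rng.uniform(0.0, 2.0 * np.pi)
    velocity = adjust_velocity_magnitude(
        start, (np.sin(angle), np.cos(angle)), magnitude, n_steps, scene.shape, patch_size
    )
    traj = GazeTrajectory(start=start, velocity=velocity, n_steps=n_steps)
    frames = np.stack(
        [scene[r : r + patch_size, c : c + patch_size] for r, c in traj.window_corners()]
    )
    return frames, {"start": start, "velocity": velocity}


# ---------------------------------------------------------------------------
# bar stimuli


def _bar_anchors(orientation: float) -> tuple[np.ndarray, np.ndarray]:
    """Normal vector and the 41 anchor offsets along it for one orientation.

    The bar axis is the line through an anchor point at angle theta; pixels
    whose center lies at perpendicular distance < 2 px belong to the bar
    (constant 4 px width). Anchors are evenly spaced along the normal
    n = (-sin t, cos t) over the projection of the 64x64 image box, inset so
    the first and last bars touch opposite borders. The 2.25 px inset keeps
    anchors off the half-integer grid for axis-aligned orientations, so every
    horizontal bar covers exactly 4 complete pixel rows.
    """
    n = np.array([-np.sin(orientation), np.cos(orientation)])  # (x, y) normal
    corners = np.array([[0, 0], [PATCH_SIZE, 0], [0, PATCH_SIZE], [PATCH_SIZE, PATCH_SIZE]])
    proj = corners @ n
    lo, hi = proj.min(), proj.max()
    step = (hi - lo - 4.0) / (N_POSITIONS - 1)
    offsets = lo + 2.25 + step * np.arange(N_POSITIONS)
    return n, offsets


def rasterize_bar(orientation: float, position_index: int) -> BarFrame:
    """Rasterize one binary bar (value 1 on the bar, 0 elsewhere)."""
    matches = [k for k in range(N_ORIENTATIONS) if np.isclose(orientation, ORIENTATIONS[k])]
    if not matches:
        raise ValueError(f"orientation must be one of k*pi/8, k=0..7; got {orientation}")
    if not 0 <= position_index < N_POSITIONS:
        raise ValueError(f"position_index must be in [0, {N_POSITIONS - 1}]")
    theta = ORIENTATIONS[matches[0]]
    n, offsets = _bar_anchors(theta)
    yy, xx = np.mgrid[0:PATCH_SIZE, 0:PATCH_SIZE]
    # pixel centers at (col+0.5, row+0.5) in (x, y) coordinates
    dist = np.abs((xx + 0.5) * n[0] + (yy + 0.5) * n[1] - offsets[position_index])
    pixels = (dist < BAR_WIDTH / 2.0).astype(float)
    return BarFrame(pixels=pixels, orientation=theta, position_index=position_index)


def make_smooth_bar_sequences() -> list[StimulusSequence]:
    """All 16 smoothly moving bars: 8 orientations x {forward, backward}."""
    sequences: list[StimulusSequence] = []
    for theta in ORIENTATIONS:
        frames = np.stack(
            [rasterize_bar(theta, p).pixels for p in range(N_POSITIONS)]
        )
        positions = list(range(N_POSITIONS))
        sequences.append(
            StimulusSequence(
                frames=frames,
                kind="smooth_bar_forward",
                metadata={"orientation": theta, "positions": positions},
            )
        )
        sequences.append(
            StimulusSequence(
                frames=frames[::-1].copy(),
                kind="smooth_bar_backward",
                metadata={"orientation": theta, "positions": positions[::-1]},
            )
        )
    return sequences


def make_random_bar_sequence(orientation: float, seed: int) -> StimulusSequence:
    """A bar visiting all 41 positions once, in uniformly random order."""
    rng = substream(seed, "bar_permutation")
    order = rng.permutation(N_POSITIONS)
    frames = np.stack([rasterize_bar(orientation, int(p)).pixels for p in order])
    return StimulusSequence(
        frames=frames,
        kind="random_bar",
        metadata={"orientation": orientation, "positions": [int(p) for p in order], "seed": seed},
    )


def make_static_sequence(frame: BarFrame, n_steps: int) -> StimulusSequence:
    """Continuous presentation of one bar image for ``n_steps`` steps."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    frames = np.repeat(frame.pixels[None, :, :], n_steps, axis=0)
    return StimulusSequence(
        frames=frames,
        kind="static_bar",
        metadata={"orientation": frame.orientation, "position": frame.position_index},
    )


# ---------------------------------------------------------------------------
# noise augmentation


def add_noise(frame: np.ndarray, sigma: float, seed: int) -> np.ndarray:
    """Add i.i.d. zero-mean Gaussian pixel noise of standard deviation sigma.

    The result is intentionally not re-clipped to [0, 1]: clipping would
    shrink the effective noise standard deviation near the range edges.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    frame = np.asarray(frame, dtype=float)
    if sigma == 0:
        return frame.copy()
    rng = substream(seed, "noise")
    return frame + rng.normal(0.0, sigma, size=frame.shape)


def noise_augment_set(
    frames: np.ndarray,
    sigma: float,
    n_samples: int,
    master_seed: int,
    which: str,
    dtype=float,
) -> np.ndarray:
    """``n_samples`` independently noised copies of a frame stack.

    ``which`` names the substream ("train" or "test") so the two sets draw
    from disjoint noise streams of the same master seed. Returns an array of
    shape (n_samples,) + frames.shape. ``dtype=np.float32`` generates the
    noise in single precision (used by the bulk decoding pipelines).
    """
    if which not in ("train", "test"):
        raise ValueError("which must be 'train' or 'test'")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    dtype = np.dtype(dtype)
    frames = np.asarray(frames, dtype=dtype)
    rng = substream(master_seed, f"noise-{which}")
    noise = rng.standard_normal(size=(n_samples,) + frames.shape, dtype=dtype)
    noise *= dtype.type(sigma)
    noise += frames[None, ...]
    return noise


# ---------------------------------------------------------------------------
# fixture IO: lossless grayscale PNG for single images, .npy + JSON sidecar
# for sequences


def save_image_png(path: str | Path, image: np.ndarray) -> None:
    """Write a [0, 1] grayscale image as a lossless 16-bit PNG."""
    import imageio.v3 as iio

    arr = np.asarray(image, dtype=float)
    if arr.min() < 0 or arr.max() > 1:
        raise ValueError("image values must lie in [0, 1] for PNG export")
    iio.imwrite(Path(path), np.round(arr * 65535).astype(np.uint16))


def load_image_png(path: str | Path) -> np.ndarray:
    import imageio.v3 as iio

    return iio.imread(Path(path)).astype(float) / 65535.0


def save_sequence(path_stem: str | Path, seq: StimulusSequence) -> None:
    """Dump a sequence as <stem>.npy plus a <stem>.json metadata sidecar."""
    stem = Path(path_stem)
    np.save(stem.with_suffix(".npy"), seq.frames)
    meta = {"kind": seq.kind, **_jsonable(seq.metadata)}
    stem.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_sequence(path_stem: str | Path) -> StimulusSequence:
    stem = Path(path_stem)
    frames = np.load(stem.with_suffix(".npy"))
    meta = json.loads(stem.with_suffix(".json").read_text())
    kind = meta.pop("kind")
    return StimulusSequence(frames=frames, kind=kind, metadata=meta)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
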
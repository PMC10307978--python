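"""End-to-end orchestration: train all three coding regimes, then analyze.

A run executes seven stages — train, stimuli, responses, correlations,
distances, decoding, report — writing every artifact under one output
directory together with a manifest (config snapshot, per-stage seeds and
timings, artifact checksums). Runs are deterministic given (config, master
seed) and resumable: a stage whose artifacts already exist under a matching
config is skipped.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from ._substreams import substream_seed
from .analysis import (
    DECODERS,
    collect_position_responses,
    mean_adjacent_correlation,
    moving_vs_moving_decode,
    decode_suite,
    offset_distance_profile,
    static_vs_moving_distance,
    unit_trajectory_correlations,
)
from .network import Architecture, run_batch, load_params, save_params
from .objective import ObjectiveConfig, TrainingConfig, train
from .stimuli import (
    N_POSITIONS,
    ORIENTATIONS,
    make_random_bar_sequence,
    make_smooth_bar_sequences,
    rasterize_bar,
)

__all__ = ["RunConfig", "RunManifest", "PROFILES", "load_config", "run_all", "report"]

STAGES = ("train", "stimuli", "responses", "correlations", "distances", "decoding", "report")
CONDITIONS = ("stec", "sec", "tec")


@dataclass
class RunConfig:
    """Configuration for one end-to-end run."""

    master_seed: int = 0
    profile: str = "custom"
    n_lower: int = 64
    n_upper: int = 64
    iterations_per_repetition: int = 10_000
    repetitions: int = 5
    minibatch: int = 100
    n_scenes: int = 64
    n_bins: int = 16
    lambdas: dict = field(
        default_factory=lambda: {"stec": 5.0, "sec": 1000.0, "tec": 0.01}
    )
    orientations: list = field(default_factory=lambda: [0.0])
    noise_sigmas: list = field(default_factory=lambda: [0.1])
    decoders: list = field(default_factory=lambda: list(DECODERS))
    n_augment: int = 300
    bptt: bool = False
    credit_assignment: str = "combined"
    outdir: str = "scratch/run"

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def arch(self) -> Architecture:
        return Architecture(frame_shape=(64, 64), n_lower=self.n_lower, n_upper=self.n_upper)


#: named run profiles: smoke (CI-scale), desk (reduced replication), paper
#: (the full-scale protocol)
PROFILES: dict[str, dict] = {
    "smoke": dict(
        profile="smoke", n_lower=32, n_upper=32, iterations_per_repetition=500,
        repetitions=1, minibatch=20, n_scenes=16, orientations=[0.0, np.pi / 2],
        decoders=["naive_bayes", "lda"], n_augment=60,
    ),
    "desk": dict(
        profile="desk", n_lower=64, n_upper=64, iterations_per_repetition=2000,
        repetitions=1, minibatch=50, n_scenes=64,
        orientations=[float(t) for t in ORIENTATIONS],
    ),
    "paper": dict(
        profile="paper", n_lower=64, n_upper=64, iterations_per_repetition=10_000,
        repetitions=5, minibatch=100, n_scenes=256,
        orientations=[float(t) for t in ORIENTATIONS],
        noise_sigmas=[0.025, 0.05, 0.1, 0.2, 0.4],
    ),
}


def load_config(path: str | Path | None = None, profile: str | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from a YAML file and/or a named profile."""
    data: dict = {}
    if profile is not None:
        if profile not in PROFILES:
            raise ValueError(f"unknown profile {profile!r}; choose from {sorted(PROFILES)}")
        data.update(PROFILES[profile])
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError("config file must contain a mapping")
        data.update(loaded)
    data.update(overrides)
    return RunConfig.from_dict(data)


@dataclass
class RunManifest:
    """Record of one run: config, seeds, artifacts, timings."""

    config: dict
    master_seed: int
    version: str = __version__
    stage_seeds: dict = field(default_factory=dict)
    stage_timings: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)  # path -> sha256
    completed_stages: list = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, default=float))

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class StageDependencyError(RuntimeError):
    """An upstream stage's artifact is missing; names the missing stage."""


def _register(manifest: RunManifest, outdir: Path, *paths: Path) -> None:
    for p in paths:
        manifest.artifacts[str(p.relative_to(outdir))] = _sha256(p)


def _require(manifest: RunManifest, stage: str) -> None:
    if stage not in manifest.completed_stages:
        raise StageDependencyError(f"stage '{stage}' has not produced its artifacts yet")


# ---------------------------------------------------------------------------
# stages


def _stage_train(cfg: RunConfig, outdir: Path, manifest: RunManifest) -> None:
    for cond in CONDITIONS:
        stem = outdir / f"params_{cond}"
        if stem.with_suffix(".npz").exists():
            continue
        seed = substream_seed(cfg.master_seed, "train", cond)
        manifest.stage_seeds[f"train/{cond}"] = seed
        obj = ObjectiveConfig(lambda_=cfg.lambdas[cond], n_bins=cfg.n_bins)
        trn = TrainingConfig(
            iterations_per_repetition=cfg.iterations_per_repetition,
            repetitions=cfg.repetitions,
            minibatch=cfg.minibatch,
            n_scenes=cfg.n_scenes,
            master_seed=seed,
            bptt=cfg.bptt,
            credit_assignment=cfg.credit_assignment,
        )
        params, trace = train(obj, trn, cfg.arch)
        save_params(stem, params, meta={"condition": cond, "lambda": cfg.lambdas[cond], "seed": seed})
        trace.to_csv(outdir / f"loss_trace_{cond}.csv", index=False)
        _register(manifest, outdir, stem.with_suffix(".npz"), stem.with_suffix(".json"),
                  outdir / f"loss_trace_{cond}.csv")


def _stage_stimuli(cfg: RunConfig, outdir: Path, manifest: RunManifest) -> None:
    seed = substream_seed(cfg.master_seed, "stimuli")
    manifest.stage_seeds["stimuli"] = seed
    smooth = make_smooth_bar_sequences()
    random_orders = {
        f"{theta:.4f}/{i}": make_random_bar_sequence(theta, seed=substream_seed(seed, i, k)).metadata["positions"]
        for k, theta in enumerate(ORIENTATIONS)
        for i in range(N_POSITIONS)
    }
    summary = {
        "n_smooth_sequences": len(smooth),
        "n_orientations": len(ORIENTATIONS),
        "n_positions": N_POSITIONS,
        "frames_per_sequence": int(len(smooth[0])),
        "n_random_sequences_per_orientation": N_POSITIONS,
        "random_orders": random_orders,
    }
    path = outdir / "stimuli_summary.json"
    path.write_text(json.dumps(summary, indent=2))
    _register(manifest, outdir, path)


def _load_condition_params(cfg: RunConfig, outdir: Path) -> dict:
    params = {}
    for cond in CONDITIONS:
        stem = outdir / f"params_{cond}"
        if not stem.with_suffix(".npz").exists():
            raise StageDependencyError("stage 'train' has not produced its artifacts yet")
        params[cond], _ = load_params(stem)
    return params


def _stage_responses(cfg: RunConfig, outdir: Path, manifest: RunManifest) -> None:
    params = _load_condition_params(cfg, outdir)
    arrays = {}
    for cond, p in params.items():
        for h in ("lower", "upper"):
            for theta in cfg.orientations:
                for movement in ("smooth_fwd", "smooth_bwd", "static"):
                    pset = collect_position_responses(p, theta, movement, h, cond)
                    arrays[f"{cond}/{h}/{theta:.4f}/{movement}"] = pset.responses
    path = outdir / "position_responses.npz"
    np.savez(path, **arrays)
    _register(manifest, outdir, path)


def _stage_correlations(cfg: RunConfig, outdir: Path, manifest: RunManifest) -> None:
    params = _load_condition_params(cfg, outdir)
    rows = []
    for cond, p in params.items():
        for h in ("lower", "upper"):
            for theta in cfg.orientations:
                bars = np.stack([rasterize_bar(theta, q).pixels for q in range(N_POSITIONS)])
                traj = run_batch(p, bars[None])
                resp = getattr(traj, h)[:, 0]
                pset = collect_position_responses(p, theta, "smooth_fwd", h, cond)
                utc = unit_trajectory_correlations(resp)
                rows.append(
                    {
                        "condition": cond, "hierarchy": h, "orientation": theta,
                        "mean_adjacent_correlation": mean_adjacent_correlation(pset),
                        "positive_significant_fraction": utc["positive_significant_fraction"],
                        "median_abs_correlation": float(np.median(utc["abs_correlations"])),
                        "n_pairs": utc["n_pairs"],
                        "n_excluded_pairs": utc["n_excluded_pairs"],
                    }
                )
    path = outdir / "correlations.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    _register(manifest, outdir, path)


def _stage_distances(cfg: RunConfig, outdir: Path, manifest: RunManifest) -> None:
    params = _load_condition_params(cfg, outdir)
    rows = []
    for cond, p in params.items():
        for h in ("lower", "upper"):
            for theta in cfg.orientations:
                static = collect_position_responses(p, theta, "static", h, cond)
                for movement in ("smooth_fwd", "random"):
                    moving = collect_position_responses(
                        p, theta, movement, h, cond,
                        random_seed=substream_seed(cfg.master_seed, "distances", cond, h),
                    )
                    D = static_vs_moving_distance(static, moving)
                    profile = offset_distance_profile(D, max_offset=5)
                    rho = stats.spearmanr(np.arange(profile.size), profile).statistic
                    rows.append(
                        {
                            "condition": cond, "hierarchy": h, "orientation": theta,
                            "movement": movement,
                            "mean_diagonal_distance": float(np.diagonal(D).mean()),
                            "offset_spearman_rho": float(rho),
                            **{f"offset_{k}": float(v) for k, v in enumerate(profile)},
                        }
                    )
    path = outdir / "distances.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    _register(manifest, outdir, path)


def _stage_decoding(cfg: RunConfig, outdir: Path, manifest: RunManifest) -> None:
    params = _load_condition_params(cfg, outdir)
    rows = []
    for cond in ("stec", "sec"):
        for h in ("lower", "upper"):
            for task in ("position", "orientation"):
                for sigma in cfg.noise_sigmas:
                    seed = substream_seed(cfg.master_seed, "decode", cond, h, task, sigma)
                    suite = decode_suite(
                        params[cond], task, cfg.decoders, sigma, seed, hierarchy=h,
                        n_samples=cfg.n_augment, condition=cond,
                    )
                    for dec, res in suite.items():
                        rows.append(
                            {
                                "condition": cond, "hierarchy": h, "task": task,
                                "decoder": dec, "noise_sigma": sigma, "train": "static",
                                "test": "moving", "accuracy": res.accuracy,
                                "n_train": res.n_train, "n_test": res.n_test,
                            }
                        )
    for cond in ("stec", "tec"):
        for dec in cfg.decoders:
            sigma = cfg.noise_sigmas[0]
            seed = substream_seed(cfg.master_seed, "decode-mm", cond, dec)
            res = moving_vs_moving_decode(
                params[cond], "position", dec, sigma, seed,
                hierarchy="lower", n_samples=cfg.n_augment, condition=cond,
            )
            rows.append(
                {
                    "condition": cond, "hierarchy": "lower", "task": "position",
                    "decoder": dec, "noise_sigma": sigma, "train": "moving",
                    "test": "moving", "accuracy": res.accuracy,
                    "n_train": res.n_train, "n_test": res.n_test,
                }
            )
    path = outdir / "decoding.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    _register(manifest, outdir, path)


def _stage_report(cfg: RunConfig, outdir: Path, manifest: RunManifest) -> None:
    rep = report(manifest, outdir=outdir)
    path = outdir / "report.json"
    path.write_text(json.dumps(rep, indent=2, default=float))
    _register(manifest, outdir, path)


_STAGE_FUNCS = {
    "train": _stage_train,
    "stimuli": _stage_stimuli,
    "responses": _stage_responses,
    "correlations": _stage_correlations,
    "distances": _stage_distances,
    "decoding": _stage_decoding,
    "report": _stage_report,
}


def run_all(
    config: RunConfig | str | Path | dict | None = None,
    profile: str | None = None,
    stages: tuple[str, ...] = STAGES,
) -> RunManifest:
    """Execute the pipeline stages in order and return the manifest."""
    if isinstance(config, RunConfig):
        cfg = config
    elif isinstance(config, dict):
        cfg = RunConfig.from_dict(config)
    else:
        cfg = load_config(config, profile=profile)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists():
        manifest = RunManifest.load(manifest_path)
        if manifest.config != cfg.to_dict():
            raise ValueError(
                f"{manifest_path} was produced under a different config; "
                "use a fresh output directory"
            )
    else:
        manifest = RunManifest(config=cfg.to_dict(), master_seed=cfg.master_seed)
    unknown = sorted(set(stages) - set(STAGES))
    if unknown:
        raise ValueError(f"unknown stage(s): {', '.join(unknown)}")
    for stage in STAGES:
        if stage not in stages or stage in manifest.completed_stages:
            continue
        t0 = time.perf_counter()
        _STAGE_FUNCS[stage](cfg, outdir, manifest)
        manifest.stage_timings[stage] = time.perf_counter() - t0
        manifest.completed_stages.append(stage)
        manifest.save(manifest_path)
    return manifest


# ---------------------------------------------------------------------------
# report


def _directional(df: pd.DataFrame | None, check) -> dict:
    if df is None:
        return {"status": "not run"}
    try:
        passed = bool(check(df))
    except Exception as exc:  # pragma: no cover - defensive
        return {"status": "error", "detail": str(exc)}
    return {"status": "pass" if passed else "fail"}


def report(manifest: RunManifest, outdir: str | Path | None = None) -> dict:
    """Summarize a run: headline counts plus the five directional checks.

    The directional checks mirror the qualitative claims of the study:
    smoother adjacent-position correlations and stronger unit-pair
    correlations under balanced coding than under spatial-only coding;
    smaller static-vs-moving distances with locally increasing offset
    profile; higher static->moving decoding accuracy; and higher
    moving->moving position accuracy for balanced than temporal-only coding.
    """
    outdir = Path(outdir if outdir is not None else manifest.config.get("outdir", "."))

    def read_csv(name: str) -> pd.DataFrame | None:
        p = outdir / name
        return pd.read_csv(p) if p.exists() else None

    corr = read_csv("correlations.csv")
    dist = read_csv("distances.csv")
    deco = read_csv("decoding.csv")
    stim_path = outdir / "stimuli_summary.json"
    stim = json.loads(stim_path.read_text()) if stim_path.exists() else None

    def mean_by_cond(df, col, **filt):
        sub = df
        for k, v in filt.items():
            sub = sub[sub[k] == v]
        return sub.groupby("condition")[col].mean()

    def corr_check(df):
        m = mean_by_cond(df, "mean_adjacent_correlation")
        return m["stec"] > m["sec"]

    def unitcorr_check(df):
        f = mean_by_cond(df, "positive_significant_fraction")
        a = mean_by_cond(df, "median_abs_correlation")
        return f["stec"] > f["sec"] and a["stec"] > a["sec"]

    def dist_check(df):
        sub = df[df.movement == "smooth_fwd"]
        m = mean_by_cond(sub, "mean_diagonal_distance")
        rho = mean_by_cond(sub[sub.condition == "stec"], "offset_spearman_rho")
        return m["stec"] < m["sec"] and rho["stec"] > 0

    def decode_check(df):
        sub = df[(df.train == "static") & (df.decoder.isin(["naive_bayes", "lda"]))]
        m = sub.groupby("condition")["accuracy"].mean()
        return m["stec"] > m["sec"]

    def movmov_check(df):
        sub = df[df.train == "moving"]
        piv = sub.pivot_table(index="decoder", columns="condition", values="accuracy")
        return (piv["stec"] > piv["tec"]).mean() > 0.5

    checks = {
        "adjacent_position_correlation_stec_gt_sec": _directional(corr, corr_check),
        "unit_pair_correlations_stec_gt_sec": _directional(corr, unitcorr_check),
        "static_moving_distance_stec_lt_sec": _directional(dist, dist_check),
        "static_to_moving_decoding_stec_gt_sec": _directional(deco, decode_check),
        "moving_to_moving_decoding_stec_gt_tec": _directional(deco, movmov_check),
    }
    incomplete = [s for s in STAGES[:-1] if s not in manifest.completed_stages]
    out = {
        "version": manifest.version,
        "master_seed": manifest.master_seed,
        "profile": manifest.config.get("profile"),
        "stimuli": {k: v for k, v in (stim or {}).items() if k != "random_orders"}
        if stim else {"status": "not run"},
        "chance_levels": {"position": 1.0 / 9.0, "orientation": 1.0 / 8.0},
        "directional_checks": checks,
    }
    if incomplete:
        out["warning"] = f"partial report; stages not run: {', '.join(incomplete)}"
    return out
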
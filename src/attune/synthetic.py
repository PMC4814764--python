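"""Coupled gesture/speech event-stream simulator with known ground truth.

A latent sequence of "understanding states" alternates over the session,
each with a geometric dwell time and a tier (sensorimotor or
representational). Each state may be expressed in each stream as one
coded episode, delayed by a stream-specific lag plus optional Gaussian
jitter, with a geometric episode duration and a level drawn uniformly
from the state's tier. A mismatch probability lets a stream express the
other tier, producing gesture-speech mismatches.

Durations are drawn comonotonically across streams (one shared uniform
per state, inverted through each stream's geometric CDF), so equal
episode-duration means give identical durations and a pure time-shift
construction, while unequal means impose a dwell-time (trapping-time)
asymmetry.

All event boundaries are whole seconds, so rasterization is exact.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .events import ChildMeta, CodedEvent, write_events, write_metadata

S_TIER_LEVELS = (1, 2, 3)
R_TIER_LEVELS = (4, 5, 6)


@dataclass(frozen=True)
class GenParams:
    """Parameters of one simulated child."""

    duration_s: int = 480
    mean_state_dwell_s: float = 20.0
    p_tier_R: float = 0.5
    lag_gesture_s: int = 0
    lag_speech_s: int = 0
    jitter_sd_s: float = 0.0
    mean_episode_gesture_s: float = 6.0
    mean_episode_speech_s: float = 6.0
    p_express_gesture: float = 1.0
    p_express_speech: float = 1.0
    p_mismatch: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "p_tier_R",
            "p_express_gesture",
            "p_express_speech",
            "p_mismatch",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.duration_s < 1:
            raise ValueError("duration_s must be positive")
        if self.mean_state_dwell_s < 1:
            raise ValueError("mean_state_dwell_s must be >= 1")
        if min(self.mean_episode_gesture_s, self.mean_episode_speech_s) < 1:
            raise ValueError("episode duration means must be >= 1")
        if self.lag_gesture_s < 0 or self.lag_speech_s < 0:
            raise ValueError("lags must be non-negative")
        if self.jitter_sd_s < 0:
            raise ValueError("jitter_sd_s must be >= 0")
        if max(self.mean_episode_gesture_s, self.mean_episode_speech_s) >= (
            3 * self.mean_state_dwell_s
        ):
            warnings.warn(
                "episode means approach/exceed 3x the state dwell; episodes "
                "will be heavily clipped",
                stacklevel=2,
            )


@dataclass(frozen=True)
class GroundTruth:
    """What the generator imposed, for recovery checks."""

    intended_lead_s: int  # lag_speech - lag_gesture; positive = gestures lead
    intended_tt_ratio: float  # mean_episode_gesture / mean_episode_speech

    @staticmethod
    def from_params(params: GenParams) -> "GroundTruth":
        return GroundTruth(
            intended_lead_s=params.lag_speech_s - params.lag_gesture_s,
            intended_tt_ratio=(
                params.mean_episode_gesture_s / params.mean_episode_speech_s
            ),
        )


def _geometric_from_uniform(u: float, mean: float) -> int:
    """Geometric (support 1, 2, ...) quantile at u, with the given mean."""
    p = 1.0 / mean
    if p >= 1.0:
        return 1
    # inverse CDF: smallest k with 1 - (1-p)^k >= u
    return max(1, int(math.ceil(math.log1p(-u) / math.log1p(-p))))


def generate_child(
    params: GenParams,
) -> tuple[list[CodedEvent], list[CodedEvent], GroundTruth]:
    """Simulate one child's gesture and speech event streams.

    Returns ``(gesture_events, speech_events, ground_truth)``; fully
    reproducible from ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    duration = params.duration_s
    horizon = duration + params.lag_gesture_s + params.lag_speech_s + 1

    # latent state sequence: onset, dwell, tier
    states: list[tuple[int, int, int]] = []
    t = 0
    while t < horizon:
        dwell = _geometric_from_uniform(float(rng.random()), params.mean_state_dwell_s)
        tier = 2 if rng.random() < params.p_tier_R else 1
        states.append((t, dwell, tier))
        t += dwell

    streams = {
        "gesture": dict(
            lag=params.lag_gesture_s,
            mean_episode=params.mean_episode_gesture_s,
            p_express=params.p_express_gesture,
            events=[],
            last_end=0,
        ),
        "speech": dict(
            lag=params.lag_speech_s,
            mean_episode=params.mean_episode_speech_s,
            p_express=params.p_express_speech,
            events=[],
            last_end=0,
        ),
    }

    for onset, dwell, tier in states:
        u_dur = float(rng.random())  # shared across streams: comonotone durations
        # per-stream draws, in a fixed order for reproducibility
        draws = {
            name: dict(
                express=rng.random() < spec["p_express"],
                jitter=(
                    int(round(rng.normal(0.0, params.jitter_sd_s)))
                    if params.jitter_sd_s > 0
                    else 0
                ),
                mismatch=rng.random() < params.p_mismatch,
                level_u=float(rng.random()),
            )
            for name, spec in streams.items()
        }
        for name, spec in streams.items():
            d = draws[name]
            if not d["express"]:
                continue
            ep_tier = (3 - tier) if d["mismatch"] else tier  # flip 1 <-> 2
            levels = S_TIER_LEVELS if ep_tier == 1 else R_TIER_LEVELS
            level = levels[int(d["level_u"] * len(levels))]
            dur = _geometric_from_uniform(u_dur, spec["mean_episode"])
            start = onset + spec["lag"] + d["jitter"]
            start = max(start, spec["last_end"])  # enforce within-stream non-overlap
            end = min(start + dur, duration)
            if end <= start or start >= duration:
                continue
            spec["events"].append(
                CodedEvent(
                    stream=name,
                    start_s=float(start),
                    end_s=float(end),
                    category="representation",
                    level=int(level),
                )
            )
            spec["last_end"] = end

    return (
        streams["gesture"]["events"],
        streams["speech"]["events"],
        GroundTruth.from_params(params),
    )


@dataclass(frozen=True)
class CovariateLink:
    """Linear-plus-noise link from a ground-truth field to a covariate.

    ``covariate = intercept + slope * truth + Normal(0, noise_sd)``, then
    clipped/rounded to the covariate's legal range.
    """

    truth_field: str = "intended_lead_s"
    covariate: str = "age_months"
    intercept: float = 64.0
    slope: float = 0.0
    noise_sd: float = 1.0


_COVARIATE_RANGES = {
    "age_months": (40, 90),
    "math_score": (1, 5),
    "language_score": (1, 5),
    "avg_past_score": (0.0, 3.0),
}


def generate_cohort(
    n_children: int,
    params_ranges: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    links: Sequence[CovariateLink] = (),
    base_params: GenParams | None = None,
) -> tuple[dict[str, list[CodedEvent]], list[ChildMeta], dict[str, GroundTruth]]:
    """Simulate a cohort; optionally write event/metadata/scenario files.

    ``params_ranges`` maps GenParams field names to (low, high) uniform
    ranges sampled per child (integer fields are rounded). Covariates are
    drawn through the given linear links so correlation recovery can be
    exercised; unlinked covariates are drawn independently. With
    ``out_dir`` set, one events CSV per child, a metadata CSV, and a YAML
    scenario capturing each child's parameters are written.
    """
    if n_children < 1:
        raise ValueError("n_children must be >= 1")
    params_ranges = dict(params_ranges or {})
    base = base_params or GenParams()
    rng = np.random.default_rng(seed)
    int_fields = {"duration_s", "lag_gesture_s", "lag_speech_s", "seed"}

    events: dict[str, list[CodedEvent]] = {}
    metas: list[ChildMeta] = []
    truths: dict[str, GroundTruth] = {}
    scenario: dict[str, dict] = {}

    for k in range(n_children):
        child_id = f"c{k + 1:02d}"
        overrides = {}
        for name, (lo, hi) in params_ranges.items():
            v = lo + (hi - lo) * rng.random()
            overrides[name] = int(round(v)) if name in int_fields else float(v)
        overrides["seed"] = int(rng.integers(0, 2**31 - 1))
        params = GenParams(**{**asdict(base), **overrides})
        g_events, s_events, truth = generate_child(params)
        events[child_id] = sorted(g_events + s_events, key=lambda e: (e.stream, e.start_s))
        truths[child_id] = truth
        scenario[child_id] = asdict(params)

        cov: dict[str, float] = {}
        for link in links:
            truth_val = getattr(truth, link.truth_field)
            cov[link.covariate] = link.intercept + link.slope * truth_val + rng.normal(
                0.0, link.noise_sd
            )
        meta = ChildMeta(
            child_id=child_id,
            grade="KG" if k < n_children // 2 else "1",
            age_months=int(np.clip(round(cov.get("age_months", rng.normal(64, 6))), *_COVARIATE_RANGES["age_months"])),
            math_score=float(np.clip(round(cov.get("math_score", rng.integers(1, 6))), *_COVARIATE_RANGES["math_score"])),
            language_score=float(np.clip(round(cov.get("language_score", rng.integers(1, 6))), *_COVARIATE_RANGES["language_score"])),
            avg_past_score=float(np.clip(cov.get("avg_past_score", rng.uniform(0.5, 3.0)), *_COVARIATE_RANGES["avg_past_score"])),
        )
        metas.append(meta)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for child_id, evs in events.items():
            write_events({child_id: evs}, out_dir / f"{child_id}.csv")
        write_metadata(metas, out_dir / "metadata.csv")
        with (out_dir / "scenario.yaml").open("w", encoding="utf-8") as fh:
            yaml.safe_dump(scenario, fh, sort_keys=True)

    return events, metas, truths
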
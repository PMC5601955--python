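"""Real-time motion-test simulation and its four performance metrics.

A prompted motion produces a stream of classifier predictions: the first
prediction becomes available once the first full analysis window plus the
processing latency has elapsed (200 ms + 11 ms = 211 ms under defaults),
and subsequent predictions follow every window increment (50 ms). The
trial completes when ``required_correct`` predictions (not necessarily
consecutive) match the prompt before the timeout, which runs from the
motion prompt.

Metric conventions (fixed by the two published floors):

- selection time = elapsed time from the first non-rest prediction to the
  first correct prediction, plus the first-window latency
  (window + processing latency). An immediately-correct stream therefore
  scores the 0.211 s floor.
- completion time = elapsed time from the first non-rest prediction to the
  completing prediction, plus the same latency; an always-correct stream
  with 20 required predictions scores 0.211 + 19 * 0.050 = 1.161 s
  (1.16 s to two decimals).
- real-time accuracy = required_correct / number of predictions issued
  from the first non-rest prediction through the completing one.
- completion percentage = completed trials / attempted trials * 100.

Time and accuracy aggregates are computed over completed trials only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from emgpr.features import FeatureSpec, extract_features
from emgpr.lda import OvoClassifier
from emgpr.preprocess import SegmentationSpec, WindowSet
from emgpr.sessions import ProtocolSpec, REST_LABEL
from emgpr.synth import ActivationModel, FrontEndSpec, generate_stream


@dataclass(frozen=True)
class MotionTestConfig:
    required_correct: int = 20
    timeout_s: float = 10.0
    window_ms: float = 200.0
    increment_ms: float = 50.0
    processing_latency_ms: float = 11.0
    trials_per_motion: int = 1
    n_tests: int = 2
    include_rest_prompt: bool = False

    def __post_init__(self) -> None:
        if self.required_correct < 1:
            raise ValueError("required_correct must be >= 1")
        floor_s = (self.window_ms + (self.required_correct - 1) * self.increment_ms) / 1000.0
        if self.timeout_s <= floor_s:
            raise ValueError(
                f"timeout_s={self.timeout_s} not above the theoretical floor {floor_s} s"
            )

    @property
    def first_event_ms(self) -> float:
        """Time from prompt to the first available prediction."""
        return self.window_ms + self.processing_latency_ms

    @property
    def latency_offset_s(self) -> float:
        """Latency added to selection/completion times (the 0.211 s floor)."""
        return self.first_event_ms / 1000.0


@dataclass
class PredictionStream:
    """Timed classifier predictions for one prompted motion."""

    prompted: str
    events: list[tuple[float, str]]  # (time from prompt in ms, predicted label)
    source: str = "scripted"

    def labels(self) -> list[str]:
        return [lab for _t, lab in self.events]


def scripted_stream(
    prompted: str, labels: Sequence[str], config: MotionTestConfig
) -> PredictionStream:
    """Build a stream from a plain label sequence at the configured cadence."""
    events = [
        (config.first_event_ms + i * config.increment_ms, lab)
        for i, lab in enumerate(labels)
    ]
    return PredictionStream(prompted=prompted, events=events, source="scripted")


@dataclass
class MotionTrialResult:
    prompted: str
    completed: bool
    selection_time_s: float | None
    completion_time_s: float | None
    realtime_accuracy: float | None
    predictions_to_completion: int | None
    test_index: int = 0


def _first_indices(stream: PredictionStream, config: MotionTestConfig):
    """(first non-rest index, first correct index, completing index) or Nones.

    Only events at or before the timeout count.
    """
    timeout_ms = config.timeout_s * 1000.0
    i_nonrest = i_correct = i_complete = None
    n_correct = 0
    for i, (t, lab) in enumerate(stream.events):
        if t > timeout_ms:
            break
        if i_nonrest is None and lab != REST_LABEL:
            i_nonrest = i
        if lab == stream.prompted:
            if i_correct is None:
                i_correct = i
            n_correct += 1
            if n_correct == config.required_correct:
                i_complete = i
                break
    return i_nonrest, i_correct, i_complete


def selection_time(stream: PredictionStream, config: MotionTestConfig) -> float | None:
    """Seconds from first non-rest to first correct prediction, plus latency.

    None when the stream never leaves rest or never predicts the prompt
    (within the timeout).
    """
    i_nonrest, i_correct, _ = _first_indices(stream, config)
    if i_nonrest is None or i_correct is None:
        return None
    t0 = stream.events[i_nonrest][0]
    t1 = stream.events[i_correct][0]
    return (t1 - t0) / 1000.0 + config.latency_offset_s


def realtime_accuracy(stream: PredictionStream, config: MotionTestConfig) -> float:
    """required_correct / predictions from first non-rest through completion."""
    i_nonrest, _i_correct, i_complete = _first_indices(stream, config)
    if i_complete is None:
        raise ValueError("real-time accuracy is only defined for completed trials")
    return config.required_correct / (i_complete - i_nonrest + 1)


def evaluate_trial(
    stream: PredictionStream, config: MotionTestConfig, test_index: int = 0
) -> MotionTrialResult:
    """Score one prompted-motion trial from its prediction stream."""
    i_nonrest, i_correct, i_complete = _first_indices(stream, config)
    if i_complete is None:
        return MotionTrialResult(
            prompted=stream.prompted, completed=False, selection_time_s=None,
            completion_time_s=None, realtime_accuracy=None,
            predictions_to_completion=None, test_index=test_index,
        )
    if i_nonrest is None:  # rest-prompted trial: clock from the first correct event
        i_nonrest = i_correct
    t0 = stream.events[i_nonrest][0]
    sel = (stream.events[i_correct][0] - t0) / 1000.0 + config.latency_offset_s
    comp = (stream.events[i_complete][0] - t0) / 1000.0 + config.latency_offset_s
    k = i_complete - i_nonrest + 1
    return MotionTrialResult(
        prompted=stream.prompted, completed=True, selection_time_s=sel,
        completion_time_s=comp, realtime_accuracy=config.required_correct / k,
        predictions_to_completion=k, test_index=test_index,
    )


@dataclass
class MotionTestResult:
    trials: list[MotionTrialResult]
    config: MotionTestConfig

    @property
    def n_attempted(self) -> int:
        return len(self.trials)

    @property
    def n_completed(self) -> int:
        return sum(t.completed for t in self.trials)

    @property
    def completion_percentage(self) -> float:
        return 100.0 * self.n_completed / self.n_attempted if self.trials else 0.0

    def _completed_values(self, attr: str) -> np.ndarray:
        return np.array([getattr(t, attr) for t in self.trials if t.completed], dtype=float)

    def aggregates(self) -> dict[str, dict[str, float | None]]:
        """Mean and standard error per metric, completed trials only."""
        out: dict[str, dict[str, float | None]] = {
            "completion_percentage": {"mean": self.completion_percentage, "se": None},
        }
        for metric in ("selection_time_s", "completion_time_s", "realtime_accuracy"):
            vals = self._completed_values(metric)
            if vals.size == 0:
                out[metric] = {"mean": None, "se": None}
            else:
                se = float(np.std(vals, ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else None
                out[metric] = {"mean": float(np.mean(vals)), "se": se}
        return out

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame([t.__dict__ for t in self.trials]).to_csv(path, index=False)

    def summary_json(self, path: str | Path) -> None:
        times, fracs = cumulative_completion_curve(self)
        payload = {
            "n_attempted": self.n_attempted,
            "n_completed": self.n_completed,
            "aggregates": self.aggregates(),
            "completion_curve": {"time_s": list(times), "completed_fraction": list(fracs)},
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def cumulative_completion_curve(result: MotionTestResult) -> tuple[np.ndarray, np.ndarray]:
    """Step-function breakpoints: fraction of attempted motions completed by t.

    Returns (times, fractions) where fractions[i] is the completed fraction
    at and after times[i]; the curve starts at (0, 0) and ends at the
    overall completion fraction.
    """
    if not result.trials:
        raise ValueError("need at least one trial")
    comp_times = np.sort(result._completed_values("completion_time_s"))
    n = result.n_attempted
    times = [0.0]
    fracs = [0.0]
    for i, t in enumerate(comp_times):
        times.append(float(t))
        fracs.append((i + 1) / n)
    return np.array(times), np.array(fracs)


StreamSource = Callable[[str, int], PredictionStream]


def classifier_stream_source(
    clf: OvoClassifier,
    protocol: ProtocolSpec,
    model: ActivationModel,
    frontend: FrontEndSpec,
    feature_spec: FeatureSpec,
    config: MotionTestConfig,
) -> StreamSource:
    """Stream factory: synthesize a movement's signal, window it at the
    test cadence, and run the classifier on each window's features."""
    fs = protocol.sampling_rate
    w = int(np.floor(config.window_ms * fs / 1000.0))
    step = int(np.floor(config.increment_ms * fs / 1000.0))

    def source(movement: str, seed: int) -> PredictionStream:
        duration = config.timeout_s + config.window_ms / 1000.0
        sig = generate_stream(protocol, model, movement, duration, seed, frontend)
        n_events = (sig.shape[0] - w) // step + 1
        windows = [(movement, k * step, k * step + w) for k in range(n_events)]
        ws = WindowSet(windows=windows, signals={movement: sig},
                       window_samples=w, increment_samples=step)
        fm = extract_features(ws, feature_spec)
        preds = clf.predict(fm.values)
        events = [
            (config.first_event_ms + i * config.increment_ms, str(p))
            for i, p in enumerate(preds)
        ]
        return PredictionStream(prompted=movement, events=events, source="classifier")

    return source


def run_motion_test(
    stream_source: StreamSource,
    motions: Sequence[str],
    config: MotionTestConfig,
    rng_seed: int = 0,
) -> MotionTestResult:
    """Run the full test: each motion prompted in random order, repeated
    ``trials_per_motion`` times per test, for ``n_tests`` tests.

    Deterministic for a fixed seed: motion order and per-trial stream seeds
    all derive from ``rng_seed``.
    """
    rng = np.random.default_rng(rng_seed)
    trials: list[MotionTrialResult] = []
    for test_idx in range(config.n_tests):
        prompts = [m for m in motions for _ in range(config.trials_per_motion)]
        order = rng.permutation(len(prompts))
        for j in order:
            trial_seed = int(rng.integers(0, 2**31 - 1))
            stream = stream_source(prompts[j], trial_seed)
            trials.append(evaluate_trial(stream, config, test_index=test_idx))
    return MotionTestResult(trials=trials, config=config)
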
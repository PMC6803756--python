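"""Event-locked skin-conductance windowing and aSCR responder profiling.

Raw conductance (microsiemens) is averaged in fixed windows locked to the
per-trial card-selection markers: a 1250 ms *anticipatory* window ending
at the marker and a 1250 ms *post-election* window starting at it.  The
aSCR index of a subject is

    mean anticipatory conductance before A/B (disadvantageous) choices
  - mean anticipatory conductance before C/D (advantageous) choices

A positive index (aSCR+) marks stronger anticipatory responses to the
disadvantageous decks; a negative index marks the reverse (aSCR-).  No
deconvolution or peak scoring is applied: windows average the raw signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .igt_task import ADVANTAGEOUS, DECK_IDS

DEFAULT_WINDOW_MS = 1250.0
DEFAULT_BASELINE_SPAN_S = 60.0

GROUP_POS = "aSCR+"
GROUP_NEG = "aSCR-"
GROUP_TIE = "indeterminate"


class WindowError(ValueError):
    """A requested window falls outside the recording or contains no samples."""


@dataclass
class SCRTrace:
    """Uniformly sampled conductance with per-trial selection markers.

    ``samples`` are in microsiemens; sample i sits at time i / sampling_rate
    seconds from recording onset.  ``markers`` are card-selection times in
    seconds.  The first ``baseline_span_s`` seconds precede the task.
    """

    samples: np.ndarray
    sampling_rate: float
    markers: np.ndarray
    baseline_span_s: float = DEFAULT_BASELINE_SPAN_S

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.markers = np.asarray(self.markers, dtype=float)
        if self.markers.size and np.any(np.diff(self.markers) < 1.0 - 1e-9):
            raise ValueError("markers must be at least 1 s apart (task minimum interval)")
        if self.markers.size and np.any(np.diff(self.markers) <= 0):
            raise ValueError("markers must be strictly increasing")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate

    def to_csv(self, trace_path, marker_path) -> None:
        pd.DataFrame({"time_s": self.times, "conductance_uS": self.samples}).to_csv(
            trace_path, index=False
        )
        pd.DataFrame(
            {"trial": np.arange(1, self.markers.size + 1), "time_s": self.markers}
        ).to_csv(marker_path, index=False)

    @classmethod
    def from_csv(
        cls, trace_path, marker_path, baseline_span_s: float = DEFAULT_BASELINE_SPAN_S
    ) -> "SCRTrace":
        tr = pd.read_csv(trace_path)
        mk = pd.read_csv(marker_path)
        for df, cols, what in (
            (tr, {"time_s", "conductance_uS"}, "trace"),
            (mk, {"trial", "time_s"}, "marker"),
        ):
            missing = cols - set(df.columns)
            if missing:
                raise ValueError(f"{what} CSV missing columns: {sorted(missing)}")
        t = tr["time_s"].to_numpy()
        dt = np.diff(t)
        if t.size < 2 or np.ptp(dt) > 1e-6:
            raise ValueError("trace must be uniformly sampled")
        return cls(
            samples=tr["conductance_uS"].to_numpy(),
            sampling_rate=1.0 / float(dt[0]),
            markers=mk.sort_values("trial")["time_s"].to_numpy(),
            baseline_span_s=baseline_span_s,
        )


def window_mean(
    trace: SCRTrace,
    marker_s: float,
    duration_ms: float = DEFAULT_WINDOW_MS,
    direction: str = "pre",
) -> float:
    """Mean conductance in a half-open window locked to a marker.

    pre : samples in [marker - duration, marker)  — excludes the marker sample
    post: samples in [marker, marker + duration)  — includes it
    """
    if direction not in ("pre", "post"):
        raise ValueError(f"direction must be 'pre' or 'post', got {direction!r}")
    dur = duration_ms / 1000.0
    lo, hi = (marker_s - dur, marker_s) if direction == "pre" else (marker_s, marker_s + dur)
    if lo < -1e-9 or hi > trace.duration_s + 1e-9:
        raise WindowError(
            f"window [{lo:.3f}, {hi:.3f}) s outside recording of {trace.duration_s:.3f} s"
        )
    i0 = int(np.ceil(lo * trace.sampling_rate - 1e-9))
    i1 = int(np.ceil(hi * trace.sampling_rate - 1e-9))  # exclusive
    if i1 <= i0:
        raise WindowError("window contains no samples (sampling rate too low)")
    return float(trace.samples[i0:i1].mean())


def baseline_mean(trace: SCRTrace) -> float:
    """Mean conductance over the pre-task baseline span."""
    if trace.baseline_span_s <= 0:
        raise ValueError("trace has no baseline span")
    n = int(round(trace.baseline_span_s * trace.sampling_rate))
    if n == 0 or trace.samples.size < n:
        raise ValueError("recording shorter than the baseline span")
    return float(trace.samples[:n].mean())


def anticipatory_means(
    trace: SCRTrace, duration_ms: float = DEFAULT_WINDOW_MS
) -> np.ndarray:
    """Per-trial mean conductance over the pre-marker window."""
    return np.array([window_mean(trace, m, duration_ms, "pre") for m in trace.markers])


def post_means(trace: SCRTrace, duration_ms: float = DEFAULT_WINDOW_MS) -> np.ndarray:
    """Per-trial mean conductance over the post-marker window."""
    return np.array([window_mean(trace, m, duration_ms, "post") for m in trace.markers])


def ascr_index(anticipatory: Sequence[float], choices: Sequence[str]) -> float:
    """Signed aSCR index: mean over A/B trials minus mean over C/D trials."""
    anticipatory = np.asarray(anticipatory, dtype=float)
    if anticipatory.size != len(choices):
        raise ValueError("need exactly one anticipatory mean per trial")
    bad = set(choices) - set(DECK_IDS)
    if bad:
        raise ValueError(f"invalid deck labels: {sorted(bad)}")
    adv = np.array([c in ADVANTAGEOUS for c in choices])
    if adv.all() or not adv.any():
        raise ValueError("aSCR index undefined: a deck type was never chosen")
    return float(anticipatory[~adv].mean() - anticipatory[adv].mean())


def assign_group(index: float) -> str:
    """aSCR+ for a positive index, aSCR- for negative, tie -> indeterminate."""
    if not np.isfinite(index):
        raise ValueError("aSCR index must be finite")
    if index > 0:
        return GROUP_POS
    if index < 0:
        return GROUP_NEG
    return GROUP_TIE


@dataclass
class ASCRProfile:
    """One subject's windowed-SCR summary and responder label."""

    subject_id: str
    anticipatory_means: np.ndarray
    post_means: np.ndarray
    baseline_mean: float
    ascr_index: float
    group_label: str
    per_type_anticipatory: dict = field(default_factory=dict)

    @classmethod
    def from_trace(
        cls,
        trace: SCRTrace,
        choices: Sequence[str],
        subject_id: str = "",
        window_ms: float = DEFAULT_WINDOW_MS,
        post_window_ms: float | None = None,
    ) -> "ASCRProfile":
        ant = anticipatory_means(trace, window_ms)
        post = post_means(trace, post_window_ms if post_window_ms is not None else window_ms)
        idx = ascr_index(ant, choices)
        adv = np.array([c in ADVANTAGEOUS for c in choices])
        return cls(
            subject_id=subject_id,
            anticipatory_means=ant,
            post_means=post,
            baseline_mean=baseline_mean(trace),
            ascr_index=idx,
            group_label=assign_group(idx),
            per_type_anticipatory={
                "disadvantageous": float(ant[~adv].mean()),
                "advantageous": float(ant[adv].mean()),
            },
        )


def profile_table(profiles: Sequence[ASCRProfile]) -> pd.DataFrame:
    """One row per subject: baseline, per-type anticipatory means, index, group."""
    return pd.DataFrame(
        [
            {
                "subject_id": p.subject_id,
                "baseline_uS": p.baseline_mean,
                "anticipatory_disadv_uS": p.per_type_anticipatory.get("disadvantageous"),
                "anticipatory_adv_uS": p.per_type_anticipatory.get("advantageous"),
                "ascr_index_uS": p.ascr_index,
                "group": p.group_label,
            }
            for p in profiles
        ]
    )
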
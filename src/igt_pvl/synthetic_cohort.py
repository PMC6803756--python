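"""Synthetic study cohorts: PVL-driven sessions, SCR traces, response times.

Emulates the structure of a two-group anticipatory-SCR study: 14 aSCR-
and 15 aSCR+ subjects, each completing a 100-trial ABCD session generated
by a PVL agent whose parameters are drawn from group-specific
distributions (group means/SDs default to the study-style MLE values),
plus a skin-conductance trace whose anticipatory amplitude before
disadvantageous vs. advantageous decks differs by group, and lognormal
response times whose location decreases over blocks (steepest between the
first and second block).

The generator's purpose is statistical, not physiological: traces carry a
tonic baseline, slow autocorrelated drift, event-locked phasic bumps
inside the 1250 ms pre-choice window, and white measurement noise — the
window-level statistics the analysis consumes — and nothing finer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
from scipy.stats import truncnorm

from .igt_task import ADVANTAGEOUS, SessionLog, TaskConfig, build_standard_decks
from .pvl_model import DEFAULT_OUTCOME_SCALE, MLE_BOUNDS, PVLParameters, simulate_agent
from .scr_pipeline import DEFAULT_BASELINE_SPAN_S, DEFAULT_WINDOW_MS, SCRTrace

#: block-wise target mean RTs (ms) for the lognormal generator; the steep
#: drop sits between blocks 1 and 2, matching the qualitative task pattern
DEFAULT_BLOCK_RT_MEANS_MS = (2900.0, 2080.0, 1960.0, 1820.0, 1790.0)
DEFAULT_RT_SIGMA = 0.40  # lognormal shape

PARAM_ORDER = ("alpha", "lam", "A", "c")
_PVL_FIELD = {"alpha": "alpha", "lam": "lam", "A": "recency_A", "c": "consistency_c"}


@dataclass(frozen=True)
class GroupProfile:
    """Generative description of one responder group."""

    label: str
    n_subjects: int
    param_means: dict[str, float]
    param_sds: dict[str, float]
    baseline_mean_uS: float
    baseline_sd_uS: float
    amp_disadv_uS: float  # phasic amplitude before A/B choices
    amp_adv_uS: float  # phasic amplitude before C/D choices

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("group needs at least 2 subjects")
        if any(self.param_sds[k] < 0 for k in PARAM_ORDER):
            raise ValueError("parameter SDs must be non-negative")


def default_negative_group() -> GroupProfile:
    return GroupProfile(
        label="aSCR-",
        n_subjects=14,
        param_means={"alpha": 0.557, "lam": 3.00, "A": 0.495, "c": 0.365},
        param_sds={"alpha": 0.41, "lam": 2.17, "A": 0.31, "c": 0.36},
        baseline_mean_uS=4.82,
        baseline_sd_uS=3.25,
        amp_disadv_uS=0.2,
        amp_adv_uS=0.5,
    )


def default_positive_group() -> GroupProfile:
    return GroupProfile(
        label="aSCR+",
        n_subjects=15,
        param_means={"alpha": 0.165, "lam": 2.57, "A": 0.458, "c": 0.998},
        param_sds={"alpha": 0.26, "lam": 2.22, "A": 0.32, "c": 1.16},
        baseline_mean_uS=6.66,
        baseline_sd_uS=4.46,
        amp_disadv_uS=0.5,
        amp_adv_uS=0.2,
    )


@dataclass(frozen=True)
class CohortSpec:
    """Full recipe for one synthetic cohort."""

    groups: tuple[GroupProfile, ...] = field(
        default_factory=lambda: (default_negative_group(), default_positive_group())
    )
    rule: str = "decay"
    task: TaskConfig = field(default_factory=TaskConfig)
    outcome_scale: float = DEFAULT_OUTCOME_SCALE
    sampling_rate_hz: float = 32.0
    noise_ar_coef: float = 0.95
    noise_ar_sd_uS: float = 0.02  # AR(1) innovation SD
    noise_white_sd_uS: float = 0.02
    bump_sigma_ms: float = 300.0
    bump_shape: str = "half_gaussian"  # or "rect"
    block_rt_means_ms: tuple[float, ...] = DEFAULT_BLOCK_RT_MEANS_MS
    rt_sigma: float = DEFAULT_RT_SIGMA
    shuffle_cycles: bool = False

    def __post_init__(self) -> None:
        if self.bump_shape not in ("half_gaussian", "rect"):
            raise ValueError(f"unknown bump shape {self.bump_shape!r}")
        for g in self.groups:
            hi, lo = (g.amp_disadv_uS, g.amp_adv_uS)
            if g.label == "aSCR+" and hi <= lo:
                raise ValueError("aSCR+ group must have larger pre-A/B amplitude")
            if g.label == "aSCR-" and hi >= lo:
                raise ValueError("aSCR- group must have larger pre-C/D amplitude")
        if len(self.block_rt_means_ms) != self.task.n_blocks:
            raise ValueError("need one RT location per block")


@dataclass
class SubjectRecord:
    subject_id: str
    true_group: str
    true_params: PVLParameters
    baseline_uS: float
    session: SessionLog
    trace: SCRTrace
    seed: int


@dataclass
class Cohort:
    spec: CohortSpec
    subjects: list[SubjectRecord]
    seed: int

    def sessions(self) -> list[SessionLog]:
        return [s.session for s in self.subjects]

    def by_group(self, label: str) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.true_group == label]


def _truncated_normal(mean: float, sd: float, lo: float, hi: float, rng) -> float:
    if sd == 0:
        return float(np.clip(mean, lo + 1e-9, hi - 1e-9))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def draw_group_params(profile: GroupProfile, rule: str, rng) -> PVLParameters:
    """One subject's PVL parameters: truncated normal inside the MLE box."""
    vals = {}
    for name in PARAM_ORDER:
        lo, hi = MLE_BOUNDS[name]
        # open interval: keep strictly inside
        vals[name] = _truncated_normal(
            profile.param_means[name], profile.param_sds[name], lo + 1e-6, hi - 1e-6, rng
        )
    return PVLParameters(
        alpha=vals["alpha"],
        lam=vals["lam"],
        recency_A=vals["A"],
        consistency_c=vals["c"],
        rule=rule,
    )


def draw_response_times(spec: CohortSpec, rng) -> np.ndarray:
    """Lognormal RTs (ms) with block-wise decreasing location."""
    out = np.empty(spec.task.n_trials)
    for b, target in enumerate(spec.block_rt_means_ms):
        mu = np.log(target) - spec.rt_sigma**2 / 2.0
        sl = slice(b * spec.task.block_size, (b + 1) * spec.task.block_size)
        out[sl] = rng.lognormal(mu, spec.rt_sigma, spec.task.block_size)
    return out


def marker_times(rts_ms: np.ndarray, min_interval_s: float = 1.0,
                 task_start_s: float = DEFAULT_BASELINE_SPAN_S) -> np.ndarray:
    """Card-selection timestamps: each trial waits the minimum interval,
    then the subject deliberates for its response time."""
    gaps = min_interval_s + np.asarray(rts_ms, float) / 1000.0
    return task_start_s + np.cumsum(gaps)


def generate_trace(
    session: SessionLog,
    baseline_uS: float,
    amp_disadv_uS: float,
    amp_adv_uS: float,
    seed: int,
    spec: CohortSpec | None = None,
) -> SCRTrace:
    """Synthesize one subject's conductance trace around a session.

    Components: constant tonic level; AR(1) drift; white noise; one phasic
    bump per trial, confined to the 1250 ms pre-marker window, with
    amplitude set by the upcoming deck's type.  The bump is a half-Gaussian
    rising to its peak at the marker (or a rectangle covering the window,
    for exact-arithmetic fixtures).
    """
    spec = spec or CohortSpec()
    rts = session.rts_ms
    if np.any(rts < 0):
        raise ValueError("negative response times")
    markers = marker_times(rts, spec.task.min_inter_choice_interval_s)
    if np.any(np.diff(markers) < spec.task.min_inter_choice_interval_s - 1e-9):
        raise ValueError("marker spacing violates the minimum inter-choice interval")
    fs = spec.sampling_rate_hz
    dur = markers[-1] + DEFAULT_WINDOW_MS / 1000.0 + 1.0
    n = int(np.ceil(dur * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(seed)

    sig = np.full(n, float(baseline_uS))
    # slow drift: AR(1) + white component
    if spec.noise_ar_sd_uS > 0:
        innov = rng.normal(0, spec.noise_ar_sd_uS, n)
        drift = np.empty(n)
        acc = 0.0
        a = spec.noise_ar_coef
        for i in range(n):  # short enough at 32 Hz; ~O(n)
            acc = a * acc + innov[i]
            drift[i] = acc
        sig += drift
    if spec.noise_white_sd_uS > 0:
        sig += rng.normal(0, spec.noise_white_sd_uS, n)

    win_s = DEFAULT_WINDOW_MS / 1000.0
    sigma_s = spec.bump_sigma_ms / 1000.0
    for m, deck in zip(markers, session.choices):
        amp = amp_disadv_uS if deck not in ADVANTAGEOUS else amp_adv_uS
        if amp == 0:
            continue
        in_win = (t >= m - win_s) & (t < m)
        if spec.bump_shape == "rect":
            sig[in_win] += amp
        else:
            sig[in_win] += amp * np.exp(-((t[in_win] - m) ** 2) / (2 * sigma_s**2))
    return SCRTrace(samples=sig, sampling_rate=fs, markers=markers)


def generate_cohort(spec: CohortSpec | None = None, seed: int = 0) -> Cohort:
    """Generate a complete cohort; fully reproducible under ``seed``."""
    spec = spec or CohortSpec()
    ss = np.random.SeedSequence(seed)
    deck_set = build_standard_decks()
    if spec.shuffle_cycles:
        deck_set = deck_set.shuffled_within_cycles(int(ss.generate_state(1)[0] % 2**31))
    subjects: list[SubjectRecord] = []
    idx = 0
    for g_i, group in enumerate(spec.groups):
        for s_i in range(group.n_subjects):
            idx += 1
            sub_ss = np.random.SeedSequence(entropy=seed, spawn_key=(g_i, s_i))
            rng = np.random.default_rng(sub_ss)
            sub_seed = int(sub_ss.generate_state(1)[0] % 2**31)
            params = draw_group_params(group, spec.rule, rng)
            rts = draw_response_times(spec, rng)
            session = simulate_agent(
                params,
                deck_set=deck_set,
                config=spec.task,
                seed=sub_seed,
                outcome_scale=spec.outcome_scale,
                rts_ms=rts,
            )
            session.subject_id = f"S{idx:02d}"
            baseline = _truncated_normal(
                group.baseline_mean_uS, group.baseline_sd_uS, 0.5, 100.0, rng
            )
            trace = generate_trace(
                session,
                baseline_uS=baseline,
                amp_disadv_uS=group.amp_disadv_uS,
                amp_adv_uS=group.amp_adv_uS,
                seed=sub_seed + 1,
                spec=spec,
            )
            subjects.append(
                SubjectRecord(
                    subject_id=session.subject_id,
                    true_group=group.label,
                    true_params=params,
                    baseline_uS=baseline,
                    session=session,
                    trace=trace,
                    seed=sub_seed,
                )
            )
    return Cohort(spec=spec, subjects=subjects, seed=seed)


def write_cohort(cohort: Cohort, outdir) -> Path:
    """Write session/trace/marker CSVs plus a manifest with the truths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cohort.seed, "subjects": []}
    for sub in cohort.subjects:
        sid = sub.subject_id
        session_f = outdir / f"{sid}_session.csv"
        trace_f = outdir / f"{sid}_trace.csv"
        marker_f = outdir / f"{sid}_markers.csv"
        sub.session.to_csv(session_f)
        sub.trace.to_csv(trace_f, marker_f)
        manifest["subjects"].append(
            {
                "subject_id": sid,
                "true_group": sub.true_group,
                "true_params": {
                    "alpha": sub.true_params.alpha,
                    "lam": sub.true_params.lam,
                    "A": sub.true_params.recency_A,
                    "c": sub.true_params.consistency_c,
                    "rule": sub.true_params.rule,
                },
                "baseline_uS": sub.baseline_uS,
                "seed": sub.seed,
                "files": {
                    "session": session_f.name,
                    "trace": trace_f.name,
                    "markers": marker_f.name,
                },
            }
        )
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
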
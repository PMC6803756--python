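"""Prospect Valence Learning (PVL) model of Iowa Gambling Task choice.

The model combines three components applied trial by trial:

1. a prospect-theory power utility with loss aversion,
       u(x) = x**alpha          if x >= 0
       u(x) = -lam * |x|**alpha if x <  0
2. an expectancy update for the four decks — either the *decay* rule
   (every deck's expectancy decays by factor A each trial, the chosen
   deck additionally receives u) or the *delta* (Rescorla–Wagner) rule
   (only the chosen deck moves toward u at learning rate A);
3. a softmax choice rule with inverse temperature theta = 3**c - 1,
   so c = 0 yields fully random choice and large c near-deterministic
   choice.

Net payoffs are rescaled (default: divided by 100, i.e. expressed in
units of 100 EUR) before entering the utility; with raw EUR amounts and
consistency values up to 5 the softmax exponent overflows.  The scale
factor is a parameter everywhere it matters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.special import log_softmax

from .igt_task import (
    DECK_IDS,
    DeckSet,
    SessionLog,
    TaskConfig,
    build_standard_decks,
    play_session,
)

RULES = ("decay", "delta")
DEFAULT_OUTCOME_SCALE = 100.0

#: parameter boxes (open intervals) per estimation scheme: (alpha, lam, A, c)
MLE_BOUNDS = {"alpha": (0.0, 1.0), "lam": (0.0, 5.0), "A": (0.0, 1.0), "c": (0.0, 5.0)}
HBA_BOUNDS = {"alpha": (0.0, 2.0), "lam": (0.0, 10.0), "A": (0.0, 1.0), "c": (0.0, 5.0)}


def theta_from_c(c: float) -> float:
    """Softmax inverse temperature, theta = 3**c - 1."""
    return 3.0**c - 1.0


@dataclass(frozen=True)
class PVLParameters:
    """The four PVL parameters plus the update-rule tag.

    alpha : outcome-sensitivity exponent of the power utility
    lam   : loss aversion (>1 means losses loom larger than gains)
    recency_A : decay rate (decay rule) or learning rate (delta rule)
    consistency_c : choice consistency; theta = 3**c - 1
    """

    alpha: float
    lam: float
    recency_A: float
    consistency_c: float
    rule: str = "decay"

    def __post_init__(self) -> None:
        if self.rule not in RULES:
            raise ValueError(f"unknown rule {self.rule!r}; expected one of {RULES}")
        if not 0.0 < self.recency_A < 1.0:
            raise ValueError("recency_A must lie in (0, 1)")
        for name in ("alpha", "lam", "consistency_c"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be positive")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.alpha, self.lam, self.recency_A, self.consistency_c], dtype=float
        )

    def to_json(self, bound_scheme: str = "mle") -> str:
        return json.dumps(
            {
                "alpha": self.alpha,
                "lam": self.lam,
                "recency_A": self.recency_A,
                "consistency_c": self.consistency_c,
                "rule": self.rule,
                "bound_scheme": bound_scheme,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "PVLParameters":
        d = json.loads(text)
        return cls(
            alpha=d["alpha"],
            lam=d["lam"],
            recency_A=d["recency_A"],
            consistency_c=d["consistency_c"],
            rule=d.get("rule", "decay"),
        )


@dataclass
class ExpectancyState:
    """Per-deck expectancies E_j(t); all zero before the first trial."""

    E: np.ndarray = field(default_factory=lambda: np.zeros(4))
    trial_index: int = 0

    def copy(self) -> "ExpectancyState":
        return ExpectancyState(E=self.E.copy(), trial_index=self.trial_index)


def utility(x: float | np.ndarray, alpha: float, lam: float) -> float | np.ndarray:
    """Prospect-theory value of a (scaled) net outcome x."""
    if alpha <= 0 or lam <= 0:
        raise ValueError("alpha and lam must be positive")
    x = np.asarray(x, dtype=float)
    out = np.where(x >= 0, np.abs(x) ** alpha, -lam * np.abs(x) ** alpha)
    return float(out) if out.ndim == 0 else out


def update_expectancies(
    state: ExpectancyState,
    chosen: str,
    u: float,
    recency_A: float,
    rule: str = "decay",
) -> ExpectancyState:
    """Apply one expectancy update; returns a new state (input untouched)."""
    if rule not in RULES:
        raise ValueError(f"unknown rule {rule!r}")
    j = DECK_IDS.index(chosen)
    E = state.E.copy()
    if rule == "decay":
        E *= recency_A
        E[j] += u
    else:  # delta: only the chosen deck moves
        E[j] += recency_A * (u - E[j])
    return ExpectancyState(E=E, trial_index=state.trial_index + 1)


def choice_probabilities(
    state: ExpectancyState,
    consistency_c: float,
    available: np.ndarray | None = None,
) -> np.ndarray:
    """Softmax choice probabilities over the four decks.

    Computed in the log domain (max-shifted) so large theta*E never
    overflows.  ``available`` is an optional boolean mask; exhausted decks
    receive probability zero with renormalization over the rest.
    """
    if consistency_c < 0:
        raise ValueError("consistency_c must be non-negative")
    theta = theta_from_c(consistency_c)
    logits = theta * state.E
    if available is not None:
        available = np.asarray(available, dtype=bool)
        if not available.any():
            raise RuntimeError("no decks available")
        logits = np.where(available, logits, -np.inf)
    return np.exp(log_softmax(logits))


# ---------------------------------------------------------------------------
# Fast sequence likelihood (hot path for MLE and MCMC)

@njit(cache=True)
def _loglik_core(
    alpha: float,
    lam: float,
    A: float,
    c: float,
    decay: bool,
    choices: np.ndarray,  # int64, 0..3
    x: np.ndarray,  # float64, scaled nets
    total_cards: int,
) -> float:
    n = choices.shape[0]
    theta = 3.0**c - 1.0
    E = np.zeros(4)
    counts = np.zeros(4, dtype=np.int64)
    ll = 0.0
    for t in range(n):
        # log-softmax over available decks, max-shifted
        m = -1.0e308
        for j in range(4):
            if counts[j] < total_cards:
                v = theta * E[j]
                if v > m:
                    m = v
        s = 0.0
        for j in range(4):
            if counts[j] < total_cards:
                s += np.exp(theta * E[j] - m)
        k = choices[t]
        ll += theta * E[k] - m - np.log(s)
        counts[k] += 1
        # utility of this trial's outcome
        xt = x[t]
        if xt >= 0.0:
            u = xt**alpha
        else:
            u = -lam * (-xt) ** alpha
        if decay:
            for j in range(4):
                E[j] *= A
            E[k] += u
        else:
            E[k] += A * (u - E[k])
    return ll


def encode_session(
    session: SessionLog, outcome_scale: float = DEFAULT_OUTCOME_SCALE
) -> tuple[np.ndarray, np.ndarray]:
    """Session -> (choice indices, scaled net outcomes) for the fast core."""
    try:
        choices = np.array([DECK_IDS.index(d) for d in session.choices], dtype=np.int64)
    except ValueError as exc:
        raise ValueError(f"session contains an invalid deck label: {exc}") from None
    x = session.nets / outcome_scale
    return choices, x


def sequence_loglik(
    params: PVLParameters,
    session: SessionLog,
    outcome_scale: float = DEFAULT_OUTCOME_SCALE,
    total_cards: int = 40,
) -> float:
    """Log-likelihood of an observed choice sequence under the PVL model.

    Trial-1 probabilities are uniform over available decks (expectancies
    start at zero); thereafter exhausted decks are masked out exactly as
    the task engine masks them.
    """
    if session.n_trials == 0:
        raise ValueError("empty session")
    choices, x = encode_session(session, outcome_scale)
    return float(
        _loglik_core(
            params.alpha,
            params.lam,
            params.recency_A,
            params.consistency_c,
            params.rule == "decay",
            choices,
            x,
            total_cards,
        )
    )


def sequence_loglik_reference(
    params: PVLParameters,
    session: SessionLog,
    outcome_scale: float = DEFAULT_OUTCOME_SCALE,
) -> float:
    """Slow trial-by-trial replay through the public single-step operations.

    Exists as an independently-written cross-check of the compiled core.
    """
    state = ExpectancyState()
    counts = dict.fromkeys(DECK_IDS, 0)
    ll = 0.0
    for rec in session.records:
        avail = np.array([counts[d] < 40 for d in DECK_IDS])
        p = choice_probabilities(state, params.consistency_c, available=avail)
        ll += float(np.log(p[DECK_IDS.index(rec.deck)]))
        u = utility(rec.net / outcome_scale, params.alpha, params.lam)
        state = update_expectancies(state, rec.deck, u, params.recency_A, params.rule)
        counts[rec.deck] += 1
    return ll


def simulate_agent(
    params: PVLParameters,
    deck_set: DeckSet | None = None,
    config: TaskConfig | None = None,
    seed: int = 0,
    outcome_scale: float = DEFAULT_OUTCOME_SCALE,
    rts_ms=None,
) -> SessionLog:
    """Simulate a full session of a PVL agent on the task engine.

    ``play_session`` drives the loop; the agent digests any history entries
    it has not yet seen (its own past outcomes) before each choice.
    """
    state = ExpectancyState()
    digested = 0

    def chooser(history, available, rng):
        nonlocal state, digested
        while digested < len(history):
            rec = history[digested]
            u = utility(rec.net / outcome_scale, params.alpha, params.lam)
            state = update_expectancies(state, rec.deck, u, params.recency_A, params.rule)
            digested += 1
        avail_mask = np.array([d in available for d in DECK_IDS])
        p = choice_probabilities(state, params.consistency_c, available=avail_mask)
        j = int(rng.choice(4, p=p))
        return DECK_IDS[j]

    return play_session(
        chooser,
        config=config,
        seed=seed,
        deck_set=deck_set or build_standard_decks(),
        rts_ms=rts_ms,
    )
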
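"""Iowa Gambling Task payoff engine.

The classical ABCD task: four decks of 40 cards each, drawn one card per
trial for 100 trials.  Decks A and B are disadvantageous — every full
10-card cycle nets a 250 EUR loss — while decks C and D are advantageous,
netting +250 EUR per cycle.  A and C spread their losses over five cards
per cycle; B and D concentrate them in a single large loss.  Card stacks
are deterministic: outcome depends only on (deck, draw position).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

DECK_IDS = ("A", "B", "C", "D")

#: deck classification used throughout: C/D advantageous, A/B disadvantageous
ADVANTAGEOUS = frozenset({"C", "D"})
DISADVANTAGEOUS = frozenset({"A", "B"})


class DeckExhaustedError(RuntimeError):
    """A deck was drawn past its 40th card."""


class PolicyContractError(RuntimeError):
    """A choice policy returned a deck that is not available."""


@dataclass(frozen=True)
class DeckSchedule:
    """Payoff contingencies of a single deck.

    ``loss_sequence`` holds one 10-card cycle of losses (0 = no loss on
    that card); the same cycle repeats four times over the 40-card stack.
    All amounts are exact integer EUR.
    """

    deck_id: str
    gain_per_card: int
    loss_sequence: tuple[int, ...]
    total_cards: int = 40
    cycle_length: int = 10

    def __post_init__(self) -> None:
        if self.deck_id not in DECK_IDS:
            raise ValueError(f"unknown deck id {self.deck_id!r}")
        if len(self.loss_sequence) != self.cycle_length:
            raise ValueError("loss_sequence must cover one full cycle")
        if self.total_cards != 4 * self.cycle_length:
            raise ValueError("total_cards must be 4 cycles")

    @property
    def cycle_net(self) -> int:
        return self.gain_per_card * self.cycle_length - sum(self.loss_sequence)

    def loss_at(self, draw_index: int) -> int:
        """Loss on the ``draw_index``-th draw (1-based)."""
        if not 1 <= draw_index <= self.total_cards:
            raise DeckExhaustedError(
                f"deck {self.deck_id}: draw {draw_index} outside 1..{self.total_cards}"
            )
        return self.loss_sequence[(draw_index - 1) % self.cycle_length]


@dataclass(frozen=True)
class CardOutcome:
    gain: int
    loss: int

    @property
    def net(self) -> int:
        return self.gain - self.loss


@dataclass(frozen=True)
class TaskConfig:
    starting_balance: int = 2000
    n_trials: int = 100
    block_size: int = 20
    min_inter_choice_interval_s: float = 1.0
    currency_label: str = "EUR"

    def __post_init__(self) -> None:
        if self.n_trials % self.block_size:
            raise ValueError("n_trials must be divisible by block_size")
        if self.n_trials > 160:
            raise ValueError("n_trials cannot exceed the 160 cards available")

    @property
    def n_blocks(self) -> int:
        return self.n_trials // self.block_size


# Classical fixed within-cycle layouts.  Loss positions follow the original
# ABCD stacks: deck A loses on cards 3,5,7,9,10 of each cycle, deck C on
# 3,5,7,9,10, decks B and D on card 9.  Magnitudes are fixed so each cycle
# nets exactly -250 (A, B) or +250 (C, D).
_A_LOSSES = {3: 150, 5: 300, 7: 200, 9: 250, 10: 350}
_B_LOSSES = {9: 1250}
_C_LOSSES = {3: 50, 5: 25, 7: 50, 9: 50, 10: 75}
_D_LOSSES = {9: 250}


def _cycle(losses: dict[int, int]) -> tuple[int, ...]:
    return tuple(losses.get(pos, 0) for pos in range(1, 11))


@dataclass(frozen=True)
class DeckSet:
    """The four deck schedules, keyed by deck id."""

    decks: dict[str, DeckSchedule]

    def __getitem__(self, deck_id: str) -> DeckSchedule:
        try:
            return self.decks[deck_id]
        except KeyError:
            raise KeyError(f"unknown deck id {deck_id!r}") from None

    def shuffled_within_cycles(self, seed: int) -> "DeckSet":
        """Return a copy with loss positions shuffled inside each cycle.

        Magnitudes and per-cycle nets are preserved; only the within-cycle
        order changes (independently per deck, deterministic under seed).
        """
        rng = np.random.default_rng(seed)
        out = {}
        for did, deck in self.decks.items():
            seq = np.array(deck.loss_sequence)
            rng.shuffle(seq)
            out[did] = replace(deck, loss_sequence=tuple(int(v) for v in seq))
        return DeckSet(out)

    def to_json(self) -> str:
        payload = {
            did: {
                "gain_per_card": d.gain_per_card,
                "loss_sequence": list(d.loss_sequence),
                "total_cards": d.total_cards,
                "cycle_length": d.cycle_length,
            }
            for did, d in self.decks.items()
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DeckSet":
        payload = json.loads(text)
        return cls(
            {
                did: DeckSchedule(
                    deck_id=did,
                    gain_per_card=spec["gain_per_card"],
                    loss_sequence=tuple(spec["loss_sequence"]),
                    total_cards=spec.get("total_cards", 40),
                    cycle_length=spec.get("cycle_length", 10),
                )
                for did, spec in payload.items()
            }
        )


def build_standard_decks() -> DeckSet:
    """Build the classical ABCD deck set.

    Deck A: gain 100, five losses per cycle in 150..350 summing to 1250.
    Deck B: gain 100, one loss of 1250 per cycle.
    Deck C: gain 50, five losses per cycle in 25..75 summing to 250.
    Deck D: gain 50, one loss of 250 per cycle.
    """
    return DeckSet(
        {
            "A": DeckSchedule("A", 100, _cycle(_A_LOSSES)),
            "B": DeckSchedule("B", 100, _cycle(_B_LOSSES)),
            "C": DeckSchedule("C", 50, _cycle(_C_LOSSES)),
            "D": DeckSchedule("D", 50, _cycle(_D_LOSSES)),
        }
    )


def draw_card(deck_set: DeckSet, deck_id: str, draw_index: int) -> CardOutcome:
    """Outcome of the ``draw_index``-th draw (1-based) from a deck.

    Deterministic: the stacks are fixed card sequences, not distributions.
    """
    deck = deck_set[deck_id]
    loss = deck.loss_at(draw_index)
    return CardOutcome(gain=deck.gain_per_card, loss=loss)


@dataclass
class TrialRecord:
    trial: int  # 1-based
    deck: str
    gain: int
    loss: int
    net: int
    balance: int
    rt_ms: float


@dataclass
class SessionLog:
    """One subject's complete trial-by-trial task record."""

    subject_id: str
    records: list[TrialRecord]
    config: TaskConfig = field(default_factory=TaskConfig)
    seed: int | None = None

    @property
    def n_trials(self) -> int:
        return len(self.records)

    @property
    def choices(self) -> list[str]:
        return [r.deck for r in self.records]

    @property
    def nets(self) -> np.ndarray:
        return np.array([r.net for r in self.records], dtype=float)

    @property
    def rts_ms(self) -> np.ndarray:
        return np.array([r.rt_ms for r in self.records], dtype=float)

    @property
    def final_balance(self) -> int:
        return self.records[-1].balance if self.records else self.config.starting_balance

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "trial": r.trial,
                    "deck": r.deck,
                    "gain": r.gain,
                    "loss": r.loss,
                    "net": r.net,
                    "balance": r.balance,
                    "rt_ms": r.rt_ms,
                }
                for r in self.records
            ]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, subject_id: str = "", config: TaskConfig | None = None) -> "SessionLog":
        df = pd.read_csv(path)
        required = {"trial", "deck", "gain", "loss", "net", "balance", "rt_ms"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"session CSV missing columns: {sorted(missing)}")
        records = [
            TrialRecord(
                trial=int(row.trial),
                deck=str(row.deck),
                gain=int(row.gain),
                loss=int(row.loss),
                net=int(row.net),
                balance=int(row.balance),
                rt_ms=float(row.rt_ms),
            )
            for row in df.itertuples()
        ]
        return cls(subject_id=subject_id, records=records, config=config or TaskConfig())


Chooser = Callable[[list[TrialRecord], Sequence[str], np.random.Generator], str]
"""Choice policy: (history, available decks, rng) -> deck id."""


def play_session(
    chooser: Chooser,
    config: TaskConfig | None = None,
    seed: int = 0,
    deck_set: DeckSet | None = None,
    subject_id: str = "anon",
    rts_ms: Sequence[float] | None = None,
) -> SessionLog:
    """Run one session, applying ``chooser`` on every trial.

    Exhausted decks (40 draws reached) are removed from the set offered to
    the policy; a policy returning an unavailable deck raises
    :class:`PolicyContractError`.  ``rts_ms`` optionally supplies recorded
    response times (default 0 for engine-level runs).
    """
    config = config or TaskConfig()
    deck_set = deck_set or build_standard_decks()
    rng = np.random.default_rng(seed)
    counts = {d: 0 for d in DECK_IDS}
    balance = config.starting_balance
    records: list[TrialRecord] = []
    for t in range(1, config.n_trials + 1):
        available = [d for d in DECK_IDS if counts[d] < deck_set[d].total_cards]
        if not available:
            raise RuntimeError("all decks exhausted")  # unreachable for n_trials <= 160
        deck = chooser(records, available, rng)
        if deck not in available:
            raise PolicyContractError(
                f"trial {t}: policy chose {deck!r}, available {available}"
            )
        counts[deck] += 1
        outcome = draw_card(deck_set, deck, counts[deck])
        balance += outcome.net
        rt = float(rts_ms[t - 1]) if rts_ms is not None else 0.0
        records.append(
            TrialRecord(
                trial=t,
                deck=deck,
                gain=outcome.gain,
                loss=outcome.loss,
                net=outcome.net,
                balance=balance,
                rt_ms=rt,
            )
        )
    return SessionLog(subject_id=subject_id, records=records, config=config, seed=seed)
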
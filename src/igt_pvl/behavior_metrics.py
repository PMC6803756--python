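"""Classical IGT behavioral measures.

Gambling Index GI = (#C + #D) - (#A + #B): positive values indicate
predominantly advantageous play.  Partial GIs are computed over blocks of
20 trials (B1..B5 for the standard 100-trial session).  Response-time
summaries are tabulated per block and deck type.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .igt_task import ADVANTAGEOUS, DECK_IDS, SessionLog

DEFAULT_BLOCK_SIZE = 20


def _validate(choices: Sequence[str]) -> None:
    bad = set(choices) - set(DECK_IDS)
    if bad:
        raise ValueError(f"invalid deck labels: {sorted(bad)}")


def gambling_index(choices: Sequence[str]) -> int:
    """(#C + #D) - (#A + #B) over a choice sequence."""
    _validate(choices)
    adv = sum(1 for c in choices if c in ADVANTAGEOUS)
    return 2 * adv - len(choices)


def block_indices(choices: Sequence[str], block_size: int = DEFAULT_BLOCK_SIZE) -> list[int]:
    """Gambling index of each contiguous block, in order."""
    if len(choices) % block_size:
        raise ValueError(
            f"sequence length {len(choices)} not divisible by block size {block_size}"
        )
    return [
        gambling_index(choices[i : i + block_size])
        for i in range(0, len(choices), block_size)
    ]


@dataclass(frozen=True)
class GamblingIndices:
    total_gi: int
    block_gis: tuple[int, ...]
    deck_counts: dict[str, int]
    advantageous_count: int
    disadvantageous_count: int

    @classmethod
    def from_choices(
        cls, choices: Sequence[str], block_size: int = DEFAULT_BLOCK_SIZE
    ) -> "GamblingIndices":
        _validate(choices)
        counts = {d: 0 for d in DECK_IDS}
        for c in choices:
            counts[c] += 1
        adv = counts["C"] + counts["D"]
        return cls(
            total_gi=gambling_index(choices),
            block_gis=tuple(block_indices(choices, block_size)),
            deck_counts=counts,
            advantageous_count=adv,
            disadvantageous_count=len(choices) - adv,
        )


def rt_summary(session: SessionLog, block_size: int = DEFAULT_BLOCK_SIZE) -> pd.DataFrame:
    """Mean and SD of response times per block and deck type, in ms.

    Cells with no choices of a type are missing (NaN), as is the SD of a
    single observation; nothing is imputed.
    """
    df = session.to_frame()
    if df["rt_ms"].isna().all():
        raise ValueError("session has no response times")
    df["block"] = (df["trial"] - 1) // block_size + 1
    df["deck_type"] = np.where(
        df["deck"].isin(sorted(ADVANTAGEOUS)), "advantageous", "disadvantageous"
    )
    out = (
        df.groupby(["block", "deck_type"])["rt_ms"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    # reindex to the full block x type grid so empty cells appear as missing
    blocks = range(1, session.n_trials // block_size + 1)
    grid = pd.MultiIndex.from_product(
        [blocks, ["advantageous", "disadvantageous"]], names=["block", "deck_type"]
    )
    out = out.set_index(["block", "deck_type"]).reindex(grid).reset_index()
    out["n"] = out["n"].fillna(0).astype(int)
    return out


def metrics_table(
    sessions: Sequence[SessionLog], block_size: int = DEFAULT_BLOCK_SIZE
) -> pd.DataFrame:
    """One row per subject: total/block GIs, deck counts, RT summaries."""
    rows = []
    for s in sessions:
        gi = GamblingIndices.from_choices(s.choices, block_size)
        row: dict = {"subject_id": s.subject_id, "total_gi": gi.total_gi}
        for i, b in enumerate(gi.block_gis, start=1):
            row[f"b{i}"] = b
        for d in DECK_IDS:
            row[f"n_{d}"] = gi.deck_counts[d]
        row["adv"] = gi.advantageous_count
        row["disadv"] = gi.disadvantageous_count
        rt = rt_summary(s, block_size)
        for r in rt.itertuples():
            tag = "adv" if r.deck_type == "advantageous" else "dis"
            row[f"rt_b{r.block}_{tag}_mean"] = r.mean
            row[f"rt_b{r.block}_{tag}_sd"] = r.sd
        rows.append(row)
    return pd.DataFrame(rows)
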
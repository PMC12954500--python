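"""Per-player per-season injury sequences and transition-pair extraction.

A sequence is the date-ordered list of one player's injuries within one
competitive season; seasons are treated independently (the summer break cuts
the chain), so no pair ever crosses a season or player boundary.  Under chain
semantics every injury except the last of a season is the initial injury of
exactly one transition — to its immediate successor, the first subsequent
injury — so the number of transitions equals the number of subsequent
injuries: sum over sequences of (length - 1).  Star semantics (only the
season's first injury emits its one pair) is available for sensitivity
analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .preprocessing import _season_labels
from .records import InjuryRecord, RecordSet

__all__ = [
    "PlayerSeasonSequence",
    "build_sequences",
    "extract_transitions",
    "transitions_from_recordset",
    "TRANSITION_COLUMNS",
]

#: columns of the tidy transitions table (one row per from->to pair)
TRANSITION_COLUMNS = (
    "player_id",
    "season_label",
    "from_date",
    "from_body_part",
    "from_nature",
    "from_category",
    "to_date",
    "to_body_part",
    "to_nature",
    "to_category",
    "gap_days",
)


@dataclass
class PlayerSeasonSequence:
    """Date-ordered injuries of one player within one season (length >= 2)."""

    player_id: str
    season_label: str
    frame: pd.DataFrame  # sorted by date, ties in input row order

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def records(self) -> list[InjuryRecord]:
        return RecordSet(self.frame.drop(columns=["body_part_raw"], errors="ignore")).records


def _sorted_frame(rs: RecordSet, season_start_month: int) -> pd.DataFrame:
    frame = rs.frame.copy()
    frame["season_label"] = _season_labels(frame, season_start_month)
    frame["_row"] = range(len(frame))
    # mergesort is stable: same-day injuries keep input row order
    frame = frame.sort_values(
        ["player_id", "season_label", "injury_date", "_row"], kind="mergesort"
    )
    return frame


def build_sequences(rs: RecordSet, season_start_month: int = 7) -> list[PlayerSeasonSequence]:
    """Group a preprocessed RecordSet into per-(player, season) sequences.

    Only groups with at least two injuries are returned (a lone injury has no
    transition).  Same-day ties keep input row order; a warning is emitted
    when ties are present, since the source data define no order for them.
    """
    frame = _sorted_frame(rs, season_start_month)
    ties = frame.duplicated(["player_id", "season_label", "injury_date"]).sum()
    if ties:
        warnings.warn(f"{int(ties)} same-day injury pair(s): order falls back to input row order", stacklevel=2)
    out: list[PlayerSeasonSequence] = []
    for (pid, season), grp in frame.groupby(["player_id", "season_label"], sort=True):
        if len(grp) < 2:
            continue
        out.append(PlayerSeasonSequence(pid, season, grp.drop(columns=["_row"])))
    return out


def _pairs(frame: pd.DataFrame, first_only: bool) -> pd.DataFrame:
    """Consecutive-pair extraction on a frame already sorted within groups."""
    same_group = (frame["player_id"].shift(-1) == frame["player_id"]) & (
        frame["season_label"].shift(-1) == frame["season_label"]
    )
    if first_only:
        first_of_group = ~(
            (frame["player_id"].shift(1) == frame["player_id"])
            & (frame["season_label"].shift(1) == frame["season_label"])
        )
        same_group &= first_of_group
    src = frame[same_group]
    dst = frame.shift(-1)[same_group]
    out = pd.DataFrame(
        {
            "player_id": src["player_id"].to_numpy(),
            "season_label": src["season_label"].to_numpy(),
            "from_date": src["injury_date"].to_numpy(),
            "from_body_part": src["body_part"].to_numpy(),
            "from_nature": src["nature"].to_numpy(),
            "from_category": src["category"].to_numpy(),
            "to_date": dst["injury_date"].to_numpy(),
            "to_body_part": dst["body_part"].to_numpy(),
            "to_nature": dst["nature"].to_numpy(),
            "to_category": dst["category"].to_numpy(),
        }
    )
    out["gap_days"] = (pd.to_datetime(out["to_date"]) - pd.to_datetime(out["from_date"])).dt.days
    if (out["gap_days"] < 0).any():
        raise ValueError("negative gap: sequences not date-ordered")
    return out


def extract_transitions(
    seqs: list[PlayerSeasonSequence], first_only: bool = False
) -> pd.DataFrame:
    """Transition pairs from sequences.

    Chain semantics (default): a sequence [I1, ..., Ik] yields the k-1
    consecutive pairs (I1->I2), ..., (Ik-1->Ik) — each initial injury's first
    subsequent injury.  ``first_only=True`` keeps only (I1->I2) per sequence
    (star semantics).
    """
    if not seqs:
        return pd.DataFrame(columns=list(TRANSITION_COLUMNS))
    frame = pd.concat([s.frame for s in seqs], ignore_index=True)
    return _pairs(frame, first_only)


def transitions_from_recordset(
    rs: RecordSet, season_start_month: int = 7, first_only: bool = False
) -> pd.DataFrame:
    """Sort, group and pair a preprocessed RecordSet in one vectorized pass.

    Equivalent to ``extract_transitions(build_sequences(rs))``; used by the
    estimator on large cohorts.
    """
    if len(rs) == 0:
        return pd.DataFrame(columns=list(TRANSITION_COLUMNS))
    frame = _sorted_frame(rs, season_start_month)
    return _pairs(frame, first_only)
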
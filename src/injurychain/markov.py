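"""First-order Markov model of within-season subsequent injuries.

An injury *state* is either the side-qualified body part combined with the
tissue nature ("Thigh|L:muscle") or a specific diagnosis category label
("Hamstring Muscle Injury").  Transition probabilities are estimated by
counting observed (from, to) pairs and dividing by one of two denominators:

* ``global`` — the total number of subsequent-injury transitions in the
  cohort, so all cell probabilities sum to 1 (the convention behind the
  reported matrices and their binomial confidence intervals);
* ``row`` — the number of transitions leaving the from-state, so each
  occupied row sums to 1 (the conditional next-injury distribution, the
  convention the definition of a Markov transition matrix implies).

Both are provided because figure-level reporting and the textbook definition
genuinely differ; pick explicitly.  Each part-nature transition is classified
into the subsequent-injury scenarios of the re-injury literature: same body
part and same nature (re-injury proper), same body part with different
nature, and the all-inclusive "any" scenario.

The surface is the sklearn-style :class:`MarkovTransitionEstimator`;
the module-level functions are the individual steps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .records import InjuryRecord, RecordSet
from .sequences import transitions_from_recordset
from .stats import attach_cis

__all__ = [
    "InjuryState",
    "TransitionCountMatrix",
    "SCENARIOS",
    "state_of",
    "state_label",
    "count_transitions",
    "estimate_probabilities",
    "classify_scenario",
    "filter_transitions",
    "scenario_table",
    "MarkovTransitionEstimator",
    "DEFAULT_EXCLUDED_CATEGORIES",
]

#: scenario tokens; scenario-1 and -2 are disjoint and partition the
#: same-body-part pairs; every pair belongs to "any"
SCENARIOS = ("same_part_same_nature", "same_part_diff_nature", "any")

_SCENARIO_ALIASES = {
    "1": "same_part_same_nature",
    "2": "same_part_diff_nature",
    "3": "any",
    "all": "any",
}

DEFAULT_EXCLUDED_CATEGORIES = ("Unsure", "Others")

_SEP = ":"  # joins side-qualified body part and nature in a state label


@dataclass(frozen=True)
class InjuryState:
    """A Markov state at one of two granularities.

    ``part_nature`` states carry the side-qualified body part and nature;
    ``categorization`` states carry the diagnosis category label only.
    Exactly the fields of the level are populated.
    """

    level: str
    body_part: str | None = None
    nature: str | None = None
    category: str | None = None

    def __post_init__(self):
        if self.level == "part_nature":
            if not self.body_part or self.nature is None or self.category is not None:
                raise ValueError("part_nature state requires body_part and nature only")
        elif self.level == "categorization":
            if not self.category or self.body_part is not None or self.nature is not None:
                raise ValueError("categorization state requires category only")
        else:
            raise ValueError(f"unknown state level: {self.level!r}")

    @property
    def label(self) -> str:
        if self.level == "part_nature":
            return f"{self.body_part}{_SEP}{self.nature}"
        return self.category  # type: ignore[return-value]

    def __str__(self) -> str:
        return self.label


def state_label(body_part: str, nature: str) -> str:
    """Canonical part-nature state label, e.g. ``"Thigh|L:muscle"``."""
    return f"{body_part}{_SEP}{nature}"


def split_state_label(label: str) -> tuple[str, str]:
    part, _, nature = label.rpartition(_SEP)
    return part, nature


def state_of(
    record: InjuryRecord,
    level: str = "part_nature",
    excluded_categories: Sequence[str] = DEFAULT_EXCLUDED_CATEGORIES,
) -> InjuryState | None:
    """State of a record, or None if it is excluded at this level.

    At categorization level, records with an empty category or one in the
    exclusion list (default "Unsure", "Others") are excluded from analysis.
    """
    if level == "part_nature":
        if not record.body_part:
            raise ValueError("record has no body_part")
        return InjuryState(level="part_nature", body_part=record.body_part, nature=record.nature)
    if level == "categorization":
        if not record.category or record.category in set(excluded_categories):
            return None
        return InjuryState(level="categorization", category=record.category)
    raise ValueError(f"unknown state level: {level!r}")


def _transition_state_labels(
    transitions: pd.DataFrame,
    level: str,
    excluded_categories: Sequence[str],
) -> pd.DataFrame:
    """Add from_state/to_state label columns; drop excluded rows (categorization)."""
    t = transitions.copy()
    if level == "part_nature":
        t["from_state"] = t["from_body_part"] + _SEP + t["from_nature"]
        t["to_state"] = t["to_body_part"] + _SEP + t["to_nature"]
    elif level == "categorization":
        excluded = set(excluded_categories) | {""}
        keep = ~t["from_category"].isin(excluded) & ~t["to_category"].isin(excluded)
        t = t[keep].copy()
        t["from_state"] = t["from_category"]
        t["to_state"] = t["to_category"]
    else:
        raise ValueError(f"unknown state level: {level!r}")
    return t


@dataclass
class TransitionCountMatrix:
    """Square matrix of observed (from, to) transition counts."""

    level: str
    states: list[str]
    counts: pd.DataFrame  # index = from-state, columns = to-state
    total_transitions: int

    def check(self) -> None:
        if int(self.counts.to_numpy().sum()) != self.total_transitions:
            raise ValueError("count matrix inconsistent: sum(counts) != total_transitions")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative transition count")


def count_transitions(
    transitions: pd.DataFrame,
    level: str = "part_nature",
    excluded_categories: Sequence[str] = DEFAULT_EXCLUDED_CATEGORIES,
) -> TransitionCountMatrix:
    """Tally transitions into a state x state count matrix.

    At categorization level, pairs with an excluded or empty category at
    either end are dropped before counting, so the matrix total may be
    smaller than the number of input pairs.
    """
    t = _transition_state_labels(transitions, level, excluded_categories)
    states = sorted(set(t["from_state"]) | set(t["to_state"]))
    tally = t.groupby(["from_state", "to_state"]).size()
    counts = tally.unstack(fill_value=0).reindex(index=states, columns=states, fill_value=0)
    counts = counts.astype(int)
    m = TransitionCountMatrix(level=level, states=states, counts=counts, total_transitions=int(len(t)))
    m.check()
    return m


def estimate_probabilities(m: TransitionCountMatrix, denominator: str = "global") -> pd.DataFrame:
    """Transition probabilities from a count matrix, one row per observed pair.

    ``global``: p = count / total transitions (all probabilities sum to 1);
    ``row``: p = count / transitions leaving the from-state (each occupied
    row sums to 1).  Only pairs with count > 0 are emitted; the denominator
    convention and its n are recorded on every row.
    """
    if denominator not in ("global", "row"):
        raise ValueError(f"unknown denominator: {denominator!r}")
    long = m.counts.stack()
    long = long[long > 0]
    if len(long) == 0:
        if denominator == "global":
            raise ValueError("no transitions: global probabilities undefined")
        return pd.DataFrame(
            columns=["from_state", "to_state", "count", "denominator", "n_denominator", "p", "level"]
        )
    est = long.rename("count").reset_index()
    est.columns = ["from_state", "to_state", "count"]
    if denominator == "global":
        est["n_denominator"] = m.total_transitions
    else:
        row_totals = m.counts.sum(axis=1)
        est["n_denominator"] = est["from_state"].map(row_totals).astype(int)
    est["denominator"] = denominator
    est["p"] = est["count"] / est["n_denominator"]
    est["level"] = m.level
    return est[["from_state", "to_state", "count", "denominator", "n_denominator", "p", "level"]]


def classify_scenario(from_state: InjuryState, to_state: InjuryState) -> str:
    """Scenario of a part-nature pair.

    same body part & same nature -> "same_part_same_nature" (re-injury);
    same body part, different nature -> "same_part_diff_nature"; different
    body parts -> "any" only.  Mixed-level input is fatal; categorization-
    level analyses use scenario "any" throughout.
    """
    if from_state.level != to_state.level:
        raise ValueError("cannot classify a mixed-level state pair")
    if from_state.level != "part_nature":
        raise ValueError("scenario taxonomy is anatomical: states must be part_nature level")
    if from_state.body_part == to_state.body_part:
        if from_state.nature == to_state.nature:
            return "same_part_same_nature"
        return "same_part_diff_nature"
    return "any"


def _classify_frame(est: pd.DataFrame) -> pd.Series:
    fp, fn = zip(*(split_state_label(s) for s in est["from_state"])) if len(est) else ((), ())
    tp, tn = zip(*(split_state_label(s) for s in est["to_state"])) if len(est) else ((), ())
    fp, fn, tp, tn = (np.array(x, dtype=object) for x in (fp, fn, tp, tn))
    out = np.where(
        fp == tp,
        np.where(fn == tn, "same_part_same_nature", "same_part_diff_nature"),
        "any",
    )
    return pd.Series(out, index=est.index, dtype=object)


def filter_transitions(estimates: pd.DataFrame, min_p: float = 0.002) -> pd.DataFrame:
    """Drop estimates with probability strictly below ``min_p``.

    Presentation-layer only: counts, totals and denominators are computed on
    the unfiltered data; p exactly at the threshold survives.
    """
    if len(estimates) == 0:
        return estimates.copy()
    return estimates[estimates["p"] >= min_p].copy()


def scenario_table(estimates: pd.DataFrame, scenario: str = "any") -> pd.DataFrame:
    """Restrict an estimate table to one subsequent-injury scenario.

    Accepts the scenario tokens or the aliases "1", "2", "3"/"all";
    "any" returns everything.
    """
    scenario = _SCENARIO_ALIASES.get(str(scenario), scenario)
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario: {scenario!r}")
    if scenario == "any" or len(estimates) == 0:
        return estimates.copy()
    if "scenario" not in estimates.columns:
        raise ValueError("estimates carry no scenario column (categorization level?)")
    return estimates[estimates["scenario"] == scenario].copy()


class MarkovTransitionEstimator(BaseEstimator):
    """Estimate a first-order within-season injury transition model.

    Fits on a *preprocessed* :class:`RecordSet` (labels normalized, side
    merged into the body part, single-injury player-seasons removed):
    builds per-player-season date-ordered sequences, extracts each initial
    injury's first subsequent injury as a transition pair, tallies the
    (from, to) counts and estimates probabilities with binomial confidence
    intervals.

    Parameters
    ----------
    level : "part_nature" or "categorization"
        State granularity: side-qualified body part x tissue nature, or the
        specific diagnosis category.
    denominator : "global" or "row"
        Probability denominator — the cohort-wide transition total (matrix
        cells sum to 1) or the from-state row total (rows sum to 1).
    min_p : float
        Reporting threshold; estimates below it are excluded from
        :meth:`estimates` output (never from counts or denominators).
    ci_method, confidence : CI settings ("wald" or "wilson").
    excluded_categories : category labels dropped at categorization level.
    first_transition_only : star semantics (one pair per season) instead of
        the default chain semantics.
    season_start_month : used when season labels must be derived from dates.

    Attributes
    ----------
    transitions_ : tidy table of extracted pairs
    count_matrix_ : :class:`TransitionCountMatrix`
    states_ : ordered state labels
    n_transitions_ : total pairs counted at this level
    estimates_ : unfiltered estimate table with CIs and scenario labels
    transition_matrix_ : row-stochastic DataFrame (conditional next-state law)
    """

    def __init__(
        self,
        level: str = "part_nature",
        denominator: str = "global",
        min_p: float = 0.002,
        ci_method: str = "wald",
        confidence: float = 0.95,
        excluded_categories: Sequence[str] = DEFAULT_EXCLUDED_CATEGORIES,
        first_transition_only: bool = False,
        season_start_month: int = 7,
    ):
        self.level = level
        self.denominator = denominator
        self.min_p = min_p
        self.ci_method = ci_method
        self.confidence = confidence
        self.excluded_categories = excluded_categories
        self.first_transition_only = first_transition_only
        self.season_start_month = season_start_month

    def fit(self, X: RecordSet | pd.DataFrame, y=None) -> "MarkovTransitionEstimator":
        """Fit on a preprocessed RecordSet (or an already-extracted pair table)."""
        if isinstance(X, RecordSet):
            transitions = transitions_from_recordset(
                X, season_start_month=self.season_start_month, first_only=self.first_transition_only
            )
        elif isinstance(X, pd.DataFrame) and "from_body_part" in X.columns:
            transitions = X
        else:
            raise TypeError("X must be a RecordSet or a transitions DataFrame")
        self.transitions_ = transitions
        m = count_transitions(transitions, level=self.level, excluded_categories=self.excluded_categories)
        self.count_matrix_ = m
        self.states_ = list(m.states)
        self.n_transitions_ = m.total_transitions
        est = estimate_probabilities(m, denominator=self.denominator)
        if self.level == "part_nature":
            est["scenario"] = _classify_frame(est)
        else:
            est["scenario"] = "any"
        est = attach_cis(est, method=self.ci_method, confidence=self.confidence)
        self.estimates_ = est
        row_totals = m.counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            tm = m.counts.div(row_totals.replace(0, np.nan), axis=0).fillna(0.0)
        self.transition_matrix_ = tm
        return self

    def estimates(self, scenario: str = "any", filtered: bool = True) -> pd.DataFrame:
        """Estimate table, optionally restricted to a scenario and thresholded."""
        est = scenario_table(self.estimates_, scenario) if self.level == "part_nature" else self.estimates_.copy()
        if filtered:
            est = filter_transitions(est, self.min_p)
        return est

    def predict_proba(self, X: Iterable[str]) -> np.ndarray:
        """Conditional next-state distribution for each given from-state label.

        Rows are in the order of ``states_``; an unseen from-state yields a
        zero row.
        """
        tm = self.transition_matrix_
        labels = list(X)
        out = np.zeros((len(labels), len(self.states_)))
        for i, s in enumerate(labels):
            if s in tm.index:
                out[i] = tm.loc[s].to_numpy()
        return out

    def predict(self, X: Iterable[str]) -> np.ndarray:
        """Most probable next state for each from-state label (ties: first label)."""
        proba = self.predict_proba(X)
        idx = proba.argmax(axis=1)
        return np.array([self.states_[i] for i in idx], dtype=object)
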
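"""Binomial proportion confidence intervals and cohort-level summaries.

The transition-probability intervals are normal-approximation (Wald)
intervals, p +/- z*sqrt(p(1-p)/n), the convention whose half-widths match
figure-level reporting at the cohort's global subsequent-injury count; Wilson
score intervals (via statsmodels) are offered for small counts, where the
Wald interval is known to misbehave.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

from .records import RecordSet

__all__ = [
    "ProportionCI",
    "CohortSummary",
    "wald_halfwidth",
    "proportion_ci",
    "attach_cis",
    "cohort_summary",
]


def wald_halfwidth(p, n, confidence: float = 0.95):
    """Half-width of the Wald binomial interval, z * sqrt(p(1-p)/n).

    ``z`` is the standard-normal quantile at (1+confidence)/2 (1.959964 at
    95%).  Vectorized over ``p``.  ``n`` must be >= 1.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p must lie in [0, 1]")
    n = np.asarray(n, dtype=float)
    if np.any(n < 1):
        raise ValueError("n must be >= 1")
    z = norm.ppf(0.5 * (1.0 + confidence))
    out = z * np.sqrt(p * (1.0 - p) / n)
    return float(out) if out.ndim == 0 else out


@dataclass
class ProportionCI:
    """A binomial proportion with its confidence interval, clipped to [0,1]."""

    p: float
    n: int
    confidence: float
    method: str
    half_width: float
    low: float
    high: float


def proportion_ci(count: int, n: int, method: str = "wald", confidence: float = 0.95) -> ProportionCI:
    """Confidence interval for a count out of n trials.

    ``method`` is "wald" (authored here, the reporting convention) or
    "wilson" (statsmodels score interval).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    p = count / n
    if method == "wald":
        hw = wald_halfwidth(p, n, confidence)
        low, high = max(0.0, p - hw), min(1.0, p + hw)
    elif method == "wilson":
        low, high = proportion_confint(count, n, alpha=1.0 - confidence, method="wilson")
        hw = (high - low) / 2.0
    else:
        raise ValueError(f"unknown CI method: {method!r}")
    return ProportionCI(p=p, n=n, confidence=confidence, method=method, half_width=float(hw), low=float(low), high=float(high))


def attach_cis(estimates: pd.DataFrame, method: str = "wald", confidence: float = 0.95) -> pd.DataFrame:
    """Populate ci_low / ci_high on a transition-estimate table.

    Each row must carry ``p`` and ``n_denominator``.  Intervals are clipped to
    [0, 1]; the estimate table is returned as a copy.
    """
    est = estimates.copy()
    if len(est) == 0:
        est["ci_low"] = pd.Series(dtype=float)
        est["ci_high"] = pd.Series(dtype=float)
        return est
    if method == "wald":
        hw = wald_halfwidth(est["p"].to_numpy(), est["n_denominator"].to_numpy(), confidence)
        est["ci_low"] = np.clip(est["p"] - hw, 0.0, 1.0)
        est["ci_high"] = np.clip(est["p"] + hw, 0.0, 1.0)
    elif method == "wilson":
        low, high = proportion_confint(
            est["count"].to_numpy(), est["n_denominator"].to_numpy(), alpha=1.0 - confidence, method="wilson"
        )
        est["ci_low"] = low
        est["ci_high"] = high
    else:
        raise ValueError(f"unknown CI method: {method!r}")
    est["ci_method"] = method
    est["confidence"] = confidence
    return est


@dataclass
class CohortSummary:
    """Headline counts of a surveillance cohort.

    ``subsequent_share`` is the number of within-season subsequent injuries
    (= transitions under chain semantics) over all recorded injuries;
    ``mean``/``sd_subsequent_per_player_season`` are computed over
    player-seasons with at least one subsequent injury (configurable to all
    player-seasons).  ``body_part_distribution`` is in percent over all
    recorded injuries, pre-exclusion.
    """

    n_injuries: int
    n_subsequent: int
    subsequent_share: float
    n_players_with_subsequent: int
    mean_subsequent_per_player_season: float | None
    sd_subsequent_per_player_season: float | None
    body_part_distribution: Mapping[str, float]

    def as_dict(self) -> dict:
        return {
            "n_injuries": self.n_injuries,
            "n_subsequent": self.n_subsequent,
            "subsequent_share": self.subsequent_share,
            "n_players_with_subsequent": self.n_players_with_subsequent,
            "mean_subsequent_per_player_season": self.mean_subsequent_per_player_season,
            "sd_subsequent_per_player_season": self.sd_subsequent_per_player_season,
            "body_part_distribution": dict(self.body_part_distribution),
        }


def cohort_summary(
    rs_raw: RecordSet,
    rs_clean: RecordSet,
    transitions: pd.DataFrame,
    per_player_season: str = "with_subsequent",
) -> CohortSummary:
    """Cohort-level summary from the pipeline's artifacts.

    ``rs_raw`` is the full recorded cohort (denominator of the subsequent
    share and base of the body-part distribution); ``transitions`` must be
    derived from ``rs_clean``.  ``per_player_season`` chooses the denominator
    of the per-player-season mean: "with_subsequent" (default) or "all"
    (every player-season present in the clean set).
    """
    n_injuries = len(rs_raw)
    n_subsequent = len(transitions)
    share = n_subsequent / n_injuries if n_injuries else 0.0

    if n_subsequent:
        per_ps = transitions.groupby(["player_id", "season_label"]).size()
        if per_player_season == "all":
            all_ps = rs_clean.frame.groupby(["player_id", "season_label"]).size()
            per_ps = per_ps.reindex(all_ps.index, fill_value=0)
        elif per_player_season != "with_subsequent":
            raise ValueError(f"unknown per_player_season: {per_player_season!r}")
        mean = float(per_ps.mean())
        sd = float(per_ps.std(ddof=1)) if len(per_ps) > 1 else 0.0
        n_players = int(transitions["player_id"].nunique())
    else:
        mean = sd = None
        n_players = 0

    parts = rs_raw.frame.get("body_part_raw", rs_raw.frame["body_part"])
    parts = parts[parts != ""]
    if len(parts):
        dist = (parts.value_counts() / len(parts) * 100.0).to_dict()
    else:
        dist = {}
    return CohortSummary(
        n_injuries=n_injuries,
        n_subsequent=n_subsequent,
        subsequent_share=share,
        n_players_with_subsequent=n_players,
        mean_subsequent_per_player_season=mean,
        sd_subsequent_per_player_season=sd,
        body_part_distribution=dist,
    )
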
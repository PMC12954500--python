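"""Synthetic injury-surveillance cohorts with a known transition kernel.

The generator emulates the structure and scale of a professional-league
time-loss surveillance dataset: ~1,250 players followed over 8 seasons with
~4,700 injuries whose body-part marginal is thigh-dominant (thigh 32.4%,
knee 15.7%, ankle 14.3%, hip and groin 12.9%, lower leg 9.7%, remainder
spread).  Injury counts per player-season are Negative Binomial — injury
burden in team sports is strongly overdispersed, with a minority of players
carrying most recurrences; a Poisson count with the same mean cannot produce
a realistic subsequent-injury share.  Within a player-season, injury states
follow a first-order Markov chain: the first injury is drawn from the
marginal, each later one from the kernel row of its predecessor.

Realistic ingest noise is injected on top of the latent truth: contact-caused
injuries, blanked core fields, raw label variants (case / suffix noise) that
the exact-match normalization map undoes, and "Unsure"/"Others" diagnosis
categories.  The ground truth (kernel, marginal, per-record latent state) is
returned alongside and is never read by the analysis path; it feeds the
independent brute-force oracle :func:`reference_statistics` used for
parameter-recovery and equivalence testing.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from .preprocessing import NormalizationMap
from .records import COLUMNS, RecordSet, SIDE_TOKENS, Provenance

__all__ = [
    "StateSpec",
    "SyntheticCohortConfig",
    "GroundTruth",
    "ReferenceStatistics",
    "default_state_space",
    "build_kernel",
    "generate_cohort",
    "reference_statistics",
    "default_normalization_map",
    "label_variants",
]


class StateSpec(BaseModel):
    """One latent injury state: side-qualified body part x tissue nature."""

    body_part: str
    side: str = "unspecified"
    nature: str
    weight: float = Field(gt=0)
    category: str = ""

    @property
    def label(self) -> str:
        return f"{self.body_part}|{SIDE_TOKENS[self.side]}:{self.nature}"


def default_state_space() -> list[StateSpec]:
    """14 states approximating the reported body-part marginal."""
    spec = [
        ("Thigh", "left", "muscle", 0.162, "Hamstring Muscle Injury"),
        ("Thigh", "right", "muscle", 0.162, "Hamstring Muscle Injury"),
        ("Knee", "left", "ligament", 0.0785, "ACL"),
        ("Knee", "right", "ligament", 0.0785, "MCL"),
        ("Ankle", "left", "sprain", 0.0715, "Ankle Sprain"),
        ("Ankle", "right", "sprain", 0.0715, "Ankle Sprain"),
        ("Hip and Groin", "left", "muscle", 0.0545, "Groin Muscle Injury"),
        ("Hip and Groin", "right", "muscle", 0.0545, "Groin Muscle Injury"),
        ("Hip and Groin", "left", "tendon", 0.010, "Groin Tendon Injury"),
        ("Hip and Groin", "right", "tendon", 0.010, "Groin Tendon Injury"),
        ("Lower Leg", "left", "muscle", 0.0485, "Calf Muscle Injury"),
        ("Lower Leg", "right", "muscle", 0.0485, "Calf Muscle Injury"),
        ("Foot", "unspecified", "other", 0.075, "Foot Injury"),
        ("Trunk", "unspecified", "other", 0.075, "Back Injury"),
    ]
    return [
        StateSpec(body_part=b, side=s, nature=n, weight=w, category=c)
        for b, s, n, w, c in spec
    ]


DEFAULT_SEASONS = tuple(f"{y}-{(y + 1) % 100:02d}" for y in range(2013, 2021))


class SyntheticCohortConfig(BaseModel):
    """Generator parameters; defaults are the emulated study conditions.

    ``mean_injuries_per_player_season`` 0.47 over 1,250 players x 8 seasons
    gives ~4,700 injuries; ``dispersion`` is the Negative Binomial size r
    (None for Poisson).  ``kernel`` may be given explicitly (row-stochastic
    over the state space) or is built from ``diag_boost`` (excess re-injury
    mass on the diagonal) and ``same_part_boost`` (excess mass on same-body-
    part cells) on top of the marginal.  ``second_order_weight`` > 0 violates
    the first-order assumption on purpose (misspecification mode) by drawing
    from the grand-predecessor's kernel row with that probability.
    """

    n_players: int = 1250
    seasons: list[str] = Field(default_factory=lambda: list(DEFAULT_SEASONS))
    mean_injuries_per_player_season: float = 0.47
    dispersion: float | None = 0.6
    state_space: list[StateSpec] = Field(default_factory=default_state_space)
    kernel: list[list[float]] | None = None
    diag_boost: float = 0.12
    same_part_boost: float = 0.05
    contact_prob: float = 0.10
    unknown_contact_prob: float = 0.02
    missing_field_prob: float = 0.02
    label_noise_prob: float = 0.15
    unsure_category_prob: float = 0.04
    second_order_weight: float = 0.0
    season_start_month: int = 7
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SyntheticCohortConfig":
        w = np.array([s.weight for s in self.state_space])
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"state weights sum to {w.sum()}, not 1")
        if self.kernel is not None:
            k = np.asarray(self.kernel, dtype=float)
            if k.shape != (len(w), len(w)):
                raise ValueError("kernel shape does not match state space")
            if np.any(np.abs(k.sum(axis=1) - 1.0) > 1e-9):
                raise ValueError("kernel rows must sum to 1")
        return self

    @classmethod
    def from_file(cls, path: str | Path) -> "SyntheticCohortConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=False)


def build_kernel(
    states: Sequence[StateSpec], diag_boost: float = 0.12, same_part_boost: float = 0.05
) -> np.ndarray:
    """Row-stochastic kernel: background marginal + re-injury/same-part excess.

    K[i, j] = (1 - d - s) * w[j] + d * 1[i == j] + s * SamePart[i, j], where
    SamePart is the row-normalized same-body-part indicator (including the
    diagonal).  Rows sum to 1 by construction.
    """
    w = np.array([s.weight for s in states])
    n = len(states)
    parts = [s.body_part for s in states]
    same = np.array([[1.0 if parts[i] == parts[j] else 0.0 for j in range(n)] for i in range(n)])
    same /= same.sum(axis=1, keepdims=True)
    k = (1.0 - diag_boost - same_part_boost) * np.tile(w, (n, 1))
    k += diag_boost * np.eye(n)
    k += same_part_boost * same
    return k


# noise variants undone by the default normalization map ----------------------

def label_variants(label: str, kind: str) -> list[str]:
    """Raw-export spellings of a canonical label (case / suffix noise)."""
    if kind == "nature":
        return [label.capitalize(), label.upper(), f"{label} injury"]
    return [label.lower(), label.upper(), f"{label} area"]


def default_normalization_map(
    states: Sequence[StateSpec] | None = None, strict: bool = False
) -> NormalizationMap:
    """Exact-match map undoing the generator's label noise."""
    states = list(states) if states is not None else default_state_space()
    body_part: dict[str, str] = {}
    nature: dict[str, str] = {}
    for s in states:
        for v in label_variants(s.body_part, "body_part"):
            if v != s.body_part:
                body_part[v] = s.body_part
        for v in label_variants(s.nature, "nature"):
            if v != s.nature:
                nature[v] = s.nature
    return NormalizationMap(body_part=body_part, nature=nature, category={}, strict=strict)


@dataclass
class GroundTruth:
    """Latent truth of a generated cohort; never read by the analysis path."""

    config: SyntheticCohortConfig
    state_labels: list[str]
    marginal: pd.Series
    kernel: pd.DataFrame
    state_index: np.ndarray  # latent state per record, frame-row order
    seq_id: np.ndarray  # player-season id per record
    position: np.ndarray  # 0-based position within the player-season
    contact: np.ndarray  # "yes"/"no"/"unknown" per record
    missing_player: np.ndarray  # bool, player_id blanked
    missing_part: np.ndarray  # bool, body_part blanked
    category: np.ndarray  # final category label per record (incl. Unsure/Others)

    def to_json_dict(self) -> dict:
        return {
            "state_labels": self.state_labels,
            "marginal": self.marginal.tolist(),
            "kernel": self.kernel.to_numpy().tolist(),
            "state_index": self.state_index.tolist(),
            "seq_id": self.seq_id.tolist(),
        }


def _sample_rows(rng: np.random.Generator, cum_rows: np.ndarray, row_idx: np.ndarray) -> np.ndarray:
    u = rng.random(len(row_idx))
    return (u[:, None] < cum_rows[row_idx]).argmax(axis=1)


def generate_cohort(cfg: SyntheticCohortConfig) -> tuple[RecordSet, GroundTruth]:
    """Generate a surveillance-format cohort plus its latent ground truth.

    Reproducible given ``cfg.seed`` (single numpy Generator, PCG64; field
    draws occur in a fixed order).  Records are emitted grouped by player and
    season with dates sorted within each player-season, so chronological
    order coincides with latent chain order (same-day ties keep chain order
    via the stable input-row tie-break downstream).
    """
    rng = np.random.default_rng(cfg.seed)
    states = cfg.state_space
    n_states = len(states)
    w = np.array([s.weight for s in states])
    kernel = np.asarray(cfg.kernel, dtype=float) if cfg.kernel is not None else build_kernel(
        states, cfg.diag_boost, cfg.same_part_boost
    )
    labels = [s.label for s in states]

    seasons = list(cfg.seasons)
    n_seasons = len(seasons)
    n_ps = cfg.n_players * n_seasons
    mu = cfg.mean_injuries_per_player_season
    if mu <= 0:
        counts = np.zeros(n_ps, dtype=np.int64)
    elif cfg.dispersion is None:
        counts = rng.poisson(mu, n_ps)
    else:
        r = cfg.dispersion
        counts = rng.negative_binomial(r, r / (r + mu), n_ps)
    total = int(counts.sum())

    seq_id = np.repeat(np.arange(n_ps), counts)
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    pos = np.arange(total) - np.repeat(starts, counts)

    # latent chain
    state_idx = np.empty(total, dtype=np.int64)
    first = pos == 0
    state_idx[first] = np.searchsorted(np.cumsum(w), rng.random(int(first.sum())))
    cum_k = np.cumsum(kernel, axis=1)
    max_len = int(counts.max()) if total else 0
    for k in range(1, max_len):
        idx = np.nonzero(pos == k)[0]
        if len(idx) == 0:
            continue
        prev = state_idx[idx - 1]
        nxt = _sample_rows(rng, cum_k, prev)
        if cfg.second_order_weight > 0 and k >= 2:
            use2 = rng.random(len(idx)) < cfg.second_order_weight
            if use2.any():
                prev2 = state_idx[idx - 2]
                nxt[use2] = _sample_rows(rng, cum_k, prev2[use2])
        state_idx[idx] = nxt

    # dates: uniform within the season window, sorted within each sequence
    season_of_ps = np.arange(n_ps) % n_seasons
    start_years = np.array([int(s.split("-")[0]) for s in seasons])
    window_days = 334  # season start month through end of May
    season_starts = np.array(
        [np.datetime64(dt.date(y, cfg.season_start_month, 1)) for y in start_years]
    )
    offsets = rng.integers(0, window_days, total)
    order = np.lexsort((offsets, seq_id))
    offsets = offsets[order]  # sorted within each contiguous sequence block
    dates = season_starts[season_of_ps[seq_id]] + offsets.astype("timedelta64[D]")

    # observed fields
    player_of_ps = np.arange(n_ps) // n_seasons
    width = len(str(max(cfg.n_players, 1)))
    player_names = np.array([f"P{i + 1:0{width}d}" for i in range(cfg.n_players)])
    player_id = player_names[player_of_ps[seq_id]]
    season_label = np.array(seasons, dtype=object)[season_of_ps[seq_id]]

    part = np.array([s.body_part for s in states], dtype=object)[state_idx]
    side = np.array([s.side for s in states], dtype=object)[state_idx]
    nature = np.array([s.nature for s in states], dtype=object)[state_idx]
    category = np.array([s.category for s in states], dtype=object)[state_idx]

    u_cat = rng.random(total)
    category = category.copy()
    category[u_cat < cfg.unsure_category_prob / 2] = "Unsure"
    category[(u_cat >= cfg.unsure_category_prob / 2) & (u_cat < cfg.unsure_category_prob)] = "Others"

    u_contact = rng.random(total)
    contact = np.where(
        u_contact < cfg.contact_prob,
        "yes",
        np.where(u_contact < cfg.contact_prob + cfg.unknown_contact_prob, "unknown", "no"),
    ).astype(object)

    u_onset = rng.random(total)
    onset = np.where(u_onset < 0.8, "sudden", "gradual").astype(object)
    u_ctx = rng.random(total)
    context = np.where(
        onset == "gradual", "not_applicable", np.where(u_ctx < 0.6, "match", "training")
    ).astype(object)
    severity = rng.geometric(0.15, total)

    prev_same = np.zeros(total, dtype=bool)
    if total:
        prev_same[1:] = (seq_id[1:] == seq_id[:-1]) & (state_idx[1:] == state_idx[:-1])
    u_rec = rng.random(total)
    recurrence = np.where(prev_same, np.where(u_rec < 0.1, "exacerbation", "reinjury"), "index").astype(object)

    # ingest noise: raw label variants, then blanked core fields
    part_obs = part.copy()
    nature_obs = nature.copy()
    u_noise = rng.random(total)
    noisy = u_noise < cfg.label_noise_prob
    variant_choice = rng.integers(0, 3, total)
    for i in np.nonzero(noisy)[0]:
        part_obs[i] = label_variants(str(part[i]), "body_part")[variant_choice[i]]
        nature_obs[i] = label_variants(str(nature[i]), "nature")[variant_choice[i]]

    u_missing = rng.random(total)
    missing_player = u_missing < cfg.missing_field_prob / 2
    missing_part = (u_missing >= cfg.missing_field_prob / 2) & (u_missing < cfg.missing_field_prob)
    player_obs = player_id.astype(object)
    player_obs[missing_player] = ""
    part_obs[missing_part] = ""

    frame = pd.DataFrame(
        {
            "player_id": player_obs,
            "injury_date": pd.to_datetime(dates),
            "season_label": season_label,
            "body_part": part_obs,
            "side": side,
            "nature": nature_obs,
            "category": category,
            "onset": onset,
            "severity_days": severity.astype(np.int64),
            "contact": contact,
            "context": context,
            "recurrence_class": recurrence,
        },
        columns=list(COLUMNS),
    )
    rs = RecordSet(
        frame,
        Provenance(source="synthetic", dialect="generated", rows_read=total, rows_accepted=total),
    )
    gt = GroundTruth(
        config=cfg,
        state_labels=labels,
        marginal=pd.Series(w, index=labels),
        kernel=pd.DataFrame(kernel, index=labels, columns=labels),
        state_index=state_idx,
        seq_id=seq_id,
        position=pos,
        contact=contact,
        missing_player=missing_player,
        missing_part=missing_part,
        category=category,
    )
    return rs, gt


# ---------------------------------------------------------------------------
# independent brute-force oracle

@dataclass
class ReferenceStatistics:
    """Brute-force tallies computed from latent states, not the pipeline."""

    counts: dict[tuple[str, str], int]
    total_transitions: int
    row_totals: dict[str, int]
    global_p: dict[tuple[str, str], float] = dc_field(default_factory=dict)
    row_p: dict[tuple[str, str], float] = dc_field(default_factory=dict)
    n_sequences: int = 0
    n_surviving_records: int = 0


def reference_statistics(
    rs: RecordSet,
    gt: GroundTruth,
    drop_unknown_contact: bool = False,
    level: str = "part_nature",
    excluded_categories: Sequence[str] = ("Unsure", "Others"),
    first_only: bool = False,
) -> ReferenceStatistics:
    """Expected pipeline output, tallied by plain loops over the latent truth.

    Mirrors the cleaning rules record by record (contact exclusion, blanked
    core fields, single-injury player-seasons) and pairs surviving records
    consecutively within each player-season; at categorization level, pairs
    touching an excluded category are dropped after pairing, exactly as the
    analysis path does.  Shares no code with the estimator.
    """
    n = len(gt.state_index)
    survive = []
    for i in range(n):
        if gt.contact[i] == "yes":
            survive.append(False)
        elif drop_unknown_contact and gt.contact[i] == "unknown":
            survive.append(False)
        elif gt.missing_player[i] or gt.missing_part[i]:
            survive.append(False)
        else:
            survive.append(True)

    by_seq: dict[int, list[int]] = {}
    for i in range(n):
        if survive[i]:
            by_seq.setdefault(int(gt.seq_id[i]), []).append(i)

    counts: dict[tuple[str, str], int] = {}
    excluded = set(excluded_categories) | {""}
    n_sequences = 0
    n_surviving = 0
    for seq in sorted(by_seq):
        idx = by_seq[seq]
        if len(idx) < 2:
            continue
        n_sequences += 1
        n_surviving += len(idx)
        pairs = [(idx[0], idx[1])] if first_only else list(zip(idx[:-1], idx[1:]))
        for a, b in pairs:
            if level == "part_nature":
                key = (gt.state_labels[gt.state_index[a]], gt.state_labels[gt.state_index[b]])
            else:
                ca, cb = str(gt.category[a]), str(gt.category[b])
                if ca in excluded or cb in excluded:
                    continue
                key = (ca, cb)
            counts[key] = counts.get(key, 0) + 1

    total = sum(counts.values())
    row_totals: dict[str, int] = {}
    for (a, _), c in counts.items():
        row_totals[a] = row_totals.get(a, 0) + c
    ref = ReferenceStatistics(
        counts=counts,
        total_transitions=total,
        row_totals=row_totals,
        n_sequences=n_sequences,
        n_surviving_records=n_surviving,
    )
    for key, c in counts.items():
        ref.global_p[key] = c / total
        ref.row_p[key] = c / row_totals[key[0]]
    return ref


# ---------------------------------------------------------------------------
# parameter-recovery experiment

@dataclass
class RecoveryResult:
    """Outcome of a replicated kernel-recovery simulation."""

    n_replicates: int
    n_eligible_cells: int
    fraction_within_3se: float
    wald_coverage: float
    mean_transitions_per_replicate: float


def kernel_recovery_experiment(
    n_replicates: int = 200,
    n_players: int = 5000,
    seasons: Sequence[str] = DEFAULT_SEASONS,
    seed: int = 0,
    min_expected_count: float = 25.0,
    confidence: float = 0.95,
) -> RecoveryResult:
    """How well row-denominator estimates recover a known kernel.

    Generates ``n_replicates`` clean cohorts (no contact / missing-field /
    label noise) from the default kernel, runs each through the preprocessing
    and estimation path, and evaluates every kernel cell whose mean observed
    count across replicates reaches ``min_expected_count``:

    * the fraction of (cell, replicate) estimates within 3 true standard
      errors sqrt(p(1-p)/n_row) of the true cell value, and
    * the empirical coverage of the Wald interval built from the estimate.

    Child seeds are spawned deterministically from ``seed``.
    """
    from .markov import MarkovTransitionEstimator
    from .preprocessing import preprocess
    from scipy.stats import norm as _norm

    states = default_state_space()
    kernel = build_kernel(states)
    labels = [s.label for s in states]
    n_states = len(labels)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)

    counts = np.zeros((n_replicates, n_states, n_states))
    for r in range(n_replicates):
        cfg = SyntheticCohortConfig(
            n_players=n_players,
            seasons=seasons,
            contact_prob=0.0,
            unknown_contact_prob=0.0,
            missing_field_prob=0.0,
            label_noise_prob=0.0,
            unsure_category_prob=0.0,
            seed=int(child_seeds[r]),
        )
        rs, _ = generate_cohort(cfg)
        clean, _report = preprocess(rs)
        model = MarkovTransitionEstimator(denominator="row").fit(clean)
        counts[r] = (
            model.count_matrix_.counts.reindex(index=labels, columns=labels, fill_value=0).to_numpy()
        )

    row_n = counts.sum(axis=2)
    eligible = counts.mean(axis=0) >= min_expected_count
    p_hat = counts / np.maximum(row_n[:, :, None], 1)
    p_true = kernel[None, :, :]
    se_true = np.sqrt(p_true * (1 - p_true) / np.maximum(row_n[:, :, None], 1))
    within = np.abs(p_hat - p_true) <= 3 * se_true
    z = _norm.ppf(0.5 * (1 + confidence))
    se_hat = np.sqrt(p_hat * (1 - p_hat) / np.maximum(row_n[:, :, None], 1))
    covered = (p_true >= p_hat - z * se_hat) & (p_true <= p_hat + z * se_hat)
    return RecoveryResult(
        n_replicates=n_replicates,
        n_eligible_cells=int(eligible.sum()),
        fraction_within_3se=float(within[:, eligible].mean()),
        wald_coverage=float(covered[:, eligible].mean()),
        mean_transitions_per_replicate=float(row_n.sum(axis=1).mean()),
    )
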
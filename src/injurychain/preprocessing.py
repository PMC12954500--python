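"""Cleaning and exclusion rules producing the analysis-ready dataset.

The pipeline applies, in a fixed order: label normalization, removal of
records missing the core identifying fields (player id, body part), exclusion
of contact-caused injuries, folding of the laterality field into the body
part (left thigh and right thigh become distinct anatomical tokens), and
finally removal of player-seasons with a single injury — a lone injury has no
within-season predecessor and cannot contribute a transition.  The
single-injury rule runs last and is iterated to a fixed point because the
earlier exclusions can reduce a player-season to one record.

Exposed both as plain functions and as the sklearn-style transformer
:class:`InjuryPreprocessor` so the cleaning step composes with pipelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml
from sklearn.base import BaseEstimator, TransformerMixin

from .records import RecordSet, SIDE_TOKENS, derive_season_labels

__all__ = [
    "NormalizationMap",
    "PreprocessReport",
    "normalize_labels",
    "drop_missing_core",
    "drop_contact",
    "drop_exacerbations",
    "merge_side_into_body_part",
    "drop_single_injury_player_seasons",
    "preprocess",
    "InjuryPreprocessor",
]

_NORMALIZED_FIELDS = ("body_part", "nature", "category")


@dataclass
class NormalizationMap:
    """Exact-match mapping from raw labels to canonical labels.

    One mapping per normalized field.  Canonical labels must be fixed points
    of their own map (idempotence): a canonical value may never appear as a
    key mapping elsewhere.  In strict mode an unmapped, non-canonical label
    is fatal; otherwise it passes through with a warning.
    """

    body_part: dict[str, str] = field(default_factory=dict)
    nature: dict[str, str] = field(default_factory=dict)
    category: dict[str, str] = field(default_factory=dict)
    strict: bool = False

    def __post_init__(self) -> None:
        for fname in _NORMALIZED_FIELDS:
            mapping = getattr(self, fname)
            for canonical in mapping.values():
                if canonical in mapping and mapping[canonical] != canonical:
                    raise ValueError(
                        f"normalization map for {fname} is not idempotent: "
                        f"canonical {canonical!r} maps to {mapping[canonical]!r}"
                    )

    @classmethod
    def from_file(cls, path: str | Path, strict: bool = False) -> "NormalizationMap":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(
            body_part=dict(data.get("body_part", {})),
            nature=dict(data.get("nature", {})),
            category=dict(data.get("category", {})),
            strict=strict,
        )

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {f: getattr(self, f) for f in _NORMALIZED_FIELDS}, fh, sort_keys=True
            )


@dataclass
class PreprocessReport:
    """Removal counts per rule; each record attributed to exactly one rule."""

    n_before: int = 0
    n_after: int = 0
    removed: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def check(self) -> None:
        if self.n_before - self.n_after != sum(self.removed.values()):
            raise ValueError("preprocess report inconsistent: before - after != sum(removals)")

    def merge(self, other: "PreprocessReport") -> None:
        for rule, n in other.removed.items():
            self.removed[rule] = self.removed.get(rule, 0) + n
        self.warnings.extend(other.warnings)


def normalize_labels(rs: RecordSet, nmap: NormalizationMap) -> RecordSet:
    """Replace raw body-part / nature / category labels by canonical forms."""
    frame = rs.frame.copy()
    offenders: list[str] = []
    for fname in _NORMALIZED_FIELDS:
        mapping = getattr(nmap, fname)
        if not mapping:  # no normalization configured for this field
            continue
        col = frame[fname]
        frame[fname] = col.map(mapping).fillna(col)
        canonical = set(mapping.values())
        unmapped = sorted(set(col) - set(mapping) - canonical - {""})
        for label in unmapped:
            offenders.append(f"{fname}:{label}")
    if offenders:
        if nmap.strict:
            raise ValueError("unmapped labels in strict mode: " + ", ".join(offenders))
        warnings.warn(f"unmapped labels passed through: {', '.join(offenders)}", stacklevel=2)
    return rs.with_frame(frame)


def _filtered(rs: RecordSet, keep: pd.Series, rule: str) -> tuple[RecordSet, PreprocessReport]:
    report = PreprocessReport(n_before=len(rs), n_after=int(keep.sum()), removed={rule: int((~keep).sum())})
    report.check()
    return rs.with_frame(rs.frame[keep]), report


def drop_missing_core(rs: RecordSet) -> tuple[RecordSet, PreprocessReport]:
    """Remove records with empty player_id or body_part (core identifiers)."""
    f = rs.frame
    keep = (f["player_id"] != "") & (f["body_part"] != "")
    return _filtered(rs, keep, "missing_core")


def drop_contact(rs: RecordSet, drop_unknown: bool = False) -> tuple[RecordSet, PreprocessReport]:
    """Exclude contact-caused injuries.

    Records with an unknown contact mechanism are retained by default (only
    injuries positively caused by contact are excluded); pass
    ``drop_unknown=True`` for the strict reading.
    """
    bad = rs.frame["contact"] == "yes"
    if drop_unknown:
        bad |= rs.frame["contact"] == "unknown"
    return _filtered(rs, ~bad, "contact")


def drop_exacerbations(rs: RecordSet) -> tuple[RecordSet, PreprocessReport]:
    """Optionally remove exacerbations (recurrence before return to play)."""
    keep = rs.frame["recurrence_class"] != "exacerbation"
    return _filtered(rs, keep, "exacerbation")


def merge_side_into_body_part(rs: RecordSet) -> RecordSet:
    """Fold laterality into the body part: (Thigh, left) -> "Thigh|L".

    The same body part on different sides becomes a distinct anatomical
    token; bilateral maps to "B" and unspecified to "U".  The pre-merge label
    is preserved in a ``body_part_raw`` column for audit.
    """
    frame = rs.frame.copy()
    if "body_part_raw" in frame.columns:  # already merged — idempotent
        return rs.with_frame(frame)
    frame["body_part_raw"] = frame["body_part"]
    tokens = frame["side"].map(SIDE_TOKENS).fillna("U")
    merged = frame["body_part"] + "|" + tokens
    frame["body_part"] = merged.where(frame["body_part"] != "", "")
    return rs.with_frame(frame)


def _season_labels(frame: pd.DataFrame, season_start_month: int) -> pd.Series:
    labels = frame["season_label"].astype(str)
    missing = labels == ""
    if missing.any():
        dates = pd.to_datetime(frame.loc[missing, "injury_date"], errors="coerce")
        if dates.isna().any():
            raise ValueError("season unresolvable: records with neither season_label nor a valid date")
        labels = labels.copy()
        labels[missing] = derive_season_labels(dates, season_start_month)
    return labels


def drop_single_injury_player_seasons(
    rs: RecordSet, season_start_month: int = 7
) -> tuple[RecordSet, PreprocessReport]:
    """Remove player-seasons with a single injury (no within-season predecessor).

    Iterated to a fixed point; a single pass already is one, since removing a
    whole group never changes another group's size.
    """
    frame = rs.frame
    n_before = len(frame)
    while True:
        if len(frame) == 0:
            break
        labels = _season_labels(frame, season_start_month)
        sizes = frame.groupby([frame["player_id"], labels])["player_id"].transform("size")
        keep = sizes >= 2
        if keep.all():
            break
        frame = frame[keep]
    report = PreprocessReport(
        n_before=n_before, n_after=len(frame), removed={"single_injury": n_before - len(frame)}
    )
    report.check()
    return rs.with_frame(frame), report


def preprocess(
    rs: RecordSet,
    nmap: NormalizationMap | None = None,
    drop_unknown_contact: bool = False,
    drop_exacerbations_flag: bool = False,
    season_start_month: int = 7,
) -> tuple[RecordSet, PreprocessReport]:
    """Full cleaning sequence in the fixed rule order.

    normalize labels -> drop missing core -> drop contact -> (optional)
    drop exacerbations -> merge side into body part -> drop single-injury
    player-seasons.  The report attributes each removed record to exactly one
    rule, in application order.
    """
    report = PreprocessReport(n_before=len(rs))
    if nmap is not None:
        rs = normalize_labels(rs, nmap)
    rs, sub = drop_missing_core(rs)
    report.merge(sub)
    rs, sub = drop_contact(rs, drop_unknown=drop_unknown_contact)
    report.merge(sub)
    if drop_exacerbations_flag:
        rs, sub = drop_exacerbations(rs)
        report.merge(sub)
    rs = merge_side_into_body_part(rs)
    rs, sub = drop_single_injury_player_seasons(rs, season_start_month)
    report.merge(sub)
    report.n_after = len(rs)
    report.check()

    dup_cols = ["player_id", "injury_date", "body_part", "nature"]
    n_dup = int(rs.frame.duplicated(dup_cols).sum())
    if n_dup:
        report.warnings.append(f"{n_dup} same-day duplicate record(s) kept")
    return rs, report


class InjuryPreprocessor(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer wrapping :func:`preprocess`.

    Parameters
    ----------
    normalization_map : NormalizationMap or None
        Exact-match label cleaning applied first.
    drop_unknown_contact : bool
        Exclude records with contact mechanism "unknown" as well as "yes".
    drop_exacerbations : bool
        Remove exacerbations before the single-injury rule.
    season_start_month : int
        Month a season starts in (used when season labels must be derived).

    After :meth:`transform`, ``report_`` holds the removal accounting of the
    most recent call.
    """

    def __init__(
        self,
        normalization_map: NormalizationMap | None = None,
        drop_unknown_contact: bool = False,
        drop_exacerbations: bool = False,
        season_start_month: int = 7,
    ):
        self.normalization_map = normalization_map
        self.drop_unknown_contact = drop_unknown_contact
        self.drop_exacerbations = drop_exacerbations
        self.season_start_month = season_start_month

    def fit(self, X: RecordSet, y=None) -> "InjuryPreprocessor":
        return self

    def transform(self, X: RecordSet) -> RecordSet:
        cleaned, report = preprocess(
            X,
            nmap=self.normalization_map,
            drop_unknown_contact=self.drop_unknown_contact,
            drop_exacerbations_flag=self.drop_exacerbations,
            season_start_month=self.season_start_month,
        )
        self.report_ = report
        return cleaned
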
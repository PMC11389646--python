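"""Delphi-round consensus statistics for core-outcome-set selection.

A Delphi round asks a panel of experts to rate each candidate outcome on a
1-9 importance scale (1-3 unimportant, 4-6 important but not critical, 7-9
critical).  This module computes, per outcome, the band frequencies, the
agreement coefficients (share of votes in the critical band, and in the
important-plus-critical bands), the mean/SD/coefficient-of-variation of the
scores, and applies the selection rule: an outcome is *flagged* when the
selection-agreement coefficient falls below a threshold (default 80%) AND the
CV is at or above a threshold (default 0.3).  Flagged outcomes are excluded
unless an evidence-based override retains them.

Panel reliability is summarised by the expert authority coefficient
Cr = (Ca + Cs)/2, where Ca weights the declared bases of judgement
(theoretical analysis, practical experience, literature, intuition, each at
high/medium/low impact) and Cs weights self-rated familiarity on a five-point
scale.  Cr > 0.7 is conventionally read as acceptable reliability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from ._round import round_half_up

__all__ = [
    "BASES",
    "FAMILIARITY_LEVELS",
    "IMPACT_LEVELS",
    "AuthorityWeights",
    "ExpertProfile",
    "PanelAuthority",
    "RatingMatrix",
    "SelectionConfig",
    "agreement_coefficients",
    "apply_selection_rules",
    "authority_coefficient",
    "band_counts",
    "evaluate_round",
    "familiarity_coefficient",
    "familiarity_coefficient_from_counts",
    "judgement_coefficient",
    "judgement_coefficient_from_counts",
    "rating_descriptives",
    "response_rate",
]

BASES = ("theoretical_analysis", "practical_experience", "literature", "intuition")
IMPACT_LEVELS = ("high", "medium", "low")
FAMILIARITY_LEVELS = (
    "very_familiar",
    "quite_familiar",
    "moderately_familiar",
    "not_very_familiar",
    "unfamiliar",
)

Decision = Literal["selected", "flagged", "excluded", "retained_by_override"]


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RatingMatrix:
    """Complete experts x outcomes matrix of integer 1-9 importance scores."""

    expert_ids: tuple[str, ...]
    outcome_ids: tuple[str, ...]
    ratings: np.ndarray  # shape (n_experts, n_outcomes), int

    def __post_init__(self) -> None:
        arr = np.asarray(self.ratings)
        if arr.shape != (len(self.expert_ids), len(self.outcome_ids)):
            raise ValidationError(
                f"ratings shape {arr.shape} does not match "
                f"{len(self.expert_ids)} experts x {len(self.outcome_ids)} outcomes"
            )
        if len(self.expert_ids) < 2:
            raise ValidationError("a Delphi panel needs at least 2 experts")
        if len(self.outcome_ids) < 1:
            raise ValidationError("at least one outcome is required")
        if len(set(self.expert_ids)) != len(self.expert_ids):
            raise ValidationError("duplicate expert ids")
        if len(set(self.outcome_ids)) != len(self.outcome_ids):
            raise ValidationError("duplicate outcome ids")
        _validate_scores(arr, self.expert_ids, self.outcome_ids)
        object.__setattr__(self, "ratings", arr.astype(np.int64))

    @property
    def n_experts(self) -> int:
        return len(self.expert_ids)

    def column(self, outcome_id: str) -> np.ndarray:
        try:
            j = self.outcome_ids.index(outcome_id)
        except ValueError:
            raise ValidationError(f"unknown outcome id {outcome_id!r}") from None
        return self.ratings[:, j]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RatingMatrix":
        """Build from a long-format frame with columns expert_id, outcome_id, score."""
        required = {"expert_id", "outcome_id", "score"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"missing columns: {sorted(missing)}")
        wide = df.pivot_table(
            index="expert_id", columns="outcome_id", values="score", aggfunc="first"
        )
        if wide.isna().any().any():
            cell = wide.isna().stack()
            first = cell[cell].index[0]
            raise ValidationError(f"missing rating for expert {first[0]!r}, outcome {first[1]!r}")
        return cls(
            expert_ids=tuple(str(i) for i in wide.index),
            outcome_ids=tuple(str(c) for c in wide.columns),
            ratings=wide.to_numpy(),
        )


@dataclass(frozen=True)
class ExpertProfile:
    """One expert's self-declared bases of judgement and familiarity level."""

    expert_id: str
    basis_levels: Mapping[str, str]  # basis -> high|medium|low
    familiarity: str

    def __post_init__(self) -> None:
        missing = set(BASES) - set(self.basis_levels)
        if missing:
            raise ValidationError(f"expert {self.expert_id!r}: missing bases {sorted(missing)}")
        for basis, level in self.basis_levels.items():
            if basis not in BASES:
                raise ValidationError(f"expert {self.expert_id!r}: unknown basis {basis!r}")
            if level not in IMPACT_LEVELS:
                raise ValidationError(
                    f"expert {self.expert_id!r}: unknown impact level {level!r} for {basis}"
                )
        if self.familiarity not in FAMILIARITY_LEVELS:
            raise ValidationError(
                f"expert {self.expert_id!r}: unknown familiarity {self.familiarity!r}"
            )


@dataclass(frozen=True)
class AuthorityWeights:
    """Weights behind the judgement (Ca) and familiarity (Cs) coefficients.

    Defaults follow the conventional table: theoretical analysis 0.3/0.2/0.1,
    practical experience 0.5/0.4/0.3, literature and intuition 0.1 at every
    level; familiarity 1.0/0.8/0.6/0.4/0.2 from very familiar down to
    unfamiliar.
    """

    basis_weights: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "theoretical_analysis": (0.3, 0.2, 0.1),
            "practical_experience": (0.5, 0.4, 0.3),
            "literature": (0.1, 0.1, 0.1),
            "intuition": (0.1, 0.1, 0.1),
        }
    )
    familiarity_weights: tuple[float, float, float, float, float] = (1.0, 0.8, 0.6, 0.4, 0.2)

    def __post_init__(self) -> None:
        for basis in BASES:
            if basis not in self.basis_weights:
                raise ValidationError(f"missing weights for basis {basis!r}")
            hi, med, lo = self.basis_weights[basis]
            if not (hi >= med >= lo >= 0):
                raise ValidationError(
                    f"weights for {basis!r} must satisfy high >= medium >= low >= 0"
                )
        if any(w < 0 for w in self.familiarity_weights):
            raise ValidationError("familiarity weights must be non-negative")


@dataclass(frozen=True)
class PanelAuthority:
    """Panel-level reliability summary: Ca, Cs, Cr and the response rate."""

    Ca: float
    Cs: float
    Cr: float
    acceptable: bool
    response_rate_percent: float | None = None


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds and overrides for the outcome selection rule.

    ``agreement_threshold`` is compared strictly (< flags) and ``cv_threshold``
    non-strictly (>= flags); this is the only combination consistent with
    retaining outcomes sitting exactly at 80% agreement with a high CV.
    ``agreement_basis`` picks which coefficient drives the rule; the selection
    coefficient (votes in bands 4-9) is the default.  ``flag_high_cv_only``
    inverts the CV polarity for sensitivity analyses.
    """

    agreement_threshold: float = 80.0
    cv_threshold: float = 0.3
    band_edges: tuple[int, int] = (3, 6)
    override_set: Mapping[str, str] = field(default_factory=dict)  # outcome -> justification
    agreement_basis: Literal["selection", "importance"] = "selection"
    flag_high_cv_only: bool = True
    sd_ddof: int = 1  # sample SD by default

    def __post_init__(self) -> None:
        if not (0 < self.agreement_threshold <= 100):
            raise ValidationError("agreement_threshold must be in (0, 100]")
        if self.cv_threshold <= 0:
            raise ValidationError("cv_threshold must be positive")
        lo, hi = self.band_edges
        if not (1 <= lo < hi <= 8):
            raise ValidationError("band edges must be strictly increasing inside [1, 9]")


# ---------------------------------------------------------------------------
# per-outcome statistics
# ---------------------------------------------------------------------------


def _validate_scores(arr: np.ndarray, expert_ids=None, outcome_ids=None) -> None:
    flat = np.asarray(arr, dtype=float)
    bad = ~np.isfinite(flat) | (flat != np.floor(flat)) | (flat < 1) | (flat > 9)
    if bad.any():
        idx = tuple(int(i) for i in np.argwhere(bad)[0])
        loc = ""
        if expert_ids is not None and flat.ndim == 2:
            loc = f" (expert {expert_ids[idx[0]]!r}, outcome {outcome_ids[idx[1]]!r})"
        raise ValidationError(
            f"rating {np.asarray(arr).ravel()[np.flatnonzero(bad.ravel())[0]]!r} is not an "
            f"integer in [1, 9]{loc}"
        )


def band_counts(
    scores: Sequence[int], band_edges: tuple[int, int] = (3, 6)
) -> tuple[int, int, int]:
    """Count scores in the critical / important / unimportant bands.

    Under default edges (3, 6): scores 7-9 are critical, 4-6 important but not
    critical, 1-3 unimportant.  Returns ``(n_critical, n_important,
    n_unimportant)``; the three counts sum to ``len(scores)``.
    """
    arr = np.asarray(list(scores))
    if arr.size == 0:
        raise ValidationError("score list is empty")
    _validate_scores(arr)
    lo, hi = band_edges
    n_unimp = int(np.count_nonzero(arr <= lo))
    n_crit = int(np.count_nonzero(arr > hi))
    n_imp = int(arr.size - n_unimp - n_crit)
    return n_crit, n_imp, n_unimp


def agreement_coefficients(
    bands: tuple[int, int, int], n: int
) -> tuple[float, float]:
    """Agreement coefficients (percent) from band counts.

    * importance agreement: share of votes in the critical band (7-9);
    * selection agreement: share in important-plus-critical (4-9).

    Both are returned rounded half-up to 2 decimals, the precision of the
    reported consensus tables.
    """
    if n <= 0:
        raise ValidationError("panel size must be positive")
    n_crit, n_imp, n_unimp = bands
    if min(bands) < 0 or n_crit + n_imp + n_unimp != n:
        raise ValidationError(f"band counts {bands} do not sum to panel size {n}")
    return (
        round_half_up(100.0 * n_crit / n, 2),
        round_half_up(100.0 * (n_crit + n_imp) / n, 2),
    )


def rating_descriptives(
    scores: Sequence[int], ddof: int = 1
) -> tuple[float, float, float]:
    """Mean, standard deviation and coefficient of variation of one outcome's scores.

    The SD uses the sample convention (``ddof=1``) by default; CV = SD/mean and
    is 0 for constant scores.  Values are returned unrounded.
    """
    arr = np.asarray(list(scores), dtype=float)
    if arr.size == 0:
        raise ValidationError("score list is empty")
    _validate_scores(arr)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=ddof)) if arr.size > ddof else 0.0
    cv = sd / mean if mean != 0 else float("inf")
    return mean, sd, cv


# ---------------------------------------------------------------------------
# expert authority
# ---------------------------------------------------------------------------


def _profile_counts(profiles: Iterable[ExpertProfile]):
    basis_counts = {b: dict.fromkeys(IMPACT_LEVELS, 0) for b in BASES}
    fam_counts = dict.fromkeys(FAMILIARITY_LEVELS, 0)
    n = 0
    for p in profiles:
        n += 1
        for basis in BASES:
            basis_counts[basis][p.basis_levels[basis]] += 1
        fam_counts[p.familiarity] += 1
    if n == 0:
        raise ValidationError("no expert profiles supplied")
    return basis_counts, fam_counts, n


def judgement_coefficient_from_counts(
    basis_counts: Mapping[str, Mapping[str, int]],
    n: int,
    weights: AuthorityWeights | None = None,
) -> float:
    """Judgement coefficient Ca from per-basis impact-level frequencies.

    Ca is the sum over the four bases of the weighted level frequencies divided
    by the panel size: Ca = sum_b sum_l w(b, l) * count(b, l) / n.  Under the
    default weights Ca lies in [0.6, 1.0].
    """
    if n <= 0:
        raise ValidationError("panel size must be positive")
    weights = weights or AuthorityWeights()
    total = 0.0
    for basis in BASES:
        counts = basis_counts.get(basis)
        if counts is None:
            raise ValidationError(f"missing counts for basis {basis!r}")
        if sum(counts.values()) != n:
            raise ValidationError(
                f"counts for basis {basis!r} sum to {sum(counts.values())}, expected {n}"
            )
        w = weights.basis_weights[basis]
        total += sum(w[i] * counts[level] for i, level in enumerate(IMPACT_LEVELS))
    return total / n


def judgement_coefficient(
    profiles: Sequence[ExpertProfile], weights: AuthorityWeights | None = None
) -> float:
    """Judgement coefficient Ca computed from individual expert profiles."""
    basis_counts, _, n = _profile_counts(profiles)
    return judgement_coefficient_from_counts(basis_counts, n, weights)


def familiarity_coefficient_from_counts(
    familiarity_counts: Mapping[str, int] | Sequence[int],
    n: int,
    weights: AuthorityWeights | None = None,
) -> float:
    """Familiarity coefficient Cs from the five familiarity-level frequencies.

    Cs = sum_l w(l) * count(l) / n with default weights (1.0, 0.8, 0.6, 0.4,
    0.2) from "very familiar" down to "unfamiliar"; Cs lies in [0.2, 1.0].
    """
    if n <= 0:
        raise ValidationError("panel size must be positive")
    weights = weights or AuthorityWeights()
    if isinstance(familiarity_counts, Mapping):
        unknown = set(familiarity_counts) - set(FAMILIARITY_LEVELS)
        if unknown:
            raise ValidationError(f"unknown familiarity levels: {sorted(unknown)}")
        counts = [familiarity_counts.get(level, 0) for level in FAMILIARITY_LEVELS]
    else:
        counts = list(familiarity_counts)
        if len(counts) != len(FAMILIARITY_LEVELS):
            raise ValidationError("expected five familiarity counts")
    if sum(counts) != n:
        raise ValidationError(f"familiarity counts sum to {sum(counts)}, expected {n}")
    return sum(w * c for w, c in zip(weights.familiarity_weights, counts)) / n


def familiarity_coefficient(
    profiles: Sequence[ExpertProfile], weights: AuthorityWeights | None = None
) -> float:
    """Familiarity coefficient Cs computed from individual expert profiles."""
    _, fam_counts, n = _profile_counts(profiles)
    return familiarity_coefficient_from_counts(fam_counts, n, weights)


def authority_coefficient(Ca: float, Cs: float) -> tuple[float, bool]:
    """Authority coefficient Cr = (Ca + Cs)/2 and whether it exceeds 0.7.

    Cr > 0.7 is the conventional bar for acceptable panel reliability.
    """
    for name, v in (("Ca", Ca), ("Cs", Cs)):
        if not (0 < v <= 1):
            raise ValidationError(f"{name}={v} outside (0, 1]")
    Cr = (Ca + Cs) / 2.0
    return Cr, Cr > 0.7


def response_rate(n_returned: int, n_distributed: int) -> float:
    """Questionnaire response rate in percent (the expert-enthusiasm measure)."""
    if n_distributed <= 0:
        raise ValidationError("n_distributed must be positive")
    if not (0 <= n_returned <= n_distributed):
        raise ValidationError("n_returned must be between 0 and n_distributed")
    return 100.0 * n_returned / n_distributed


def panel_authority(
    profiles: Sequence[ExpertProfile],
    weights: AuthorityWeights | None = None,
    n_distributed: int | None = None,
) -> PanelAuthority:
    """Convenience wrapper computing Ca, Cs, Cr and the response rate together."""
    Ca = judgement_coefficient(profiles, weights)
    Cs = familiarity_coefficient(profiles, weights)
    Cr, ok = authority_coefficient(Ca, Cs)
    rr = response_rate(len(profiles), n_distributed) if n_distributed else None
    return PanelAuthority(Ca=Ca, Cs=Cs, Cr=Cr, acceptable=ok, response_rate_percent=rr)


# ---------------------------------------------------------------------------
# round evaluation and selection rules
# ---------------------------------------------------------------------------

STATS_COLUMNS = [
    "outcome_id",
    "n_critical",
    "n_important",
    "n_unimportant",
    "agreement_importance",
    "agreement_selection",
    "mean",
    "sd",
    "cv",
]


def evaluate_round(matrix: RatingMatrix, config: SelectionConfig | None = None) -> pd.DataFrame:
    """Compute per-outcome consensus statistics for one Delphi round.

    Returns a frame with band counts, agreement coefficients (rounded to 2
    decimals), mean, SD and CV (unrounded), ordered by importance agreement
    descending, then outcome id, mirroring the layout of published consensus
    tables.
    """
    config = config or SelectionConfig()
    rows = []
    n = matrix.n_experts
    for outcome in matrix.outcome_ids:
        scores = matrix.column(outcome)
        bands = band_counts(scores, config.band_edges)
        agr_imp, agr_sel = agreement_coefficients(bands, n)
        mean, sd, cv = rating_descriptives(scores, ddof=config.sd_ddof)
        rows.append(
            dict(
                outcome_id=outcome,
                n_critical=bands[0],
                n_important=bands[1],
                n_unimportant=bands[2],
                agreement_importance=agr_imp,
                agreement_selection=agr_sel,
                mean=mean,
                sd=sd,
                cv=cv,
            )
        )
    df = pd.DataFrame(rows, columns=STATS_COLUMNS)
    return df.sort_values(
        ["agreement_importance", "outcome_id"], ascending=[False, True]
    ).reset_index(drop=True)


def apply_selection_rules(
    stats: pd.DataFrame, config: SelectionConfig | None = None
) -> pd.DataFrame:
    """Partition outcomes into selected / excluded / retained_by_override.

    An outcome is *flagged* when its driving agreement coefficient is strictly
    below ``agreement_threshold`` and its CV is at or above ``cv_threshold``
    (polarity invertible via ``flag_high_cv_only``).  Flagged outcomes in the
    override set are retained with their justification recorded; the rest are
    excluded; unflagged outcomes are selected.  Every outcome receives exactly
    one decision.
    """
    config = config or SelectionConfig()
    if stats.empty:
        return stats.assign(
            decision=pd.Series(dtype=str), override_justification=pd.Series(dtype=str)
        )
    agr_col = (
        "agreement_selection" if config.agreement_basis == "selection" else "agreement_importance"
    )
    for col in (agr_col, "cv", "outcome_id"):
        if col not in stats.columns:
            raise ValidationError(f"stats table missing column {col!r}")
    unknown = set(config.override_set) - set(stats["outcome_id"])
    if unknown:
        raise ValidationError(f"override ids not present in stats: {sorted(unknown)}")

    cv_flag = (
        stats["cv"] >= config.cv_threshold
        if config.flag_high_cv_only
        else stats["cv"] < config.cv_threshold
    )
    flagged = (stats[agr_col] < config.agreement_threshold) & cv_flag
    overridden = stats["outcome_id"].isin(config.override_set)

    decision = np.where(
        flagged & overridden,
        "retained_by_override",
        np.where(flagged, "excluded", "selected"),
    )
    justification = [
        config.override_set.get(o, "") if d == "retained_by_override" else ""
        for o, d in zip(stats["outcome_id"], decision)
    ]
    out = stats.copy()
    out["flagged"] = flagged.to_numpy()
    out["decision"] = decision
    out["override_justification"] = justification
    return out


def decision_counts(decisions: pd.DataFrame) -> dict[str, int]:
    """Tally of decisions from an ``apply_selection_rules`` result."""
    counts = decisions["decision"].value_counts().to_dict() if len(decisions) else {}
    return {
        k: int(counts.get(k, 0)) for k in ("selected", "retained_by_override", "excluded")
    }
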
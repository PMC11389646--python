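"""AGREE II guideline-quality appraisal: standardized domain scores, rater ICC,
and recommendation-level grading.

The AGREE II instrument has 23 items in six domains (scope & purpose, items
1-3; stakeholder involvement, 4-6; rigor of development, 7-14; clarity of
expression, 15-17; applicability, 18-21; editorial independence, 22-23), each
item scored 1-7 by every appraiser.  A domain's standardized score is

    100 * (obtained - min_possible) / (max_possible - min_possible)

with obtained the sum of all appraiser x item scores in the domain and the
min/max the all-1 and all-7 totals.  Rater agreement is summarised with a
two-way intraclass correlation coefficient, and documents receive an A/B/C
recommendation level from a configurable domain-score rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._round import round_percent

__all__ = [
    "DOMAIN_ITEMS",
    "DOMAIN_NAMES",
    "AppraisalMatrix",
    "DomainScoreSet",
    "GradingRule",
    "IccResult",
    "appraise_document",
    "domain_mean",
    "icc",
    "recommendation_level",
    "standardized_domain_score",
]


class ValidationError(ValueError):
    pass


#: item numbers (1-based) belonging to each of the six AGREE II domains
DOMAIN_ITEMS: dict[int, tuple[int, ...]] = {
    1: (1, 2, 3),
    2: (4, 5, 6),
    3: (7, 8, 9, 10, 11, 12, 13, 14),
    4: (15, 16, 17),
    5: (18, 19, 20, 21),
    6: (22, 23),
}

DOMAIN_NAMES = {
    1: "Scope and Purpose",
    2: "Stakeholder Involvement",
    3: "Rigor of Development",
    4: "Clarity of Expression",
    5: "Applicability",
    6: "Editorial Independence",
}

N_ITEMS = 23
SCALE_MIN, SCALE_MAX = 1, 7


@dataclass(frozen=True)
class AppraisalMatrix:
    """Appraisers x 23 items of AGREE II scores for one document.

    Two ingest modes exist:

    * per-rater: ``item_scores`` holds each appraiser's integer 1-7 score and
      ICC is computable;
    * aggregated: only item means across appraisers are known (published
      tables typically print these); ``from_item_means`` stores the means
      replicated per appraiser so that domain totals reproduce
      ``n_appraisers * sum(item means)``, and ICC is unavailable.
    """

    document_id: str
    appraiser_ids: tuple[str, ...]
    item_scores: np.ndarray  # (n_appraisers, 23), float
    aggregated: bool = False

    def __post_init__(self) -> None:
        arr = np.asarray(self.item_scores, dtype=float)
        if arr.shape != (len(self.appraiser_ids), N_ITEMS):
            raise ValidationError(
                f"{self.document_id}: item_scores shape {arr.shape}, expected "
                f"({len(self.appraiser_ids)}, {N_ITEMS})"
            )
        if len(self.appraiser_ids) < 1:
            raise ValidationError("at least one appraiser required")
        if self.aggregated:
            # published item means occasionally dip below the scale minimum;
            # accept [0, 7] here, per-rater mode stays strict
            if ((arr < 0) | (arr > SCALE_MAX)).any():
                raise ValidationError(f"{self.document_id}: aggregated mean outside [0, 7]")
        else:
            bad = (arr != np.floor(arr)) | (arr < SCALE_MIN) | (arr > SCALE_MAX)
            if bad.any():
                a, i = map(int, np.argwhere(bad)[0])
                raise ValidationError(
                    f"{self.document_id}: score {arr[a, i]!r} for appraiser "
                    f"{self.appraiser_ids[a]!r}, item {i + 1} is not an integer in [1, 7]"
                )
        object.__setattr__(self, "item_scores", arr)

    @classmethod
    def from_item_means(
        cls, document_id: str, item_means: Sequence[float], n_appraisers: int
    ) -> "AppraisalMatrix":
        """Aggregated-mode constructor from 23 published item means."""
        means = np.asarray(list(item_means), dtype=float)
        if means.shape != (N_ITEMS,):
            raise ValidationError(f"expected {N_ITEMS} item means, got {means.shape}")
        if n_appraisers < 1:
            raise ValidationError("n_appraisers must be >= 1")
        scores = np.tile(means, (n_appraisers, 1))
        ids = tuple(f"appraiser_{k + 1}" for k in range(n_appraisers))
        return cls(document_id, ids, scores, aggregated=True)

    def domain_block(self, domain: int) -> np.ndarray:
        items = DOMAIN_ITEMS.get(domain)
        if items is None:
            raise ValidationError(f"unknown domain {domain}")
        return self.item_scores[:, [i - 1 for i in items]]


@dataclass(frozen=True)
class IccResult:
    """Intraclass correlation with its F-test p-value.

    ``status`` is "ok", "degenerate" (no between-subject variance, ICC
    undefined) or "unavailable" (aggregated input without per-rater scores).
    """

    estimate: float | None
    p_value: float | None
    model: str
    status: str = "ok"


@dataclass(frozen=True)
class GradingRule:
    """Recommendation-level rule: A if every domain >= ``a_floor`` percent,
    C if fewer than ``c_min_domains`` domains reach ``c_floor``, else B."""

    a_floor: float = 60.0
    c_floor: float = 30.0
    c_min_domains: int = 3


@dataclass(frozen=True)
class DomainScoreSet:
    document_id: str
    domain_scores: tuple[int, int, int, int, int, int]  # standardized %, rounded
    recommendation_level: str
    icc: IccResult


def standardized_domain_score(
    scores: np.ndarray | Sequence[Sequence[float]],
    scale: tuple[int, int] = (SCALE_MIN, SCALE_MAX),
) -> int:
    """Standardized percentage score for one domain block (appraisers x items).

    100 * (obtained - min_possible)/(max_possible - min_possible), where the
    min/max totals correspond to every appraiser giving every item the scale
    minimum/maximum.  Returned rounded half-up to an integer percent, the
    precision used when such scores are reported.
    """
    arr = np.asarray(scores, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.size == 0:
        raise ValidationError("empty domain block")
    lo, hi = scale
    if (arr > hi).any() or (arr < 0).any():
        raise ValidationError("domain scores outside the rating scale")
    # per-rater item scores are integers, so the true obtained total is an
    # integer; snapping undoes the rounding error carried by published item
    # means (e.g. 2.67 standing for 8/3) before standardizing
    obtained = float(np.rint(arr.sum()))
    min_possible = arr.size * lo
    max_possible = arr.size * hi
    return round_percent(100.0 * (obtained - min_possible) / (max_possible - min_possible))


def domain_mean(scores_across_documents: Sequence[float]) -> int:
    """Cross-document mean of one domain's standardized scores, integer percent."""
    vals = list(scores_across_documents)
    if not vals:
        raise ValidationError("no domain scores supplied")
    return round_percent(float(np.mean(vals)))


def recommendation_level(
    domain_scores: Sequence[float], rule: GradingRule | None = None
) -> str:
    """Grade a document A/B/C from its six standardized domain scores."""
    rule = rule or GradingRule()
    scores = list(domain_scores)
    if len(scores) != 6:
        raise ValidationError(f"expected 6 domain scores, got {len(scores)}")
    if any(not (0 <= s <= 100) for s in scores):
        raise ValidationError("domain scores must lie in [0, 100]")
    if all(s >= rule.a_floor for s in scores):
        return "A"
    if sum(s >= rule.c_floor for s in scores) < rule.c_min_domains:
        return "C"
    return "B"


def icc(
    ratings: np.ndarray | Sequence[Sequence[float]], model: str = "ICC2"
) -> IccResult:
    """Two-way intraclass correlation for a raters x subjects matrix.

    ``model`` is "ICC2" (two-way random effects, absolute agreement, single
    measures — the default) or "ICC3" (two-way mixed, consistency, single
    measures).  Degenerate inputs with no between-subject variance return an
    explicit "degenerate" status instead of NaN.
    """
    arr = np.asarray(ratings, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValidationError("need at least 2 raters and 2 subjects")
    if not np.isfinite(arr).all():
        raise ValidationError("ratings must be finite and complete")
    if model not in ("ICC2", "ICC3"):
        raise ValidationError(f"unknown ICC model {model!r}")
    if np.allclose(arr.var(axis=0).sum() + arr.var(axis=1).sum(), 0.0):
        return IccResult(None, None, model, status="degenerate")

    n_raters, n_subjects = arr.shape
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n_subjects), n_raters),
            "rater": np.tile(np.arange(n_raters), n_subjects),
            "score": arr.T.ravel(),
        }
    )
    import pingouin as pg  # deferred: pingouin import is slow

    with np.errstate(divide="ignore", invalid="ignore"):
        table = pg.intraclass_corr(
            data=long, targets="subject", raters="rater", ratings="score"
        )
    labels = {"ICC2": ("ICC(A,1)", "ICC2"), "ICC3": ("ICC(C,1)", "ICC3")}[model]
    indexed = table.set_index("Type")
    label = next(l for l in labels if l in indexed.index)
    row = indexed.loc[label]
    est, p = float(row["ICC"]), float(row["pval"])
    if not np.isfinite(est):
        return IccResult(None, None, model, status="degenerate")
    return IccResult(est, p, model, status="ok")


def appraise_document(
    matrix: AppraisalMatrix,
    rule: GradingRule | None = None,
    icc_model: str = "ICC2",
) -> DomainScoreSet:
    """Six standardized domain scores, recommendation level and rater ICC."""
    scores = tuple(
        standardized_domain_score(matrix.domain_block(d)) for d in range(1, 7)
    )
    level = recommendation_level(scores, rule)
    if matrix.aggregated or len(matrix.appraiser_ids) < 2:
        icc_res = IccResult(None, None, icc_model, status="unavailable")
    else:
        icc_res = icc(matrix.item_scores, model=icc_model)  # raters x items-as-subjects
    return DomainScoreSet(matrix.document_id, scores, level, icc_res)


def appraise_documents(
    matrices: Sequence[AppraisalMatrix],
    rule: GradingRule | None = None,
) -> pd.DataFrame:
    """Appraise several documents and append the cross-document domain means.

    Returns a frame with one row per document (six domain-score columns plus
    the recommendation level) and a final "Mean" row averaging each domain.
    """
    if not matrices:
        raise ValidationError("no appraisal matrices supplied")
    results = [appraise_document(m, rule) for m in matrices]
    rows = [
        {
            "document_id": r.document_id,
            **{f"domain_{d}": r.domain_scores[d - 1] for d in range(1, 7)},
            "recommendation_level": r.recommendation_level,
            "icc": float("nan") if r.icc.estimate is None else r.icc.estimate,
        }
        for r in results
    ]
    df = pd.DataFrame(rows)
    mean_row: dict = {
        "document_id": "Mean", "recommendation_level": "", "icc": float("nan")
    }
    for d in range(1, 7):
        mean_row[f"domain_{d}"] = domain_mean(df[f"domain_{d}"].tolist())
    return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)
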
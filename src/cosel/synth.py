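"""Synthetic inputs with the statistical structure each pipeline stage assumes.

Every generator is deterministic under its seed and emits objects that pass
the corresponding stage's validators, so the full pipeline — Delphi round,
AGREE II appraisal, outcome tally, network meta-analysis — runs end to end
with no external data.

Defaults mirror the study conditions the stages were designed around: a
15-expert panel rating outcomes 1-9, 3 appraisers on the 23 AGREE II items,
~500 trial extraction records, and small multi-treatment networks with known
relative effects and between-trial heterogeneity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .agree import AppraisalMatrix, DOMAIN_ITEMS
from .delphi import (
    BASES,
    FAMILIARITY_LEVELS,
    IMPACT_LEVELS,
    ExpertProfile,
    RatingMatrix,
)
from .nma import ArmRecord
from .pool import ExtractionRecord

__all__ = [
    "NetworkSpec",
    "PanelSpec",
    "gen_appraisals",
    "gen_extraction",
    "gen_network",
    "gen_panel",
]


class ValidationError(ValueError):
    pass


def _check_probs(p: Sequence[float], what: str) -> np.ndarray:
    arr = np.asarray(list(p), dtype=float)
    if (arr < 0).any() or not math.isclose(arr.sum(), 1.0, abs_tol=1e-9):
        raise ValidationError(f"{what} probabilities must be non-negative and sum to 1")
    return arr


# ---------------------------------------------------------------------------
# Delphi panels
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PanelSpec:
    """Latent structure of a synthetic expert panel.

    Each outcome o has a latent importance mu_o in [1, 9]; expert ratings are
    round(clip(Normal(mu_o, sigma_o), 1, 9)).  Judgement-basis and familiarity
    profiles are drawn from the categorical distributions; the defaults put
    most mass on high practical experience and good familiarity, the typical
    make-up of a clinical consensus panel.
    """

    outcome_mu: Mapping[str, float]
    outcome_sigma: Mapping[str, float] | float = 1.0
    n_experts: int = 15
    basis_probs: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "theoretical_analysis": (0.5, 0.45, 0.05),
            "practical_experience": (0.7, 0.2, 0.1),
            "literature": (0.6, 0.4, 0.0),
            "intuition": (0.05, 0.25, 0.7),
        }
    )
    familiarity_probs: tuple[float, ...] = (0.35, 0.45, 0.2, 0.0, 0.0)
    seed: int = 0

    def sigma_for(self, outcome: str) -> float:
        if isinstance(self.outcome_sigma, Mapping):
            return float(self.outcome_sigma[outcome])
        return float(self.outcome_sigma)

    def __post_init__(self) -> None:
        if self.n_experts < 2:
            raise ValidationError("panel needs at least 2 experts")
        for o, mu in self.outcome_mu.items():
            if not (1 <= mu <= 9):
                raise ValidationError(f"latent importance for {o!r} outside [1, 9]")
            if self.sigma_for(o) <= 0:
                raise ValidationError(f"rating sd for {o!r} must be positive")
        for basis in BASES:
            _check_probs(self.basis_probs[basis], f"basis {basis!r}")
        _check_probs(self.familiarity_probs, "familiarity")


def gen_panel(spec: PanelSpec) -> tuple[RatingMatrix, list[ExpertProfile]]:
    """Draw a complete rating matrix and matching expert profiles."""
    rng = np.random.default_rng(spec.seed)
    outcomes = tuple(spec.outcome_mu)
    ratings = np.empty((spec.n_experts, len(outcomes)), dtype=int)
    for j, o in enumerate(outcomes):
        raw = rng.normal(spec.outcome_mu[o], spec.sigma_for(o), size=spec.n_experts)
        ratings[:, j] = np.clip(np.rint(raw), 1, 9).astype(int)
    profiles = []
    for i in range(spec.n_experts):
        levels = {
            basis: IMPACT_LEVELS[rng.choice(3, p=_check_probs(spec.basis_probs[basis], basis))]
            for basis in BASES
        }
        fam = FAMILIARITY_LEVELS[
            rng.choice(len(FAMILIARITY_LEVELS), p=_check_probs(spec.familiarity_probs, "fam"))
        ]
        profiles.append(ExpertProfile(f"expert_{i + 1:02d}", levels, fam))
    matrix = RatingMatrix(
        expert_ids=tuple(p.expert_id for p in profiles),
        outcome_ids=outcomes,
        ratings=ratings,
    )
    return matrix, profiles


# ---------------------------------------------------------------------------
# AGREE II appraisals
# ---------------------------------------------------------------------------


def gen_appraisals(
    true_domain_quality: Sequence[float],
    n_appraisers: int = 3,
    noise_sd: float = 0.5,
    seed: int = 0,
    document_id: str = "synthetic_guideline",
) -> AppraisalMatrix:
    """Appraiser x item matrix around latent per-domain quality in [0, 1].

    Item scores are round(clip(1 + 6 q_domain + Normal(0, noise_sd), 1, 7)),
    so quality 0 maps to all-1 items (domain score 0%) and quality 1 to all-7
    items (100%) in the noiseless limit.
    """
    q = np.asarray(list(true_domain_quality), dtype=float)
    if q.shape != (6,):
        raise ValidationError("need six domain quality values")
    if ((q < 0) | (q > 1)).any():
        raise ValidationError("domain quality must lie in [0, 1]")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    scores = np.empty((n_appraisers, 23))
    for domain, items in DOMAIN_ITEMS.items():
        latent = 1.0 + 6.0 * q[domain - 1]
        for item in items:
            raw = latent + rng.normal(0.0, noise_sd, size=n_appraisers) if noise_sd else latent
            scores[:, item - 1] = np.clip(np.rint(raw), 1, 7)
    ids = tuple(f"appraiser_{k + 1}" for k in range(n_appraisers))
    return AppraisalMatrix(document_id, ids, scores.astype(int))


# ---------------------------------------------------------------------------
# trial outcome-extraction records
# ---------------------------------------------------------------------------


def gen_extraction(
    n_trials: int,
    reporting_probs: Mapping[str, float],
    domains: Mapping[str, str] | None = None,
    seed: int = 0,
) -> list[ExtractionRecord]:
    """Each trial reports each outcome independently with its probability."""
    if n_trials < 1:
        raise ValidationError("n_trials must be >= 1")
    for o, p in reporting_probs.items():
        if not (0 <= p <= 1):
            raise ValidationError(f"reporting probability for {o!r} outside [0, 1]")
    domains = domains or {}
    rng = np.random.default_rng(seed)
    outcomes = list(reporting_probs)
    probs = np.array([reporting_probs[o] for o in outcomes])
    hits = rng.random((n_trials, len(outcomes))) < probs
    records = []
    for i in range(n_trials):
        pairs = [
            (o, domains.get(o, "unspecified"))
            for o, h in zip(outcomes, hits[i])
            if h
        ]
        records.append(ExtractionRecord.from_pairs(f"trial_{i + 1:04d}", pairs))
    return records


# ---------------------------------------------------------------------------
# treatment networks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NetworkSpec:
    """Generative model for arm-level trial data around known relative effects.

    ``d`` maps treatments to their true basic parameters (reference value 0;
    MD scale for continuous, logRR for binary).  Each listed comparison gets
    ``trials_per_comparison`` two-arm trials; the trial-level true contrast is
    d_a - d_b + Normal(0, tau).  Continuous arms report the sample mean of n
    draws from Normal(baseline + effect, arm_sd); binary arms report
    Binomial(n, risk) events with the risk implied by the log link, clipped
    at ``risk_clip`` with a warning (rejection mode available via
    ``on_invalid_risk="error"``).
    """

    d: Mapping[str, float]
    comparisons: tuple[tuple[str, str], ...]
    tau: float = 0.2
    trials_per_comparison: int = 4
    n_per_arm: int = 100
    measure: str = "md"
    baseline_mean: float = 50.0
    arm_sd: float = 10.0
    baseline_risk: float = 0.2
    risk_clip: float = 0.99
    on_invalid_risk: str = "clip"  # or "error"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValidationError("tau must be >= 0")
        if self.n_per_arm < 2:
            raise ValidationError("n_per_arm must be >= 2")
        if not (0 < self.baseline_risk < 1):
            raise ValidationError("baseline_risk must lie in (0, 1)")
        for a, b in self.comparisons:
            if a not in self.d or b not in self.d:
                raise ValidationError(f"comparison ({a}, {b}) uses unknown treatment")


def gen_network(spec: NetworkSpec) -> list[ArmRecord]:
    """Simulate arm-level records from the random-effects consistency model."""
    rng = np.random.default_rng(spec.seed)
    arms: list[ArmRecord] = []
    t = 0
    for a, b in spec.comparisons:
        for _ in range(spec.trials_per_comparison):
            t += 1
            tid = f"trial_{t:03d}"
            true_contrast = spec.d[a] - spec.d[b] + rng.normal(0.0, spec.tau)
            if spec.measure == "md":
                base = spec.baseline_mean + rng.normal(0.0, 5.0)
                for treat, loc in ((b, base), (a, base + true_contrast)):
                    draws = rng.normal(loc, spec.arm_sd, size=spec.n_per_arm)
                    arms.append(
                        ArmRecord(
                            tid,
                            treat,
                            spec.n_per_arm,
                            mean=float(draws.mean()),
                            sd=float(draws.std(ddof=1)),
                        )
                    )
            else:
                p_base = spec.baseline_risk
                p_treat = p_base * math.exp(true_contrast)
                if p_treat >= 1.0:
                    if spec.on_invalid_risk == "error":
                        raise ValidationError(
                            f"{tid}: implied risk {p_treat:.3f} >= 1 for {a}"
                        )
                    import warnings

                    warnings.warn(
                        f"{tid}: implied risk clipped to {spec.risk_clip}",
                        stacklevel=2,
                    )
                    p_treat = spec.risk_clip
                for treat, p in ((b, p_base), (a, p_treat)):
                    events = int(rng.binomial(spec.n_per_arm, p))
                    arms.append(ArmRecord(tid, treat, spec.n_per_arm, events=events))
    return arms
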
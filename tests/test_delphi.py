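"""Delphi consensus statistics: banding, agreement, descriptives, authority,
selection rules, and their invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cosel import datasets as ds
from cosel import delphi
from cosel.delphi import (
    AuthorityWeights,
    ExpertProfile,
    RatingMatrix,
    SelectionConfig,
    ValidationError,
)

score_lists = st.lists(st.integers(1, 9), min_size=1, max_size=40)


# ---------------------------------------------------------------------------
# banding and agreement
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "scores, expected",
    [
        ([8] * 15, (15, 0, 0)),  # unanimous critical panel
        ((8, 8, 4, 4, 2), (2, 2, 1)),
        ([1, 3, 4, 6, 7, 9], (2, 2, 2)),
    ],
)
def test_band_counts_examples(scores, expected):
    assert delphi.band_counts(scores) == expected


@given(score_lists)
@settings(max_examples=50, deadline=None)
def test_band_counts_matches_per_element_tally(scores):
    """Vectorized banding equals an element-by-element loop."""
    n_crit = sum(1 for s in scores if 7 <= s <= 9)
    n_imp = sum(1 for s in scores if 4 <= s <= 6)
    n_unimp = sum(1 for s in scores if 1 <= s <= 3)
    assert delphi.band_counts(scores) == (n_crit, n_imp, n_unimp)
    assert sum(delphi.band_counts(scores)) == len(scores)


@pytest.mark.parametrize("bad", [[0], [10], [4.5], []])
def test_band_counts_rejects_invalid_scores(bad):
    with pytest.raises(ValidationError):
        delphi.band_counts(bad)


@pytest.mark.parametrize(
    "bands, n, expected",
    [
        ((12, 2, 1), 15, (80.00, 93.33)),
        ((5, 6, 4), 15, (33.33, 73.33)),
        ((15, 0, 0), 15, (100.00, 100.00)),
        ((0, 0, 7), 7, (0.00, 0.00)),
    ],
)
def test_agreement_coefficients_examples(bands, n, expected):
    assert delphi.agreement_coefficients(bands, n) == expected


def test_agreement_coefficients_validation():
    with pytest.raises(ValidationError):
        delphi.agreement_coefficients((1, 1, 1), 0)
    with pytest.raises(ValidationError):
        delphi.agreement_coefficients((1, 1, 1), 5)


@given(score_lists)
@settings(max_examples=50, deadline=None)
def test_selection_agreement_dominates_importance_agreement(scores):
    bands = delphi.band_counts(scores)
    imp, sel = delphi.agreement_coefficients(bands, len(scores))
    assert 0 <= imp <= sel <= 100


# ---------------------------------------------------------------------------
# descriptives
# ---------------------------------------------------------------------------


def test_descriptives_constant_scores():
    assert delphi.rating_descriptives([7] * 12) == (7.0, 0.0, 0.0)


def test_descriptives_hand_computed():
    mean, sd, cv = delphi.rating_descriptives((9, 8, 7))
    assert (mean, sd, cv) == (8.0, 1.0, 0.125)


@given(score_lists.filter(lambda xs: len(xs) >= 2))
@settings(max_examples=50, deadline=None)
def test_descriptives_match_brute_force(scores):
    mean, sd, cv = delphi.rating_descriptives(scores)
    m = sum(scores) / len(scores)
    var = sum((s - m) ** 2 for s in scores) / (len(scores) - 1)
    assert mean == pytest.approx(m)
    assert sd == pytest.approx(var**0.5)
    assert cv == pytest.approx(var**0.5 / m)


# ---------------------------------------------------------------------------
# expert authority
# ---------------------------------------------------------------------------


def _uniform_profiles(n, level, familiarity="very_familiar"):
    return [
        ExpertProfile(f"e{i}", dict.fromkeys(delphi.BASES, level), familiarity)
        for i in range(n)
    ]


def test_judgement_coefficient_published_panel():
    """The published basis-impact frequencies give Ca = 0.913 (3 dp)."""
    ca = delphi.judgement_coefficient_from_counts(ds.JUDGEMENT_BASIS_COUNTS, ds.N_EXPERTS)
    assert ca == pytest.approx(0.9133, abs=5e-5)


def test_judgement_coefficient_extremes():
    assert delphi.judgement_coefficient(_uniform_profiles(15, "high")) == pytest.approx(1.0)
    assert delphi.judgement_coefficient(_uniform_profiles(15, "low")) == pytest.approx(0.6)


def test_familiarity_coefficient_published_panel():
    """Familiarity frequencies (5,7,3,0,0)/15 give Cs = 0.83 at 2 dp."""
    cs = delphi.familiarity_coefficient_from_counts(ds.FAMILIARITY_COUNTS, ds.N_EXPERTS)
    assert cs == pytest.approx(0.82667, abs=5e-6)
    assert round(cs, 2) == 0.83


def test_familiarity_coefficient_extremes():
    assert delphi.familiarity_coefficient(
        _uniform_profiles(10, "high", "very_familiar")
    ) == pytest.approx(1.0)
    assert delphi.familiarity_coefficient(
        _uniform_profiles(10, "high", "unfamiliar")
    ) == pytest.approx(0.2)


@pytest.mark.parametrize(
    "ca, cs, cr, ok",
    [(0.92, 0.83, 0.875, True), (1.0, 1.0, 1.0, True), (0.6, 0.2, 0.4, False)],
)
def test_authority_coefficient(ca, cs, cr, ok):
    assert delphi.authority_coefficient(ca, cs) == (pytest.approx(cr), ok)


@given(st.floats(0.6, 1.0), st.floats(0.2, 1.0), st.floats(0.0, 0.05))
@settings(max_examples=50, deadline=None)
def test_authority_monotone_in_both_coefficients(ca, cs, eps):
    cr, _ = delphi.authority_coefficient(ca, cs)
    cr_up, _ = delphi.authority_coefficient(min(ca + eps, 1.0), cs)
    assert cr_up >= cr


@pytest.mark.parametrize(
    "returned, distributed, expected", [(15, 15, 100.0), (0, 10, 0.0), (7, 14, 50.0)]
)
def test_response_rate(returned, distributed, expected):
    assert delphi.response_rate(returned, distributed) == expected


def test_response_rate_rejects_zero_distribution():
    with pytest.raises(ValidationError):
        delphi.response_rate(1, 0)


def test_profile_validation():
    with pytest.raises(ValidationError):
        ExpertProfile("e1", {"theoretical_analysis": "high"}, "very_familiar")
    with pytest.raises(ValidationError):
        ExpertProfile("e1", dict.fromkeys(delphi.BASES, "extreme"), "very_familiar")
    with pytest.raises(ValidationError):
        AuthorityWeights(basis_weights={
            "theoretical_analysis": (0.1, 0.2, 0.3),  # not monotone
            "practical_experience": (0.5, 0.4, 0.3),
            "literature": (0.1, 0.1, 0.1),
            "intuition": (0.1, 0.1, 0.1),
        })


# ---------------------------------------------------------------------------
# round evaluation
# ---------------------------------------------------------------------------


def test_evaluate_round_degenerate_outcome():
    ratings = np.column_stack([np.full(15, 8), np.tile([4, 8, 2], 5)])
    m = RatingMatrix(
        tuple(f"e{i}" for i in range(15)), ("A", "B"), ratings
    )
    stats = delphi.evaluate_round(m).set_index("outcome_id")
    a = stats.loc["A"]
    assert (a.n_critical, a.n_important, a.n_unimportant) == (15, 0, 0)
    assert (a.agreement_importance, a.agreement_selection) == (100.0, 100.0)
    assert a.cv == 0.0


def test_evaluate_round_matches_componentwise_recomputation(small_panel):
    matrix, _ = small_panel
    stats = delphi.evaluate_round(matrix).set_index("outcome_id")
    for outcome in matrix.outcome_ids:
        scores = matrix.column(outcome)
        bands = delphi.band_counts(scores)
        imp, sel = delphi.agreement_coefficients(bands, matrix.n_experts)
        mean, sd, cv = delphi.rating_descriptives(scores)
        row = stats.loc[outcome]
        assert (row.n_critical, row.n_important, row.n_unimportant) == bands
        assert (row.agreement_importance, row.agreement_selection) == (imp, sel)
        assert row["mean"] == pytest.approx(mean)
        assert row.cv == pytest.approx(cv)


def test_evaluate_round_invariant_to_expert_permutation(small_panel, rng):
    matrix, _ = small_panel
    perm = rng.permutation(matrix.n_experts)
    shuffled = RatingMatrix(
        tuple(matrix.expert_ids[i] for i in perm),
        matrix.outcome_ids,
        matrix.ratings[perm],
    )
    a = delphi.evaluate_round(matrix)
    b = delphi.evaluate_round(shuffled)
    pd.testing.assert_frame_equal(a, b)


def test_rating_matrix_validation():
    with pytest.raises(ValidationError):
        RatingMatrix(("e1",), ("A",), np.array([[5]]))  # one expert
    with pytest.raises(ValidationError) as err:
        RatingMatrix(("e1", "e2"), ("A",), np.array([[5], [11]]))
    assert "e2" in str(err.value)


# ---------------------------------------------------------------------------
# selection rules
# ---------------------------------------------------------------------------


def test_selection_rules_reproduce_published_consensus_round():
    """On the published consensus table the flagged and excluded sets match."""
    cfg = SelectionConfig(override_set=ds.DELPHI_OVERRIDE_SET)
    dec = delphi.apply_selection_rules(ds.delphi_consensus_frame(), cfg)
    assert set(dec.loc[dec.flagged, "outcome_id"]) == set(ds.EXPECTED_FLAGGED)
    assert set(dec.loc[dec.decision == "excluded", "outcome_id"]) == set(
        ds.EXPECTED_EXCLUDED
    )
    retained = set(dec.loc[dec.decision == "retained_by_override", "outcome_id"])
    assert retained == set(ds.DELPHI_OVERRIDE_SET)


def test_agreement_exactly_at_threshold_is_not_flagged():
    """High CV alone does not flag an outcome sitting exactly at 80% agreement."""
    stats = pd.DataFrame(
        [{"outcome_id": "crp", "agreement_selection": 80.0,
          "agreement_importance": 33.33, "cv": 0.41}]
    )
    dec = delphi.apply_selection_rules(stats)
    assert dec.decision.tolist() == ["selected"]


def test_selection_rules_empty_table():
    empty = ds.delphi_consensus_frame().iloc[0:0]
    assert len(delphi.apply_selection_rules(empty)) == 0


def test_selection_rules_partition_and_idempotence():
    cfg = SelectionConfig(override_set=ds.DELPHI_OVERRIDE_SET)
    dec = delphi.apply_selection_rules(ds.delphi_consensus_frame(), cfg)
    assert set(dec.decision) <= {"selected", "excluded", "retained_by_override"}
    assert len(dec) == len(ds.DELPHI_CONSENSUS_TABLE)
    again = delphi.apply_selection_rules(dec, cfg)
    assert (again.decision == dec.decision).all()
    counts = delphi.decision_counts(dec)
    assert sum(counts.values()) == len(dec)


def test_selection_rules_unknown_override_rejected():
    with pytest.raises(ValidationError):
        delphi.apply_selection_rules(
            ds.delphi_consensus_frame(),
            SelectionConfig(override_set={"no such outcome": "x"}),
        )
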
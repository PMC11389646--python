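"""Network construction, the MCMC fit, convergence diagnostics, ranking and
the Bucher consistency check."""

import math

import numpy as np
import pytest

from cosel import nma, synth
from cosel.nma import (
    ArmRecord,
    DisconnectedNetworkError,
    McmcConfig,
    NmaResult,
    ValidationError,
    build_network,
    combine_legs,
    psrf,
)


def _cont(tid, treat, n=50, mean=0.0, sd=1.0):
    return ArmRecord(tid, treat, n, mean=mean, sd=sd)


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------


def test_build_network_chains_are_connected():
    net = build_network(
        [_cont("t1", "A"), _cont("t1", "B"), _cont("t2", "B"), _cont("t2", "C")],
        "md",
    )
    assert set(net.treatments) == {"A", "B", "C"}
    assert net.comparison_trials("A", "B") == ["t1"]


def test_build_network_disconnected_raises():
    with pytest.raises(DisconnectedNetworkError):
        build_network(
            [_cont("t1", "A"), _cont("t1", "B"), _cont("t2", "C"), _cont("t2", "D")],
            "md",
        )


@pytest.mark.parametrize(
    "arms, message",
    [
        ([_cont("t1", "A")], "fewer than two arms"),
        ([_cont("t1", "A"), _cont("t1", "A")], "duplicate treatment"),
    ],
)
def test_build_network_rejects_malformed_trials(arms, message):
    with pytest.raises(ValidationError, match=message):
        build_network(arms, "md")


def test_connectivity_agrees_with_union_find(rng):
    """networkx connectivity matches a brute-force union-find over random graphs."""
    for _ in range(30):
        n_treat = int(rng.integers(3, 7))
        treats = [f"T{i}" for i in range(n_treat)]
        edges = []
        for t in range(int(rng.integers(2, 8))):
            a, b = rng.choice(n_treat, size=2, replace=False)
            edges.append((f"tr{t}", treats[a], treats[b]))
        parent = list(range(n_treat))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        used = sorted({a for _, a, _ in edges} | {b for _, _, b in edges})
        for _, a, b in edges:
            parent[find(treats.index(a))] = find(treats.index(b))
        connected = len({find(treats.index(t)) for t in used}) == 1
        arms = [
            arm
            for tid, a, b in edges
            for arm in (_cont(tid, a, mean=0.0), _cont(tid, b, mean=1.0))
        ]
        if connected:
            assert set(build_network(arms, "md").treatments) == set(used)
        else:
            with pytest.raises(DisconnectedNetworkError):
                build_network(arms, "md")


def test_reference_defaults_to_control_label():
    net = build_network(
        [_cont("t1", "CI"), _cont("t1", "A_CI"), _cont("t2", "CI"), _cont("t2", "B_CI")],
        "md",
    )
    assert net.reference == "CI"


# ---------------------------------------------------------------------------
# PSRF
# ---------------------------------------------------------------------------


def test_psrf_stationary_chains_near_one(rng):
    chains = rng.normal(0, 1, size=(3, 4000))
    assert psrf(chains) == pytest.approx(1.0, abs=0.02)


def test_psrf_offset_chains_flag_nonconvergence(rng):
    chains = rng.normal(0, 1, size=(2, 500))
    chains[1] += 50.0
    assert psrf(chains) > 10


def test_psrf_matches_hand_formula():
    chains = np.array([[1.0, 2, 3, 4, 5, 6, 7, 8, 9, 10],
                       [2.0, 3, 4, 5, 6, 7, 8, 9, 10, 11]])
    n = 10
    w = (chains.var(axis=1, ddof=1)).mean()
    b_n = chains.mean(axis=1).var(ddof=1)
    expected = math.sqrt(((n - 1) / n * w + b_n) / w)
    assert psrf(chains) == pytest.approx(expected, abs=1e-12)


def test_psrf_degenerate_chains():
    assert psrf(np.ones((2, 20))) == 1.0
    assert psrf(np.vstack([np.ones(20), np.full(20, 2.0)])) == math.inf
    with pytest.raises(ValidationError):
        psrf(np.ones((1, 20)))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

FAST = McmcConfig(n_chains=2, n_iterations=1500, n_burnin=400, seed=11)


def test_single_trial_posterior_tracks_observed_difference():
    """A saturated two-arm case: the basic parameter sits at the observed MD."""
    arms = [
        _cont("t1", "CI", n=400, mean=10.0, sd=4.0),
        _cont("t1", "A", n=400, mean=12.5, sd=4.0),
    ]
    net = build_network(arms, "md", reference="CI")
    res = nma.fit_nma(net, McmcConfig(n_chains=2, n_iterations=3000, n_burnin=800,
                                      seed=3, tau_upper=0.01))
    est, _ = nma.relative_effects(res, ("A", "CI"), point="mean")
    se = math.sqrt(2 * 4.0**2 / 400)
    assert est == pytest.approx(2.5, abs=3 * se)


def test_seeded_fit_is_bit_reproducible(small_md_network):
    net = build_network(small_md_network, "md")
    a = nma.fit_nma(net, FAST)
    b = nma.fit_nma(net, FAST)
    assert np.array_equal(a.d_samples, b.d_samples)
    assert np.array_equal(a.tau_samples, b.tau_samples)


def test_fit_reports_psrf_and_reference_is_zero(small_md_network):
    net = build_network(small_md_network, "md")
    res = nma.fit_nma(net, FAST)
    assert set(res.psrf) == {"d[A]", "d[B]", "tau"}
    assert (res.d_samples[:, :, 0] == 0).all()
    assert (res.tau_samples >= 0).all()


def test_consistency_identity_holds_in_every_draw(small_md_network):
    net = build_network(small_md_network, "md")
    res = nma.fit_nma(net, FAST)
    dab = res.contrast_draws("A", "B")
    dac = res.contrast_draws("A", "CI")
    dcb = res.contrast_draws("CI", "B")
    assert np.allclose(dab, dac + dcb)


def test_binary_fit_recovers_log_relative_risk():
    spec = synth.NetworkSpec(
        d={"CI": 0.0, "A": math.log(1.5)},
        comparisons=(("A", "CI"),),
        tau=0.0,
        trials_per_comparison=8,
        n_per_arm=300,
        measure="rr",
        baseline_risk=0.2,
        seed=21,
    )
    net = build_network(synth.gen_network(spec), "rr", reference="CI")
    res = nma.fit_nma(net, McmcConfig(n_chains=2, n_iterations=3000, n_burnin=800,
                                      seed=5, tau_upper=0.05))
    rr, (lo, hi) = nma.relative_effects(res, ("A", "CI"))
    assert lo < 1.5 < hi
    assert rr == pytest.approx(1.5, rel=0.15)


# ---------------------------------------------------------------------------
# relative effects and SUCRA
# ---------------------------------------------------------------------------


def _result_from_draws(draws, treatments=("CI", "A", "B")):
    d = np.asarray(draws, dtype=float)[None, :, :]
    return NmaResult(
        treatments=tuple(treatments),
        measure="md",
        d_samples=d,
        tau_samples=np.zeros(d.shape[:2]),
        psrf={},
        converged=True,
        config=McmcConfig(),
    )


def test_relative_effect_identity_and_antisymmetry(small_md_network):
    net = build_network(small_md_network, "md")
    res = nma.fit_nma(net, FAST)
    est, (lo, hi) = nma.relative_effects(res, ("A", "A"))
    assert (est, lo, hi) == (0.0, 0.0, 0.0)
    assert np.array_equal(res.contrast_draws("A", "B"), -res.contrast_draws("B", "A"))


def test_relative_effect_interval_matches_quantile_oracle(small_md_network, rng):
    net = build_network(small_md_network, "md")
    res = nma.fit_nma(net, FAST)
    draws = res.contrast_draws("A", "CI")
    est, (lo, hi) = nma.relative_effects(res, ("A", "CI"))
    assert est == pytest.approx(float(np.median(draws)))
    assert lo == pytest.approx(float(np.quantile(draws, 0.025)))
    assert hi == pytest.approx(float(np.quantile(draws, 0.975)))
    with pytest.raises(ValidationError):
        nma.relative_effects(res, ("A", "nope"))


def test_sucra_certain_winner():
    draws = np.tile([0.0, 1.0, 2.0], (200, 1))
    rank = nma.sucra(_result_from_draws(draws), higher_is_better=True)
    by = dict(zip(rank.treatments, rank.sucra))
    assert by["B"] == 1.0 and by["CI"] == 0.0 and by["A"] == 0.5


def test_sucra_symmetric_coin_flip():
    draws = np.array([[0.0, 1.0], [1.0, 0.0]] * 100)
    rank = nma.sucra(_result_from_draws(draws, ("X", "Y")))
    assert np.allclose(rank.sucra, 0.5)


def test_sucra_identities_on_random_draws(rng):
    draws = rng.normal(0, 1, size=(500, 5))
    rank = nma.sucra(_result_from_draws(draws, tuple("ABCDE")))
    T = 5
    # rank-probability matrix is doubly stochastic
    assert np.allclose(rank.rank_probabilities.sum(axis=1), 1.0)
    assert np.allclose(rank.rank_probabilities.sum(axis=0), 1.0)
    # SUCRA = (T - E[rank])/(T-1) equals the cumulative-probability form
    cum = rank.rank_probabilities[:, :-1].cumsum(axis=1).mean(axis=1)
    assert np.allclose(rank.sucra, cum)
    assert np.allclose(rank.sucra, (T - rank.expected_rank) / (T - 1))
    assert rank.sucra.mean() == pytest.approx(0.5)


def test_sucra_direction_flag_reverses_ranking():
    draws = np.tile([0.0, 1.0, 2.0], (50, 1))
    hi = nma.sucra(_result_from_draws(draws), higher_is_better=True)
    lo = nma.sucra(_result_from_draws(draws), higher_is_better=False)
    assert np.allclose(hi.sucra, lo.sucra[::-1])
    assert hi.sucra.argmax() == 2 and lo.sucra.argmax() == 0


def test_sucra_all_tied_draws():
    draws = np.zeros((100, 3))
    rank = nma.sucra(_result_from_draws(draws))
    assert np.allclose(rank.sucra, 0.5)
    assert np.allclose(rank.rank_probabilities, 1.0 / 3)


# ---------------------------------------------------------------------------
# Bucher consistency check
# ---------------------------------------------------------------------------


def test_combine_legs_additivity():
    est, se = combine_legs((1.0, 0.5), (0.5, 0.5))
    assert est == 1.5
    assert se == pytest.approx(0.7071, abs=5e-5)
    with pytest.raises(ValidationError):
        combine_legs((1.0, 0.0), (0.5, 0.5))


def test_bucher_on_consistent_network(small_md_network):
    net = build_network(small_md_network, "md")
    split = nma.bucher_node_split(net, ("A", "CI"))
    assert split.comparator == "B"
    assert split.direct[1] > 0 and split.indirect[1] > 0
    assert 0 <= split.p_value <= 1
    assert split.z == pytest.approx(split.difference / split.se_difference)


def test_bucher_requires_direct_evidence_and_loop():
    arms = [
        _cont("t1", "A", mean=1.0), _cont("t1", "B"),
        _cont("t2", "B", mean=0.5), _cont("t2", "C"),
    ]
    net = build_network(arms, "md")
    with pytest.raises(ValidationError, match="no direct evidence"):
        nma.bucher_node_split(net, ("A", "C"))
    with pytest.raises(ValidationError, match="indirect path"):
        nma.bucher_node_split(net, ("A", "B"))


def test_mcmc_config_validation():
    with pytest.raises(ValidationError):
        McmcConfig(n_chains=1)
    with pytest.raises(ValidationError):
        McmcConfig(n_burnin=10_000, n_iterations=10_000)
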
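"""Bayesian random-effects network meta-analysis with SUCRA ranking.

The model is the arm-based consistency formulation.  Each trial *i* has a
baseline parameter mu_i on the model scale (arm mean for continuous data, log
event risk for binary data).  A non-baseline arm with treatment k in a trial
whose baseline treatment is b has expectation

    theta = mu_i + delta,     delta ~ Normal(d_k - d_b, tau^2)

where d_k is the basic parameter of treatment k relative to the reference
(d_ref = 0) and tau is the between-trial heterogeneity SD.  Continuous arms
contribute Normal(y | theta, se^2) with se = sd/sqrt(n); binary arms
contribute Binomial(events | n, exp(theta)) — a log link, so contrasts are
log relative risks.  Priors: basic parameters and baselines Normal(0, 100^2);
tau Uniform(0, U) with U chosen from the data scale.

Sampling is adaptive random-walk Metropolis-within-Gibbs: baselines and
trial-level deviations are updated in vectorized blocks, basic parameters and
tau individually, with per-block step sizes tuned toward a 44% acceptance
rate during burn-in only (so the post-burn-in chain is a valid Markov chain).
Convergence is monitored with the classic Gelman-Rubin potential scale
reduction factor over parallel chains.  Rankings are summarised with rank
probabilities and SUCRA = (T - E[rank])/(T - 1); consistency between direct
and indirect evidence is checked with a first-order Bucher comparison over
one triangle loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ArmRecord",
    "McmcConfig",
    "Network",
    "NmaResult",
    "NodeSplitResult",
    "RankSummary",
    "bucher_node_split",
    "build_network",
    "combine_legs",
    "fit_nma",
    "pairwise_pooled",
    "psrf",
    "relative_effects",
    "sucra",
]

Measure = Literal["md", "rr"]


class ValidationError(ValueError):
    pass


class DisconnectedNetworkError(ValidationError):
    pass


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArmRecord:
    """Arm-level summary: (n, mean, sd) for continuous or (n, events) for binary."""

    trial_id: str
    treatment: str
    n: int
    mean: float | None = None
    sd: float | None = None
    events: int | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError(f"{self.trial_id}/{self.treatment}: n must be >= 1")
        if self.sd is not None and self.sd <= 0:
            raise ValidationError(f"{self.trial_id}/{self.treatment}: sd must be > 0")
        if self.events is not None and not (0 <= self.events <= self.n):
            raise ValidationError(
                f"{self.trial_id}/{self.treatment}: events must be in [0, n]"
            )

    @property
    def is_continuous(self) -> bool:
        return self.mean is not None and self.sd is not None


@dataclass(frozen=True)
class Network:
    """Treatment network of grouped trial arms with a designated reference."""

    treatments: tuple[str, ...]  # reference first
    trials: Mapping[str, tuple[ArmRecord, ...]]
    measure: Measure

    @property
    def reference(self) -> str:
        return self.treatments[0]

    def comparison_trials(self, a: str, b: str) -> list[str]:
        """Trial ids containing both treatments (direct evidence for a vs b)."""
        out = []
        for tid, arms in self.trials.items():
            present = {arm.treatment for arm in arms}
            if a in present and b in present:
                out.append(tid)
        return out


def build_network(
    arms: Sequence[ArmRecord], measure: Measure, reference: str | None = None
) -> Network:
    """Group arms by trial, pick the reference, and verify connectivity.

    The reference defaults to the treatment named "CI" (conventional
    intervention/control) when present, else the most frequently studied
    treatment.  Trials with fewer than two distinct treatments, duplicate
    (trial, treatment) pairs, arms whose summary type does not match the
    measure, and disconnected networks all raise.
    """
    if not arms:
        raise ValidationError("no arms supplied")
    trials: dict[str, list[ArmRecord]] = {}
    for arm in arms:
        if measure == "md" and not arm.is_continuous:
            raise ValidationError(
                f"{arm.trial_id}/{arm.treatment}: continuous measure needs mean and sd"
            )
        if measure == "rr" and arm.events is None:
            raise ValidationError(
                f"{arm.trial_id}/{arm.treatment}: binary measure needs event counts"
            )
        trials.setdefault(arm.trial_id, []).append(arm)

    g = nx.Graph()
    for tid, trial_arms in trials.items():
        treats = [a.treatment for a in trial_arms]
        if len(set(treats)) != len(treats):
            raise ValidationError(f"trial {tid!r}: duplicate treatment arm")
        if len(treats) < 2:
            raise ValidationError(f"trial {tid!r}: fewer than two arms")
        for i, t1 in enumerate(treats):
            for t2 in treats[i + 1 :]:
                g.add_edge(t1, t2)
    if not nx.is_connected(g):
        comps = [sorted(c) for c in nx.connected_components(g)]
        raise DisconnectedNetworkError(f"network is disconnected: components {comps}")

    all_treats = sorted(g.nodes)
    if reference is None:
        degree = {
            t: sum(1 for arms_ in trials.values() for a in arms_ if a.treatment == t)
            for t in all_treats
        }
        reference = "CI" if "CI" in degree else max(all_treats, key=lambda t: degree[t])
    elif reference not in all_treats:
        raise ValidationError(f"reference {reference!r} not in network")
    ordered = (reference, *[t for t in all_treats if t != reference])
    return Network(
        treatments=ordered,
        trials={tid: tuple(a) for tid, a in trials.items()},
        measure=measure,
    )


@dataclass(frozen=True)
class McmcConfig:
    """MCMC settings: 3 chains of 10,000 iterations with 1,000 burn-in by default."""

    n_chains: int = 3
    n_iterations: int = 10_000
    n_burnin: int = 1_000
    thin: int = 1
    seed: int = 0
    prior_d_sd: float = 100.0
    tau_upper: float | None = None  # default: 5x pooled sd (md) or 2 (rr)
    psrf_limits: tuple[float, float] = (1.00, 1.05)

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValidationError("need at least 2 chains for convergence checks")
        if not (0 <= self.n_burnin < self.n_iterations):
            raise ValidationError("burn-in must be shorter than the chain")
        if self.thin < 1:
            raise ValidationError("thin must be >= 1")


@dataclass(frozen=True)
class NmaResult:
    """Posterior draws of the basic parameters and heterogeneity SD.

    ``d_samples`` has shape (n_chains, n_kept, n_treatments) with the
    reference column identically zero; contrasts derive as d_A - d_B so the
    consistency identity holds in every draw by construction.
    """

    treatments: tuple[str, ...]
    measure: Measure
    d_samples: np.ndarray
    tau_samples: np.ndarray
    psrf: Mapping[str, float]
    converged: bool
    config: McmcConfig

    @property
    def pooled_d(self) -> np.ndarray:
        """Draws pooled across chains, shape (n_chains * n_kept, n_treatments)."""
        return self.d_samples.reshape(-1, self.d_samples.shape[-1])

    def _index(self, treatment: str) -> int:
        try:
            return self.treatments.index(treatment)
        except ValueError:
            raise ValidationError(f"unknown treatment {treatment!r}") from None

    def contrast_draws(self, a: str, b: str) -> np.ndarray:
        """Per-draw relative effect of a vs b on the model scale (MD or logRR)."""
        d = self.pooled_d
        return d[:, self._index(a)] - d[:, self._index(b)]


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------


def _flatten(network: Network):
    """Flatten the network into arrays for vectorized likelihood updates."""
    t_index = {t: i for i, t in enumerate(network.treatments)}
    trial_ids = list(network.trials)
    trial_index = {tid: i for i, tid in enumerate(trial_ids)}
    rows = []
    for tid, arms in network.trials.items():
        # baseline arm: reference if present, else first in treatment order
        present = sorted(arms, key=lambda a: t_index[a.treatment])
        base_treat = present[0].treatment
        for arm in arms:
            rows.append((trial_index[tid], t_index[arm.treatment],
                         int(arm.treatment == base_treat), arm))
    trial_idx = np.array([r[0] for r in rows])
    treat_idx = np.array([r[1] for r in rows])
    is_base = np.array([r[2] for r in rows], dtype=bool)
    arms = [r[3] for r in rows]
    base_treat_per_trial = np.zeros(len(trial_ids), dtype=int)
    for ti, tk, b, _ in rows:
        if b:
            base_treat_per_trial[ti] = tk
    return trial_idx, treat_idx, is_base, arms, base_treat_per_trial, len(trial_ids)


def fit_nma(network: Network, config: McmcConfig | None = None) -> NmaResult:
    """Fit the random-effects consistency model by MCMC.

    Returns posterior draws of the basic parameters (relative to the
    reference) and tau, with Gelman-Rubin PSRF per parameter.  A result whose
    PSRF leaves the configured limits is returned flagged ``converged=False``
    rather than rejected.  Runs with the same config and seed are
    bit-reproducible.
    """
    config = config or McmcConfig()
    (trial_idx, treat_idx, is_base, arms, base_treat, n_trials) = _flatten(network)
    n_arms = len(arms)
    K = len(network.treatments)
    continuous = network.measure == "md"

    if continuous:
        y = np.array([a.mean for a in arms], float)
        se = np.array([a.sd / math.sqrt(a.n) for a in arms], float)
        tau_upper = config.tau_upper or 5.0 * float(np.median([a.sd for a in arms]))
    else:
        r = np.array([a.events for a in arms], float)
        n_obs = np.array([a.n for a in arms], float)
        tau_upper = config.tau_upper or 2.0

    nonbase = ~is_base
    nb_idx = np.flatnonzero(nonbase)
    nb_trial = trial_idx[nb_idx]
    nb_treat = treat_idx[nb_idx]
    nb_base_treat = base_treat[nb_trial]
    prior_var = config.prior_d_sd**2

    def arm_loglik(theta: np.ndarray) -> np.ndarray:
        if continuous:
            return -0.5 * ((y - theta) / se) ** 2
        # binomial log-likelihood with log link; p >= 1 is rejected outright
        p = np.exp(theta)
        out = np.full(theta.shape, -np.inf)
        ok = p < 1.0
        if ok.any():
            pk = p[ok]
            out[ok] = r[ok] * theta[ok] + (n_obs[ok] - r[ok]) * np.log1p(-pk)
        return out

    n_kept = (config.n_iterations - config.n_burnin) // config.thin
    d_out = np.zeros((config.n_chains, n_kept, K))
    tau_out = np.zeros((config.n_chains, n_kept))

    for chain in range(config.n_chains):
        rng = np.random.default_rng(config.seed + 1000 * chain)
        # --- initial values from the observed data
        mu = np.zeros(n_trials)
        delta = np.zeros(n_arms)  # zero on baseline arms
        if continuous:
            for i in range(n_trials):
                sel = (trial_idx == i) & is_base
                mu[i] = y[sel][0]
            delta[nb_idx] = y[nb_idx] - mu[nb_trial]
        else:
            phat = (r + 0.5) / (n_obs + 1.0)
            for i in range(n_trials):
                sel = (trial_idx == i) & is_base
                mu[i] = math.log(phat[sel][0])
            delta[nb_idx] = np.log(phat[nb_idx]) - mu[nb_trial]
        d = np.zeros(K)
        tau = max(tau_upper / 10.0, 1e-3)

        step_mu = np.full(n_trials, 0.5)
        step_delta = np.full(len(nb_idx), 0.5)
        step_d = np.full(K, 0.5)
        step_joint = np.full(K, 0.5)
        step_tau = tau_upper / 10.0
        acc = {k: np.zeros_like(v) for k, v in
               (("mu", step_mu), ("delta", step_delta), ("d", step_d),
                ("joint", step_joint))}
        acc_tau = 0.0
        window = 50

        theta = mu[trial_idx] + delta
        ll_arm = arm_loglik(theta)

        kept = 0
        for it in range(config.n_iterations):
            # --- baselines (conditionally independent across trials)
            prop_mu = mu + step_mu * rng.standard_normal(n_trials)
            theta_p = prop_mu[trial_idx] + delta
            ll_p = arm_loglik(theta_p)
            dll = np.bincount(trial_idx, ll_p - ll_arm, minlength=n_trials)
            dll += (mu**2 - prop_mu**2) / (2 * prior_var)
            accept = np.log(rng.random(n_trials)) < dll
            mu = np.where(accept, prop_mu, mu)
            theta = np.where(accept[trial_idx], theta_p, theta)
            ll_arm = np.where(accept[trial_idx], ll_p, ll_arm)
            acc["mu"] += accept

            # --- trial-level deviations (one per non-baseline arm)
            prop = delta[nb_idx] + step_delta * rng.standard_normal(len(nb_idx))
            theta_p = theta.copy()
            theta_p[nb_idx] = mu[nb_trial] + prop
            ll_p = arm_loglik(theta_p)
            mean_delta = d[nb_treat] - d[nb_base_treat]
            dll = (ll_p[nb_idx] - ll_arm[nb_idx]) + (
                (delta[nb_idx] - mean_delta) ** 2 - (prop - mean_delta) ** 2
            ) / (2 * tau**2)
            accept = np.log(rng.random(len(nb_idx))) < dll
            delta[nb_idx] = np.where(accept, prop, delta[nb_idx])
            theta = mu[trial_idx] + delta
            ll_arm[nb_idx] = np.where(accept, ll_p[nb_idx], ll_arm[nb_idx])
            acc["delta"] += accept

            # --- basic parameters (reference fixed at zero)
            dev = delta[nb_idx]
            for k in range(1, K):
                involved = (nb_treat == k) | (nb_base_treat == k)
                if not involved.any():
                    continue
                prop_k = d[k] + step_d[k] * rng.standard_normal()
                d_prop = d.copy()
                d_prop[k] = prop_k
                m_old = d[nb_treat[involved]] - d[nb_base_treat[involved]]
                m_new = d_prop[nb_treat[involved]] - d_prop[nb_base_treat[involved]]
                dll_k = float(
                    np.sum((dev[involved] - m_old) ** 2 - (dev[involved] - m_new) ** 2)
                ) / (2 * tau**2) + (d[k] ** 2 - prop_k**2) / (2 * prior_var)
                if math.log(rng.random()) < dll_k:
                    d[k] = prop_k
                    acc["d"][k] += 1

            # --- joint translation of d_k with its deviations: moves along the
            # ridge that couples them when tau is small (prior residuals are
            # unchanged, so acceptance is governed by the data likelihood)
            for k in range(1, K):
                fwd = nb_idx[nb_treat == k]
                bwd = nb_idx[nb_base_treat == k]
                if fwd.size == 0 and bwd.size == 0:
                    continue
                eps = step_joint[k] * rng.standard_normal()
                theta_p = theta.copy()
                theta_p[fwd] += eps
                theta_p[bwd] -= eps
                touched = np.concatenate([fwd, bwd])
                ll_all = arm_loglik(theta_p)
                dll_j = float(np.sum(ll_all[touched] - ll_arm[touched]))
                prop_k = d[k] + eps
                dll_j += (d[k] ** 2 - prop_k**2) / (2 * prior_var)
                if math.log(rng.random()) < dll_j:
                    d[k] = prop_k
                    delta[fwd] += eps
                    delta[bwd] -= eps
                    theta = theta_p
                    ll_arm[touched] = ll_all[touched]
                    acc["joint"][k] += 1

            # --- heterogeneity SD, uniform(0, tau_upper) prior
            prop_tau = tau + step_tau * rng.standard_normal()
            if 0 < prop_tau < tau_upper:
                mean_delta = d[nb_treat] - d[nb_base_treat]
                ss = float(np.sum((dev - mean_delta) ** 2))
                m = len(nb_idx)
                dll_t = (
                    -m * math.log(prop_tau) - ss / (2 * prop_tau**2)
                    + m * math.log(tau) + ss / (2 * tau**2)
                )
                if math.log(rng.random()) < dll_t:
                    tau = prop_tau
                    acc_tau += 1

            # --- step-size adaptation, burn-in only
            if it < config.n_burnin and (it + 1) % window == 0:
                for name, steps in (("mu", step_mu), ("delta", step_delta),
                                    ("d", step_d), ("joint", step_joint)):
                    rate = acc[name] / window
                    steps *= np.exp(rate - 0.44)
                    acc[name][:] = 0
                step_tau *= math.exp(acc_tau / window - 0.44)
                acc_tau = 0.0

            if it >= config.n_burnin and (it - config.n_burnin) % config.thin == 0:
                d_out[chain, kept] = d
                tau_out[chain, kept] = tau
                kept += 1

    rhat: dict[str, float] = {}
    for k in range(1, K):
        rhat[f"d[{network.treatments[k]}]"] = psrf(d_out[:, :, k])
    rhat["tau"] = psrf(tau_out)
    lo, hi = config.psrf_limits
    finite = [v for v in rhat.values() if np.isfinite(v)]
    converged = bool(finite) and all(v <= hi for v in finite)
    return NmaResult(
        treatments=network.treatments,
        measure=network.measure,
        d_samples=d_out,
        tau_samples=tau_out,
        psrf=rhat,
        converged=converged,
        config=config,
    )


# ---------------------------------------------------------------------------
# diagnostics and summaries
# ---------------------------------------------------------------------------


def psrf(chains: np.ndarray) -> float:
    """Classic Gelman-Rubin potential scale reduction factor.

    ``chains`` has shape (n_chains, n_draws).  With W the mean within-chain
    variance and B/n the variance of the chain means, the pooled posterior
    variance estimate is (n-1)/n * W + B/n and PSRF is the square root of its
    ratio to W.  Returns ``inf`` for degenerate chains with zero within-chain
    variance but distinct means, and 1.0 when all draws are identical.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 10:
        raise ValidationError("need >= 2 chains of length >= 10")
    n = arr.shape[1]
    w = float(arr.var(axis=1, ddof=1).mean())
    b_over_n = float(arr.mean(axis=1).var(ddof=1))
    if w == 0.0:
        return 1.0 if b_over_n == 0.0 else float("inf")
    var_hat = (n - 1) / n * w + b_over_n
    return math.sqrt(var_hat / w)


def relative_effects(
    result: NmaResult,
    pair: tuple[str, str],
    point: Literal["median", "mean"] = "median",
    level: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Point estimate and central credible interval for one contrast.

    For the RR measure the log-scale contrast draws are exponentiated, so the
    estimate and interval come back on the relative-risk scale; for MD they
    are on the raw outcome scale.
    """
    a, b = pair
    draws = result.contrast_draws(a, b)
    if result.measure == "rr":
        draws = np.exp(draws)
    alpha = (1 - level) / 2
    est = float(np.median(draws) if point == "median" else np.mean(draws))
    lo, hi = np.quantile(draws, [alpha, 1 - alpha])
    return est, (float(lo), float(hi))


@dataclass(frozen=True)
class RankSummary:
    """Rank probabilities and SUCRA per treatment."""

    treatments: tuple[str, ...]
    rank_probabilities: np.ndarray  # (n_treatments, n_ranks), rows sum to 1
    sucra: np.ndarray  # in [0, 1]
    expected_rank: np.ndarray
    higher_is_better: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "treatment": self.treatments,
                "sucra": self.sucra,
                "expected_rank": self.expected_rank,
            }
        ).sort_values("sucra", ascending=False).reset_index(drop=True)


def sucra(result: NmaResult, higher_is_better: bool = True) -> RankSummary:
    """Rank probabilities and SUCRA from the posterior draws.

    Each draw ranks the treatments by effect (rank 1 = best in the stated
    direction).  SUCRA_t = (T - E[rank_t])/(T - 1), identical to the mean of
    the cumulative rank probabilities over ranks 1..T-1.  Exact ties within a
    draw share their rank positions equally.
    """
    d = result.pooled_d
    n_draws, T = d.shape
    if T < 2:
        raise ValidationError("ranking needs at least 2 treatments")
    keys = -d if higher_is_better else d

    order = np.argsort(keys, axis=1, kind="stable")
    ranks = np.empty_like(order, dtype=float)
    ranks[np.arange(n_draws)[:, None], order] = np.arange(1, T + 1)
    prob = np.zeros((T, T))
    tied_rows = np.flatnonzero((np.diff(np.sort(keys, axis=1), axis=1) == 0).any(axis=1))
    clean = np.ones(n_draws, dtype=bool)
    clean[tied_rows] = False
    if clean.any():
        flat_r = ranks[clean].astype(int)
        for t in range(T):
            prob[t] = np.bincount(flat_r[:, t] - 1, minlength=T)
    for i in tied_rows:  # ties: average ranks, split rank-slot mass equally
        row = keys[i]
        r = sps.rankdata(row, method="average")
        ranks[i] = r
        for t in range(T):
            lo = int(np.ceil(r[t] - (np.sum(row == row[t]) - 1) / 2))
            m = int(np.sum(row == row[t]))
            for slot in range(lo, lo + m):
                prob[t, slot - 1] += 1.0 / m
    prob /= n_draws
    expected_rank = ranks.mean(axis=0)
    sucra_vals = (T - expected_rank) / (T - 1)
    return RankSummary(
        treatments=result.treatments,
        rank_probabilities=prob,
        sucra=sucra_vals,
        expected_rank=expected_rank,
        higher_is_better=higher_is_better,
    )


# ---------------------------------------------------------------------------
# Bucher direct-vs-indirect consistency check
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NodeSplitResult:
    """First-order direct-vs-indirect comparison for one contrast.

    This is a Bucher-style triangle check (a declared simplification of full
    node-splitting): the indirect estimate chains the two legs through one
    common comparator, with variances summed.
    """

    pair: tuple[str, str]
    comparator: str
    direct: tuple[float, float]  # estimate, se
    indirect: tuple[float, float]
    difference: float
    se_difference: float
    z: float
    p_value: float
    method: str = "bucher_first_order_loop"


def combine_legs(
    leg1: tuple[float, float], leg2: tuple[float, float]
) -> tuple[float, float]:
    """Chain two contrast legs: estimates add, variances add.

    For d_AB and d_BC this yields the indirect d_AC = d_AB + d_BC with
    se = sqrt(se_AB^2 + se_BC^2).
    """
    (e1, s1), (e2, s2) = leg1, leg2
    if s1 <= 0 or s2 <= 0:
        raise ValidationError("leg standard errors must be positive")
    return e1 + e2, math.sqrt(s1**2 + s2**2)


def _trial_contrast(
    arms: Sequence[ArmRecord], a: str, b: str, measure: Measure
) -> tuple[float, float]:
    """Within-trial contrast of a vs b with its variance-based SE.

    Continuous: difference in means, var = se_a^2 + se_b^2.  Binary: log
    relative risk with a 0.5 continuity correction applied to all four cells
    when any event count is 0 or n (closed-form path only; the Bayesian
    likelihood never uses the correction).
    """
    by_treat = {arm.treatment: arm for arm in arms}
    x, z = by_treat[a], by_treat[b]
    if measure == "md":
        se = math.sqrt(x.sd**2 / x.n + z.sd**2 / z.n)
        return x.mean - z.mean, se
    rx, nx_, rz, nz = float(x.events), float(x.n), float(z.events), float(z.n)
    if rx in (0.0, nx_) or rz in (0.0, nz):
        rx, rz, nx_, nz = rx + 0.5, rz + 0.5, nx_ + 1.0, nz + 1.0
    est = math.log((rx / nx_) / (rz / nz))
    se = math.sqrt(1 / rx - 1 / nx_ + 1 / rz - 1 / nz)
    return est, se


def pairwise_pooled(
    network: Network,
    pair: tuple[str, str],
    exclude_trials: frozenset[str] | set[str] = frozenset(),
) -> tuple[float, float]:
    """DerSimonian-Laird random-effects pooled contrast from head-to-head trials."""
    from statsmodels.stats.meta_analysis import combine_effects

    a, b = pair
    tids = [t for t in network.comparison_trials(a, b) if t not in exclude_trials]
    if not tids:
        raise ValidationError(f"no direct evidence for {a} vs {b}")
    ests, variances = [], []
    for tid in tids:
        e, s = _trial_contrast(network.trials[tid], a, b, network.measure)
        ests.append(e)
        variances.append(s**2)
    if len(ests) == 1:
        return ests[0], math.sqrt(variances[0])
    with np.errstate(invalid="ignore"):  # statsmodels' unused HKSJ variant
        res = combine_effects(np.array(ests), np.array(variances), method_re="dl")
    frame = res.summary_frame()
    row = frame.loc["random effect"]
    return float(row["eff"]), float(row["sd_eff"])


def bucher_node_split(
    network: Network, pair: tuple[str, str], comparator: str | None = None
) -> NodeSplitResult:
    """Compare direct and indirect evidence for one contrast through a loop.

    The direct estimate pools the head-to-head trials; the indirect estimate
    chains a-vs-c and c-vs-b legs built from trials *excluding* the direct
    ones, so the two sources are independent.  The difference is tested with
    a two-sided normal z-test.  Raises when no direct evidence or no complete
    independent loop exists.
    """
    a, b = pair
    direct_trials = set(network.comparison_trials(a, b))
    if not direct_trials:
        raise ValidationError(f"no direct evidence for {a} vs {b}")
    direct = pairwise_pooled(network, pair)

    candidates = [comparator] if comparator else [
        t for t in network.treatments if t not in pair
    ]
    indirect = None
    used = None
    for c in candidates:
        leg_ac = [t for t in network.comparison_trials(a, c) if t not in direct_trials]
        leg_cb = [t for t in network.comparison_trials(c, b) if t not in direct_trials]
        if leg_ac and leg_cb:
            est_ac = pairwise_pooled(network, (a, c), exclude_trials=direct_trials)
            est_cb = pairwise_pooled(network, (c, b), exclude_trials=direct_trials)
            indirect = combine_legs(est_ac, est_cb)
            used = c
            break
    if indirect is None:
        raise ValidationError(
            f"no independent first-order indirect path for {a} vs {b}"
        )
    diff = direct[0] - indirect[0]
    se_diff = math.sqrt(direct[1] ** 2 + indirect[1] ** 2)
    z = diff / se_diff
    p = 2 * (1 - sps.norm.cdf(abs(z)))
    return NodeSplitResult(
        pair=pair,
        comparator=used,
        direct=direct,
        indirect=indirect,
        difference=diff,
        se_difference=se_diff,
        z=z,
        p_value=float(p),
    )
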
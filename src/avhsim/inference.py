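"""Variational belief updating over hidden states and policies.

The posterior over hidden variables is factorized mean-field style,
``Q(s, pi) = Q(pi) prod_tau Q(s_tau | pi)``, and each policy-conditioned
state posterior is optimized by exact coordinate ascent: every factor-by-
timestep update combines the expected log-likelihood of observed outcomes
(marginalizing the other factors), a forward message ``E_q[ln B] . q(tau-1)``
(the initial prior D at tau = 1) and the matching backward message from
``q(tau+1)``.  Coordinate ascent on the mean-field free energy makes the
variational free energy non-increasing across sweeps, and the backward
messages implement Bayesian smoothing (postdiction): later observations
revise beliefs about earlier states.

Policies are scored by ``Q(pi) = softmax(-F(pi) - gamma * G(pi))``: the
expected free energy G supplies the prior over policies and the accumulated
evidence F updates it.  Beliefs irrespective of policy are recovered by
Bayesian model averaging, ``Q(s_tau) = sum_pi Q(s_tau|pi) Q(pi)``.

Structural priors (transition and initial-state columns) are floored in
probability space at ``exp(-13)`` before their logs are taken, so a
contradicted deterministic prior costs 13 nats; likelihood logs carry only
a numerical guard, because the auditory likelihood's effective floor,
``exp(-10 zeta)``, is set by the precision weighting and must be free to
rise above or fall below the prior floor as zeta varies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import softmax, xlogy

from .environment import Observation
from .model import CONTENT, GenerativeModel, LISTEN, SPEAK

__all__ = [
    "LOG_FLOOR",
    "NumericalError",
    "FactorizedPOMDP",
    "InferenceResult",
    "BeliefState",
    "as_pomdp",
    "infer_states",
    "expected_free_energy",
    "policy_posterior",
    "bayesian_model_average",
    "select_action",
]

#: Probability-space floor for structural priors (transitions and initial
#: states): a contradicted deterministic (one-hot) prior column costs 13
#: nats.  The value is set by the two regimes the precision parameter must
#: separate: a policy-driven prior can only override silence at reduced
#: precision if the floor exceeds the 10-nat likelihood penalty at
#: zeta = 1, and precise evidence can only repair an anomalous narrative
#: (one transition floor plus one listening-state floor) if twice the
#: floor stays below the 30-nat penalty at zeta = 3.  That bounds the
#: floor to (10, 15) nats; 13 sits at the margin-maximizing point.
LOG_FLOOR: float = float(np.exp(-13.0))

#: Numerical guard for likelihood logs.  The auditory likelihood carries its
#: own uncertainty floor, exp(-10 * zeta), from the precision weighting, so
#: its log-penalties must be allowed to scale with zeta rather than being
#: clipped at the structural-prior floor: sensory evidence can then override
#: a deterministic prior at high precision (30 > 13 nats at zeta = 3) but
#: not at low precision (10 < 13 nats at zeta = 1), which is the central
#: precision dissociation.
LIKELIHOOD_GUARD: float = float(np.exp(-32.0))

_LETTERS = "abcdefgh"


class NumericalError(RuntimeError):
    """A belief became non-normalizable during updating."""


def _log(x: np.ndarray | float) -> np.ndarray:
    return np.log(np.asarray(x, dtype=float) + LOG_FLOOR)


def _log_lik(x: np.ndarray | float) -> np.ndarray:
    return np.log(np.asarray(x, dtype=float) + LIKELIHOOD_GUARD)


@dataclass
class FactorizedPOMDP:
    """Engine-level description of a discrete generative model.

    ``A[m]`` has shape ``(n_outcomes_m, *sizes_of_dep_factors)`` with
    ``A_deps[m]`` naming the hidden factors it depends on; ``B[f]`` has shape
    ``(n_f, n_f, n_actions_f)``; ``C[m]`` and ``D[f]`` are outcome preferences
    and initial priors.
    """

    A: list[np.ndarray]
    A_deps: list[tuple[int, ...]]
    B: list[np.ndarray]
    C: list[np.ndarray]
    D: list[np.ndarray]
    horizon: int

    @property
    def n_factors(self) -> int:
        return len(self.B)

    @property
    def factor_sizes(self) -> list[int]:
        return [b.shape[0] for b in self.B]


def as_pomdp(model: GenerativeModel) -> FactorizedPOMDP:
    """View the song model through the generic engine interface."""
    return FactorizedPOMDP(
        A=[model.A_aud, model.A_prop],
        A_deps=[(0, 1, 2), (2,)],
        B=[model.B_content[:, :, None], model.B_listen, model.B_speak],
        C=[model.C["auditory"], model.C["proprioceptive"]],
        D=list(model.D),
        horizon=model.horizon,
    )


def _factor_actions(pomdp: FactorizedPOMDP, policy: np.ndarray) -> np.ndarray:
    """Expand a high-level listen/speak sequence to per-factor action indices.

    The content factor is uncontrolled (single action); the listening and
    speaking factors are yoked to the policy's action code.  Per-factor
    action matrices pass through unchanged.
    """
    policy = np.asarray(policy, dtype=int)
    if policy.ndim == 2:
        return policy
    n = policy.shape[0]
    out = np.zeros((n, pomdp.n_factors), dtype=int)
    if pomdp.n_factors == 3:
        out[:, 1] = policy
        out[:, 2] = policy
    elif pomdp.n_factors == 1:
        out[:, 0] = policy
    else:
        raise ValueError("provide a (transitions, n_factors) action matrix")
    return out


def _resolve(model, policy):
    pomdp = as_pomdp(model) if isinstance(model, GenerativeModel) else model
    actions = _factor_actions(pomdp, np.asarray(policy, dtype=int))
    if actions.shape[0] != pomdp.horizon - 1:
        raise ValueError("policy length must be horizon - 1")
    return pomdp, actions


def _observation_indices(observations, n_modalities: int) -> list[tuple[int, ...]]:
    out = []
    for obs in observations:
        if isinstance(obs, Observation):
            out.append((obs.auditory_index, obs.proprioceptive_index))
        else:
            idx = tuple(int(i) for i in obs)
            if len(idx) != n_modalities:
                raise ValueError("one outcome index per modality is required")
            out.append(idx)
    return out


def _expected_log_likelihood(lnAo: np.ndarray, deps: tuple[int, ...], qs, tau: int, factor: int) -> np.ndarray:
    """E over the other dependent factors of ln A[o | s], as a function of
    ``factor``'s state."""
    sub = _LETTERS[: len(deps)]
    operands, scripts = [lnAo], [sub]
    out = ""
    for letter, d in zip(sub, deps):
        if d == factor:
            out = letter
        else:
            operands.append(qs[d][tau])
            scripts.append(letter)
    return np.einsum(",".join(scripts) + "->" + out, *operands)


def _full_expectation(lnAo: np.ndarray, deps: tuple[int, ...], qs, tau: int) -> float:
    sub = _LETTERS[: len(deps)]
    operands = [lnAo] + [qs[d][tau] for d in deps]
    return float(np.einsum(",".join([sub] + list(sub)) + "->", *operands))


@dataclass
class InferenceResult:
    """Policy-conditioned posteriors and their free energy."""

    qs: list[np.ndarray]  # per factor, (horizon, n_states)
    F: float  # variational free energy (nats) at convergence
    F_trace: list[float]  # free energy after each sweep
    n_sweeps: int


def infer_states(
    model,
    observations,
    policy,
    *,
    max_sweeps: int = 16,
    tol: float = 1e-4,
) -> InferenceResult:
    """Infer policy-conditioned state posteriors for observed timesteps 1..t.

    ``observations`` may be :class:`~avhsim.environment.Observation` records
    or per-modality outcome-index tuples; timesteps beyond the observations
    receive prior-predictive beliefs under the policy.  Iteration stops when
    the free energy changes by less than ``tol`` nats or after
    ``max_sweeps`` full sweeps.
    """
    pomdp, actions = _resolve(model, policy)
    T = pomdp.horizon
    obs = _observation_indices(observations, len(pomdp.A))
    t_obs = len(obs)
    if t_obs > T:
        raise ValueError("more observations than timesteps in the horizon")

    lnA = [_log_lik(a) for a in pomdp.A]
    lnD = [_log(d) for d in pomdp.D]
    # lnB[f][t] is the floored log-transition into timestep t+2 (0-based t).
    lnB = [
        [_log(pomdp.B[f][:, :, actions[t, f]]) for t in range(T - 1)]
        for f in range(pomdp.n_factors)
    ]

    def free_energy(qs) -> float:
        F = 0.0
        for f in range(pomdp.n_factors):
            F += float(xlogy(qs[f], qs[f]).sum())
            F -= float(qs[f][0] @ lnD[f])
            for t in range(1, T):
                F -= float(qs[f][t] @ lnB[f][t - 1] @ qs[f][t - 1])
        for t in range(t_obs):
            for m, deps in enumerate(pomdp.A_deps):
                F -= _full_expectation(lnA[m][obs[t][m]], deps, qs, t)
        return F

    def run_schedule(timestep_order) -> InferenceResult:
        # Flat initialization: the first sweep is then driven by evidence
        # and messages symmetrically, so jointly supported state
        # combinations (e.g. listening-while-speaking plus a content
        # reroute) can emerge.  Unobserved timesteps still converge to the
        # prior-predictive chain.
        qs = [np.full((T, n), 1.0 / n) for n in pomdp.factor_sizes]
        trace: list[float] = []
        for sweep in range(max_sweeps):
            for t in timestep_order:
                for f in range(pomdp.n_factors):
                    logq = np.zeros(pomdp.factor_sizes[f])
                    if t < t_obs:
                        for m, deps in enumerate(pomdp.A_deps):
                            if f in deps:
                                logq += _expected_log_likelihood(
                                    lnA[m][obs[t][m]], deps, qs, t, f
                                )
                    if t == 0:
                        logq += lnD[f]
                    else:
                        logq += lnB[f][t - 1] @ qs[f][t - 1]
                    if t < T - 1:
                        logq += lnB[f][t].T @ qs[f][t + 1]
                    q = softmax(logq)
                    if not np.all(np.isfinite(q)):
                        raise NumericalError(
                            f"non-normalizable belief at timestep {t + 1}, factor {f}: logq={logq}"
                        )
                    qs[f][t] = q
            trace.append(free_energy(qs))
            if sweep > 0 and abs(trace[-2] - trace[-1]) < tol:
                break
        return InferenceResult(qs=qs, F=trace[-1], F_trace=trace, n_sweeps=len(trace))

    # Mean-field coordinate ascent is order-dependent when deterministic
    # narrative priors and precise evidence disagree: earliest-first sweeps
    # let the forward prior chain commit before late evidence arrives,
    # latest-first sweeps let postdictive evidence shape early beliefs
    # first.  Run both schedules and keep the lower-free-energy solution
    # (multi-start selection; each schedule is still monotone in F).
    forward_first = run_schedule(range(T))
    backward_first = run_schedule(list(reversed(range(T))))
    return forward_first if forward_first.F <= backward_first.F else backward_first


def expected_free_energy(model, qs: list[np.ndarray], policy, from_timestep: int) -> float:
    """Expected free energy (nats) of a policy over timesteps after
    ``from_timestep`` (1-based), given its policy-conditioned beliefs.

    Sums, per remaining timestep and modality, the ambiguity (expected
    entropy of the likelihood under predicted states) and the risk
    (divergence of predicted outcomes from the preferences C).  With flat C
    the risk reduces to the negative entropy of predicted outcomes up to a
    constant, so policies are ranked purely by expected information gain.
    """
    pomdp, _ = _resolve(model, policy)
    G = 0.0
    for t in range(from_timestep, pomdp.horizon):
        for m, deps in enumerate(pomdp.A_deps):
            sub = _LETTERS[: len(deps)]
            qvecs = [qs[d][t] for d in deps]
            qo = np.einsum("o" + sub + "," + ",".join(sub) + "->o", pomdp.A[m], *qvecs)
            # ambiguity: expected entropy of the likelihood columns
            H_cols = -xlogy(pomdp.A[m], pomdp.A[m]).sum(axis=0)
            G += float(np.einsum(sub + "," + ",".join(sub) + "->", H_cols, *qvecs))
            # risk: KL from preferred outcomes
            G += float(qo @ (_log(qo) - _log(pomdp.C[m])))
    return G


def policy_posterior(F, G, gamma: float) -> np.ndarray:
    """``Q(pi) = softmax(-F - gamma G)``: the expected-free-energy prior
    updated by each policy's accumulated evidence."""
    F = np.asarray(F, dtype=float)
    G = np.asarray(G, dtype=float)
    if F.shape != G.shape:
        raise ValueError("F and G must have one entry per policy")
    return softmax(-F - gamma * G)


def bayesian_model_average(qs_per_policy, q_policy) -> list[np.ndarray]:
    """Policy-weighted mixture of state beliefs, per factor and timestep."""
    q_policy = np.asarray(q_policy, dtype=float)
    n_factors = len(qs_per_policy[0])
    out = []
    for f in range(n_factors):
        mix = sum(w * qs[f] for w, qs in zip(q_policy, qs_per_policy))
        out.append(mix / mix.sum(axis=-1, keepdims=True))
    return out


def select_action(
    q_policy,
    policies,
    transition_index: int,
    mode: str = "argmax",
    rng: np.random.Generator | None = None,
) -> int:
    """Choose listen or speak at one transition from the policy posterior.

    The marginal probability of each action sums the policy posterior over
    policies prescribing it.  ``argmax`` breaks exact ties toward listening;
    ``sample`` draws from the marginal with the supplied generator.
    """
    q_policy = np.asarray(q_policy, dtype=float)
    policies = np.asarray(policies, dtype=int)
    prescribed = policies[:, transition_index]
    p_speak = float(q_policy[prescribed == SPEAK].sum())
    p_listen = float(q_policy[prescribed == LISTEN].sum())
    total = p_listen + p_speak
    if mode == "argmax":
        return SPEAK if p_speak > p_listen else LISTEN
    if mode == "sample":
        if rng is None:
            raise ValueError("sample mode requires a seeded generator")
        return int(rng.choice([LISTEN, SPEAK], p=[p_listen / total, p_speak / total]))
    raise ValueError(f"unknown action-selection mode {mode!r}")


@dataclass
class BeliefState:
    """Full belief snapshot after assimilating observations up to a timestep.

    ``q_states[k][f]`` is policy k's posterior over factor f across all
    timesteps; ``q_policy`` is Q(pi); ``q_marginal`` the Bayesian model
    average; ``F_per_policy`` and ``G_per_policy`` are in nats.
    """

    q_states: list[list[np.ndarray]]
    q_policy: np.ndarray
    q_marginal: list[np.ndarray]
    F_per_policy: np.ndarray
    G_per_policy: np.ndarray
    n_sweeps: list[int] = field(default_factory=list)

    def recomputed_marginal(self) -> list[np.ndarray]:
        return bayesian_model_average(self.q_states, self.q_policy)
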
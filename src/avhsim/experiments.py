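"""Closed-loop trials, percept classification and the four-experiment suite.

A trial couples the agent (generative model + inference engine) to the
singing partner (generative process).  At every timestep the agent receives
an observation, re-infers its policy-conditioned state posteriors over the
whole trajectory (Bayesian smoothing), updates the policy posterior and its
Bayesian model average, and -- until the horizon -- selects the next action
from the policy posterior.

Percepts are read off the final belief-averaged trajectory: the agent
"hears" at a timestep when its averaged probability of being in the
listening state exceeds a threshold (0.5 by default), and the perceived word
is the most probable content state.  A hallucination is hearing when the
environment was silent; a misperception is failing to hear when sound was
present; a hallucination is in-context when the hallucinated word is the
veridical song word for that timestep.

The preset experiments cross likelihood precision (zeta = 3 normal, zeta = 1
reduced) with the content narrative (veridical / anomalous):

1. normal precision, veridical narrative  -- ordinary duet, no hallucinations
2. reduced precision, veridical narrative -- in-context hallucinations
3. normal precision, anomalous narrative  -- "prodromal": aberrant priors
   corrected by precise evidence, no hallucinations
4. reduced precision, anomalous narrative -- out-of-context hallucinations
   ("It's after It's all!")
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .environment import (
    Observation,
    SequenceError,
    env_step,
    initial_state,
    partner_sings,
    song_word,
)
from .inference import (
    BeliefState,
    NumericalError,
    bayesian_model_average,
    expected_free_energy,
    infer_states,
    policy_posterior,
    select_action,
)
from .model import (
    ACTION_LABELS,
    GenerativeModel,
    LISTEN,
    LISTENING_YES,
    SILENCE,
    SPEAK,
    WORDS,
    build_song_model,
)

__all__ = [
    "TrialConfig",
    "TrialRecord",
    "PerceptLabels",
    "EXPERIMENT_PRESETS",
    "run_trial",
    "classify_percepts",
    "locate_misperceptions",
    "run_experiment_suite",
    "trial_to_json",
    "trial_to_frame",
    "load_config",
]

logger = logging.getLogger("avhsim")

#: Likelihood precision presets: the paper's normal and reduced values.
ZETA_NORMAL: float = 3.0
ZETA_REDUCED: float = 1.0

EXPERIMENT_PRESETS: dict[int, dict] = {
    1: {"zeta": ZETA_NORMAL, "transition_mode": "veridical", "label": "normal"},
    2: {"zeta": ZETA_REDUCED, "transition_mode": "veridical", "label": "in-context hallucinations"},
    3: {"zeta": ZETA_NORMAL, "transition_mode": "anomalous", "label": "prodromal"},
    4: {"zeta": ZETA_REDUCED, "transition_mode": "anomalous", "label": "out-of-context hallucinations"},
}


@dataclass(frozen=True)
class TrialConfig:
    """Resolved configuration of one closed-loop trial."""

    zeta: float = ZETA_NORMAL
    transition_mode: str = "veridical"
    gamma: float = 16.0
    horizon: int = 6
    seed: int = 0
    action_mode: str = "argmax"  # argmax | sample
    threshold: float = 0.5
    label: str = ""

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


def load_config(path: str | Path) -> TrialConfig:
    """Read a trial configuration from a JSON or YAML file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    known = {k: v for k, v in data.items() if k in TrialConfig.__dataclass_fields__}
    return TrialConfig(**known)


@dataclass
class TrialRecord:
    """Complete trajectory of one closed-loop trial."""

    config: TrialConfig
    observations: list[Observation]
    actions: list[int]  # executed action per transition (into timesteps 2..horizon)
    beliefs: list[BeliefState]  # snapshot after each timestep's update
    model: GenerativeModel

    @property
    def final_beliefs(self) -> BeliefState:
        return self.beliefs[-1]

    @property
    def action_labels(self) -> list[str]:
        return [ACTION_LABELS[a] for a in self.actions]

    def executed_action_at(self, timestep: int) -> int:
        """Action in force at a 1-based timestep (listening at the cue)."""
        return LISTEN if timestep == 1 else self.actions[timestep - 2]


def run_trial(config: TrialConfig, forced_actions: list[int] | None = None) -> TrialRecord:
    """Run the closed loop for ``config.horizon`` timesteps.

    At the first timestep the agent listens for its cue while the partner
    sings "It's"; afterwards each transition's action comes from the policy
    posterior (or from ``forced_actions``, used to probe counterfactual
    action sequences).
    """
    model = build_song_model(
        zeta=config.zeta,
        transition_mode=config.transition_mode,
        gamma=config.gamma,
        horizon=config.horizon,
    )
    rng = np.random.default_rng(config.seed)
    state = initial_state(config.horizon)
    observations: list[Observation] = []
    actions: list[int] = []
    snapshots: list[BeliefState] = []

    action = LISTEN  # the cue
    for tau in range(1, config.horizon + 1):
        if tau > 1:
            actions.append(action)
        obs, state = env_step(state, action)
        observations.append(obs)

        qs_per_policy, F, G, sweeps = [], [], [], []
        for k in range(model.policies.shape[0]):
            try:
                res = infer_states(model, observations, model.policies[k])
            except NumericalError as err:
                raise NumericalError(f"timestep {tau}, policy {k}: {err}") from err
            qs_per_policy.append(res.qs)
            F.append(res.F)
            sweeps.append(res.n_sweeps)
            G.append(expected_free_energy(model, res.qs, model.policies[k], tau))
        q_pi = policy_posterior(F, G, model.gamma)
        snapshots.append(
            BeliefState(
                q_states=qs_per_policy,
                q_policy=q_pi,
                q_marginal=bayesian_model_average(qs_per_policy, q_pi),
                F_per_policy=np.asarray(F),
                G_per_policy=np.asarray(G),
                n_sweeps=sweeps,
            )
        )
        logger.debug(
            "tau=%d F=%s G=%s Qpi=%s sweeps=%s",
            tau, np.round(F, 3), np.round(G, 3), np.round(q_pi, 4), sweeps,
        )

        if tau < config.horizon:
            if forced_actions is not None:
                action = forced_actions[tau - 1]
            else:
                action = select_action(
                    q_pi, model.policies, tau - 1, mode=config.action_mode, rng=rng
                )

    return TrialRecord(
        config=config,
        observations=observations,
        actions=actions,
        beliefs=snapshots,
        model=model,
    )


@dataclass
class PerceptLabels:
    """Per-timestep percepts with hallucination/misperception flags."""

    percepts: list[str]  # word label or silence, per timestep
    confidence: list[float]  # max belief-averaged content probability when hearing
    hears: list[bool]
    hallucination: list[bool]
    misperception: list[bool]
    in_context: list[bool | None]  # defined only where hallucination is True

    @property
    def hallucination_timesteps(self) -> list[int]:
        return [t + 1 for t, h in enumerate(self.hallucination) if h]

    @property
    def misperception_timesteps(self) -> list[int]:
        return [t + 1 for t, m in enumerate(self.misperception) if m]

    @property
    def heard_string(self) -> str:
        """Words perceived as heard, concatenated in timestep order."""
        return " ".join(p for p, h in zip(self.percepts, self.hears) if h)


def classify_percepts(trial: TrialRecord, threshold: float | None = None) -> PerceptLabels:
    """Binarize the final belief-averaged trajectory into percept labels.

    ``hears(tau)`` iff the averaged listening probability exceeds the
    threshold; the percept is then the most probable content word.  Flags
    follow the operational definitions: hallucination = hearing into
    silence, misperception = sound present but not heard, in-context =
    hallucinated word matches the veridical song word at that timestep.
    """
    if threshold is None:
        threshold = trial.config.threshold
    marg = trial.final_beliefs.q_marginal
    percepts, conf, hears, halluc, misperc, in_ctx = [], [], [], [], [], []
    for t, obs in enumerate(trial.observations):
        p_listen = float(marg[1][t, LISTENING_YES])
        hearing = p_listen > threshold
        word_idx = int(np.argmax(marg[0][t]))
        percept = WORDS[word_idx] if hearing else SILENCE
        h = hearing and not obs.sound_present
        m = (not hearing) and obs.sound_present
        percepts.append(percept)
        conf.append(float(marg[0][t, word_idx]) if hearing else float("nan"))
        hears.append(hearing)
        halluc.append(h)
        misperc.append(m)
        in_ctx.append((percept == song_word(t + 1)) if h else None)
    return PerceptLabels(percepts, conf, hears, halluc, misperc, in_ctx)


def locate_misperceptions(trial: TrialRecord, labels: PerceptLabels | None = None) -> dict[str, int | None]:
    """Attribute misperceived timesteps to self-generated vs partner speech.

    ``own_voice``: the latest misperceived timestep at which the agent was
    speaking (failing to hear its own word); ``partner_voice``: the earliest
    misperceived timestep at which the partner was singing.  Timesteps where
    agent and partner co-sing can satisfy both.
    """
    if labels is None:
        labels = classify_percepts(trial)
    own = [
        t for t in labels.misperception_timesteps
        if trial.executed_action_at(t) == SPEAK and trial.observations[t - 1].sound_present
    ]
    partner = [
        t for t in labels.misperception_timesteps
        if partner_sings(t) and trial.observations[t - 1].sound_present
    ]
    return {
        "own_voice": max(own) if own else None,
        "partner_voice": min(partner) if partner else None,
    }


def run_experiment_suite(
    seed: int = 0,
    zeta_normal: float = ZETA_NORMAL,
    zeta_reduced: float = ZETA_REDUCED,
    action_mode: str = "argmax",
    threshold: float = 0.5,
) -> tuple[dict[int, TrialRecord], dict[int, PerceptLabels], pd.DataFrame]:
    """Run Experiments 1-4 and summarize them in a tidy table."""
    trials: dict[int, TrialRecord] = {}
    labels: dict[int, PerceptLabels] = {}
    rows = []
    for exp, preset in EXPERIMENT_PRESETS.items():
        zeta = zeta_normal if preset["zeta"] == ZETA_NORMAL else zeta_reduced
        cfg = TrialConfig(
            zeta=zeta,
            transition_mode=preset["transition_mode"],
            seed=seed,
            action_mode=action_mode,
            threshold=threshold,
            label=preset["label"],
        )
        trial = run_trial(cfg)
        lab = classify_percepts(trial)
        trials[exp], labels[exp] = trial, lab
        halluc = lab.hallucination_timesteps
        rows.append(
            {
                "experiment": exp,
                "label": preset["label"],
                "zeta": zeta,
                "transition_mode": preset["transition_mode"],
                "actions": " ".join(trial.action_labels),
                "hallucination_timesteps": halluc,
                "misperception_timesteps": lab.misperception_timesteps,
                "in_context": [lab.in_context[t - 1] for t in halluc],
                "heard_string": lab.heard_string,
            }
        )
    return trials, labels, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# serialization

def trial_to_json(trial: TrialRecord, labels: PerceptLabels | None = None) -> str:
    """Serialize a trial (and optional percept labels) to JSON."""
    if labels is None:
        labels = classify_percepts(trial)
    final = trial.final_beliefs
    payload = {
        "config": asdict(trial.config),
        "observations": [
            {"timestep": o.timestep, "auditory": o.auditory, "proprioceptive": o.proprioceptive}
            for o in trial.observations
        ],
        "actions": trial.action_labels,
        "q_policy": final.q_policy.tolist(),
        "F_per_policy": final.F_per_policy.tolist(),
        "G_per_policy": final.G_per_policy.tolist(),
        "q_marginal": {
            "content": final.q_marginal[0].tolist(),
            "listening": final.q_marginal[1].tolist(),
            "speaking": final.q_marginal[2].tolist(),
        },
        "percepts": labels.percepts,
        "hears": labels.hears,
        "hallucination": labels.hallucination,
        "misperception": labels.misperception,
        "in_context": labels.in_context,
        "heard_string": labels.heard_string,
    }
    return json.dumps(payload, indent=2)


def trial_to_frame(trial: TrialRecord) -> pd.DataFrame:
    """Tidy frame: one row per timestep x factor x state with the final
    belief-averaged probability."""
    marg = trial.final_beliefs.q_marginal
    names = [("content", WORDS), ("listening", ("yes", "no")), ("speaking", ("yes", "no"))]
    rows = []
    for f, (fname, states) in enumerate(names):
        for t in range(trial.config.horizon):
            for i, sname in enumerate(states):
                rows.append(
                    {
                        "timestep": t + 1,
                        "factor": fname,
                        "state": sname,
                        "probability": float(marg[f][t, i]),
                    }
                )
    return pd.DataFrame(rows)
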
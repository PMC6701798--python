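"""The generative process: a partner who sings the veridical song.

The environment is a second agent that always follows the true song order
and sounds every second word, beginning with "It's" at the first timestep
(odd timesteps 1, 3, 5, ...).  Whenever the subject chooses to speak, a
sound is produced; the word is always the veridical song word for that
timestep, because the narrative content belongs to the environment, not to
the agent's choices.  If the agent sings at a timestep where the partner is
also singing, they share the single word (a duet), not a collision.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import ACTION_LABELS, LISTEN, SPEAK, SILENCE, WORDS

__all__ = [
    "Observation",
    "EnvironmentState",
    "SequenceError",
    "song_word",
    "partner_sings",
    "initial_state",
    "env_step",
]


class SequenceError(RuntimeError):
    """Raised when the environment is stepped past its horizon."""


@dataclass(frozen=True)
class Observation:
    """One timestep's outcome pair, as labels plus outcome indices."""

    auditory: str
    proprioceptive: str
    timestep: int  # 1-based

    @property
    def auditory_index(self) -> int:
        return WORDS.index(self.auditory) if self.auditory != SILENCE else len(WORDS)

    @property
    def proprioceptive_index(self) -> int:
        return 0 if self.proprioceptive == "speaking" else 1

    @property
    def sound_present(self) -> bool:
        return self.auditory != SILENCE


@dataclass(frozen=True)
class EnvironmentState:
    """True state of the duet: position in the veridical song and time."""

    timestep: int  # 1-based index of the timestep about to be emitted
    word_index: int  # position in the veridical song at this timestep
    horizon: int

    @property
    def partner_sings(self) -> bool:
        return self.timestep % 2 == 1


def song_word(timestep: int) -> str:
    """Veridical song word at a 1-based timestep (the song repeats)."""
    return WORDS[(timestep - 1) % len(WORDS)]


def partner_sings(timestep: int) -> bool:
    """The partner sounds exactly at odd timesteps."""
    return timestep % 2 == 1


def initial_state(horizon: int = 6) -> EnvironmentState:
    return EnvironmentState(timestep=1, word_index=0, horizon=horizon)


def env_step(state: EnvironmentState, agent_action: int) -> tuple[Observation, EnvironmentState]:
    """Emit the observation for the current timestep and advance the song.

    The auditory outcome is the veridical word whenever the partner sings or
    the agent speaks, and silence otherwise; proprioception reflects the
    agent's executed action.
    """
    if agent_action not in (LISTEN, SPEAK):
        raise ValueError(f"invalid action {agent_action!r}; expected one of {ACTION_LABELS}")
    if state.timestep > state.horizon:
        raise SequenceError(
            f"environment stepped past its horizon ({state.timestep} > {state.horizon})"
        )
    sounding = state.partner_sings or agent_action == SPEAK
    obs = Observation(
        auditory=WORDS[state.word_index] if sounding else SILENCE,
        proprioceptive="speaking" if agent_action == SPEAK else "not-speaking",
        timestep=state.timestep,
    )
    nxt = EnvironmentState(
        timestep=state.timestep + 1,
        word_index=(state.word_index + 1) % len(WORDS),
        horizon=state.horizon,
    )
    return obs, nxt
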
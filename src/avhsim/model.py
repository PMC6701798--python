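"""Generative model for the dyadic singing task.

The agent's internal model is a partially observed Markov decision process
with three hidden-state factors -- lexical content (the six words of the
song), whether the agent is listening, and whether it is speaking -- and two
outcome modalities, audition (the six words plus silence) and proprioception
(speaking / not speaking).

Content evolves autonomously under a deterministic transition matrix
(the "narrative"): either the veridical song order or an anomalous order in
which "after" follows "It's".  Listening and speaking are controlled by the
agent's actions; the three allowable policies are always-listen,
always-speak, and alternate (listening first).

The auditory likelihood is passed through a precision (inverse temperature)
parameter zeta: ``A_bar = softmax(zeta * log(A + exp(-10)))`` applied
column-wise.  High zeta gives a near-deterministic mapping from states to
sounds; zeta = 0 makes every outcome equally likely regardless of the state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np
from scipy.special import softmax

__all__ = [
    "WORDS",
    "SILENCE",
    "AUDITORY_OUTCOMES",
    "PROPRIOCEPTIVE_OUTCOMES",
    "LISTEN",
    "SPEAK",
    "ACTION_LABELS",
    "SongLexicon",
    "GenerativeModel",
    "precision_weight",
    "build_content_transitions",
    "build_policies",
    "build_song_model",
]

#: The six words of the song, in veridical order.
WORDS: tuple[str, ...] = ("It's", "a", "small", "world", "after", "all!")

#: Distinguished seventh auditory outcome (never a content state).
SILENCE: str = "silence"

AUDITORY_OUTCOMES: tuple[str, ...] = WORDS + (SILENCE,)
PROPRIOCEPTIVE_OUTCOMES: tuple[str, ...] = ("speaking", "not-speaking")

# Action codes shared by the listening and speaking factors.
LISTEN: int = 0
SPEAK: int = 1
ACTION_LABELS: tuple[str, str] = ("listen", "speak")

# Hidden-state index conventions (index 0 = "yes" on both binary factors).
CONTENT, LISTENING, SPEAKING = 0, 1, 2
LISTENING_YES, LISTENING_NO = 0, 1
SPEAKING_YES, SPEAKING_NO = 0, 1

#: Default floor added inside the precision-weighting log.
DEFAULT_FLOOR: float = float(np.exp(-10.0))


@dataclass(frozen=True)
class SongLexicon:
    """The ordered lexicon of the song plus the silence label."""

    words: tuple[str, ...] = WORDS
    silence_label: str = SILENCE

    def __post_init__(self) -> None:
        if len(self.words) != 6:
            raise ValueError("the song lexicon has exactly six words")
        if self.silence_label in self.words:
            raise ValueError("silence is an outcome label, never a content word")

    def index(self, word: str) -> int:
        return self.words.index(word)


def precision_weight(column: np.ndarray, zeta: float, floor: float = DEFAULT_FLOOR) -> np.ndarray:
    """Apply likelihood precision to one outcome distribution.

    Returns ``softmax(zeta * log(column + floor))``.  At ``zeta = 0`` the
    result is uniform; as ``zeta`` grows the result approaches the one-hot
    column.  Applied column-wise to the auditory likelihood only.
    """
    column = np.asarray(column, dtype=float)
    if np.any(column < 0):
        raise ValueError("outcome distribution has negative entries")
    if zeta < 0:
        raise ValueError("precision zeta must be non-negative")
    return softmax(zeta * np.log(column + floor))


def build_content_transitions(mode: str) -> np.ndarray:
    """6x6 one-hot content transition matrix ``B[i, j] = P(next=i | prev=j)``.

    ``veridical``: each word maps to its successor in the song, cyclically.
    ``anomalous``: "after" follows "It's" (so the private narrative cycles
    It's -> after -> all! -> It's); the remaining words keep their veridical
    successors, in particular "a" still precedes "small".
    """
    successor = {i: (i + 1) % 6 for i in range(6)}
    if mode == "anomalous":
        successor[WORDS.index("It's")] = WORDS.index("after")
    elif mode != "veridical":
        raise ValueError(f"unknown transition mode {mode!r}; use 'veridical' or 'anomalous'")
    B = np.zeros((6, 6))
    for prev, nxt in successor.items():
        B[nxt, prev] = 1.0
    return B


def build_policies(horizon: int) -> np.ndarray:
    """The three allowable policies as (3, horizon-1) arrays of action codes.

    Policy 0 always listens, policy 1 always speaks, policy 2 alternates
    starting with listen (so it is listening at even timesteps 2, 4, 6).
    Each entry yokes the listening and speaking factors: an agent following
    a policy is listening or speaking, never both.
    """
    if horizon < 2:
        raise ValueError("horizon must be at least 2")
    n = horizon - 1
    always_listen = np.full(n, LISTEN)
    always_speak = np.full(n, SPEAK)
    alternate = np.array([LISTEN if k % 2 == 0 else SPEAK for k in range(n)])
    return np.stack([always_listen, always_speak, alternate])


def _binary_forced_transitions() -> np.ndarray:
    """(2, 2, 2) action-conditioned table forcing a binary factor to a state.

    ``B[:, :, a]`` maps any previous state to state ``a`` (columns one-hot).
    """
    B = np.zeros((2, 2, 2))
    for a in range(2):
        B[a, :, a] = 1.0
    return B


@dataclass
class GenerativeModel:
    """Complete agent-side model for the singing task.

    Arrays follow the convention that *columns* (the trailing state axes)
    are the conditioning variables and each column sums to one.
    """

    A_aud: np.ndarray  # (7, 6, 2, 2): outcome x content x listening x speaking
    A_prop: np.ndarray  # (2, 2): outcome x speaking (identity)
    B_content: np.ndarray  # (6, 6)
    B_listen: np.ndarray  # (2, 2, 2): next x prev x action
    B_speak: np.ndarray  # (2, 2, 2)
    C: dict[str, np.ndarray]  # flat outcome preferences per modality
    D: list[np.ndarray]  # initial priors per factor [content, listening, speaking]
    policies: np.ndarray  # (3, horizon-1) action codes
    zeta: float
    gamma: float
    horizon: int
    transition_mode: str
    floor: float = DEFAULT_FLOOR
    lexicon: SongLexicon = field(default_factory=SongLexicon)

    @property
    def factor_sizes(self) -> tuple[int, int, int]:
        return (6, 2, 2)

    def content_transition(self) -> np.ndarray:
        return self.B_content

    def factor_B(self, factor: int, action: int) -> np.ndarray:
        """Transition matrix for one factor under one (yoked) action code."""
        if factor == CONTENT:
            return self.B_content
        if factor == LISTENING:
            return self.B_listen[:, :, action]
        if factor == SPEAKING:
            return self.B_speak[:, :, action]
        raise IndexError(factor)

    def to_json(self) -> str:
        """Serialize the model to JSON (nested row-major arrays; every
        likelihood/transition column -- trailing axes -- sums to one)."""
        payload = {
            "convention": "arrays are row-major nested lists; distributions run "
            "down axis 0 and are conditioned on the trailing axes",
            "words": list(WORDS),
            "silence": SILENCE,
            "zeta": self.zeta,
            "gamma": self.gamma,
            "horizon": self.horizon,
            "transition_mode": self.transition_mode,
            "floor": self.floor,
            "A_aud": self.A_aud.tolist(),
            "A_prop": self.A_prop.tolist(),
            "B_content": self.B_content.tolist(),
            "B_listen": self.B_listen.tolist(),
            "B_speak": self.B_speak.tolist(),
            "C": {k: v.tolist() for k, v in self.C.items()},
            "D": [d.tolist() for d in self.D],
            "policies": self.policies.tolist(),
        }
        return json.dumps(payload, indent=2)


def build_song_model(
    zeta: float = 3.0,
    transition_mode: str = "veridical",
    gamma: float = 16.0,
    horizon: int = 6,
    floor: float = DEFAULT_FLOOR,
    uniform_initial_states: bool = False,
) -> GenerativeModel:
    """Construct the full generative model for the singing task.

    Before precision weighting, the auditory likelihood assigns probability 1
    to the content word whenever the agent is in the listening state, and
    probability 1 to silence when it is not listening (even while speaking:
    unattended self-generated sound is not heard); ``precision_weight`` is
    then applied column-wise with the given ``zeta``.  Proprioception is an
    identity mapping at every zeta (proprioception is assumed error-free).

    By default the initial priors D encode the agent "getting its cue":
    listening, not speaking, content at "It's".  ``uniform_initial_states``
    flattens them instead.
    """
    if zeta < 0 or gamma < 0:
        raise ValueError("precisions must be non-negative")
    if horizon < 2:
        raise ValueError("horizon must be at least 2")

    # Base auditory likelihood, then column-wise precision weighting.
    # Audition reports what the agent hears: the content word when it is in
    # the listening state, silence otherwise -- including while speaking
    # without listening, which is the model's sensory attenuation of
    # self-generated sound.  The speaking axis is carried for the full
    # state space but does not alter the auditory mapping.
    A_aud = np.zeros((7, 6, 2, 2))
    for c in range(6):
        for l in range(2):
            for s in range(2):
                if l == LISTENING_YES:
                    A_aud[c, c, l, s] = 1.0
                else:
                    A_aud[6, c, l, s] = 1.0
    for c in range(6):
        for l in range(2):
            for s in range(2):
                A_aud[:, c, l, s] = precision_weight(A_aud[:, c, l, s], zeta, floor)

    A_prop = np.eye(2)

    B_content = build_content_transitions(transition_mode)
    B_listen = _binary_forced_transitions()  # action code == resulting state
    B_speak = np.zeros((2, 2, 2))
    B_speak[SPEAKING_NO, :, LISTEN] = 1.0
    B_speak[SPEAKING_YES, :, SPEAK] = 1.0

    C = {
        "auditory": np.full(7, 1.0 / 7.0),
        "proprioceptive": np.full(2, 0.5),
    }

    if uniform_initial_states:
        D = [np.full(6, 1 / 6), np.full(2, 0.5), np.full(2, 0.5)]
    else:
        d_content = np.zeros(6)
        d_content[0] = 1.0  # "It's"
        d_listen = np.array([1.0, 0.0])  # listening
        d_speak = np.array([0.0, 1.0])  # not speaking
        D = [d_content, d_listen, d_speak]

    return GenerativeModel(
        A_aud=A_aud,
        A_prop=A_prop,
        B_content=B_content,
        B_listen=B_listen,
        B_speak=B_speak,
        C=C,
        D=D,
        policies=build_policies(horizon),
        zeta=float(zeta),
        gamma=float(gamma),
        horizon=int(horizon),
        transition_mode=transition_mode,
        floor=float(floor),
    )
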
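"""Belief-trajectory figures: outcomes, percepts, state and policy beliefs."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .experiments import PerceptLabels, TrialRecord, classify_percepts
from .model import SILENCE, WORDS

__all__ = ["plot_trial"]


def plot_trial(trial: TrialRecord, labels: PerceptLabels | None = None):
    """Render one trial as stacked panels (grayscale belief heatmaps).

    Hallucinated timesteps are boxed in red in the percept row; percept
    text alpha tracks the belief-averaged confidence.
    """
    if labels is None:
        labels = classify_percepts(trial)
    marg = trial.final_beliefs.q_marginal
    T = trial.config.horizon

    fig, axes = plt.subplots(
        5, 1, figsize=(1.6 * T, 9),
        gridspec_kw={"height_ratios": [1, 1, 3, 2, 2]}, constrained_layout=True,
    )
    ax_out, ax_per, ax_content, ax_bin, ax_pol = axes

    ax_out.set_title(f"outcomes (zeta={trial.config.zeta}, {trial.config.transition_mode})")
    ax_out.set_xlim(0.5, T + 0.5)
    ax_out.set_ylim(0, 2)
    ax_out.set_yticks([0.5, 1.5])
    ax_out.set_yticklabels(["proprioception", "audition"])
    for t, obs in enumerate(trial.observations, start=1):
        ax_out.text(t, 1.5, obs.auditory if obs.auditory != SILENCE else "-", ha="center")
        ax_out.text(t, 0.5, "speaking" if obs.proprioceptive == "speaking" else "-", ha="center")
    ax_out.set_xticks([])

    ax_per.set_title("percepts (red box = hallucination)")
    ax_per.set_xlim(0.5, T + 0.5)
    ax_per.set_ylim(0, 1)
    ax_per.set_yticks([])
    for t in range(1, T + 1):
        word = labels.percepts[t - 1]
        conf = labels.confidence[t - 1]
        alpha = conf if np.isfinite(conf) else 0.3
        ax_per.text(t, 0.5, word if word != SILENCE else "-", ha="center", alpha=max(alpha, 0.2))
        if labels.hallucination[t - 1]:
            ax_per.add_patch(
                plt.Rectangle((t - 0.45, 0.1), 0.9, 0.8, fill=False, edgecolor="red", lw=1.5)
            )
    ax_per.set_xticks([])

    ax_content.imshow(
        1 - marg[0].T, cmap="gray", vmin=0, vmax=1, aspect="auto",
        extent=(0.5, T + 0.5, 5.5, -0.5),
    )
    ax_content.set_yticks(range(6))
    ax_content.set_yticklabels(WORDS)
    ax_content.set_title("beliefs: content")
    ax_content.set_xticks([])

    binary = np.vstack([marg[1][:, 0], marg[2][:, 0]])
    ax_bin.imshow(
        1 - binary, cmap="gray", vmin=0, vmax=1, aspect="auto",
        extent=(0.5, T + 0.5, 1.5, -0.5),
    )
    ax_bin.set_yticks([0, 1])
    ax_bin.set_yticklabels(["listening", "speaking"])
    ax_bin.set_title("beliefs: listening / speaking")
    ax_bin.set_xticks([])

    q_pi = np.vstack([b.q_policy for b in trial.beliefs]).T
    ax_pol.imshow(
        1 - q_pi, cmap="gray", vmin=0, vmax=1, aspect="auto",
        extent=(0.5, T + 0.5, 2.5, -0.5),
    )
    ax_pol.set_yticks([0, 1, 2])
    ax_pol.set_yticklabels(["always listen", "always speak", "alternate"])
    ax_pol.set_title("beliefs: policies (after each timestep)")
    ax_pol.set_xlabel("timestep")
    return fig
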
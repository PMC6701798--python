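# avhsim

Discrete-state active-inference simulations of auditory verbal
hallucinations (AVH) that are either consistent with the environment
(*in-context*) or not (*out-of-context*), for computational-psychiatry
researchers studying false-positive perceptual inference.

## The model

A synthetic subject sings the six-word song *"It's a small world after
all!"* as a duet with a partner who always sings the odd timesteps
(1, 3, 5) in the true order. The subject is a partially observed Markov
decision process agent with three hidden-state factors — lexical **content**
(6 words), **listening** (yes/no) and **speaking** (yes/no) — and two outcome
modalities, **audition** (6 words + silence) and **proprioception**
(speaking / not-speaking). Perception and action both minimize variational
free energy:

- beliefs follow the mean-field posterior `Q(s̃, π) = Q(π) ∏τ Q(sτ|π)`,
  optimized by coordinate ascent with forward and backward (postdictive)
  messages, so `F(π) = E_Q[ln Q(s̃|π) − ln P(õ, s̃|π)]` never increases;
- policies (always listen, always speak, alternate) are scored by
  `Q(π) = σ(−F(π) − γ·G(π))`, where the expected free energy `G` supplies
  the prior `P(π) = σ(−γ·G(π))`; with flat outcome preferences `G` reduces
  to epistemic value;
- percepts come from the Bayesian model average `Q(sτ) = Σπ Q(sτ|π) Q(π)`.

Two lesions generate the phenomenology. The auditory likelihood is
precision-weighted column-wise, `Ā = σ(ζ·log(A + e⁻¹⁰))`: at ζ = 3 sensory
evidence overrides action-driven expectations, at ζ = 1 it cannot. The
content narrative `Bᶜ` is either the veridical song cycle or an anomalous
matrix in which "after" follows "It's". Crossing the two gives four
experiments: normal, in-context hallucinating, "prodromal" (aberrant priors
corrected by precise evidence), and out-of-context hallucinating.

A timestep is flagged a **hallucination** when the belief-averaged
probability of listening exceeds 0.5 while the environment was silent, a
**misperception** when sound was present but that probability stayed below
0.5, and a hallucination is **in-context** when the hallucinated word is the
veridical song word for that timestep.

## Worked example

```bash
avhsim suite --out out/
```

prints (abridged):

```
 experiment                         label  zeta transition_mode hallucination_timesteps misperception_timesteps           in_context          heard_string
          1                        normal   3.0       veridical                      []                      []                   []      It's small after
          2     in-context hallucinations   1.0       veridical               [2, 4, 6]                  [3, 5]   [True, True, True]     It's a world all!
          3                     prodromal   3.0       anomalous                      []                      []                   []      It's small after
          4 out-of-context hallucinations   1.0       anomalous               [2, 4, 6]                  [3, 5] [False, False, True]  It's after It's all!
```

Reading the table: the normal singer (1) hears exactly the words that were
sounded. Reducing auditory precision (2) makes it hallucinate the expected
song words into every silent timestep (all in-context) while failing to
register its own voice and the partner's. The prodromal singer (3) carries
the anomalous narrative but, with intact precision, still perceives the true
song. When both lesions combine (4) the same timesteps are hallucinated but
the content is now disordered — the agent perceives **"It's after It's
all!"** — out-of-context at timesteps 2 and 4. Note that experiments 2 and
4 share identical action sequences: the narrative lesion changes *what* is
hallucinated, never *when*.

Single trials, JSON/CSV exports and custom configurations:

```bash
avhsim simulate --experiment 4 --out out/            # preset 4
avhsim simulate --config my.yaml --format csv --out out/
```

or from Python:

```python
from avhsim import TrialConfig, run_trial, classify_percepts
trial = run_trial(TrialConfig(zeta=1.0, transition_mode="anomalous"))
print(classify_percepts(trial).heard_string)   # It's after It's all!
```

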
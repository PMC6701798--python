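# Methods

## Model

The agent is a finite-horizon (default T = 6), discrete-state partially
observed Markov decision process with three mean-field hidden-state factors
and two outcome modalities.

**Hidden states.** Content c ∈ {It's, a, small, world, after, all!};
listening l ∈ {yes, no}; speaking s ∈ {yes, no}. Content is deliberately
factorized away from who is producing the sound ("what" vs "who"): a word
keeps its identity whether it is heard, spoken, or both.

**Likelihoods.** Audition reports what the agent *hears*: when l = yes the
content word is observed with probability one (before precision weighting);
when l = no the seventh outcome, silence, is observed — including while
speaking. That unattended self-generated sound maps to silence is the
model's minimal stand-in for sensory attenuation; it is also what lets the
normal agent *infer* it is listening from the presence of its own voice,
and the impaired agent fail to. The likelihood array keeps the full
(7 × 6 × 2 × 2) state space; the speaking axis does not modulate audition.
Proprioception is a 2 × 2 identity on the speaking factor at every
precision (proprioception is assumed error-free). The auditory table is
then precision-weighted column-wise,

    Ā(:, c, l, s) = softmax( ζ · log(A(:, c, l, s) + e⁻¹⁰) ),

so each column's off entries sit at ≈ e^(−10ζ): ζ = 0 yields uniform
columns, large ζ a near-deterministic mapping. Only audition is weighted.

**Transitions.** Content evolves autonomously under a one-hot matrix Bᶜ:
the veridical 6-cycle of the song, or the anomalous matrix that differs in
a single column — "It's" → "after" instead of "It's" → "a" (equivalently, a
3-cycle It's → after → all! into which a → small → world feeds). The
columns for "small" and "world" keep their veridical successors: nothing in
the out-of-context trajectory ever visits them, and the anomalous matrix
must still favor "a" before "small". Listening and speaking are forced
deterministically by the executed action; one action code per transition
drives both factors (listen ⇒ l=yes, s=no; speak ⇒ l=no, s=yes), so a
policy never prescribes listening and speaking simultaneously, although
*inference* may conclude both are true when the evidence demands it.

**Policies, preferences, priors.** Three policies of length T−1: always
listen, always speak, alternate starting with listen (hence listening at
even timesteps). Outcome preferences C are flat in both modalities, so
expected free energy reduces to epistemic value up to a constant. Initial
priors D encode the cue: content "It's", listening, not speaking
(configurable to uniform). Policy precision γ defaults to 16, a
conventional high-confidence value, and is never modulated — only ζ and Bᶜ
vary across experiments.

## Environment (the generative process)

The partner sings the veridical song words at odd timesteps 1, 3, 5
regardless of the agent's behavior; whenever the agent speaks, the
veridical word for that timestep is sounded (the environment owns content —
the agent chooses whether to sing, not what). Simultaneous singing yields
the single shared word. Proprioception always reflects the executed action.
This generative process is the package's only data source: it emulates a
maximally reliable dyadic context (deterministic word order, perfectly
regular turn structure, no acoustic noise). Passing tests therefore show
that the *belief dynamics* reproduce the intended phenomenology under ideal
context; they say nothing about noisy partners, lexical choice, or real
speech acoustics.

## Inference

Per policy, the mean-field posterior over all factors and timesteps is
optimized by exact coordinate ascent: each update combines (i) the expected
log-likelihood of observed outcomes, marginalizing the other factors
through ln Ā, (ii) the forward message E_q[ln B̃]·q(τ−1) (ln D̃ at τ = 1) and
(iii) the matching backward message from q(τ+1) (Bayesian smoothing /
postdiction). Unobserved future timesteps carry prior-predictive beliefs.
The accumulated F(π) and the expected free energy over the remaining
horizon, G(π) = ambiguity + risk, give the policy posterior
Q(π) = softmax(−F − γG); the equation defining the policy *prior*,
σ(−γG), is updated by the evidence each policy accrues, which reproduces
the observation-driven elimination of inconsistent policies. State beliefs
are averaged over policies (Bayesian model averaging) before percepts are
read off.

Actions: the marginal probability of listen/speak at a transition sums the
policy posterior over prescribing policies. Argmax mode (default;
deterministic, ties broken toward listening) or seeded sampling.

## Numerical choices

- **Structural-prior floor exp(−13).** One-hot transition and initial-state
  columns are floored at exp(−13) before their logs, so a contradicted
  deterministic prior costs 13 nats. The admissible window is derived from
  the two precision regimes: a policy-driven expectation must beat silence
  at ζ = 1 (floor > 10 nats, the likelihood penalty e^(−10ζ)), and precise
  evidence must be able to repair an anomalous narrative at ζ = 3, which
  requires one content floor plus one listening floor to undercut a 30-nat
  observation (2·floor < 30). Hence floor ∈ (10, 15) nats; 13 maximizes the
  smaller margin. Outside this window the phenomenology provably inverts
  (no hallucinations, or an incorrigible normal agent).
- **Likelihood logs are only guarded** (exp(−32)) against log 0. Clipping
  them at the structural floor would cap evidence at exactly the prior
  cost, making correction of deterministic priors impossible at any ζ.
- **Two sweep schedules.** Coordinate ascent here is order-dependent:
  sweeping timesteps earliest-first lets the forward narrative commit
  before late evidence arrives (trapping the prodromal agent in a
  mishearing minimum), latest-first can build an unanchored chain backward
  at low precision. `infer_states` runs both schedules from flat
  initializations and returns the lower-free-energy solution; each
  schedule is monotone in F (asserted to 1e−9 per sweep), and in every
  study condition the correct phenomenology is the lower-F solution.
- **Iteration control:** at most 16 sweeps, stopping when F changes by
  < 1e−4 nats; the presets converge in 2–4 sweeps.
- **Degenerate inputs:** ζ = 0 gives uniform likelihoods and
  prior-predictive posteriors; horizon must be ≥ 2 (the environment raises
  on stepping past it); non-normalizable beliefs raise a diagnostic error
  with the timestep and factor attached.

## Percept classification

"Hearing" at a timestep is the belief-averaged probability of the listening
state exceeding 0.5 — the least arbitrary binarization of the belief plots,
exposed as a parameter. The percept is the most probable content word;
hallucination = hearing into silence; misperception = sound present but not
heard; in-context = hallucinated word equals the veridical song word.
Misperceptions are attributed to *own voice* (latest misperceived timestep
while speaking) and *partner's voice* (earliest misperceived timestep at
which the partner sang); in the reduced-precision trials the agent co-sings
at both misperceived timesteps, so the two descriptions pick out timesteps
5 and 3 respectively.

## Behavior at the presets, and two knife-edges

With ζ ∈ {3, 1} crossed with {veridical, anomalous}: the normal and
prodromal agents hallucinate nowhere and perceive every sounded word; both
reduced-precision agents hallucinate exactly at the silent timesteps 2, 4,
6 and misperceive at 3, 5, with identical action sequences; only the
content differs (in-context "a world all!" vs out-of-context
"after It's … all!"). Two quantities sit on exact symmetries worth knowing
about:

- **Prodromal postdiction at τ = 2.** Given "It's" at τ = 1 and (precisely
  heard) "small" at τ = 3, the two explanations — veridical "a" (violating
  the anomalous prior It's → after) and prior-consistent "after" (violating
  after → small) — each cost exactly one floor, so the posterior is an
  exact 50/50 tie between "a" and "after" with "a" recovered as a modal
  word. Strict concentration on "a" would require graded anomalous
  columns, which the one-hot narrative deliberately excludes.
- **Weak veridical belief at τ = 4 (out-of-context trial).** While
  hallucinating "It's", the unique runner-up content state is the veridical
  "world", carried at the floor scale (≈ e⁻¹³): the agent still weakly
  entertains the sound a veridical order would produce.

## Limitations

No hierarchical selection between transition matrices (the anomalous
narrative is simply always present and is *revealed* at low precision); no
learning of likelihoods or transitions; no sensory-attenuation dynamics
beyond the static listening-conditioned mapping; no affective or memory
content; γ fixed. The dyadic context is a six-step, single-song toy:
quantitative outputs (free energies, confidence values) characterize this
model, not empirical data.
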
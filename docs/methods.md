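# Methods

## Model overview

The simulator implements a discrete-event automaton for contextual fear
conditioning. Time is counted in *samples*: at each step one attribute of
the current context enters entorhinal working memory and a full
perception–recall–decision cycle runs. No wall-clock model of sampling is
attempted; every quantity is a function of sample number.

The circuit has five stations:

* **Entorhinal input (EC_in)** — one binary cell per possible attribute
  (`N_Ctx`), with working-memory persistence for the duration of a visit.
* **Dentate (DG)** — `N_Hipp` cells, each innervated by `F` random EC_in
  cells through Hebbian synapses that transmit nothing until potentiated.
  K-winners-take-all (KWTA) firing during representation creation; graded,
  rate-coded firing during recall.
* **CA3** — `N_Hipp` cells paired one-to-one with dentate cells (dyads),
  with an independent random direct EC_in innervation (`F` synapses), a
  fully connected recurrent collateral system, and always-on KWTA.
* **Entorhinal output (EC_out)** — one cell per attribute, fired when at
  least `ThrshCtx` of the active CA3 cells hold potentiated synapses onto
  it; its active set is the recalled attribute pattern.
* **Amygdala** — a rate-coded fear unit driven by potentiated CA3 synapses.

Three operating modes reconfigure the circuit. In **creation** every
anatomical entorhinal synapse transmits with unit strength irrespective of
potentiation; the `K` most innervated dentate cells win a noisy KWTA, the
dyads become the permanent representation, and all co-active Hebbian
synapses potentiate. In **recall** nothing is plastic; dentate cells fire
at the fraction of their learned attributes currently observed, CA3 sums
the dyad relay with `dpf` times the direct pathway, KWTA produces the
pre-recurrent pattern `Ptrn_o`, and — provided at least `K_0` cells fired —
two recurrent iterations with tie-*preserving* KWTA settle the final
pattern. Ties are preserved rather than broken there because an evidence
tie between two representations must surface as an over-size final pattern
(more than `K` cells), which suppresses all downstream action, rather than
being resolved arbitrarily. In **update** the active representation's
cells (never new cells) potentiate synapses from every currently sampled or
recalled attribute, extending the representation's attribute set.

## The evidence computation

The controller evaluates, after every sample, the log10 Bayes factor

`B_Rep = log10 P[Z_com | Same, Z_cur, Z_rec] − log10 P[Z_com | Diff, Z_cur, Z_rec]`

* Under **Same**, the recalled set is a subset of the current context's
  `N_A` attributes and the sample is uniform without replacement, so
  `Z_com ~ Hypergeom(N_A, Z_rec, Z_cur)`.
* Under **Diff**, only recalled attributes also present in the current
  context can be sampled. Writing `m` for that count,
  `Z_com | m ~ Hypergeom(N_A, m, Z_cur)`, and the distribution of `m`
  depends on how two different contexts relate:
  * `diff_model="ensemble"` (default): unique attributes of different
    contexts are independent draws from the non-general pool, so the pair
    shares `u ~ Hypergeom(N_Ctx − N_Gen, N_A − N_Gen, N_A − N_Gen)` uniques
    by chance and `m | u ~ Hypergeom(N_A, N_Gen + u, Z_rec)`. This is the
    *exact* Bayesian observer for the synthetic world implemented here, and
    the test suite validates it against a Monte-Carlo of that world.
  * `diff_model="shared_core"`: different contexts share exactly the
    general core (`u = 0`). This is the back-of-envelope variant — at full
    sampling the evidence is `Z_rec · log10 2`, which makes the
    minimum-useful representation size exactly 10 — and it is kept as an
    option, but it is *harder* than the ensemble model at high overlap
    (it declares impossibility where chance unique overlap is merely
    unlikely), which in long sessions in very similar contexts lets the
    evidence cross the update threshold before the context is discredited
    and thereby corrupt a valid representation. The ensemble observer is
    both the generatively correct one and the one that reproduces the
    misattribution dynamics robustly, so it is the default.

Under the ensemble observer the expected-evidence curve
`Expected B_Rep(Z, Z)` first reaches the conditioning threshold `B_old`
at exactly `Z = 45`, which is why `Z_0 = 45` is the default creation
minimum: a context encoded from `Z_0` samples supports conditioning on a
later visit no later than on the visit of its creation.

Special cases: evidence is exactly 0 whenever EC_out is silent (including
the `X_Po < K_0` and over-size-pattern suppressions) or the final pattern
matches no registered representation; it is floored at `b_floor = −50`
when the observation is impossible under Same — in particular whenever
`Z_cur − Z_com + Z_rec > N_A`, and whenever `Z_rec > N_A` (a representation
that has been updated in two different contexts recalls more attributes
than one context holds and thereby discredits itself); and it is clamped
at +50 when impossible under Diff. The clamps sit far beyond every
decision threshold, so control behaviour never depends on them.

`Expected B_Rep(Z_cur, Z_rec)` evaluates the evidence at the real-valued
expected overlap `Z_cur·Z_rec/N_A` by linear interpolation between the two
adjacent integer overlaps; interpolation (rather than rounding) avoids
artificial jumps in threshold-crossing scans. During a session in which a
representation was created, the evidence that drives conditionability and
fear is `Expected B_Rep(Z_cur, Z_cur)` — the newly created representation
is valid by fiat, but its conditionability should not exceed what the same
information would support on a later visit, which yields the observed
gradual rise rather than a step.

A purely functional emulation of the evidence computation by rate-coded
neurons is included (`calibrate_approx_circuit`): an envelope cell
(power function of `Z_com`), a divisive-inhibition cell (power function of
`Z_hi · (Z_lo − Z_com)`), a leaky output cell and an impossibility detector,
least-squares fitted to the exact surface on a `Z` grid from 30 to 100 in
steps of 5. The fit residual (RMSE ≈ 2.7 log10 units over a ~60-unit
surface) is recorded in the calibration result; the circuit is an
existence proof, not part of the control path.

## Mode-control rules

* **Update** when a representation was created this session, or the active
  representation's evidence reaches `B_add`.
* **Create** (at most once per session) when `Z_cur ≥ Z_0`, creation is not
  suppressed, and either the evidence fell below `B_new` or the hippocampus
  has been silent all session (`X_Po < K_0` and no recalled output yet) —
  the novel-distinctive-context route. The silence trigger is evaluated at
  every sample from `Z_0` on, not only at `Z_0`.
* **Suppression**: once any representation's evidence reaches `B_pv`, it
  suppresses creation for the rest of the session until that same
  representation is discredited (evidence below `B_new` while active).
  A representation that merely stops being active keeps suppressing — the
  conservative reading.
* **Conditioning**: a shock increments the amygdala weight of every cell in
  the active pattern by `α · Cnd` with `Cnd = linsig(B | B_old, B_add)`.
  Weights never decrease; extinction is deliberately out of scope.
* **Fear**: `V = Ge'/(1 + Ge')` with `Ge' = linsig(B | 0, B_add) · Ge`.
  Expression is gated from zero (not `B_old`): it is better to err on the
  side of fear. With the default `α = 0.025` and `K = 60`, one
  full-strength shock yields an asymptotic fear of `1.5/2.5 = 0.6`.

On a cycle in which creation occurs, fear and conditioning use the freshly
created representation's cells (the decision-then-express ordering); the
alternative ordering only shifts one sample and nothing downstream depends
on it.

## Parameters

| name | default | meaning |
|------|---------|---------|
| `N_Ctx` | 1000 | attribute universe size (EC cells per layer) |
| `N_Hipp` | 10000 | dentate/CA3 dyads |
| `N_A` | 100 | attributes per context |
| `N_Gen` | 50 | attributes common to all contexts |
| `F` | 60 | EC afferents per dentate and per CA3 cell |
| `K` | 60 | KWTA winner count |
| `K_0` | 15 | minimum `Ptrn_o` size to engage recurrents |
| `Z_0` | 45 | minimum samples for representation creation |
| `ThrshCtx` | 42 | active potentiated CA3 inputs to fire an EC_out cell |
| `B_old, B_new, B_add, B_pv` | 3, −3, 15, 3 | evidence thresholds (log10) |
| `alpha` | 0.025 | amygdala learning rate per shock |
| `dpf` | 0 | direct-path strength in recall (0 = indirect only) |
| `E_rev` | 1 | excitatory reversal potential (dimensionless) |
| `noise_eps` | 1e−6 | KWTA tie-break noise half-width (excitation units) |
| `n_recurrent_iters` | 2 | recurrent cycles to the final pattern |
| `b_floor` | −50 | finite stand-in for −∞ evidence |
| `diff_model` | ensemble | Diff-hypothesis generative model (above) |

`noise_eps` is orders of magnitude below the excitation quantum (one
synaptic weight), so noise can only resolve exact ties, never reorder
distinct excitation levels; the choice of its magnitude was verified to be
immaterial over six orders of magnitude.

## Numerical and implementation choices

* All hypergeometric probabilities go through `scipy.stats.hypergeom`
  (log-gamma based); the Diff mixture is a two-level sum (`u`, then `m`)
  that collapses the full class decomposition exactly, and per-query PMF
  vectors are memoized.
* Potentiated entorhinal weights on a cell are always equal and sum to one,
  so only the potentiation mask and per-cell counts are stored; a cell's
  recall rate is "fraction of its learned attributes currently observed".
  Equal weights are the maximum-entropy completion of the sum-to-one
  normalization constraint.
* Recurrent and CA3→EC_out potentiated weights are binary; recurrent
  iterations are driven by recurrent excitation only (no residual afferent
  term).
* Creation-mode excitation is the unweighted count of active anatomical
  afferents; the dentate→CA3 relay during creation is modelled by copying
  the winner set to the dyad partners (the relay is strong enough to decide
  CA3 firing, so no numeric gain is needed).
* Per-cell potentiation counts are maintained incrementally (only touched
  columns are recounted) so that a recall cycle costs a sparse row-sum, not
  a full-matrix reduction.
* All randomness flows from explicit `numpy` Generators; experiments derive
  per-replicate child seeds from one base seed, and every run is
  bit-reproducible from its arguments.

## The synthetic world, and what it does not emulate

Contexts are exact-size attribute sets: unconstrained contexts draw their
`N_A − N_Gen` uniques independently from the non-general pool; a context at
similarity `s` to a reference shares exactly `s·N_A` attributes (the whole
general core plus uniformly chosen reference uniques), with fresh attributes
drawn excluding the reference's uniques so realized similarity is exact
rather than in expectation. Sampling within a visit is a uniform random
permutation. Not emulated: attribute salience (all attributes are equally
likely to be sampled), any slowing of sampling over time or during
freezing, contexts of unequal size, and partial recurrent connectivity.
Passing tests therefore speak to the model's logic under idealized uniform
sampling, not to quantitative freezing curves in real animals.

## Experiment operationalizations

* **Familiarization to a target recalled count** `v`: one creation from
  `Z_0` randomly sampled attributes followed by one update to a random
  `v`-superset. Under the model any schedule reaching `v` is equivalent.
* **Misattribution tests** report both the whole-session mean fear and the
  *settled* fear over the final quarter of the test session. The settled
  readout is the discriminative one: in a 95%-similar pair the evidence
  trajectories — and hence fear — are nearly identical until the test
  context is finally discredited and re-identified, so early-session fear
  mostly reflects the shared identification transient.
* **Pathway-separation sweeps** reuse the same network and sampling order
  across `dpf` values (paired design) and report the A-minus-B cell count
  in `Ptrn_o`. The ordering direct-only < indirect-only < weak-mixed holds
  in the settled phase (last quarter of the session). Early in a session
  the comparison inverts for an uninteresting reason: with only 2–3
  potentiated direct synapses per cell, most cells are silent and the
  direct pathway's apparent "separation" is a presence/absence sparsity
  effect, not discrimination; the richer dentate innervation makes nearly
  every representation cell fire weakly, which drags the early indirect
  separation toward zero.
* **Lesion suite**: dentate manipulations are applied per phase; chronic
  conditions (relay off during both encoding and recall, or plasticity off)
  also apply to the preceding filler-context encodings, acute ones do not.
  The suite runs with `dpf = 0.15` so that a recall-side dentate lesion
  leaves the direct pathway operative instead of silencing CA3 outright.
  Filler contexts exist precisely so that an encoding-only lesion leaves
  stale dentate potentiation to mislead subsequent intact recall.
* **Problem sizes**: behavioural properties run at full `N_Hipp = 10,000`
  where representation overlap matters (misattribution, generalization,
  pathway sweeps) and at 2,000–4,000 cells where it does not (session-level
  conditionability properties, lesion contrasts); pattern-separation means
  use 100 replicate context pairs.

## Known limitations

* No extinction and no time model (both deliberate): fear curves rise and
  plateau; declines in real test data reflect extinction the model omits.
* Representation overlap for 90%-similar contexts encoded from *full*
  attribute sets computes to ~48%, not ~30%: with these parameters the
  afferent-count correlation at the KWTA threshold fixes this value, and a
  bivariate-hypergeometric estimate reproduces it analytically, so the
  lower figure is not attainable by any tie-breaking or noise choice. The
  operating point that matters behaviourally — creation from `Z_0`
  samples — computes to ~8–10% overlap as expected.
* The threshold scan of `Expected B_Rep(Z, Z)` against `B_add` crosses at
  67–71 (model-dependent), not at `Z_0 = 45`; `Z_0 = 45` is instead exactly
  the `B_old` crossing of the ensemble observer. Consequently, in a
  creation session conditionability reaches its maximum near sample 70,
  about 25 samples after creation.
* In very long sessions in a context ≥95% similar to a familiar one, the
  evidence can reach `B_add` before the context is discredited, adding
  wrong-context attributes to a valid representation. The `Z_rec > N_A`
  floor lets such corrupted representations discredit themselves, but the
  transient misattribution is a real (and arguably realistic) behaviour of
  the model.
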
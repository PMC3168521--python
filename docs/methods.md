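# Methods

## The model

Song is modeled at the syllable level. A bout is a sequence of syllables;
each syllable contributes one observation vector
y_t = (duration [ms], mean pitch [Hz], mean Wiener entropy [–]) and occupies
one hidden state z_t ∈ {1,…,K}. An order-r Gaussian-emission hidden Markov
model factorizes

    p(y, z) = p(z_1) ∏ p(z_t | z_{t−1}, …, z_{t−r}) ∏ N(y_t | μ_{z_t}, Σ_{z_t})

with full 3×3 emission covariances (at D = 3 a full covariance is cheap and
strictly more expressive than a diagonal one). Order 0 drops the transition
structure entirely and is exactly the Gaussian mixture model; order 2 is
reduced to an equivalent first-order chain over *context states* — ordered
pairs of consecutive states, K² + K of them once a dummy symbol padding the
bout start is included. Appending state k to context (a, b) deterministically
yields context (b, k), so the transition support is structural, giving each
context exactly K reachable successors. Orders above 2 are out of scope
(their cost grows exponentially with r).

The scientific point of the state space: the state→syllable map is
many-to-one. With *redundant* states (K larger than the number of syllable
types), two states can share a syllable's acoustics while occupying
different sequential contexts, which lets a first-order hidden chain emit
label sequences with second-order context dependency.

## Inference

Fitting is mean-field Variational Bayes with conjugate priors:

- each transition row and the initial distribution: symmetric Dirichlet,
  concentration α₀ = 1;
- each state's (mean, precision): Normal–Wishart with m₀ = the training
  data mean, β₀ = 1, ν₀ = D + 2 (the smallest value with a finite expected
  covariance), and W₀ = (data covariance)⁻¹ / ν₀ so the prior expected
  precision matches the data. All are overridable (`VBHyperparams`).

Features are z-scored per bird before fitting; the scaler is stored on the
results object so held-out data and annotations map back consistently.

Each iteration runs an E-step — forward-backward on the (context-expanded)
chain using expected-log parameters (digamma-based Dirichlet expectations
and the expected Gaussian log density under the Normal–Wishart posterior) —
followed by conjugate M-step updates. The forward-backward recursions are
implemented with per-step scaling (normalized linear-space messages whose
log scale factors accumulate into the log normalizer), so sequences of at
least 10⁴ syllables are handled without underflow; the unit tests verify
exactness against exhaustive path enumeration at small T, K to 1e-10.

After every E-step the variational lower bound on the log marginal
likelihood is recorded:

    L = Σ_bouts ln Z̃  −  KL(q(π)‖p(π))  −  Σ_rows KL(q(A_row)‖p(A_row))
        −  Σ_states KL(q(μ, Λ)‖p(μ, Λ)),

where ln Z̃ is the forward normalizer under expected-log parameters. L is
non-decreasing over iterations (asserted with 1e-8 slack) and equals the
exact conjugate log marginal for K = 1, which the tests check against the
closed form. The bound is the model-selection score: with a uniform prior
over model structures m = (r, K), maximizing L approximates maximizing
p(m | Y), and its KL terms implement the Occam penalty that lets smaller
models win when they suffice.

Convergence: absolute bound increment < 1e-6, at most 500 iterations.
Initialization: responsibilities from seeded k-means, with restarts
alternating between plain k-means on y_t and a context-aware variant that
appends the down-weighted features of the two neighboring syllables
(states that differ only in sequential context then start out separated);
default 5 restarts, best final bound kept. A state that loses all
responsibility reverts to its prior (it is never deleted, so K stays honest
in the bound's complexity penalty); the event is logged.

Predictive likelihood on held-out bouts is plug-in at posterior-mean
parameters (E[mean] = m, E[precision] = νW), evaluated by an exact forward
pass; a variational-predictive variant would be a refinement, but the
plug-in form is standard and comparable across orders.

Decoding is per-syllable marginal-posterior argmax (the Baum-Welch gammas;
for order 2, context posteriors are first summed over contexts sharing the
same current state). Viterbi decoding is available as an option. States are
aligned to reference labels by majority vote over the positions they claim,
ties broken lexicographically and logged, many-to-one allowed.

## The context-dependency test

For each candidate syllable s (≥ 2 distinct observed predecessors and ≥ 2
distinct observed successors), the test compares the successor counts of s
restricted to occurrences after its most frequent predecessor against
expected counts proportional to s's context-free successor distribution:
χ² = Σ (O − E)²/E, df = (#categories − 1), with p from the upper tail and
significance at α/n_candidates (Bonferroni, α = 0.05). Successor categories
with expected count < 1 are pooled into one residual category (df reduced);
fewer than two remaining categories makes the syllable untestable (flagged,
not an error). A "nonrepeat" variant removes self-transitions before
candidate selection and testing. Ties for the most frequent predecessor are
broken lexicographically and logged.

Because the conditioned counts are a subset of the marginal counts they are
compared against, the test is conservative: its realized family-wise error
under a first-order null is well below the nominal α (the acceptance suite
measures it at 500 replicates). Power against the example grammar's 0.99
conditional is essentially 1 at 30 bouts.

## The synthetic-song generator

No recordings ship with the package; all experiments run on POMM-generated
data, so what the generator emulates bounds what the tests can show.

The example grammar has six states over five syllables {a, b, c, d, j},
with "b" split into contexts b_a (after "a") and b_c (after "c") and
P(d | b_c) = 0.99. The transition defaults are chosen so that (i) the
context-collapsed successor row of "b" is close to 0.13 / 0.55 / 0.31 over
a / d / c, (ii) the chunks "bcbd" and "jcd" arise as high-probability
paths, and (iii) bouts average ≈ 40–50 syllables (termination probabilities
0.08 after "d", 0.02 after "j", hard cap `max_len`; real bout-length
distributions are not modeled). Thirty training and ten held-out bouts per
simulated bird are the default study design.

Emission means sit at plausible feature scales (durations 60–150 ms, pitch
2.5–5.5 kHz, negative entropy) with a common diagonal covariance
(8 ms / 150 Hz / 0.15); absolute scales are inert because fitting z-scores
per bird. The single `overlap ∈ [0, 1]` dial controls how far the
context-separable states converge acoustically: at 0 every state is well
separated (the b_a/b_c means sit a Mahalanobis distance of 6 apart) and at
1 the b_a/b_c means coincide and the documented confusable cross-label pair
(a, d) shares one emission distribution. The cross-label overlap is
deliberate: real song shows overlapping feature-space clusters *across*
syllable categories, and without it a context-blind mixture model loses
nothing at the label level (any split of a single-label cloud still maps
back to that label under many-to-one alignment). The default overlap is
0.5 — most syllables acoustically distinct, the context-split states
appreciably overlapping — which is the regime the order-selection
experiments use; the annotation-mechanism experiments use overlap = 1,
where identity is recoverable only through context.

At overlap = 1 the acoustic space collapses to four clouds, and the bound
then genuinely favors the second-order model at any K: with that much
acoustic information destroyed, richer transition structure pays for
itself. This is a property of the regime, not of real song, which is why
order-recovery claims are made at moderate overlap.

Two auxiliary generators serve specific experiments: a stereotyped 5-state
first-order chain (advance 0.93 / skip 0.05 / end 0.02, separated means)
for transition-matrix recovery — near-deterministic rows keep the sampling
error of count-based estimates within the 0.05 recovery tolerance at 30
bouts, mirroring the stereotypy of real motifs — and a dense second-order
process (independent Dirichlet trigram rows, concentration 0.5, expressed
as a POMM over K² label-pair states) on which a first-order chain with only
K states provably cannot represent the law. A strictly first-order
one-state-per-label chain (the example grammar collapsed over context, with
the 0.13/0.55/0.32 row for "b") is the null model for error-control
studies.

All sampling flows from one integer seed per call through a single
`numpy` generator; identical seeds give byte-identical datasets on disk.

## Experiment sizes

The validation suite uses, per experiment: 100 random draws for
forward-backward exactness (T ≤ 6, K ≤ 3, r ≤ 2); 50 seeds × 3 orders for
bound monotonicity; 20 replicates for transition recovery (r = 1, K = 5)
and for Markov-order recovery at redundant K (plus 10 for the dense
second-order regime); 500 null and 200 alternative replicates for the
dependency test; and 10 simulated birds for the annotation mechanism
(order-1 kappa in the almost-perfect band, order-0 at or below
substantial, and the context-split count). These sizes are the package's
chosen experiment scale; all thresholds are stated in the tests themselves.

## Numerical choices and edge cases

- Log-domain or scaled computations throughout; forbidden transitions are
  −∞ log-scores that exponentiate to exact zeros.
- Bands for kappa are closed on the left and open on the right, except
  [0.81, 1.00] closed on both ends; negative kappa is "Poor agreement".
  When both annotators are constant and identical, chance agreement is 1
  and kappa is defined as 1 with a warning.
- Kappa items are individual syllables pooled over bouts.
- Grid-search cells fail independently: a failed fit records its error in
  the grid row and the scan continues. Selection ties break toward smaller
  K, then smaller order.
- Across-bird averaging z-scores each bird's grid before averaging (birds
  with different bout lengths are otherwise incommensurable); a bird whose
  grid is constant is excluded with a warning.
- Context-split counting: a significant syllable counts as split when ≥ 2
  occupied states align to it and a χ² test on the states × predecessor
  table (bout-initial positions excluded) rejects homogeneity at 0.05.
  This operationalizes "divided according to the preceding syllable"; other
  reasonable operationalizations would give different absolute counts.

## Limitations

- The generator emulates POMM-structured syntax with Gaussian acoustics; it
  does not model repeat-count adaptation, bout-length distributions, drift
  within a session, or non-Gaussian feature noise. Passing tests show the
  chain of methods is correct and powerful *in this regime*, not that real
  recordings would yield any particular kappa or selected order.
- Syllable segmentation and feature extraction from audio are out of scope;
  the package consumes per-syllable feature tables.
- The second-order label test conditions only on the single most frequent
  predecessor (the quoted procedure); conditioning on every predecessor
  would be a different (more powerful, less comparable) test.
- No confidence intervals on kappa and no ANOVA-style across-bird
  inference; grids report means ± SD only.
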
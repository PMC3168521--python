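# songhmm

Hidden-Markov analysis of birdsong syllable syntax.

Bengalese finch song is a sequence of discrete syllables with *higher-order
context dependency*: which syllable comes next can depend on more than the
current syllable. For example, a syllable "b" may be followed by "d" with
probability 0.99 when preceded by "c", even though the context-free
transition probability from "b" to "d" is only ~0.55. Yet a **first-order**
hidden Markov chain can generate exactly such sequences if it is allowed
*redundant hidden states* with a many-to-one state→syllable map: two hidden
states can emit the same syllable while occupying different sequential
contexts. `songhmm` implements the full analysis chain needed to detect,
model, and evaluate this mechanism, for researchers in computational
ethology and behavioral sequence analysis.

## What it does

- **Synthetic song generation** (`songhmm.pomm`): partially observable
  Markov models (POMMs) — hidden-state chains with many-to-one
  state→syllable maps and 3-d Gaussian acoustic emissions per state
  (syllable duration [ms], mean pitch [Hz], mean Wiener entropy). An
  example grammar reproduces the context-split "b" syllable with
  P(d | b, preceded by c) = 0.99 and tunable acoustic overlap between
  context-separable states.
- **Context-dependency testing** (`songhmm.context`): candidate syllables
  (≥2 predecessors and ≥2 successors) are tested by a χ² goodness-of-fit
  between the successor distribution conditioned on the most frequent
  predecessor and the context-free successor distribution, Bonferroni
  corrected over candidates; plus bigram automata and POMM-representation
  graphs with context-split states.
- **VB hidden Markov models** (`songhmm.hmm`): Gaussian-emission HMMs of
  Markov order r ∈ {0, 1, 2} over per-syllable features, fitted by
  Variational Bayes with conjugate Dirichlet / Normal–Wishart priors. Order
  0 is exactly the Bayesian Gaussian mixture model; order 2 is handled by
  expanding state pairs into *context states* (K² + K of them, with a dummy
  start symbol), reducing it to a first-order chain. Every fit records the
  variational lower bound L on the log marginal likelihood ln p(Y | m).
- **Model selection** (`songhmm.selection`): grid search over (r, K),
  selection by argmax L (with a uniform model prior, the maximum-posterior
  model), cross-validated predictive log-likelihood on held-out bouts, and
  z-scored averaging of grids across birds.
- **Annotation and agreement** (`songhmm.annotate`, `songhmm.agreement`):
  per-syllable posterior decoding (Baum-Welch marginals), majority-vote
  alignment of states to reference labels, context-split counting, and
  Cohen's / Fleiss's kappa with the conventional qualitative bands.

## Worked example

```python
import songhmm as sh

# a simulated bird: 30 training bouts from the example grammar in which
# states distinguishable only by context have fully overlapping emissions
pomm = sh.example_song_pomm(overlap=1.0)
train = sh.sample_dataset(pomm, n_bouts=30, max_len=100, seed=100)

# 1. second-order context dependency in the label sequences
for r in sh.run_dependency_tests(train.label_sequences(), alpha=0.05):
    print(f"{r.syllable}: chi2={r.chi2:.1f} df={r.df} p={r.p_value:.3g} "
          f"significant={r.significant}")

# 2. fit a first-order HMM with redundant states and a context-blind GMM
for order in (0, 1):
    fit = sh.vb_fit(train, order=order, n_states=8, seed=10, n_restarts=5)
    ann = sh.annotate(fit, train)
    res = sh.cohen_kappa(ann.label_sequences, train.label_sequences())
    print(f"order {order}: L={fit.lower_bound:.1f} "
          f"kappa={res.kappa:.3f} ({res.band})")
```

Output:

```
a: chi2=2.5 df=2 p=0.28 significant=False
b: chi2=110.8 df=2 p=8.9e-25 significant=True
c: chi2=0.5 df=2 p=0.762 significant=False
d: chi2=0.3 df=1 p=0.585 significant=False
j: chi2=0.4 df=1 p=0.525 significant=False
order 0: L=-2979.7 kappa=0.753 (Substantial agreement)
order 1: L=-2279.3 kappa=0.964 (Almost perfect agreement)
```

Syllable "b" carries a strong second-order dependency — its successors
after the most frequent predecessor differ sharply from its context-free
successors — while the other four candidates do not approach the
Bonferroni-corrected threshold 0.05/5. The first-order HMM attains a much larger lower bound than the
mixture model and annotates the song in the "almost perfect" band, because
it uses redundant states to resolve syllables whose acoustics overlap but
whose sequential contexts differ — the mixture model, blind to context,
saturates at "substantial" agreement.

The same pipeline is scriptable from the shell:

```sh
songhmm run --seed 7 --out results/run7        # simulate → test → fit → report
songhmm simulate --n-bouts 30 --seed 1 --out song.tsv
songhmm fit --features song.tsv --order 1 --n-states 8
```

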
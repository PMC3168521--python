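"""Label-sequence analysis: transition counts, the second-order context-
dependency test, and POMM representations of syllable syntax.

The test asks, for each candidate syllable, whether the successor
distribution conditioned on the most frequent preceding syllable differs
from the successor distribution that ignores the preceding syllable — a
chi-square goodness-of-fit test with a Bonferroni correction over the number
of candidate syllables.  Candidates are syllables with at least two distinct
observed predecessors and at least two distinct observed successors.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "TransitionCounts",
    "DependencyTestResult",
    "LabelPOMM",
    "count_transitions",
    "find_candidates",
    "test_second_order",
    "run_dependency_tests",
    "build_pomm_representation",
    "bigram_automaton",
    "automaton_to_dot",
]


@dataclass
class TransitionCounts:
    """Within-bout n-gram counts over an ordered label alphabet.

    Counts never cross bout boundaries: the last syllable of a bout has no
    successor and the first has no predecessor.
    """

    unigram: Counter
    bigram: Counter
    trigram: Counter
    labels: tuple

    def successors(self, s, exclude=()):
        """Successor counts of ``s`` from bigrams, minus excluded labels."""
        return {y: n for (x, y), n in self.bigram.items() if x == s and y not in exclude and n > 0}

    def predecessors(self, s, exclude=()):
        return {x: n for (x, y), n in self.bigram.items() if y == s and x not in exclude and n > 0}

    def context_successors(self, pred, s, exclude=()):
        """Successor counts of ``s`` restricted to occurrences preceded by ``pred``."""
        return {
            z: n
            for (x, y, z), n in self.trigram.items()
            if x == pred and y == s and z not in exclude and n > 0
        }


def count_transitions(sequences) -> TransitionCounts:
    """Count unigrams, bigrams and trigrams within each bout.

    ``sequences`` is a collection of label sequences (one per bout); bouts
    are never concatenated.
    """
    sequences = [list(s) for s in sequences]
    if not sequences:
        raise ValueError("no label sequences given")
    uni, bi, tri = Counter(), Counter(), Counter()
    for seq in sequences:
        uni.update(seq)
        bi.update(zip(seq, seq[1:]))
        tri.update(zip(seq, seq[1:], seq[2:]))
    labels = tuple(sorted(uni))
    return TransitionCounts(uni, bi, tri, labels)


def find_candidates(counts: TransitionCounts, variant: str = "all") -> list:
    """Labels with >= 2 distinct predecessors and >= 2 distinct successors.

    ``variant="nonrepeat"`` removes self-transitions (predecessor or
    successor equal to the label itself) before the count, restricting the
    analysis to non-repeated syllables.  Order is deterministic
    (lexicographic over the alphabet).
    """
    _check_variant(variant)
    out = []
    for s in counts.labels:
        exclude = (s,) if variant == "nonrepeat" else ()
        if len(counts.predecessors(s, exclude)) >= 2 and len(counts.successors(s, exclude)) >= 2:
            out.append(s)
    return out


@dataclass
class DependencyTestResult:
    """Chi-square test of second-order context dependency for one syllable."""

    syllable: str
    conditioning_pred: str
    chi2: float
    df: int
    p_value: float
    n_candidates: int
    alpha: float
    significant: bool
    variant: str
    testable: bool = True
    n_pooled: int = 0


def _check_variant(variant):
    if variant not in ("all", "nonrepeat"):
        raise ValueError("variant must be 'all' or 'nonrepeat'")


def test_second_order(
    counts: TransitionCounts,
    syllable,
    alpha: float = 0.05,
    n_candidates: int = 1,
    variant: str = "all",
) -> DependencyTestResult:
    """Chi-square goodness-of-fit: context-conditioned vs marginal successors.

    Observed counts are the successors of ``syllable`` among its occurrences
    preceded by its most frequent predecessor; expected counts scale the
    marginal successor distribution (ignoring predecessors) to the same
    total.  Successor categories with expected count < 1 are pooled into a
    single residual category.  Significance uses the Bonferroni-corrected
    level ``alpha / n_candidates``.
    """
    _check_variant(variant)
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    exclude = (syllable,) if variant == "nonrepeat" else ()
    preds = counts.predecessors(syllable, exclude)
    if not preds:
        raise ValueError(f"{syllable!r} has no usable predecessors under variant {variant!r}")
    top = max(preds.values())
    tied = sorted(x for x, n in preds.items() if n == top)
    if len(tied) > 1:
        logger.info("tie for most frequent predecessor of %r among %s; using %r", syllable, tied, tied[0])
    pred = tied[0]

    marg = counts.successors(syllable, exclude)
    obs_map = counts.context_successors(pred, syllable, exclude)
    cats = sorted(marg)
    n_obs = sum(obs_map.get(y, 0) for y in cats)
    untestable = DependencyTestResult(
        syllable, pred, float("nan"), 0, float("nan"), n_candidates, alpha, False, variant, testable=False
    )
    if len(cats) < 2 or n_obs == 0:
        return untestable
    marg_tot = sum(marg.values())
    expected = np.array([n_obs * marg[y] / marg_tot for y in cats])
    observed = np.array([obs_map.get(y, 0) for y in cats], dtype=float)

    pool = expected < 1.0
    n_pooled = int(pool.sum())
    if n_pooled:
        observed = np.append(observed[~pool], observed[pool].sum())
        expected = np.append(expected[~pool], expected[pool].sum())
        keep = expected > 0
        observed, expected = observed[keep], expected[keep]
    if len(expected) < 2:
        untestable.n_pooled = n_pooled
        return untestable
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    df = len(expected) - 1
    p = float(stats.chi2.sf(chi2, df))
    return DependencyTestResult(
        syllable, pred, chi2, df, p, n_candidates, alpha,
        significant=p < alpha / n_candidates, variant=variant, n_pooled=n_pooled,
    )


def run_dependency_tests(sequences, alpha: float = 0.05, variant: str = "all"):
    """Candidate selection plus the per-syllable test with Bonferroni correction.

    Returns the list of :class:`DependencyTestResult`, one per candidate, with
    ``n_candidates`` equal to the number of candidates under this variant.
    """
    counts = count_transitions(sequences)
    cands = find_candidates(counts, variant)
    return [test_second_order(counts, s, alpha, max(len(cands), 1), variant) for s in cands]


# ---------------------------------------------------------------------------
# Graph representations
# ---------------------------------------------------------------------------

@dataclass
class LabelPOMM:
    """POMM-like graph estimated from label counts (no emissions).

    States are either plain labels or ``(label, predecessor)`` pairs for the
    context-split syllables; ``trans`` maps state -> {state: probability} and
    ``counts`` holds the underlying transition counts.
    """

    states: list
    label_map: dict
    trans: dict
    counts: dict

    def out_distribution(self, state) -> dict:
        return dict(self.trans.get(state, {}))


def build_pomm_representation(counts: TransitionCounts, significant) -> LabelPOMM:
    """Split each significant syllable into one state per observed predecessor.

    Transition probabilities out of split states are re-estimated from
    trigram counts (conditioned on the predecessor); unsplit states keep
    bigram estimates.  Target states are resolved to the split state
    ``(y, s)`` whenever the successor ``y`` is itself significant.
    """
    significant = set(significant)
    unknown = significant - set(counts.labels)
    if unknown:
        raise ValueError(f"significant labels not in alphabet: {sorted(unknown)}")

    def node_for(y, coming_from):
        return (y, coming_from) if y in significant else y

    states = []
    label_map = {}
    for s in counts.labels:
        if s in significant:
            for p in sorted(counts.predecessors(s)):
                states.append((s, p))
                label_map[(s, p)] = s
        else:
            states.append(s)
            label_map[s] = s

    trans, raw = {}, {}
    for st in states:
        if isinstance(st, tuple):
            s, p = st
            succ = counts.context_successors(p, s)
        else:
            s = st
            succ = counts.successors(s)
        agg = Counter()
        for y, n in succ.items():
            agg[node_for(y, s)] += n
        tot = sum(agg.values())
        raw[st] = dict(agg)
        trans[st] = {t: n / tot for t, n in agg.items()} if tot else {}
    return LabelPOMM(states, label_map, trans, raw)


def bigram_automaton(counts: TransitionCounts, prune_below: float = 0.0) -> list:
    """Edge list ``(from, to, prob, n)`` of the first-order label automaton.

    Rows are normalized before pruning; edges with probability below
    ``prune_below`` are omitted.
    """
    if not 0.0 <= prune_below < 1.0:
        raise ValueError("prune_below must lie in [0, 1)")
    edges = []
    for s in counts.labels:
        succ = counts.successors(s)
        tot = sum(succ.values())
        for y in sorted(succ):
            p = succ[y] / tot
            if p >= prune_below:
                edges.append((s, y, p, succ[y]))
    return edges


def automaton_to_dot(edges, name: str = "song") -> str:
    """Render an edge list as a GraphViz DOT digraph."""

    def fmt(node):
        return "_".join(map(str, node)) if isinstance(node, tuple) else str(node)

    lines = [f"digraph {name} {{", "  rankdir=LR;"]
    for frm, to, p, n in edges:
        lines.append(f'  "{fmt(frm)}" -> "{fmt(to)}" [label="{p:.2f}"];')
    lines.append("}")
    return "\n".join(lines)
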
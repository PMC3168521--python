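"""Model-based song annotation.

A fitted model labels each syllable with the hidden state of highest
marginal posterior; states are then aligned to reference labels by majority
vote over the positions they claim (many states may map to one syllable —
the many-to-one mapping that lets a first-order chain carry syllable
context).  The module also counts *context splits*: reference syllables with
significant second-order dependency that the model divided into states whose
predecessor distributions differ.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .hmm import VBHMMResults
from .pomm import SongDataset

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationResult",
    "UNASSIGNED",
    "decode_states",
    "align_labels",
    "annotate",
    "annotation_accuracy",
    "count_context_splits",
]

#: Sentinel label for states that claimed no syllable.
UNASSIGNED = "unassigned"


@dataclass
class AnnotationResult:
    """Decoded states, aligned labels and occupancy for one dataset."""

    state_sequences: list      # per bout, list of state indices
    label_sequences: list      # per bout, list of aligned labels
    alignment: dict            # state index -> reference label
    occupancy: Counter         # state index -> positions claimed

    def to_json(self, path) -> None:
        obj = {
            "alignment": {str(k): v for k, v in sorted(self.alignment.items())},
            "occupancy": {str(k): v for k, v in sorted(self.occupancy.items())},
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1, sort_keys=True)


def decode_states(fit: VBHMMResults, data: SongDataset, method: str = "posterior") -> list:
    """Per-bout state sequences (marginal-posterior decoding by default)."""
    return fit.decode(data, method=method)


def align_labels(decoded, reference) -> dict:
    """Map each state to the reference label most frequent at its positions.

    Many-to-one is allowed; ties are broken lexicographically (and logged);
    states decoding nothing map to :data:`UNASSIGNED`.
    """
    votes = {}
    states_seen = set()
    for dec, ref in zip(decoded, reference, strict=True):
        if len(dec) != len(ref):
            raise ValueError("decoded and reference bout lengths differ")
        for s, lab in zip(dec, ref):
            states_seen.add(s)
            votes.setdefault(s, Counter())[str(lab)] += 1
    alignment = {}
    for s in sorted(states_seen):
        cnt = votes[s]
        top = max(cnt.values())
        tied = sorted(lab for lab, n in cnt.items() if n == top)
        if len(tied) > 1:
            logger.info("alignment tie for state %s among %s; using %r", s, tied, tied[0])
        alignment[s] = tied[0]
    return alignment


def annotate(fit: VBHMMResults, data: SongDataset, reference=None,
             method: str = "posterior") -> AnnotationResult:
    """Decode ``data`` and align states against ``reference`` label sequences.

    ``reference`` defaults to the dataset's own labels.  States with zero
    occupancy (never the argmax anywhere) are mapped to :data:`UNASSIGNED`.
    """
    if reference is None:
        reference = data.label_sequences()
    decoded = decode_states(fit, data, method=method)
    alignment = align_labels(decoded, reference)
    for s in range(fit.n_states):
        alignment.setdefault(s, UNASSIGNED)
    occupancy = Counter(s for seq in decoded for s in seq)
    labels = [[alignment[s] for s in seq] for seq in decoded]
    return AnnotationResult(decoded, labels, alignment, occupancy)


def annotation_accuracy(annotation: AnnotationResult, reference) -> float:
    """Fraction of syllables whose aligned model label matches the reference."""
    hit = tot = 0
    for lab, ref in zip(annotation.label_sequences, reference, strict=True):
        for a, b in zip(lab, ref, strict=True):
            hit += a == str(b)
            tot += 1
    return hit / tot


def count_context_splits(
    annotation: AnnotationResult,
    reference,
    significant,
    alpha: float = 0.05,
) -> int:
    """Number of significant syllables the model split by preceding context.

    A syllable counts when (i) at least two occupied states align to it and
    (ii) a chi-square test on the states x predecessor-label contingency
    table (bout-initial positions excluded) rejects homogeneity at
    ``alpha``.  This operationalizes "divided into distinct states according
    to the preceding syllables".
    """
    n_split = 0
    for syl in significant:
        syl = str(syl)
        states = sorted(
            s for s, lab in annotation.alignment.items()
            if lab == syl and annotation.occupancy.get(s, 0) > 0
        )
        if len(states) < 2:
            continue
        table = {s: Counter() for s in states}
        for dec, ref in zip(annotation.state_sequences, reference, strict=True):
            for t in range(1, len(ref)):
                if str(ref[t]) == syl and dec[t] in table:
                    table[dec[t]][str(ref[t - 1])] += 1
        preds = sorted({p for cnt in table.values() for p in cnt})
        mat = np.array([[table[s].get(p, 0) for p in preds] for s in states])
        mat = mat[mat.sum(axis=1) > 0]
        mat = mat[:, mat.sum(axis=0) > 0]
        if mat.shape[0] < 2 or mat.shape[1] < 2:
            continue
        _, p, _, _ = stats.chi2_contingency(mat, correction=False)
        if p < alpha:
            n_split += 1
    return n_split
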
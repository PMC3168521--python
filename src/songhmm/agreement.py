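"""Inter-annotator agreement for categorical syllable labels.

Cohen's kappa scores two annotators and Fleiss's kappa three or more; both
correct raw percent agreement for agreement expected by chance.  Scores map
onto the conventional qualitative bands (``Almost perfect`` down to
``Poor``).  Items are individual syllables pooled over bouts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import cohen_kappa_score
from statsmodels.stats import inter_rater

logger = logging.getLogger(__name__)

__all__ = ["AgreementResult", "BANDS", "cohen_kappa", "fleiss_kappa", "interpret_kappa"]

#: Interpretation bands: closed on the left, open on the right, except the
#: top band [0.81, 1.00] which is closed on both ends; negative kappa is
#: "Poor agreement".
BANDS = (
    (0.81, "Almost perfect agreement"),
    (0.61, "Substantial agreement"),
    (0.41, "Moderate agreement"),
    (0.21, "Fair agreement"),
    (0.0, "Slight agreement"),
)


@dataclass
class AgreementResult:
    """A kappa score with its qualitative band and problem size."""

    kappa: float
    band: str
    n_items: int
    n_categories: int

    def __float__(self):
        return self.kappa


def interpret_kappa(kappa: float) -> str:
    """Qualitative band for a kappa value (see :data:`BANDS`)."""
    if kappa > 1.0 + 1e-12:
        raise ValueError("kappa cannot exceed 1")
    if kappa < 0.0:
        return "Poor agreement"
    for lo, band in BANDS:
        if kappa >= lo:
            return band
    return "Slight agreement"


def _flatten(sequences):
    if sequences and not isinstance(sequences[0], (list, tuple, np.ndarray)):
        sequences = [sequences]
    return [str(x) for seq in sequences for x in seq]


def cohen_kappa(a, b) -> AgreementResult:
    """Cohen's kappa between two annotations of the same syllables.

    ``a`` and ``b`` are label sequences (or lists of per-bout sequences);
    items are pooled over bouts.  kappa = (p_o - p_e) / (1 - p_e) with p_e
    from the product of the two annotators' marginals.  If both annotators
    are constant and identical, chance agreement is 1 and kappa is defined
    as 1 (with a warning).
    """
    xa, xb = _flatten(a), _flatten(b)
    if len(xa) != len(xb):
        raise ValueError("annotations must cover the same number of items")
    if not xa:
        raise ValueError("no items to compare")
    cats = sorted(set(xa) | set(xb))
    if len(cats) == 1:
        logger.warning("both annotators constant; chance agreement is 1, kappa defined as 1")
        return AgreementResult(1.0, interpret_kappa(1.0), len(xa), 1)
    kappa = float(cohen_kappa_score(xa, xb, labels=cats))
    return AgreementResult(kappa, interpret_kappa(kappa), len(xa), len(cats))


def fleiss_kappa(annotations) -> AgreementResult:
    """Fleiss's kappa across two or more annotators of the same syllables.

    ``annotations`` is a list with one entry per annotator, each a label
    sequence or list of per-bout sequences.
    """
    if len(annotations) < 2:
        raise ValueError("Fleiss's kappa needs at least two raters")
    flat = [_flatten(a) for a in annotations]
    n = len(flat[0])
    if any(len(f) != n for f in flat):
        raise ValueError("all annotators must label the same items")
    if n == 0:
        raise ValueError("no items to compare")
    items = np.array(flat).T  # (items, raters)
    cats = sorted(set(items.ravel()))
    if len(cats) == 1:
        logger.warning("all raters constant; chance agreement is 1, kappa defined as 1")
        return AgreementResult(1.0, interpret_kappa(1.0), n, 1)
    table, _ = inter_rater.aggregate_raters(items, n_cat=None)
    kappa = float(inter_rater.fleiss_kappa(table, method="fleiss"))
    if np.isnan(kappa) and all(len(set(row)) == 1 for row in items):
        kappa = 1.0
    return AgreementResult(kappa, interpret_kappa(kappa), n, len(cats))
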
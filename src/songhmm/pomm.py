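"""Partially observable Markov models (POMMs) of song syntax and synthetic data.

A POMM is a Markov chain over hidden states together with a many-to-one map
from states to syllable labels, so that two different states may emit the
same syllable.  This is the mechanism by which a first-order chain produces
label sequences with higher-order context dependency: the split states carry
the context that the label alone hides.

The module provides

* :class:`POMMSpec` — a validated generative model with per-state Gaussian
  emissions over the three acoustic features (syllable duration in ms, mean
  pitch in Hz, mean Wiener entropy, dimensionless),
* :func:`example_song_pomm` — a six-state Bengalese-finch-like grammar with a
  context-split "b" syllable whose conditional transition to "d" is 0.99,
* :func:`null_label_chain` — a strictly first-order label chain (no hidden
  context), used as the null model in type-I-error studies,
* :func:`dense_second_order_pomm` — a genuinely second-order label process
  expressed as a POMM over label-pair states,
* :func:`sample_dataset` — seeded bout sampling, and TSV/JSON round-trip I/O.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "POMMSpec",
    "Bout",
    "SongDataset",
    "POMMValidationError",
    "FeatureTableError",
    "example_song_pomm",
    "null_label_chain",
    "dense_second_order_pomm",
    "sample_dataset",
    "write_feature_table",
    "read_feature_table",
    "write_label_file",
    "read_label_file",
]

FEATURE_NAMES = ("duration_ms", "pitch_hz", "wiener_entropy")
FEATURE_DIM = 3

_PROB_ATOL = 1e-12


class POMMValidationError(ValueError):
    """A POMMSpec invariant is violated; the message names the invariant."""


class FeatureTableError(ValueError):
    """A feature table could not be parsed; the message names the line."""


@dataclass(frozen=True)
class POMMSpec:
    """Generative partially observable Markov model.

    Parameters
    ----------
    state_ids
        Opaque state identifiers (order fixes the matrix indexing).
    label_map
        state id -> syllable label; many-to-one allowed.
    initial
        Probability vector over states, length ``len(state_ids)``.
    trans
        Row ``i`` holds P(next state | current state i); together with
        ``end_prob[i]`` each row sums to 1.
    end_prob
        Per-state probability of terminating the bout after emitting.
    emissions
        state id -> (mean 3-vector, 3x3 SPD covariance) in feature units.
    """

    state_ids: tuple
    label_map: dict
    initial: np.ndarray
    trans: np.ndarray
    end_prob: np.ndarray
    emissions: dict

    def __post_init__(self):
        object.__setattr__(self, "initial", np.asarray(self.initial, dtype=float))
        object.__setattr__(self, "trans", np.asarray(self.trans, dtype=float))
        object.__setattr__(self, "end_prob", np.asarray(self.end_prob, dtype=float))
        self.validate()

    @property
    def n_states(self) -> int:
        return len(self.state_ids)

    @property
    def labels(self) -> tuple:
        return tuple(sorted({self.label_map[s] for s in self.state_ids}))

    def validate(self) -> None:
        n = self.n_states
        if self.trans.shape != (n, n):
            raise POMMValidationError(f"trans must be {n}x{n}, got {self.trans.shape}")
        if self.initial.shape != (n,) or self.end_prob.shape != (n,):
            raise POMMValidationError("initial and end_prob must have one entry per state")
        for arr, name in ((self.initial, "initial"), (self.trans, "trans"), (self.end_prob, "end_prob")):
            if np.any(arr < -_PROB_ATOL) or np.any(arr > 1 + _PROB_ATOL):
                raise POMMValidationError(f"{name} has probabilities outside [0, 1]")
        if abs(self.initial.sum() - 1.0) > _PROB_ATOL:
            raise POMMValidationError("initial distribution does not sum to 1")
        row_tot = self.trans.sum(axis=1) + self.end_prob
        bad = np.where(np.abs(row_tot - 1.0) > _PROB_ATOL)[0]
        if bad.size:
            raise POMMValidationError(
                f"trans row {self.state_ids[bad[0]]} plus end_prob sums to {row_tot[bad[0]]!r}, not 1"
            )
        if set(self.label_map) != set(self.state_ids):
            raise POMMValidationError("label_map must cover exactly the state ids")
        for sid in self.state_ids:
            mean, cov = self.emissions[sid]
            mean = np.asarray(mean, float)
            cov = np.asarray(cov, float)
            if mean.shape != (FEATURE_DIM,):
                raise POMMValidationError(f"emission mean of {sid} is not a 3-vector")
            if cov.shape != (FEATURE_DIM, FEATURE_DIM) or not np.allclose(cov, cov.T):
                raise POMMValidationError(f"emission covariance of {sid} is not symmetric 3x3")
            try:
                np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                raise POMMValidationError(f"emission covariance of {sid} is not positive definite")

    # ---- serialization ------------------------------------------------

    def to_json(self, path) -> None:
        obj = {
            "state_ids": list(self.state_ids),
            "label_map": {str(s): self.label_map[s] for s in self.state_ids},
            "initial": self.initial.tolist(),
            "trans": self.trans.tolist(),
            "end_prob": self.end_prob.tolist(),
            "emissions": {
                str(s): {
                    "mean": np.asarray(self.emissions[s][0], float).tolist(),
                    "cov": np.asarray(self.emissions[s][1], float).tolist(),
                }
                for s in self.state_ids
            },
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "POMMSpec":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            state_ids=tuple(obj["state_ids"]),
            label_map={s: obj["label_map"][str(s)] for s in obj["state_ids"]},
            initial=np.array(obj["initial"]),
            trans=np.array(obj["trans"]),
            end_prob=np.array(obj["end_prob"]),
            emissions={
                s: (np.array(obj["emissions"][str(s)]["mean"]), np.array(obj["emissions"][str(s)]["cov"]))
                for s in obj["state_ids"]
            },
        )


@dataclass
class Bout:
    """One song bout: aligned features, labels and (if synthetic) true states."""

    features: np.ndarray  # (T, 3)
    labels: list
    states: list | None = None

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2 or self.features.shape[1] != FEATURE_DIM:
            raise ValueError("features must be a (T, 3) array")
        if len(self.labels) != len(self.features):
            raise ValueError("labels and features must have equal length")
        if self.states is not None and len(self.states) != len(self.features):
            raise ValueError("states and features must have equal length")
        if len(self.features) < 1:
            raise ValueError("a bout must contain at least one syllable")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features must be finite")

    def __len__(self):
        return len(self.labels)


@dataclass
class SongDataset:
    """An ordered collection of bouts from one bird."""

    bouts: list
    bird_id: str = "bird00"
    role: str = "train"

    def __len__(self):
        return len(self.bouts)

    def __iter__(self):
        return iter(self.bouts)

    @property
    def n_syllables(self) -> int:
        return sum(len(b) for b in self.bouts)

    def label_sequences(self) -> list:
        return [list(b.labels) for b in self.bouts]

    def state_sequences(self) -> list:
        return [list(b.states) for b in self.bouts]

    def stacked_features(self) -> np.ndarray:
        return np.concatenate([b.features for b in self.bouts], axis=0)

    def subset(self, idx, role=None) -> "SongDataset":
        return SongDataset([self.bouts[i] for i in idx], self.bird_id, role or self.role)


# ---------------------------------------------------------------------------
# Example grammars
# ---------------------------------------------------------------------------

#: Per-label base emission means in feature units (duration ms, pitch Hz,
#: Wiener entropy).  Scales mimic Bengalese finch syllables; downstream
#: fitting z-scores features so the absolute scale is inert.
_BASE_MEANS = {
    "a": np.array([60.0, 4500.0, -1.5]),
    "b": np.array([120.0, 3000.0, -2.5]),
    "c": np.array([90.0, 5000.0, -2.0]),
    "d": np.array([150.0, 2500.0, -3.0]),
    "j": np.array([70.0, 5500.0, -1.2]),
}

#: Common within-state covariance (diagonal; sd 8 ms, 150 Hz, 0.15).
_BASE_COV = np.diag([8.0**2, 150.0**2, 0.15**2])

#: Mahalanobis distance between the means of the two "b" context states at
#: overlap=0 (the documented maximum separation).
MAX_SPLIT_SEPARATION = 6.0

#: Cross-label state pairs whose emission means converge as overlap -> 1.
#: These are states whose identity is recoverable from sequential context,
#: emulating the overlapping feature-space clusters seen in real song; at
#: overlap=0 every state is well separated.
CONFUSABLE_PAIRS = (("a", "d"),)


def example_song_pomm(overlap: float = 0.5) -> POMMSpec:
    """Six-state POMM for a Bengalese-finch-like song with a context-split "b".

    The grammar contains two hidden states for syllable "b": ``b_a`` (entered
    after "a") and ``b_c`` (entered after "c").  From ``b_c`` the next
    syllable is "d" with probability 0.99, while collapsing over context the
    successor distribution of "b" is approximately a=0.13, d=0.55, c=0.31.
    The chunks "bcbd" (via a→b_a→c→b_c→d) and "jcd" (via j→c→d) are
    high-probability paths.

    Parameters
    ----------
    overlap : float in [0, 1]
        Acoustic convergence of context-separable states.  At 0 all states
        have well-separated emission means (the b_a/b_c means sit a
        Mahalanobis distance of :data:`MAX_SPLIT_SEPARATION` apart); at 1 the
        b_a/b_c means are identical and the confusable cross-label pairs
        (c,j) and (a,d) share identical emission distributions, so states are
        distinguishable only through sequential context.
    """
    if not 0.0 <= overlap <= 1.0:
        raise ValueError("overlap must lie in [0, 1]")
    states = ("a", "b_a", "b_c", "c", "d", "j")
    label_map = {"a": "a", "b_a": "b", "b_c": "b", "c": "c", "d": "d", "j": "j"}
    idx = {s: i for i, s in enumerate(states)}
    n = len(states)
    trans = np.zeros((n, n))
    end_prob = np.zeros(n)

    def row(s, end=0.0, **to):
        for t, p in to.items():
            trans[idx[s], idx[t]] = p
        end_prob[idx[s]] = end

    # Documented default transition structure; only the 0.99 conditional is
    # anchored, the rest is chosen so the collapsed successor row of "b"
    # approximates a=0.13, d=0.55, c=0.31.
    row("a", a=0.50, b_a=0.45, j=0.05)
    row("b_a", a=0.26, c=0.63, d=0.11)
    row("b_c", a=0.005, c=0.005, d=0.99)
    row("c", b_c=0.55, d=0.30, a=0.15)
    row("d", j=0.75, a=0.17, end=0.08)
    row("j", c=0.93, j=0.05, end=0.02)
    initial = np.zeros(n)
    initial[idx["a"]] = 0.7
    initial[idx["j"]] = 0.3

    sep = 1.0 - overlap
    chol = np.linalg.cholesky(_BASE_COV)
    # unit direction in the Mahalanobis metric along which split means move
    u = np.array([1.0, -1.0, 1.0]) / np.sqrt(3.0)
    offset = chol @ u * (MAX_SPLIT_SEPARATION / 2.0) * sep

    emissions = {s: (_BASE_MEANS[label_map[s]].copy(), _BASE_COV.copy()) for s in states}
    emissions["b_a"] = (_BASE_MEANS["b"] - offset, _BASE_COV.copy())
    emissions["b_c"] = (_BASE_MEANS["b"] + offset, _BASE_COV.copy())
    for x, y in CONFUSABLE_PAIRS:
        mid = 0.5 * (_BASE_MEANS[x] + _BASE_MEANS[y])
        emissions[x] = (mid + sep * (_BASE_MEANS[x] - mid), _BASE_COV.copy())
        emissions[y] = (mid + sep * (_BASE_MEANS[y] - mid), _BASE_COV.copy())
    return POMMSpec(states, label_map, initial, trans, end_prob, emissions)


def null_label_chain() -> POMMSpec:
    """Strictly first-order label chain (one state per label, no hidden context).

    The successor row of "b" is the context-collapsed marginal
    a=0.13, d=0.55, c=0.32 (renormalized to machine precision); the other
    rows are the example grammar's rows with the "b" context states merged.
    Sequences from this chain have, by construction, no second-order
    dependency, which makes it the null model for the dependency test's
    family-wise error studies.
    """
    states = ("a", "b", "c", "d", "j")
    idx = {s: i for i, s in enumerate(states)}
    n = len(states)
    trans = np.zeros((n, n))
    end_prob = np.zeros(n)
    rows = {
        "a": {"a": 0.50, "b": 0.45, "j": 0.05},
        "b": {"a": 0.13, "d": 0.55, "c": 0.32},
        "c": {"b": 0.55, "d": 0.30, "a": 0.15},
        "d": {"j": 0.75, "a": 0.17},
        "j": {"c": 0.93, "j": 0.05},
    }
    ends = {"d": 0.08, "j": 0.02}
    for s, to in rows.items():
        for t, p in to.items():
            trans[idx[s], idx[t]] = p
        end_prob[idx[s]] = ends.get(s, 0.0)
    initial = np.zeros(n)
    initial[idx["a"]] = 0.7
    initial[idx["j"]] = 0.3
    emissions = {s: (_BASE_MEANS[s], _BASE_COV.copy()) for s in states}
    return POMMSpec(states, {s: s for s in states}, initial, trans, end_prob, emissions)


def stereotyped_chain_pomm(
    n_states: int = 5,
    advance: float = 0.93,
    skip: float = 0.05,
    end_prob: float = 0.02,
    mean_scale: float = 6.0,
) -> POMMSpec:
    """Stereotyped first-order chain: state i advances to i+1, rarely skips.

    Mimics the near-deterministic motif structure of stereotyped song: each
    state moves to the next (mod ``n_states``) with probability ``advance``,
    skips one ahead with ``skip``, and ends the bout with ``end_prob``
    (defaults give a mean bout length of 50 syllables).  One state per
    label, well-separated Gaussian emissions.  This is the ground-truth
    model for transition-recovery experiments, where near-0/1 rows keep the
    sampling error of count-based estimates small.
    """
    if abs(advance + skip + end_prob - 1.0) > 1e-9:
        raise ValueError("advance + skip + end_prob must sum to 1")
    K = int(n_states)
    labels = [chr(ord("a") + i) for i in range(K)]
    trans = np.zeros((K, K))
    for i in range(K):
        trans[i, (i + 1) % K] = advance
        trans[i, (i + 2) % K] = skip
    ends = np.full(K, end_prob)
    initial = np.full(K, 1.0 / K)
    chol = np.linalg.cholesky(_BASE_COV)
    emissions = {}
    for i, lab in enumerate(labels):
        z = np.zeros(FEATURE_DIM)
        z[i % FEATURE_DIM] = mean_scale * (1 + i // FEATURE_DIM)
        emissions[lab] = (_BASE_MEANS["b"] + chol @ z, _BASE_COV.copy())
    return POMMSpec(tuple(labels), {l: l for l in labels}, initial, trans, ends, emissions)


def dense_second_order_pomm(
    n_labels: int = 4,
    seed: int = 0,
    concentration: float = 0.5,
    end_prob: float = 0.02,
    mean_scale: float = 6.0,
) -> POMMSpec:
    """Genuinely second-order label process as a POMM over label-pair states.

    Every trigram row P(next | prev, cur) is an independent Dirichlet draw,
    so no first-order chain over ``n_labels`` states can represent the
    sequence law.  The POMM has one state per ordered label pair
    ``(prev, cur)`` emitting ``cur``; emissions are shared by label and well
    separated (means on a scaled simplex, unit covariance in z-units scaled
    into feature units).
    """
    rng = np.random.default_rng(seed)
    labels = [chr(ord("a") + i) for i in range(n_labels)]
    states = tuple((p, c) for p in labels for c in labels)
    idx = {s: i for i, s in enumerate(states)}
    n = len(states)
    trans = np.zeros((n, n))
    for (p, c) in states:
        row = rng.dirichlet(np.full(n_labels, concentration))
        for k, nxt in enumerate(labels):
            trans[idx[(p, c)], idx[(c, nxt)]] = row[k] * (1.0 - end_prob)
    ends = np.full(n, end_prob)
    # initial: uniform over current label, entered through a uniform dummy prev
    initial = np.zeros(n)
    first = rng.dirichlet(np.full(n_labels, 1.0))
    for k, c in enumerate(labels):
        w = first[k] / n_labels
        for p in labels:
            initial[idx[(p, c)]] = w
    chol = np.linalg.cholesky(_BASE_COV)
    means = {}
    for k, lab in enumerate(labels):
        direction = np.zeros(FEATURE_DIM)
        direction[k % FEATURE_DIM] = 1.0
        z = direction * mean_scale * (1 + k // FEATURE_DIM)
        means[lab] = _BASE_MEANS["b"] + chol @ z
    emissions = {s: (means[s[1]], _BASE_COV.copy()) for s in states}
    label_map = {s: s[1] for s in states}
    return POMMSpec(states, label_map, initial, trans, ends, emissions)


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def sample_dataset(
    pomm: POMMSpec,
    n_bouts: int,
    max_len: int = 100,
    seed: int = 0,
    bird_id: str = "bird00",
    role: str = "train",
) -> SongDataset:
    """Sample bouts state-by-state from a POMM; identical seed, identical data.

    Each bout starts from ``pomm.initial``, follows ``pomm.trans`` and stops
    with probability ``end_prob`` after each syllable, truncated at
    ``max_len``.  Acoustic features are drawn from the occupied state's
    Gaussian and labels come from ``label_map``.
    """
    pomm.validate()
    if n_bouts < 1:
        raise ValueError("n_bouts must be >= 1")
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    rng = np.random.default_rng(seed)
    n = pomm.n_states
    chols = {s: np.linalg.cholesky(np.asarray(pomm.emissions[s][1], float)) for s in pomm.state_ids}
    means = {s: np.asarray(pomm.emissions[s][0], float) for s in pomm.state_ids}
    bouts = []
    for _ in range(n_bouts):
        states = []
        cur = rng.choice(n, p=pomm.initial)
        while True:
            states.append(cur)
            if len(states) >= max_len:
                break
            if rng.random() < pomm.end_prob[cur]:
                break
            cont = pomm.trans[cur]
            tot = cont.sum()
            if tot <= 0:
                break
            cur = rng.choice(n, p=cont / tot)
        sids = [pomm.state_ids[i] for i in states]
        feats = np.empty((len(sids), FEATURE_DIM))
        for t, s in enumerate(sids):
            feats[t] = means[s] + chols[s] @ rng.standard_normal(FEATURE_DIM)
        bouts.append(Bout(feats, [pomm.label_map[s] for s in sids], sids))
    return SongDataset(bouts, bird_id=bird_id, role=role)


# ---------------------------------------------------------------------------
# Feature-table and label-file I/O
# ---------------------------------------------------------------------------

_HEADER = ["bird_id", "bout_id", "pos", "label", "duration_ms", "pitch_hz", "wiener_entropy"]


def write_feature_table(dataset: SongDataset, path) -> None:
    """Write a dataset as the canonical TSV (one row per syllable).

    Columns: ``bird_id bout_id pos label duration_ms pitch_hz
    wiener_entropy``; ``pos`` is 0-based within bout; a missing label is
    written as ".".  True state sequences are not persisted.
    """
    rows = []
    for b_id, bout in enumerate(dataset.bouts):
        for pos in range(len(bout)):
            lab = bout.labels[pos]
            rows.append(
                (
                    dataset.bird_id,
                    b_id,
                    pos,
                    "." if lab is None else str(lab),
                    repr(float(bout.features[pos, 0])),
                    repr(float(bout.features[pos, 1])),
                    repr(float(bout.features[pos, 2])),
                )
            )
    df = pd.DataFrame(rows, columns=_HEADER)
    df.to_csv(path, sep="\t", index=False)


def read_feature_table(path) -> SongDataset:
    """Read a feature-table TSV back into a :class:`SongDataset`.

    Raises :class:`FeatureTableError` naming the 1-based line of the first
    malformed row.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].split("\t") != _HEADER:
        raise FeatureTableError("line 1: missing or malformed header")
    records = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != len(_HEADER):
            raise FeatureTableError(f"line {lineno}: expected {len(_HEADER)} fields, got {len(parts)}")
        bird, bout_id, pos, label, *feats = parts
        try:
            bout_id = int(bout_id)
            pos = int(pos)
            feats = [float(x) for x in feats]
        except ValueError as exc:
            raise FeatureTableError(f"line {lineno}: {exc}") from None
        records.append((bird, bout_id, pos, None if label == "." else label, feats))
    if not records:
        return SongDataset([], bird_id="bird00")
    bird_id = records[0][0]
    bouts = {}
    for bird, bout_id, pos, label, feats in records:
        bouts.setdefault(bout_id, []).append((pos, label, feats))
    out = []
    for bout_id in sorted(bouts):
        rows = sorted(bouts[bout_id])
        out.append(Bout(np.array([r[2] for r in rows]), [r[1] for r in rows]))
    return SongDataset(out, bird_id=bird_id)


def write_label_file(sequences, path) -> None:
    """Write label sequences, one bout per line, whitespace-separated."""
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(" ".join(str(s) for s in seq) + "\n")


def read_label_file(path) -> list:
    """Read a label file (one bout per line, whitespace-separated labels)."""
    with open(path) as fh:
        return [line.split() for line in fh if line.strip()]
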
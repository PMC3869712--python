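"""Back-propagation neural-network species assignment.

A single-hidden-layer sigmoid network trained with per-sample stochastic
gradient descent plus momentum on one-hot encoded alignment columns.
The reference/query split is stratified by species at a ~1:1 ratio.
All randomness flows through an explicit seed.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import AnalysisError, BarcodekitError
from .seqio import Alignment, BarcodeRecord

_ONEHOT = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class BpConfig:
    learning_rate: float = 0.2
    momentum: float = 0.5
    training_goal: float = 1e-5
    max_epochs: int = 50_000
    hidden_units: int = 20
    seed: int = 0
    confidence_cutoff: float = 0.95

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise BarcodekitError("learning_rate must be > 0")
        if not (0 <= self.momentum < 1):
            raise BarcodekitError("momentum must lie in [0, 1)")
        if self.training_goal <= 0:
            raise BarcodekitError("training_goal must be > 0")


@dataclass
class BpModel:
    w_hidden: np.ndarray  # (n_features, hidden)
    b_hidden: np.ndarray
    w_out: np.ndarray  # (hidden, n_species)
    b_out: np.ndarray
    species_order: tuple[str, ...]
    loss_trace: list[float]
    converged: bool
    config: BpConfig

    @property
    def n_features(self) -> int:
        return self.w_hidden.shape[0]


@dataclass(frozen=True)
class BpPrediction:
    query_id: str
    true_species: str
    predicted_species: str
    confidence: float
    low_confidence: bool

    @property
    def correct(self) -> bool:
        return self.predicted_species == self.true_species


def encode(aln: Alignment) -> np.ndarray:
    """One-of-four indicator per column; gaps/ambiguities -> all-zero."""
    X = np.zeros((len(aln), 4 * aln.length), dtype=float)
    for i, rec in enumerate(aln.records):
        for j, c in enumerate(rec.sequence):
            k = _ONEHOT.get(c)
            if k is not None:
                X[i, 4 * j + k] = 1.0
    return X


def split_reference_query(
    aln: Alignment, seed: int = 0, ratio: float = 0.5
) -> tuple[Alignment, Alignment, tuple[str, ...]]:
    """Stratified reference/query split (default ~1:1).

    Per species, ceil(n * ratio) sequences go to the reference (at least one
    stays in each set).  Species with a single sequence cannot seed both
    sets and are excluded; their ids are returned alongside the two
    alignments.
    """
    if not (0 < ratio < 1):
        raise BarcodekitError("ratio must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    by_species: dict[str, list[BarcodeRecord]] = {}
    for rec in aln.records:
        by_species.setdefault(rec.species, []).append(rec)
    reference, query, excluded = [], [], []
    for sp in sorted(by_species):
        recs = by_species[sp]
        if len(recs) < 2:
            excluded.extend(r.seq_id for r in recs)
            continue
        order = rng.permutation(len(recs))
        n_ref = min(max(math.ceil(len(recs) * ratio), 1), len(recs) - 1)
        for k, idx in enumerate(order):
            (reference if k < n_ref else query).append(recs[idx])
    if not reference or not query:
        raise AnalysisError("split produced an empty reference or query set")
    return (
        Alignment.from_records(reference),
        Alignment.from_records(query),
        tuple(excluded),
    )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def train(reference: Alignment, cfg: BpConfig = BpConfig()) -> BpModel:
    """Train the classifier on a reference alignment.

    One-hot species targets, mean-squared-error objective; per-sample SGD
    with momentum, stopping at MSE <= training_goal or at max_epochs
    (returning the model with ``converged=False`` in the latter case).
    """
    species_order = tuple(sorted({r.species for r in reference.records}))
    if len(species_order) < 2:
        raise AnalysisError("training needs at least 2 species in the reference set")
    X = encode(reference)
    idx = {sp: k for k, sp in enumerate(species_order)}
    Y = np.zeros((len(reference), len(species_order)))
    for i, rec in enumerate(reference.records):
        Y[i, idx[rec.species]] = 1.0

    rng = np.random.default_rng(cfg.seed)
    n_feat, n_hidden, n_out = X.shape[1], cfg.hidden_units, len(species_order)
    w1 = rng.normal(0.0, 1.0 / math.sqrt(n_feat), size=(n_feat, n_hidden))
    b1 = np.zeros(n_hidden)
    w2 = rng.normal(0.0, 1.0 / math.sqrt(n_hidden), size=(n_hidden, n_out))
    b2 = np.zeros(n_out)
    v_w1 = np.zeros_like(w1)
    v_b1 = np.zeros_like(b1)
    v_w2 = np.zeros_like(w2)
    v_b2 = np.zeros_like(b2)

    lr, mom = cfg.learning_rate, cfg.momentum
    trace: list[float] = []
    converged = False
    for _epoch in range(cfg.max_epochs):
        for i in rng.permutation(X.shape[0]):
            x, y = X[i], Y[i]
            h = _sigmoid(x @ w1 + b1)
            o = _sigmoid(h @ w2 + b2)
            delta_o = (o - y) * o * (1.0 - o)
            delta_h = (w2 @ delta_o) * h * (1.0 - h)
            v_w2 = mom * v_w2 - lr * np.outer(h, delta_o)
            v_b2 = mom * v_b2 - lr * delta_o
            v_w1 = mom * v_w1 - lr * np.outer(x, delta_h)
            v_b1 = mom * v_b1 - lr * delta_h
            w2 += v_w2
            b2 += v_b2
            w1 += v_w1
            b1 += v_b1
        H = _sigmoid(X @ w1 + b1)
        O = _sigmoid(H @ w2 + b2)
        mse = float(np.mean((O - Y) ** 2))
        trace.append(mse)
        if mse <= cfg.training_goal:
            converged = True
            break
    if not converged:
        import warnings

        warnings.warn(
            f"training did not reach goal {cfg.training_goal} "
            f"within {cfg.max_epochs} epochs (final MSE {trace[-1]:.3g})"
        )
    return BpModel(
        w_hidden=w1, b_hidden=b1, w_out=w2, b_out=b2,
        species_order=species_order, loss_trace=trace,
        converged=converged, config=cfg,
    )


def classify(
    model: BpModel, query: Alignment
) -> tuple[list[BpPrediction], float]:
    """Winner-take-all prediction for each query plus the success rate.

    Low-confidence correct predictions still count as correct in the
    success rate.
    """
    X = encode(query)
    if X.shape[1] != model.n_features:
        raise AnalysisError(
            f"query encoding width {X.shape[1]} != model width {model.n_features}"
        )
    H = _sigmoid(X @ model.w_hidden + model.b_hidden)
    O = _sigmoid(H @ model.w_out + model.b_out)
    cutoff = model.config.confidence_cutoff
    preds = []
    for i, rec in enumerate(query.records):
        k = int(np.argmax(O[i]))
        conf = float(O[i, k])
        preds.append(
            BpPrediction(
                query_id=rec.seq_id,
                true_species=rec.species,
                predicted_species=model.species_order[k],
                confidence=conf,
                low_confidence=conf < cutoff,
            )
        )
    rate = sum(p.correct for p in preds) / len(preds) if preds else float("nan")
    return preds, rate


def predictions_to_tsv(preds: Sequence[BpPrediction], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["query_id", "true_species", "predicted_species", "confidence", "low_confidence"])
        for p in preds:
            w.writerow(
                [p.query_id, p.true_species, p.predicted_species,
                 f"{p.confidence:.6f}", int(p.low_confidence)]
            )
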
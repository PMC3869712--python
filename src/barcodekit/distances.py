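"""Kimura two-parameter distances, distance partitioning and gap analysis.

All distances use pairwise deletion: an alignment column contributes to a
comparison only when both sequences carry an unambiguous A/C/G/T at that
column.  Distances are kept in substitutions/site; conversion to percent
happens only at the reporting layer.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    AnalysisError,
    LabelingError,
    SaturationError,
    UndefinedDistanceError,
)
from .seqio import Alignment

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def encode(sequence: str) -> np.ndarray:
    """Encode a nucleotide string as int8 codes; non-ACGT -> -1."""
    arr = np.full(len(sequence), -1, dtype=np.int8)
    for i, c in enumerate(sequence):
        arr[i] = _CODE.get(c, -1)
    return arr


def encode_alignment(aln: Alignment) -> np.ndarray:
    """(n_records, length) int8 code matrix in record order."""
    mat = np.empty((len(aln), aln.length), dtype=np.int8)
    for i, rec in enumerate(aln.records):
        mat[i] = encode(rec.sequence)
    return mat


@dataclass(frozen=True)
class PairwiseComparison:
    """Transition/transversion proportions and the K2P distance of one pair."""

    p: float
    q: float
    sites_compared: int
    distance: float


def k2p_from_counts(
    transitions: int, transversions: int, sites_compared: int, pair=None
) -> PairwiseComparison:
    """Evaluate d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q)."""
    if sites_compared <= 0:
        raise UndefinedDistanceError("no comparable sites", pair=pair)
    p = transitions / sites_compared
    q = transversions / sites_compared
    a = 1.0 - 2.0 * p - q
    b = 1.0 - 2.0 * q
    if a <= 0.0 or b <= 0.0:
        raise SaturationError(
            f"K2P undefined (saturation): P={p:.4f}, Q={q:.4f}", pair=pair
        )
    d = -0.5 * math.log(a) - 0.25 * math.log(b)
    # exact-zero guarantee for identical pairs
    if transitions == 0 and transversions == 0:
        d = 0.0
    return PairwiseComparison(p=p, q=q, sites_compared=sites_compared, distance=d)


def _pair_counts(ca: np.ndarray, cb: np.ndarray) -> tuple[int, int, int]:
    valid = (ca >= 0) & (cb >= 0)
    diff = valid & (ca != cb)
    # purines are codes 0 (A) and 2 (G): transition iff parity matches
    ts = diff & ((ca & 1) == (cb & 1))
    n_diff = int(diff.sum())
    n_ts = int(ts.sum())
    return n_ts, n_diff - n_ts, int(valid.sum())


def k2p(a: str | np.ndarray, b: str | np.ndarray, pair=None) -> PairwiseComparison:
    """K2P comparison of two equal-length aligned sequences.

    Transitions are A<->G and C<->T; every other differing resolved pair is
    a transversion.  Columns where either sequence is not A/C/G/T are
    excluded (pairwise deletion).
    """
    ca = encode(a) if isinstance(a, str) else np.asarray(a, dtype=np.int8)
    cb = encode(b) if isinstance(b, str) else np.asarray(b, dtype=np.int8)
    if ca.shape != cb.shape:
        raise UndefinedDistanceError(
            f"length mismatch: {ca.shape[0]} vs {cb.shape[0]}", pair=pair
        )
    ts, tv, sites = _pair_counts(ca, cb)
    return k2p_from_counts(ts, tv, sites, pair=pair)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric K2P distance matrix with compared-site bookkeeping."""

    ids: tuple[str, ...]
    d: np.ndarray
    sites: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "_index", {i: k for k, i in enumerate(self.ids)})

    def get(self, id_a: str, id_b: str) -> float:
        return float(self.d[self._index[id_a], self._index[id_b]])

    def index(self, seq_id: str) -> int:
        return self._index[seq_id]

    def __len__(self) -> int:
        return len(self.ids)

    def submatrix(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self._index[i] for i in ids]
        return DistanceMatrix(
            ids=tuple(ids), d=self.d[np.ix_(idx, idx)], sites=self.sites[np.ix_(idx, idx)]
        )

    def pairs(self) -> Iterable[tuple[str, str, float]]:
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                yield self.ids[i], self.ids[j], float(self.d[i, j])

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["id", *self.ids])
            for i, sid in enumerate(self.ids):
                w.writerow([sid, *(f"{x:.8f}" for x in self.d[i])])

    def to_phylip_lower(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, sid in enumerate(self.ids):
                row = " ".join(f"{self.d[i, j]:.8f}" for j in range(i))
                fh.write(f"{sid:<12s}{row}\n".rstrip() + "\n")


def distance_matrix_from_codes(
    codes: np.ndarray, ids: Sequence[str]
) -> DistanceMatrix:
    n = codes.shape[0]
    d = np.zeros((n, n), dtype=float)
    sites = np.zeros((n, n), dtype=int)
    np.fill_diagonal(sites, codes.shape[1])
    for i in range(n):
        for j in range(i + 1, n):
            cmp = k2p(codes[i], codes[j], pair=(ids[i], ids[j]))
            d[i, j] = d[j, i] = cmp.distance
            sites[i, j] = sites[j, i] = cmp.sites_compared
    return DistanceMatrix(ids=tuple(ids), d=d, sites=sites)


def distance_matrix(aln: Alignment) -> DistanceMatrix:
    """All-pairs K2P matrix of an alignment (symmetric, zero diagonal)."""
    if len(aln) < 2:
        raise AnalysisError("distance matrix needs at least 2 records")
    return distance_matrix_from_codes(encode_alignment(aln), aln.ids)


def default_genus(species: str) -> str:
    """Genus = first whitespace-delimited token of the species label."""
    return species.split()[0] if species.split() else species


@dataclass(frozen=True)
class IntraPair:
    id_a: str
    id_b: str
    distance: float
    species: str


@dataclass(frozen=True)
class InterPair:
    id_a: str
    id_b: str
    distance: float
    species_a: str
    species_b: str
    congeneric: bool


@dataclass(frozen=True)
class DistancePartition:
    """Every unordered pair classified into exactly one category."""

    intra_within_pop: tuple[IntraPair, ...]
    intra_between_pop: tuple[IntraPair, ...]
    inter: tuple[InterPair, ...]

    @property
    def intra(self) -> tuple[IntraPair, ...]:
        return self.intra_within_pop + self.intra_between_pop

    @property
    def intra_values(self) -> np.ndarray:
        return np.array([p.distance for p in self.intra], dtype=float)

    @property
    def inter_values(self) -> np.ndarray:
        return np.array([p.distance for p in self.inter], dtype=float)

    def n_pairs(self) -> int:
        return len(self.intra_within_pop) + len(self.intra_between_pop) + len(self.inter)


def partition_distances(
    dm: DistanceMatrix,
    species: Mapping[str, str],
    population: Mapping[str, str] | None = None,
    genus: Mapping[str, str] | None = None,
) -> DistancePartition:
    """Partition all pairs into within-population / between-population /
    interspecific distances.

    An empty population string is treated as its own group within a species.
    The genus defaults to the first token of the species label.
    """
    missing = [i for i in dm.ids if i not in species]
    if missing:
        raise LabelingError(f"ids missing a species label: {', '.join(missing)}")
    pop = population or {}
    within, between, inter = [], [], []
    for id_a, id_b, d in dm.pairs():
        sp_a, sp_b = species[id_a], species[id_b]
        if sp_a == sp_b:
            if pop.get(id_a, "") == pop.get(id_b, ""):
                within.append(IntraPair(id_a, id_b, d, sp_a))
            else:
                between.append(IntraPair(id_a, id_b, d, sp_a))
        else:
            g_a = genus[id_a] if genus else default_genus(sp_a)
            g_b = genus[id_b] if genus else default_genus(sp_b)
            inter.append(InterPair(id_a, id_b, d, sp_a, sp_b, g_a == g_b))
    return DistancePartition(
        intra_within_pop=tuple(within),
        intra_between_pop=tuple(between),
        inter=tuple(inter),
    )


@dataclass(frozen=True)
class GapReport:
    """Barcode gap/overlap between intraspecific and interspecific distances."""

    max_intra: float
    min_inter: float
    overlap_interval: tuple[float, float] | None
    gap_width: float | None
    bin_width: float
    bin_edges: np.ndarray
    intra_counts: np.ndarray
    inter_counts: np.ndarray

    @property
    def has_overlap(self) -> bool:
        return self.overlap_interval is not None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "max_intra": self.max_intra,
            "min_inter": self.min_inter,
            "overlap_interval": list(self.overlap_interval) if self.overlap_interval else None,
            "gap_width": self.gap_width,
            "bin_width": self.bin_width,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def histogram_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["bin_start", "bin_end", "intra_count", "inter_count"])
            for k in range(len(self.intra_counts)):
                w.writerow(
                    [
                        f"{self.bin_edges[k]:.6f}",
                        f"{self.bin_edges[k + 1]:.6f}",
                        int(self.intra_counts[k]),
                        int(self.inter_counts[k]),
                    ]
                )


def gap_analysis(part: DistancePartition, bin_width: float = 0.005) -> GapReport:
    """Overlap interval / gap width between the intra and inter distributions."""
    intra = part.intra_values
    inter = part.inter_values
    if intra.size == 0:
        raise AnalysisError("empty category: intraspecific")
    if inter.size == 0:
        raise AnalysisError("empty category: interspecific")
    max_intra = float(intra.max())
    min_inter = float(inter.min())
    if max_intra >= min_inter:
        overlap: tuple[float, float] | None = (min_inter, max_intra)
        gap = None
    else:
        overlap = None
        gap = min_inter - max_intra
    top = max(float(intra.max()), float(inter.max()), bin_width)
    n_bins = int(math.ceil(top / bin_width)) or 1
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    intra_counts, _ = np.histogram(intra, bins=edges)
    inter_counts, _ = np.histogram(inter, bins=edges)
    return GapReport(
        max_intra=max_intra,
        min_inter=min_inter,
        overlap_interval=overlap,
        gap_width=gap,
        bin_width=bin_width,
        bin_edges=edges,
        intra_counts=intra_counts,
        inter_counts=inter_counts,
    )


def intra_percentile_threshold(part: DistancePartition, q: float = 95.0) -> float:
    """q-th percentile (linear interpolation) of pooled intraspecific distances."""
    intra = part.intra_values
    if intra.size == 0:
        raise AnalysisError("no intraspecific distances to take a percentile of")
    return float(np.percentile(intra, q, method="linear"))
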
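"""Leave-one-out species identification and threshold optimization.

Implements three identification protocols over a precomputed distance
matrix — best match (BM), best close match (BCM) and all species barcodes
(ASB) — plus the TP/FP/TN/FN threshold sweep and the regression-based
ad hoc threshold solving a target relative identification error.

Every sequence is queried against the library with itself removed
(leave-one-out).  Ties are exact floating-point distance equalities:
distances derive from integer site counts, so coincidences are exact.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import AnalysisError, LabelingError
from .distances import DistanceMatrix

PROTOCOLS = ("BM", "BCM", "ASB")
VERDICTS = ("correct", "ambiguous", "incorrect", "no_match")


@dataclass(frozen=True)
class MatchEvidence:
    seq_id: str
    species: str
    distance: float


@dataclass(frozen=True)
class IdOutcome:
    """Per-query identification verdict with best-match evidence."""

    query_id: str
    protocol: str
    verdict: str
    best_distance: float
    best_match_species: frozenset[str]
    true_species: str
    evidence: tuple[MatchEvidence, ...]
    threshold: float | None = None

    @property
    def truth_in_ties(self) -> bool:
        return self.true_species in self.best_match_species


@dataclass(frozen=True)
class IdSummary:
    """Verdict counts over all queries of one protocol run."""

    protocol: str
    threshold: float | None
    counts: Mapping[str, int]
    excluded: tuple[str, ...] = ()

    @property
    def n_queries(self) -> int:
        return sum(self.counts.values())

    def percentage(self, verdict: str) -> float:
        n = self.n_queries
        return 100.0 * self.counts.get(verdict, 0) / n if n else float("nan")

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "threshold": self.threshold,
            "n_queries": self.n_queries,
            "counts": dict(self.counts),
            "percentages": {v: self.percentage(v) for v in VERDICTS},
            "excluded": list(self.excluded),
        }


def _check_labels(dm: DistanceMatrix, species: Mapping[str, str]) -> None:
    missing = [i for i in dm.ids if i not in species]
    if missing:
        raise LabelingError(f"ids missing a species label: {', '.join(missing)}")


def _species_counts(dm: DistanceMatrix, species: Mapping[str, str]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for i in dm.ids:
        counts[species[i]] = counts.get(species[i], 0) + 1
    return counts


def best_match(
    query_id: str,
    dm: DistanceMatrix,
    species: Mapping[str, str],
    evidence_depth: int = 10,
) -> tuple[float, frozenset[str], tuple[MatchEvidence, ...]]:
    """Nearest library match(es) of a query under leave-one-out.

    Returns the minimal distance, the species pooled over all exact ties at
    that distance, and a ranked evidence list (ascending distance, ties
    broken by seq_id).
    """
    _check_labels(dm, species)
    library = [i for i in dm.ids if i != query_id]
    if not library:
        raise AnalysisError("library is empty after leave-one-out")
    ranked = sorted(library, key=lambda i: (dm.get(query_id, i), i))
    best_d = dm.get(query_id, ranked[0])
    tied = frozenset(species[i] for i in ranked if dm.get(query_id, i) == best_d)
    evidence = tuple(
        MatchEvidence(i, species[i], dm.get(query_id, i))
        for i in ranked[:evidence_depth]
    )
    return best_d, tied, evidence


def _bm_verdict(true_sp: str, tied: frozenset[str]) -> str:
    if tied == {true_sp}:
        return "correct"
    if len(tied) > 1:
        return "ambiguous"
    return "incorrect"


def _query_ids(
    dm: DistanceMatrix, species: Mapping[str, str], min_per_species: int
) -> tuple[list[str], list[str]]:
    counts = _species_counts(dm, species)
    queries = [i for i in dm.ids if counts[species[i]] >= min_per_species]
    excluded = [i for i in dm.ids if counts[species[i]] < min_per_species]
    return queries, excluded


def _summarize(
    outcomes: Sequence[IdOutcome],
    protocol: str,
    threshold: float | None,
    excluded: Sequence[str],
) -> IdSummary:
    counts = {v: 0 for v in VERDICTS}
    for o in outcomes:
        counts[o.verdict] += 1
    return IdSummary(
        protocol=protocol, threshold=threshold, counts=counts, excluded=tuple(excluded)
    )


def bm_identify(
    dm: DistanceMatrix,
    species: Mapping[str, str],
    evidence_depth: int = 10,
) -> tuple[list[IdOutcome], IdSummary]:
    """Best match: assign the species of the nearest barcode, no threshold.

    Queries are restricted to species with >=2 sequences so a conspecific
    remains in the library after omission; others are reported as excluded.
    """
    _check_labels(dm, species)
    queries, excluded = _query_ids(dm, species, min_per_species=2)
    outcomes = []
    for q in queries:
        best_d, tied, evidence = best_match(q, dm, species, evidence_depth)
        outcomes.append(
            IdOutcome(
                query_id=q,
                protocol="BM",
                verdict=_bm_verdict(species[q], tied),
                best_distance=best_d,
                best_match_species=tied,
                true_species=species[q],
                evidence=evidence,
            )
        )
    return outcomes, _summarize(outcomes, "BM", None, excluded)


def bcm_identify(
    dm: DistanceMatrix,
    species: Mapping[str, str],
    threshold: float,
    evidence_depth: int = 10,
) -> tuple[list[IdOutcome], IdSummary]:
    """Best close match: BM restricted to matches within a threshold.

    A query whose best distance exceeds the threshold is ``no_match``;
    otherwise BM rules apply to the minimal-distance tie set.
    """
    if threshold < 0:
        raise AnalysisError("threshold must be >= 0")
    _check_labels(dm, species)
    queries, excluded = _query_ids(dm, species, min_per_species=2)
    outcomes = []
    for q in queries:
        best_d, tied, evidence = best_match(q, dm, species, evidence_depth)
        verdict = "no_match" if best_d > threshold else _bm_verdict(species[q], tied)
        outcomes.append(
            IdOutcome(
                query_id=q,
                protocol="BCM",
                verdict=verdict,
                best_distance=best_d,
                best_match_species=tied,
                true_species=species[q],
                evidence=evidence,
                threshold=threshold,
            )
        )
    return outcomes, _summarize(outcomes, "BCM", threshold, excluded)


def asb_identify(
    dm: DistanceMatrix,
    species: Mapping[str, str],
    threshold: float,
    evidence_depth: int = 10,
) -> tuple[list[IdOutcome], IdSummary]:
    """All species barcodes: the query must be followed by every conspecific
    barcode before any heterospecific one.

    Let D be the maximum distance from the query to any remaining
    conspecific barcode.  The verdict is ``no_match`` when the nearest
    conspecific exceeds the threshold; ``incorrect`` when the minimal-distance
    tie set contains no conspecific; ``correct`` when every heterospecific
    barcode lies strictly beyond D; otherwise ``ambiguous``.  Queries whose
    species retains fewer than two barcodes after omission are excluded.
    """
    if threshold < 0:
        raise AnalysisError("threshold must be >= 0")
    _check_labels(dm, species)
    queries, excluded = _query_ids(dm, species, min_per_species=3)
    outcomes = []
    for q in queries:
        best_d, tied, evidence = best_match(q, dm, species, evidence_depth)
        true_sp = species[q]
        consp = [i for i in dm.ids if i != q and species[i] == true_sp]
        hetero = [i for i in dm.ids if i != q and species[i] != true_sp]
        consp_d = [dm.get(q, i) for i in consp]
        hetero_d = [dm.get(q, i) for i in hetero]
        d_max_consp = max(consp_d)
        if min(consp_d) > threshold:
            verdict = "no_match"
        elif true_sp not in tied:
            verdict = "incorrect"
        elif all(h > d_max_consp for h in hetero_d):
            verdict = "correct"
        else:
            verdict = "ambiguous"
        outcomes.append(
            IdOutcome(
                query_id=q,
                protocol="ASB",
                verdict=verdict,
                best_distance=best_d,
                best_match_species=tied,
                true_species=true_sp,
                evidence=evidence,
                threshold=threshold,
            )
        )
    return outcomes, _summarize(outcomes, "ASB", threshold, excluded)


@dataclass(frozen=True)
class SweepRow:
    """Confusion counts and derived metrics at one distance threshold."""

    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def discarded(self) -> int:
        return self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def precision(self) -> float | None:
        kept = self.tp + self.fp
        return self.tp / kept if kept else None

    @property
    def overall_id_error(self) -> float:
        return (self.fp + self.fn) / self.total

    @property
    def relative_id_error(self) -> float | None:
        kept = self.tp + self.fp
        return self.fp / kept if kept else None


def confusion_classify(outcomes: Sequence[IdOutcome]) -> SweepRow:
    """TP/FP/TN/FN tally of BCM outcomes at a single threshold.

    TP: kept and correct.  FP: kept but ambiguous or incorrect.  Among
    discarded queries, FN: the best match is conspecific; TN: the best
    match is heterospecific (or no conspecific exists in the library).
    """
    thresholds = {o.threshold for o in outcomes}
    if len(thresholds) != 1 or None in thresholds:
        raise AnalysisError("confusion_classify needs BCM outcomes at one threshold")
    tp = fp = tn = fn = 0
    for o in outcomes:
        if o.verdict == "no_match":
            if o.truth_in_ties:
                fn += 1
            else:
                tn += 1
        elif o.verdict == "correct":
            tp += 1
        else:
            fp += 1
    return SweepRow(threshold=thresholds.pop(), tp=tp, fp=fp, tn=tn, fn=fn)


def threshold_sweep(
    dm: DistanceMatrix,
    species: Mapping[str, str],
    n_thresholds: int = 30,
    thresholds: Sequence[float] | None = None,
) -> list[SweepRow]:
    """Confusion sweep over descending thresholds.

    The default grid is linearly spaced from the largest query best-match
    distance (nothing discarded, equivalent to BM) down to 0 inclusive.
    """
    _check_labels(dm, species)
    queries, _ = _query_ids(dm, species, min_per_species=2)
    if not queries:
        raise AnalysisError("no eligible queries for the sweep")
    per_query = []
    for q in queries:
        best_d, tied, _ = best_match(q, dm, species, evidence_depth=1)
        per_query.append((best_d, _bm_verdict(species[q], tied), species[q] in tied))
    max_best = max(b for b, _, _ in per_query)
    if thresholds is None:
        if max_best == 0.0:
            import warnings

            warnings.warn("max best-match distance is 0; single-threshold sweep")
            grid = [0.0]
        else:
            if n_thresholds < 2:
                raise AnalysisError("need at least 2 thresholds")
            grid = list(np.linspace(max_best, 0.0, n_thresholds))
    else:
        grid = sorted((float(t) for t in thresholds), reverse=True)
    rows = []
    for thr in grid:
        tp = fp = tn = fn = 0
        for best_d, bm_verdict, truth_tied in per_query:
            if best_d > thr:
                if truth_tied:
                    fn += 1
                else:
                    tn += 1
            elif bm_verdict == "correct":
                tp += 1
            else:
                fp += 1
        rows.append(SweepRow(threshold=float(thr), tp=tp, fp=fp, tn=tn, fn=fn))
    return rows


def sweep_to_tsv(rows: Sequence[SweepRow], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(
            [
                "threshold", "tp", "fp", "tn", "fn", "discarded",
                "accuracy", "precision", "overall_id_error", "relative_id_error",
            ]
        )
        for r in rows:
            w.writerow(
                [
                    f"{r.threshold:.6f}", r.tp, r.fp, r.tn, r.fn, r.discarded,
                    f"{r.accuracy:.6f}",
                    "" if r.precision is None else f"{r.precision:.6f}",
                    f"{r.overall_id_error:.6f}",
                    "" if r.relative_id_error is None else f"{r.relative_id_error:.6f}",
                ]
            )


@dataclass(frozen=True)
class AdHocFit:
    """OLS fit of relative ID error on threshold and its target solution."""

    slope: float
    intercept: float
    target_error: float
    threshold_at_target: float
    attainable: bool
    n_points: int

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "target_error": self.target_error,
            "threshold_at_target": self.threshold_at_target,
            "attainable": self.attainable,
            "n_points": self.n_points,
        }


def adhoc_threshold(rows: Sequence[SweepRow], target_error: float = 0.05) -> AdHocFit:
    """Solve the fitted relative-ID-error line for the target error.

    Rows with undefined relative error (no kept queries) are excluded from
    the regression.  The solution is unattainable when it is negative or
    when a non-positive slope leaves the intercept above the target.
    """
    pts = [(r.threshold, r.relative_id_error) for r in rows if r.relative_id_error is not None]
    if len(pts) < 2:
        raise AnalysisError("need at least 2 sweep rows with a defined relative error")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.allclose(x, x[0]):
        raise AnalysisError("degenerate sweep: all thresholds identical")
    fit = stats.linregress(x, y)
    slope, intercept = float(fit.slope), float(fit.intercept)
    if slope != 0.0:
        thr = (target_error - intercept) / slope
    else:
        thr = math.inf if intercept <= target_error else -math.inf
    attainable = thr >= 0 and not (slope <= 0 and intercept > target_error)
    return AdHocFit(
        slope=slope,
        intercept=intercept,
        target_error=target_error,
        threshold_at_target=thr,
        attainable=attainable,
        n_points=len(pts),
    )


def outcomes_to_tsv(outcomes: Sequence[IdOutcome], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(
            ["query_id", "protocol", "true_species", "verdict", "best_distance",
             "best_match_species", "threshold"]
        )
        for o in outcomes:
            w.writerow(
                [
                    o.query_id, o.protocol, o.true_species, o.verdict,
                    f"{o.best_distance:.6f}",
                    ";".join(sorted(o.best_match_species)),
                    "" if o.threshold is None else f"{o.threshold:.6f}",
                ]
            )


def summary_to_json(summary: IdSummary, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary.to_dict(), indent=2))
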
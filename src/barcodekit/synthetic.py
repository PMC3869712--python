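"""Synthetic barcode libraries with known ground truth.

Sequences evolve under the Kimura two-parameter substitution process on a
star design: a common ancestor, per-species ancestors at the configured
interspecific divergence, population ancestors below them and individuals
below those.  Branch lengths are halved per lineage so pairwise
expectations match the configured targets.  Oversplit scenarios assign
several nominal species labels to the populations of one true species.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import BarcodekitError
from .seqio import Alignment, BarcodeRecord

_BASES = np.array([0, 1, 2, 3], dtype=np.int8)
_TO_CHAR = np.array(list("ACGT"))
#: transition partner of each base code (A<->G, C<->T)
_TS_PARTNER = np.array([2, 3, 0, 1], dtype=np.int8)
#: the two transversion partners of each base code
_TV_PARTNERS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]], dtype=np.int8)


@dataclass(frozen=True)
class SimConfig:
    n_true_species: int = 6
    populations_per_species: int | Mapping[str, int] = 2
    individuals_per_population: int = 5
    alignment_length: int = 658
    kappa: float = 2.0
    intra_within_pop_target: float = 0.005
    intra_between_pop_target: float = 0.02
    inter_target: float = 0.06
    oversplit_map: Mapping[str, Sequence[str]] | None = None
    shared_haplotype_rate: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not (
            0 <= self.intra_within_pop_target
            <= self.intra_between_pop_target
            < self.inter_target
        ):
            raise BarcodekitError(
                "targets must satisfy 0 <= within <= between < inter"
            )
        if self.n_true_species < 1 or self.individuals_per_population < 1:
            raise BarcodekitError("all counts must be >= 1")
        if self.kappa <= 0:
            raise BarcodekitError("kappa must be > 0")
        if not (0 <= self.shared_haplotype_rate <= 1):
            raise BarcodekitError("shared_haplotype_rate must lie in [0, 1]")

    def species_names(self) -> list[str]:
        return [f"Simulus sp{i + 1:02d}" for i in range(self.n_true_species)]

    def n_populations(self, species: str) -> int:
        if isinstance(self.populations_per_species, Mapping):
            fallback = self.populations_per_species.get("default", 1)
            n = int(self.populations_per_species.get(species, fallback))
        else:
            n = int(self.populations_per_species)
        if n < 1:
            raise BarcodekitError(f"{species}: populations must be >= 1")
        return n

    def nominal_labels(self, species: str) -> Sequence[str] | None:
        if self.oversplit_map and species in self.oversplit_map:
            labels = list(self.oversplit_map[species])
            if not labels:
                raise BarcodekitError(f"{species}: empty oversplit label list")
            if len(labels) > self.n_populations(species):
                raise BarcodekitError(
                    f"{species}: {len(labels)} nominal labels but only "
                    f"{self.n_populations(species)} populations"
                )
            return labels
        return None


@dataclass(frozen=True)
class GroundTruth:
    """Per-sequence true/nominal labels of a simulated library."""

    true_species: Mapping[str, str]
    nominal_species: Mapping[str, str]
    population: Mapping[str, str]

    def same_true_species(self, nominal_a: str, nominal_b: str) -> bool:
        def truth_of(nom: str) -> set[str]:
            return {
                t for sid, t in self.true_species.items()
                if self.nominal_species[sid] == nom
            }

        a, b = truth_of(nominal_a), truth_of(nominal_b)
        if not a or not b:
            raise BarcodekitError("unknown nominal species label")
        return a == b

    @property
    def oversplit_labels(self) -> frozenset[str]:
        """Nominal labels that do not coincide with their true species."""
        return frozenset(
            nom for sid, nom in self.nominal_species.items()
            if nom != self.true_species[sid]
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "true_species": dict(self.true_species),
                    "nominal_species": dict(self.nominal_species),
                    "population": dict(self.population),
                },
                indent=2,
            )
        )


def _k80_probs(t: float, kappa: float) -> tuple[float, float]:
    """Per-site (transition, per-target transversion) probabilities after
    time t under K80 normalized to one expected substitution per unit t."""
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e4 = math.exp(-4.0 * beta * t)
    e2 = math.exp(-2.0 * (alpha + beta) * t)
    p_ts = 0.25 + 0.25 * e4 - 0.5 * e2
    p_tv_each = 0.25 - 0.25 * e4
    return p_ts, p_tv_each


def random_sequence(length: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 4, size=length).astype(np.int8)


def evolve(
    seq: np.ndarray | str,
    branch_length: float,
    kappa: float,
    rng: np.random.Generator,
) -> np.ndarray | str:
    """Evolve a sequence for ``branch_length`` expected substitutions/site
    under the K80 process with the given transition/transversion ratio."""
    if branch_length < 0:
        raise BarcodekitError("branch_length must be >= 0")
    as_str = isinstance(seq, str)
    codes = (
        np.array([{"A": 0, "C": 1, "G": 2, "T": 3}[c] for c in seq], dtype=np.int8)
        if as_str
        else np.asarray(seq, dtype=np.int8).copy()
    )
    if branch_length > 0:
        p_ts, p_tv = _k80_probs(branch_length, kappa)
        u = rng.random(codes.shape[0])
        pick = rng.integers(0, 2, size=codes.shape[0])
        ts_sites = u < p_ts
        tv_sites = (~ts_sites) & (u < p_ts + 2 * p_tv)
        out = codes.copy()
        out[ts_sites] = _TS_PARTNER[codes[ts_sites]]
        out[tv_sites] = _TV_PARTNERS[codes[tv_sites], pick[tv_sites]]
        codes = out
    return "".join(_TO_CHAR[codes]) if as_str else codes


def simulate_library(cfg: SimConfig) -> tuple[Alignment, GroundTruth]:
    """Generate an aligned library plus its ground truth, fully seeded."""
    rng = np.random.default_rng(cfg.seed)
    root = random_sequence(cfg.alignment_length, rng)
    records: list[BarcodeRecord] = []
    true_sp: dict[str, str] = {}
    nominal: dict[str, str] = {}
    population: dict[str, str] = {}
    # sequences indexed by (species, population index, individual index)
    seqs: dict[tuple[str, int, int], np.ndarray] = {}

    for s_idx, sp in enumerate(cfg.species_names()):
        sp_anc = evolve(root, cfg.inter_target / 2.0, cfg.kappa, rng)
        n_pops = cfg.n_populations(sp)
        for p_idx in range(n_pops):
            pop_anc = evolve(
                sp_anc, cfg.intra_between_pop_target / 2.0, cfg.kappa, rng
            )
            for k in range(cfg.individuals_per_population):
                seqs[(sp, p_idx, k)] = evolve(
                    pop_anc, cfg.intra_within_pop_target / 2.0, cfg.kappa, rng
                )

    # cross-population haplotype sharing by copying
    for s_idx, sp in enumerate(cfg.species_names()):
        n_pops = cfg.n_populations(sp)
        if n_pops < 2 or cfg.shared_haplotype_rate == 0:
            continue
        labels = cfg.nominal_labels(sp)

        def label_of(p: int) -> str:
            return labels[p % len(labels)] if labels else sp

        copied_cross_label = False
        for p_idx in range(n_pops):
            for k in range(cfg.individuals_per_population):
                if rng.random() < cfg.shared_haplotype_rate:
                    other = int(rng.integers(0, n_pops - 1))
                    src_pop = other if other < p_idx else other + 1
                    src_k = int(rng.integers(0, cfg.individuals_per_population))
                    seqs[(sp, p_idx, k)] = seqs[(sp, src_pop, src_k)].copy()
                    if label_of(p_idx) != label_of(src_pop):
                        copied_cross_label = True
        # oversplit scenarios must carry at least one cross-nominal-label
        # shared haplotype by construction
        if labels is not None and len(labels) > 1 and not copied_cross_label:
            target = next(
                (p for p in range(1, n_pops) if label_of(p) != label_of(0)),
                n_pops - 1,
            )
            seqs[(sp, target, 0)] = seqs[(sp, 0, 0)].copy()

    for s_idx, sp in enumerate(cfg.species_names()):
        labels = cfg.nominal_labels(sp)
        n_pops = cfg.n_populations(sp)
        for p_idx in range(n_pops):
            pop_name = f"sp{s_idx + 1:02d}_pop{p_idx + 1}"
            nom = labels[p_idx % len(labels)] if labels else sp
            for k in range(cfg.individuals_per_population):
                sid = f"sp{s_idx + 1:02d}_p{p_idx + 1}_i{k + 1}"
                seq = "".join(_TO_CHAR[seqs[(sp, p_idx, k)]])
                records.append(
                    BarcodeRecord(
                        seq_id=sid,
                        species=nom,
                        population=pop_name,
                        locality=pop_name,
                        sequence=seq,
                    )
                )
                true_sp[sid] = sp
                nominal[sid] = nom
                population[sid] = pop_name
    aln = Alignment.from_records(records)
    truth = GroundTruth(
        true_species=true_sp, nominal_species=nominal, population=population
    )
    return aln, truth


#: expectation classes used by downstream ground-truth tests
MUST_BE_CORRECT = "must_be_correct"
MAY_FAIL = "may_fail"


def expected_verdicts(truth: GroundTruth) -> dict[str, str]:
    """Per-query expectation class for best-match identification.

    Queries from oversplit nominal species (or nominal species left with a
    single sequence) may legitimately fail; all others must be identified
    correctly on well-separated libraries.
    """
    counts: dict[str, int] = {}
    for nom in truth.nominal_species.values():
        counts[nom] = counts.get(nom, 0) + 1
    oversplit = truth.oversplit_labels
    out = {}
    for sid, nom in truth.nominal_species.items():
        if nom in oversplit or counts[nom] < 2:
            out[sid] = MAY_FAIL
        else:
            out[sid] = MUST_BE_CORRECT
    return out
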
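"""Pair classification and balanced benchmark sampling.

Two proteins are *homologous* (benchmark sense) when their effective
architectures — clan-level identifier sequences — are identical position by
position, and *non-homologous* when they share no effective identifier in
any order.  Pairs meeting neither condition are *ambiguous* and excluded
from evaluation.

Positives are sampled per architecture per genome (at most a small number
of proteins per genome, all pairs among the selection, within and across
genomes) to avoid biasing toward highly populated families while still
covering a range of evolutionary distances.  Negatives are drawn per anchor
architecture by pairing its proteins with proteins from randomly chosen
disjoint architectures until there are as many negatives as positives.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .architectures import SCHEMES, Architecture, ProteinRecord

__all__ = [
    "PairLabel",
    "BenchmarkPair",
    "SamplerConfig",
    "ShortfallWarning",
    "classify_pair",
    "sample_positives",
    "sample_negatives",
    "sample_benchmark",
    "label_pairs_all_schemes",
    "UNCOVERED",
]

logger = logging.getLogger(__name__)

#: Sentinel label for pairs where a protein lacks an architecture in a scheme.
UNCOVERED = "uncovered"


class PairLabel(str, enum.Enum):
    HOMOLOGOUS = "homologous"
    NON_HOMOLOGOUS = "non_homologous"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class BenchmarkPair:
    """An unordered benchmark pair; ``protein_a < protein_b`` canonically."""

    protein_a: str
    protein_b: str
    scheme: str
    label: PairLabel
    role: str  # "positive" | "negative"
    anchor_architecture: str

    def __post_init__(self) -> None:
        if self.protein_a == self.protein_b:
            raise ValueError(f"self-pair {self.protein_a!r}")
        if self.role == "positive" and self.label is not PairLabel.HOMOLOGOUS:
            raise ValueError("positive pairs must be homologous")
        if self.role == "negative" and self.label is not PairLabel.NON_HOMOLOGOUS:
            raise ValueError("negative pairs must be non-homologous")

    @property
    def key(self) -> tuple[str, str]:
        return (self.protein_a, self.protein_b)


@dataclass
class SamplerConfig:
    proteins_per_genome_per_architecture: int = 2
    rng_seed: int = 0
    negatives_per_positive: float = 1.0
    protein_disjoint_negatives: bool = False
    #: give up after this many rejection attempts per requested negative
    max_attempts_per_negative: int = 200

    def __post_init__(self) -> None:
        if self.proteins_per_genome_per_architecture < 1:
            raise ValueError("proteins_per_genome_per_architecture must be >= 1")
        if self.negatives_per_positive <= 0:
            raise ValueError("negatives_per_positive must be > 0")


@dataclass
class ShortfallWarning:
    """Negative-sampling quota not met for one anchor architecture."""

    anchor_architecture: str
    requested: int
    obtained: int
    reason: str


def classify_pair(arch_a: Architecture, arch_b: Architecture) -> PairLabel:
    """Homologous if identical identifier sequences; non-homologous if the
    identifier sets are disjoint; ambiguous otherwise."""
    if arch_a.effective_ids == arch_b.effective_ids:
        return PairLabel.HOMOLOGOUS
    if arch_a.id_set.isdisjoint(arch_b.id_set):
        return PairLabel.NON_HOMOLOGOUS
    return PairLabel.AMBIGUOUS


def _group_by_architecture(
    records: Sequence[ProteinRecord], scheme: str
) -> dict[str, dict[str, list[str]]]:
    """arch string -> genome -> sorted protein IDs (covered proteins only)."""
    grouped: dict[str, dict[str, list[str]]] = {}
    for rec in records:
        arch = rec.architecture_for(scheme)
        if arch is None:
            continue
        grouped.setdefault(arch.string_form, {}).setdefault(rec.genome_id, []).append(
            rec.protein_id
        )
    for genomes in grouped.values():
        for pids in genomes.values():
            pids.sort()
    return grouped


def _canonical(pid1: str, pid2: str) -> tuple[str, str]:
    return (pid1, pid2) if pid1 < pid2 else (pid2, pid1)


def sample_positives(
    records: Sequence[ProteinRecord],
    scheme: str,
    config: SamplerConfig,
    rng: np.random.Generator | None = None,
) -> list[BenchmarkPair]:
    """Per architecture, draw up to the configured number of proteins per
    genome uniformly without replacement and emit every unordered pair among
    the drawn proteins, within and across genomes.

    Architectures represented by a single protein yield no pair (logged).
    Deterministic for a fixed seed.
    """
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    grouped = _group_by_architecture(records, scheme)
    k = config.proteins_per_genome_per_architecture
    pairs: list[BenchmarkPair] = []
    seen: set[tuple[str, str]] = set()
    for arch_str in sorted(grouped):
        chosen: list[str] = []
        for genome in sorted(grouped[arch_str]):
            pool = grouped[arch_str][genome]
            n_draw = min(k, len(pool))
            idx = rng.choice(len(pool), size=n_draw, replace=False)
            chosen.extend(pool[i] for i in sorted(idx))
        if len(chosen) < 2:
            logger.info(
                "architecture %s has a single protein; no positive pair", arch_str
            )
            continue
        for pid1, pid2 in combinations(sorted(chosen), 2):
            key = _canonical(pid1, pid2)
            if key in seen:
                continue
            seen.add(key)
            pairs.append(
                BenchmarkPair(
                    protein_a=key[0],
                    protein_b=key[1],
                    scheme=scheme,
                    label=PairLabel.HOMOLOGOUS,
                    role="positive",
                    anchor_architecture=arch_str,
                )
            )
    return pairs


def sample_negatives(
    positives: Sequence[BenchmarkPair],
    records: Sequence[ProteinRecord],
    scheme: str,
    config: SamplerConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[BenchmarkPair], list[ShortfallWarning]]:
    """For each anchor architecture with ``p`` positives, rejection-sample
    ``ceil(p * negatives_per_positive)`` pairs of one anchor protein and one
    protein from a uniformly chosen architecture with a fully disjoint
    identifier set.  Quota shortfalls are reported, not raised.
    """
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed + 1)
    grouped = _group_by_architecture(records, scheme)
    arch_proteins = {
        a: sorted(p for pids in genomes.values() for p in pids)
        for a, genomes in grouped.items()
    }
    arch_objects = {a: Architecture(tuple(a.split("_"))) for a in grouped}

    pos_counts: dict[str, int] = {}
    for p in positives:
        pos_counts[p.anchor_architecture] = pos_counts.get(p.anchor_architecture, 0) + 1

    negatives: list[BenchmarkPair] = []
    shortfalls: list[ShortfallWarning] = []
    seen: set[tuple[str, str]] = set()
    used_proteins: set[str] = set()

    for anchor in sorted(pos_counts):
        quota = math.ceil(pos_counts[anchor] * config.negatives_per_positive)
        anchor_set = arch_objects[anchor].id_set
        candidates = sorted(
            a
            for a in grouped
            if a != anchor and arch_objects[a].id_set.isdisjoint(anchor_set)
        )
        if not candidates:
            shortfalls.append(
                ShortfallWarning(anchor, quota, 0, "no disjoint architecture exists")
            )
            logger.warning("no disjoint architecture for anchor %s", anchor)
            continue
        obtained = 0
        attempts_left = quota * config.max_attempts_per_negative
        anchor_pool = arch_proteins[anchor]
        while obtained < quota and attempts_left > 0:
            attempts_left -= 1
            pid_a = anchor_pool[rng.integers(len(anchor_pool))]
            partner_arch = candidates[rng.integers(len(candidates))]
            partner_pool = arch_proteins[partner_arch]
            pid_b = partner_pool[rng.integers(len(partner_pool))]
            if pid_a == pid_b:
                continue
            if config.protein_disjoint_negatives and (
                pid_a in used_proteins or pid_b in used_proteins
            ):
                continue
            key = _canonical(pid_a, pid_b)
            if key in seen:
                continue
            # a protein may carry several architectures' identifiers only via
            # its single architecture here, so the disjoint-architecture draw
            # already guarantees non-homology; verify anyway for safety
            if (
                classify_pair(arch_objects[anchor], arch_objects[partner_arch])
                is not PairLabel.NON_HOMOLOGOUS
            ):
                continue
            seen.add(key)
            used_proteins.update(key)
            obtained += 1
            negatives.append(
                BenchmarkPair(
                    protein_a=key[0],
                    protein_b=key[1],
                    scheme=scheme,
                    label=PairLabel.NON_HOMOLOGOUS,
                    role="negative",
                    anchor_architecture=anchor,
                )
            )
        if obtained < quota:
            shortfalls.append(
                ShortfallWarning(
                    anchor, quota, obtained, "candidate pairs exhausted"
                )
            )
            logger.warning(
                "negative shortfall for anchor %s: %d/%d", anchor, obtained, quota
            )
    return negatives, shortfalls


def sample_benchmark(
    records: Sequence[ProteinRecord],
    scheme: str,
    config: SamplerConfig,
) -> tuple[list[BenchmarkPair], list[ShortfallWarning]]:
    """Positives then negatives from a single seeded RNG stream."""
    rng = np.random.default_rng(config.rng_seed)
    positives = sample_positives(records, scheme, config, rng)
    negatives, shortfalls = sample_negatives(positives, records, scheme, config, rng)
    return positives + negatives, shortfalls


def label_pairs_all_schemes(
    pairs: Sequence[BenchmarkPair],
    records: Iterable[ProteinRecord],
    schemes: Sequence[str] = SCHEMES,
) -> pd.DataFrame:
    """Label every pair under every scheme for congruence analysis.

    Returns a DataFrame with columns ``protein_a``, ``protein_b``, ``role``
    and one column per scheme holding the :class:`PairLabel` value or
    ``"uncovered"`` when either protein lacks an architecture in that scheme.
    """
    by_id: Mapping[str, ProteinRecord] = {r.protein_id: r for r in records}
    rows = []
    for pair in pairs:
        row: dict[str, object] = {
            "protein_a": pair.protein_a,
            "protein_b": pair.protein_b,
            "role": pair.role,
            "sampling_scheme": pair.scheme,
        }
        rec_a = by_id[pair.protein_a]
        rec_b = by_id[pair.protein_b]
        for scheme in schemes:
            arch_a = rec_a.architecture_for(scheme)
            arch_b = rec_b.architecture_for(scheme)
            if arch_a is None or arch_b is None:
                row[scheme] = UNCOVERED
            else:
                row[scheme] = classify_pair(arch_a, arch_b).value
        rows.append(row)
    return pd.DataFrame(rows)
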
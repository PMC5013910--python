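"""Protein multi-domain architectures from domain annotations.

A protein's architecture is the ordered list of domain identifiers along its
sequence, considered at the clan/superfamily level where a grouping is
defined.  Architectures are the unit from which gold-standard homologous and
non-homologous protein pairs are derived: two multi-domain proteins are
treated as homologous when their effective architectures are identical, and
as non-homologous when they share no effective identifier at all.

This module turns per-protein domain hit tables (InterPro-style, 1-based
inclusive residue coordinates) into :class:`Architecture` objects, applying

* clan/superfamily mapping (family IDs replaced by group IDs where defined),
* collapsing of consecutive repeat/motif-type domains (Pfam scheme only,
  since repeat copy number is highly variable),
* a coverage filter discarding proteins with long unannotated regions
  (default: any run of >= 50 consecutive residues not assigned to a domain),
* a minimum-architecture-length requirement (default: two domains).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "SCHEMES",
    "ARCH_SEPARATOR",
    "DomainHit",
    "ClanMap",
    "FamilyMeta",
    "Architecture",
    "DiscardReason",
    "FilterConfig",
    "ProteinRecord",
    "max_unassigned_run",
    "build_architecture",
    "architecture_string",
    "parse_architecture_string",
    "build_protein_records",
]

#: Domain-definition schemes supported throughout the package.
SCHEMES = ("pfam", "superfamily", "gene3d")

#: Separator used in the canonical architecture string form.
ARCH_SEPARATOR = "_"


@dataclass(frozen=True)
class DomainHit:
    """One domain match on a protein: family, scheme and residue interval.

    Coordinates are 1-based and inclusive on both ends (InterPro/Pfam
    convention).
    """

    protein_id: str
    family_id: str
    start: int
    end: int
    scheme: str

    def __post_init__(self) -> None:
        if not self.family_id:
            raise ValueError(f"empty family_id for protein {self.protein_id!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}] for "
                f"{self.protein_id!r}/{self.family_id!r}: need 1 <= start <= end"
            )
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; expected one of {SCHEMES}")


class ClanMap:
    """Family -> clan/superfamily mapping for one scheme.

    Families absent from the mapping are their own group: ``group_of``
    returns the family ID unchanged.
    """

    def __init__(self, mapping: Mapping[str, str], scheme: str = "pfam"):
        self.mapping = dict(mapping)
        self.scheme = scheme

    def group_of(self, family_id: str) -> str:
        return self.mapping.get(family_id, family_id)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ClanMap)
            and self.mapping == other.mapping
            and self.scheme == other.scheme
        )

    def __repr__(self) -> str:
        return f"ClanMap(scheme={self.scheme!r}, n_mapped={len(self.mapping)})"


FAMILY_TYPES = ("domain", "repeat", "motif", "other")

#: Family types collapsed when occurring as consecutive identical copies.
COLLAPSIBLE_TYPES = frozenset({"repeat", "motif"})


class FamilyMeta:
    """Family -> type (domain/repeat/motif/other) lookup.

    Families without an explicit type default to ``"domain"``.
    """

    def __init__(self, types: Mapping[str, str] | None = None):
        types = dict(types or {})
        for fam, ftype in types.items():
            if ftype not in FAMILY_TYPES:
                raise ValueError(f"unknown family_type {ftype!r} for {fam!r}")
        self.types = types

    def type_of(self, family_id: str) -> str:
        return self.types.get(family_id, "domain")

    def is_collapsible(self, family_id: str) -> bool:
        return self.type_of(family_id) in COLLAPSIBLE_TYPES


@dataclass(frozen=True)
class Architecture:
    """Ordered effective (clan-mapped) domain identifiers of one protein."""

    effective_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "effective_ids", tuple(self.effective_ids))

    @property
    def string_form(self) -> str:
        return architecture_string(self)

    @property
    def id_set(self) -> frozenset[str]:
        return frozenset(self.effective_ids)

    def __len__(self) -> int:
        return len(self.effective_ids)

    def __str__(self) -> str:
        return self.string_form


class DiscardReason(str, enum.Enum):
    """Why a protein was excluded from a scheme's benchmark."""

    UNASSIGNED_GAP = "unassigned_gap"
    TOO_FEW_DOMAINS = "too_few_domains"
    NO_ANNOTATION = "no_annotation"


@dataclass
class FilterConfig:
    """Architecture-construction filters.

    max_unassigned_run
        A protein is discarded when it contains a run of at least this many
        consecutive residues not covered by any domain hit (terminal tails
        count).  Default 50.
    filter_enabled
        Disable to reproduce the unfiltered benchmark variant that keeps
        proteins with long unannotated (often disordered) regions.
    min_domains
        Minimum architecture length after clan mapping and repeat collapsing.
    collapse_all_duplicates
        Extend repeat collapsing to all consecutive duplicate identifiers in
        every scheme (sensitivity-analysis switch; default off, in which case
        only repeat/motif-type families collapse, and only under Pfam).
    """

    max_unassigned_run: int = 50
    filter_enabled: bool = True
    min_domains: int = 2
    collapse_all_duplicates: bool = False

    def __post_init__(self) -> None:
        if self.max_unassigned_run < 1:
            raise ValueError("max_unassigned_run must be >= 1")
        if self.min_domains < 2:
            raise ValueError("min_domains must be >= 2")


@dataclass
class ProteinRecord:
    """A benchmark protein: sequence, genome, and per-scheme architecture.

    For each scheme the protein either has an architecture or a discard
    reason, never both.
    """

    protein_id: str
    genome_id: str
    sequence: str
    architectures: dict[str, Architecture] = field(default_factory=dict)
    discard_reasons: dict[str, DiscardReason] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"empty sequence for protein {self.protein_id!r}")

    def architecture_for(self, scheme: str) -> Architecture | None:
        return self.architectures.get(scheme)


def _merged_intervals(hits: Iterable[DomainHit]) -> list[tuple[int, int]]:
    ivs = sorted((h.start, h.end) for h in hits)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def max_unassigned_run(sequence_length: int, hits: Sequence[DomainHit]) -> int:
    """Length of the longest run of residues covered by no domain hit.

    Overlapping hit intervals are merged before gap computation; uncovered
    N- and C-terminal tails count as runs.
    """
    if sequence_length < 1:
        raise ValueError("sequence_length must be >= 1")
    for h in hits:
        if h.end > sequence_length:
            raise ValueError(
                f"hit {h.protein_id!r}/{h.family_id!r} [{h.start}, {h.end}] "
                f"extends beyond sequence length {sequence_length}"
            )
    if not hits:
        return sequence_length
    merged = _merged_intervals(hits)
    longest = merged[0][0] - 1  # N-terminal tail
    for (_, prev_end), (next_start, _) in zip(merged, merged[1:]):
        longest = max(longest, next_start - prev_end - 1)
    longest = max(longest, sequence_length - merged[-1][1])  # C-terminal tail
    return longest


def _sorted_hits(hits: Sequence[DomainHit]) -> list[DomainHit]:
    # Overlaps are kept; order by start, then end, then family_id — the
    # minimal deterministic linearization.
    return sorted(hits, key=lambda h: (h.start, h.end, h.family_id))


def collapse_consecutive(
    effective_ids: Sequence[str],
    collapsible: Sequence[bool],
) -> tuple[list[str], list[bool]]:
    """Collapse runs of consecutive identical identifiers flagged collapsible.

    A copy is dropped when it equals the previously kept identifier and is
    itself collapsible.  Idempotent.
    """
    out_ids: list[str] = []
    out_flags: list[bool] = []
    for ident, flag in zip(effective_ids, collapsible):
        if out_ids and ident == out_ids[-1] and flag:
            continue
        out_ids.append(ident)
        out_flags.append(flag)
    return out_ids, out_flags


def build_architecture(
    hits: Sequence[DomainHit],
    clan_map: ClanMap,
    family_meta: FamilyMeta,
    config: FilterConfig,
    sequence_length: int,
) -> Architecture | DiscardReason:
    """Build one protein's architecture under one scheme, or a discard reason.

    Pipeline: sort hits by position, replace family IDs with group IDs where
    the clan map defines one, collapse consecutive repeat/motif copies (Pfam
    scheme only unless ``collapse_all_duplicates``), then apply the
    unassigned-region filter and the minimum-length requirement.
    """
    if not hits:
        return DiscardReason.NO_ANNOTATION
    schemes = {h.scheme for h in hits}
    if len(schemes) > 1:
        raise ValueError(f"hits span multiple schemes: {sorted(schemes)}")
    proteins = {h.protein_id for h in hits}
    if len(proteins) > 1:
        raise ValueError(f"hits span multiple proteins: {sorted(proteins)}")
    scheme = next(iter(schemes))

    ordered = _sorted_hits(hits)
    effective = [clan_map.group_of(h.family_id) for h in ordered]

    if config.collapse_all_duplicates:
        flags = [True] * len(ordered)
        effective, _ = collapse_consecutive(effective, flags)
    elif scheme == "pfam":
        flags = [family_meta.is_collapsible(h.family_id) for h in ordered]
        effective, _ = collapse_consecutive(effective, flags)

    if config.filter_enabled:
        gap = max_unassigned_run(sequence_length, ordered)
        if gap >= config.max_unassigned_run:
            return DiscardReason.UNASSIGNED_GAP
    if len(effective) < config.min_domains:
        return DiscardReason.TOO_FEW_DOMAINS
    return Architecture(tuple(effective))


def architecture_string(arch: Architecture) -> str:
    """Canonical string form: identifiers joined by underscores."""
    if not arch.effective_ids:
        raise ValueError("cannot render an empty architecture")
    for ident in arch.effective_ids:
        if ARCH_SEPARATOR in ident:
            raise ValueError(
                f"identifier {ident!r} contains the separator {ARCH_SEPARATOR!r}"
            )
    return ARCH_SEPARATOR.join(arch.effective_ids)


def parse_architecture_string(s: str) -> Architecture:
    """Inverse of :func:`architecture_string`."""
    if not s:
        raise ValueError("empty architecture string")
    return Architecture(tuple(s.split(ARCH_SEPARATOR)))


def build_protein_records(
    sequences: Mapping[str, str],
    genome_map: Mapping[str, str],
    hits: Iterable[DomainHit],
    clan_maps: Mapping[str, ClanMap],
    family_meta: FamilyMeta,
    config: FilterConfig | None = None,
    schemes: Sequence[str] = SCHEMES,
) -> list[ProteinRecord]:
    """Assemble per-protein records with one architecture attempt per scheme.

    Proteins appearing in ``sequences`` but with no hits under some scheme
    get ``DiscardReason.NO_ANNOTATION`` for that scheme.  Ordered by
    protein ID for reproducibility.
    """
    config = config or FilterConfig()
    by_protein_scheme: dict[tuple[str, str], list[DomainHit]] = {}
    for h in hits:
        if h.protein_id not in sequences:
            raise ValueError(f"hit references unknown protein {h.protein_id!r}")
        by_protein_scheme.setdefault((h.protein_id, h.scheme), []).append(h)

    records = []
    for pid in sorted(sequences):
        rec = ProteinRecord(
            protein_id=pid,
            genome_id=genome_map.get(pid, "unknown"),
            sequence=sequences[pid],
        )
        for scheme in schemes:
            result = build_architecture(
                by_protein_scheme.get((pid, scheme), []),
                clan_maps[scheme],
                family_meta,
                config,
                len(rec.sequence),
            )
            if isinstance(result, Architecture):
                rec.architectures[scheme] = result
            else:
                rec.discard_reasons[scheme] = result
        records.append(rec)
    return records
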
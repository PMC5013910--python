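"""Self-contained mock proteomes with controlled homology structure.

The generator emulates the statistical structure the benchmark assumes:
domain families (some grouped into clans, some repeat/motif-type),
multi-domain architectures shared within and across mock genomes, protein
sequences built from per-family consensus copies under a tunable point
mutation and indel process, random inter-domain linkers, and occasional
unannotated low-complexity insertions (the classic false-positive bait for
sequence-similarity searches).  Every annotation table, mapping table and
FASTA file the rest of the package consumes is emitted, together with the
ground truth needed for assertions.

The sequence model is deliberately minimal: uniform amino-acid background,
uniform substitutions over the 19 alternatives, single-residue indels with
geometric extension.  It exercises alignment scoring; it does not attempt
phylogenetic realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .architectures import (
    SCHEMES,
    Architecture,
    ClanMap,
    DomainHit,
    FamilyMeta,
    collapse_consecutive,
)
from .sampling import classify_pair

__all__ = [
    "SynthConfig",
    "Families",
    "SynthBundle",
    "generate_families",
    "generate_proteome",
    "generate_benchmark_fixture",
]

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class SynthConfig:
    """Knobs of the mock-proteome generator.

    Defaults give a small benchmark (12 families, 8 architectures, 3 mock
    genomes, 3 proteins per architecture per genome) that runs end-to-end
    in seconds.  Domain units are motif-scale (15-35 residues) so that at
    intermediate divergence the homologous signal sits near the
    random-local-alignment background — the remote-homology twilight zone
    a challenging benchmark must probe; with longer units even heavily
    mutated pairs remain trivially separable.  ``mutation_rate`` is the
    per-residue substitution probability applied to each domain copy
    independently (pairwise divergence is roughly twice it);
    ``scheme_divergence`` is the per-family probability that the
    second/third annotation scheme draws its clan boundary differently
    (granularity only — never domain order).
    """

    n_families: int = 12
    n_clans: int = 3
    clan_assignment_fraction: float = 0.5
    n_architectures: int = 8
    domains_per_architecture: tuple[int, int] = (2, 3)
    n_genomes: int = 3
    proteins_per_architecture_per_genome: int = 3
    domain_length: tuple[int, int] = (15, 35)
    linker_length: tuple[int, int] = (5, 30)
    mutation_rate: float = 0.3
    indel_rate: float = 0.03
    low_complexity_insertion_probability: float = 0.1
    repeat_family_fraction: float = 0.25
    #: probability that a repeat-type domain slot is emitted as 2-3 copies.
    #: Off by default: per-protein copy-number variation is a cross-scheme
    #: disagreement source of its own (collapsing is Pfam-only), so it is a
    #: separate knob rather than part of scheme_divergence.
    repeat_expansion_probability: float = 0.0
    scheme_divergence: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "clan_assignment_fraction",
            "mutation_rate",
            "indel_rate",
            "low_complexity_insertion_probability",
            "repeat_family_fraction",
            "repeat_expansion_probability",
            "scheme_divergence",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_clans > self.n_families:
            raise ValueError("n_clans must be <= n_families")
        for name in ("domains_per_architecture", "domain_length", "linker_length"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        if self.domains_per_architecture[0] < 2:
            raise ValueError("architectures need at least 2 domain slots")
        if self.domains_per_architecture[1] > self.n_families:
            raise ValueError(
                "architecture length exceeds the number of distinct families"
            )


@dataclass
class Families:
    """Family consensus sequences plus metadata and per-scheme clan maps."""

    consensus: dict[str, str]
    meta: FamilyMeta
    clan_maps: dict[str, ClanMap]


@dataclass
class SynthBundle:
    """Everything a benchmark run consumes, plus ground truth."""

    config: SynthConfig
    families: Families
    sequences: dict[str, str]
    genome_map: dict[str, str]
    annotations: pd.DataFrame  # protein_id, scheme, family_id, start, end
    #: family-level domain-ID tuple per protein (pre-mapping, pre-collapse)
    family_architectures: dict[str, tuple[str, ...]]
    #: effective ground-truth architecture per (protein, scheme)
    true_architectures: dict[tuple[str, str], Architecture]

    def domain_hits(self) -> list[DomainHit]:
        return [
            DomainHit(
                protein_id=row.protein_id,
                family_id=row.family_id,
                start=int(row.start),
                end=int(row.end),
                scheme=row.scheme,
            )
            for row in self.annotations.itertuples(index=False)
        ]

    def true_label(self, protein_a: str, protein_b: str, scheme: str):
        return classify_pair(
            self.true_architectures[(protein_a, scheme)],
            self.true_architectures[(protein_b, scheme)],
        )

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Emit FASTA + TSV inputs; returns the paths written."""
        from . import io as pio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": out / "proteins.fasta",
            "annotations": out / "annotations.tsv",
            "clan_map": out / "clan_map.tsv",
            "family_types": out / "family_types.tsv",
            "genome_map": out / "genome_map.tsv",
        }
        pio.write_fasta(self.sequences, paths["fasta"])
        pio.write_annotations(self.annotations, paths["annotations"])
        pio.write_clan_maps(self.families.clan_maps, paths["clan_map"])
        pio.write_family_types(self.families.meta, paths["family_types"])
        pio.write_genome_map(self.genome_map, paths["genome_map"])
        return paths


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(AMINO_ACIDS[rng.integers(20, size=length)])


def generate_families(
    config: SynthConfig, rng: np.random.Generator | None = None
) -> Families:
    """Consensus sequences, repeat flags and per-scheme clan maps."""
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    family_ids = [f"F{i:03d}" for i in range(config.n_families)]
    consensus = {
        fid: _random_sequence(
            rng, int(rng.integers(config.domain_length[0], config.domain_length[1] + 1))
        )
        for fid in family_ids
    }

    n_repeat = int(round(config.repeat_family_fraction * config.n_families))
    repeat_fids = list(rng.choice(family_ids, size=n_repeat, replace=False))
    meta = FamilyMeta({fid: "repeat" for fid in repeat_fids})

    n_in_clans = int(round(config.clan_assignment_fraction * config.n_families))
    clan_members = list(rng.choice(family_ids, size=n_in_clans, replace=False))
    base_map: dict[str, str] = {}
    if config.n_clans > 0:
        for i, fid in enumerate(sorted(clan_members)):
            base_map[fid] = f"CL{i % config.n_clans:03d}"

    clan_maps: dict[str, ClanMap] = {SCHEMES[0]: ClanMap(dict(base_map), SCHEMES[0])}
    for scheme in SCHEMES[1:]:
        derived = dict(base_map)
        for fid in family_ids:
            if rng.random() >= config.scheme_divergence:
                continue
            if fid in derived:
                del derived[fid]  # split: family becomes its own group
            elif config.n_clans > 0 and base_map:
                # merge into an existing clan (none are invented: a scheme
                # without clans stays without clans)
                derived[fid] = f"CL{int(rng.integers(config.n_clans)):03d}"
        clan_maps[scheme] = ClanMap(derived, scheme)
    return Families(consensus=consensus, meta=meta, clan_maps=clan_maps)


def _mutate_domain(
    rng: np.random.Generator, consensus: str, config: SynthConfig
) -> str:
    """Point mutations plus single-residue indels with geometric extension."""
    out: list[str] = []
    for ch in consensus:
        r = rng.random()
        if r < config.indel_rate / 2:  # deletion
            continue
        if r < config.indel_rate:  # insertion before the residue
            ins_len = 1 + int(rng.geometric(0.5)) - 1
            out.append(_random_sequence(rng, ins_len))
        if rng.random() < config.mutation_rate:
            alternatives = AMINO_ACIDS[AMINO_ACIDS != ch]
            out.append(str(alternatives[rng.integers(len(alternatives))]))
        else:
            out.append(ch)
    if not out:  # pathological deletion of everything
        out.append(_random_sequence(rng, 1))
    return "".join(out)


def _low_complexity_segment(rng: np.random.Generator) -> str:
    """Homopolymer or dipeptide run of 20-60 residues, never annotated."""
    length = int(rng.integers(20, 61))
    if rng.random() < 0.5:
        return str(AMINO_ACIDS[rng.integers(20)]) * length
    a, b = AMINO_ACIDS[rng.choice(20, size=2, replace=False)]
    return (str(a) + str(b)) * (length // 2) + (str(a) if length % 2 else "")


def _true_architecture(
    family_ids: Sequence[str],
    clan_map: ClanMap,
    meta: FamilyMeta,
    scheme: str,
) -> Architecture:
    effective = [clan_map.group_of(fid) for fid in family_ids]
    if scheme == "pfam":
        flags = [meta.is_collapsible(fid) for fid in family_ids]
        effective, _ = collapse_consecutive(effective, flags)
    return Architecture(tuple(effective))


def generate_proteome(
    families: Families,
    config: SynthConfig,
    rng: np.random.Generator | None = None,
) -> SynthBundle:
    """Architectures, genomes, mutated protein sequences and annotations."""
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed + 1)
    family_ids = sorted(families.consensus)

    # distinct architectures (families unique within each); distinctness is
    # enforced at the effective clan level of the base scheme — two family
    # tuples with one effective architecture would be the same PMDA
    base_scheme = SCHEMES[0]
    architectures: list[tuple[str, ...]] = []
    seen_effective: set[tuple[str, ...]] = set()
    attempts = 0
    while len(architectures) < config.n_architectures:
        attempts += 1
        if attempts > 1000 * config.n_architectures:
            raise ValueError("cannot draw enough distinct architectures; enlarge config")
        length = int(
            rng.integers(
                config.domains_per_architecture[0],
                config.domains_per_architecture[1] + 1,
            )
        )
        arch = tuple(rng.choice(family_ids, size=length, replace=False))
        effective = _true_architecture(
            arch, families.clan_maps[base_scheme], families.meta, base_scheme
        ).effective_ids
        if effective not in seen_effective:
            seen_effective.add(effective)
            architectures.append(arch)

    genome_ids = [f"genome{g:02d}" for g in range(config.n_genomes)]
    sequences: dict[str, str] = {}
    genome_map: dict[str, str] = {}
    family_architectures: dict[str, tuple[str, ...]] = {}
    true_architectures: dict[tuple[str, str], Architecture] = {}
    ann_rows: list[dict[str, object]] = []

    for a_idx, arch in enumerate(architectures):
        for genome in genome_ids:
            for rep in range(config.proteins_per_architecture_per_genome):
                pid = f"{genome}_arch{a_idx:02d}_p{rep}"
                # expand repeat-type slots into consecutive copies
                slots: list[str] = []
                for fid in arch:
                    copies = 1
                    if families.meta.is_collapsible(fid) and (
                        rng.random() < config.repeat_expansion_probability
                    ):
                        copies = int(rng.integers(2, 4))
                    slots.extend([fid] * copies)

                parts: list[str] = []
                pos = 0  # 0-based length so far
                lo, hi = config.linker_length

                def _linker() -> str:
                    seg = _random_sequence(rng, int(rng.integers(lo, hi + 1)))
                    if rng.random() < config.low_complexity_insertion_probability:
                        cut = int(rng.integers(len(seg) + 1)) if seg else 0
                        seg = seg[:cut] + _low_complexity_segment(rng) + seg[cut:]
                    return seg

                tail = _linker()
                parts.append(tail)
                pos += len(tail)
                for s_idx, fid in enumerate(slots):
                    domain_seq = _mutate_domain(rng, families.consensus[fid], config)
                    start = pos + 1  # 1-based inclusive
                    end = pos + len(domain_seq)
                    parts.append(domain_seq)
                    pos = end
                    for scheme in SCHEMES:
                        ann_rows.append(
                            {
                                "protein_id": pid,
                                "scheme": scheme,
                                "family_id": fid,
                                "start": start,
                                "end": end,
                            }
                        )
                    if s_idx < len(slots) - 1:
                        linker = _linker()
                        parts.append(linker)
                        pos += len(linker)
                tail = _linker()
                parts.append(tail)
                pos += len(tail)

                sequences[pid] = "".join(parts)
                genome_map[pid] = genome
                family_architectures[pid] = tuple(slots)
                for scheme in SCHEMES:
                    true_architectures[(pid, scheme)] = _true_architecture(
                        slots, families.clan_maps[scheme], families.meta, scheme
                    )

    annotations = pd.DataFrame(
        ann_rows, columns=["protein_id", "scheme", "family_id", "start", "end"]
    )
    return SynthBundle(
        config=config,
        families=families,
        sequences=sequences,
        genome_map=genome_map,
        annotations=annotations,
        family_architectures=family_architectures,
        true_architectures=true_architectures,
    )


def generate_benchmark_fixture(
    config: SynthConfig | None = None,
    out_dir: str | Path | None = None,
) -> SynthBundle:
    """One call yielding the complete input bundle (optionally written out)."""
    config = config or SynthConfig()
    rng = np.random.default_rng(config.rng_seed)
    families = generate_families(config, rng)
    bundle = generate_proteome(families, config, rng)
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle
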
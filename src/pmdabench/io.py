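"""Readers and writers for the package's plain-text interchange formats.

All tables are UTF-8, tab-separated, with a header row.  FASTA handling
goes through Biopython; the protein ID is the first whitespace-delimited
token of the header line.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .architectures import ClanMap, DomainHit, FamilyMeta
from .sampling import BenchmarkPair, PairLabel
from .scoring import ScoredPair

ANNOTATION_COLUMNS = ["protein_id", "scheme", "family_id", "start", "end"]
PAIR_COLUMNS = ["protein_a", "protein_b", "scheme", "role", "label", "anchor_architecture"]
SCORE_COLUMNS = ["protein_a", "protein_b", "tool", "bit_score", "e_value", "found", "proxy_applied"]


def read_fasta(path: str | Path) -> dict[str, str]:
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        sequences[record.id] = str(record.seq)
    return sequences


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=pid, description="") for pid, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def read_annotations(path: str | Path) -> list[DomainHit]:
    df = _read_tsv(path, ANNOTATION_COLUMNS)
    return [
        DomainHit(
            protein_id=row.protein_id,
            family_id=row.family_id,
            start=int(row.start),
            end=int(row.end),
            scheme=row.scheme,
        )
        for row in df.itertuples(index=False)
    ]


def write_annotations(annotations: pd.DataFrame, path: str | Path) -> None:
    annotations.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_clan_maps(path: str | Path) -> dict[str, ClanMap]:
    df = _read_tsv(path, ["family_id", "group_id", "scheme"])
    maps: dict[str, ClanMap] = {}
    for scheme, sub in df.groupby("scheme", sort=True):
        maps[str(scheme)] = ClanMap(
            dict(zip(sub["family_id"], sub["group_id"])), str(scheme)
        )
    return maps


def write_clan_maps(clan_maps: Mapping[str, ClanMap], path: str | Path) -> None:
    rows = [
        {"family_id": fid, "group_id": gid, "scheme": scheme}
        for scheme in sorted(clan_maps)
        for fid, gid in sorted(clan_maps[scheme].mapping.items())
    ]
    pd.DataFrame(rows, columns=["family_id", "group_id", "scheme"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def read_family_types(path: str | Path) -> FamilyMeta:
    df = _read_tsv(path, ["family_id", "family_type"])
    return FamilyMeta(dict(zip(df["family_id"], df["family_type"])))


def write_family_types(meta: FamilyMeta, path: str | Path) -> None:
    rows = [
        {"family_id": fid, "family_type": ftype}
        for fid, ftype in sorted(meta.types.items())
    ]
    pd.DataFrame(rows, columns=["family_id", "family_type"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def read_genome_map(path: str | Path) -> dict[str, str]:
    df = _read_tsv(path, ["protein_id", "genome_id"])
    return dict(zip(df["protein_id"], df["genome_id"]))


def write_genome_map(genome_map: Mapping[str, str], path: str | Path) -> None:
    rows = [
        {"protein_id": pid, "genome_id": gid} for pid, gid in sorted(genome_map.items())
    ]
    pd.DataFrame(rows, columns=["protein_id", "genome_id"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def write_pairs(pairs: Sequence[BenchmarkPair], path: str | Path) -> None:
    rows = [
        {
            "protein_a": p.protein_a,
            "protein_b": p.protein_b,
            "scheme": p.scheme,
            "role": p.role,
            "label": p.label.value,
            "anchor_architecture": p.anchor_architecture,
        }
        for p in pairs
    ]
    pd.DataFrame(rows, columns=PAIR_COLUMNS).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def read_pairs(path: str | Path) -> list[BenchmarkPair]:
    df = _read_tsv(path, PAIR_COLUMNS)
    return [
        BenchmarkPair(
            protein_a=row.protein_a,
            protein_b=row.protein_b,
            scheme=row.scheme,
            label=PairLabel(row.label),
            role=row.role,
            anchor_architecture=row.anchor_architecture,
        )
        for row in df.itertuples(index=False)
    ]


def write_scores(scored: Sequence[ScoredPair], path: str | Path) -> None:
    rows = [
        {
            "protein_a": sp.pair.protein_a,
            "protein_b": sp.pair.protein_b,
            "tool": sp.tool_name,
            "bit_score": f"{sp.bit_score:.6g}",
            "e_value": "" if sp.e_value is None else f"{sp.e_value:.6g}",
            "found": str(sp.found).lower(),
            "proxy_applied": str(sp.proxy_applied).lower(),
        }
        for sp in scored
    ]
    pd.DataFrame(rows, columns=SCORE_COLUMNS).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def read_scores(
    path: str | Path, pairs: Sequence[BenchmarkPair]
) -> list[ScoredPair]:
    """Re-attach stored scores to their benchmark pairs (order-aligned)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if len(df) != len(pairs):
        raise ValueError(
            f"{path}: {len(df)} score rows but {len(pairs)} benchmark pairs"
        )
    scored = []
    for pair, row in zip(pairs, df.itertuples(index=False)):
        if (row.protein_a, row.protein_b) != (pair.protein_a, pair.protein_b):
            raise ValueError(
                f"{path}: score row ({row.protein_a}, {row.protein_b}) does not "
                f"match pair ({pair.protein_a}, {pair.protein_b})"
            )
        e_raw = row.e_value
        e_value = None if (e_raw is None or pd.isna(e_raw) or e_raw == "") else float(e_raw)
        scored.append(
            ScoredPair(
                pair=pair,
                tool_name=row.tool,
                bit_score=float(row.bit_score),
                e_value=e_value,
                found=row.found == "true",
                proxy_applied=row.proxy_applied == "true",
            )
        )
    return scored
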
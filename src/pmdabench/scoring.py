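"""Pairwise scoring of benchmark pairs through a uniform adapter contract.

Each benchmark pair is scored in a 1-to-1 setup — one protein as query, the
other as a single-sequence database.  Adapters wrap external search tools
(invoked with maximally inclusive reporting thresholds and parsed from their
tabular output); a built-in Smith–Waterman local aligner is always available
so the pipeline never depends on third-party binaries.  Only the single best
HSP's bit score is used per pair, with no merging of hit fragments.  Pairs
for which a tool reports no alignment at all receive a maximally poor proxy
score of 0 bits.
"""

from __future__ import annotations

import logging
import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import biotite.sequence as bseq
import biotite.sequence.align as balign
import numpy as np

from .sampling import BenchmarkPair

__all__ = [
    "ScoringParams",
    "ScoreOutcome",
    "ScoredPair",
    "ToolAdapter",
    "BuiltinAligner",
    "ExternalToolAdapter",
    "smith_waterman_score",
    "raw_to_bits_and_evalue",
    "score_pairs",
    "parse_tool_tabular",
    "TabularParseError",
]

logger = logging.getLogger(__name__)

#: Residues accepted by the built-in aligner (X scores near-neutrally).
ALLOWED_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

LN2 = math.log(2.0)


@dataclass
class ScoringParams:
    """Built-in aligner constants.

    ``matrix_name`` is either a named substitution matrix (``"BLOSUM62"``)
    or ``"simple:<match>,<mismatch>"`` for a uniform match/mismatch matrix.
    Gap convention: a gap of length L costs ``gap_open + (L-1)*gap_extend``
    (the opening penalty covers the first gapped residue), so a linear gap
    model is obtained with ``gap_open == gap_extend``.  ``lam`` and ``k``
    are Karlin–Altschul parameters converting raw scores to bit scores.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    lam: float = 0.267
    k: float = 0.041

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")
        if self.lam <= 0 or self.k <= 0:
            raise ValueError("Karlin-Altschul lambda and K must be > 0")


@dataclass(frozen=True)
class ScoreOutcome:
    """What an adapter reports for one query/database pair."""

    bit_score: float | None
    e_value: float | None
    found: bool

    def __post_init__(self) -> None:
        if not self.found and (self.bit_score is not None or self.e_value is not None):
            raise ValueError("found=False outcomes carry no scores")
        if self.found and (self.bit_score is None or not math.isfinite(self.bit_score)):
            raise ValueError("found=True outcomes need a finite bit score")


@dataclass(frozen=True)
class ScoredPair:
    """A benchmark pair with its best-HSP score from one tool."""

    pair: BenchmarkPair
    tool_name: str
    bit_score: float
    e_value: float | None
    found: bool
    proxy_applied: bool

    def __post_init__(self) -> None:
        if self.proxy_applied and self.bit_score != 0.0:
            raise ValueError("proxy-scored pairs carry bit_score 0")
        if self.found and self.proxy_applied:
            raise ValueError("found pairs are never proxy-scored")


@runtime_checkable
class ToolAdapter(Protocol):
    """Contract every scoring backend fulfils."""

    tool_name: str

    def score(self, query_sequence: str, database_sequence: str) -> ScoreOutcome: ...

    def available(self) -> bool: ...


_MATRIX_CACHE: dict[str, balign.SubstitutionMatrix] = {}


def _substitution_matrix(name: str) -> balign.SubstitutionMatrix:
    if name in _MATRIX_CACHE:
        return _MATRIX_CACHE[name]
    if name.startswith("simple:"):
        try:
            match_s, mismatch_s = name.removeprefix("simple:").split(",")
            match, mismatch = float(match_s), float(mismatch_s)
        except ValueError as exc:
            raise ValueError(f"bad simple matrix spec {name!r}") from exc
        alph = bseq.ProteinSequence.alphabet
        n = len(alph)
        scores = np.full((n, n), int(mismatch), dtype=np.int32)
        np.fill_diagonal(scores, int(match))
        matrix = balign.SubstitutionMatrix(alph, alph, scores)
    else:
        matrix = balign.SubstitutionMatrix(
            bseq.ProteinSequence.alphabet,
            bseq.ProteinSequence.alphabet,
            name,
        )
    _MATRIX_CACHE[name] = matrix
    return matrix


def _validate_sequence(seq: str, which: str) -> None:
    if not seq:
        raise ValueError(f"{which} sequence is empty")
    for i, ch in enumerate(seq):
        if ch not in ALLOWED_RESIDUES:
            raise ValueError(
                f"illegal character {ch!r} at position {i + 1} of {which} sequence"
            )


def smith_waterman_score(seq_a: str, seq_b: str, params: ScoringParams) -> float:
    """Maximum local alignment score under affine gaps (>= 0).

    Sequences are over the 20-letter amino-acid alphabet plus X.
    """
    _validate_sequence(seq_a, "first")
    _validate_sequence(seq_b, "second")
    matrix = _substitution_matrix(params.matrix_name)
    alignments = balign.align_optimal(
        bseq.ProteinSequence(seq_a),
        bseq.ProteinSequence(seq_b),
        matrix,
        gap_penalty=(-params.gap_open, -params.gap_extend),
        local=True,
        max_number=1,
    )
    return float(max(alignments[0].score, 0))


def raw_to_bits_and_evalue(
    raw_score: float, m: int, n: int, params: ScoringParams
) -> tuple[float, float]:
    """Karlin–Altschul conversion of a raw local alignment score.

    bit_score = (lambda * raw - ln K) / ln 2, clamped at 0 so the proxy
    score is always the minimum; E = m * n * 2^(-bit_score).
    """
    if m <= 0 or n <= 0:
        raise ValueError("sequence lengths must be positive")
    if raw_score < 0:
        raise ValueError("raw score must be >= 0")
    bits = (params.lam * raw_score - math.log(params.k)) / LN2
    bits = max(bits, 0.0)
    e_value = m * n * 2.0 ** (-bits)
    return bits, e_value


class BuiltinAligner:
    """Reference scorer: exact Smith–Waterman with bit-score conversion."""

    def __init__(self, params: ScoringParams | None = None):
        self.params = params or ScoringParams()
        self.tool_name = "builtin_sw"

    def available(self) -> bool:
        return True

    def score(self, query_sequence: str, database_sequence: str) -> ScoreOutcome:
        raw = smith_waterman_score(query_sequence, database_sequence, self.params)
        bits, e_value = raw_to_bits_and_evalue(
            raw, len(query_sequence), len(database_sequence), self.params
        )
        return ScoreOutcome(bit_score=bits, e_value=e_value, found=True)


class TabularParseError(ValueError):
    def __init__(self, line_number: int, message: str):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


DIALECTS = ("blast_tab", "hmmer_domtbl", "fasta_m8", "usearch_b6")


def parse_tool_tabular(
    output_text: str, dialect: str
) -> tuple[float | None, float | None, bool]:
    """Extract the best-HSP (maximum bit score) record from tool output.

    ``blast_tab``, ``fasta_m8`` and ``usearch_b6`` share the 12-column
    BLAST tabular layout (E-value in column 11, bit score in column 12);
    ``hmmer_domtbl`` is HMMER's per-domain table (per-domain score and
    independent E-value).  Returns ``(None, None, False)`` for output with
    no hit lines.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    best: tuple[float, float] | None = None
    for lineno, line in enumerate(output_text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if dialect == "hmmer_domtbl":
            fields = stripped.split()
            if len(fields) < 14:
                raise TabularParseError(lineno, f"expected >= 14 fields, got {len(fields)}")
            try:
                e_value = float(fields[12])  # independent (per-domain) E-value
                bits = float(fields[13])
            except ValueError as exc:
                raise TabularParseError(lineno, str(exc)) from exc
        else:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12:
                fields = stripped.split()
            if len(fields) < 12:
                raise TabularParseError(lineno, f"expected >= 12 fields, got {len(fields)}")
            try:
                e_value = float(fields[10])
                bits = float(fields[11])
            except ValueError as exc:
                raise TabularParseError(lineno, str(exc)) from exc
        if best is None or bits > best[0]:
            best = (bits, e_value)
    if best is None:
        return None, None, False
    return best[0], best[1], True


@dataclass
class ExternalToolAdapter:
    """Invoke an installed search tool once per pair and parse its output.

    ``argv_template`` entries may contain ``{query}`` and ``{db}``
    placeholders, replaced by temporary single-record FASTA paths.  Extra
    flags (e.g. maximally inclusive E-value thresholds) belong in the
    template.  Standard output is parsed according to ``dialect``.
    """

    tool_name: str
    argv_template: Sequence[str]
    dialect: str = "blast_tab"
    timeout: float = 300.0

    def available(self) -> bool:
        return shutil.which(self.argv_template[0]) is not None

    def score(self, query_sequence: str, database_sequence: str) -> ScoreOutcome:
        if not self.available():
            raise EnvironmentError(
                f"executable {self.argv_template[0]!r} for tool "
                f"{self.tool_name!r} not found on PATH"
            )
        with tempfile.TemporaryDirectory(prefix="pmdabench_") as tmp:
            query_path = Path(tmp) / "query.fasta"
            db_path = Path(tmp) / "db.fasta"
            query_path.write_text(f">query\n{query_sequence}\n")
            db_path.write_text(f">db\n{database_sequence}\n")
            argv = [
                arg.format(query=str(query_path), db=str(db_path))
                for arg in self.argv_template
            ]
            proc = subprocess.run(
                argv, capture_output=True, text=True, timeout=self.timeout
            )
            if proc.returncode != 0:
                raise RuntimeError(
                    f"{self.tool_name} exited {proc.returncode}: {proc.stderr[:500]}"
                )
            bits, e_value, found = parse_tool_tabular(proc.stdout, self.dialect)
        if not found:
            return ScoreOutcome(bit_score=None, e_value=None, found=False)
        return ScoreOutcome(bit_score=bits, e_value=e_value, found=True)


def blastp_adapter(evalue_ceiling: float = 1e6) -> ExternalToolAdapter:
    """NCBI blastp in pairwise -subject mode, maximally inclusive reporting."""
    return ExternalToolAdapter(
        tool_name="ncbi_blastp",
        argv_template=[
            "blastp",
            "-query", "{query}",
            "-subject", "{db}",
            "-outfmt", "6",
            "-evalue", str(evalue_ceiling),
        ],
        dialect="blast_tab",
    )


def score_pairs(
    pairs: Sequence[BenchmarkPair],
    sequences: dict[str, str],
    adapter: ToolAdapter,
    direction: str = "query_a",
) -> list[ScoredPair]:
    """Score every pair, in input order, applying the proxy rule.

    ``direction="query_a"`` uses protein_a as query and protein_b as the
    database; ``"max"`` scores both directions and keeps the higher bit
    score.  Adapter failures on individual pairs are recorded as not-found
    (proxy bit score 0) rather than aborting the run; an unavailable
    external executable aborts immediately.
    """
    if direction not in ("query_a", "max"):
        raise ValueError(f"unknown direction {direction!r}")
    if not adapter.available():
        raise EnvironmentError(f"tool {adapter.tool_name!r} is not available")
    missing = [
        pid
        for pair in pairs
        for pid in (pair.protein_a, pair.protein_b)
        if pid not in sequences
    ]
    if missing:
        raise ValueError(f"sequences missing for proteins: {sorted(set(missing))[:5]}")

    scored: list[ScoredPair] = []
    for pair in pairs:
        seq_a = sequences[pair.protein_a]
        seq_b = sequences[pair.protein_b]
        try:
            outcome = adapter.score(seq_a, seq_b)
            if direction == "max":
                reverse = adapter.score(seq_b, seq_a)
                if reverse.found and (
                    not outcome.found or reverse.bit_score > outcome.bit_score
                ):
                    outcome = reverse
        except EnvironmentError:
            raise
        except Exception as exc:  # per-pair tool crash -> proxy, keep going
            logger.warning(
                "tool %s failed on pair (%s, %s): %s",
                adapter.tool_name, pair.protein_a, pair.protein_b, exc,
            )
            outcome = ScoreOutcome(bit_score=None, e_value=None, found=False)
        if outcome.found:
            scored.append(
                ScoredPair(
                    pair=pair,
                    tool_name=adapter.tool_name,
                    bit_score=float(outcome.bit_score),
                    e_value=outcome.e_value,
                    found=True,
                    proxy_applied=False,
                )
            )
        else:
            scored.append(
                ScoredPair(
                    pair=pair,
                    tool_name=adapter.tool_name,
                    bit_score=0.0,
                    e_value=None,
                    found=False,
                    proxy_applied=True,
                )
            )
    return scored
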
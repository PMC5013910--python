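"""Independent oracles and small constructors shared across the test suite.

Everything here is deliberately written from first principles (per-residue
scans, quadratic dynamic programming, explicit shuffle averaging) so that
it exercises none of the code paths it is used to check.
"""

from __future__ import annotations

import numpy as np

from pmdabench.architectures import Architecture
from pmdabench.sampling import BenchmarkPair, PairLabel
from pmdabench.scoring import ScoredPair, ScoringParams

# ---------------------------------------------------------------------------
# pair-classification oracle: direct transcription of the two textual rules

def bruteforce_classify(ids_a: tuple[str, ...], ids_b: tuple[str, ...]) -> str:
    """Homologous iff the identifier sequences match position by position;
    non-homologous iff no identifier of one occurs anywhere in the other."""
    same_order = len(ids_a) == len(ids_b) and all(
        x == y for x, y in zip(ids_a, ids_b)
    )
    if same_order:
        return "homologous"
    shares_any = False
    for x in ids_a:
        for y in ids_b:
            if x == y:
                shares_any = True
    if not shares_any:
        return "non_homologous"
    return "ambiguous"


# ---------------------------------------------------------------------------
# per-residue coverage scan: oracle for the unassigned-run computation

def bruteforce_longest_gap(length: int, intervals: list[tuple[int, int]]) -> int:
    covered = [False] * (length + 1)  # 1-based
    for s, e in intervals:
        for i in range(s, e + 1):
            covered[i] = True
    longest = run = 0
    for i in range(1, length + 1):
        run = 0 if covered[i] else run + 1
        longest = max(longest, run)
    return longest


# ---------------------------------------------------------------------------
# quadratic Gotoh local-alignment DP: oracle for the built-in aligner.
# Gap convention: a gap of length L costs open + (L-1) * extend.

BLOSUM62_TEXT: dict[tuple[str, str], int] = {}


def _pair_score(a: str, b: str, params: ScoringParams) -> float:
    if params.matrix_name.startswith("simple:"):
        match, mismatch = (float(x) for x in params.matrix_name[7:].split(","))
        return match if a == b else mismatch
    # read BLOSUM62 through biotite's data table once, by letter lookup only
    import biotite.sequence.align as balign
    import biotite.sequence as bseq

    if not BLOSUM62_TEXT:
        m = balign.SubstitutionMatrix(
            bseq.ProteinSequence.alphabet, bseq.ProteinSequence.alphabet, "BLOSUM62"
        )
        alph = list(str(c) for c in m.get_alphabet1())
        arr = m.score_matrix()
        for i, x in enumerate(alph):
            for j, y in enumerate(alph):
                BLOSUM62_TEXT[(x, y)] = int(arr[i][j])
    return float(BLOSUM62_TEXT[(a, b)])


def gotoh_local_score(seq_a: str, seq_b: str, params: ScoringParams) -> float:
    """Textbook O(nm) affine-gap local alignment, three explicit matrices."""
    n, m = len(seq_a), len(seq_b)
    neg = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in seq_b (left moves)
    F = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in seq_a (up moves)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(E[i][j - 1] - params.gap_extend,
                          H[i][j - 1] - params.gap_open)
            F[i][j] = max(F[i - 1][j] - params.gap_extend,
                          H[i - 1][j] - params.gap_open)
            diag = H[i - 1][j - 1] + _pair_score(seq_a[i - 1], seq_b[j - 1], params)
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


# ---------------------------------------------------------------------------
# shuffle-average ROC oracle

def shuffle_average_roc(
    scores: np.ndarray,
    positive: np.ndarray,
    n_shuffles: int,
    rng: np.random.Generator,
) -> tuple[float, float, np.ndarray]:
    """Mean full-curve step AUC (and its SE) plus the mean cumulative-TP
    profile after each FP, over random orderings within score ties."""
    order = np.argsort(-scores, kind="stable")
    scores = scores[order]
    labels = positive[order].astype(int)
    # boundaries of tie runs
    runs: list[tuple[int, int]] = []
    i = 0
    while i < len(scores):
        j = i
        while j < len(scores) and scores[j] == scores[i]:
            j += 1
        runs.append((i, j))
        i = j
    P = int(labels.sum())
    N = len(labels) - P
    aucs = np.empty(n_shuffles)
    tp_profiles = np.zeros((n_shuffles, N))
    for r in range(n_shuffles):
        lab = labels.copy()
        for a, b in runs:
            lab[a:b] = lab[a:b][rng.permutation(b - a)]
        tp_cum = np.cumsum(lab)
        tp_at_fp = tp_cum[lab == 0]  # TP count as each FP is passed
        tp_profiles[r] = tp_at_fp
        aucs[r] = tp_at_fp.sum() / (P * N)
    se = aucs.std(ddof=1) / np.sqrt(n_shuffles)
    return float(aucs.mean()), float(se), tp_profiles.mean(axis=0)


# ---------------------------------------------------------------------------
# compact constructors for evaluation-layer tests

def make_pair(i: int, role: str, scheme: str = "pfam") -> BenchmarkPair:
    label = PairLabel.HOMOLOGOUS if role == "positive" else PairLabel.NON_HOMOLOGOUS
    return BenchmarkPair(
        protein_a=f"pa{i:04d}",
        protein_b=f"pb{i:04d}",
        scheme=scheme,
        label=label,
        role=role,
        anchor_architecture="A_B",
    )


def make_scored(
    values_roles: list[tuple[float, str]], tool: str = "toy"
) -> list[ScoredPair]:
    out = []
    for i, (score, role) in enumerate(values_roles):
        proxy = score == 0.0 and role.endswith("!proxy")
        role = role.removesuffix("!proxy")
        out.append(
            ScoredPair(
                pair=make_pair(i, role),
                tool_name=tool,
                bit_score=float(score),
                e_value=None if proxy else 2.0 ** (-score),
                found=not proxy,
                proxy_applied=proxy,
            )
        )
    return out


def make_architecture(*ids: str) -> Architecture:
    return Architecture(tuple(ids))
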
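"""Semi-global alignment with affine, position-dependent gap penalties.

Needleman-Wunsch-style dynamic programming in which terminal (end) gaps on
both sequences are free, internal gaps cost go + L*ge for a run of length L,
and gap transitions are forbidden at cells where the query's predicted
secondary structure and the template's observed secondary structure agree on
helix or strand.  Adjacent insertion and deletion runs between two matches
are disallowed (gap states are enterable only from the match state), and an
alignment must contain at least one matched pair.

Tie-breaking in the traceback is fixed (match > deletion, i.e. gap in query,
> insertion) so alignments are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple, Union

import numpy as np

from .scoring import ScoreMatrix

__all__ = ["AlignmentResult", "gap_forbidden", "align", "recompute_score"]

NEG_INF = float("-inf")


@dataclass
class AlignmentResult:
    """Matched index pairs plus the raw DP score and gap bookkeeping."""

    pairs: List[Tuple[int, int]]
    raw_score: float
    query_len: int
    template_len: int
    #: internal gap runs as (kind, positions): kind 'query' = gap in query
    #: (template residues skipped), kind 'template' = gap in template.
    gap_segments: List[Tuple[str, List[int]]] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def gap_forbidden(i: int, j: int, q_ss: str, t_ss: str) -> bool:
    """True when no gap may be placed at cell (i, j): the two secondary
    structures agree and the shared state is helix or strand."""
    return q_ss[i] == t_ss[j] and q_ss[i] in "HE"


def align(
    matrix: Union[ScoreMatrix, np.ndarray],
    q_ss: str,
    t_ss: str,
    go: float,
    ge: float,
) -> AlignmentResult:
    """Optimal ends-free alignment of the score matrix under the gap model.

    ``go``/``ge`` are non-positive opening and extension penalties; a gap of
    length L costs go + L*ge.  Raises ValueError on an empty matrix.
    """
    E = matrix.values if isinstance(matrix, ScoreMatrix) else np.asarray(matrix, dtype=float)
    if E.ndim != 2 or E.size == 0:
        raise ValueError("score matrix must be non-empty and 2-D")
    if not np.all(np.isfinite(E)):
        raise ValueError("score matrix must be finite")
    if go > 0 or ge > 0:
        raise ValueError("gap penalties must be <= 0")
    Lq, Lt = E.shape
    if len(q_ss) != Lq or len(t_ss) != Lt:
        raise ValueError("secondary-structure strings must match matrix shape")

    # DP over prefixes: index (i, j) = q[:i] vs t[:j].  State M ends in a
    # match of (i-1, j-1); X ends in a gap-in-query consuming t[j-1]; Y ends
    # in a gap-in-template consuming q[i-1].
    M = np.full((Lq + 1, Lt + 1), NEG_INF)
    X = np.full((Lq + 1, Lt + 1), NEG_INF)
    Y = np.full((Lq + 1, Lt + 1), NEG_INF)
    # pointers: 0=fresh start, 1=M, 2=X, 3=Y
    ptr_m = np.zeros((Lq + 1, Lt + 1), dtype=np.int8)
    ptr_x = np.zeros((Lq + 1, Lt + 1), dtype=np.int8)
    ptr_y = np.zeros((Lq + 1, Lt + 1), dtype=np.int8)

    for i in range(1, Lq + 1):
        for j in range(1, Lt + 1):
            # match: free leading overhangs let any cell start fresh (value 0)
            best, src = 0.0, 0
            for val, code in ((M[i - 1, j - 1], 1), (X[i - 1, j - 1], 2), (Y[i - 1, j - 1], 3)):
                if val > best:
                    best, src = val, code
            M[i, j] = E[i - 1, j - 1] + best
            ptr_m[i, j] = src

            if not gap_forbidden(i - 1, j - 1, q_ss, t_ss):
                open_x = M[i, j - 1] + go + ge
                ext_x = X[i, j - 1] + ge
                if open_x >= ext_x:
                    X[i, j], ptr_x[i, j] = open_x, 1
                else:
                    X[i, j], ptr_x[i, j] = ext_x, 2
                open_y = M[i - 1, j] + go + ge
                ext_y = Y[i - 1, j] + ge
                if open_y >= ext_y:
                    Y[i, j], ptr_y[i, j] = open_y, 1
                else:
                    Y[i, j], ptr_y[i, j] = ext_y, 3

    # free trailing overhangs: alignment may end with a match anywhere
    end = (1, 1)
    best = NEG_INF
    for i in range(1, Lq + 1):
        for j in range(1, Lt + 1):
            if M[i, j] > best:
                best, end = M[i, j], (i, j)
    raw_score = float(best)

    pairs: List[Tuple[int, int]] = []
    gap_segments: List[Tuple[str, List[int]]] = []
    i, j = end
    state = 1
    current_gap: List[int] = []
    current_kind = ""
    while True:
        if state == 1:
            pairs.append((i - 1, j - 1))
            src = ptr_m[i, j]
            i, j = i - 1, j - 1
            if src == 0:
                break
            state = src
        elif state == 2:  # gap in query, consumed t[j-1]
            if current_kind != "query":
                if current_gap:
                    gap_segments.append((current_kind, current_gap[::-1]))
                current_gap, current_kind = [], "query"
            current_gap.append(j - 1)
            src = ptr_x[i, j]
            j -= 1
            if src == 1:
                gap_segments.append((current_kind, current_gap[::-1]))
                current_gap, current_kind = [], ""
                state = 1
        else:  # gap in template, consumed q[i-1]
            if current_kind != "template":
                if current_gap:
                    gap_segments.append((current_kind, current_gap[::-1]))
                current_gap, current_kind = [], "template"
            current_gap.append(i - 1)
            src = ptr_y[i, j]
            i -= 1
            if src == 1:
                gap_segments.append((current_kind, current_gap[::-1]))
                current_gap, current_kind = [], ""
                state = 1
    pairs.reverse()
    gap_segments.reverse()
    return AlignmentResult(
        pairs=pairs,
        raw_score=raw_score,
        query_len=Lq,
        template_len=Lt,
        gap_segments=gap_segments,
    )


def recompute_score(
    result: AlignmentResult,
    matrix: Union[ScoreMatrix, np.ndarray],
    go: float,
    ge: float,
) -> float:
    """Re-sum an alignment's score independently of the DP.

    Adds E(i, j) over matched pairs plus go + L*ge for every internal gap run
    inferred from the pair list.  Raises ValueError on inconsistent pairs.
    """
    E = matrix.values if isinstance(matrix, ScoreMatrix) else np.asarray(matrix, dtype=float)
    if not result.pairs:
        raise ValueError("alignment has no matched pairs")
    score = 0.0
    prev = None
    for i, j in result.pairs:
        if not (0 <= i < E.shape[0] and 0 <= j < E.shape[1]):
            raise ValueError(f"pair ({i}, {j}) outside the matrix")
        if prev is not None:
            di, dj = i - prev[0] - 1, j - prev[1] - 1
            if di < 0 or dj < 0:
                raise ValueError("pairs are not strictly increasing")
            if di > 0 and dj > 0:
                raise ValueError("adjacent insertion and deletion between matches")
            if di > 0:
                score += go + di * ge
            if dj > 0:
                score += go + dj * ge
        score += E[i, j]
        prev = (i, j)
    return score
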
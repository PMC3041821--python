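"""Score normalization and template ranking.

Raw alignment scores grow with length, so templates are compared on two
normalized scores: Sn1 divides the raw score S by the full alignment length
including every gap column, Sn2 by the alignment length excluding the query's
terminal gap columns (the template overhangs).  A query's template library is
ranked by whichever mode attains the larger maximum, with Sn1 winning ties.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

from .align import AlignmentResult

__all__ = ["TemplateRanking", "normalized_scores", "rank_templates", "write_ranking"]


@dataclass
class TemplateRanking:
    """Ordered templates with raw and normalized scores.

    ``entries`` maps template id -> (S, Sn1, Sn2); ``order`` lists ids by the
    chosen mode's score, descending, ties broken by id.
    """

    entries: Dict[str, Tuple[float, float, float]]
    chosen_mode: str
    order: List[str]

    @property
    def top(self) -> str:
        return self.order[0]


def normalized_scores(result: AlignmentResult) -> Tuple[float, float]:
    """Return (Sn1, Sn2) for one alignment.

    The full alignment length (Sn1 denominator) counts one column per matched
    pair and one per gapped residue on either sequence, terminal overhangs
    included: Lq + Lt - n_pairs.  Sn2 removes the query-side ending gap
    columns, i.e. the template residues overhanging before the first and
    after the last matched pair.
    """
    if not result.pairs:
        raise ValueError("cannot normalize an empty alignment")
    n = result.n_pairs
    full_len = result.query_len + result.template_len - n
    j_first = result.pairs[0][1]
    j_last = result.pairs[-1][1]
    query_end_gaps = j_first + (result.template_len - 1 - j_last)
    sn2_len = full_len - query_end_gaps
    if full_len <= 0 or sn2_len <= 0:
        raise ValueError("zero-length normalization denominator")
    return result.raw_score / full_len, result.raw_score / sn2_len


def rank_templates(results: Dict[str, AlignmentResult]) -> TemplateRanking:
    """Rank a template library for one query.

    If the maximal Sn1 over the library is greater than or equal to the
    maximal Sn2, templates are ranked by Sn1, otherwise by Sn2.
    """
    if not results:
        raise ValueError("no alignment results to rank")
    entries = {}
    for tid, res in results.items():
        sn1, sn2 = normalized_scores(res)
        entries[tid] = (res.raw_score, sn1, sn2)
    max_sn1 = max(e[1] for e in entries.values())
    max_sn2 = max(e[2] for e in entries.values())
    mode = "Sn1" if max_sn1 >= max_sn2 else "Sn2"
    col = 1 if mode == "Sn1" else 2
    order = sorted(entries, key=lambda tid: (-entries[tid][col], tid))
    return TemplateRanking(entries=entries, chosen_mode=mode, order=order)


def write_ranking(ranking: TemplateRanking, path) -> None:
    """Write the ranking report as a tab-separated table."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("template_id\tS\tSn1\tSn2\trank\tmode\n")
        for rank, tid in enumerate(ranking.order, start=1):
            s, sn1, sn2 = ranking.entries[tid]
            fh.write(f"{tid}\t{s:.6f}\t{sn1:.6f}\t{sn2:.6f}\t{rank}\t{ranking.chosen_mode}\n")
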
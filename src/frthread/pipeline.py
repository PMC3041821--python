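"""Convenience wiring: score + align one query against templates."""

from __future__ import annotations

from typing import Dict, Iterable, Optional

import numpy as np

from .align import AlignmentResult, align
from .io_formats import QueryProfile, TemplateRecord
from .lspp import EnergyTable
from .rank_select import TemplateRanking, rank_templates
from .scoring import ScoringWeights, build_score_matrix

__all__ = ["thread_template", "thread_library"]


def thread_template(
    query: QueryProfile,
    template: TemplateRecord,
    weights: ScoringWeights,
    table3: Optional[EnergyTable] = None,
    table9: Optional[EnergyTable] = None,
    hydro_matrix: Optional[np.ndarray] = None,
) -> AlignmentResult:
    """Build the score matrix for one query/template pair and align it."""
    matrix = build_score_matrix(query, template, weights, table3, table9, hydro_matrix)
    return align(matrix, query.pred_ss, template.obs_ss, weights.go, weights.ge)


def thread_library(
    query: QueryProfile,
    templates: Iterable[TemplateRecord],
    weights: ScoringWeights,
    table3: Optional[EnergyTable] = None,
    table9: Optional[EnergyTable] = None,
    hydro_matrix: Optional[np.ndarray] = None,
) -> tuple[Dict[str, AlignmentResult], TemplateRanking]:
    """Thread a query through a template library and rank the results."""
    results = {
        t.id: thread_template(query, t, weights, table3, table9, hydro_matrix)
        for t in templates
    }
    return results, rank_templates(results)
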
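"""Alignment-accuracy evaluation and scoring-weight training.

Accuracy is the percentage of a gold-standard residue correspondence that a
threading alignment reproduces.  Training maximizes the total number of
matches with the gold alignments over a set of structure pairs by coordinate
ascent on per-parameter grids with random restarts: derivative-free,
reproducible, and adequate for the 5 (three-term mode) or 7 (five-term mode)
free parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .io_formats import QueryProfile, TemplateRecord
from .lspp import EnergyTable
from .pipeline import thread_template
from .scoring import ScoringWeights

logger = logging.getLogger(__name__)

__all__ = [
    "GoldAlignment",
    "TrainingPair",
    "TrainingConfig",
    "TrainingResult",
    "alignment_accuracy",
    "match_count_objective",
    "optimize_weights",
    "DEFAULT_GRIDS",
]

FRT3_PARAMS = ("w2", "w3", "e_shift", "go", "ge")
FRT5_PARAMS = FRT3_PARAMS + ("w4", "w5")

#: Logarithmic default grids per parameter (the gap penalties non-positive).
DEFAULT_GRIDS: Dict[str, Tuple[float, ...]] = {
    "w2": (0.0, 0.125, 0.25, 0.5, 1.0, 2.0, 4.0),
    "w3": (0.0, 0.125, 0.25, 0.5, 1.0, 2.0, 4.0),
    "w4": (0.0, 0.125, 0.25, 0.5, 1.0, 2.0, 4.0),
    "w5": (0.0, 0.125, 0.25, 0.5, 1.0, 2.0, 4.0),
    "e_shift": (-2.0, -1.0, -0.5, 0.0, 0.5),
    "go": (-8.0, -4.0, -2.0, -1.0, -0.5),
    "ge": (-2.0, -1.0, -0.5, -0.25, -0.125),
}


@dataclass
class GoldAlignment:
    """Reference residue correspondence from a structural superposition."""

    pairs: List[Tuple[int, int]]
    source: str = ""

    def __post_init__(self) -> None:
        for (i1, j1), (i2, j2) in zip(self.pairs, self.pairs[1:]):
            if i2 <= i1 or j2 <= j1:
                raise ValueError("gold pairs must be strictly increasing in both coordinates")

    @classmethod
    def read(cls, path) -> "GoldAlignment":
        """Read a tab-separated (query_pos, template_pos) file, 0-based, with
        a header line naming the pair."""
        with open(path, "r", encoding="utf-8") as fh:
            header = fh.readline().strip().lstrip("#").strip()
            pairs = []
            for line in fh:
                if not line.strip():
                    continue
                qi, tj = line.split()[:2]
                pairs.append((int(qi), int(tj)))
        return cls(pairs=pairs, source=header)

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# {self.source or 'gold alignment'}\n")
            for qi, tj in self.pairs:
                fh.write(f"{qi}\t{tj}\n")


@dataclass
class TrainingPair:
    query: QueryProfile
    template: TemplateRecord
    gold: GoldAlignment


@dataclass
class TrainingConfig:
    """Grids, restart/sweep counts and seed for weight optimization."""

    mode: str = "fr-t5"
    grids: Dict[str, Tuple[float, ...]] = field(default_factory=lambda: dict(DEFAULT_GRIDS))
    restarts: int = 3
    max_sweeps: int = 10
    seed: int = 0

    def parameters(self) -> Tuple[str, ...]:
        if self.mode == "fr-t3":
            return FRT3_PARAMS
        if self.mode == "fr-t5":
            return FRT5_PARAMS
        raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class TrainingResult:
    weights: ScoringWeights
    objective: int
    #: (iteration, weights, objective) log; objectives are non-decreasing.
    history: List[Tuple[int, ScoringWeights, int]]


def alignment_accuracy(test, gold: GoldAlignment) -> float:
    """Percentage of gold pairs reproduced by the test alignment."""
    if not gold.pairs:
        raise ValueError("gold alignment is empty")
    test_pairs = set(test.pairs if hasattr(test, "pairs") else test)
    return 100.0 * len(test_pairs & set(gold.pairs)) / len(gold.pairs)


def match_count_objective(
    weights: ScoringWeights,
    training_pairs: Sequence[TrainingPair],
    table3: Optional[EnergyTable] = None,
    table9: Optional[EnergyTable] = None,
) -> int:
    """Total number of gold pairs reproduced over the training set."""
    total = 0
    for pair in training_pairs:
        result = thread_template(pair.query, pair.template, weights, table3, table9)
        total += len(set(result.pairs) & set(pair.gold.pairs))
    return total


def _weights_from(params: Dict[str, float]) -> ScoringWeights:
    return ScoringWeights(**params)


def optimize_weights(
    cfg: TrainingConfig,
    training_pairs: Sequence[TrainingPair],
    table3: Optional[EnergyTable] = None,
    table9: Optional[EnergyTable] = None,
) -> TrainingResult:
    """Coordinate ascent over per-parameter grids with random restarts.

    Each restart draws a start point from the grids, then sweeps the
    parameters in a fixed order, replacing each with its best grid value
    while the others are held; sweeps repeat until no improvement or
    ``max_sweeps``.  The best point visited across restarts is returned.
    Identical config and seed give identical results.
    """
    if not training_pairs:
        raise ValueError("training set is empty")
    names = cfg.parameters()
    for name in names:
        if name not in cfg.grids or not cfg.grids[name]:
            raise ValueError(f"empty grid for parameter {name!r}")
    if cfg.mode == "fr-t5" and (table3 is None or table9 is None):
        raise ValueError("fr-t5 training requires both fragment energy tables")
    rng = np.random.default_rng(cfg.seed)

    def objective(params: Dict[str, float]) -> int:
        return match_count_objective(_weights_from(params), training_pairs, table3, table9)

    best_params: Optional[Dict[str, float]] = None
    best_obj = -1
    history: List[Tuple[int, ScoringWeights, int]] = []
    iteration = 0
    for restart in range(cfg.restarts):
        params = {name: float(rng.choice(cfg.grids[name])) for name in names}
        if cfg.mode == "fr-t3":
            params["w4"] = params["w5"] = 0.0
        obj = objective(params)
        if obj > best_obj:
            best_obj, best_params = obj, dict(params)
        for sweep in range(cfg.max_sweeps):
            improved = False
            for name in names:
                best_val, best_local = params[name], obj
                for value in cfg.grids[name]:
                    if value == params[name]:
                        continue
                    trial = dict(params)
                    trial[name] = float(value)
                    trial_obj = objective(trial)
                    if trial_obj > best_local:
                        best_local, best_val = trial_obj, float(value)
                if best_val != params[name]:
                    params[name], obj, improved = best_val, best_local, True
            iteration += 1
            if obj > best_obj:
                best_obj, best_params = obj, dict(params)
            history.append((iteration, _weights_from(params), obj))
            if not improved:
                break
        logger.info("restart %d: objective %d with %s", restart, obj, params)
    assert best_params is not None
    # history reported as the running best so objectives are non-decreasing
    running: List[Tuple[int, ScoringWeights, int]] = []
    best_so_far = -1
    for it, w, obj in history:
        if obj > best_so_far:
            best_so_far = obj
            best_w = w
        running.append((it, best_w, best_so_far))
    return TrainingResult(weights=_weights_from(best_params), objective=best_obj, history=running)
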
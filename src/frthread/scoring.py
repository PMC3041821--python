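"""The five-term sequence-structure match score.

The score for aligning query position i with template position j is the
linear combination

    E(i,j) = w1*E_seq + w2*E_2nd + w3*E_hydro + w4*(-E_frag3) + w5*(-E_frag9)
             + E_shift

with w1 fixed at 1 as the scale normalization.  E_seq is the query frequency
vector dotted with the template log-odds column; E_2nd a +/-1 secondary-
structure match indicator; E_hydro a 20x20 hydrophobic-pattern score; the two
fragment terms are local structural preference potentials, negated so that
favorable (low-energy) conformations raise the match score.  The three-term
variant (FR-t3) is the special case w4 = w5 = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .geometry import BREAK, ConformationBin
from .io_formats import QueryProfile, TemplateRecord, SS_STATES
from .lspp import EnergyTable, lookup_fragment_energy
from .residues import AA20, AA_INDEX, HNP_CLASS

logger = logging.getLogger(__name__)

__all__ = [
    "ScoringWeights",
    "ScoreMatrix",
    "e_seq",
    "e_2nd",
    "e_hydro",
    "e_frag3",
    "e_frag9",
    "build_score_matrix",
    "default_hydro_matrix",
    "read_hydro_matrix",
]


@dataclass(frozen=True)
class ScoringWeights:
    """Scoring-function parameters; w1 is fixed at 1 by normalization.

    FR-t3 carries 5 free parameters (w2, w3, e_shift, go, ge); FR-t5 adds
    w4 and w5 for the two fragment potentials.  go/ge are the (non-positive)
    affine gap opening and extension penalties, applied additively.

    The defaults are the result of training on the synthetic fixture suite
    (coordinate ascent on the gold-match objective); they are fixture-trained
    values, suitable for the synthetic regime, not values calibrated on real
    structure databases.
    """

    w2: float = 4.0
    w3: float = 2.0
    w4: float = 0.0
    w5: float = 0.0
    e_shift: float = 0.0
    go: float = -4.0
    ge: float = -0.5

    w1: float = 1.0

    def __post_init__(self) -> None:
        if self.w1 != 1.0:
            raise ValueError("w1 is the scale normalization and is fixed at 1")
        for name in ("w2", "w3", "w4", "w5"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.go > 0 or self.ge > 0:
            raise ValueError("gap penalties go and ge must be <= 0")

    @property
    def mode(self) -> str:
        return "fr-t3" if self.w4 == 0.0 and self.w5 == 0.0 else "fr-t5"


@dataclass
class ScoreMatrix:
    """Per-cell alignment scores, query rows by template columns."""

    values: np.ndarray
    components: Optional[dict] = None

    @property
    def shape(self):
        return self.values.shape


def default_hydro_matrix() -> np.ndarray:
    """Hydrophobic-pattern score from HNP classes: +1 same class, -1 for
    hydrophobic vs polar, 0 otherwise."""
    m = np.zeros((20, 20))
    for a, aa in enumerate(AA20):
        for b, bb in enumerate(AA20):
            ca, cb = HNP_CLASS[aa], HNP_CLASS[bb]
            if ca == cb:
                m[a, b] = 1.0
            elif {ca, cb} == {"H", "P"}:
                m[a, b] = -1.0
    return m


def read_hydro_matrix(path) -> np.ndarray:
    """Read a whitespace-separated 20x20 matrix with a residue-order header row."""
    with open(path) as fh:
        tokens = fh.readline().split()
        if sorted(tokens) != sorted(AA20):
            raise ValueError(f"{path}: header must list the 20 standard residues")
        rows = [[float(t) for t in line.split()] for line in fh if line.strip()]
    arr = np.asarray(rows)
    if arr.shape != (20, 20):
        raise ValueError(f"{path}: expected 20x20 matrix, got {arr.shape}")
    perm = [tokens.index(aa) for aa in AA20]
    return arr[np.ix_(perm, perm)]


def e_seq(query: QueryProfile, i: int, template: TemplateRecord, j: int) -> float:
    """Profile match: query frequency vector . template log-odds column."""
    return float(np.dot(query.freq[i], template.pssm[j]))


def e_2nd(ss_q: str, ss_t: str) -> float:
    """Secondary-structure match indicator: +1 equal states, -1 otherwise."""
    if ss_q not in SS_STATES or ss_t not in SS_STATES:
        raise ValueError(f"SS states must be in {SS_STATES}")
    return 1.0 if ss_q == ss_t else -1.0


def e_hydro(aa_q: str, aa_t: str, matrix: np.ndarray) -> float:
    """Hydrophobic-pattern score m[query residue, template residue]."""
    a, b = AA_INDEX.get(aa_q), AA_INDEX.get(aa_t)
    if a is None or b is None:
        logger.warning("non-standard residue pair (%s, %s): hydrophobic score 0", aa_q, aa_t)
        return 0.0
    return float(matrix[a, b])


def _query_key3(query: QueryProfile, i: int) -> Optional[str]:
    if i < 1 or i >= len(query) - 1:
        return None
    key = query.sequence[i - 1 : i + 2]
    if any(aa not in AA20 for aa in key):
        return None
    return key


def _query_key9(query: QueryProfile, i: int) -> Optional[str]:
    if i < 4 or i >= len(query) - 4:
        return None
    return query.hnp[i - 4 : i + 5]


def _frag_term(table: EnergyTable, key: Optional[str], bin_entry) -> float:
    """Fragment energy assuming the query fragment adopts the template
    conformation; any undefined side scores the reference value 0."""
    if bin_entry is BREAK:
        return lookup_fragment_energy(table, key or "", ConformationBin(0, 0, 0, 0), True)
    if key is None or bin_entry is None:
        return 0.0
    return lookup_fragment_energy(table, key, bin_entry, False)


def e_frag3(query: QueryProfile, i: int, template: TemplateRecord, j: int,
            table3: EnergyTable) -> float:
    return _frag_term(table3, _query_key3(query, i), template.bins3[j])


def e_frag9(query: QueryProfile, i: int, template: TemplateRecord, j: int,
            table9: EnergyTable) -> float:
    return _frag_term(table9, _query_key9(query, i), template.bins9[j])


def build_score_matrix(
    query: QueryProfile,
    template: TemplateRecord,
    weights: ScoringWeights,
    table3: Optional[EnergyTable] = None,
    table9: Optional[EnergyTable] = None,
    hydro_matrix: Optional[np.ndarray] = None,
    keep_components: bool = False,
) -> ScoreMatrix:
    """Assemble the full query x template score matrix.

    Fragment tables are required only when their weights are nonzero, so the
    FR-t3 path never touches a potential table.
    """
    Lq, Lt = len(query), len(template)
    seq_term = query.freq @ template.pssm.T

    q_ss = np.frombuffer(query.pred_ss.encode(), dtype=np.uint8)
    t_ss = np.frombuffer(template.obs_ss.encode(), dtype=np.uint8)
    ss_term = np.where(q_ss[:, None] == t_ss[None, :], 1.0, -1.0)

    if hydro_matrix is None:
        hydro_matrix = default_hydro_matrix()
    m21 = np.zeros((21, 21))
    m21[:20, :20] = hydro_matrix
    q_idx = np.array([AA_INDEX.get(aa, 20) for aa in query.sequence])
    t_idx = np.array([AA_INDEX.get(aa, 20) for aa in template.sequence])
    hydro_term = m21[np.ix_(q_idx, t_idx)]

    total = weights.w1 * seq_term + weights.w2 * ss_term + weights.w3 * hydro_term
    components = {"seq": seq_term, "ss": ss_term, "hydro": hydro_term}

    for w, table, key_fn, bins in (
        (weights.w4, table3, _query_key3, "bins3"),
        (weights.w5, table9, _query_key9, "bins9"),
    ):
        if w == 0.0:
            continue
        if table is None:
            raise ValueError(f"nonzero fragment weight requires a {bins} energy table")
        frag = np.zeros((Lq, Lt))
        keys = [key_fn(query, i) for i in range(Lq)]
        bin_entries = getattr(template, bins)
        for j, entry in enumerate(bin_entries):
            if entry is None:
                continue
            if entry is BREAK:
                continue  # break and undefined both contribute 0
            col_cache = {}
            for i, key in enumerate(keys):
                if key is None:
                    continue
                val = col_cache.get(key)
                if val is None:
                    val = lookup_fragment_energy(table, key, entry, False)
                    col_cache[key] = val
                frag[i, j] = val
        total = total + w * (-frag)
        components[bins] = frag

    total = total + weights.e_shift
    return ScoreMatrix(values=total, components=components if keep_components else None)
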
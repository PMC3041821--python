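"""Readers for the external file formats the threader consumes.

Supported dialects: PDB ATOM records (via Biopython), the PSI-BLAST ASCII
PSSM, PSIPRED VFORMAT ss2 files, and classic DSSP output.  All readers accept
plain or gzip-compressed input.  An internal torsion-box secondary-structure
assignment is provided as a fallback so no external binary is ever executed:
profile search and secondary-structure prediction/assignment are documented
upstream protocols, not steps this package performs.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from Bio.PDB import PDBParser
from Bio.SeqUtils import seq1

from . import geometry
from .geometry import BackboneStructure, CA_BREAK_DISTANCE
from .residues import AA20, AA_INDEX, hnp_reduce

logger = logging.getLogger(__name__)

__all__ = [
    "QueryProfile",
    "TemplateRecord",
    "read_pssm",
    "read_ss2",
    "read_dssp",
    "read_pdb_backbone",
    "assign_ss_fallback",
    "hnp_reduce",
    "ParseError",
]

SS_STATES = "HEC"

#: DSSP 8-state to 3-state collapse.
_DSSP_COLLAPSE = {"H": "H", "G": "H", "I": "H", "E": "E", "B": "E"}


class ParseError(ValueError):
    """A file does not conform to its declared dialect."""


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "r", encoding="utf-8")


@dataclass
class QueryProfile:
    """Query-side inputs: sequence, residue frequencies, predicted SS.

    ``freq`` is an (L, 20) array in canonical residue order; every row sums
    to 1.  ``pred_ss`` is a string over {H, E, C}; ``hnp`` is the HNP-reduced
    sequence used by the 9-residue fragment term.
    """

    sequence: str
    freq: np.ndarray
    pred_ss: str
    hnp: str = ""
    ss_conf: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        if not self.hnp:
            self.hnp = hnp_reduce(self.sequence)
        L = len(self.sequence)
        if self.freq.shape != (L, 20):
            raise ValueError(f"freq shape {self.freq.shape} != ({L}, 20)")
        if len(self.pred_ss) != L or len(self.hnp) != L:
            raise ValueError("sequence, pred_ss and hnp lengths differ")
        if set(self.pred_ss) - set(SS_STATES):
            raise ValueError(f"pred_ss contains states outside {SS_STATES}")
        sums = self.freq.sum(axis=1)
        if L and not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("per-position frequencies must sum to 1")

    @classmethod
    def from_files(cls, pssm_path, ss2_path) -> "QueryProfile":
        sequence, _, freq = read_pssm(pssm_path)
        pred_ss, conf = read_ss2(ss2_path)
        if len(pred_ss) != len(sequence):
            raise ParseError("PSSM and ss2 files describe different lengths")
        return cls(sequence=sequence, freq=freq, pred_ss=pred_ss, ss_conf=conf)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class TemplateRecord:
    """Template-side inputs with precomputed per-position conformation bins."""

    id: str
    sequence: str
    pssm: np.ndarray
    obs_ss: str
    backbone: BackboneStructure
    bins3: List[object] = field(default_factory=list)
    bins9: List[object] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pssm = np.asarray(self.pssm, dtype=float)
        L = len(self.sequence)
        if self.pssm.shape != (L, 20):
            raise ValueError(f"pssm shape {self.pssm.shape} != ({L}, 20)")
        if len(self.obs_ss) != L:
            raise ValueError("sequence and obs_ss lengths differ")
        if set(self.obs_ss) - set(SS_STATES):
            raise ValueError(f"obs_ss contains states outside {SS_STATES}")
        if not self.bins3:
            self.bins3 = geometry.position_bins(self.backbone, "frag3")
        if not self.bins9:
            self.bins9 = geometry.position_bins(self.backbone, "frag9")

    @classmethod
    def from_backbone(
        cls,
        id: str,
        backbone: BackboneStructure,
        pssm: Optional[np.ndarray] = None,
        obs_ss: Optional[str] = None,
    ) -> "TemplateRecord":
        """Build a record, defaulting to a self-sequence log-odds profile and
        the internal torsion-box SS assignment."""
        if obs_ss is None:
            obs_ss = assign_ss_fallback(backbone)
        if pssm is None:
            pssm = np.zeros((len(backbone), 20))
            for i, aa in enumerate(backbone.sequence):
                k = AA_INDEX.get(aa)
                if k is not None:
                    pssm[i, k] = 4.0
        return cls(id=id, sequence=backbone.sequence, pssm=pssm, obs_ss=obs_ss, backbone=backbone)

    def __len__(self) -> int:
        return len(self.sequence)


def read_pssm(path) -> Tuple[str, np.ndarray, np.ndarray]:
    """Parse a PSI-BLAST ASCII PSSM.

    Returns (sequence, log-odds (L, 20), frequencies (L, 20)), both arrays in
    canonical residue order.  Frequencies are renormalized to sum to 1 per
    position; all-zero percentage rows become the uniform vector.
    """
    order = list(AA20)
    sequence: List[str] = []
    log_odds: List[List[float]] = []
    freqs: List[List[float]] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if all(len(t) == 1 and t.isalpha() for t in tokens) and len(tokens) in (20, 40):
                header = tokens[:20]
                if sorted(header) != sorted(AA20):
                    raise ParseError(f"{path}:{lineno}: unexpected residue columns")
                order = header
                continue
            if not tokens[0].lstrip("-").isdigit():
                continue
            if len(tokens) < 42:
                raise ParseError(
                    f"{path}:{lineno}: expected 42+ columns in PSSM row, got {len(tokens)}"
                )
            aa = tokens[1]
            if len(aa) != 1 or not aa.isalpha():
                raise ParseError(f"{path}:{lineno}: bad residue letter {aa!r}")
            try:
                lo = [float(t) for t in tokens[2:22]]
                pc = [float(t) for t in tokens[22:42]]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric PSSM value") from exc
            sequence.append(aa)
            log_odds.append(lo)
            freqs.append(pc)
    if not sequence:
        raise ParseError(f"{path}: no PSSM rows found")
    # map file column order onto canonical order
    perm = [order.index(aa) for aa in AA20]
    lo_arr = np.asarray(log_odds)[:, perm]
    fq_arr = np.asarray(freqs)[:, perm]
    sums = fq_arr.sum(axis=1)
    zero = sums <= 0
    fq_arr[zero] = 1.0 / 20.0
    sums[zero] = 1.0
    fq_arr /= sums[:, None]
    return "".join(sequence), lo_arr, fq_arr


def read_ss2(path) -> Tuple[str, np.ndarray]:
    """Parse a PSIPRED VFORMAT ss2 file.

    Returns the predicted 3-state string and the (L, 3) confidence array in
    (C, H, E) column order as printed by PSIPRED.
    """
    states: List[str] = []
    conf: List[List[float]] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens or tokens[0].startswith("#"):
                continue
            if len(tokens) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 columns in ss2 row")
            state = tokens[2]
            if state not in SS_STATES:
                raise ParseError(f"{path}:{lineno}: unknown SS state {state!r}")
            states.append(state)
            try:
                conf.append([float(t) for t in tokens[3:6]])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric confidence") from exc
    if not states:
        raise ParseError(f"{path}: no ss2 rows found")
    return "".join(states), np.asarray(conf)


def read_dssp(path) -> str:
    """Parse classic DSSP output into a 3-state string ({H,G,I}->H, {E,B}->E, else C)."""
    out: List[str] = []
    in_body = False
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("  #  RESIDUE"):
                in_body = True
                continue
            if not in_body:
                continue
            if len(line.rstrip("\n")) < 17:
                raise ParseError(f"{path}:{lineno}: truncated DSSP record")
            if line[13] == "!":  # chain-break pseudo-residue
                continue
            out.append(_DSSP_COLLAPSE.get(line[16], "C"))
    if not in_body:
        raise ParseError(f"{path}: no DSSP residue section found")
    return "".join(out)


def read_pdb_backbone(path, chain: Optional[str] = None) -> BackboneStructure:
    """Extract an N/CA/C backbone from PDB ATOM records.

    First model only; disordered atoms resolve to altloc A when present.
    Residues without a CA atom are dropped with a warning.  Chain breaks are
    flagged from both residue-numbering gaps and CA-CA distances above the
    4.25 A virtual-bond tolerance.
    """
    parser = PDBParser(QUIET=True)
    with _open_text(path) as fh:
        model = next(iter(parser.get_structure("tpl", fh)))
    chains = {c.id: c for c in model}
    if chain is None:
        chain_obj = next(iter(model))
    elif chain in chains:
        chain_obj = chains[chain]
    else:
        raise ParseError(f"{path}: chain {chain!r} not found (have {sorted(chains)})")

    def coord(residue, name):
        if name not in residue:
            return np.full(3, np.nan)
        atom = residue[name]
        if atom.is_disordered():
            ids = atom.disordered_get_id_list()
            atom = atom.disordered_get("A") if "A" in ids else atom.disordered_get_list()[0]
        return np.asarray(atom.get_coord(), dtype=float)

    seq: List[str] = []
    n_xyz: List[np.ndarray] = []
    ca_xyz: List[np.ndarray] = []
    c_xyz: List[np.ndarray] = []
    numbers: List[int] = []
    for residue in chain_obj:
        if residue.id[0] != " ":
            continue
        if "CA" not in residue:
            logger.warning("%s: residue %s lacks CA, dropped", path, residue.id)
            continue
        one = seq1(residue.get_resname())
        seq.append(one if one in AA20 else "X")
        n_xyz.append(coord(residue, "N"))
        ca_xyz.append(coord(residue, "CA"))
        c_xyz.append(coord(residue, "C"))
        numbers.append(residue.id[1])
    structure = BackboneStructure(
        sequence="".join(seq),
        n=np.asarray(n_xyz).reshape(-1, 3),
        ca=np.asarray(ca_xyz).reshape(-1, 3),
        c=np.asarray(c_xyz).reshape(-1, 3),
    )
    for i in range(1, len(structure)):
        if numbers[i] - numbers[i - 1] != 1:
            structure.break_before[i] = True
    return structure


# Torsion boxes for the fallback assignment (degrees).
_H_BOX = ((-100.0, -30.0), (-80.0, -5.0))
_E_BOX = ((-180.0, -90.0), (90.0, 180.0))
_MIN_RUN = 3


def assign_ss_fallback(backbone: BackboneStructure) -> str:
    """Assign 3-state secondary structure from backbone torsions.

    Residues with (phi, psi) in the helical box map to H, in the extended box
    to E, all others (including terminals and break-adjacent residues, whose
    torsions are undefined) to C.  H/E runs shorter than 3 are demoted to C.
    """
    L = len(backbone)
    states = ["C"] * L
    for i in range(1, L - 1):
        if backbone.break_before[i] or backbone.break_before[i + 1]:
            continue
        try:
            phi = geometry.dihedral(backbone.c[i - 1], backbone.n[i], backbone.ca[i], backbone.c[i])
            psi = geometry.dihedral(backbone.n[i], backbone.ca[i], backbone.c[i], backbone.n[i + 1])
        except geometry.GeometryError:
            continue
        if not (np.isfinite(phi) and np.isfinite(psi)):
            continue
        if _H_BOX[0][0] <= phi <= _H_BOX[0][1] and _H_BOX[1][0] <= psi <= _H_BOX[1][1]:
            states[i] = "H"
        elif _E_BOX[0][0] <= phi <= _E_BOX[0][1] and _E_BOX[1][0] <= psi <= _E_BOX[1][1]:
            states[i] = "E"
    # demote short H/E runs
    i = 0
    while i < L:
        j = i
        while j < L and states[j] == states[i]:
            j += 1
        if states[i] in "HE" and j - i < _MIN_RUN:
            for k in range(i, j):
                states[k] = "C"
        i = j
    return "".join(states)
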
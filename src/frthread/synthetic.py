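"""Synthetic fixtures with known ground truth.

Generates ideal-geometry backbones from torsion lists, segmented
helix/strand/coil structures, concentrated sequence profiles in the
PSI-BLAST ASCII dialect, remote-homolog pairs with gold alignments, and
decoy template libraries — everything the threader consumes, without any
external data.  Identical spec + seed give byte-identical outputs.

These fixtures emulate the *shape* of real inputs, not their physics: no
side chains, no solvent, and indels only inside coil segments so gold
alignments stay unambiguous.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .geometry import BackboneStructure
from .io_formats import QueryProfile, TemplateRecord
from .residues import AA20
from .train import GoldAlignment

__all__ = [
    "FixtureSpec",
    "make_backbone",
    "make_segmented_structure",
    "make_profile",
    "make_homolog_pair",
    "make_template_library",
    "make_structure_set",
    "write_pdb",
    "write_ss2",
    "HELIX_TORSIONS",
    "STRAND_TORSIONS",
]

# Ideal peptide geometry (Engh-Huber-like): bond lengths in Angstroms,
# bond angles in degrees, trans peptide (omega = 180).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
OMEGA = 180.0

HELIX_TORSIONS = (-57.0, -47.0)
STRAND_TORSIONS = (-120.0, 130.0)

_BACKGROUND = 0.05  # uniform residue background for log-odds


@dataclass(frozen=True)
class FixtureSpec:
    """Ground-truth parameters for fixture generation.

    ``segments`` lists (secondary-structure kind, length) in order;
    ``noise_sigma`` is the Gaussian torsion noise in degrees;
    ``sharpness`` the probability mass the profile puts on the true residue;
    ``mutation_rate`` the per-position substitution rate of homolog pairs;
    ``n_indels``/``indel_len`` the coil-restricted deletions in the query.
    """

    seed: int = 0
    segments: Tuple[Tuple[str, int], ...] = (
        ("H", 12), ("C", 4), ("E", 8), ("C", 4), ("H", 12), ("C", 4), ("E", 8),
    )
    noise_sigma: float = 0.0
    sharpness: float = 0.5
    mutation_rate: float = 0.1
    n_indels: int = 0
    indel_len: int = 2

    @property
    def length(self) -> int:
        return sum(n for _, n in self.segments)


def _wrap(deg: float) -> float:
    deg = (deg + 180.0) % 360.0 - 180.0
    return 180.0 if deg == -180.0 else deg


def _place(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Next atom position from internal coordinates (standard NERF step)."""
    theta = math.radians(angle_deg)
    chi = math.radians(torsion_deg)
    bc = c - b
    bc_hat = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc_hat)
    n_hat = n / np.linalg.norm(n)
    m = np.cross(n_hat, bc_hat)
    d_local = bond * np.array(
        [-math.cos(theta), math.cos(chi) * math.sin(theta), math.sin(chi) * math.sin(theta)]
    )
    return c + d_local[0] * bc_hat + d_local[1] * m + d_local[2] * n_hat


def make_backbone(
    torsions: Sequence[Tuple[float, float]], sequence: Optional[str] = None
) -> BackboneStructure:
    """Build an N/CA/C backbone from per-residue (phi, psi) torsions.

    Ideal bond lengths and angles, trans peptide bonds.  phi of the first
    residue and psi of the last are not used.  Round trip holds exactly:
    the fragment-geometry torsions recover the inputs.
    """
    L = len(torsions)
    if sequence is None:
        sequence = "A" * L
    if len(sequence) != L:
        raise ValueError("sequence and torsion list lengths differ")
    if L == 0:
        return BackboneStructure("", np.zeros((0, 3)), np.zeros((0, 3)), np.zeros((0, 3)))
    theta = math.radians(ANGLE_N_CA_C)
    n_xyz = [np.zeros(3)]
    ca_xyz = [np.array([BOND_N_CA, 0.0, 0.0])]
    c_xyz = [ca_xyz[0] + BOND_CA_C * np.array([-math.cos(theta), math.sin(theta), 0.0])]
    for k in range(L - 1):
        psi_k = torsions[k][1]
        phi_next = torsions[k + 1][0]
        n_next = _place(n_xyz[k], ca_xyz[k], c_xyz[k], BOND_C_N, ANGLE_CA_C_N, psi_k)
        ca_next = _place(ca_xyz[k], c_xyz[k], n_next, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        c_next = _place(c_xyz[k], n_next, ca_next, BOND_CA_C, ANGLE_N_CA_C, phi_next)
        n_xyz.append(n_next)
        ca_xyz.append(ca_next)
        c_xyz.append(c_next)
    return BackboneStructure(
        sequence=sequence, n=np.array(n_xyz), ca=np.array(ca_xyz), c=np.array(c_xyz)
    )


def _segment_torsions(kind: str, length: int, rng: np.random.Generator) -> List[Tuple[float, float]]:
    if kind == "H":
        return [HELIX_TORSIONS] * length
    if kind == "E":
        return [STRAND_TORSIONS] * length
    if kind == "C":
        # positive-phi region: outside both the helical and extended boxes
        return [
            (float(rng.uniform(30.0, 100.0)), float(rng.uniform(0.0, 80.0)))
            for _ in range(length)
        ]
    raise ValueError(f"unknown segment kind {kind!r}")


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def make_segmented_structure(
    spec: FixtureSpec, rng: Optional[np.random.Generator] = None
) -> Tuple[BackboneStructure, str]:
    """Concatenated helix/strand/coil segments with per-residue true labels.

    Gaussian torsion noise of ``spec.noise_sigma`` degrees is added when
    nonzero.  Returns (structure, true secondary-structure string).
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    torsions: List[Tuple[float, float]] = []
    labels: List[str] = []
    for kind, length in spec.segments:
        torsions.extend(_segment_torsions(kind, length, rng))
        labels.extend(kind * length)
    if spec.noise_sigma > 0:
        torsions = [
            (
                _wrap(phi + rng.normal(0.0, spec.noise_sigma)),
                _wrap(psi + rng.normal(0.0, spec.noise_sigma)),
            )
            for phi, psi in torsions
        ]
    sequence = _random_sequence(len(torsions), rng)
    return make_backbone(torsions, sequence), "".join(labels)


def make_profile(
    sequence: str, sharpness: float, seed: int = 0
) -> Tuple[str, np.ndarray, np.ndarray]:
    """Per-position profile concentrated on the true residue.

    The true residue receives ``sharpness`` frequency mass, the rest is
    uniform; log-odds are round(2 * log2(freq / background)) as in the
    PSI-BLAST dialect.  Returns (PSSM file text, frequencies, log-odds).
    """
    if not 0.0 < sharpness <= 1.0:
        raise ValueError("sharpness must be in (0, 1]")
    L = len(sequence)
    freq = np.full((L, 20), (1.0 - sharpness) / 19.0)
    for i, aa in enumerate(sequence):
        k = AA20.index(aa)
        freq[i, :] = (1.0 - sharpness) / 19.0
        freq[i, k] = sharpness
    log_odds = np.round(2.0 * np.log2(np.clip(freq, 1e-4, None) / _BACKGROUND))
    text = _format_pssm(sequence, log_odds, freq)
    return text, freq, log_odds


def _format_pssm(sequence: str, log_odds: np.ndarray, freq: np.ndarray) -> str:
    buf = io.StringIO()
    buf.write(
        "\nLast position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts\n"
    )
    letters = "   ".join(AA20)
    buf.write(f"            {letters}   {letters}\n")
    for i, aa in enumerate(sequence):
        lo = " ".join(f"{int(v):3d}" for v in log_odds[i])
        pc = " ".join(f"{int(round(v * 100)):3d}" for v in freq[i])
        buf.write(f"{i + 1:5d} {aa} {lo}  {pc}  0.50 0.10\n")
    buf.write("\n")
    return buf.getvalue()


def write_ss2(pred_ss: str, conf: Optional[np.ndarray] = None) -> str:
    """Render a predicted SS string in the PSIPRED VFORMAT dialect."""
    buf = io.StringIO()
    buf.write("# PSF format file (PSIPRED V4.0)\n\n")
    for i, state in enumerate(pred_ss):
        if conf is not None:
            c, h, e = conf[i]
        else:
            c = 1.0 if state == "C" else 0.0
            h = 1.0 if state == "H" else 0.0
            e = 1.0 if state == "E" else 0.0
        buf.write(f"{i + 1:4d} A {state} {c:6.3f} {h:6.3f} {e:6.3f}\n")
    return buf.getvalue()


_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


def write_pdb(structure: BackboneStructure, chain: str = "A") -> str:
    """Render a backbone as PDB ATOM records (N, CA, C per residue)."""
    buf = io.StringIO()
    serial = 1
    for i, aa in enumerate(structure.sequence):
        resname = _THREE.get(aa, "UNK")
        for name, xyz in (("N", structure.n[i]), ("CA", structure.ca[i]), ("C", structure.c[i])):
            if not np.all(np.isfinite(xyz)):
                continue
            element = name[0]
            buf.write(
                f"ATOM  {serial:5d}  {name:<4s}{resname} {chain}{i + 1:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {element:>2s}\n"
            )
            serial += 1
    buf.write("TER\nEND\n")
    return buf.getvalue()


def _mutate(sequence: str, rate: float, rng: np.random.Generator) -> str:
    # A replacement never duplicates an adjacent residue of the source
    # sequence, so point mutations cannot fake a one-off register shift and
    # the identity gold mapping stays unambiguous.
    out = []
    for i, aa in enumerate(sequence):
        if rng.random() < rate:
            avoid = {aa}
            if i > 0:
                avoid.add(sequence[i - 1])
            if i + 1 < len(sequence):
                avoid.add(sequence[i + 1])
            choices = [x for x in AA20 if x not in avoid]
            out.append(str(rng.choice(choices)))
        else:
            out.append(aa)
    return "".join(out)


def make_homolog_pair(
    spec: FixtureSpec,
) -> Tuple[QueryProfile, TemplateRecord, GoldAlignment]:
    """A remote-homolog (query, template, gold) triple with known truth.

    The template is a segmented structure; the query is its sequence with
    point mutations at ``mutation_rate`` and ``n_indels`` deletions of
    ``indel_len`` residues placed inside coil segments, so the gold mapping
    is the identity restricted to retained positions.
    """
    rng = np.random.default_rng(spec.seed)
    backbone, true_ss = make_segmented_structure(spec, rng)
    _, t_freq, t_lo = make_profile(backbone.sequence, spec.sharpness)
    template = TemplateRecord(
        id=f"tpl-{spec.seed}",
        sequence=backbone.sequence,
        pssm=t_lo,
        obs_ss=true_ss,
        backbone=backbone,
    )

    keep = np.ones(len(backbone), dtype=bool)
    if spec.n_indels > 0:
        coil_runs = []
        start = 0
        for kind, length in spec.segments:
            if kind == "C" and length > spec.indel_len:
                coil_runs.append((start, length))
            start += length
        chosen = rng.permutation(len(coil_runs))[: spec.n_indels]
        for idx in sorted(chosen):
            run_start, run_len = coil_runs[idx]
            offset = int(rng.integers(0, run_len - spec.indel_len + 1))
            keep[run_start + offset : run_start + offset + spec.indel_len] = False

    kept_positions = np.flatnonzero(keep)
    q_sequence = _mutate("".join(backbone.sequence[p] for p in kept_positions),
                         spec.mutation_rate, rng)
    q_pred_ss = "".join(true_ss[p] for p in kept_positions)
    _, q_freq, _ = make_profile(q_sequence, spec.sharpness)
    query = QueryProfile(sequence=q_sequence, freq=q_freq, pred_ss=q_pred_ss)
    gold = GoldAlignment(
        pairs=[(qi, int(tj)) for qi, tj in enumerate(kept_positions)],
        source=f"synthetic pair seed={spec.seed}",
    )
    return query, template, gold


def make_structure_set(
    n: int, seed: int = 0, noise_sigma: float = 8.0
) -> List[Tuple[BackboneStructure, str]]:
    """Random segmented structures for potential building."""
    rng = np.random.default_rng(seed)
    kinds = ["H", "E", "C"]
    out = []
    for _ in range(n):
        n_seg = int(rng.integers(3, 7))
        segments = tuple(
            (kinds[int(rng.integers(0, 3))], int(rng.integers(5, 14))) for _ in range(n_seg)
        )
        sub = FixtureSpec(seed=int(rng.integers(0, 2 ** 31 - 1)), segments=segments,
                          noise_sigma=noise_sigma)
        out.append(make_segmented_structure(sub, np.random.default_rng(sub.seed)))
    return out


def make_template_library(
    spec: FixtureSpec, n_templates: int = 10, include_true: bool = True
) -> Tuple[QueryProfile, List[TemplateRecord], Optional[str]]:
    """A query plus a decoy library containing (optionally) one true fold.

    The true template shares the query's segment architecture; decoys carry
    shuffled architectures and unrelated random sequences.  Returns
    (query, templates, true template id or None).
    """
    rng = np.random.default_rng(spec.seed)
    true_backbone, true_ss = make_segmented_structure(spec, rng)
    templates: List[TemplateRecord] = []
    true_id: Optional[str] = None
    if include_true:
        true_id = "true-template"
        _, _, lo = make_profile(true_backbone.sequence, spec.sharpness)
        templates.append(
            TemplateRecord(
                id=true_id,
                sequence=true_backbone.sequence,
                pssm=lo,
                obs_ss=true_ss,
                backbone=true_backbone,
            )
        )
    n_decoys = n_templates - len(templates)
    for d in range(n_decoys):
        perm = rng.permutation(len(spec.segments))
        segments = tuple(spec.segments[int(p)] for p in perm)
        decoy_spec = replace(spec, segments=segments, seed=int(rng.integers(0, 2 ** 31 - 1)))
        backbone, ss = make_segmented_structure(decoy_spec, np.random.default_rng(decoy_spec.seed))
        _, _, lo = make_profile(backbone.sequence, spec.sharpness)
        templates.append(
            TemplateRecord(
                id=f"decoy-{d:02d}",
                sequence=backbone.sequence,
                pssm=lo,
                obs_ss=ss,
                backbone=backbone,
            )
        )
    q_sequence = _mutate(true_backbone.sequence, spec.mutation_rate, rng)
    _, q_freq, _ = make_profile(q_sequence, spec.sharpness)
    query = QueryProfile(sequence=q_sequence, freq=q_freq, pred_ss=true_ss)
    return query, templates, true_id
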
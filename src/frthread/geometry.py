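"""Coarse-grained backbone geometry for 3- and 9-residue fragments.

A fragment conformation is reduced to four angular variables: two torsions
(theta1, theta2) and two bend angles (theta3, theta4) built from bisecting
vectors and in-plane vectors of the backbone trace.  For 3-residue fragments
the torsions are the central residue's (phi, psi); for 9-residue fragments
they are virtual dihedrals over consecutive C-alpha atoms.  Each variable is
discretized on a fixed grid (60, 60, 30, 30 degrees wide), giving 6 bins per
variable and 6**4 = 1296 joint conformation bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np

__all__ = [
    "BackboneStructure",
    "FragmentConformation",
    "ConformationBin",
    "GeometryError",
    "FragmentUndefined",
    "ChainBreakInFragment",
    "dihedral",
    "bend_angle",
    "bisector",
    "plane_vector",
    "conformation3",
    "conformation9",
    "bin_conformation",
    "position_bins",
    "BREAK",
    "N_JOINT_BINS",
    "CA_BREAK_DISTANCE",
]

#: CA(i-1)->CA(i) distances above this flag a chain break (virtual bond ~3.8 A).
CA_BREAK_DISTANCE = 4.25

#: Joint conformation-bin count: 6 * 6 * 6 * 6.
N_JOINT_BINS = 6 ** 4

_BIN_WIDTHS = (60.0, 60.0, 30.0, 30.0)


class GeometryError(ValueError):
    """Degenerate geometry (collinear or coincident points) — angle undefined."""


class FragmentUndefined(Exception):
    """The fragment window runs off a chain terminus."""


class ChainBreakInFragment(Exception):
    """The fragment window contains a flagged chain break."""


#: Sentinel marking a chain break in per-position bin annotations.
BREAK = "break"


class ConformationBin(NamedTuple):
    b1: int
    b2: int
    b3: int
    b4: int


class FragmentConformation(NamedTuple):
    """Angles in degrees: torsions in (-180, 180], bends in [0, 180]."""

    theta1: float
    theta2: float
    theta3: float
    theta4: float


@dataclass
class BackboneStructure:
    """Ordered backbone of one chain.

    ``n``, ``ca``, ``c`` are (L, 3) coordinate arrays in Angstroms; rows may be
    NaN where an atom is absent (CA-only coarse use).  ``break_before[i]`` is
    True when the chain is discontinuous between residues i-1 and i;
    ``break_before[0]`` is True by convention.
    """

    sequence: str
    n: np.ndarray
    ca: np.ndarray
    c: np.ndarray
    break_before: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        L = len(self.sequence)
        self.n = np.asarray(self.n, dtype=float).reshape(L, 3) if L else np.zeros((0, 3))
        self.ca = np.asarray(self.ca, dtype=float).reshape(L, 3) if L else np.zeros((0, 3))
        self.c = np.asarray(self.c, dtype=float).reshape(L, 3) if L else np.zeros((0, 3))
        if self.break_before is None:
            self.break_before = self._detect_breaks()
        else:
            self.break_before = np.asarray(self.break_before, dtype=bool).reshape(L)
        if L:
            self.break_before[0] = True

    def _detect_breaks(self) -> np.ndarray:
        L = len(self.sequence)
        breaks = np.zeros(L, dtype=bool)
        if L == 0:
            return breaks
        breaks[0] = True
        d = np.linalg.norm(np.diff(self.ca, axis=0), axis=1)
        breaks[1:] = ~np.isfinite(d) | (d > CA_BREAK_DISTANCE)
        return breaks

    def __len__(self) -> int:
        return len(self.sequence)

    def has_break_inside(self, lo: int, hi: int) -> bool:
        """True if a break falls strictly inside residues lo..hi (inclusive)."""
        return bool(self.break_before[lo + 1 : hi + 1].any())


def _unit(v: np.ndarray, what: str = "vector") -> np.ndarray:
    v = np.asarray(v, dtype=float)
    norm = np.linalg.norm(v)
    if norm < 1e-10:
        raise GeometryError(f"zero-length {what}")
    return v / norm


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, IUPAC convention.

    Returns values in (-180, 180]; cis = 0, trans = 180.  Raises
    :class:`GeometryError` when either bonded triple is collinear.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise GeometryError("collinear triple: torsion undefined")
    m1 = np.cross(_unit(b2), n1)
    deg = float(np.degrees(np.arctan2(np.dot(m1, n2), np.dot(n1, n2))))
    if deg <= -180.0:
        deg += 360.0
    return deg


def bend_angle(u, v) -> float:
    """Unsigned angle between two vectors, degrees in [0, 180]."""
    u = _unit(u)
    v = _unit(v)
    return float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))


def bisector(u, v) -> np.ndarray:
    """Unit vector bisecting u and v; undefined for antiparallel inputs."""
    s = _unit(u) + _unit(v)
    if np.linalg.norm(s) < 1e-10:
        raise GeometryError("antiparallel vectors: bisector undefined")
    return s / np.linalg.norm(s)


def plane_vector(a, b, c) -> np.ndarray:
    """Unit vector in plane(a, b, c) perpendicular to the local bisector.

    The bisector is bisector(b->a, b->c); the result is oriented so that its
    dot product with (b->c) is non-negative.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    normal = np.cross(a - b, c - b)
    if np.linalg.norm(normal) < 1e-10:
        raise GeometryError("collinear points: plane undefined")
    bis = bisector(a - b, c - b)
    v = _unit(np.cross(normal, bis))
    if np.dot(v, c - b) < 0:
        v = -v
    return v


def _require_window(structure: BackboneStructure, lo: int, hi: int) -> None:
    if lo < 0 or hi >= len(structure):
        raise FragmentUndefined(f"window {lo}..{hi} off the chain")
    if structure.has_break_inside(lo, hi):
        raise ChainBreakInFragment(f"chain break inside window {lo}..{hi}")


def conformation3(structure: BackboneStructure, i: int) -> FragmentConformation:
    """Four-angle conformation of the 3-residue fragment centered at i.

    theta1 = phi(i), theta2 = psi(i); theta3/theta4 are the bend angles between
    the CA-trace bisector at i and the N/CA/C in-plane bisectors of residues
    i-1 and i+1.
    """
    _require_window(structure, i - 1, i + 1)
    n, ca, c = structure.n, structure.ca, structure.c
    for arr, j in ((n, i - 1), (n, i), (n, i + 1), (c, i - 1), (c, i), (c, i + 1)):
        if not np.all(np.isfinite(arr[j])):
            raise GeometryError(f"missing backbone atom at residue {j}")
    theta1 = dihedral(c[i - 1], n[i], ca[i], c[i])
    theta2 = dihedral(n[i], ca[i], c[i], n[i + 1])
    b_i = bisector(ca[i - 1] - ca[i], ca[i + 1] - ca[i])
    v_prev = bisector(n[i - 1] - ca[i - 1], c[i - 1] - ca[i - 1])
    v_next = bisector(n[i + 1] - ca[i + 1], c[i + 1] - ca[i + 1])
    return FragmentConformation(theta1, theta2, bend_angle(b_i, v_prev), bend_angle(b_i, v_next))


def conformation9(structure: BackboneStructure, i: int) -> FragmentConformation:
    """Four-angle coarse conformation of the 9-residue fragment centered at i.

    Only C-alpha atoms are used: theta1/theta2 are virtual dihedrals over
    CA(i-2..i+1) and CA(i-1..i+2); theta3/theta4 mix the trace bisectors b and
    the in-plane vectors v at neighboring centers i and i+1.
    """
    _require_window(structure, i - 4, i + 4)
    ca = structure.ca
    if not np.all(np.isfinite(ca[i - 2 : i + 3])):
        raise GeometryError("missing CA atom in fragment")
    theta1 = dihedral(ca[i - 2], ca[i - 1], ca[i], ca[i + 1])
    theta2 = dihedral(ca[i - 1], ca[i], ca[i + 1], ca[i + 2])

    def b(j: int) -> np.ndarray:
        return bisector(ca[j - 1] - ca[j], ca[j + 1] - ca[j])

    def v(j: int) -> np.ndarray:
        return plane_vector(ca[j - 1], ca[j], ca[j + 1])

    theta3 = bend_angle(b(i), v(i + 1))
    theta4 = bend_angle(b(i + 1), v(i))
    return FragmentConformation(theta1, theta2, theta3, theta4)


def bin_conformation(conf: FragmentConformation) -> ConformationBin:
    """Discretize a conformation; torsion bins are 60 deg wide, bend bins 30 deg."""
    out = []
    for k, (theta, width) in enumerate(zip(conf, _BIN_WIDTHS)):
        if k < 2:
            if not (-180.0 < theta <= 180.0):
                raise ValueError(f"torsion {theta} outside (-180, 180]")
            b = int((theta + 180.0) // width)
        else:
            if not (0.0 <= theta <= 180.0):
                raise ValueError(f"bend angle {theta} outside [0, 180]")
            b = int(theta // width)
        out.append(min(b, 5))
    return ConformationBin(*out)


def position_bins(
    structure: BackboneStructure, kind: str
) -> list[Optional[object]]:
    """Per-position conformation bins for ``kind`` in {'frag3', 'frag9'}.

    Returns one entry per residue: a :class:`ConformationBin`, the
    :data:`BREAK` sentinel when the fragment window contains a chain break,
    or None when the fragment is undefined (terminal window or degenerate
    geometry / missing atoms).
    """
    if kind == "frag3":
        conf_fn = conformation3
    elif kind == "frag9":
        conf_fn = conformation9
    else:
        raise ValueError(f"unknown fragment kind {kind!r}")
    out: list[Optional[object]] = []
    for i in range(len(structure)):
        try:
            out.append(bin_conformation(conf_fn(structure, i)))
        except ChainBreakInFragment:
            out.append(BREAK)
        except (FragmentUndefined, GeometryError):
            out.append(None)
    return out
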
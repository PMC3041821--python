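"""Independent reference implementations used only to cross-check the package.

These deliberately share no code with frthread: a separately formulated
torsion, a bisection solver for the potential calibration, and an exhaustive
enumeration of legal gapped alignments.
"""

from __future__ import annotations

import math

import numpy as np


def random_count_table(rng, kind="frag3", n_classes=30, heavy_tail=True):
    """Random sparse count table; with heavy_tail, Ntilde > N everywhere."""
    from frthread.geometry import ConformationBin
    from frthread.lspp import CountTable
    from frthread.residues import AA20

    table = CountTable(kind)
    for _ in range(n_classes):
        key = "".join(rng.choice(list(AA20), size=3))
        if heavy_tail:
            # >= 4 occupied bins with counts 1-2 guarantees Ntilde > N per entry
            n_bins, hi = int(rng.integers(4, 9)), 3
        else:
            n_bins, hi = int(rng.integers(1, 4)), 6
        bins = set()
        while len(bins) < n_bins:
            bins.add(ConformationBin(*(int(b) for b in rng.integers(0, 6, size=4))))
        for conf_bin in bins:
            for _ in range(int(rng.integers(1, hi))):
                table.add(key, conf_bin)
    return table


def random_alignment_instance(rng, max_dim=5):
    """Random small score matrix + SS strings + affine penalties."""
    Lq = int(rng.integers(1, max_dim + 1))
    Lt = int(rng.integers(1, max_dim + 1))
    E = rng.integers(-3, 4, size=(Lq, Lt)).astype(float)
    q_ss = "".join(rng.choice(list("HEC"), size=Lq))
    t_ss = "".join(rng.choice(list("HEC"), size=Lt))
    go = float(-rng.integers(0, 4))
    ge = float(-rng.integers(0, 3))
    return E, q_ss, t_ss, go, ge


def dihedral_oracle(p0, p1, p2, p3) -> float:
    """Torsion via tangent-plane projections (independent atan2 formulation)."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b1 = b1 / np.linalg.norm(b1)
    b2 = p3 - p2
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    deg = float(np.degrees(np.arctan2(np.cross(b1, v) @ w, v @ w)))
    return 180.0 if deg <= -180.0 else deg


def mu_bisection_oracle(counts: dict, class_totals: dict, pseudo: float = 0.5,
                        tol: float = 1e-14) -> float:
    """Solve mean occupied energy = 0 for mu by bisection on (0, 1)."""

    def mean_energy(mu: float) -> float:
        total = 0.0
        for (key, _bin), n in counts.items():
            nt = class_totals[key] - n
            if n == 0 or nt == 0:
                n_adj, nt_adj = n + pseudo, nt + pseudo
            else:
                n_adj, nt_adj = float(n), float(nt)
            total += -math.log(mu * n_adj / ((1.0 - mu) * nt_adj))
        return total / len(counts)

    lo, hi = 1e-12, 1.0 - 1e-12
    # mean energy is strictly decreasing in mu
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_energy(mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def _forbidden(i: int, j: int, q_ss: str, t_ss: str) -> bool:
    return q_ss[i] == t_ss[j] and q_ss[i] in "HE"


def _enumerate_pairings(Lq: int, Lt: int):
    """All nonempty strictly increasing pair sequences."""
    stack = [((i, j),) for i in range(Lq) for j in range(Lt)]
    while stack:
        pairing = stack.pop()
        yield pairing
        i, j = pairing[-1]
        for qi in range(i + 1, Lq):
            for tj in range(j + 1, Lt):
                stack.append(pairing + ((qi, tj),))


def score_pairing(pairing, E, q_ss, t_ss, go, ge):
    """Score one pairing under the gap model, or None when illegal.

    Internal gap runs cost go + L*ge; a run is illegal if any skipped residue
    sits at a cell where the two secondary structures agree on H or E, and
    regions needing simultaneous insertion and deletion are illegal.  End
    gaps are free.
    """
    score = E[pairing[0]]
    for (i1, j1), (i2, j2) in zip(pairing, pairing[1:]):
        di, dj = i2 - i1 - 1, j2 - j1 - 1
        if di > 0 and dj > 0:
            return None
        if dj > 0:  # gap in query: template residues j1+1..j2-1 skipped
            if any(_forbidden(i1, j, q_ss, t_ss) for j in range(j1 + 1, j2)):
                return None
            score += go + dj * ge
        if di > 0:  # gap in template: query residues skipped
            if any(_forbidden(i, j1, q_ss, t_ss) for i in range(i1 + 1, i2)):
                return None
            score += go + di * ge
        score += E[i2, j2]
    return score


def brute_force_align(E, q_ss, t_ss, go, ge) -> float:
    """Optimal score by exhaustive enumeration of all legal alignments."""
    E = np.asarray(E, dtype=float)
    best = -math.inf
    for pairing in _enumerate_pairings(*E.shape):
        s = score_pairing(pairing, E, q_ss, t_ss, go, ge)
        if s is not None and s > best:
            best = s
    return best
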
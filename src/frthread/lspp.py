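"""Local structural preference potentials (LSPPs) for short backbone fragments.

For every (fragment sequence class, conformation bin) pair observed in a set
of structures, the potential is the log-odds energy

    E(s, j) = -ln( mu * N(s,j) / ((1 - mu) * Ntilde(s,j)) )        [nats]

where N is the count of observations of class s in bin j and Ntilde is the
count of observations of s *not* in bin j.  The single weight mu in (0, 1)
balances positive against negative counts and is calibrated so that the net
interaction — the mean energy over all occupied entries — is exactly zero.
Because Ntilde typically dwarfs N, the calibrated mu exceeds 0.5.

Two fragment sizes are supported: 3-residue fragments keyed by the ordered
amino-acid triplet (20**3 = 8000 sequence classes) and 9-residue fragments
keyed by the HNP-reduced 9-mer (3**9 = 19683 classes).  Storage is sparse
throughout: the 9-residue joint space of 3**9 * 6**4 ≈ 25.5 million bins is
never materialized.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Tuple

from .geometry import (
    BREAK,
    BackboneStructure,
    ChainBreakInFragment,
    ConformationBin,
    FragmentUndefined,
    GeometryError,
    N_JOINT_BINS,
    bin_conformation,
    conformation3,
    conformation9,
)
from .residues import AA20, hnp_reduce

logger = logging.getLogger(__name__)

__all__ = [
    "CountTable",
    "EnergyTable",
    "count_fragments",
    "calibrate_mu",
    "energy",
    "build_energy_table",
    "lookup_fragment_energy",
    "save_table",
    "load_table",
    "sequence_class_count",
    "joint_bin_space",
    "PSEUDO_COUNT",
    "TABLE_FORMAT_VERSION",
]

#: Pseudo-count applied to N and Ntilde when either is zero for an occupied entry.
PSEUDO_COUNT = 0.5

TABLE_FORMAT_VERSION = 1

_KINDS = ("frag3", "frag9")

Key = Tuple[str, ConformationBin]


def sequence_class_count(kind: str) -> int:
    """Number of fragment sequence classes: 20**3 for frag3, 3**9 for frag9."""
    _check_kind(kind)
    return 20 ** 3 if kind == "frag3" else 3 ** 9


def joint_bin_space(kind: str) -> int:
    """Size of the full (sequence class x conformation bin) space."""
    return sequence_class_count(kind) * N_JOINT_BINS


def _check_kind(kind: str) -> None:
    if kind not in _KINDS:
        raise ValueError(f"unknown fragment kind {kind!r}; expected one of {_KINDS}")


@dataclass
class CountTable:
    """Sparse observation counts per (fragment class, conformation bin)."""

    kind: str
    counts: Dict[Key, int] = field(default_factory=dict)
    class_totals: Dict[str, int] = field(default_factory=dict)

    def add(self, seq_key: str, conf_bin: ConformationBin) -> None:
        k = (seq_key, conf_bin)
        self.counts[k] = self.counts.get(k, 0) + 1
        self.class_totals[seq_key] = self.class_totals.get(seq_key, 0) + 1

    def n_tilde(self, seq_key: str, conf_bin: ConformationBin) -> int:
        """Observations of this class that fall outside the given bin."""
        return self.class_totals.get(seq_key, 0) - self.counts.get((seq_key, conf_bin), 0)

    @property
    def total_observations(self) -> int:
        return sum(self.class_totals.values())


@dataclass
class EnergyTable:
    """Calibrated sparse LSPP energies in nats; chain-broken fragments score 0."""

    kind: str
    mu: float
    energies: Dict[Key, float]
    unseen_energy: float
    n_observations: int = 0
    chain_break_energy: float = 0.0


def _frag3_observations(structure: BackboneStructure) -> Iterable[Tuple[str, ConformationBin]]:
    seq = structure.sequence
    for i in range(1, len(structure) - 1):
        if structure.has_break_inside(i - 1, i + 1):
            continue
        key = seq[i - 1 : i + 2]
        if any(aa not in AA20 for aa in key):
            logger.warning("skipping frag3 center %d: non-standard residue in %r", i, key)
            continue
        try:
            yield key, bin_conformation(conformation3(structure, i))
        except (GeometryError, FragmentUndefined, ChainBreakInFragment) as exc:
            logger.warning("skipping frag3 center %d: %s", i, exc)


def _frag9_observations(structure: BackboneStructure) -> Iterable[Tuple[str, ConformationBin]]:
    seq = structure.sequence
    for i in range(4, len(structure) - 4):
        if structure.has_break_inside(i - 4, i + 4):
            continue
        key = hnp_reduce(seq[i - 4 : i + 5])
        try:
            yield key, bin_conformation(conformation9(structure, i))
        except (GeometryError, FragmentUndefined, ChainBreakInFragment) as exc:
            logger.warning("skipping frag9 center %d: %s", i, exc)


def count_fragments(structures: Iterable[BackboneStructure], kind: str) -> CountTable:
    """Count one observation per eligible fragment center over all structures.

    Fragments whose window contains a chain break or runs off a terminus are
    skipped; frag3 windows with non-standard residues are skipped with a
    warning (frag9 maps unknowns into the neutral HNP class instead).
    """
    _check_kind(kind)
    obs_fn = _frag3_observations if kind == "frag3" else _frag9_observations
    table = CountTable(kind)
    for structure in structures:
        for key, conf_bin in obs_fn(structure):
            table.add(key, conf_bin)
    return table


def _adjusted(n: int, n_tilde: int) -> Tuple[float, float]:
    if n == 0 or n_tilde == 0:
        return n + PSEUDO_COUNT, n_tilde + PSEUDO_COUNT
    return float(n), float(n_tilde)


def calibrate_mu(table: CountTable) -> float:
    """Solve for the mu that makes the net interaction energy zero.

    Setting the mean of E(s,j) = -ln(mu N / ((1-mu) Ntilde)) over occupied
    entries to zero gives the closed form

        mu / (1 - mu) = geometric mean over occupied entries of (Ntilde / N).
    """
    if not table.counts:
        raise ValueError("cannot calibrate mu on an empty count table")
    log_ratio_sum = 0.0
    for (seq_key, conf_bin), n in table.counts.items():
        n_adj, nt_adj = _adjusted(n, table.n_tilde(seq_key, conf_bin))
        log_ratio_sum += math.log(nt_adj / n_adj)
    odds = math.exp(log_ratio_sum / len(table.counts))
    return odds / (1.0 + odds)


def energy(table: CountTable, mu: float, seq_key: str, conf_bin: ConformationBin) -> float:
    """LSPP energy in nats for one occupied (class, bin) entry."""
    if not 0.0 < mu < 1.0:
        raise ValueError("mu must lie in (0, 1)")
    n = table.counts.get((seq_key, conf_bin), 0)
    if n == 0:
        raise KeyError(f"unseen entry {(seq_key, conf_bin)}")
    n_adj, nt_adj = _adjusted(n, table.n_tilde(seq_key, conf_bin))
    return -math.log(mu * n_adj / ((1.0 - mu) * nt_adj))


def build_energy_table(structures: Iterable[BackboneStructure], kind: str) -> EnergyTable:
    """Count fragments, calibrate mu, and tabulate energies for occupied entries.

    Unseen (class, bin) pairs are capped at the maximum occupied energy of the
    table, keeping unobserved conformations unfavorable without infinities.
    """
    counts = count_fragments(structures, kind)
    mu = calibrate_mu(counts)
    energies = {key: energy(counts, mu, *key) for key in counts.counts}
    return EnergyTable(
        kind=kind,
        mu=mu,
        energies=energies,
        unseen_energy=max(energies.values()),
        n_observations=counts.total_observations,
    )


def lookup_fragment_energy(
    table: EnergyTable, seq_key: str, conf_bin: ConformationBin, has_break: bool
) -> float:
    """Energy for a fragment adopting a template conformation.

    Fragments containing a chain break contribute the reference value 0.
    """
    if has_break:
        return table.chain_break_energy
    return table.energies.get((seq_key, conf_bin), table.unseen_energy)


def save_table(table: EnergyTable, path) -> None:
    """Write a versioned JSON serialization (deterministic, exact floats)."""
    entries = sorted(
        ((key, list(conf_bin), value) for (key, conf_bin), value in table.energies.items()),
        key=lambda e: (e[0], e[1]),
    )
    payload = {
        "format": "frthread-lspp-table",
        "version": TABLE_FORMAT_VERSION,
        "kind": table.kind,
        "mu": table.mu,
        "unseen_energy": table.unseen_energy,
        "n_observations": table.n_observations,
        "entries": [[k, b, v] for k, b, v in entries],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, separators=(",", ":"), sort_keys=True)
        fh.write("\n")


def load_table(path) -> EnergyTable:
    """Load a table written by :func:`save_table`; round trip is bit-exact."""
    try:
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ValueError(f"corrupt energy-table file {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format") != "frthread-lspp-table":
        raise ValueError(f"{path} is not an energy-table file")
    if payload.get("version") != TABLE_FORMAT_VERSION:
        raise ValueError(
            f"unsupported table version {payload.get('version')!r}; "
            f"expected {TABLE_FORMAT_VERSION}"
        )
    _check_kind(payload["kind"])
    energies = {
        (key, ConformationBin(*bins)): value for key, bins, value in payload["entries"]
    }
    return EnergyTable(
        kind=payload["kind"],
        mu=payload["mu"],
        energies=energies,
        unseen_energy=payload["unseen_energy"],
        n_observations=payload.get("n_observations", 0),
    )
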
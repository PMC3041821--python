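# frthread

Protein fold recognition (threading) with local structural preference
potentials.

When a protein sequence has no close homolog of known structure, its fold can
still often be recognized by *threading*: aligning the sequence onto a library
of template structures with a scoring function that mixes sequence and
structure information, and ranking the templates by normalized alignment
score.  This package implements a five-term threading method whose
distinguishing ingredient is a pair of statistics-based **local structural
preference potentials (LSPPs)** for 3-residue and 9-residue fragments,
alongside the three classic terms (sequence profile, secondary structure,
hydrophobic pattern).  It is aimed at structural bioinformaticians who want a
small, fully testable threading stack that runs on synthetic or user-supplied
structure sets without any external binaries or database downloads.

## The method

**Fragment potentials.**  The local conformation of a fragment centered at
residue *i* is reduced to four angles: for 3-residue fragments the central
(φ, ψ) torsions plus two bend angles between backbone bisector vectors; for
9-residue fragments two virtual Cα dihedrals plus two bend angles of the
Cα-trace, with the sequence reduced to the three-letter HNP
(hydrophobic / neutral / polar) alphabet.  Each angle is binned
(60°, 60°, 30°, 30° widths → 6⁴ = 1296 joint bins).  For a fragment sequence
class *s* and conformation bin *j*, with N observations in the bin and Ñ
outside it, the potential is the log-odds energy

    E(s, j) = −ln[ µ·N(s,j) / ((1−µ)·Ñ(s,j)) ]      (nats)

The single weight µ ∈ (0, 1) is calibrated so that the *net interaction* —
the mean energy over all occupied entries — is exactly zero; in closed form
µ/(1−µ) equals the geometric mean of Ñ/N over occupied entries.  The
3-residue table spans all 20³ = 8000 residue triplets; the 9-residue joint
space holds 3⁹·6⁴ ≈ 25.5 million entries and is stored sparsely.

**Scoring.**  The score for aligning query position *i* to template position
*j* is

    E(i,j) = w₁·E_seq + w₂·E_2nd + w₃·E_hydro + w₄·(−E_frag3)
             + w₅·(−E_frag9) + E_shift

with w₁ ≡ 1 as scale normalization.  E_seq dots the query's residue
frequency vector with the template's PSSM column; E_2nd is a ±1
secondary-structure match indicator; E_hydro is a 20×20 hydrophobic-pattern
matrix (HNP-class default, user-overridable); the fragment terms score the
query fragment adopting the template's local conformation.  Setting
w₄ = w₅ = 0 gives the three-term variant (FR-t3); the five-term method is
FR-t5.

**Alignment and ranking.**  Needleman–Wunsch dynamic programming with free
end gaps, affine internal gap cost go + L·ge, and a position-dependent rule:
no gap may be placed where the query's predicted and the template's observed
secondary structure agree on helix or strand.  Each template's raw score S
is normalized two ways — Sn1 by the full alignment length including gaps,
Sn2 by that length excluding query ending gaps — and the library is ranked
by whichever mode attains the larger maximum.

**Training.**  The free parameters (5 in FR-t3, 7 in FR-t5) are fitted by
seeded coordinate ascent on per-parameter grids, maximizing the number of
matches with gold-standard (structural-superposition) alignments.

## Worked example

Build potentials from 50 synthetic structures and thread a query against a
10-template decoy library:

```python
from frthread.synthetic import FixtureSpec, make_structure_set, make_template_library
from frthread.lspp import build_energy_table
from frthread.scoring import ScoringWeights
from frthread.pipeline import thread_library

structures = [s for s, _ in make_structure_set(50, seed=42)]
table3 = build_energy_table(structures, "frag3")
table9 = build_energy_table(structures, "frag9")
print(f"frag3 table: {len(table3.energies)} occupied bins, mu = {table3.mu:.4f}")

query, templates, true_id = make_template_library(FixtureSpec(seed=0, noise_sigma=6.0))
weights = ScoringWeights(w4=2.0, w5=2.0)      # fixture-trained FR-t5 defaults
results, ranking = thread_library(query, templates, weights, table3, table9)
print(f"ranked by {ranking.chosen_mode}; true template: {true_id}")
for rank, tid in enumerate(ranking.order[:3], start=1):
    S, sn1, sn2 = ranking.entries[tid]
    print(f"{rank}  {tid:<14s} S={S:8.1f}  Sn1={sn1:6.3f}  Sn2={sn2:6.3f}")
```

Output:

```
frag3 table: 1928 occupied bins, mu = 0.2971
ranked by Sn1; true template: true-template
1  true-template  S=    56.3  Sn1= 1.083  Sn2= 1.083
2  decoy-01       S=    13.4  Sn1= 0.133  Sn2= 0.258
3  decoy-03       S=    13.4  Sn1= 0.133  Sn2= 0.258
```

The template sharing the query's segment architecture scores far above the
shuffled decoys; Sn1 = Sn2 for the true hit because its alignment has no
query ending gaps.  (µ < 0.5 here: the small synthetic training set
concentrates most classes in few bins, so negative counts do not dominate
the way they do in large structure databases.)

The same workflow is available from the shell via the `lspp` entry point:
`lspp fixtures`, `lspp build-potentials`, `lspp thread`, `lspp rank`,
`lspp train` (see `--help` on each).

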
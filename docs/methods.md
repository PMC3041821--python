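# Methods

This note records the model, the conventions fixed where the method leaves a
choice open, the synthetic data regime the package is tested in, and the
limits of what those tests show.

## Fragment geometry

A fragment conformation is a four-angle summary `(θ1, θ2, θ3, θ4)`.

*3-residue fragments* (center *i*): θ1 = φᵢ = dihedral(Cᵢ₋₁, Nᵢ, CAᵢ, Cᵢ) and
θ2 = ψᵢ = dihedral(Nᵢ, CAᵢ, Cᵢ, Nᵢ₊₁); θ3 = ∠(bᵢ, vᵢ₋₁) and θ4 = ∠(bᵢ, vᵢ₊₁),
where bᵢ bisects the two CA virtual bonds at *i* and vⱼ bisects CAⱼ→Nⱼ and
CAⱼ→Cⱼ (a vector in residue *j*'s backbone plane).

*9-residue fragments* (center *i*): only Cα atoms are used.  θ1 and θ2 are
the virtual dihedrals over CA(i−2..i+1) and CA(i−1..i+2); θ3 = ∠(bᵢ, vᵢ₊₁)
and θ4 = ∠(bᵢ₊₁, vᵢ) with bⱼ the CA-trace bisector and vⱼ the in-plane
vector perpendicular to bⱼ, oriented toward the chain's forward direction.
Using b and v at *neighboring* centers is deliberate: at the same center the
two vectors are coplanar by construction and the bend angles would carry no
twist information.

Conventions that keep every angle well defined and every input binnable:
torsions live in (−180°, 180°] (IUPAC sign, verified against an independent
formulation to 1e−9°); bends in [0°, 180°].  Bins are left-closed with the
upper endpoint folded into the last bin, widths (60°, 60°, 30°, 30°), so
binning is total and deterministic.  The in-plane vector's two-fold sign
ambiguity is fixed by requiring a non-negative dot product with the forward
virtual bond.  Degenerate geometry (collinear atoms) raises an error rather
than returning an arbitrary angle.

Chain breaks are flagged when the CA–CA virtual bond exceeds 4.25 Å (the
ideal trans value is ≈3.80 Å) or the source file's residue numbering jumps.
A fragment is *undefined* at termini (window off the chain) and *broken*
when a flagged break falls inside its window; the two signals are distinct
because broken fragments score the reference energy 0 while undefined ones
are simply skipped.  The 9-residue window is the full i−4..i+4 span for both
counting and annotation — slightly stricter than the geometric minimum of
i−2..i+2, but uniform, and it makes the chain-break contract unconditional.

## The potentials

For fragment class *s* (residue triplet, or HNP 9-mer with
H = {F,W,Y,C,M,I,L,V}, N = {A,G,T,S,P}, P = {N,Q,D,E,H,R,K}) and bin *j*:

    E(s, j) = −ln( µ N / ((1−µ) Ñ) ),   Ñ(s,j) = T(s) − N(s,j)

Ñ is per-class, not pooled: it counts observations of the *same* sequence
class falling outside the bin, which is what makes E a preference rather
than an abundance measure.  One global µ per fragment size is calibrated so
the mean energy over occupied entries is zero; the closed form
µ/(1−µ) = geomean(Ñ/N) is cross-checked against a bisection solver to 1e−10.
When Ñ exceeds N for every occupied entry — the regime of any large
structure database — the geometric mean exceeds 1 and µ > 0.5 follows.
Small synthetic training sets can sit in the opposite regime (many classes
observed in a single bin), giving µ < 0.5; this is expected and harmless
because only energy *differences* across bins matter after the weights are
trained.

Numerical choices: a pseudo-count of 0.5 is added to N and Ñ only when one
of them is zero (single-bin classes), keeping every occupied energy finite;
unseen (class, bin) pairs score the maximum occupied energy of the table — a
data-driven unfavorable cap instead of an infinity.  Counting is
per-position with overlapping windows.  Energies are in nats; the scale is
absorbed by the trained weights.  Tables are serialized as versioned JSON
with sorted entries, so identical inputs give byte-identical files and round
trips are exact.

## Scoring, gaps, alignment

The per-cell score is the linear combination given in the README with
w₁ ≡ 1; the fragment energies enter negated so that favorable (negative)
energies raise the match score.  The secondary-structure term is the ±1
indicator; PSIPRED confidences are parsed and retained but unused by
default.  The hydrophobic default matrix is +1 within an HNP class, −1 for
hydrophobic↔polar, 0 otherwise; a 20×20 file can override it.  Any side of a
fragment term that is undefined (query too close to a terminus, template bin
undefined) contributes 0, and a template chain break contributes exactly 0.

Alignment is ends-free Needleman–Wunsch: terminal gaps on both sequences are
free, an internal gap of length L costs go + L·ge, and both penalties are
non-positive.  The no-gap mask blocks transitions into and through gap
states at any cell where the query's predicted and template's observed
secondary structures agree on H or E; end gaps are exempt because they carry
no penalty and model unaligned overhangs rather than insertions.  Adjacent
insertion-plus-deletion between two matches is disallowed (gap states are
enterable only from the match state); such regions are reachable instead
through an intermediate match.  Traceback ties resolve as match > deletion
(gap in query) > insertion, making alignments deterministic.  The central
correctness argument is not the implementation but the contract: on all
small instances the DP score equals an exhaustive enumeration over every
legal alignment, masks included.

Score normalization: Sn1 = S / (full alignment length including every gap
column) = S / (Lq + Lt − n_pairs); Sn2 = S / (that length minus the query's
ending gap columns, i.e. the template overhang).  A library is ranked by Sn1
when max Sn1 ≥ max Sn2, else by Sn2 — Sn2 rescues short queries threaded
into long templates, where overhang columns dilute Sn1.  The mode is chosen
once per query over the whole library; ties in the ranking break by template
id.

## Training

Training data are (query bundle, template bundle, gold alignment) triples;
gold alignments are inputs in a plain 0-based TSV and can come from any
structural superposition.  The objective is the total number of aligned
pairs shared with the gold standards.  The optimizer is coordinate ascent:
each restart draws a start point from per-parameter grids (log-spaced for
the weights, non-positive for go/ge), sweeps the parameters in a fixed
order replacing each by its best grid value, and stops when a sweep brings
no improvement; the best point across restarts wins.  It is derivative-free,
reproducible under a seed, and sufficient for 5–7 parameters; grids are
config-exposed.  The reported history is the running best, so objectives are
non-decreasing by construction.

The shipped default weights (w2 = 4, w3 = 2, w4 = w5 = 2, E_shift = 0,
go = −4, ge = −0.5) are the output of this procedure on the synthetic
fixture suite.  They are fixture-trained values: appropriate for the
synthetic regime the tests run in, and a starting point — not a calibrated
setting — for real data.

## The synthetic data regime

The generator emulates the *formats and structure* of real inputs with known
ground truth: ideal-geometry backbones (N–CA 1.458 Å, CA–C 1.525 Å,
C–N 1.329 Å, ω = 180°) built from torsion lists; segmented
helix/strand/coil architectures with ideal torsions (−57°, −47°),
(−120°, 130°) and positive-φ coil, plus optional Gaussian torsion noise;
PSI-BLAST-dialect profiles putting a configurable frequency mass
(default 0.5, a realistic profile softness) on the true residue; homolog
pairs made by point mutation (default rate 0.1) and coil-restricted
deletions; and decoy libraries of shuffled architectures.  Two generator
choices keep the gold mapping unambiguous by construction: indels are placed
only inside coil segments, and a mutated residue never duplicates an
adjacent template residue (which would fake a register shift no
sequence-based scorer could reject).

What these fixtures do **not** emulate: real torsion distributions and their
correlations, side chains, non-ideal bond geometry, genuinely remote
homology (20–30 % identity), profile columns estimated from real alignments,
or a realistic fold library.  Passing tests therefore demonstrate the
*mechanics* — correct geometry, calibration, alignment optimality,
bookkeeping, and end-to-end signal integration — not benchmark-level
accuracy on real proteins, which would require a large curated structure
database and upstream profile/secondary-structure tools.

Problem sizes used by the test suite and acceptance script — 50 training
structures of ~40–80 residues for the potentials, 10-template libraries over
10 seeds, 220 enumeration-checked alignment instances up to 5×5 — were
chosen as the smallest sizes at which every contract is exercised with
comfortable statistical margin.

## Known limitations

- The 3- and 9-residue bend-angle constructions are one concrete realization
  of a bisector/in-plane-vector scheme; other sign and pairing conventions
  exist, and the discretization (fixed bin widths) is not revisited here.
- Single-chain templates only; first PDB model only; no mmCIF.
- The gap model is position-dependent but not context-specific (no
  profile-derived gap penalties).
- No statistical significance (Z-score/E-value) attaches to rankings.
- 3-D model building from the ranked templates is out of scope.
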
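"""Amino-acid alphabets: the 20 standard residues and the HNP reduction."""

from __future__ import annotations

import warnings

#: Canonical residue order (PSI-BLAST PSSM column order).
AA20 = "ARNDCQEGHILKMFPSTWYV"

AA_INDEX = {aa: k for k, aa in enumerate(AA20)}

#: Three-class hydrophobic/neutral/polar reduction of the 20 amino acids.
HNP_CLASS = {}
for _aa in "FWYCMILV":
    HNP_CLASS[_aa] = "H"
for _aa in "AGTSP":
    HNP_CLASS[_aa] = "N"
for _aa in "NQDEHRK":
    HNP_CLASS[_aa] = "P"


def hnp_reduce(sequence: str) -> str:
    """Map a residue string onto the HNP alphabet.

    Unknown letters map to the neutral class N with a warning.
    """
    out = []
    for aa in sequence:
        cls = HNP_CLASS.get(aa)
        if cls is None:
            warnings.warn(f"unknown residue {aa!r} mapped to HNP class N", stacklevel=2)
            cls = "N"
        out.append(cls)
    return "".join(out)
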
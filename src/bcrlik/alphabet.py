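"""The canonical 20-letter amino-acid alphabet.

All probability matrices in this package have 20 columns ordered by this
alphabet; positions map letter <-> column index bijectively.
"""

from __future__ import annotations

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
N_AA: int = len(AMINO_ACIDS)

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def is_canonical(sequence: str) -> bool:
    """True if every letter of ``sequence`` is one of the 20 canonical residues."""
    return all(c in AA_INDEX for c in sequence)


def aa_indices(sequence: str) -> list[int]:
    """Column indices of each residue; raises KeyError on non-canonical letters."""
    return [AA_INDEX[c] for c in sequence]
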
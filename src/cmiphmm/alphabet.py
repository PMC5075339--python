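"""Amino-acid alphabet constants shared across the package.

The canonical ordering ``ACDEFGHIKLMNPQRSTVWY`` is used for every
20-vector in the package (emission distributions, Fisher scores).
AAindex flat files list residues in their own two-row layout; the parser
re-orders them into this canonical order at the I/O boundary.
"""

from __future__ import annotations

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
N_AA: int = 20

GAP_CHARS = frozenset("-.")

#: Residue ordering of the two "I" rows in an AAindex1 record:
#: A/L  R/K  N/M  D/F  C/P  Q/S  E/T  G/W  H/Y  I/V
AAINDEX_ROW1 = "ARNDCQEGHI"
AAINDEX_ROW2 = "LKMFPSTWYV"


def is_gap(ch: str) -> bool:
    return ch in GAP_CHARS


def validate_residue(ch: str, *, position: int | None = None,
                     context: str = "sequence") -> None:
    """Raise ``ValueError`` for any letter outside the 20-residue alphabet."""
    if ch not in AA_INDEX:
        where = f" at position {position + 1}" if position is not None else ""
        raise ValueError(
            f"unknown residue letter {ch!r}{where} in {context}; "
            f"expected one of {AMINO_ACIDS}"
        )
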
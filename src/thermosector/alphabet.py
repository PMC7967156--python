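"""Residue alphabet shared across the package.

Every statistic in this package is defined over the 20 standard amino
acids plus the gap symbol ``-`` (21 symbols in total).  Ambiguity and
non-standard codes (B, J, Z, X, U, O) carry no frequency slot in the
model and are normalized to gap at read time.
"""

from __future__ import annotations

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
GAP: str = "-"
ALPHABET: str = AMINO_ACIDS + GAP
N_SYMBOLS: int = len(ALPHABET)  # 21
GAP_INDEX: int = ALPHABET.index(GAP)

#: symbols silently rewritten to gap on input (ambiguity / rare residues)
NONSTANDARD: frozenset[str] = frozenset("BJZXUO")

SYMBOL_INDEX: dict[str, int] = {s: i for i, s in enumerate(ALPHABET)}


def symbol_to_index(symbol: str) -> int:
    """Map a one-letter symbol to its alphabet index; raise on unknown symbols."""
    try:
        return SYMBOL_INDEX[symbol]
    except KeyError:
        raise ValueError(f"symbol {symbol!r} outside the 20-aa+gap alphabet") from None
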
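"""In-silico trypsin digestion and observable-peptide bookkeeping.

Intensity-based absolute quantification divides a protein's summed peptide
intensity by the number of tryptic peptides the mass spectrometer could in
principle have seen.  This module produces those denominators: the complete
(zero missed cleavages) tryptic peptide list of a sequence, and the count
and summed length of the peptides falling inside the detectability window.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Detectability window (residues, inclusive) for "theoretically observable"
#: tryptic peptides.  6-30 is the standard iBAQ convention.
DEFAULT_WINDOW: tuple[int, int] = (6, 30)


@dataclass(frozen=True)
class DigestResult:
    """Tryptic digestion of one sequence plus observable-peptide totals."""

    peptides: tuple[str, ...]
    observable_count: int
    observable_length: int


def tryptic_peptides(sequence: str) -> list[str]:
    """Cleave a sequence C-terminal to K or R, except before proline.

    Complete digestion: zero missed cleavages.  Peptides are returned in
    N-to-C order and concatenate back to the input sequence.

    Parameters
    ----------
    sequence : str
        Non-empty amino-acid sequence.

    Raises
    ------
    ValueError
        If the sequence is empty.
    """
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    peptides: list[str] = []
    start = 0
    # Keil rule: K/R followed by P suppresses cleavage.
    for i in range(len(sequence) - 1):
        if sequence[i] in "KR" and sequence[i + 1] != "P":
            peptides.append(sequence[start : i + 1])
            start = i + 1
    peptides.append(sequence[start:])
    return peptides


def observable_stats(
    sequence: str,
    min_len: int = DEFAULT_WINDOW[0],
    max_len: int = DEFAULT_WINDOW[1],
) -> tuple[int, int]:
    """Count and total length of tryptic peptides inside the length window.

    Returns ``(observable_count, observable_length)`` where the length is
    the summed residue count of the observable peptides only — unobservable
    stretches of the protein contribute nothing to either total.
    """
    if not 1 <= min_len <= max_len:
        raise ValueError(f"invalid window [{min_len}, {max_len}]")
    count = 0
    length = 0
    for pep in tryptic_peptides(sequence):
        if min_len <= len(pep) <= max_len:
            count += 1
            length += len(pep)
    return count, length


def digest(
    sequence: str,
    min_len: int = DEFAULT_WINDOW[0],
    max_len: int = DEFAULT_WINDOW[1],
) -> DigestResult:
    """Full digestion record for one sequence."""
    peps = tuple(tryptic_peptides(sequence))
    count, length = observable_stats(sequence, min_len, max_len)
    return DigestResult(peptides=peps, observable_count=count, observable_length=length)
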
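"""Shared scoring configuration for pairwise alignment and pair screening."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ScoringConfig:
    """Parameters for Smith-Waterman alignment and the k-mer prefilter.

    Attributes
    ----------
    matrix_name:
        Name of the substitution matrix (any matrix shipped with
        ``Bio.Align.substitution_matrices``).
    gap_open:
        Gap opening penalty (positive number). A gap of length ``g`` costs
        ``gap_open + g * gap_extend``, the BLAST-style convention.
    gap_extend:
        Per-residue gap extension penalty (positive number).
    kmer_length:
        Exact-match word length used to screen sequence pairs before full
        alignment; only pairs sharing at least one common word of this
        length are aligned.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0
    kmer_length: int = 4

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be nonnegative")
        if self.kmer_length < 1:
            raise ValueError("kmer_length must be >= 1")


DEFAULT_SCORING = ScoringConfig()
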
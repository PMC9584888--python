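"""Small built-in motif library for demos and quick starts."""

from __future__ import annotations

from .matrices import MotifCountMatrix, build_pfm_from_sequences

__all__ = ["POLYA_HEXAMER_VARIANTS", "polyadenylation_matrix"]

#: The twelve common single-base variants of the polyadenylation signal
#: hexamer observed upstream of human cleavage sites, headed by the canonical
#: AATAAA (AAUAAA on the mRNA).  Useful as a ready-made A-rich search matrix
#: for poly(A)-site screening in mRNA or genomic sequence.
POLYA_HEXAMER_VARIANTS: tuple[str, ...] = (
    "AATAAA", "ATTAAA", "TATAAA", "AGTAAA", "AAGAAA", "AATATA",
    "AATACA", "CATAAA", "GATAAA", "AATGAA", "TTTAAA", "ACTAAA",
)


def polyadenylation_matrix() -> MotifCountMatrix:
    """Count matrix built from the twelve poly(A)-signal hexamer variants."""
    return build_pfm_from_sequences(list(POLYA_HEXAMER_VARIANTS),
                                    matrix_id="POLYA", name="polyA_signal")
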
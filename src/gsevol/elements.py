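"""Shared container for full-length LTR retrotransposon candidates.

An LTR retrotransposon inserts with two byte-identical long terminal
repeats; their subsequent divergence K dates the insertion via T = K/(2r).
Detection (structural scan) and dating (alignment + distance correction)
both operate on this object.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class LTRElement:
    """A full-length LTR element candidate on a genome sequence.

    Coordinates are 0-based half-open on the forward strand.  ``ltr5`` always
    denotes the upstream copy; dating is invariant to the 5'/3' labelling.
    """

    seq_id: str
    ltr5: tuple[int, int]
    ltr3: tuple[int, int]
    pair_identity: float
    motif_ok: bool = False
    tsd5: str = ""
    tsd3: str = ""
    score: float = 0.0
    # dating results, filled by gsevol.dating
    p_distance: float | None = None
    K: float | None = None
    T_years: float | None = None
    saturated: bool = False

    def __post_init__(self) -> None:
        s5, e5 = self.ltr5
        s3, e3 = self.ltr3
        if not (0 <= s5 < e5 <= s3 < e3):
            raise ValueError(
                f"invalid LTR pair intervals ltr5={self.ltr5} ltr3={self.ltr3}"
            )
        if not 0.0 <= self.pair_identity <= 1.0:
            raise ValueError("pair_identity must lie in [0, 1]")

    @property
    def internal(self) -> tuple[int, int]:
        """Interval between the two LTR copies."""
        return (self.ltr5[1], self.ltr3[0])

    @property
    def span(self) -> tuple[int, int]:
        """Full element span (5' LTR start to 3' LTR end)."""
        return (self.ltr5[0], self.ltr3[1])

    @property
    def separation(self) -> int:
        """Start-to-start distance between the two copies."""
        return self.ltr3[0] - self.ltr5[0]

    @property
    def has_tsd(self) -> bool:
        return bool(self.tsd5) and self.tsd5 == self.tsd3
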
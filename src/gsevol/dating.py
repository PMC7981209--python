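"""Molecular-clock dating of LTR retrotransposon insertions.

The two terminal repeats of an LTR element are identical at insertion and
diverge afterwards at the neutral substitution rate.  Aligning the 5' and
3' copies, correcting the observed mismatch fraction p for multiple hits
(Jukes–Cantor or Kimura two-parameter), and dividing by twice the per-site
annual rate gives the insertion age:

    T = K / (2 r),    default r = 1.3e-8 substitutions / site / year.

Pairs near saturation (p >= 3/4 under JC69) carry no usable signal and are
flagged undatable rather than dated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import Align

from .elements import LTRElement
from .genome import GenomeSequence

#: substitutions per site per year for neutrally evolving plant LTR pairs
DEFAULT_RATE = 1.3e-8

_MODELS = ("raw", "JC69", "K2P")

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


class SaturationError(ValueError):
    """Divergence too high for the chosen correction (element undatable)."""


@dataclass
class DatingParams:
    """Clock and distance-model settings.

    ``model`` is one of ``raw`` (uncorrected p-distance), ``JC69`` or
    ``K2P``; gapped alignment columns are always excluded from p.
    ``terminal_trim`` bases are dropped from each end of each LTR copy
    before aligning: the structural detector fixes boundaries on the TG/CA
    termini and on match-rich extension endpoints, so the outermost columns
    are conditioned on being identical and would bias divergence low.
    """

    r: float = DEFAULT_RATE
    model: str = "JC69"
    terminal_trim: int = 2

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("substitution rate r must be positive")
        if self.model not in _MODELS:
            raise ValueError(f"model must be one of {_MODELS}")
        if self.terminal_trim < 0:
            raise ValueError("terminal_trim must be non-negative")


@dataclass
class PairwiseAlignment:
    """A global pairwise alignment as two gapped rows of equal length."""

    row1: str
    row2: str
    score: float

    def __post_init__(self) -> None:
        if len(self.row1) != len(self.row2):
            raise ValueError("aligned rows must have equal length")

    def ungapped_columns(self) -> list[tuple[str, str]]:
        return [
            (a, b)
            for a, b in zip(self.row1, self.row2)
            if a != "-" and b != "-"
        ]


def align_ltr_pair(
    ltr5_seq: str,
    ltr3_seq: str,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -10.0,
    gap_extend: float = -4.0,
) -> PairwiseAlignment:
    """Optimal global alignment of an LTR pair under affine gap penalties.

    ``gap_open`` is the score of the first gapped position of a gap and
    ``gap_extend`` of each further position.  The highest-scoring alignment
    is returned; among co-optimal alignments the aligner's first enumeration
    is taken, which is deterministic for fixed inputs and scores.
    """
    if not ltr5_seq or not ltr3_seq:
        raise ValueError("both LTR sequences must be non-empty")
    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=match,
        mismatch_score=mismatch,
        open_gap_score=gap_open,
        extend_gap_score=gap_extend,
    )
    aln = aligner.align(ltr5_seq.upper(), ltr3_seq.upper())[0]
    return PairwiseAlignment(row1=str(aln[0]), row2=str(aln[1]), score=aln.score)


def pairwise_divergence(aln: PairwiseAlignment, model: str = "JC69") -> float:
    """Per-site divergence K from an alignment under the chosen model.

    raw:   K = p
    JC69:  K = -(3/4) ln(1 - (4/3) p)
    K2P:   K = -(1/2) ln(1 - 2P - Q) - (1/4) ln(1 - 2Q)
           with P, Q the transition / transversion column fractions.

    Raises :class:`SaturationError` when the correction's logarithm argument
    is non-positive.
    """
    if model not in _MODELS:
        raise ValueError(f"model must be one of {_MODELS}")
    cols = aln.ungapped_columns()
    if not cols:
        raise ValueError("alignment has no ungapped columns")
    n = len(cols)
    transitions = transversions = 0
    for a, b in cols:
        if a == b:
            continue
        if (a in _PURINES and b in _PURINES) or (
            a in _PYRIMIDINES and b in _PYRIMIDINES
        ):
            transitions += 1
        else:
            transversions += 1
    p = (transitions + transversions) / n
    if model == "raw":
        return p
    if model == "JC69":
        arg = 1.0 - 4.0 / 3.0 * p
        if arg <= 0:
            raise SaturationError(f"JC69 saturated at p = {p:.4f}")
        return -0.75 * math.log(arg)
    P, Q = transitions / n, transversions / n
    arg1, arg2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if arg1 <= 0 or arg2 <= 0:
        raise SaturationError(f"K2P saturated at P = {P:.4f}, Q = {Q:.4f}")
    return -0.5 * math.log(arg1) - 0.25 * math.log(arg2)


def insertion_time(K: float, params: DatingParams) -> float:
    """Insertion age in years: T = K / (2 r)."""
    if K < 0:
        raise ValueError("K must be non-negative")
    return K / (2.0 * params.r)


def date_element(
    genome: GenomeSequence,
    element: LTRElement,
    params: DatingParams | None = None,
    **align_kwargs,
) -> LTRElement:
    """Align the element's LTR pair and fill p, K and T in place.

    Saturated pairs get ``saturated=True`` with K and T left unset.
    """
    params = params or DatingParams()
    s5, e5 = element.ltr5
    s3, e3 = element.ltr3
    trim = params.terminal_trim
    if min(e5 - s5, e3 - s3) <= 2 * trim + 10:
        trim = 0
    aln = align_ltr_pair(
        genome.residues[s5 + trim : e5 - trim],
        genome.residues[s3 + trim : e3 - trim],
        **align_kwargs,
    )
    element.p_distance = pairwise_divergence(aln, model="raw")
    try:
        element.K = pairwise_divergence(aln, model=params.model)
    except SaturationError:
        element.saturated = True
        element.K = None
        element.T_years = None
        return element
    element.T_years = insertion_time(element.K, params)
    return element


def date_elements(
    genome: GenomeSequence,
    elements: Iterable[LTRElement],
    params: DatingParams | None = None,
) -> tuple[list[LTRElement], int]:
    """Date every element; returns (elements, number of saturated pairs)."""
    params = params or DatingParams()
    dated = [date_element(genome, el, params) for el in elements]
    return dated, sum(el.saturated for el in dated)


def write_elements_tsv(elements: Sequence[LTRElement], path) -> None:
    """Per-element table: coordinates, identity, flags, p, K, T."""
    rows = []
    for i, el in enumerate(elements):
        rows.append(
            {
                "element_id": f"ltr{i}",
                "seq_id": el.seq_id,
                "ltr5_start": el.ltr5[0], "ltr5_end": el.ltr5[1],
                "ltr3_start": el.ltr3[0], "ltr3_end": el.ltr3[1],
                "pair_identity": el.pair_identity,
                "motif_ok": el.motif_ok,
                "tsd": el.tsd5,
                "score": el.score,
                "p_distance": el.p_distance,
                "K": el.K,
                "T_years": el.T_years,
                "saturated": el.saturated,
            }
        )
    import pandas as pd

    pd.DataFrame(
        rows,
        columns=[
            "element_id", "seq_id", "ltr5_start", "ltr5_end", "ltr3_start",
            "ltr3_end", "pair_identity", "motif_ok", "tsd", "score",
            "p_distance", "K", "T_years", "saturated",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_elements_tsv(path) -> list[LTRElement]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        el = LTRElement(
            seq_id=str(row["seq_id"]),
            ltr5=(int(row["ltr5_start"]), int(row["ltr5_end"])),
            ltr3=(int(row["ltr3_start"]), int(row["ltr3_end"])),
            pair_identity=float(row["pair_identity"]),
            motif_ok=bool(row["motif_ok"]),
            tsd5="" if pd.isna(row["tsd"]) else str(row["tsd"]),
            tsd3="" if pd.isna(row["tsd"]) else str(row["tsd"]),
            score=float(row["score"]),
        )
        if not pd.isna(row.get("K")):
            el.K = float(row["K"])
        if not pd.isna(row.get("T_years")):
            el.T_years = float(row["T_years"])
        if not pd.isna(row.get("p_distance")):
            el.p_distance = float(row["p_distance"])
        el.saturated = bool(row.get("saturated", False))
        out.append(el)
    return out


def species_mean_insertion_time(elements: Sequence[LTRElement]) -> float:
    """Unweighted arithmetic mean insertion time in Myr.

    Undatable (saturated) elements are excluded; with no datable element the
    result is NaN so missingness propagates through the species table.
    """
    times = [el.T_years for el in elements if el.T_years is not None]
    if not times:
        return math.nan
    return sum(times) / len(times) / 1e6
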
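"""Synthetic genomes with planted repeats of known class and age.

Every downstream stage of the toolkit (tandem finder, library masker,
structural LTR detector, molecular-clock dating, comparative regression) is
validated against ground truth produced here:

* genomes are i.i.d. background sequence at a stated GC content, with
  non-overlapping planted elements — full-length LTR retrotransposons whose
  two terminal repeats were identical at insertion and have diverged for a
  known number of years under a Jukes–Cantor clock, tandem arrays, and
  LINE/DNA decoys derived from a known consensus library;
* species panels carry a trait that is linear in a predictor with
  Brownian-motion residuals on a known phylogeny, so regression slope
  recovery and PGLS calibration can be measured exactly.

All randomness flows through a single :class:`numpy.random.Generator`; the
same config and seed reproduce byte-identical FASTA and truth files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .genome import GenomeSequence, write_fasta
from .gffio import write_gff3

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# planted-element ground truth
# ---------------------------------------------------------------------------

@dataclass
class PlantedElement:
    """Ground truth for one planted repeat.

    ``true_interval`` is the 0-based half-open span of the element body in
    the final genome; for LTR elements it runs from the 5' LTR start to the
    3' LTR end (TSDs flank it on both sides).
    """

    element_class: str  # LTR | tandem | LINE | DNA
    sequence: str
    age_years: float = 0.0
    ltr_length: int = 0
    internal_length: int = 0
    tsd: str = ""
    family_id: str = ""
    insert_position: int = -1          # 0-based offset of the full insert (incl. TSD)
    true_interval: tuple[int, int] = (0, 0)
    ltr5_interval: tuple[int, int] = (0, 0)
    ltr3_interval: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.age_years < 0:
            raise ValueError("age_years must be non-negative")


@dataclass
class SimulationConfig:
    """Parameters of one synthetic genome.

    Defaults emulate a small plant genome region: GC 36%, LTR elements with
    500 bp terminal repeats and a 1 kb internal region, substitution rate
    r = 1.3e-8 per site per year, ages spread over the last few Myr (most
    real LTR bursts date to < 3 Mya).
    """

    genome_length: int = 300_000
    gc_content: float = 0.36
    n_ltr: int = 20
    n_tandem: int = 10
    n_line: int = 5
    n_dna: int = 5
    ltr_age_distribution: Sequence[float] = (0.5e6, 1.0e6, 2.0e6, 3.0e6)
    substitution_rate: float = 1.3e-8
    ltr_length: int = 500
    internal_length: int = 1000
    tsd_length: int = 5
    tandem_period_range: tuple[int, int] = (2, 10)
    tandem_copies_range: tuple[int, int] = (20, 40)
    line_length: int = 2000
    dna_length: int = 600
    decoy_divergence: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must lie in (0, 1)")
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if self.total_planted_length() >= self.genome_length:
            raise ValueError(
                "total planted length "
                f"({self.total_planted_length()}) must be below genome_length "
                f"({self.genome_length})"
            )

    def total_planted_length(self) -> int:
        ltr_span = 2 * self.tsd_length + 2 * self.ltr_length + self.internal_length
        tandem_max = self.tandem_period_range[1] * self.tandem_copies_range[1]
        return (
            self.n_ltr * ltr_span
            + self.n_tandem * tandem_max
            + self.n_line * self.line_length
            + self.n_dna * self.dna_length
        )


def random_dna(n: int, gc: float, rng: np.random.Generator) -> str:
    """i.i.d. DNA string of length n at the given GC content."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p).tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# LTR elements and Jukes–Cantor aging
# ---------------------------------------------------------------------------

def simulate_ltr_element(
    ltr_len: int,
    internal_len: int,
    tsd_len: int,
    rng: np.random.Generator,
    gc: float = 0.5,
) -> PlantedElement:
    """Build a freshly inserted full-length LTR element.

    Layout is ``TSD + 5'LTR + internal + 3'LTR + TSD`` with the two LTR
    copies byte-identical (age 0), each starting TG and ending CA, and the
    same target-site duplication on both flanks.
    """
    if not 100 <= ltr_len <= 5000:
        raise ValueError("ltr_len must lie in [100, 5000]")
    if not 4 <= tsd_len <= 6:
        raise ValueError("tsd_len must lie in [4, 6]")
    if internal_len < 0:
        raise ValueError("internal_len must be non-negative")
    ltr = "TG" + random_dna(ltr_len - 4, gc, rng) + "CA"
    internal = random_dna(internal_len, gc, rng)
    tsd = random_dna(tsd_len, gc, rng)
    return PlantedElement(
        element_class="LTR",
        sequence=tsd + ltr + internal + ltr + tsd,
        age_years=0.0,
        ltr_length=ltr_len,
        internal_length=internal_len,
        tsd=tsd,
    )


def jc_substitution_probability(rate: float, age_years: float) -> float:
    """Probability a site differs from its initial state after ``age_years``.

    Exact Jukes–Cantor transition: (3/4)(1 - exp(-4/3 * rate * t)).
    """
    return 0.75 * (1.0 - np.exp(-4.0 / 3.0 * rate * age_years))


def _mutate(seq: str, p_site: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < p_site
    n_hit = int(hit.sum())
    if n_hit:
        # substitute to one of the three other bases, uniformly
        idx = np.searchsorted(_BASES, arr[hit])
        shift = rng.integers(1, 4, size=n_hit)
        arr[hit] = _BASES[(idx + shift) % 4]
    return arr.tobytes().decode("ascii")


def age_element(
    element: PlantedElement,
    age_years: float,
    rate: float,
    rng: np.random.Generator,
) -> PlantedElement:
    """Apply ``age_years`` of independent Jukes–Cantor substitution.

    Every site of the element (both LTR copies and the internal region)
    mutates independently; because both copies drift away from the common
    insertion state, the expected JC-corrected divergence between them is
    2 * rate * age_years — the quantity the T = K/(2r) clock inverts.
    """
    if age_years < 0:
        raise ValueError("age_years must be non-negative")
    if rate <= 0:
        raise ValueError("rate must be positive")
    p_site = jc_substitution_probability(rate, age_years)
    mutated = _mutate(element.sequence, p_site, rng)
    return dataclasses.replace(element, sequence=mutated, age_years=age_years)


# ---------------------------------------------------------------------------
# whole-genome simulation
# ---------------------------------------------------------------------------

@dataclass
class LibraryEntry:
    family_id: str
    repeat_class: str
    consensus: str


def _place_elements(
    lengths: list[int], genome_length: int, rng: np.random.Generator
) -> list[int]:
    """Non-overlapping start offsets with >= 10 bp margins.

    The free space left over after all elements and margins is split into
    random inter-element gaps (stars-and-bars), so placement succeeds even
    at high occupancy; element order along the genome is randomised.
    """
    n = len(lengths)
    if n == 0:
        return []
    margin = 10
    free = genome_length - sum(lengths) - margin * (n + 1)
    if free < 0:
        raise ValueError(
            "planted elements plus margins exceed genome_length; genome too full"
        )
    cuts = np.sort(rng.integers(0, free + 1, size=n))
    gaps = np.diff(np.concatenate(([0], cuts, [free])))
    order = rng.permutation(n)
    starts = [0] * n
    pos = 0
    for slot, i in enumerate(order):
        pos += int(gaps[slot]) + margin
        starts[i] = pos
        pos += lengths[i]
    return starts


def make_decoy_library(
    config: SimulationConfig, rng: np.random.Generator
) -> list[LibraryEntry]:
    """Random LINE/DNA consensus families decoy copies are mutated from."""
    library = []
    for cls, count, length in (
        ("LINE", config.n_line, config.line_length),
        ("DNA", config.n_dna, config.dna_length),
    ):
        for i in range(count):
            library.append(
                LibraryEntry(
                    f"{cls}_fam_{i}", cls, random_dna(length, config.gc_content, rng)
                )
            )
    return library


def simulate_genome(
    config: SimulationConfig,
    seq_id: str = "synth1",
    library: list[LibraryEntry] | None = None,
) -> tuple[GenomeSequence, list[PlantedElement], list[LibraryEntry]]:
    """Simulate one genome: background + planted elements + decoy library.

    Returns the genome, the ground-truth planted elements (positions filled
    in), and the repeat library holding the LINE/DNA consensi the decoys
    were mutated from (usable directly by the library masker).  Passing a
    shared ``library`` plants decoys from it instead of generating new
    families — use this when simulating a multi-species panel masked
    against one library.
    """
    rng = np.random.default_rng(config.seed)
    gc = config.gc_content

    planted: list[PlantedElement] = []
    if library is None:
        library = make_decoy_library(config, rng)

    ages = list(config.ltr_age_distribution) or [0.0]
    for i in range(config.n_ltr):
        el = simulate_ltr_element(
            config.ltr_length, config.internal_length, config.tsd_length, rng, gc
        )
        el = age_element(el, ages[i % len(ages)], config.substitution_rate, rng)
        el.family_id = f"LTR_planted_{i}"
        planted.append(el)

    for i in range(config.n_tandem):
        period = int(rng.integers(*config.tandem_period_range, endpoint=True))
        copies = int(rng.integers(*config.tandem_copies_range, endpoint=True))
        motif = random_dna(period, gc, rng)
        planted.append(
            PlantedElement(
                element_class="tandem",
                sequence=motif * copies,
                family_id=f"tandem_planted_{i}",
            )
        )

    from .genome import revcomp

    for cls, count in (("LINE", config.n_line), ("DNA", config.n_dna)):
        fams = [e for e in library if e.repeat_class == cls]
        for i in range(count):
            entry = fams[i % len(fams)] if fams else None
            if entry is None:
                continue
            copy = _mutate(entry.consensus, config.decoy_divergence, rng)
            if rng.random() < 0.5:  # plant either strand
                copy = revcomp(copy)
            planted.append(
                PlantedElement(
                    element_class=cls, sequence=copy, family_id=entry.family_id
                )
            )

    background = np.frombuffer(
        random_dna(config.genome_length, gc, rng).encode("ascii"), dtype=np.uint8
    ).copy()

    starts = _place_elements(
        [len(p.sequence) for p in planted], config.genome_length, rng
    )
    for el, s in zip(planted, starts):
        e = s + len(el.sequence)
        background[s:e] = np.frombuffer(el.sequence.encode("ascii"), dtype=np.uint8)
        el.insert_position = s
        if el.element_class == "LTR":
            t = len(el.tsd)
            body = (s + t, e - t)  # exclude TSDs from the element body
            el.true_interval = body
            el.ltr5_interval = (body[0], body[0] + el.ltr_length)
            el.ltr3_interval = (body[1] - el.ltr_length, body[1])
        else:
            el.true_interval = (s, e)

    genome = GenomeSequence(seq_id, background.tobytes().decode("ascii"))
    planted.sort(key=lambda p: p.true_interval[0])
    return genome, planted, library


def write_truth_gff(
    planted: Sequence[PlantedElement], seq_id: str, path: str | Path
) -> None:
    """Write ground truth as GFF3 with element_class / age_years attributes."""
    rows = []
    for i, el in enumerate(planted):
        s, e = el.true_interval
        attrs = {
            "ID": f"planted{i}",
            "element_class": el.element_class,
            "family_id": el.family_id or None,
            "age_years": f"{el.age_years:g}" if el.element_class == "LTR" else None,
            "ltr_length": el.ltr_length if el.element_class == "LTR" else None,
        }
        rows.append((seq_id, "gsevol_sim", "planted_repeat", s, e, None, "+", attrs))
    write_gff3(rows, path)


def write_library_fasta(library: Sequence[LibraryEntry], path: str | Path) -> None:
    """Write the decoy library; class is encoded as ``family#class`` in the id."""
    write_fasta(
        [
            GenomeSequence(f"{e.family_id}#{e.repeat_class}", e.consensus)
            for e in library
        ],
        path,
    )


# ---------------------------------------------------------------------------
# phylogeny and trait-panel simulation
# ---------------------------------------------------------------------------

def simulate_yule_tree(
    n_tips: int, birth_rate: float, rng: np.random.Generator
) -> dendropy.Tree:
    """Pure-birth (Yule) tree with strictly positive branch lengths.

    Lineages split at rate ``birth_rate`` each; after the n-th tip appears,
    all pending branches are extended by the waiting time to the next
    (uncommitted) speciation so that no terminal branch has zero length.
    """
    if n_tips < 3:
        raise ValueError("n_tips must be at least 3")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    left, right = root.new_child(edge_length=0.0), root.new_child(edge_length=0.0)
    active = [left, right]
    while len(active) < n_tips:
        wait = rng.exponential(1.0 / (birth_rate * len(active)))
        for node in active:
            node.edge.length += wait
        idx = int(rng.integers(len(active)))
        parent = active.pop(idx)
        for _ in range(2):
            active.append(parent.new_child(edge_length=0.0))
    tail = rng.exponential(1.0 / (birth_rate * len(active)))
    for node in active:
        node.edge.length += tail
    for i, node in enumerate(active, start=1):
        node.taxon = taxa.new_taxon(label=f"T{i}")
    return tree


def simulate_species_panel(
    tree: dendropy.Tree,
    slope: float,
    intercept: float,
    bm_sigma2: float,
    rng: np.random.Generator,
    x_low: float = 0.0,
    x_high: float = 100.0,
) -> pd.DataFrame:
    """Per-tip traits with a planted linear relationship and BM residuals.

    The predictor x is i.i.d. uniform on [x_low, x_high]; the response is
    ``y = intercept + slope * x + eps`` where eps is multivariate normal with
    covariance ``bm_sigma2 * V`` and V the Brownian-motion (shared path
    length) matrix of the tree.  Rows are ordered as in the covariance.
    """
    from .comparative import bm_covariance

    if bm_sigma2 < 0:
        raise ValueError("bm_sigma2 must be non-negative")
    V, labels = bm_covariance(tree)
    n = len(labels)
    x = rng.uniform(x_low, x_high, size=n)
    if bm_sigma2 > 0:
        L = np.linalg.cholesky(bm_sigma2 * V)
        eps = L @ rng.standard_normal(n)
    else:
        eps = np.zeros(n)
    y = intercept + slope * x + eps
    return pd.DataFrame({"species": labels, "x": x, "y": y}).set_index("species")
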
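"""Detector correctness against planted truth and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from gsevol.annotate import (
    DEFAULT_PRIORITY,
    RepeatAnnotation,
    RepeatLibrary,
    compute_class_proportions,
    find_ltr_candidates,
    find_tandem_repeats,
    ltr_elements_to_annotations,
    mask_with_library,
    resolve_overlaps,
)
from gsevol.genome import GenomeSequence, revcomp
from gsevol.simulate import (
    LibraryEntry,
    SimulationConfig,
    random_dna,
    simulate_genome,
    _mutate,
)


def jaccard(a, b):
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    return inter / ((a[1] - a[0]) + (b[1] - b[0]) - inter)


# ---------------------------------------------------------------------------
# tandem repeats
# ---------------------------------------------------------------------------

class TestTandemFinder:
    def test_perfect_dinucleotide_array(self):
        anns = find_tandem_repeats("ACACACACACAC", min_period=2, min_copies=4)
        assert len(anns) == 1
        a = anns[0]
        assert (a.start, a.end) == (0, 12)
        assert a.family_id == "period_2"
        assert a.identity == 1.0

    def test_empty_sequence_gives_empty_result(self):
        assert find_tandem_repeats("") == []

    def test_parameter_bounds(self):
        with pytest.raises(ValueError):
            find_tandem_repeats("ACGT", min_period=0)
        with pytest.raises(ValueError):
            find_tandem_repeats("ACGT", min_period=5, max_period=2)

    def test_random_sequence_false_positive_rate(self):
        # expected < 1 spurious array over many random 10 kb draws
        hits = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            s = random_dna(10_000, 0.5, rng)
            hits += len(find_tandem_repeats(s, min_copies=10, min_identity=0.95))
        assert hits / 30 < 1

    def test_planted_pentamer_array_recovered(self, standard_fixture):
        rng = np.random.default_rng(0)
        motif = random_dna(5, 0.5, rng)
        array = motif * 30
        flank = random_dna(3000, 0.36, rng)
        seq = flank + array + flank
        truth = (3000, 3000 + len(array))
        anns = find_tandem_repeats(seq, min_copies=10)
        assert any(jaccard((a.start, a.end), truth) >= 0.9 for a in anns)

    def test_agrees_with_brute_force_on_small_sequences(self):
        # oracle: exhaustive scan of every (start, period) perfect maximal array
        def brute_force_perfect(s, min_copies):
            found = set()
            for p in range(1, len(s) // min_copies + 1):
                i = 0
                while i + p <= len(s):
                    j = i
                    while j + p < len(s) and s[j + p] == s[j]:
                        j += 1
                    span = (j + p) - i
                    if span >= min_copies * p and span // p >= min_copies:
                        found.add((i, i + span))
                        i = j + 1
                    else:
                        i += 1
            return found

        rng = np.random.default_rng(3)
        base = random_dna(300, 0.5, rng)
        seq = base[:100] + "TTAGG" * 12 + base[100:200] + "CA" * 15 + base[200:]
        oracle = brute_force_perfect(seq, min_copies=8)
        anns = find_tandem_repeats(seq, min_copies=8, min_identity=1.0)
        for a in anns:
            assert any(jaccard((a.start, a.end), o) >= 0.9 for o in oracle)
        for o in oracle:
            assert any(jaccard((a.start, a.end), o) >= 0.9 for a in anns)


# ---------------------------------------------------------------------------
# library masking
# ---------------------------------------------------------------------------

class TestLibraryMasking:
    def test_genome_identical_to_consensus(self, rng):
        cons = random_dna(400, 0.5, rng)
        lib = RepeatLibrary([LibraryEntry("f1", "LINE", cons)])
        hits = mask_with_library(cons, lib)
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end) == (0, 400)
        assert hits[0].identity == 1.0
        assert hits[0].repeat_class == "LINE"

    def test_empty_library_gives_no_hits(self, rng):
        assert mask_with_library(random_dna(1000, 0.5, rng), RepeatLibrary([])) == []

    def test_diverged_copy_recovered_with_high_coverage(self, rng):
        cons = random_dna(800, 0.5, rng)
        copy = _mutate(cons, 0.05, rng)
        flank = random_dna(2000, 0.36, rng)
        seq = flank + copy + flank
        truth = (2000, 2800)
        lib = RepeatLibrary([LibraryEntry("f1", "LINE", cons)])
        hits = mask_with_library(seq, lib, min_identity=0.8)
        covered = sum(
            max(0, min(h.end, truth[1]) - max(h.start, truth[0])) for h in hits
        )
        assert covered / 800 >= 0.9

    def test_reverse_complement_copy_recovered(self, rng):
        cons = random_dna(600, 0.5, rng)
        flank = random_dna(1500, 0.36, rng)
        seq = flank + revcomp(_mutate(cons, 0.03, rng)) + flank
        lib = RepeatLibrary([LibraryEntry("f1", "DNA", cons)])
        hits = mask_with_library(seq, lib, min_identity=0.8)
        truth = (1500, 2100)
        covered = sum(
            max(0, min(h.end, truth[1]) - max(h.start, truth[0])) for h in hits
        )
        assert covered / 600 >= 0.9
        assert any(h.strand == "-" for h in hits)

    def test_lower_identity_threshold_never_loses_hits(self, rng):
        cons = random_dna(500, 0.5, rng)
        seq = (
            random_dna(800, 0.36, rng)
            + _mutate(cons, 0.1, rng)
            + random_dna(800, 0.36, rng)
        )
        lib = RepeatLibrary([LibraryEntry("f1", "LINE", cons)])
        n_strict = len(mask_with_library(seq, lib, min_identity=0.9))
        n_loose = len(mask_with_library(seq, lib, min_identity=0.7))
        assert n_loose >= n_strict

    def test_word_size_bounds(self, rng):
        lib = RepeatLibrary([LibraryEntry("f1", "LINE", "ACGT" * 50)])
        with pytest.raises(ValueError):
            mask_with_library("ACGT" * 100, lib, word_size=6)
        with pytest.raises(ValueError):
            mask_with_library("ACGT" * 100, lib, min_hit_len=4, word_size=8)


# ---------------------------------------------------------------------------
# structural LTR detection
# ---------------------------------------------------------------------------

class TestLTRDetector:
    def test_planted_elements_recovered(self):
        cfg = SimulationConfig(
            genome_length=150_000, n_ltr=20, n_tandem=0, n_line=0, n_dna=0,
            ltr_age_distribution=[1e6], seed=5,
        )
        genome, truth, _ = simulate_genome(cfg)
        found = find_ltr_candidates(genome)
        matched = 0
        for el in truth:
            for c in found:
                if (
                    jaccard(c.ltr5, el.ltr5_interval) >= 0.8
                    and jaccard(c.ltr3, el.ltr3_interval) >= 0.8
                ):
                    matched += 1
                    break
        assert matched / len(truth) >= 0.9

    def test_age_zero_pair_identity_is_one(self):
        cfg = SimulationConfig(
            genome_length=60_000, n_ltr=3, n_tandem=0, n_line=0, n_dna=0,
            ltr_age_distribution=[0.0], seed=6,
        )
        genome, _, _ = simulate_genome(cfg)
        found = find_ltr_candidates(genome)
        assert found
        for c in found:
            assert c.pair_identity == 1.0
            assert c.motif_ok and c.has_tsd

    def test_shuffled_genome_has_no_structural_candidates(self):
        cfg = SimulationConfig(
            genome_length=100_000, n_ltr=10, n_tandem=0, n_line=0, n_dna=0,
            ltr_age_distribution=[1e6], seed=8,
        )
        genome, _, _ = simulate_genome(cfg)
        arr = np.frombuffer(genome.residues.encode(), dtype=np.uint8)
        total = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            shuffled = arr[rng.permutation(arr.size)].tobytes().decode()
            cands = find_ltr_candidates(shuffled)
            total += sum(1 for c in cands if c.motif_ok and c.has_tsd)
        assert total == 0

    def test_separation_bounds_validated(self):
        with pytest.raises(ValueError):
            find_ltr_candidates("ACGT" * 1000, min_ltr=50)
        with pytest.raises(ValueError):
            find_ltr_candidates("ACGT" * 1000, min_sep=5000, max_sep=1000)

    def test_reported_identity_respects_threshold(self):
        cfg = SimulationConfig(
            genome_length=100_000, n_ltr=10, n_tandem=0, n_line=0, n_dna=0,
            ltr_age_distribution=[3e6], seed=9,
        )
        genome, _, _ = simulate_genome(cfg)
        for c in find_ltr_candidates(genome, min_identity=0.85):
            assert c.pair_identity >= 0.85


# ---------------------------------------------------------------------------
# overlap resolution and proportions
# ---------------------------------------------------------------------------

def _brute_force_resolution(annotations, priority):
    """Base-wise oracle: claim every base for the top-priority annotation."""
    rank = {cls: i for i, cls in enumerate(priority)}
    span = max(a.end for a in annotations)
    owner = [None] * span
    order = sorted(
        range(len(annotations)),
        key=lambda i: (rank[annotations[i].repeat_class], -annotations[i].score,
                       annotations[i].start),
    )
    for i in order:
        for pos in range(annotations[i].start, annotations[i].end):
            if owner[pos] is None:
                owner[pos] = annotations[i].repeat_class
    return owner


class TestOverlapResolution:
    def test_priority_wins_on_identical_intervals(self):
        anns = [
            RepeatAnnotation("s", 10, 20, "tandem", 1.0, 5.0),
            RepeatAnnotation("s", 10, 20, "LTR", 1.0, 5.0),
        ]
        out = resolve_overlaps(anns)
        assert len(out) == 1
        assert out[0].repeat_class == "LTR"

    def test_disjoint_intervals_unchanged(self):
        anns = [
            RepeatAnnotation("s", 0, 10, "LINE", 1.0, 1.0),
            RepeatAnnotation("s", 20, 30, "DNA", 1.0, 1.0),
        ]
        out = resolve_overlaps(anns)
        assert [(a.start, a.end, a.repeat_class) for a in out] == [
            (0, 10, "LINE"), (20, 30, "DNA"),
        ]

    def test_nested_tandem_truncated_matches_base_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            anns = []
            for _k in range(rng.integers(2, 7)):
                s = int(rng.integers(0, 80))
                e = s + int(rng.integers(1, 40))
                cls = ["LTR", "LINE", "DNA", "tandem"][rng.integers(0, 4)]
                anns.append(
                    RepeatAnnotation("s", s, e, cls, 1.0, float(rng.integers(1, 10)))
                )
            out = resolve_overlaps(anns)
            oracle = _brute_force_resolution(anns, DEFAULT_PRIORITY)
            span = max(a.end for a in anns)
            resolved = [None] * span
            for a in out:
                for pos in range(a.start, a.end):
                    assert resolved[pos] is None, "output overlaps"
                    resolved[pos] = a.repeat_class
            assert resolved == oracle

    def test_conservation_of_bases(self):
        rng = np.random.default_rng(13)
        anns = [
            RepeatAnnotation(
                "s", int(s := rng.integers(0, 500)), int(s + rng.integers(1, 100)),
                "LTR" if i % 2 else "tandem", 1.0, float(i),
            )
            for i in range(10)
        ]
        out = resolve_overlaps(anns)
        genome_length = 700
        assigned = sum(a.length for a in out)
        props = compute_class_proportions(out, genome_length)
        assert props.total == pytest.approx(assigned / genome_length)


class TestClassProportions:
    def test_single_interval_fraction(self):
        anns = [RepeatAnnotation("s", 0, 210_000, "LTR", 1.0, 1.0)]
        props = compute_class_proportions(anns, 1_000_000)
        assert props.fractions["LTR"] == pytest.approx(0.21)
        assert props.percent("LTR") == pytest.approx(21.0)

    def test_empty_annotations(self):
        props = compute_class_proportions([], 1000)
        assert props.total == 0.0

    def test_overlap_raises_contract_error(self):
        anns = [
            RepeatAnnotation("s", 0, 10, "LTR", 1.0, 1.0),
            RepeatAnnotation("s", 5, 15, "DNA", 1.0, 1.0),
        ]
        with pytest.raises(ValueError, match="overlap"):
            compute_class_proportions(anns, 100)

    def test_truth_proportions_match_planted_fractions(self, standard_fixture):
        cfg, genome, truth, _ = standard_fixture
        anns = [
            RepeatAnnotation("s", el.true_interval[0], el.true_interval[1],
                             el.element_class, 1.0, 1.0)
            for el in truth
        ]
        props = compute_class_proportions(anns, genome.length)
        for cls in ("LTR", "tandem", "LINE", "DNA"):
            planted = sum(
                el.true_interval[1] - el.true_interval[0]
                for el in truth if el.element_class == cls
            )
            assert props.fractions[cls] == pytest.approx(planted / genome.length)


@given(st.integers(min_value=1, max_value=50), st.integers(min_value=1, max_value=50))
def test_annotation_interval_validation(start, length):
    a = RepeatAnnotation("s", start, start + length, "LTR", 0.9, 1.0)
    assert a.length == length
    with pytest.raises(ValueError):
        RepeatAnnotation("s", start, start, "LTR", 0.9, 1.0)
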
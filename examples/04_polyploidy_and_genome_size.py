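"""Polyploidization fold and genome-size fold worked values.

PF = 2^m x 3^n counts cumulative genome multiplication from m whole-genome
duplications and n triplications since the angiosperm ancestor; GF scales
an assembly by the ancestral haploid genome size (1.73 pg x 978 Mb/pg).
"""

from gsevol import ancestral_size_mb, genome_size_fold, polyploidization_fold

anc = ancestral_size_mb(1.73, 978)
print(f"ancestral angiosperm genome: 1.73 pg x 978 Mb/pg = {anc:.2f} Mb")

# Utricularia gibba: three WGDs plus one WGT despite its ~100 Mb genome
print(f"PF(m=3, n=1) = {polyploidization_fold(3, 1)}  (highest fold in the panel)")
print(f"PF(m=0, n=0) = {polyploidization_fold(0, 0)}  (Amborella-like baseline)")

for size in (100.0, 3027.0):
    print(f"GF of a {size:7.1f} Mb assembly = {genome_size_fold(size, anc):.5f}")
ratio = genome_size_fold(3027.0, anc) / genome_size_fold(100.0, anc)
print(f"size range across those extremes: {ratio:.1f}-fold (~30)")
# Note the contrast: the smallest genome carries the largest polyploidy
# fold -- repeated polyploidization does not imply a large genome.
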
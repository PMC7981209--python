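# Methods

This note documents the models and procedures implemented in `gsevol`,
their assumptions, the parameters that matter, and the design choices made
where more than one reasonable option existed.

## Scope and shape

`gsevol` is a library first: the public API plus the narrative scripts in
`examples/` are the primary interface, and the `gsevol` CLI is a thin
wrapper for file-based runs of the same functions. The pipeline
(`gsevol.pipeline`) chains five stages — simulate, annotate, date, metrics,
correlate — through plain files (FASTA, GFF3, TSV, Newick) so any stage can
be replaced by an external tool's output with the same schema.

## Synthetic genomes with known truth

The simulator exists so that every downstream stage has an exact oracle.

**Background.** Sequence is i.i.d. over {A,C,G,T} at a configurable GC
content (default 0.36, typical of plant genomes). No higher-order
composition, isochores or N runs are modelled; the background's only job is
to provide realistic *k*-mer noise for detector specificity.

**LTR elements.** A fresh element is `TSD + 5'LTR + internal + 3'LTR +
TSD` with byte-identical LTR copies, TG…CA termini on each copy, and an
identical 4–6 bp target-site duplication on both flanks — the structure a
retrotransposon leaves at insertion. Aging applies an exact Jukes–Cantor
process: each site substitutes with probability
p_site = ¾(1 − e^(−4/3·r·t)), independently in both copies, so the
pairwise divergence between copies follows a JC process over 2t and the
JC-corrected distance has expectation exactly 2·r·t. This matches the
correction used in dating, which makes clock-recovery tests exact in
expectation. Indels are not simulated: the dating method uses
substitutions only, and gapped columns are excluded from divergence anyway.
The whole element (including internal region and TSD copies) mutates; only
LTR–LTR divergence is used for dating, so the expectation is unaffected,
and the TSD's survival probability decays with age exactly as in real
elements.

**Other classes.** Tandem arrays are exact motif repetitions (period 2–10,
20–40 copies by default). LINE and DNA decoys are copies of random
consensus "families" mutated at 5% divergence and planted on either
strand; the family consensi form the repeat library the masker is given.
When simulating a species panel, one shared library is generated and
passed to every genome so that a single library masks the whole panel.

**Placement.** Elements are placed without overlap with ≥10 bp margins by
splitting the free space into random gaps (stars-and-bars), which succeeds
deterministically even at high occupancy; element order along the genome
is randomised. Truth is written as GFF3 with `element_class`, `age_years`
and `ltr_length` attributes.

**Phylogenies and trait panels.** Yule (pure-birth) trees are simulated
with exponential waiting times; after the n-th tip appears, all pending
branches are extended by the waiting time to the next (uncommitted)
speciation, so every terminal branch is strictly positive. Trait panels
draw a predictor x ~ Uniform(0, 100) per tip (the scale of a repeat
percentage) and set y = intercept + slope·x + ε with
ε ~ MVN(0, σ²V), V the Brownian-motion covariance of the tree.

**Determinism.** All randomness flows through one
`numpy.random.Generator` (PCG64) seeded from the config; identical
(config, seed) reproduce byte-identical FASTA and truth files. This is a
tested contract.

What passing on these data does *not* show: robustness to nested or
truncated insertions, solo LTRs, indel-rich divergence, assembly gaps or
ambiguity codes. The detectors' parameters are exposed precisely so they
can be re-tuned on real genomes.

## Repeat annotation

**Tandem finder.** For each period p, the boolean match vector
m[i] = (s[i] = s[i+p]) is scanned; runs of ≥ p consecutive matches (one
exact adjacent copy) seed candidates, adjacent runs are merged greedily
while mean adjacent-copy identity stays above the threshold, and boundary
runs shorter than p are trimmed so intervals do not leak into flanking
chance matches. Defaults: period 1–250, ≥10 copies, identity ≥0.9. A
cumulative-sum seed test skips periods with no seed in O(L). Arrays
detected at a multiple of their true period are removed by preferring the
smallest period among equal-scoring overlapping calls.

**Library masker.** Exact shared words (default 12-mers) between genome
and consensus (both strands) are grouped per diagonal, chained, and
extended without gaps under an X-drop rule (match +1, mismatch −3, drop
12); hits shorter than 50 bp or below 80% identity are discarded, and
overlapping hits of the same family are unioned (internally repetitive
consensi seed several diagonals over one copy). Extension is independent
of the identity threshold, so lowering the threshold can only add hits — a
tested monotonicity property.

**Structural LTR detector.** Exact shared 12-mers whose separation lies in
[1, 15] kb anchor a candidate pair; anchors at the same separation within
200 bp of each other are clustered (dense within a real LTR, far sparser
between distinct elements) and extended by comparing s[i] with s[i+d]
under X-drop. Boundaries are refined to TG…CA termini found in *both*
copies within a ±12 bp window; a 4–6 bp identical flanking repeat is
recorded as the TSD. Missing motif or TSD lowers the score but does not
reject — real elements lose their termini to substitution with age.
Candidates below 80% pair identity or outside 100–3500 bp copy length are
dropped; overlapping candidates are resolved by score. Words occurring
more than 100 times are skipped to avoid quadratic anchor blowup on
low-complexity sequence.

**Overlap resolution.** Every base is assigned to at most one class, in
priority order LTR > LINE > SINE > DNA > tandem > unknown (higher score,
then leftmost start break ties). LTR-first reflects that LTR content is
the analysis' headline factor; the order is configurable. The LTR class
counts the full element span (both LTRs plus internal region), as masking
tools report it. Proportions are assigned-bases / genome-length;
assignment conservation (classes + unassigned = genome) is a tested
invariant against a base-wise brute-force oracle.

## LTR insertion-time dating

The 5′ and 3′ copies are aligned globally with affine gap penalties
(Biopython's `PairwiseAligner`; match +2, mismatch −3, gap open −10,
extend −4). Two numerical choices matter and were made after measuring
their effect on simulated data:

- **Gap stiffness.** With cheap gaps (open −5, extend −2) the optimal
  global alignment of indel-free but diverged copies absorbs mismatch
  clusters into compensating gaps, deflating p and biasing ages low by
  ~1% at 4 Myr. The stiffer defaults suppress these spurious gaps; gapped
  columns are excluded from p in any case.
- **Terminal trim.** The detector fixes candidate boundaries on TG/CA
  motifs present in both copies and on match-rich extension endpoints, so
  the outermost aligned columns are conditioned on being identical; dating
  them biases divergence low. `DatingParams.terminal_trim` (default 2 bp)
  drops each copy's conditioned termini before alignment. With both
  choices, end-to-end recovery (simulate → detect → align → date) is
  unbiased within 3 Monte-Carlo SE at ages 0.5–4 Myr for 500 bp LTRs.

Divergence models: raw p, JC69 (default — it matches the simulator's
mutation process), and K2P. Saturated pairs (JC: p ≥ ¾; K2P: non-positive
log argument) are flagged undatable, excluded from species means and
counted; the species mean insertion time is the unweighted arithmetic mean
over datable elements, in Myr, and is NaN (propagated, never zero) when no
element is datable. The clock is T = K/(2r) with r = 1.3 × 10⁻⁸
substitutions/site/year; the 2r convention assumes divergence accrues on
both copies, which is how the simulator ages them. Dating is invariant to
which copy is labelled 5′.

## Species factors

Genome size is total assembly length (an `exclude_n` flag discounts N
runs). Genome-size fold divides by the ancestral angiosperm haploid genome,
1.73 pg × 978 Mb/pg = 1691.94 Mb. Polyploidization fold is PF = 2^m·3^n
from user-supplied counts of whole-genome duplications and triplications
since the angiosperm ancestor; shared ancient polyploidies are excluded by
convention (the baseline species has PF = 1), and this module never infers
WGDs from sequence. PF is exactly multiplicative in event counts, and
fold-range is invariant to the ancestral scaling — both tested.

## Comparative regression

Trees are handled with dendropy; pruning uses induced-subtree extraction,
which sums branch lengths through suppressed unary nodes so root-to-tip
path lengths are preserved (tested against a path-length oracle). The BM
covariance sets V[i,j] to the shared root-to-MRCA path length; the root's
own edge is ignored.

OLS and PGLS are fit via statsmodels (OLS / GLS with fixed Σ = V): β̂ =
(XᵀV⁻¹X)⁻¹XᵀV⁻¹y, σ̂² = rᵀV⁻¹r/df, classical t inference. No REML, no
Pagel's λ — V is the plain Brownian expectation. PGLS reports a
pseudo-R² = 1 − (rᵀV⁻¹r)/(y_cᵀV⁻¹y_c) with y centred at the V-weighted
mean, labelled as such to avoid implying the OLS quantity. Tested
contracts: PGLS equals OLS exactly (1e-10) when V = I or on equal-depth
star trees; rescaling V changes only σ̂²; coefficients match an
independently coded whitened-OLS oracle; type-I error is calibrated at 5%
for both fits under their own generating assumptions.

The suite regresses genome-size fold (response) on each factor
(predictor): tandem/LTR/LINE/SINE/DNA percentages (0–100 scale), PF, and
mean insertion time, each by OLS and by PGLS on the tree pruned to the
analysed species; species missing a factor are dropped pairwise, and
factors with no variation are skipped with a log entry. The multiple
regression models LTR percentage on species age and mean insertion time;
"age" is the terminal branch length (time since the species' last
divergence) — on ultrametric trees root-to-tip depth is constant and
carries no information. Tip labels are matched after
whitespace/underscore normalisation. Significance is reported at p < .05.

## Problem sizes used in tests

The test suite and acceptance checks run entirely on synthetic data sized
for a laptop: the standard annotation fixture is a 300 kb genome with 20
LTR elements (0.5–3 Myr), 10 tandem arrays and 10 decoys; clock-recovery
uses 200 elements per age in 450 kb genomes at ages 0.5/1/2/4 Myr; PGLS
calibration uses 500 replicate panels on a fixed 100-tip Yule tree; OLS
calibration uses 10⁴ null replicates at n = 20. These sizes give
Monte-Carlo standard errors small enough for the stated 2–3 SE assertions
while keeping the whole suite under a minute of simulation-heavy work.

## Known limitations

- Detector parameters are tuned for the simulator's clean insertions;
  real genomes (nested TEs, solo LTRs, segmental duplications, assembly
  artefacts) will need threshold adjustment and will not reach the
  synthetic sensitivity figures.
- No de novo repeat-family discovery: the masker requires a user-supplied
  classified library.
- The clock uses a single genome-wide substitution rate; per-family rate
  variation is out of scope.
- PGLS assumes plain Brownian motion; no λ/OU transformations, no
  measurement-error model, no phylogenetic signal statistics.
- PF counts only user-curated, post-ancestral polyploidy events; nothing
  is inferred from synteny or Ks distributions.
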
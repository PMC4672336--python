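# Methods

## The motif model

The query is a pair of 4-mer cores separated by a bounded spacer:
`GGAAN{s}GGAA` with `spacer_min ≤ s ≤ spacer_max` (defaults 0 and 10). With
F = GGAA and R = TTCC (its reverse complement), the orientation of the two
cores on the sense strand defines the pair type: FF, FR, RF or RR.

**Faithful mode (default).** Searching the two literal strings
`GGAAN{0,10}GGAA` and `GGAAN{0,10}TTCC` on both strands is exactly
equivalent, in sense-strand view, to pair types {FF, FR, RR}: an antisense
FF hit reads RR on the sense strand, and FR is its own reverse complement.
The RF arrangement (TTCC…GGAA) is matched by *neither* string on *either*
strand, so faithful mode excludes it. Because biologists often intend "two
cores in any orientation", `MotifPattern.all_pairs()` adds RF explicitly;
this is an extension, not the default.

**Deduplication.** A hit visible from both strands over one span (FR, and RF
in all-pairs mode) is reported once, with `strand_set` recording both
strands. The presence statistic counts sequences, not strand-hits, so this
choice cannot change any presence percentage; it only keeps match totals
honest. Overlapping and nested matches are all reported (no greedy
consumption): `GGAAGGAAGGAA` yields spans [0,8), [4,12) and [0,12). N never
matches a core position but may sit in a spacer. A palindromic core (F = R)
degenerates all pair types to one; matches are then reported once as FF on
both strands.

**Coordinates.** Internal coordinates are 0-based half-open everywhere.
TSS-relative labels are presentation-only: 1-based and zero-skipping
(−1 abuts +1), the convention of the promoter literature. A window spans
`upstream_extent` (default 500) bases before the +1 base and
`downstream_extent` (default 100) bases from it onward — the +1 base is
included in the downstream segment, giving the 600 bp total that the
equal-length random controls assume. Windows overrunning a contig edge are
an error; there is no silent clipping. Windows with > 50% N are scanned but
flagged in the log.

## Null models

**Humanized random DNA** defaults to an order-0 (i.i.d.) model with
A=T=0.295, C=G=0.205 (human genome GC ≈ 41%). The generator of the original
web-service control sets is not documented anywhere we can verify, so the
GC-matched i.i.d. model is the minimal defensible reading; an order-1 Markov
model (fitted with add-one smoothing, N excluded, requiring ≥ 100·4^order
informative bases) is available and preferred when the user supplies real
training sequence. Random-gene controls are sampled uniformly *without*
replacement — "randomly selected genes" implies distinct genes. The
dinucleotide shuffle draws a uniform Eulerian-path rearrangement
(arborescence method with rejection for connectivity), preserving exact
dinucleotide counts and both endpoints; N is a fifth symbol.

All generators are pure functions of (parameters, seed); seeds are surfaced
in output headers and run configs.

## Background presence probability

Two calculators predict P(≥ 1 match) in an i.i.d. sequence of length L:

- **Poisson closed form**: λ = Σ over pair types, spacers s and the
  L−8−s+1 admissible starts of p(core₁)·p(core₂), and P ≈ 1 − e^(−λ).
  This ignores the positive association of matches sharing a core, so it
  *overestimates* presence — by ≈ 1.1 percentage points at GC 0.41 and
  L = 600 (λ ≈ 0.26). It is kept for its interpretability and hand
  verifiability.
- **Exact automaton**: presence is a regular language, so P(≥ 1 match) is
  the absorption probability of the pattern-union DFA (lazy subset
  construction over (pattern, position) items; ~300 states for the default
  pattern) run over the i.i.d. base process. This is exact to floating
  point and costs ~0.5 s at L = 600; results are cached per (model, length,
  pattern).

At GC 0.41 and L = 600 the exact value is 0.2160; simulation agrees within
binomial error. Wherever a single number is needed (calibrating synthetic
scenarios, acceptance checks) the exact value is used; the Poisson form is
tested against it at its honest accuracy (< 2 pp for λ ≤ 0.5). Both
calculators require order 0 and direct order-1 users to Monte Carlo.

## Enrichment statistics

Presence proportions get 95% **Wilson** intervals (small sets of 58–60
sequences with proportions near the boundary make Wald intervals
untrustworthy); interval endpoints are clamped so they always contain the
point estimate and degenerate exactly at 0/n and n/n. Percentages are
rounded half-up to one decimal (30/58 → 51.7), and rendered cells suppress a
trailing ".0" (81, 25) while JSON keeps the numeric value (81.0).

The two-sided **Fisher exact test** sums hypergeometric probabilities of all
tables with the observed margins whose probability is ≤ the observed
table's (minimum-likelihood convention, relative tie tolerance 1e-12). The
enumeration uses exact integer weights `C(r1,a')·C(r2,m−a')` via
`math.comb`, so ties are decided exactly; scipy's implementation serves only
as an independent oracle in the test suite. A set of size zero is an error;
a zero *column* margin (no presence anywhere) is the degenerate single-table
case with p = 1, so comparing two all-negative sets is legal. Odds ratios
use the sample estimate with the Haldane–Anscombe 0.5 correction when any
cell is zero. No multiple-testing correction is applied: this is a
single-pattern analysis with at most a handful of pairwise set comparisons,
and the comparisons are reported jointly, not selected.

## Synthetic data

`generate_planted_set` draws each sequence from the background model and,
with probability `plant_rate`, overwrites one uniformly placed core pair
(spacer length from `spacer_weights`, orientation from `pair_type_weights`
over FF/FR/RR). Planting overwrites rather than inserts, keeping the 600 bp
window length invariant; the spacer interior keeps its background bases,
since the motif constrains only the cores. Exactly one motif is planted per
selected sequence, but spontaneous background duplications are not
suppressed — as in real promoters, the tabulated statistic is presence, not
match count. Ground truth (span, spacer, pair type per sequence) is emitted
alongside, and planted motifs are by construction always recoverable
exactly, which the tests assert as an equality, not a rate.

`make_table1_scenario` emulates the three-column study design — an ISG-like
set (n = 58), a random-gene-like set (n = 58) and a pure background set
(n = 60) — with default expected presence rates (0.81, 0.52, background).
Plant rates are derived by inverting expected presence = r + (1 − r)·P_bg
against the exact background probability (r ≈ 0.758 and 0.388 at GC 0.41).
What the synthetic sets do **not** emulate: real ISG promoter composition,
ISRE elements, TFBS co-occurrence, or any gene-level identity — passing
tests demonstrate the pipeline's correctness and statistical power under
the stated generative model, not biological fidelity of any particular
promoter list.

## Problem sizes

Defaults used by the test suite and acceptance script, chosen to give
statistically decisive checks at interactive runtimes: background-rate
simulation n = 10,000 sequences (binomial SE ≈ 0.4 pp); exact-vs-Monte-Carlo
checks n = 20,000 per GC value across GC ∈ {0.3, 0.41, 0.5, 0.6}; planted
recovery n = 10,000; scenario calibration 200 seeded scenarios (joint SE
≈ 0.4 pp per column); Fisher oracle sweep over all 2×2 tables with row
margins ≤ 30 (245,025 tables) against a vectorized hypergeometric
enumeration, plus scipy's `fisher_exact` on all tables with margins ≤ 12.

## Known limitations

- Cores are fixed 4-mers; degenerate IUPAC cores, PWMs and gapped models are
  out of scope.
- The exact presence calculator covers order-0 backgrounds only; order-1
  backgrounds need Monte Carlo.
- The humanized default is genome-wide composition; promoter-proximal
  sequence is GC- and CpG-richer, so users comparing against real promoters
  should fit the background from their own pool (`fit_composition`).
- The uniform-Eulerian shuffle is exact but rejection-sampled; pathological
  synthetic sequences with many forced edges may need several attempts
  (never an issue for genomic DNA).
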
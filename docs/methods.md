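# Methods

This note documents the models behind `plantid`, the defaults that matter,
and the limits of what the simulation-based tests demonstrate.

## Sequence panels and alignment

A panel is one marker sequence per species (uppercase A/C/G/T/N, U→T
normalised), each labelled `target` or `non_target`. Alignment is a bundled
progressive global aligner: sequences are added in input order, each aligned
to the growing profile by Needleman–Wunsch with linear gap costs
(match +1, mismatch −1, gap −2). Column scores against the profile are the
mean match/mismatch score over rows, with profile-internal gaps scoring as
mismatches. This is deliberately simple: for congeneric marker loci
(≈ 90–98 % identity, short sparse indels) a profile aligner with these costs
recovers essentially the same alignment as an external tool, and bundling
it removes any run-time dependency. A pre-computed aligned FASTA can be
supplied instead; gap columns are preserved verbatim. Coordinates are
0-based half-open everywhere, with reverse-primer sites stored by their
top-strand interval — one convention avoids off-by-one amplicon lengths.
Mapping an alignment column that holds a gap returns the next non-gap
position together with an `on_gap` flag rather than failing.

Divergence scanning slides a window (default 20 columns, stride 5 —
primer-scale) across the alignment; a species is *discriminating* in a
window iff its gapped window string differs from every other row's.

## Synthetic panel generator

`generate_synthetic_panel` emulates a nuclear ribosomal marker:
62 bp conserved 5′ flank + 238 bp variable spacer + 162 bp conserved
central gene + 238 bp variable spacer + 62 bp conserved 3′ flank
(762 bp total, the scale of a full ITS region). The conserved blocks are
fixed module constants, so "universal" primers anchored in them amplify
every synthetic species — useful as positive controls in cross-amplification
tests. Species sequences derive from one random ancestor per seed;
substitutions are drawn independently per species at the requested rate,
confined to the spacers (two independent 5 % draws give ≈ 0.905 expected
pairwise spacer identity). Two reserved positions per spacer per species
carry a planted private substitution (excluded from random mutation), so
every species is guaranteed discriminating sites at any positive
divergence; the reserved positions are interleaved across the spacer so
that different species' discriminating regions need not overlap. Zero
divergence with more than one species emits a warning: downstream design
must fail, and does.

What the generator does *not* model: indel polymorphism between species,
intragenomic ITS paralogues, base-composition bias, and chimeric or
contaminant reads. Tests passing on these fixtures therefore demonstrate
the machinery (specificity logic, search exactness, read-out round-trips),
not performance on any real taxon set.

## Oligo thermodynamics

Tm is the unified nearest-neighbour model (via Biopython's `MeltingTemp`,
DNA_NN3 parameter set) with salt correction. Default conditions are
50 mM monovalent cation, **2.5 mM Mg²⁺** (Owczarzy 2008 divalent
correction) and 0.25 µM primer in excess: the divalent term mirrors the
PCR buffer this assay class actually runs in, and under these conditions
the computed Tm of all 38 primer sequences in the bundled published panel
agrees with the reported values to within 1.7 °C (the documented tolerance
is ±3 °C). With `divalent_mM=0` the Na⁺-only entropy correction is used;
at 1 M Na⁺ both corrections vanish, which the hand-summed
nearest-neighbour ledger test exploits. The model covers perfect duplexes
of 10–40 nt only; mismatch and dangling-end thermodynamics are out of
scope — mismatches are handled combinatorially by the in-silico PCR rule.

Primer interactions use a total-complementarity score: one oligo 5′→3′
against the other 3′→5′, all ungapped offsets, +1 per Watson–Crick pair
and −1 otherwise, maximised over offsets. The flag threshold is 8
(flag ⇔ score ≥ 8), calibrated so that a published four-pair multiplex
that passed its interaction screen sits just below the line (its worst
self-alignment scores exactly 7). The self screen adds a hairpin guard:
any self-complementary stem ≥ 4 bp enclosing a loop ≥ 3 nt flags the oligo.
The score is a screening heuristic, not a free-energy model.

## Species-specific design

The specificity criterion is exact-match uniqueness: a candidate window
(or its reverse complement, for reverse primers) must occur in its own
species' sequence and in *no* other panel sequence. Defaults: 18–27 nt,
Tm 60–73 °C, self-structure clean. Candidates whose 3′-terminal 4
alignment columns differ from every other species get a ranking bonus
(3′ mismatches dominate polymerase extension), but this is a preference,
not a filter. Pairing is geometric: amplicon = reverse-site end − forward-
site start, primer sites non-overlapping, sorted shortest-first (the
miniSTR preference). `design_pairs` is a convenience wrapper that thins
candidates to one per (strand, 3′ end), screens pairs against the
non-target panel in ascending length order, and keeps at most one pair per
distinct amplicon length (30 max) so whole-panel design runs in seconds;
the underlying enumeration, pairing and screening operations are
exhaustive and independently tested against brute-force oracles.

## In-silico PCR

A primer anneals at a site iff Hamming mismatches ≤ `k_max` (default 2)
*and* the 3′-terminal `m` bases (default 3) match perfectly; template `N`
counts as a mismatch. Both strands are scanned (vectorised sliding-window
comparison; equivalent to the brute-force scan by property test). Products
are all (plus-strand forward site, minus-strand reverse site) combinations
with forward start < reverse end and length ≤ 1000 bp; multiple products
on one template are all reported, since cross-amplification evidence must
stay visible. The binary rule is conservative by construction — it says
"could prime under permissive conditions", not "will yield product at a
given annealing temperature".

Degradation is memoryless random breakage: breakpoint count ~
Poisson(L/λ), positions uniform, so an internal span of length L survives
with probability ≈ exp(−L/λ) (exactly exp(−(L−1)/λ) after discretising cut
sites, a difference far below sampling error at the tested scales). λ is
the mean intact fragment length in bases. This one-parameter model is the
simplest that reproduces the characteristic behaviour of processed
material — a long marker failing while a short internal amplicon still
amplifies.

## Multiplex selection

One pair per target species, subject to: amplicon sizes within any one dye
channel ≥ `min_spacing` bp apart (default 5); all panel oligos pairwise
dimer-clean, including self-pairs; ≤ 4 primer dyes plus one reserved
ladder dye. Selection is exact backtracking (species ordered by ascending
candidate count, candidates by ascending length) with a lower-bound prune,
minimising total amplicon length with lexicographic tie-breaks — verified
equal to exhaustive enumeration on every instance small enough to
enumerate. Spacing feasibility across channels uses the unit-interval-graph
fact that the needed channel count equals the maximum number of sizes in
any open window of `min_spacing`. Dye assignment is first-fit in ascending
size order (deterministic); single-channel FAM-only operation is the
default. Per-pair concentrations are data, not inference: the package
stores user weights (a published optimised mix ships in
`plantid.datasets.HYPERICUM_PRIMER_MIX_NM`) and the simulator consumes
them as relative efficiencies.

## CE simulation and calling

Yield model: product quantity = template amount × pair weight ×
exp(−L/λ) (1 when no degradation) — deterministic, so expectations are
testable in closed form. The trace renderer maps size to scan position
affinely (defaults 20 scans/bp, offset 500) and renders each product as a
Gaussian peak (σ = 0.35 bp) with height ∝ quantity; the ladder channel
carries the full size-standard fragment set (default: the canonical
16-fragment 35–500 nt set, shipped as `data/genescan500_rox.tsv`,
user-overridable). Additive baseline noise is N(0, σ) clipped at zero,
default 1 % of the maximum product signal; ladder intensity scales with
product intensity so noise cannot drown the standard. Products carry a
residual sizing dispersion `mobility_sd` (default **0.10 bp**): run-level
mobility drift is systematic and cancels through ladder-relative sizing,
and 0.10 bp makes the ±0.5 bp bin a 5σ interval, matching the typical
sub-0.1 bp precision of fragment-analysis sizing — a ±0.5 bin only works
in practice *because* sizing is this reproducible, and the default is
chosen so the simulation shares that property. Ladder fragments are
rendered at their exact sizes for the same reason.

The caller must not share the simulator's mobility constants: it detects
ladder peaks (windowed local maxima; the N tallest, required to stand
2× above any residual noise maxima, else "ladder failure"), matches them
in order to the known fragment sizes, and interpolates scan→size
piecewise-linearly between adjacent ladder points, refusing extrapolation.
(Local Southern sizing would be a drop-in refinement; linear interpolation
already sizes far inside the ±0.5 bp requirement at the simulated noise
levels.) Peak apexes are interpolated at sub-scan resolution by a
three-point parabola on the log signal — exact for a noiseless Gaussian —
falling back to the raw-signal parabola when a neighbour is zero. A
species is present iff a peak in its pair's channel lies within nominal ±
half-width (default 0.5 bp; comparison includes a 10⁻⁹ bp guard so an
exactly-on-edge peak is not lost to floating-point rounding). One peak
supports at most one species: nearest bin wins, exact ties go to
`unassigned_peaks` with a warning, and peaks matching no bin are reported
unassigned — those are the assay's adulterant signals.

## Problem sizes used in the tests

The test suite designs on 7-species × 762 bp synthetic panels (alignment
and design are session-scoped fixtures), checks search exactness against
brute-force oracles on inputs up to 2 kb, runs the full
design→simulate→call round trip over all 15 non-empty subsets of the four
targets across 20 seeds, and estimates degradation survival from 500
seeded replicates at λ = 300 for 160 bp vs 750 bp amplicons. These sizes
keep the whole suite well under a minute while leaving every statistical
assertion at ≥ 3σ separation.

## Known limitations

- Specificity is same-orientation exact-match uniqueness plus a mismatch
  threshold; no thermodynamic annealing probabilities, no genome-wide
  off-target search beyond the supplied panel.
- The dimer score is unweighted (G·C pairs count like A·T) and ungapped.
- The CE model omits stutter, pull-up between dyes, dye blobs and
  saturation; peak height is linear in product quantity.
- The degradation model treats breakage as sequence-independent.
- Proprietary binary trace files are out of scope; traces import/export as
  CSV plus JSON metadata.
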
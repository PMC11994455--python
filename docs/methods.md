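# Methods

## Scope and model

`epimap` implements the computational side of pooled T cell antigen
screening: peptide-oligo library design, count-table deconvolution,
saturation-mutagenesis footprints, and footprint-driven proteome scanning.
It starts from amino-acid sequences and oligo × sample count tables; read
trimming and alignment (producing those tables) and MHC binding prediction
(producing binder lists) are upstream tools whose outputs are consumed as
plain files.

## Library design

**Window/offset tiling.** Tiles of length `window` start at
0, `offset`, 2·`offset`, … while they fit (coordinates 0-based, half-open).
With `include_cterm` an extra tile over the final `window` residues is
appended whenever the arithmetic grid does not end at the C terminus, so the
union of tiles always covers the protein. Proteins shorter than the window
yield one full-length tile. Typical designs: 90/22 for a human peptidome,
56/28 for focused libraries.

**N-terminal concatenation.** Protein N termini are under-represented by
plain tiling, so the first 29 residues of each methionine-initiated protein
are prefixed with an aspartate spacer and concatenated in groups of three
(3 × 30 = 90 aa). Fragments are grouped sequentially in input order — the
grouping is arbitrary by design, since only the units themselves matter.
Leftover fragments (count not divisible by the group size) are emitted as a
shorter final concatenation rather than dropped; proteins shorter than 29 aa
contribute their whole sequence. Non-methionine starts are skipped with a
warning.

**de Bruijn-style sampling.** When a library budget allows only
`target_count` tiles, tiles are chosen to make k-mer coverage of the
proteome as uniform as possible: candidates are all window-length substrings;
greedily, the candidate whose k-mers have the lowest current mean coverage is
selected, ties broken uniformly at random under the seed. Defaults: k = 8.
The greedy objective is a committed design choice — it is deterministic
given the seed, saturates to exhaustive tiling when the budget allows, and
in tests never yields higher coverage variance than uniform random start
sampling (seed-averaged). No optimality claim is made.

**Saturation mutagenesis.** Every position of the epitope span expanded by
`flank` residues each side (default 2) is substituted to each of the 19
alternative amino acids inside the full context peptide, giving
19 × (epitope_len + 2·flank) mutants plus (default) two unmutated wild-type
control tiles. An 8-mer epitope with two flanks on each side gives 228
mutants; a 9-mer gives 247.

**Reverse translation.** Peptides are reverse-translated using human codons
above 10% per-amino-acid usage frequency ("non-rare"), sampled uniformly by
default (usage-weighted sampling and custom tables are supported; the
threshold is a design default, not a published table). Each peptide is
realized as `n_variants` pairwise-distinct nucleotide sequences (default 2):
sampling retries up to 100 times on collision, then falls back to a
deterministic single-codon rotation, which guarantees termination; a peptide
that admits fewer distinct sequences than requested (e.g. poly-M under a
single-codon table) is an error. 5′/3′ synthesis adaptors are concatenated
verbatim. Synthesis-vendor constraints (GC content, homopolymers,
restriction sites) are out of scope.

## Enrichment deconvolution

Fractional abundance per sample is `(count + pseudocount) / column sum`;
the pseudocount default 0.5 (a Laplace-style half count) keeps input
frequencies positive, since the publication regime leaves zero-count
handling unstated. Fold enrichment per oligo and sorted replicate is
`sorted frequency / input frequency`; it is invariant to sequencing depth.
Each sorted replicate is compared against the single input column.

Codon variants of one peptide are collapsed by the per-replicate **median**
— robust to a dropped-out synthesis variant; a published robust rank
aggregation tool can be substituted here and is deliberately not
reimplemented. Replicates are summarized by the geometric mean
`exp(mean(log FE))` (zero in any replicate gives 0).

Significance is a label permutation test: the oligo→peptide assignment is
shuffled (variant-group sizes preserved), the collapse + geomean recomputed,
and `p = (1 + #{null ≥ observed}) / (1 + n_permutations)` per peptide, with
Benjamini–Hochberg FDR. This is assumption-light plumbing, testable exactly
against rank bounds, not a negative-binomial count model.

## Footprint

`s_ij = clip(FE_mutant(i at j) / FE_WT, 0, 1)` with `FE_WT` the geometric
mean over the wild-type control peptides; WT cells are 1 by construction;
substitutions never measured stay NaN. Depleted mutants map linearly into
(0, 1) with no extra floor. The matrix is written as CSV (20 rows, fixed
alphabetical amino-acid order A,C,D,…,Y; columns labelled `pos:wt`; NaN
written literally) with a JSON sidecar carrying the context sequence and
positions; round trips are bit-exact (`%.17g` on write, round-trip float
parsing on read).

## Scanning

Per-position information uses the printed form

    q_j = (−s_WT,j + Σ_i (1 − s_ij)) / (20 − 1)

evaluated with s_WT,j = 1; with missing cells the denominator is
renormalized to the number of measured substitutions at that position, and a
position with none is an error. Note the printed form reaches 18/19 — not
1 — when every substitution abolishes activation, and −1/19 when none does;
it differs by 1/19 from the plain "average decrease"
`mean(1 − s_ij over substitutions)`. Both are implemented
(`variant="printed"` default, `variant="mean_decrease"`); the default
follows the formula as printed, without guessing at intent. The two differ
by a constant shift, so intervals and rankings are nearly always identical.

The epitope interval is the half-open range *spanning* all positions with
q_j ≥ 0.5·max(q) (qualifying positions need not be contiguous);
max(q) ≤ 0 means no epitope was detected. Position weights are
p_j = q_j / max(q) inside the interval and 0 outside; an interior
non-qualifying position can have q_j < 0, and its weight is clipped to 0 so
that p ∈ [0, 1] always holds.

A query k-mer x is scored `S(x) = Σ_j p_j · a_{x_j} · s_{x_j,j}` over a
contiguous block of footprint positions — by default exactly the epitope
interval (so a 9-aa interval produces a 9-mer scan), with wider windows
anchored at the interval start and clipped to fit. Residue weights a_i are
uniform 1 by default. NaN cells contribute 0. The percent score is
100·S/S_max with S_max = Σ_j p_j · max(a) — the score of any sequence
matching wild type at every interval position — so the wild-type epitope
scores exactly 100% and no k-mer can exceed it. Every k-mer of every
protein (increment 1) is scored; proteins shorter than the window, or
containing non-canonical residues (X, B, Z, U, *…), are dropped with a
warning, since the matrix has rows only for the 20 canonical residues.
Results are sorted by descending percent with deterministic tie-breaks
(k-mer lexicographic, then protein id, then offset) and carry dense 1-based
ranks on the percent score; duplicate k-mers are reported once per locus
unless `unique=True` collapses them to the first occurrence. The vectorized
scan is property-tested to be bit-identical to a naive per-k-mer loop.
Binder filtering keeps k-mers present in a precomputed list (e.g. predicted
MHC binders) and recomputes dense ranks.

## Synthetic data

The generator emulates the sampling structure of a sorted pooled screen:

* library composition ~ Dirichlet with concentration 50 per oligo
  (coefficient of variation ≈ 14%, a realistic synthesis/cloning skew);
* the input sample is one multinomial draw of the configured depth over
  those frequencies — multinomial rather than Poisson so column sums equal
  the depth exactly;
* each sorted replicate is an independent multinomial over frequencies
  proportional to `input frequency × activation`, with activation
  `baseline + weight`; baseline 1.0 centers null fold enrichment on 1;
* the default planted cognate weight is 100, comparable to the strongest
  screen enrichments; mutant tiles of a known footprint get
  `1 + 100·s_true`, so rebuilding the footprint from the simulated screen
  estimates `(1 + 100·s) / 101` — a bias below 0.01, well inside the 0.05
  recovery tolerance used in tests.

Default study conditions: sequencing depth 10⁶, three sorted replicates,
two codon variants per peptide, mutagenesis libraries of ≈ 500 oligos and
null libraries of up to 5,000 peptides. The generator does not model
sorting-gate stringency, growth between enrichment rounds, PCR jackpotting,
or replicate-level overdispersion beyond multinomial noise — so passing
recovery tests demonstrate correctness of the estimators under the stated
sampling model, not robustness to every artefact of real screens. Toy
proteomes are i.i.d.-uniform over the 20 amino acids with k-mers planted at
recorded, non-overlapping loci; real proteomes are not uniform, so scan
score *backgrounds* on real data will differ even though scores themselves
are deterministic lookups.

## Numerical and interface choices

* Coordinates 0-based half-open everywhere; matrix rows fixed alphabetical.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; repeated CLI runs are byte-identical.
* Dense ranking ties are decided on exact float equality of percent scores;
  the deterministic sort order makes output files bit-stable.
* Ambiguous-residue policy for proteomes is `drop` (with warning) or
  `error`; dropping is the default because scanning cannot score residues
  without matrix rows.
* Double-amino-acid substitutions, MHC binding prediction, read alignment
  and count-model significance (beyond the permutation test) are out of
  scope.
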
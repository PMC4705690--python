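# Methods

## The screening model

The screen identifies genes likely repressed by p53 through the
p53–p21–DREAM–CDE/CHR axis. It assumes repression is indirect: p53 does not
bind these promoters itself, so the evidence is (a) reproducible
downregulation upon p53 activation, (b) physical DREAM occupancy, and (c) a
conserved CHR element that can recruit DREAM's MuvB core. Each criterion is
binary per gene and the candidate list is their conjunction — a deliberately
stringent AND that favors specificity over sensitivity (a known consequence:
genuine targets detected with only two DREAM components are missed unless
manually curated back in, which the curation mechanism supports with
recorded provenance).

### Expression Score

Up to six independent p53-perturbation expression studies each contribute a
per-gene direction call in {−1, 0, +1}. The score is the plain sum, an
integer in [−6, +6] encoding direction and reproducibility at once;
`score ≤ −3` (inclusive) calls repression. A gene absent from a study
contributes 0 — absence carries no directional evidence — and that rule is
this package's decision for genes missing from some platforms, flagged via
`n_studies_observed`. More than six studies are accepted with a warning
(the score range widens), keeping the machinery reusable beyond the original
six inputs. The threshold is configurable (`repression_threshold`, default
−3) for sensitivity analysis.

### DREAM binding

Per-gene boolean detections for E2F4, LIN9, LIN54 and p130; bound iff at
least `min_components` (default 3) are detected. Detections are consumed as
booleans rather than peak scores because the criterion is detection-count
based; peak calling and peak-to-TSS assignment happen upstream and arrive in
the input TSV. Missing component slots are an error, never imputed. The
threshold is exposed because it is consequential: at 3-of-4 exactly 5 of the
16 detection patterns are bound, and lowering it to 2 admits known targets
that the stricter screen misses.

### Conserved CHR element

For each annotated TSS the window `[tss − flank, tss + flank)` (flank
default 1000 bp) is clipped, in order, at chromosome edges, at the gene's
own CDS (strand-aware: the window's downstream side ends before the first
coding base in transcription direction), and at every other annotated gene
interval. The clipping-rule reading is strict: neighbors are excluded on
*both* sides of the TSS (`clip_neighbors="both"`), because a promoter window
should never scan inside another gene; a `upstream_only` switch implements
the looser reading. Every clip is recorded as an event (side, cause,
removed bp). An empty post-clipping window is a valid outcome, not an error.

Scanning is exact string matching of the ten 6-mers on the forward strand
plus their reverse complements (reported as minus-strand hits with the motif
name normalized to the canonical string; TTTAAA and TTCGAA are their own
reverse complements and appear once per strand). Lowercase (soft-masked)
sequence is uppercased before matching — conservation, not masking, is the
selectivity mechanism — and non-ACGT characters never match. A hit is
retained iff its mean per-base conservation over the 6 bp is
`≥ min_conservation` (default 0.9, inclusive). Bases missing from the track
contribute 0 to the mean and flag the hit `partially_covered`, so
unalignable regions cannot look conserved. For multi-TSS genes every TSS
window is scanned and the gene passes if any window yields a retained hit;
the reported best hit maximizes mean conservation, with ties broken by
distance to the TSS and then by coordinate, making selection deterministic.

### Integration

The gene universe is the union of ids across the three stage tables. Genes
missing from a table are counted negative for that criterion and flagged in
`missing_evidence` instead of being dropped, so the 7+1 Venn partition is
exhaustive and the marginal identities (e.g. |repressed ∩ DREAM| =
|all three| + |repressed ∩ DREAM without CHR|) hold by construction.
Percentages are rounded half-up to one decimal — the convention that
reproduces published integer pairs such as 358/870 → 41.1% and
158/210 → 75.2% — and a zero-denominator percentage is reported as
undefined, never 0. Curation entries match symbols case-insensitively,
warn (not fail) on unknown symbols, fail on include+exclude conflicts, and
leave an audit trail: records minus manual overrides equal the raw screen
output exactly. The packaged 210-gene candidate list ships as a plain-text
fixture for membership checks and reporting.

A note on published counts: the candidate list of 210 is described alongside
the manual addition of two genes, while the accompanying Venn arithmetic
(358 repressed-and-bound vs 150 of those without a conserved CHR) implies a
pre-curation screen count of 208. The package does not resolve this:
`summarize_venn` reports pre-curation partition counts and `final_list`
(post-curation) separately so both readings are visible.

## Synthetic cohorts

The generator emulates the complete input bundle: single-chromosome FASTA,
GFF3 + BED12 annotation, run-length bedGraph conservation, per-component
ChIP TSV, six-study call TSV and a cell-cycle table, plus a ground-truth
table and a manifest (spec, seed, file checksums). Defaults are chosen to
make ground truth exact rather than probabilistic:

- Background sequence is i.i.d. uniform ACGT, then every promoter window is
  rejection-cleaned of accidental occurrences of all 20 strings (10 motifs +
  reverse complements) by locally redrawing non-planted bases until clean;
  overlapping windows are merged first so a redraw cannot recontaminate an
  already-cleaned neighbor.
- Planted motifs (one per selected gene, uniform over the ten variants,
  random genomic strand, offset uniform in `motif_offset_range`, default
  ±900 bp) are placed inside the gene's *clipped* window and outside every
  other gene's window, so a planted site can neither be unreachable nor leak
  into a neighbor's ground truth. Planted bases take `conservation_high`
  (default 1.0), everything else `conservation_low` (default 0.0); a partial
  overlap with a planted site can reach at most 5/6 ≈ 0.83, below the 0.9
  filter, so spurious conserved hits are impossible in the noiseless design.
- Genes alternate strands at random, one TSS each (a `multi_tss_fraction`
  adds a second, internal TSS 200 bp into the body), CDS beginning one flank
  downstream of the TSS so default windows are CDS-clip-free, and intergenic
  spacing of 2×flank so windows are neighbor-clip-free; `crowded=True`
  shrinks spacing to flank/2 to deliberately exercise neighbor clipping.
- Criterion fractions default to 0.5 each, assigned independently, so a
  mixed cohort populates all eight Venn regions. DREAM-positive genes draw
  3–4 detected components, negatives 0–2; repressed genes draw a target
  score in [−6, −3], others in [−2, +6], realized as a random mix of ±1
  calls summing to the target. Cell-cycle annotation marks 75% of
  expected-final genes (matching the published fraction) and 20% of the
  rest, with G2/M-flavored peak phases.

Regeneration with the same spec and seed is byte-identical.

What the generator does **not** emulate: read-level ChIP or expression data
(inputs are call-level by design), realistic promoter base composition or
repeat structure, correlated errors between studies, imperfect conservation
tracks, or genes spanning multiple chromosomes. Passing the noiseless
recovery tests therefore demonstrates that the pipeline's logic — window
arithmetic, both-strand matching, threshold handling, set algebra — is
exact; it says nothing about robustness to noisy real-world calls, which is
governed by the upstream data, not this code.

## Numerical and design choices

- Coordinates are 0-based half-open throughout (BED convention); GFF3 and
  wiggle are converted on read. All thresholds are inclusive (`score ≤ −3`,
  `n ≥ 3`, `mean ≥ 0.9`) per their definitions.
- Conservation means use exact float arithmetic over at most 6 bases; the
  0.9 boundary case (five bases at 1.0, one at 0.4) is asserted in tests.
- Test problem sizes (cohorts of 100–200 genes, 100 random 2-kb windows for
  the scanner/brute-force equivalence, the exhaustive 16-pattern DREAM
  enumeration) were chosen so the whole suite runs in seconds while every
  code path — clipping causes, both strands, palindromic motifs, empty
  windows, missing evidence — is exercised.
- The command-line layer is a thin `click` wrapper; all behavior lives in
  importable functions.

## Known limitations

- The published headline counts (870 → 358 → 210) depend on external ChIP,
  expression and conservation datasets and are not recomputable here; the
  package validates the arithmetic and the logic, and ships the published
  210-gene list as a fixture rather than deriving it.
- Exact string matching only: no PWM scanning, and CDE elements are out of
  scope by design (CHR-only search covers CDE/CHR promoters).
- GFF3 parsing covers the gene/mRNA/CDS subset the screen needs, not the
  full specification.
- The symbol alias map for curation is case-folding only; richer alias
  resolution (e.g. B-MYB ↔ MYBL2) is left to the caller's symbol table.
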
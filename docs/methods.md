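# Methods

## Model and assumptions

The observed ChIP read-start signal at position i is modelled, per strand,
as a linear combination of the true antibody-driven signal and nuisance
components measured by the controls:

    t̃_i = α t_i + β b_i + γ g_i + e′_i        (ChIP)
    b̃_i = b_i + e″_i                           (Input)
    g̃_i = β′ b_i + γ′ g_i + e‴_i               (IgG)

The single modelling assumption doing the work is orthogonality: the true
signal t is uncorrelated with background b, non-specific binding g and the
noise terms. Under it, the no-intercept ordinary-least-squares estimate
n̂_i = û b̃_i + v̂ g̃_i that best predicts the observed ChIP signal also
best estimates the nuisance signal, so the regression residual
t̂_i = t̃_i − n̂_i estimates α t_i. The individual structural parameters
(α, β, γ, β′, γ′) are never identified or needed — only the reduced-form
coefficients û, v̂ are fitted. The same algebra extends unchanged to K
controls. Two consequences worth stating:

- **Depth invariance.** Rescaling any track (different sequencing depths,
  prior normalizations) only rescales coefficients: control scaling leaves
  residuals bit-for-bit unchanged up to floating-point error, ChIP scaling
  scales residuals proportionally. No depth matching is performed anywhere.
- **No intercept.** The estimator has none; a constant offset in the ChIP
  track that is absent from every control would therefore survive into the
  residuals. An opt-in `intercept` flag exists as a diagnostic, default off,
  because adding one departs from the estimator the derivation justifies.
- Coefficients are not constrained non-negative — the derivation is plain
  unconstrained OLS. Negative fitted coefficients are logged; they usually
  indicate a control uncorrelated with the ChIP background in that section.

## Processing pipeline and parameters

| parameter | default | meaning |
|---|---|---|
| `section_length` | 100 000 bp | length of independently fitted sections |
| `half_width` | 5 bp | smoothing window half-width (window = 11 bp) |
| `step` | 5 bp | centre-to-centre sampling distance |
| `fill_mode` | `step` | per-bp rebuild: nearest centre, or `linear` |
| `read_length` | `auto` | dummy-read length; `auto` = modal ChIP read length |
| `residual_threshold` | 1.0 | export only residuals strictly above this |
| `pool_strands` | off | one fit on strand-summed tracks instead of two |

Reads are reduced to 5′-terminus start counts per bp and strand (sense:
interval start; antisense: interval end − 1, BED half-open), which makes
the signal independent of read length. Each section's counts are averaged
over `2*half_width + 1` bp boxcar windows and sampled every `step` bp —
the defaults give an *overlapping* design (11 bp windows every 5 bp, 6 bp
shared by neighbours). Sense and antisense are fitted as separate
regressions with their own coefficients; the strands sample the two
fragment borders and need not share background structure. After the fit,
per-centre residuals are expanded back to per-bp values, and positions with
residual > 1 emit floor(residual) dummy reads.

## Numerical and edge-case choices

- **Sectioning.** Cores tile each chromosome half-open without overlap;
  each section is padded by `half_width` bp of real data on both sides so
  smoothing windows never straddle a section gap, and every centre belongs
  to exactly one core. Centres are anchored to the padded section origin,
  which for interior sections puts the first centre exactly at the core
  start; the method does not prescribe an absolute genome-wide phase.
- **Window edges.** Windows that do not fully fit are dropped, not
  shrunk — edge means over fewer terms would be biased; section padding
  compensates for the lost half-window at interior boundaries.
- **Rank deficiency.** The solver is rank-revealing; collinear or all-zero
  controls yield the minimum-norm solution with the rank reported in the
  per-section diagnostics table, never a crash. An all-zero control design
  passes the smoothed ChIP signal through as its own residual.
- **Degenerate sections.** A section whose smoothed ChIP observations are
  all zero is skipped (all-zero residuals, flagged `degenerate`), as is a
  section shorter than one smoothing window.
- **Rebuild tie-break.** In `step` fill mode a position equidistant from
  two centres takes the left centre's value. Positions outside the centre
  span take the terminal centre's value. Both modes reproduce centre values
  exactly at the centres.
- **Export.** Negative residuals are kept in memory (diagnostically useful)
  and suppressed only at export by the `> 1` / floor rule. Antisense dummy
  reads are anchored as `[i − read_length + 1, i + 1)` so that re-extracting
  start counts from the output reproduces the floored residual exactly
  (export → import is an exact round trip); a left edge clipped at
  coordinate 0 preserves the start position. Output is byte-deterministic:
  fixed naming (`norm_<strand>_<pos>_<k>`), score 0, sorted by chromosome
  and start, LF endings.
- **Missing control chromosomes** are a hard error: zero-filling would make
  the design rank-0 there and silently pass ChIP signal through unchanged.

## Synthetic data generator

The generator emulates sonication around point-source binding events in a
short hypothetical region. Each peak is a fixed interval whose endpoints
represent the extreme borders of sonicated fragments; a fragment draws two
distinct uniform positions in the interval (ordered), emitting a sense read
at its left border and an antisense read at its right border — one fragment
= one read pair. `single_ended` instead emits one read per fragment on a
fair-coin strand, for the reading under which stated read totals count
single reads rather than fragments. Uniform noise reads are added
independently per strand and track.

Defaults are the demonstration scenario: 2000 bp region; ChIP peaks of
interval 20 bp at positions 600 and 1400; one control peak of interval
25 bp at 600 (wider interval = more fragment-length variation in the
control); 40 ChIP and 25 control peak fragments, split equally across each
track's peaks (remainder to the first); 20 noise reads per strand per
track; 30 bp reads. The peak positions are this package's choice — any
placement with one shared and one ChIP-unique locus is equivalent.
`homogeneous_config` tiles the same local recipe across a larger genome
(default 1 Mb, 100 loci alternating shared/unique, noise at the same
per-bp rate) for section-robustness checks.

What the generator does **not** emulate: mappability and GC bias,
chromatin-accessibility structure in the background, fragment-length
distributions beyond the interval mechanism, duplicate reads, or multiple
chromosomes. Passing tests on this data show the estimator's algebraic
behaviour (separation of shared vs unique signal, depth invariance,
section robustness) — not robustness to the correlated, structured
backgrounds of real experiments.

A note on the export rule at demonstration scale: on the 2000 bp scenario
the smoothed signals are on a window-mean scale where peak residuals reach
only ≈ 1–1.5, so the `> 1` + floor export attenuates the retained unique
peak substantially even though the pre-export residual track retains most
of its raw signal; the acceptance script reports both exported-signal
fractions as measured. On deeply sequenced real data, residual amplitudes
at true peaks are far above 1 and the flooring loss is marginal.

## Fragment-size estimation

`estimate_fragment_size` pairs every sense start with the nearest antisense
start at or downstream within `max_distance` (default 1000 bp) and reports
the mean of the inclusive distances (a − s + 1, so a perfectly paired
fragment of length L contributes exactly L), plus a 10 bp-binned histogram.
The nearest-downstream rule is a deliberately simple stand-in for the local
pairing heuristics of strand-aware peak callers and is accurate only on
sparse data: when unrelated antisense starts are likely to fall inside a
fragment's span (dense pile-ups, small regions) the estimate biases short.
The parameter-recovery checks scatter 1000 fragments of length 150 bp over
10 Mb, where the expected mispairing bias is about 1 bp.

## Known limitations

- Whole-track in-memory processing per chromosome; no streaming BAM input
  (convert with `bedtools bamtobed`), no bigWig export.
- One regression per section assumes background composition is locally
  constant at the 100 kb scale; sharp background discontinuities inside a
  section are averaged over.
- `pool_strands` reports pooled output on the sense strand, discarding
  strand specificity.
- The `> 1` export threshold is calibrated to window-mean-scale residuals;
  with very shallow data the normalized signal can floor to nothing even
  where enrichment is real (see the note above).
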
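# Methods

## Read and junction model

A handle-trimmed STRT-style read is modeled as

```
[UMI: L bases][ribo window: r bases][junction G run][transcript 5' seq …]
```

Junction-window positions are numbered 1..L+r *away* from the
template-switching site: position 1 is the 3'-most ribo base, positions
1..r the ribo window, positions r+1..r+L the barcode/UMI stretch. All
positional tables and decompositions use this convention, reading the
window at fixed TSO-relative read offsets (position *i* = read offset
`L + r − i`). An alternative — anchoring positions at the matched anchor
rather than at fixed offsets — would differ for reads whose junction run is
longer than the window; we fix TSO-relative offsets because the UMI and
window geometry of the oligo is known exactly, while the junction position
varies with the unknown number of added bases.

## Switching model in the simulator

The simulator is a phenomenological forward model; per molecule:

1. **Transcript**: multinomial on relative abundances; the template-switch
   site is the transcript's configured `ts_site`.
2. **Non-templated addition**: the number of added bases *k* follows
   `addition_len_probs` (default concentrated on 2–5 with mode 3, range up
   to 8). Each added base *i* (1 = first added, at the transcript end) is
   drawn from a per-position law; by default cytidine has probability
   0.94/0.83/0.57 at positions 1–3 — the read-strand G fractions observed
   at ribo positions 1–3 in degenerate-window libraries — with the
   remainder split evenly and uniform beyond position 3.
3. **Window pairing**: ribo position *i* pairs with added base *i*. A fixed
   'G' position pairs only when the added base is C; a degenerate 'N'
   position always pairs (the 4^r pool is assumed to contain the
   complementary species, which is the one captured), and its realized
   read-strand base is the complement of the added base. Position 1 — the
   TSO's 3' terminus, which the polymerase must extend from — must pair
   strictly; every other non-pairing position is tolerated independently
   with probability `mismatch_tolerance` (default 0, consistent with
   treating capture as strict Watson–Crick complementarity of the window).
   A molecule that fails any check never switches and emits no reads.
4. **Short tails** (*k < r*): whether the unpartnered 3' window bases are
   copied anyway or loop out is biochemically unresolved, so it is a config
   switch. `fill_in` (default) treats each unpaired position as a mismatch
   (subject to the same tolerance, so with tolerance 0 short-tail molecules
   never switch) and renders the full window; `loop_out` lets short-tail
   molecules switch with a shortened window.
5. **Junction G run**: added bases beyond the window (positions r+1..k)
   contribute one junction G per added C. The truth field
   `observed_g_run` is the maximal contiguous G run of window + overhang
   ending at the junction; for a fixed rGGG window this equals
   `r + (#C in overhang)` and, when all added bases are C, simply *k*. The
   measured run in a read can exceed it when the UMI happens to end in G —
   the same upper-bound ambiguity real libraries have.
6. **Rendering**: each switched molecule emits `1 + Poisson(µ − 1)` reads
   (mean-parameterized, µ = `duplication_mean`, default 3 — a modest PCR
   duplication level), sequence `handle + UMI + window + G-overhang +
   transcript[ts_site:]` truncated (A-padded) to `read_len` (default 51,
   a typical short-read length), with i.i.d. substitution errors at
   `error_rate` (default 0.001, typical Illumina scale). Read ids embed the
   molecule id for exact truth joins. Two independent RNG streams derived
   from the seed drive molecule generation and rendering, so identical
   (config, seed) give byte-identical read sets.

What the simulator does **not** model: RNA secondary structure, strand
invasion, concatemer TSOs, quality-score profiles, fragmentation, the
guanosine enrichment real libraries show at position 4 (the DNA base
preceding the ribo window), or non-C overhang bases appearing in the read
(the rendered overhang is the G-run their C content implies). Passing
tests therefore demonstrate internal consistency of the analysis chain and
correct statistical recovery under this model, not fidelity to every
feature of real sequencing data.

## Junction analysis conventions

* **Anchor matching** is exact substring search (grep semantics); each
  read is used once, at its leftmost match that leaves a full L+r window
  upstream. A homopolymer allowance (`C{2,4}TTTCCT`-style) absorbs
  sequencing errors in anchors that begin inside a homopolymer.
* **G run**: the maximal guanosine run abutting the junction, extended
  through the anchor occurrence's own leading Gs; the histogram then
  subtracts the anchor's leading-G count so that `G(n)GGAATTCT` reports
  the n in front of the anchor. Reads with n outside [n_min, n_max]
  (default 2–8) count toward `n_matched` but are not binned; both
  `n_matched` and `n_total` are exposed because the appropriate
  denominator depends on the question.
* **Positional tables** exclude reads with an N inside the first P
  positions (counted separately) so every row sums to the read count;
  an empty table flags itself rather than propagating NaNs.
* **Major site**: the probe placed after the junction G run necessarily
  skips any leading Gs of the transcript itself, so the reported offset is
  the first non-G transcript position downstream of the switch site; ties
  break toward the 5'-most offset.
* Strand: all G-run and window quantities are read-strand (sense);
  RT-added cytidines are their complements.

## UMI model

Uniform independent labeling: n molecules drawing from K = 4^L barcodes
give `E[U] = K(1 − (1 − 1/K)^n)` distinct labels; the inverse
`n̂ = ln(1 − U/K)/ln(1 − 1/K)` estimates the molecule count and is exact on
the expectation (identity to float tolerance). Saturation is declared at
`U ≥ 0.95·K` ("all or almost all combinations observed"); the estimate is
suppressed there because the inverse diverges. Filtering is a plain
read-count threshold (defaults 2 for transcripts, 10 recommended for
high-depth spikes) with no barcode-graph collapsing; subsampling is uniform
without replacement, order-stable and seed-reproducible.

## Numerical and design choices

* Probability vectors validated to sum to 1 ± 1e-9; `error_rate` capped at
  0.1; `duplication_mean ≥ 1`.
* `expected_distinct` uses `expm1`/`log1p` to stay accurate for large K.
* Concentrations are explicit (value, SI-prefixed unit) pairs; formatting
  keeps three significant figures; the Avogadro constant is the exact SI
  value 6.02214076×10²³. The spike-input arithmetic reports the unrounded
  molecule count (104 amol → 62.63 million), noting that printed
  "62.3 million / 104 amol" pairs are mutually rounded.
* Default problem sizes in tests and the acceptance script (10³–1.3×10⁵
  molecules, 200–400 Monte-Carlo replicates) were chosen to make the
  statistical bands (99% binomial/multinomial CIs, 3-SE comparisons) tight
  enough to be informative while keeping the whole suite fast on a laptop.

## Known limitations

* Positional recovery guarantees hold for the degenerate-window (rNNN)
  design; for fixed rGGG the window positions are TSO-templated and carry
  no information about the addition preference.
* The occupancy inversion assumes uniform barcode usage; synthesis bias in
  real degenerate oligos inflates collisions and biases n̂ downward.
* The estimator of molecule counts is evaluated only below saturation;
  near-saturated tallies (U just under 0.95K) have high variance that the
  point estimate does not convey.
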
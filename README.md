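# tsokit

Template-switching junction profiling for 5'-tag RNA-seq (STRT-style
libraries), with a forward read simulator that provides per-molecule ground
truth.

## The problem

MMLV-family reverse transcriptases (e.g. SuperScript II) append a few
non-templated nucleotides — preferentially cytidines — to the 3' end of the
first-strand cDNA when they reach the 5' end of the RNA template. A
template-switching oligonucleotide (TSO) carrying an amplification handle, a
degenerate barcode/UMI stretch of length *L* and a 3' ribonucleotide window
(fixed rGGG or degenerate rNNN, length *r*) anneals to those protruding
bases, and the enzyme switches template, writing the TSO sequence onto the
cDNA. In the resulting 5'-tag reads the junction looks like

```
[UMI (L)] [ribo window (r)] [G run] [transcript 5' sequence …]
```

The guanosine run at the junction mixes TSO-templated Gs with complements of
RT-added Cs, so its length *n* in a motif `G(n)<anchor>` is an **upper
bound** on the number of added bases. `tsokit` is for people who design or
debug template-switching protocols and want to quantify, from reads:

* **positional base preferences** at TSO-relative positions 1..P (position 1
  = the 3'-most ribo base, directly at the junction);
* **G-run length histograms** per transcript/spike anchor;
* the **major template-switching site** of a transcript and its read share;
* the **capture fraction** of candidate ribo-window designs: for an observed
  junction trinucleotide table with shares GGG 0.46, AGG 0.14, CGG 0.11,
  TGG 0.08, a fixed GGG window pairs with 46% of molecules while an NGG
  design captures `0.46+0.14+0.11+0.08 = 79%`;
* **UMI complexity and saturation** under the uniform-labeling occupancy
  model `E[U] = K(1 − (1 − 1/K)^n)` with `K = 4^L`, inverted as
  `n̂ = ln(1 − U/K)/ln(1 − 1/K)` to estimate absolute molecule counts;
* **reaction/dilution arithmetic** for the wet-lab side (final
  concentrations, molarities, TSO degeneracy folds).

Because full-scale sequencing data are impractical for development, the
package includes a forward simulator of the whole process (addition length
law, position-dependent C preference, window pairing, PCR duplication,
sequencing errors) that emits FASTQ plus a molecule-level truth table.

## Worked example

```python
import tsokit as tk

arch = tk.TSOArchitecture(umi_len=10, ribo_spec="NNN")
cfg = tk.SimulationConfig(transcripts=tk.ercc_spike_transcripts(),
                          architecture=arch, seed=1,
                          error_rate=0.001, duplication_mean=3.0)
reads, truth = tk.simulate_reads(cfg, 2000)
print(len(reads), "reads from", int(truth.switched.sum()), "switched molecules")

query = tk.AnchorQuery("MC28", "GGAATTCT")
decs = [tk.decompose_junction(r, s, arch)
        for r, s in tk.match_anchor(reads, query, arch)]
table = tk.positional_frequencies(decs, 13)
print("G fraction at positions 1-3:",
      [round(table.base_fraction("G", i), 3) for i in (1, 2, 3)])

hist = tk.g_run_histogram(reads, query, 2, 8, arch)
print("G-run histogram:", dict(hist.counts))

tally = tk.filter_tally(tk.tally_umis(decs), 2)
print("distinct UMIs after filtering:", tally.distinct)
print("estimated molecules:", round(tk.assess_saturation(tally).n_hat, 1))
```

prints

```
4694 reads from 1567 switched molecules
G fraction at positions 1-3: [0.95, 0.798, 0.58]
G-run histogram: {2: 1335, 3: 1439, 4: 665, 5: 183, 6: 55, 7: 19, 8: 5}
distinct UMIs after filtering: 1339
estimated molecules: 1339.9
```

The G gradient estimated from the reads recovers the simulator's configured
0.94/0.83/0.57 cytidine-addition preference (read strand shows the
complementary Gs); the G-run mode at n = 3 reflects the addition-length law;
and the count-2 UMI filter brings the distinct-UMI tally close to the true
number of switched molecules despite PCR duplicates and sequencing errors.

A CLI mirrors the library: `tsokit simulate | junction-freq | g-runs |
major-site | capture | umi | subsample | mix | run` (see `tsokit --help`).
`tsokit run --config run.yaml` executes the whole pipeline
(simulate/load → match → decompose → positional/G-run/UMI stages) and
writes TSV tables plus a versioned `summary.json`.

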
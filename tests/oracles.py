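"""Independent brute-force oracles and fixture generators for the tests."""

import re

import numpy as np

import tsokit as tk


def make_g_run_reads(n_reads: int, seed: int, anchor: str = "GGAATTCT"):
    """Synthetic reads [random UMI][G run][anchor][ACT-only tail].

    The tail avoids G so the anchor (and any G-run + anchor motif) occurs
    exactly once per read; a few reads omit the anchor entirely.
    """
    rng = np.random.default_rng(seed)
    reads = []
    for i in range(n_reads):
        umi = "".join("ACGT"[b] for b in rng.integers(0, 4, 10))
        run = "G" * int(rng.integers(0, 11))
        tail = "".join("ACT"[b] for b in rng.integers(0, 3, 25))
        if rng.random() < 0.05:  # anchor-free read
            seq = umi + run + tail + tail[:len(anchor)]
        else:
            seq = umi + run + anchor + tail
        reads.append(tk.ReadRecord(f"r{i}", seq))
    return reads


def regex_g_run_counts(reads, anchor: str, n_min: int, n_max: int):
    """Count reads exhibiting the motif G(n)<anchor> for each n, by regex.

    The lookbehind enforces maximal runs; n excludes the anchor's own
    leading guanosines.
    """
    lead = len(anchor) - len(anchor.lstrip("G"))
    core = anchor[lead:]
    counts = {}
    for n in range(n_min, n_max + 1):
        pat = re.compile(f"(?<!G)G{{{n + lead}}}{re.escape(core)}")
        counts[n] = sum(1 for r in reads if pat.search(r.seq))
    return counts
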
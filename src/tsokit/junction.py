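"""Read-level analysis of the template-switching junction.

Given handle-trimmed 5'-tag reads of structure ``[UMI][ribo window][G run]
[transcript 5' sequence]``, this module locates the known transcript/spike
5' sequence (the anchor) in each read, decomposes the upstream junction
window, and aggregates:

* per-position base frequencies at TSO-relative positions (position 1 =
  3'-most ribo base, directly at the junction);
* the histogram of junction guanosine run lengths n for motifs of the form
  ``G(n)<anchor>``, correcting for guanosines that belong to the anchor
  itself — n is an *upper bound* on the number of RT-added bases because
  TSO-templated Gs and added-C complements are indistinguishable;
* the major template-switching site of a transcript and its read share;
* the capture fraction of candidate ribo-window designs (e.g. NGG vs GGG)
  over an observed junction trinucleotide table.

Matching is exact substring search, mirroring a grep-based workflow.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    ConfigError,
    DecompositionError,
    NoSignalError,
    ReadRecord,
    TSOArchitecture,
)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class AnchorQuery:
    """A transcript/spike 5'-end query sequence.

    ``downstream_homopolymer`` optionally allows a flexible homopolymer
    prefix before the anchor core, e.g. ``("C", 2, 4)`` with anchor
    ``TTTCCT`` queries the motif ``C{2,4}TTTCCT`` (flexibility absorbs
    sequencing errors in the homopolymer).
    """

    name: str
    anchor: str
    downstream_homopolymer: tuple[str, int, int] | None = None

    def __post_init__(self) -> None:
        if len(self.anchor) < 6:
            raise ConfigError(f"anchor {self.name}: length must be >= 6")
        if any(b not in "ACGT" for b in self.anchor):
            raise ConfigError(f"anchor {self.name}: non-ACGT symbols")
        if self.downstream_homopolymer is not None:
            base, lo, hi = self.downstream_homopolymer
            if base not in "ACGT" or lo > hi or lo < 0:
                raise ConfigError(f"anchor {self.name}: bad homopolymer spec")

    def pattern(self) -> re.Pattern[str]:
        if self.downstream_homopolymer is None:
            return re.compile(re.escape(self.anchor))
        base, lo, hi = self.downstream_homopolymer
        return re.compile(f"{base}{{{lo},{hi}}}{re.escape(self.anchor)}")

    def leading_g_count(self) -> int:
        """Guanosines at the start of the effective anchor (min-homopolymer form)."""
        base, lo = ("", 0)
        if self.downstream_homopolymer is not None:
            base, lo, _ = self.downstream_homopolymer
        effective = base * lo + self.anchor
        return len(effective) - len(effective.lstrip("G"))


@dataclass(frozen=True)
class JunctionDecomposition:
    """Per-read parse of the junction window.

    ``positions`` holds bases at TSO-relative positions 1..L+r, i.e. the
    first L+r read bases reversed, so ``positions[0]`` is the 3'-most ribo
    base. ``g_run`` is the maximal guanosine run abutting the junction,
    including any leading Gs of the anchor occurrence itself (callers
    subtract the anchor's own leading-G count to report motif n).
    """

    read_id: str
    anchor_start: int
    g_run: int
    ribo_window: str
    umi: str
    positions: str


def match_anchor(
    reads: Iterable[ReadRecord],
    query: AnchorQuery,
    arch: TSOArchitecture | None = None,
) -> list[tuple[ReadRecord, int]]:
    """Exact (grep-style) anchor search.

    Each read is reported once, at the leftmost match whose start leaves a
    full junction window upstream (``>= umi_len + r`` when ``arch`` is
    given); reads without a qualifying match are dropped.
    """
    min_start = arch.junction_offset if arch is not None else 0
    pat = query.pattern()
    hits: list[tuple[ReadRecord, int]] = []
    for read in reads:
        m = pat.search(read.seq, min_start)
        if m is not None:
            hits.append((read, m.start()))
    return hits


def decompose_junction(
    read: ReadRecord, anchor_start: int, arch: TSOArchitecture
) -> JunctionDecomposition:
    """Split a handle-trimmed read into UMI, ribo window and junction G run."""
    L, r = arch.umi_len, arch.r
    if anchor_start < L + r:
        raise DecompositionError(
            f"read {read.id!r}: anchor at {anchor_start} leaves no room for a "
            f"{L}+{r} junction window (wrong architecture or malformed read)"
        )
    seq = read.seq
    # extend right through the anchor's own leading Gs, then take the
    # maximal G run ending there
    j = anchor_start
    while j < len(seq) and seq[j] == "G":
        j += 1
    i = j
    while i > 0 and seq[i - 1] == "G":
        i -= 1
    return JunctionDecomposition(
        read_id=read.id,
        anchor_start=anchor_start,
        g_run=j - i,
        ribo_window=seq[L : L + r],
        umi=seq[:L],
        positions=seq[: L + r][::-1],
    )


class PositionalFrequencyTable:
    """Base counts at TSO-relative positions 1..P across decomposed reads.

    Reads containing an N anywhere within the first P positions are
    excluded from the counts (tracked in ``n_excluded``) so each row sums
    to ``n_reads``.
    """

    def __init__(self, counts: np.ndarray, n_reads: int, n_excluded: int = 0):
        self.counts = counts  # (P, 4) over A,C,G,T
        self.n_reads = n_reads
        self.n_excluded = n_excluded

    @property
    def P(self) -> int:
        return self.counts.shape[0]

    @property
    def has_data(self) -> bool:
        return self.n_reads > 0

    @property
    def fractions(self) -> np.ndarray:
        if not self.has_data:
            raise ValueError("no decomposed reads: fractions are undefined")
        return self.counts / self.n_reads

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.counts, columns=list("ACGT"),
            index=pd.RangeIndex(1, self.P + 1, name="position"),
        )
        if self.has_data:
            for b_idx, b in enumerate("ACGT"):
                df[f"frac_{b}"] = self.counts[:, b_idx] / self.n_reads
        return df

    def base_fraction(self, base: str, position: int) -> float:
        """Fraction of reads showing ``base`` at TSO-relative ``position``."""
        return float(self.fractions[position - 1, "ACGT".index(base)])


def positional_frequencies(
    decompositions: Sequence[JunctionDecomposition], P: int
) -> PositionalFrequencyTable:
    """Count bases per TSO-relative position over a set of decompositions."""
    if decompositions and P > len(decompositions[0].positions):
        raise ValueError(f"P={P} exceeds the junction window length")
    counts = np.zeros((P, 4), dtype=np.int64)
    idx = {b: i for i, b in enumerate("ACGT")}
    n_used = n_excluded = 0
    for d in decompositions:
        window = d.positions[:P]
        if "N" in window:
            n_excluded += 1
            continue
        for pos, base in enumerate(window):
            counts[pos, idx[base]] += 1
        n_used += 1
    return PositionalFrequencyTable(counts, n_used, n_excluded)


@dataclass(frozen=True)
class GRunHistogram:
    """Distribution of junction guanosine run lengths n for one anchor.

    ``counts[n]`` bins reads with n in ``[n_min, n_max]``; reads whose run
    falls outside the range still count toward ``n_matched``. Fractions are
    computed over ``n_matched``; ``n_total`` is the number of reads queried
    (the denominator of ``fraction_with_motif``).
    """

    counts: Mapping[int, int]
    n_matched: int
    n_total: int
    n_min: int
    n_max: int

    @property
    def fraction_with_motif(self) -> float:
        return self.n_matched / self.n_total if self.n_total else 0.0

    def fractions(self) -> dict[int, float]:
        if self.n_matched == 0:
            return {n: 0.0 for n in self.counts}
        return {n: c / self.n_matched for n, c in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        fr = self.fractions()
        return pd.DataFrame(
            {
                "n": list(self.counts),
                "count": list(self.counts.values()),
                "fraction": [fr[n] for n in self.counts],
            }
        )


def g_run_histogram(
    reads: Iterable[ReadRecord],
    query: AnchorQuery,
    n_min: int = 2,
    n_max: int = 8,
    arch: TSOArchitecture | None = None,
) -> GRunHistogram:
    """Count motif instances ``G(n)<anchor>`` with n in [n_min, n_max].

    n is the maximal guanosine run immediately 5' of the anchor's non-G
    core minus the anchor's own leading-G count, evaluated at the leftmost
    anchor occurrence per read (subject to the architecture's junction
    window when ``arch`` is given).
    """
    effective_all_g = query.leading_g_count() == len(query.anchor) + (
        query.downstream_homopolymer[1] if query.downstream_homopolymer else 0
    )
    if effective_all_g:
        raise ConfigError("anchor consists only of guanosines: n is undefined")
    if n_min > n_max:
        raise ValueError("n_min must be <= n_max")

    correction = query.leading_g_count()
    min_start = arch.junction_offset if arch is not None else 0
    pat = query.pattern()
    counts: Counter[int] = Counter({n: 0 for n in range(n_min, n_max + 1)})
    n_matched = n_total = 0
    for read in reads:
        n_total += 1
        m = pat.search(read.seq, min_start)
        if m is None:
            continue
        n_matched += 1
        seq, j = read.seq, m.start()
        while j < len(seq) and seq[j] == "G":
            j += 1
        i = j
        while i > 0 and seq[i - 1] == "G":
            i -= 1
        n = (j - i) - correction
        if n_min <= n <= n_max:
            counts[n] += 1
    return GRunHistogram(dict(counts), n_matched, n_total, n_min, n_max)


def major_site(
    reads: Sequence[ReadRecord],
    transcript_seq: str,
    arch: TSOArchitecture,
    probe_len: int = 12,
) -> tuple[int, float]:
    """Locate the modal template-switching site of a transcript.

    For each read the ``probe_len``-mer following the junction (after the
    G run, so the reported offset is the first non-G transcript position
    downstream of it) is located in ``transcript_seq`` by leftmost exact
    match. Returns the modal offset and its share of located reads; ties
    break toward the 5'-most offset.
    """
    if probe_len < 8:
        raise ValueError("probe_len must be >= 8")
    if not reads:
        raise ValueError("empty input: no reads supplied")
    offsets: Counter[int] = Counter()
    for read in reads:
        j = arch.junction_offset
        seq = read.seq
        while j < len(seq) and seq[j] == "G":
            j += 1
        probe = seq[j : j + probe_len]
        if len(probe) < probe_len:
            continue
        pos = transcript_seq.find(probe)
        if pos >= 0:
            offsets[pos] += 1
    if not offsets:
        raise NoSignalError("no read probe located in the transcript sequence")
    total = sum(offsets.values())
    best = min(offsets, key=lambda o: (-offsets[o], o))
    return best, offsets[best] / total


def ribo_trinucleotide_frequencies(
    decompositions: Sequence[JunctionDecomposition],
) -> dict[str, float]:
    """Observed junction trinucleotide (window positions 3-2-1, read order)
    frequencies over N-free decompositions."""
    counter: Counter[str] = Counter()
    for d in decompositions:
        w = d.ribo_window
        if len(w) == 3 and "N" not in w:
            counter[w] += 1
    total = sum(counter.values())
    return {k: v / total for k, v in counter.items()} if total else {}


def tso_capture_fraction(
    trinuc_freqs: Mapping[str, float], ribo_pattern: str
) -> float:
    """Fraction of cDNA molecules a candidate 3-base ribo window can pair with.

    ``ribo_pattern`` is an IUPAC 3-mer in read-strand orientation (position
    3-2-1 left to right, like the keys of ``trinuc_freqs``); N matches any
    base. E.g. pattern ``NGG`` over an observed table sums every ``?GG``
    frequency.
    """
    if len(ribo_pattern) != 3:
        raise ConfigError("ribo pattern must have length 3")
    for sym in ribo_pattern:
        if sym.upper() not in IUPAC:
            raise ConfigError(f"invalid IUPAC symbol {sym!r} in ribo pattern")
    for mer, f in trinuc_freqs.items():
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"frequency of {mer} outside [0, 1]")
    total = 0.0
    sets = [IUPAC[s.upper()] for s in ribo_pattern]
    for mer, f in trinuc_freqs.items():
        if len(mer) == 3 and all(b in s for b, s in zip(mer, sets)):
            total += f
    return total


def trim_handle(reads: Iterable[ReadRecord], handle: str) -> list[ReadRecord]:
    """Drop reads not starting with the exact handle; trim it from the rest."""
    if not handle:
        return list(reads)
    out = []
    n = len(handle)
    for read in reads:
        if read.seq.startswith(handle):
            out.append(
                ReadRecord(
                    id=read.id,
                    seq=read.seq[n:],
                    qual=read.qual[n:] if read.qual else None,
                )
            )
    return out
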
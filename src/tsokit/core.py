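"""Shared primitives: read records, TSO layout, DNA helpers, exceptions.

Position numbering convention used throughout the package: junction-window
positions are 1-based counting *away* from the template-switching site, so
position 1 is the 3'-most ribonucleotide of the TSO (the base directly at the
junction), positions 1..r are the ribo window and positions r+1..r+L walk back
through the barcode/UMI stretch. All frequency tables and decompositions use
this convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

DNA_BASES = "ACGT"

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def complement(seq: str) -> str:
    """Watson-Crick complement (same orientation, not reversed)."""
    return seq.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class TsokitError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(TsokitError, ValueError):
    """Invalid configuration (probability vectors, architecture, patterns)."""


class DecompositionError(TsokitError, ValueError):
    """A read cannot be decomposed under the stated TSO architecture."""


class ParseError(TsokitError, ValueError):
    """Malformed sequence file."""


class SaturationError(TsokitError, ValueError):
    """Molecule count not recoverable: observed UMIs fill the UMI space."""


class NoSignalError(TsokitError, RuntimeError):
    """Reads were supplied but none produced a usable signal."""


@dataclass(frozen=True)
class ReadRecord:
    """A single sequencing read.

    qual, when present, is a Phred string of the same length as seq.
    """

    id: str
    seq: str
    qual: str | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"read {self.id!r}: empty sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class TSOArchitecture:
    """Layout of the template-switching oligonucleotide.

    The read structure implied by the layout (after handle trimming) is::

        [UMI: umi_len bases][ribo window: r bases][junction ...]

    Parameters
    ----------
    handle:
        5' amplification handle. Empty when reads are pre-trimmed, which is
        the default assumption of the analysis functions.
    umi_len:
        Number of degenerate DNA positions (the barcode/UMI stretch), ``L``.
    ribo_spec:
        The ribonucleotide window written 5'->3' over {G, N}: ``"GGG"`` is the
        classic fixed window, ``"NNN"`` a fully degenerate one. Its length is
        ``r``; ribo position 1 (junction-proximal) is ``ribo_spec[-1]``.
    """

    handle: str = ""
    umi_len: int = 10
    ribo_spec: str = "GGG"
    name: str = "TSO"

    def __post_init__(self) -> None:
        if any(b not in "ACGTU" for b in self.handle):
            raise ConfigError(f"handle contains non-ACGTU symbols: {self.handle!r}")
        if self.umi_len < 0:
            raise ConfigError("umi_len must be >= 0")
        if not 1 <= len(self.ribo_spec) <= 6:
            raise ConfigError("ribo window length must be in [1, 6]")
        if any(b not in "GN" for b in self.ribo_spec):
            raise ConfigError(f"ribo_spec must be over {{G, N}}: {self.ribo_spec!r}")

    @property
    def r(self) -> int:
        """Length of the ribo window."""
        return len(self.ribo_spec)

    @property
    def junction_offset(self) -> int:
        """Read offset where the junction window ends (handle-trimmed reads)."""
        return self.umi_len + self.r

    def ribo_char(self, position: int) -> str:
        """Spec character ('G' or 'N') at junction-relative ribo position 1..r."""
        if not 1 <= position <= self.r:
            raise ValueError(f"ribo position {position} outside 1..{self.r}")
        return self.ribo_spec[self.r - position]
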
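"""UMI complexity: tallies, error-threshold filtering, saturation, counting.

The collision model is uniform independent labeling of molecules with one
of ``K = 4^L`` barcodes (the occupancy / birthday setting): labeling ``n``
molecules yields on average

    E[U] = K * (1 - (1 - 1/K)**n)

distinct barcodes. Inverting the expectation gives a molecule-count
estimator from an observed distinct-UMI count U:

    n_hat = ln(1 - U/K) / ln(1 - 1/K),

defined for U < K; when the space saturates (U -> K) the count is not
recoverable. Filtering is a plain read-count threshold per barcode — UMIs
seen fewer times than the threshold are treated as likely sequencing
errors — with no graph-based barcode collapsing.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core import ReadRecord, SaturationError
from .junction import JunctionDecomposition


@dataclass(frozen=True)
class UMITally:
    """Read counts per exact UMI sequence."""

    counts: dict[str, int]
    umi_len: int

    @property
    def distinct(self) -> int:
        return len(self.counts)

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class SaturationReport:
    """Collision-model assessment of a UMI tally."""

    K: int
    U: int
    saturation_fraction: float
    saturated: bool
    expected_U: float | None = None
    n_hat: float | None = None

    def to_dict(self) -> dict:
        return {
            "umi_space": self.K,
            "distinct_umis": self.U,
            "saturation_fraction": self.saturation_fraction,
            "saturated": self.saturated,
            "expected_distinct": self.expected_U,
            "estimated_molecules": self.n_hat,
        }


def tally_umis(decompositions: Iterable[JunctionDecomposition]) -> UMITally:
    """Exact-sequence UMI tally over decomposed reads (no error merging)."""
    counter: Counter[str] = Counter()
    umi_len: int | None = None
    for d in decompositions:
        if umi_len is None:
            umi_len = len(d.umi)
        elif len(d.umi) != umi_len:
            raise ValueError(
                f"mixed UMI lengths in tally: {umi_len} vs {len(d.umi)} "
                f"(read {d.read_id!r})"
            )
        counter[d.umi] += 1
    return UMITally(dict(counter), umi_len or 0)


def filter_tally(tally: UMITally, min_count: int) -> UMITally:
    """Drop UMIs observed fewer than ``min_count`` times (new tally; input kept)."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    return UMITally(
        {u: c for u, c in tally.counts.items() if c >= min_count}, tally.umi_len
    )


def expected_distinct(n_molecules: float, K: int) -> float:
    """Expected number of distinct barcodes when n molecules draw uniformly
    from K labels: K*(1 - (1 - 1/K)^n). Monotone in n, bounded by K."""
    if n_molecules < 0:
        raise ValueError("n_molecules must be >= 0")
    if K < 1:
        raise ValueError("K must be >= 1")
    if K == 1:
        return 0.0 if n_molecules == 0 else 1.0
    return float(K * -np.expm1(n_molecules * np.log1p(-1.0 / K)))


def estimate_molecules(U: float, K: int) -> float:
    """Invert the occupancy expectation: molecules that explain U distinct UMIs.

    Exact algebraic inverse of :func:`expected_distinct`; raises
    :class:`SaturationError` at U >= K where the estimate diverges.
    """
    if U < 0:
        raise ValueError("U must be >= 0")
    if U >= K:
        raise SaturationError(
            f"distinct count U={U} fills the UMI space K={K}: "
            "molecule count not recoverable"
        )
    if U == 0:
        return 0.0
    return float(np.log1p(-U / K) / np.log1p(-1.0 / K))


def assess_saturation(
    tally: UMITally,
    umi_len: int | None = None,
    saturation_fraction: float = 0.95,
    n_molecules: float | None = None,
) -> SaturationReport:
    """Judge whether a tally saturates its 4^L space; estimate molecules if not.

    ``saturated`` means U >= saturation_fraction * K ("all, or almost all,
    combinations observed"); the inverted molecule estimate is only
    meaningful, and only reported, below that regime. When the true
    molecule count is known (simulations), pass ``n_molecules`` to also
    report the model expectation E[U].
    """
    if not 0.0 < saturation_fraction <= 1.0:
        raise ValueError("saturation_fraction must be in (0, 1]")
    L = tally.umi_len if umi_len is None else umi_len
    K = 4**L
    U = tally.distinct
    saturated = U >= saturation_fraction * K
    n_hat = None if saturated else estimate_molecules(U, K)
    expected_U = None if n_molecules is None else expected_distinct(n_molecules, K)
    return SaturationReport(
        K=K, U=U, saturation_fraction=saturation_fraction,
        saturated=saturated, expected_U=expected_U, n_hat=n_hat,
    )


def subsample_reads(
    reads: Sequence[ReadRecord], n_target: int, seed: int
) -> list[ReadRecord]:
    """Uniform sample of exactly ``n_target`` reads without replacement.

    Order-stable (selected reads keep their input order) and reproducible
    by ``seed``; sampling more reads than supplied is an error.
    """
    if n_target < 0:
        raise ValueError("n_target must be >= 0")
    if n_target > len(reads):
        raise ValueError(
            f"cannot sample {n_target} of {len(reads)} reads without replacement"
        )
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(reads), size=n_target, replace=False))
    return [reads[i] for i in idx]
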
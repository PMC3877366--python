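"""Forward simulator of STRT-style template-switched reads.

The simulator emulates the biochemistry of MMLV template switching at the
level an end-sequencing experiment can observe. Per molecule:

1. a transcript is chosen multinomially by relative abundance;
2. the reverse transcriptase appends ``k`` non-templated bases to the cDNA
   3' end (``k`` drawn from ``addition_len_probs``), each base drawn from a
   per-position distribution in which cytidine dominates close to the
   transcript end and decays with distance (``addition_base_probs``);
3. the TSO ribo window anneals to the junction-proximal added bases: ribo
   position ``i`` (1 = the TSO 3' terminus) pairs with added base ``i``.
   A fixed 'G' position pairs only when the added base is 'C'; a degenerate
   'N' position always finds a complementary partner in the pool (modeling
   selection of matching species from the 4^r mixture). Position 1 must
   pair strictly; any other non-pairing position is tolerated with
   probability ``mismatch_tolerance``, otherwise the molecule never
   switches and emits no reads;
4. added bases beyond the ribo window (the overhang, positions r+1..k)
   contribute one junction guanosine per added cytidine, so the observed
   G run mixes TSO-templated Gs with added-C complements and is an upper
   bound on the number of RT-added bases;
5. each switched molecule is PCR-duplicated (shifted Poisson) and rendered
   as reads ``handle + UMI + ribo window + G-overhang + transcript 5' seq``
   with i.i.d. substitution errors.

Ground truth for every molecule is retained so that downstream junction and
UMI analyses can be validated by exact joins.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import DNA_BASES, ConfigError, ReadRecord, TSOArchitecture, complement

#: Distribution of the number of RT-added bases. Concentrated on 2-5 with
#: mode 3, matching junction G-run observations from degenerate-window
#: libraries (where the TSO's own guanosines inflate the count the least).
DEFAULT_ADDITION_LEN_PROBS: dict[int, float] = {
    2: 0.20, 3: 0.32, 4: 0.28, 5: 0.14, 6: 0.04, 7: 0.015, 8: 0.005,
}

#: Per-position cytidine preference of the terminal-transferase addition,
#: cDNA strand, position 1 = first added base (at the transcript end).
#: 0.94/0.83/0.57 are the observed read-strand guanosine fractions at ribo
#: positions 1-3; the non-C remainder is split evenly. Positions beyond the
#: table are uniform.
DEFAULT_C_GRADIENT: tuple[float, ...] = (0.94, 0.83, 0.57)


def _gradient_to_base_probs(c_probs: Sequence[float]) -> tuple[dict[str, float], ...]:
    out = []
    for p in c_probs:
        rest = (1.0 - p) / 3.0
        out.append({"A": rest, "C": p, "G": rest, "T": rest})
    return tuple(out)


DEFAULT_ADDITION_BASE_PROBS: tuple[dict[str, float], ...] = _gradient_to_base_probs(
    DEFAULT_C_GRADIENT
)

_UNIFORM = {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}


@dataclass(frozen=True)
class TranscriptSpec:
    """One simulated transcript: sequence, abundance and its major TS site."""

    name: str
    sequence: str
    abundance: float = 1.0
    ts_site: int = 0

    def __post_init__(self) -> None:
        if any(b not in DNA_BASES for b in self.sequence):
            raise ConfigError(f"transcript {self.name}: non-ACGT symbols in sequence")
        if self.abundance <= 0:
            raise ConfigError(f"transcript {self.name}: abundance must be > 0")
        if not 0 <= self.ts_site < len(self.sequence):
            raise ConfigError(f"transcript {self.name}: ts_site outside sequence")


def _deterministic_tail(name: str, length: int) -> str:
    """Reproducible pseudo-random DNA downstream of a fixed 5' prefix."""
    rng = np.random.default_rng(zlib.crc32(name.encode()))
    return "".join(DNA_BASES[i] for i in rng.integers(0, 4, size=length))


def ercc_spike_transcripts() -> tuple[TranscriptSpec, ...]:
    """Two spike-like transcripts whose 5' ends start with GGAATTCT.

    Abundances follow the ~4:1 read ratio of the two dominant spikes in a
    typical ERCC-based template-switching run.
    """
    return (
        TranscriptSpec("MC28", "GGAATTCT" + _deterministic_tail("MC28", 112), 67.0),
        TranscriptSpec(
            "MJ-500-37", "GGAATTCT" + _deterministic_tail("MJ-500-37", 112), 16.0
        ),
    )


def human_rna_transcripts() -> tuple[TranscriptSpec, ...]:
    """Five transcripts spanning ~3 decades of abundance.

    5' junction 8-mers for RPLP1 (CCTTTCCT) and MT2A (ACCACGCC) match the
    real major-site sequences; the remaining sequences are deterministic
    stand-ins. Abundances follow the observed read-count ratios
    MALAT1 > RPLP1 > MT2A > AHSG > CNIH4.
    """
    return (
        TranscriptSpec("MALAT1", "TACTTGGCTA" + _deterministic_tail("MALAT1", 110), 4200.0),
        TranscriptSpec("RPLP1", "CCTTTCCT" + _deterministic_tail("RPLP1", 112), 1100.0),
        TranscriptSpec("MT2A", "ACCACGCC" + _deterministic_tail("MT2A", 112), 353.0),
        TranscriptSpec("AHSG", "TCTGAAGCAT" + _deterministic_tail("AHSG", 110), 91.0),
        TranscriptSpec("CNIH4", "ATGGAAGCTT" + _deterministic_tail("CNIH4", 110), 7.0),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to generate a deterministic synthetic read set."""

    transcripts: tuple[TranscriptSpec, ...]
    architecture: TSOArchitecture = field(default_factory=TSOArchitecture)
    seed: int = 0
    addition_len_probs: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_ADDITION_LEN_PROBS)
    )
    addition_base_probs: tuple[Mapping[str, float], ...] = DEFAULT_ADDITION_BASE_PROBS
    mismatch_tolerance: float = 0.0
    short_tail_mode: Literal["fill_in", "loop_out"] = "fill_in"
    duplication_mean: float = 3.0
    error_rate: float = 0.001
    read_len: int = 51

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ConfigError("at least one transcript is required")
        if abs(sum(self.addition_len_probs.values()) - 1.0) > 1e-9:
            raise ConfigError("addition_len_probs must sum to 1")
        if any(k < 0 or p < 0 for k, p in self.addition_len_probs.items()):
            raise ConfigError("addition_len_probs: negative length or probability")
        for j, dist in enumerate(self.addition_base_probs, start=1):
            if set(dist) != set(DNA_BASES) or abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ConfigError(f"addition_base_probs[{j}] is not a distribution over ACGT")
        if not 0.0 <= self.mismatch_tolerance <= 1.0:
            raise ConfigError("mismatch_tolerance must be in [0, 1]")
        if self.short_tail_mode not in ("fill_in", "loop_out"):
            raise ConfigError("short_tail_mode must be 'fill_in' or 'loop_out'")
        if self.duplication_mean < 1.0:
            raise ConfigError("duplication_mean must be >= 1")
        if not 0.0 <= self.error_rate <= 0.1:
            raise ConfigError("error_rate must be in [0, 0.1]")
        if self.read_len < self.architecture.junction_offset + 1:
            raise ConfigError("read_len shorter than UMI + ribo window")

    @property
    def k_max(self) -> int:
        return max(self.addition_len_probs)

    def base_probs_at(self, position: int) -> Mapping[str, float]:
        """Addition-base distribution at added position (1-based); uniform beyond."""
        if position <= len(self.addition_base_probs):
            return self.addition_base_probs[position - 1]
        return _UNIFORM


@dataclass(frozen=True)
class MoleculeTruth:
    """Ground truth for one cDNA molecule, switched or not."""

    molecule_id: str
    transcript: str
    ts_site: int
    k_added: int
    added_bases: str  # cDNA strand, position 1 first
    umi: str
    ribo_realized: str  # read-strand window as it appears in the read (5'->3')
    observed_g_run: int  # junction G run, excluding any UMI contribution
    switched: bool


def _g_suffix_len(s: str) -> int:
    n = 0
    for ch in reversed(s):
        if ch != "G":
            break
        n += 1
    return n


def simulate_molecules(
    config: SimulationConfig, n_molecules: int
) -> list[MoleculeTruth]:
    """Draw molecules and resolve the template-switching outcome of each.

    Deterministic given ``config.seed``; uses an RNG stream independent of
    the one :func:`render_reads` uses, so truth and rendering can be
    re-generated separately.
    """
    if n_molecules < 0:
        raise ValueError("n_molecules must be >= 0")
    if n_molecules == 0:
        return []

    rng = np.random.default_rng([config.seed, 0])
    arch = config.architecture
    r, L = arch.r, arch.umi_len
    k_max = config.k_max

    t_idx_arr = np.asarray([t.abundance for t in config.transcripts], dtype=float)
    t_idx = rng.choice(len(config.transcripts), size=n_molecules, p=t_idx_arr / t_idx_arr.sum())

    k_vals = np.array(sorted(config.addition_len_probs), dtype=int)
    k_probs = np.array([config.addition_len_probs[k] for k in k_vals])
    ks = k_vals[rng.choice(len(k_vals), size=n_molecules, p=k_probs)]

    # one column of added bases per addition position, each with its own law
    base_cols = np.empty((n_molecules, k_max), dtype="U1")
    for j in range(1, k_max + 1):
        dist = config.base_probs_at(j)
        p = np.array([dist[b] for b in DNA_BASES])
        base_cols[:, j - 1] = np.array(list(DNA_BASES))[
            rng.choice(4, size=n_molecules, p=p)
        ]

    umis = rng.integers(0, 4, size=(n_molecules, L))
    tol_draws = rng.random((n_molecules, r))
    filler = rng.integers(0, 4, size=(n_molecules, r))  # unpaired 'N' realizations

    bases = np.array(list(DNA_BASES))
    tol = config.mismatch_tolerance
    loop_out = config.short_tail_mode == "loop_out"
    molecules: list[MoleculeTruth] = []

    for i in range(n_molecules):
        t = config.transcripts[t_idx[i]]
        k = int(ks[i])
        added = "".join(base_cols[i, :k])
        umi = "".join(bases[umis[i]])
        m = min(k, r)

        switched = k > 0
        window_chars: list[str] = []  # indexed by ribo position (1..r)
        if switched:
            for pos in range(1, r + 1):
                spec = arch.ribo_char(pos)
                if pos <= m:
                    a = added[pos - 1]
                    if spec == "N":
                        window_chars.append(complement(a))
                        continue
                    window_chars.append("G")
                    if a == "C":
                        continue
                    if pos == 1 or tol_draws[i, pos - 1] >= tol:
                        switched = False
                        break
                else:  # k < r: no partner for this ribo position
                    if loop_out:
                        window_chars.append("")
                    elif tol_draws[i, pos - 1] < tol:
                        window_chars.append(
                            "G" if spec == "G" else bases[filler[i, pos - 1]]
                        )
                    else:
                        switched = False
                        break

        if switched:
            # read-order window: position r first, position 1 at the junction
            window = "".join(reversed(window_chars))
            n_extra = added[r:].count("C")
            g_run = _g_suffix_len(window + "G" * n_extra)
        else:
            window = ""
            n_extra = 0
            g_run = 0

        molecules.append(
            MoleculeTruth(
                molecule_id=f"M{i:07d}",
                transcript=t.name,
                ts_site=t.ts_site,
                k_added=k,
                added_bases=added,
                umi=umi,
                ribo_realized=window,
                observed_g_run=g_run,
                switched=switched,
            )
        )
    return molecules


def _apply_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    if hits.size == 0:
        return seq
    chars = list(seq)
    for i in hits:
        alternatives = [b for b in DNA_BASES if b != chars[i]]
        chars[i] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


def render_reads(
    molecules: Sequence[MoleculeTruth], config: SimulationConfig
) -> list[ReadRecord]:
    """Emit reads for every switched molecule.

    Duplicate count per molecule is 1 + Poisson(duplication_mean - 1).
    Reads are ``handle + UMI + window + G-overhang + transcript[ts_site:]``
    truncated (or A-padded) to ``read_len``; read ids are
    ``<molecule_id>:<copy>`` so truth joins are exact.
    """
    rng = np.random.default_rng([config.seed, 1])
    seq_by_name = {t.name: t.sequence for t in config.transcripts}
    handle = config.architecture.handle
    reads: list[ReadRecord] = []

    for mol in molecules:
        if not mol.switched:
            continue
        n_extra = mol.added_bases[config.architecture.r:].count("C")
        body = (
            handle
            + mol.umi
            + mol.ribo_realized
            + "G" * n_extra
            + seq_by_name[mol.transcript][mol.ts_site:]
        )
        body = body[: config.read_len].ljust(config.read_len, "A")
        n_copies = 1 + int(rng.poisson(config.duplication_mean - 1.0))
        for c in range(n_copies):
            seq = body
            if config.error_rate > 0:
                seq = _apply_errors(seq, rng, config.error_rate)
            reads.append(
                ReadRecord(id=f"{mol.molecule_id}:{c}", seq=seq, qual="I" * len(seq))
            )
    return reads


def truth_table(molecules: Sequence[MoleculeTruth]) -> pd.DataFrame:
    """Tabulate molecule ground truth (one row per molecule, TSV-writable)."""
    cols = [
        "molecule_id", "transcript", "ts_site", "k_added", "added_bases",
        "umi", "ribo_realized", "observed_g_run", "switched",
    ]
    if not molecules:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([vars(m) for m in molecules], columns=cols)


def simulate_reads(
    config: SimulationConfig, n_molecules: int
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Convenience: molecules -> (reads, truth table) in one call."""
    molecules = simulate_molecules(config, n_molecules)
    return render_reads(molecules, config), truth_table(molecules)
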
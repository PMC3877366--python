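"""File I/O, reaction/dilution arithmetic and pipeline orchestration.

Units are carried as explicit (value, SI-prefixed unit) pairs — no silent
unit inference; the Avogadro constant is the exact SI value. The
orchestrator wires the stages simulate -> match -> decompose -> positional
/ G-run / UMI together, writes tab-separated tables plus a versioned
machine-readable summary, and logs per-stage read counts.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .core import ConfigError, ParseError, ReadRecord, TSOArchitecture
from .junction import (
    AnchorQuery,
    decompose_junction,
    g_run_histogram,
    match_anchor,
    positional_frequencies,
    ribo_trinucleotide_frequencies,
    trim_handle,
    tso_capture_fraction,
)
from .simulate import (
    SimulationConfig,
    TranscriptSpec,
    ercc_spike_transcripts,
    human_rna_transcripts,
    simulate_molecules,
    render_reads,
    truth_table,
)
from .umi import assess_saturation, filter_tally, subsample_reads, tally_umis

logger = logging.getLogger("tsokit")

#: Exact SI Avogadro constant (molecules per mole).
AVOGADRO = 6.02214076e23

SUMMARY_SCHEMA_VERSION = 1

# ---------------------------------------------------------------------------
# SI-prefixed quantities

_PREFIX = {
    "G": 1e9, "M_": 1e6, "k": 1e3, "": 1.0, "m": 1e-3, "µ": 1e-6, "u": 1e-6,
    "n": 1e-9, "p": 1e-12, "f": 1e-15, "a": 1e-18,
}
# prefixes eligible for auto-formatting, largest first ("µ" preferred over "u")
_FORMAT_PREFIXES = ["G", "k", "", "m", "µ", "n", "p", "f", "a"]
_BASE_UNITS = ("mol", "M", "L", "l", "g", "U")


def _split_unit(unit: str) -> tuple[str, str]:
    """Split an SI-prefixed unit like 'pM' or 'amol' into (prefix, base)."""
    for base in _BASE_UNITS:
        if unit == base:
            return "", base
        if unit.endswith(base):
            pre = unit[: -len(base)]
            if pre in _PREFIX and pre != "M_":
                return pre, base
    raise ConfigError(f"unrecognized unit {unit!r}")


@dataclass(frozen=True)
class Quantity:
    """A value with an SI-prefixed unit, e.g. Quantity(10.4, 'pM')."""

    value: float
    unit: str

    def __post_init__(self) -> None:
        _split_unit(self.unit)

    @property
    def base_value(self) -> float:
        pre, _ = _split_unit(self.unit)
        return self.value * _PREFIX[pre]

    @property
    def base_unit(self) -> str:
        return _split_unit(self.unit)[1]

    def in_unit(self, unit: str) -> float:
        pre, base = _split_unit(unit)
        if base != self.base_unit:
            raise ConfigError(f"cannot express {self.base_unit} in {unit!r}")
        return self.base_value / _PREFIX[pre]

    def __str__(self) -> str:
        return f"{self.value:.3g} {self.unit}"


def parse_quantity(text: str) -> Quantity:
    """Parse '10.4 pM', '2uM' or '104 amol' into a Quantity."""
    s = text.strip()
    i = len(s)
    while i > 0 and not (s[i - 1].isdigit() or s[i - 1] == "."):
        i -= 1
    num, unit = s[:i].strip(), s[i:].strip()
    try:
        value = float(num)
    except ValueError as exc:
        raise ConfigError(f"cannot parse quantity {text!r}") from exc
    return Quantity(value, unit)


def format_si(base_value: float, base_unit: str) -> str:
    """Render a base-unit value with an auto-chosen SI prefix, 3 sig figs."""
    if base_value == 0:
        return f"0 {base_unit}"
    for pre in _FORMAT_PREFIXES:
        scaled = base_value / _PREFIX[pre]
        if 1.0 <= abs(scaled) < 1000.0:
            return f"{scaled:.3g} {pre}{base_unit}"
    return f"{base_value:.3g} {base_unit}"


# ---------------------------------------------------------------------------
# Reaction / dilution arithmetic

@dataclass(frozen=True)
class ReactionComponent:
    """One pipetted component: stock concentration and dispensed volume (µl)."""

    name: str
    stock: Quantity
    volume_ul: float

    def __post_init__(self) -> None:
        if self.stock.value < 0:
            raise ConfigError(f"{self.name}: negative concentration")
        if self.volume_ul <= 0:
            raise ConfigError(f"{self.name}: volume must be > 0")


def final_concentration(
    component: ReactionComponent, total_volume_ul: float
) -> Quantity:
    """Concentration of a component after dilution into the full reaction.

    stock × volume / total, with the stock's unit preserved (2 µM in 5 µl
    of a 10 µl reaction -> 1 µM).
    """
    if total_volume_ul < component.volume_ul:
        raise ValueError(
            f"{component.name}: total volume {total_volume_ul} µl smaller than "
            f"component volume {component.volume_ul} µl"
        )
    return Quantity(
        component.stock.value * component.volume_ul / total_volume_ul,
        component.stock.unit,
    )


def amount_to_molarity(amount_mol: float, volume_l: float) -> Quantity:
    """Molarity of an amount (moles) in a volume (liters), SI-prefix formatted.

    104 amol in 10 µl -> 10.4 pM.
    """
    if volume_l <= 0:
        raise ValueError("volume must be > 0")
    base = amount_mol / volume_l
    if base == 0:
        return Quantity(0.0, "M")
    rendered = format_si(base, "M")
    value, unit = rendered.split()
    return Quantity(float(value), unit)


def amount_to_molecules(amount_mol: float) -> float:
    """Molecule count of an amount in moles (104 amol -> ~6.26e7)."""
    if amount_mol < 0:
        raise ValueError("amount must be >= 0")
    return amount_mol * AVOGADRO


def degeneracy_fold(arch: TSOArchitecture, region: str = "ribo") -> int:
    """Effective-concentration dilution factor from degenerate positions.

    4^(degenerate positions in the region): a fully degenerate rNNN window
    dilutes each individual TSO species 64-fold.
    """
    ribo_n = arch.ribo_spec.count("N")
    if region == "ribo":
        n = ribo_n
    elif region == "umi":
        n = arch.umi_len
    elif region == "all":
        n = ribo_n + arch.umi_len
    else:
        raise ValueError(f"region must be ribo|umi|all, got {region!r}")
    return 4**n


# ---------------------------------------------------------------------------
# Sequence file I/O

def _open_text(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _infer_format(path: Path) -> str:
    name = str(path)
    if name.endswith(".gz"):
        name = name[:-3]
    if name.endswith((".fq", ".fastq")):
        return "fastq"
    if name.endswith((".fa", ".fasta", ".fna")):
        return "fasta"
    raise ConfigError(f"cannot infer sequence format from {path}")


def read_sequences(path: str | Path, fmt: str | None = None) -> list[ReadRecord]:
    """Stream FASTA/FASTQ (optionally gzipped) records in file order."""
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt not in ("fasta", "fastq"):
        raise ConfigError(f"format must be fasta or fastq, got {fmt!r}")
    records: list[ReadRecord] = []
    with _open_text(path) as handle:
        try:
            if fmt == "fastq":
                for title, seq, qual in FastqGeneralIterator(handle):
                    records.append(
                        ReadRecord(id=title.split()[0], seq=seq.upper(), qual=qual)
                    )
            else:
                for title, seq in SimpleFastaParser(handle):
                    records.append(ReadRecord(id=title.split()[0], seq=seq.upper()))
        except ValueError as exc:
            raise ParseError(
                f"{path}: malformed {fmt} near record {len(records) + 1}: {exc}"
            ) from exc
    return records


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    path = Path(path)
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as out:
        for read in reads:
            qual = read.qual or "I" * len(read.seq)
            out.write(f"@{read.id}\n{read.seq}\n+\n{qual}\n")


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def read_anchor_table(path: str | Path) -> tuple[AnchorQuery, ...]:
    """Anchor table TSV: columns name, anchor, optional homopolymer 'C:2:4'."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    queries = []
    for _, row in df.iterrows():
        homo = None
        spec = row.get("homopolymer", "")
        if spec:
            base, lo, hi = spec.split(":")
            homo = (base, int(lo), int(hi))
        queries.append(AnchorQuery(row["name"], row["anchor"], homo))
    return tuple(queries)


# ---------------------------------------------------------------------------
# Orchestration

_TRANSCRIPT_SETS = {
    "ercc": ercc_spike_transcripts,
    "human": human_rna_transcripts,
}


@dataclass(frozen=True)
class RunConfig:
    """A full analysis run: input reads (real or simulated), anchors, knobs."""

    outdir: Path
    architecture: TSOArchitecture
    anchors: tuple[AnchorQuery, ...]
    seed: int = 1
    reads_path: Path | None = None
    simulation: SimulationConfig | None = None
    n_molecules: int = 10_000
    subsample_to: int | None = None
    min_umi_count: int = 2
    positions: int | None = None
    n_min: int = 2
    n_max: int = 8
    saturation_fraction: float = 0.95

    def __post_init__(self) -> None:
        if self.reads_path is None and self.simulation is None:
            raise ConfigError("either reads_path or a simulation block is required")
        if not self.anchors:
            raise ConfigError("at least one anchor query is required")


def _transcripts_from_spec(spec) -> tuple[TranscriptSpec, ...]:
    if isinstance(spec, str):
        try:
            return _TRANSCRIPT_SETS[spec]()
        except KeyError:
            raise ConfigError(
                f"unknown transcript set {spec!r}; use one of {sorted(_TRANSCRIPT_SETS)}"
            ) from None
    return tuple(
        TranscriptSpec(
            t["name"], t["sequence"], float(t.get("abundance", 1.0)),
            int(t.get("ts_site", 0)),
        )
        for t in spec
    )


def load_run_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file (see README for the schema)."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    arch_raw = raw.get("architecture", {})
    arch = TSOArchitecture(
        handle=arch_raw.get("handle", ""),
        umi_len=int(arch_raw.get("umi_len", 10)),
        ribo_spec=arch_raw.get("ribo_spec", "GGG"),
        name=arch_raw.get("name", "TSO"),
    )
    seed = int(raw.get("seed", 1))

    anchors: tuple[AnchorQuery, ...]
    if isinstance(raw.get("anchors"), str):
        anchors = read_anchor_table(path.parent / raw["anchors"])
    else:
        anchors = tuple(
            AnchorQuery(
                a["name"], a["anchor"],
                tuple(a["homopolymer"].split(":")[0:1])
                + tuple(int(x) for x in a["homopolymer"].split(":")[1:])
                if a.get("homopolymer")
                else None,
            )
            for a in raw.get("anchors", [])
        )

    sim = None
    n_molecules = 10_000
    if "simulate" in raw:
        s = raw["simulate"]
        n_molecules = int(s.get("n_molecules", n_molecules))
        sim_kwargs = {}
        for key in (
            "mismatch_tolerance", "short_tail_mode", "duplication_mean",
            "error_rate", "read_len",
        ):
            if key in s:
                sim_kwargs[key] = s[key]
        if "addition_len_probs" in s:
            sim_kwargs["addition_len_probs"] = {
                int(k): float(v) for k, v in s["addition_len_probs"].items()
            }
        sim = SimulationConfig(
            transcripts=_transcripts_from_spec(s.get("transcripts", "ercc")),
            architecture=arch,
            seed=seed,
            **sim_kwargs,
        )

    return RunConfig(
        outdir=path.parent / raw["outdir"] if not Path(raw["outdir"]).is_absolute()
        else Path(raw["outdir"]),
        architecture=arch,
        anchors=anchors,
        seed=seed,
        reads_path=Path(raw["reads"]) if "reads" in raw else None,
        simulation=sim,
        n_molecules=n_molecules,
        subsample_to=raw.get("subsample_to"),
        min_umi_count=int(raw.get("min_umi_count", 2)),
        positions=raw.get("positions"),
        n_min=int(raw.get("n_min", 2)),
        n_max=int(raw.get("n_max", 8)),
        saturation_fraction=float(raw.get("saturation_fraction", 0.95)),
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate -> match -> decompose -> positional/G-run/UMI.

    Writes per-anchor TSV tables, a truth table when simulating, and a
    versioned ``summary.json``; returns the summary dict. Stage counts are
    logged and conserved (decomposed == matched <= total reads).
    """
    arch = config.architecture
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.simulation is not None:
        sim = replace(config.simulation, architecture=arch, seed=config.seed)
        molecules = simulate_molecules(sim, config.n_molecules)
        reads = render_reads(molecules, sim)
        truth = truth_table(molecules)
        write_fastq(reads, outdir / "reads.fastq")
        write_tsv(truth, outdir / "truth.tsv")
        logger.info(
            "simulated %d molecules (%d switched) -> %d reads",
            len(molecules), int(truth["switched"].sum()), len(reads),
        )
    else:
        reads = read_sequences(config.reads_path)
        truth = None
        logger.info("loaded %d reads from %s", len(reads), config.reads_path)

    if arch.handle:
        reads = trim_handle(reads, arch.handle)
        logger.info("handle-trimmed to %d reads", len(reads))
    if config.subsample_to is not None:
        reads = subsample_reads(reads, config.subsample_to, config.seed)
        logger.info("subsampled to %d reads", len(reads))

    P = config.positions or (arch.r + min(arch.umi_len, 10))
    pooled_trinuc: dict[str, float] = {}
    pooled_weight = 0
    summary: dict = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "seed": config.seed,
        "n_reads": len(reads),
        "anchors": {},
    }

    trimmed_arch = replace(arch, handle="")
    for query in config.anchors:
        hits = match_anchor(reads, query, trimmed_arch)
        decomps = [decompose_junction(rd, start, trimmed_arch) for rd, start in hits]
        logger.info("%s: %d/%d reads matched", query.name, len(hits), len(reads))

        freqs = positional_frequencies(decomps, P)
        write_tsv(freqs.to_frame(), outdir / f"{query.name}.positions.tsv", index=True)

        hist = g_run_histogram(reads, query, config.n_min, config.n_max, trimmed_arch)
        write_tsv(hist.to_frame(), outdir / f"{query.name}.g_runs.tsv")

        tally = tally_umis(decomps)
        filtered = filter_tally(tally, config.min_umi_count)
        write_tsv(
            pd.DataFrame(
                sorted(tally.counts.items()), columns=["umi", "count"]
            ),
            outdir / f"{query.name}.umis.tsv",
        )
        n_true = None
        if truth is not None and (truth["transcript"] == query.name).any():
            sub = truth[(truth["transcript"] == query.name) & truth["switched"]]
            n_true = int(len(sub))
        sat = assess_saturation(
            filtered, saturation_fraction=config.saturation_fraction,
            n_molecules=n_true,
        )

        trinuc = ribo_trinucleotide_frequencies(decomps)
        for mer, f in trinuc.items():
            pooled_trinuc[mer] = pooled_trinuc.get(mer, 0.0) + f * len(decomps)
        pooled_weight += len(decomps)

        summary["anchors"][query.name] = {
            "n_matched": len(hits),
            "n_decomposed": len(decomps),
            "n_excluded_N": freqs.n_excluded,
            "fraction_with_motif": hist.fraction_with_motif,
            "g_run_counts": {str(n): c for n, c in hist.counts.items()},
            "distinct_umis": tally.distinct,
            "distinct_umis_filtered": filtered.distinct,
            "true_switched_molecules": n_true,
            "saturation": sat.to_dict(),
        }

    if pooled_weight:
        pooled = {m: v / pooled_weight for m, v in pooled_trinuc.items()}
        summary["capture"] = {
            pattern: round(tso_capture_fraction(pooled, pattern), 6)
            for pattern in ("GGG", "NGG", "NNG", "NNN")
        }

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    logger.info("summary written to %s", outdir / "summary.json")
    return summary
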
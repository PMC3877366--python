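"""Junction analysis: anchor matching, decomposition, frequencies, G runs."""

import re

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import tsokit as tk

from conftest import ALL_C, delta

SPIKE_ANCHOR = tk.AnchorQuery("MC28", "GGAATTCT")


# ---------------------------------------------------------------------------
# match_anchor

def test_match_empty_input():
    assert tk.match_anchor([], SPIKE_ANCHOR) == []


def test_match_leftmost_qualifying_position(arch_g3):
    read = tk.ReadRecord("r", "ACGTACGTACGGGGGGAATTCTAAA")
    hits = tk.match_anchor([read], SPIKE_ANCHOR, arch_g3)
    assert len(hits) == 1
    _, start = hits[0]
    # brute-force oracle: leftmost offset >= L + r where the anchor occurs
    oracle = [
        i
        for i in range(arch_g3.junction_offset, len(read.seq))
        if read.seq.startswith("GGAATTCT", i)
    ]
    assert start == oracle[0] == 14


def test_match_drops_read_without_junction_room(arch_g3):
    bare = tk.ReadRecord("r", "GGAATTCT")
    assert tk.match_anchor([bare], SPIKE_ANCHOR, arch_g3) == []


def test_homopolymer_anchor_matches_flexible_prefix(arch_g3):
    rplp1 = tk.AnchorQuery("RPLP1", "TTTCCT", ("C", 2, 4))
    for n_c in (2, 3, 4):
        read = tk.ReadRecord("r", "A" * 10 + "GGGG" + "C" * n_c + "TTTCCT" + "AC" * 8)
        hits = tk.match_anchor([read], rplp1, arch_g3)
        assert len(hits) == 1
        assert hits[0][1] == 14  # start of the C run
    read = tk.ReadRecord("r", "A" * 10 + "GGGG" + "C" + "TTTCCT" + "AC" * 8)
    assert tk.match_anchor([read], rplp1, arch_g3) == []  # only one C


# ---------------------------------------------------------------------------
# decompose_junction

def test_decompose_hand_traced_layout(arch_g3):
    """UMI + GGG + G + GGAATTCT...: the junction G run through the anchor's
    own leading guanosines is 6; positions 1..3 read G, position 4 the last
    UMI base."""
    read = tk.ReadRecord("r", "ACGTACGTAC" + "GGG" + "G" + "GGAATTCT" + "AC" * 10)
    ((_, start),) = tk.match_anchor([read], SPIKE_ANCHOR, arch_g3)
    dec = tk.decompose_junction(read, start, arch_g3)
    assert dec.umi == "ACGTACGTAC"
    assert dec.ribo_window == "GGG"
    assert dec.g_run == 6
    # oracle: maximal G+ run around the junction, regex on the read
    m = re.search(r"G+(?=AATTCT)", read.seq)
    assert dec.g_run == len(m.group())
    assert dec.positions[:3] == "GGG"
    assert dec.positions[3] == "C"  # 3'-most UMI base
    assert dec.positions == read.seq[:13][::-1]


def test_decompose_run_stopped_by_umi_base(arch_g3):
    """UMI ending in T, window GGG, non-G anchor right after: run is 3."""
    read = tk.ReadRecord("r", "ACGTACGTAT" + "GGG" + "ACCACGCC" + "AC" * 10)
    dec = tk.decompose_junction(read, 13, arch_g3)
    assert dec.g_run == 3


def test_decompose_rejects_anchor_in_window(arch_g3):
    read = tk.ReadRecord("r", "ACGTACGTACGGGGGAATTCTAAA")
    with pytest.raises(tk.DecompositionError):
        tk.decompose_junction(read, 5, arch_g3)


# ---------------------------------------------------------------------------
# positional_frequencies

def test_identical_decompositions_give_unit_fractions(arch_g3):
    read = tk.ReadRecord("r", "ACGTACGTAC" + "GGG" + "GGAATTCT" + "AC" * 10)
    dec = tk.decompose_junction(read, 13, arch_g3)
    table = tk.positional_frequencies([dec] * 100, 13)
    assert table.n_reads == 100
    assert np.all(table.fractions.max(axis=1) == 1.0)
    assert np.allclose(table.fractions.sum(axis=1), 1.0)


def test_empty_table_is_flagged_not_nan():
    table = tk.positional_frequencies([], 13)
    assert not table.has_data
    assert table.counts.sum() == 0
    with pytest.raises(ValueError):
        _ = table.fractions


def test_n_containing_reads_are_excluded(arch_g3):
    good = tk.decompose_junction(
        tk.ReadRecord("a", "ACGTACGTAC" + "GGG" + "GGAATTCT" + "AC" * 10), 13, arch_g3
    )
    with_n = tk.decompose_junction(
        tk.ReadRecord("b", "ACGTACGTNC" + "GGG" + "GGAATTCT" + "AC" * 10), 13, arch_g3
    )
    table = tk.positional_frequencies([good, with_n], 13)
    assert table.n_reads == 1
    assert table.n_excluded == 1


def test_simulated_nnn_reads_recover_g_gradient(spike_config_n3, arch_n3):
    """rNNN reads at error 0: G fraction at positions 1..3 lands in the 99%
    binomial CI of the configured 0.94/0.83/0.57 gradient."""
    reads, _ = tk.simulate_reads(spike_config_n3, 30_000)
    decs = [
        tk.decompose_junction(r, s, arch_n3)
        for r, s in tk.match_anchor(reads, SPIKE_ANCHOR, arch_n3)
    ]
    table = tk.positional_frequencies(decs, 13)
    for pos, p in zip((1, 2, 3), tk.DEFAULT_C_GRADIENT):
        half = 2.576 * np.sqrt(p * (1 - p) / table.n_reads)
        assert abs(table.base_fraction("G", pos) - p) < half, f"position {pos}"


# ---------------------------------------------------------------------------
# g_run_histogram

def test_histogram_agrees_with_regex_oracle():
    from oracles import make_g_run_reads, regex_g_run_counts

    reads = make_g_run_reads(1000, seed=19)
    hist = tk.g_run_histogram(reads, SPIKE_ANCHOR, 2, 8)
    oracle = regex_g_run_counts(reads, "GGAATTCT", 2, 8)
    assert dict(hist.counts) == oracle
    assert hist.n_total == len(reads)
    assert hist.n_matched <= len(reads)


def test_anchor_leading_g_correction():
    """5 Gs before AATTCT with anchor GGAATTCT: two belong to the anchor,
    so n = 3."""
    read = tk.ReadRecord("r", "ACTACTACTACTA" + "GGGGG" + "AATTCT" + "ACGT" * 5)
    hist = tk.g_run_histogram([read], SPIKE_ANCHOR, 2, 8)
    assert hist.counts[3] == 1
    assert sum(hist.counts.values()) == 1


def test_non_g_anchor_needs_no_correction():
    mt2a = tk.AnchorQuery("MT2A", "ACCACGCC")
    read = tk.ReadRecord("r", "ACTACTACTACTA" + "GGGG" + "ACCACGCC" + "ACGT" * 5)
    hist = tk.g_run_histogram([read], mt2a, 2, 8)
    assert hist.counts[4] == 1


def test_forced_k3_reads_put_all_mass_at_3(allc_g3_config):
    """δ(k=3), all-C, rGGG: the modeled junction run is 3 for every switched
    molecule, and reads whose UMI does not end in G (which would extend the
    measured run — the upper-bound ambiguity) report exactly n = 3."""
    reads, truth = tk.simulate_reads(allc_g3_config, 800)
    switched = truth[truth.switched]
    assert (switched.observed_g_run == 3).all()

    umi_by_id = dict(zip(truth.molecule_id, truth.umi))
    clean = [r for r in reads if not umi_by_id[r.id.split(":")[0]].endswith("G")]
    hist = tk.g_run_histogram(clean, SPIKE_ANCHOR, 2, 8)
    assert hist.counts[3] == hist.n_matched == len(clean) > 0
    assert all(c == 0 for n, c in hist.counts.items() if n != 3)


def test_all_g_anchor_rejected():
    with pytest.raises(tk.ConfigError):
        tk.g_run_histogram([], tk.AnchorQuery("bad", "GGGGGG"), 2, 8)


# ---------------------------------------------------------------------------
# major_site

def _site_reads(umi, transcript, offset, n, arch):
    body = umi + "GGG" + transcript[offset:]
    return [
        tk.ReadRecord(f"s{offset}:{i}", body[:40].ljust(40, "A")) for i in range(n)
    ]


TR = "CATTCGACTAGCATCGATTACGGATCCTAGCATGCATCCGGATTACA"


def test_single_site_fraction_one(arch_g3):
    reads = _site_reads("ACGTACGTAC", TR, 0, 50, arch_g3)
    offset, fraction = tk.major_site(reads, TR, arch_g3, probe_len=12)
    assert (offset, fraction) == (0, 1.0)


def test_mixture_recovers_modal_site(arch_g3):
    reads = _site_reads("ACGTACGTAC", TR, 0, 80, arch_g3) + _site_reads(
        "TTGCAATGCA", TR, 20, 20, arch_g3
    )
    offset, fraction = tk.major_site(reads, TR, arch_g3, probe_len=12)
    assert offset == 0
    assert fraction == pytest.approx(0.8)


def test_tie_breaks_to_five_prime_offset(arch_g3):
    reads = _site_reads("ACGTACGTAC", TR, 0, 10, arch_g3) + _site_reads(
        "TTGCAATGCA", TR, 20, 10, arch_g3
    )
    offset, fraction = tk.major_site(reads, TR, arch_g3, probe_len=12)
    assert offset == 0
    assert fraction == pytest.approx(0.5)


def test_no_signal_distinct_from_empty(arch_g3):
    with pytest.raises(ValueError, match="empty"):
        tk.major_site([], TR, arch_g3)
    junk = [tk.ReadRecord("r", "T" * 40)]
    with pytest.raises(tk.NoSignalError):
        tk.major_site(junk, TR, arch_g3)


# ---------------------------------------------------------------------------
# tso_capture_fraction

OBSERVED_TRINUC = {"GGG": 0.46, "AGG": 0.14, "CGG": 0.11, "TGG": 0.08}


def test_capture_worked_examples():
    assert tk.tso_capture_fraction(OBSERVED_TRINUC, "NGG") == pytest.approx(0.79)
    assert tk.tso_capture_fraction(OBSERVED_TRINUC, "GGG") == pytest.approx(0.46)
    assert tk.tso_capture_fraction(OBSERVED_TRINUC, "NNN") == pytest.approx(
        sum(OBSERVED_TRINUC.values())
    )


def test_capture_invalid_pattern():
    with pytest.raises(tk.ConfigError):
        tk.tso_capture_fraction(OBSERVED_TRINUC, "GGQ")
    with pytest.raises(tk.ConfigError):
        tk.tso_capture_fraction(OBSERVED_TRINUC, "GGGG")


@given(
    st.dictionaries(
        st.text(alphabet="ACGT", min_size=3, max_size=3),
        st.floats(0.0, 1.0 / 64.0),
        max_size=64,
    )
)
def test_capture_monotone_in_pattern_degeneracy(freqs):
    """GGG <= NGG <= NNG <= NNN over any frequency table."""
    vals = [
        tk.tso_capture_fraction(freqs, p) for p in ("GGG", "NGG", "NNG", "NNN")
    ]
    assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))


def test_simulated_trinuc_table_roughly_matches_reported_shares(
    spike_config_n3, arch_n3
):
    """Junction trinucleotides of simulated rNNN reads reproduce the
    GGG ~ 46% share implied by the independent positional gradient."""
    reads, _ = tk.simulate_reads(spike_config_n3, 20_000)
    decs = [
        tk.decompose_junction(r, s, arch_n3)
        for r, s in tk.match_anchor(reads, SPIKE_ANCHOR, arch_n3)
    ]
    freqs = tk.ribo_trinucleotide_frequencies(decs)
    expected_ggg = 0.94 * 0.83 * 0.57  # independent per-position model
    assert freqs["GGG"] == pytest.approx(expected_ggg, abs=0.02)
    ngg = tk.tso_capture_fraction(freqs, "NGG")
    assert ngg == pytest.approx(0.94 * 0.83, abs=0.02)
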
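"""Breakpoint detection against the exhaustive split-point oracle,
duplication calling, assembly modes, and insertion confirmation."""

import numpy as np
import pytest

from ctdna_integrate.genomes import CtDNAFragment, GenomeSequence, random_sequence, revcomp
from ctdna_integrate.simulate import simulate_coculture, simulate_reads
from ctdna_integrate.transitions import (
    Contig,
    TransitionDetector,
    assemble_or_ingest,
    confirm_and_call,
    count_structural_gain,
    detect_duplications,
    detect_transitions,
)
from ctdna_integrate.variants import VariantKey

from _oracles import max_cell_prefix, min_cell_suffix_start

ADAPTOR = "GCGCTCTGTGTGCT"


def make_fragment(rng, length=300, frag_id="fragX", with_adaptor=False) -> CtDNAFragment:
    core = random_sequence(length, rng)
    seq = ADAPTOR + core + ADAPTOR if with_adaptor else core
    return CtDNAFragment(
        fragment_id=frag_id,
        sequence=seq,
        origin=("donor1", 0, length),
        adaptor_5=with_adaptor,
        adaptor_3=with_adaptor,
    )


@pytest.fixture(scope="module")
def cell():
    rng = np.random.default_rng(17)
    return GenomeSequence("cell", {"chr1": random_sequence(30_000, rng)}, role="cell")


def test_cell_only_contig_yields_nothing(cell):
    rng = np.random.default_rng(1)
    frag = make_fragment(rng)
    contig = Contig("c", cell.sequences["chr1"][2000:4000])
    assert detect_transitions(contig, cell, [frag], ADAPTOR) == []


def test_constructed_chimera_breakpoint_and_adaptor_flag(cell):
    rng = np.random.default_rng(2)
    frag = make_fragment(rng, 300)
    flank = cell.sequences["chr1"][10_000:10_500]
    with_adaptor = Contig("c1", flank + frag.core + ADAPTOR)
    tps = detect_transitions(with_adaptor, cell, [frag], ADAPTOR)
    assert len(tps) == 1
    tp = tps[0]
    assert tp.orientation == "cell_to_ctdna"
    assert tp.breakpoint == max_cell_prefix(with_adaptor.sequence, cell.sequences)
    assert tp.adaptor_adjacent is True
    assert tp.cell_segment[0] == "chr1" and tp.cell_segment[3] == "+"
    assert tp.ctdna_segment[0] == "fragX"

    without = Contig("c2", flank + frag.core)
    tps = detect_transitions(without, cell, [frag], ADAPTOR)
    assert len(tps) == 1 and tps[0].adaptor_adjacent is False


def test_double_junction_contig(cell):
    rng = np.random.default_rng(3)
    frag = make_fragment(rng, 250)
    left = cell.sequences["chr1"][5_000:5_600]
    right = cell.sequences["chr1"][5_600:6_200]
    contig = Contig("dj", left + frag.core + right)
    tps = detect_transitions(contig, cell, [frag], ADAPTOR)
    assert [t.orientation for t in tps] == ["cell_to_ctdna", "ctdna_to_cell"]
    assert tps[0].breakpoint == max_cell_prefix(contig.sequence, cell.sequences)
    assert tps[1].breakpoint == min_cell_suffix_start(contig.sequence, cell.sequences)
    calls = confirm_and_call(tps, None, set(), [frag])
    assert len(calls) == 1 and len(calls[0].transitions) == 2


def test_breakpoints_match_split_point_oracle_and_strand_symmetry(cell):
    """Randomised chimeras: detector == exhaustive oracle; reverse
    complement mirrors breakpoints and flips orientation."""
    rng = np.random.default_rng(4)
    for i in range(25):
        frag = make_fragment(rng, int(rng.integers(150, 400)), f"f{i}")
        a = int(rng.integers(0, 28_000))
        flank_len = int(rng.integers(300, 900))
        contig = Contig(f"chi{i}", cell.sequences["chr1"][a : a + flank_len] + frag.core)
        tps = detect_transitions(contig, cell, [frag], ADAPTOR)
        assert len(tps) == 1
        expected = max_cell_prefix(contig.sequence, cell.sequences)
        assert tps[0].breakpoint == expected

        mirrored = Contig(f"chi{i}rc", revcomp(contig.sequence))
        tps_rc = detect_transitions(mirrored, cell, [frag], ADAPTOR)
        assert len(tps_rc) == 1
        assert tps_rc[0].orientation == "ctdna_to_cell"
        assert tps_rc[0].breakpoint == len(contig.sequence) - expected
        assert tps_rc[0].cell_segment[3] == "-"


def test_max_gap_monotonicity(cell):
    rng = np.random.default_rng(5)
    frag = make_fragment(rng, 300)
    flank = cell.sequences["chr1"][12_000:12_500]
    junk = random_sequence(12, rng)
    contig = Contig("gap", flank + junk + frag.core)
    previous: set = set()
    for max_gap in (0, 5, 11, 12, 20, 40):
        tps = detect_transitions(contig, cell, [frag], ADAPTOR, max_gap=max_gap)
        found = {(t.orientation, t.breakpoint) for t in tps}
        assert found >= previous
        previous = found
    assert previous  # detected at the largest gap


def test_confirmation_by_private_snvs(cell):
    rng = np.random.default_rng(6)
    frag = make_fragment(rng, 300)
    flank = cell.sequences["chr1"][20_000:20_600]
    contig = Contig("conf", flank + frag.core)
    tps = detect_transitions(contig, cell, [frag], ADAPTOR)
    private = {
        VariantKey("donor1", 40, "A", "T"),
        VariantKey("donor1", 120, "C", "G"),
        VariantKey("donor1", 9_999, "A", "C"),  # outside the fragment
    }
    calls = confirm_and_call(tps, None, private, [frag])
    assert len(calls) == 1
    call = calls[0]
    assert call.status == "confirmed"
    assert [k.pos for k in call.confirming_private_snvs] == [40, 120]
    assert call.cell_locus == ("chr1", 20_600)

    unconfirmed = confirm_and_call(tps, None, set(), [frag])[0]
    assert unconfirmed.status == "unconfirmed"
    assert unconfirmed.confirming_private_snvs == []


def test_structural_gain_summary(cell):
    empty = count_structural_gain([], [])
    assert (empty.insertions, empty.confirmed_insertions, empty.duplications) == (0, 0, 0)


def _dup_contig(cell, rng, dlen, flank=400):
    """Tandem duplication with unambiguous boundaries (no microhomology)."""
    seq = cell.sequences["chr1"]
    while True:
        start = int(rng.integers(1000, 20_000))
        if seq[start] != seq[start + dlen] and seq[start - 1] != seq[start + dlen - 1]:
            break
    contig = (
        seq[start - flank : start + dlen]
        + seq[start : start + dlen]
        + seq[start + dlen : start + dlen + flank]
    )
    return Contig(f"dup{dlen}", contig), start


@pytest.mark.parametrize("dlen,expected_events", [(12, 1), (9, 0), (10, 1)])
def test_duplication_min_length_boundary(cell, dlen, expected_events):
    rng = np.random.default_rng(100 + dlen)
    contig, start = _dup_contig(cell, rng, dlen)
    events = detect_duplications([contig], cell, min_len=10)
    assert len(events) == expected_events
    if events:
        ev = events[0]
        assert (ev.start, ev.end) == (start, start + dlen)
        assert ev.length == dlen
        assert ev.coculture_unique


def test_duplication_absent_on_reference_identical_contig(cell):
    contig = Contig("plain", cell.sequences["chr1"][3000:5000])
    assert detect_duplications([contig], cell) == []


def test_min_len_monotonicity(cell):
    rng = np.random.default_rng(7)
    contig, _ = _dup_contig(cell, rng, 25)
    n_prev = None
    for min_len in (10, 20, 25, 26, 40):
        n = len(detect_duplications([contig], cell, min_len=min_len))
        if n_prev is not None:
            assert n <= n_prev
        n_prev = n


def test_cell_contigs_clear_unique_flag(cell):
    rng = np.random.default_rng(8)
    contig, start = _dup_contig(cell, rng, 15)
    cell_copy = Contig("cellview", contig.sequence, source="cell")
    events = detect_duplications([contig], cell, cell_contigs=[cell_copy])
    assert len(events) == 1 and events[0].coculture_unique is False


def test_ingest_mode_round_trip(tmp_path, cell):
    fasta = tmp_path / "contigs.fasta"
    sub = GenomeSequence("x", {
        "a": cell.sequences["chr1"][:500],
        "b": cell.sequences["chr1"][600:1200],
        "c": cell.sequences["chr1"][2000:2400],
    }, role="coculture")
    sub.to_fasta(fasta)
    contigs = assemble_or_ingest(fasta, "ingest")
    assert [c.contig_id for c in contigs] == ["a", "b", "c"]
    assert contigs[0].sequence == sub.sequences["a"]
    with pytest.raises(ValueError):
        assemble_or_ingest(fasta, "unknown")


def test_perfect_mode_spans_each_junction(small_world):
    cell, _, _, fragments = small_world
    cocu, truth = simulate_coculture(cell, fragments[:5], seed=9)
    contigs = assemble_or_ingest(None, "perfect", truth=truth, genome=cocu,
                                 fragments=fragments[:5], flank=300)
    assert len(contigs) >= 5
    by_id = {f.fragment_id: f for f in fragments[:5]}
    for ins, contig in zip(truth.planted_insertions,
                           sorted(contigs, key=lambda c: c.contig_id.split("_")[-1])):
        pass  # order differs; just check every core is inside some contig
    for ins in truth.planted_insertions:
        core = by_id[ins.fragment_id].core
        assert any(core in c.sequence for c in contigs)


def test_greedy_assembly_reconstructs_contig():
    rng = np.random.default_rng(23)
    genome = GenomeSequence("g", {"c": random_sequence(5000, rng)})
    reads = simulate_reads(genome, 40, 150, (400, 40), 0.0, seed=24)
    contigs = assemble_or_ingest(reads, "greedy")
    # the extreme ends are only covered when a sampled insert starts/ends
    # exactly at the genome boundary, so compare the interior
    interior = genome.sequences["c"][50:-50]
    assert any(interior in c.sequence for c in contigs)
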
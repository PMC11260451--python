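"""Repeat scanning, the 100-nt transition window, chi-square enrichment
and tissue specificity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctdna_integrate.genomes import TEConsensus, random_sequence, revcomp
from ctdna_integrate.repeats import (
    enrichment_test,
    filter_transition_proximal,
    proximity_stats,
    scan_repeats,
    tissue_specific_elements,
)
from ctdna_integrate.transitions import InsertionCall, TransitionPoint

from _oracles import chi2_closed_form


@pytest.fixture(scope="module")
def library(small_world):
    return small_world[2]


def test_exact_copy_full_length_hit(library):
    te = library[0]
    rng = np.random.default_rng(1)
    subject = random_sequence(200, rng) + te.sequence + random_sequence(200, rng)
    hits = scan_repeats(subject, library)
    assert len(hits) == 1
    hit = hits[0]
    assert hit.te_name == te.name
    assert hit.strand == "+"
    assert hit.percent_identity == pytest.approx(100.0)
    assert (hit.start, hit.end) == (200, 200 + len(te.sequence))


def test_reverse_complement_hit_on_minus_strand(library):
    te = library[1]
    rng = np.random.default_rng(2)
    subject = random_sequence(150, rng) + revcomp(te.sequence) + random_sequence(150, rng)
    hits = scan_repeats(subject, library)
    assert [h.te_name for h in hits] == [te.name]
    assert hits[0].strand == "-"
    assert (hits[0].start, hits[0].end) == (150, 150 + len(te.sequence))


def test_random_sequence_has_no_hit(library):
    rng = np.random.default_rng(3)
    assert scan_repeats(random_sequence(1000, rng), library) == []


def test_hit_intervals_within_bounds(library):
    rng = np.random.default_rng(4)
    subject = library[2].sequence[: len(library[2].sequence) // 2] + random_sequence(80, rng)
    for hit in scan_repeats(subject, library):
        assert 0 <= hit.start < hit.end <= len(subject)


def _tp(breakpoint=500, adaptor=True, orientation="cell_to_ctdna"):
    return TransitionPoint(
        contig_id="c", breakpoint=breakpoint, orientation=orientation,
        cell_segment=("chr1", 0, breakpoint, "+"),
        ctdna_segment=("fragX", 0, 300, "+"),
        adaptor_adjacent=adaptor, junction_gap=0,
    )


def _hit(start, end):
    from ctdna_integrate.repeats import RepeatAnnotation

    return RepeatAnnotation("c", "AluSp", "SINE", start, end, "+", 100.0, 100.0)


@pytest.mark.parametrize("distance,kept", [(50, True), (100, True), (101, False), (150, False)])
def test_window_boundary_inclusive(distance, kept):
    tp = _tp(500)
    hit = _hit(500 + distance, 500 + distance + 120)
    result = filter_transition_proximal([hit], tp, window=100)
    assert bool(result) is kept


def test_hit_overlapping_breakpoint_kept_and_cell_side_dropped():
    tp = _tp(500)
    assert filter_transition_proximal([_hit(450, 550)], tp, window=100)
    assert not filter_transition_proximal([_hit(300, 480)], tp, window=100)


def test_adaptor_required_blocks_everything():
    tp = _tp(500, adaptor=False)
    hit = _hit(520, 620)
    assert filter_transition_proximal([hit], tp, window=100, require_adaptor=True) == []
    assert filter_transition_proximal([hit], tp, window=100, require_adaptor=False) == [hit]


def test_window_monotonicity():
    tp = _tp(500)
    hits = [_hit(500 + d, 620 + d) for d in (0, 40, 90, 140, 200)]
    previous: list = []
    for window in (10, 50, 100, 160, 250):
        kept = filter_transition_proximal(hits, tp, window=window)
        assert set(map(id, previous)) <= set(map(id, kept))
        previous = kept


def test_chi_square_null_table():
    res = enrichment_test((10, 90), (10, 90))
    assert res.chi_square == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)
    assert res.odds_ratio == pytest.approx(1.0)


def test_chi_square_matches_closed_form():
    res = enrichment_test((30, 70), (10, 90))
    assert res.chi_square == pytest.approx(chi2_closed_form(30, 70, 10, 90), abs=1e-9)
    assert res.dof == 1


@settings(max_examples=300, deadline=None, derandomize=True)
@given(st.tuples(*(st.integers(1, 10_000) for _ in range(4))))
def test_chi_square_agrees_with_closed_form_on_random_tables(cells):
    a, b, c, d = cells
    res = enrichment_test((a, b), (c, d))
    assert res.chi_square == pytest.approx(chi2_closed_form(a, b, c, d), rel=1e-12, abs=1e-9)
    assert 0.0 <= res.p_value <= 1.0


def test_zero_margin_is_an_error():
    with pytest.raises(ValueError):
        enrichment_test((0, 10), (0, 20))


def test_low_expected_counts_warn_and_report_exact():
    with pytest.warns(UserWarning):
        res = enrichment_test((3, 1), (1, 4))
    assert res.expected_warning and res.fisher_p is not None


def test_haldane_odds_ratio_with_zero_cell():
    res = enrichment_test((10, 0), (5, 5))
    assert res.odds_ratio == pytest.approx((10.5 * 5.5) / (0.5 * 5.5))


def test_yates_correction_reduces_statistic():
    plain = enrichment_test((30, 70), (10, 90), continuity_correction=False)
    yates = enrichment_test((30, 70), (10, 90), continuity_correction=True)
    assert yates.chi_square < plain.chi_square


def test_tissue_specific_examples():
    assert tissue_specific_elements({"AluSp": 3}, {}) == ["AluSp"]
    assert tissue_specific_elements({"AluSp": 3, "L2a": 1}, {"L2a": 2}) == ["AluSp"]
    assert tissue_specific_elements({"A": 2, "B": 2, "C": 1}, {"C": 1}) == ["A", "B"]


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    st.dictionaries(st.sampled_from("ABCDEFG"), st.integers(0, 5)),
    st.dictionaries(st.sampled_from("ABCDEFG"), st.integers(0, 5)),
)
def test_tissue_specific_exclusivity(matched, mismatched):
    out = tissue_specific_elements(matched, mismatched)
    observed_mismatched = {k for k, v in mismatched.items() if v > 0}
    assert set(out) & observed_mismatched == set()
    assert all(matched.get(name, 0) > 0 for name in out)


def _call(distance):
    return InsertionCall(
        transitions=[], cell_locus=("chr1", 100), fragment_id="f",
        confirming_private_snvs=[], distance_to_origin=distance,
    )


def test_proximity_stats_extremes():
    all_zero = [_call(0) for _ in range(5)]
    assert proximity_stats(all_zero, window=1000).proximal_fraction == 1.0
    inter = [_call(None) for _ in range(5)]
    summary = proximity_stats(inter, window=1000)
    assert summary.proximal_fraction == 0.0
    assert summary.n_inter_contig == 5
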
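"""Caller behaviour, set logic, VAF shift and tumor-fraction estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctdna_integrate.genomes import GenomeSequence
from ctdna_integrate.simulate import (
    SimulationConfig,
    simulate_cfdna_mixture,
    simulate_genomes,
    simulate_reads,
)
from ctdna_integrate.variants import (
    SNVRecord,
    VariantKey,
    call_snvs,
    estimate_tumor_fraction,
    keys_of,
    read_vcf,
    snvs_of_interest,
    vaf_shift,
    venn_partition,
    write_vcf,
)

from _oracles import fisher_two_sided_enum, soi_triple_loop, venn_triple_loop


def _pileup(ref: GenomeSequence, entries: dict[int, dict[str, int]]) -> dict[str, np.ndarray]:
    contig = next(iter(ref.sequences))
    arr = np.zeros((len(ref.sequences[contig]), 4), dtype=np.int32)
    order = "ACGT"
    for pos, bases in entries.items():
        for base, n in bases.items():
            arr[pos, order.index(base)] = n
    return {contig: arr}


@pytest.fixture(scope="module")
def tiny_ref():
    return GenomeSequence("cell", {"chr1": "ACGT" * 50}, role="cell")


def test_no_record_without_alt_support(tiny_ref):
    counts = _pileup(tiny_ref, {10: {"G": 100}})  # ref at pos 10 is G
    assert call_snvs(counts, tiny_ref) == []


def test_af_threshold_inclusive_at_1_in_100(tiny_ref):
    # ref at pos 10 is G (pattern ACGT); alt T at 1/100 == threshold
    counts = _pileup(tiny_ref, {10: {"G": 99, "T": 1}})
    records = call_snvs(counts, tiny_ref, af_threshold=0.01, min_depth=8)
    assert len(records) == 1
    rec = records[0]
    assert (rec.ref_allele, rec.alt_allele, rec.depth_ref, rec.depth_alt) == ("G", "T", 99, 1)
    assert rec.af == pytest.approx(0.01)
    # just under threshold: 1 in 101
    counts = _pileup(tiny_ref, {10: {"G": 100, "T": 1}})
    assert call_snvs(counts, tiny_ref, af_threshold=0.01) == []


def test_min_depth_floor(tiny_ref):
    counts = _pileup(tiny_ref, {10: {"G": 4, "T": 3}})
    assert call_snvs(counts, tiny_ref, min_depth=8) == []
    assert len(call_snvs(counts, tiny_ref, min_depth=7)) == 1


def test_multiallelic_decomposition(tiny_ref):
    counts = _pileup(tiny_ref, {10: {"G": 60, "A": 20, "T": 20}})
    records = call_snvs(counts, tiny_ref)
    assert [(r.alt_allele, r.depth_alt) for r in records] == [("A", 20), ("T", 20)]


def test_threshold_monotonicity(tiny_ref, rng):
    entries = {
        int(p): {"G" if p % 4 == 2 else "A": int(rng.integers(5, 80)),
                 "C": int(rng.integers(0, 30))}
        for p in rng.choice(200, size=30, replace=False)
    }
    counts = _pileup(tiny_ref, entries)
    previous = None
    for thr in (0.01, 0.05, 0.2, 0.5):
        calls = {r.key for r in call_snvs(counts, tiny_ref, af_threshold=thr, min_depth=1)}
        if previous is not None:
            assert calls <= previous
        previous = calls


def test_caller_recovers_planted_snvs_exactly():
    """50:50 cell/donor read mixture at 30x: every donor SNV called at
    AF ~ 0.5, nothing else (error-free reads)."""
    cfg = SimulationConfig(n_contigs=1, contig_length=50_000, donor_snv_rate=1e-3)
    cell, donor, _ = simulate_genomes(cfg, seed=31)
    reads_c = simulate_reads(cell, 15, 100, (300, 30), 0.0, seed=32)
    reads_d = simulate_reads(donor, 15, 100, (300, 30), 0.0, seed=33)
    reads_c.pairs.extend(reads_d.pairs)
    records = call_snvs(reads_c, cell, af_threshold=0.01, min_depth=8)
    called = {(r.contig, r.pos, r.ref_allele, r.alt_allele) for r in records}
    truth = set(donor.private_snvs)
    assert called == truth
    for r in records:
        assert 0.2 < r.af < 0.8


def test_soi_examples():
    A = VariantKey("chr1", 1, "A", "T")
    B = VariantKey("chr1", 2, "C", "G")
    C = VariantKey("chr1", 3, "G", "A")
    soi, _ = snvs_of_interest(set(), {A}, {A})
    assert soi == {A}
    soi, _ = snvs_of_interest({B}, {A, B}, {B, C})
    assert soi == set()


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.tuples(*(st.sets(st.integers(0, 60)) for _ in range(3))))
def test_soi_and_venn_match_triple_loop(sets):
    cell, ctdna, cocu = ({VariantKey("c", i, "A", "T") for i in s} for s in sets)
    soi, venn = snvs_of_interest(cell, ctdna, cocu)
    assert soi == soi_triple_loop(cell, ctdna, cocu)
    assert venn == venn_triple_loop(cell, ctdna, cocu)
    assert sum(venn.values()) == len(cell | ctdna | cocu)


def test_vaf_shift_arithmetic_and_null():
    key = VariantKey("chr1", 5, "A", "T")
    cell = SNVRecord("chr1", 5, "A", "T", 100, 0)
    cocu = SNVRecord("chr1", 5, "A", "T", 90, 10)
    shift = vaf_shift(key, cell, cocu)
    assert shift.delta_af == pytest.approx(0.10)
    same = vaf_shift(key, SNVRecord("chr1", 5, "A", "T", 50, 50),
                     SNVRecord("chr1", 5, "A", "T", 50, 50))
    assert same.delta_af == 0.0
    assert same.p_value == pytest.approx(1.0)


def test_vaf_shift_p_matches_hypergeometric_enumeration():
    key = VariantKey("chr1", 5, "A", "T")
    cases = [((50, 0), (40, 10)), ((30, 5), (20, 15)), ((10, 1), (9, 2))]
    for (rc_, ac), (rx, ax) in cases:
        shift = vaf_shift(key, SNVRecord("chr1", 5, "A", "T", rc_, ac),
                          SNVRecord("chr1", 5, "A", "T", rx, ax))
        assert shift.p_value == pytest.approx(fisher_two_sided_enum(rc_, ac, rx, ax), rel=1e-6)


def test_vaf_shift_absent_cell_and_zero_depth():
    key = VariantKey("chr1", 5, "A", "T")
    cocu = SNVRecord("chr1", 5, "A", "T", 90, 10)
    shift = vaf_shift(key, None, cocu)
    assert shift.af_cell == 0.0 and shift.delta_af == pytest.approx(0.1)
    flagged = vaf_shift(key, None, SNVRecord("chr1", 5, "A", "T", 0, 0))
    assert flagged.flagged


def test_tumor_fraction_extremes_and_recovery():
    cfg = SimulationConfig(n_contigs=1, contig_length=60_000, donor_snv_rate=2e-3)
    cell, donor, _ = simulate_genomes(cfg, seed=41)
    tumor_keys = {VariantKey(c, p, r, a) for c, p, r, a in donor.private_snvs}

    pure = simulate_cfdna_mixture(cell, donor, 1.0, 200, seed=42)
    assert estimate_tumor_fraction(pure, tumor_keys).fraction == 1.0
    none = simulate_cfdna_mixture(cell, donor, 0.0, 200, seed=43)
    assert estimate_tumor_fraction(none, tumor_keys).fraction == 0.0

    mix = simulate_cfdna_mixture(cell, donor, 0.8, 600, seed=44)
    est = estimate_tumor_fraction(mix, tumor_keys)
    half = 1.96 * np.sqrt(0.8 * 0.2 / est.n_informative)
    assert 0.8 - half <= est.fraction <= 0.8 + half

    with pytest.raises(ValueError):
        estimate_tumor_fraction([], tumor_keys)


def test_vcf_round_trip(tmp_path, tiny_ref):
    records = [
        SNVRecord("chr1", 9, "C", "T", 30, 10, "coculture"),
        SNVRecord("chr1", 42, "G", "A", 5, 5, "coculture"),
    ]
    path = tmp_path / "x.vcf"
    write_vcf(records, path, tiny_ref)
    back = read_vcf(path)
    assert [(r.contig, r.pos, r.ref_allele, r.alt_allele, r.depth_ref, r.depth_alt) for r in back] == [
        (r.contig, r.pos, r.ref_allele, r.alt_allele, r.depth_ref, r.depth_alt) for r in records
    ]
    assert keys_of(back) == keys_of(records)
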
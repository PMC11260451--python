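"""Generator contracts: determinism, conservation, calibration, adaptors."""

import numpy as np
import pytest

from ctdna_integrate.genomes import PACBIO_ADAPTOR, revcomp
from ctdna_integrate.simulate import (
    SimulationConfig,
    fragment_genome,
    make_cassette,
    simulate_cassette_integration,
    simulate_coculture,
    simulate_ctdna,
    simulate_genomes,
    simulate_reads,
)


def test_zero_snv_rate_gives_identical_donor(small_config):
    cfg = SimulationConfig(**{**small_config.to_dict(), "donor_snv_rate": 0.0})
    cell, donor, _ = simulate_genomes(cfg, seed=1)
    assert cell.sequences == donor.sequences
    assert donor.private_snvs == []


def test_invalid_rate_rejected(small_config):
    cfg = SimulationConfig(**{**small_config.to_dict(), "donor_snv_rate": 1.5})
    with pytest.raises(ValueError):
        simulate_genomes(cfg, seed=1)


def test_snv_count_matches_sequence_diff_and_binomial():
    cfg = SimulationConfig(n_contigs=1, contig_length=100_000, donor_snv_rate=0.001)
    cell, donor, _ = simulate_genomes(cfg, seed=5)
    diff = [
        i for i, (a, b) in enumerate(zip(cell.sequences["chr1"], donor.sequences["chr1"]))
        if a != b
    ]
    recorded = [(pos, ref, alt) for _c, pos, ref, alt in donor.private_snvs]
    assert diff == [p for p, _r, _a in recorded]
    for pos, ref, alt in recorded:
        assert cell.sequences["chr1"][pos] == ref
        assert donor.sequences["chr1"][pos] == alt
    # 4 sigma of Binomial(100000, 0.001): mean 100, sd ~ 10
    assert abs(len(diff) - 100) < 4 * np.sqrt(100_000 * 0.001 * 0.999)


def test_genomes_deterministic(small_config):
    a = simulate_genomes(small_config, seed=11)
    b = simulate_genomes(small_config, seed=11)
    assert a[0].sequences == b[0].sequences
    assert a[1].sequences == b[1].sequences
    assert [(t.name, t.sequence) for t in a[2]] == [(t.name, t.sequence) for t in b[2]]


def test_te_library_labels_and_nonhomology(small_world):
    _, _, library, _ = small_world
    names = [t.name for t in library]
    assert len(names) == len(set(names))
    assert all(len(t.sequence) >= 50 for t in library)
    # mutual non-homology above the scan cutoff, via the repeat scanner itself
    from ctdna_integrate.repeats import scan_repeats

    for te in library:
        others = [o for o in library if o.name != te.name]
        assert scan_repeats(te.sequence, others, min_score=40.0) == []


def test_fragments_carry_adaptors_and_are_donor_substrings(small_world):
    _, donor, _, fragments = small_world
    for frag in fragments:
        assert frag.sequence.startswith(PACBIO_ADAPTOR)
        assert frag.sequence.endswith(PACBIO_ADAPTOR)
        contig, start, end = frag.origin
        assert donor.sequences[contig][start:end] == frag.core


def test_te_end_probability_zero_plants_nothing(small_config):
    _, donor, library = simulate_genomes(small_config, seed=2)
    frags = simulate_ctdna(donor, library, 10, te_end_probability=0.0, seed=3)
    assert all(not f.planted_te_names for f in frags)


def test_te_end_probability_one_verified_by_scanner(small_world):
    _, _, library, fragments = small_world
    from ctdna_integrate.repeats import scan_repeats

    for frag in fragments:
        assert frag.planted_te_names
        hits = scan_repeats(frag.core, library, subject_id=frag.fragment_id)
        near_end = [
            h for h in hits
            if h.start <= 100 or (len(frag.core) - h.end) <= 100
        ]
        assert near_end, f"{frag.fragment_id}: planted TE not recovered near an end"
        assert frag.planted_te_names[0] in {h.te_name for h in near_end}


def test_coculture_null_case(small_world):
    cell, _, _, fragments = small_world
    cocu, truth = simulate_coculture(cell, fragments, insertion_rate=0.0,
                                     duplication_rate=0.0, seed=4)
    assert cocu.sequences == cell.sequences
    assert not truth.planted_insertions and not truth.planted_duplications


def test_coculture_length_conservation(small_world):
    cell, _, _, fragments = small_world
    cocu, truth = simulate_coculture(cell, fragments, insertion_rate=1.0,
                                     duplication_rate=5e-5, seed=5)
    expected = (
        len(cell)
        + sum(len(f.core) for f in fragments)
        + sum(d.length for d in truth.planted_duplications)
    )
    assert len(cocu) == expected
    assert len(truth.planted_insertions) == len(fragments)


def test_planted_cores_recoverable_at_recorded_loci(small_world):
    cell, _, _, fragments = small_world
    cocu, truth = simulate_coculture(cell, fragments, seed=6)
    by_id = {f.fragment_id: f for f in fragments}
    for ins in truth.planted_insertions:
        core = by_id[ins.fragment_id].core
        got = cocu.sequences[ins.contig][ins.cocu_position : ins.cocu_position + len(core)]
        assert got == core


def test_proximity_bias_recovered_in_truth():
    cfg = SimulationConfig(n_contigs=2, contig_length=100_000, donor_snv_rate=5e-4)
    cell, donor, library = simulate_genomes(cfg, seed=9)
    frags = simulate_ctdna(donor, library, 100, te_end_probability=0.0, seed=10)
    _, truth = simulate_coculture(cell, frags, proximity_bias=0.8,
                                  proximity_window=10_000, seed=11)
    prox = sum(
        1 for i in truth.planted_insertions
        if i.distance_to_origin is not None and i.distance_to_origin <= 10_000
    )
    frac = prox / len(truth.planted_insertions)
    assert 0.8 - 1.96 * np.sqrt(0.8 * 0.2 / 100) <= frac <= 0.8 + 1.96 * np.sqrt(0.8 * 0.2 / 100) + 0.03


def test_reads_error_free_match_genome_and_depth(toy_genome):
    reads = simulate_reads(toy_genome, coverage=30, read_length=100,
                           insert_size=(300, 30), error_rate=0.0, seed=12)
    seq = toy_genome.sequences["chr1"]
    depth = np.zeros(len(seq), dtype=int)
    for pair in reads.pairs[:200]:
        for start, bases in pair.genomic_segments():
            assert seq[start : start + len(bases)] == bases
    for pair in reads.pairs:
        for start, bases in pair.genomic_segments():
            depth[start : start + len(bases)] += 1
    assert abs(depth.mean() - 30) / 30 < 0.1


def test_reads_deterministic_fastq(tmp_path, toy_genome):
    paths = []
    for sub in ("a", "b"):
        d = tmp_path / sub
        d.mkdir()
        rs = simulate_reads(toy_genome, 5, 100, (300, 30), 0.01, seed=13)
        paths.append(rs.write_fastq(d / "reads"))
    import gzip

    for p1, p2 in zip(*paths):
        assert gzip.open(p1).read() == gzip.open(p2).read()


def test_read_parameter_validation(toy_genome):
    with pytest.raises(ValueError):
        simulate_reads(toy_genome, coverage=0, seed=1)
    with pytest.raises(ValueError):
        simulate_reads(toy_genome, coverage=10, read_length=400, insert_size=(300, 30), seed=1)


def test_cassette_integration_bookkeeping(toy_genome):
    cassette = make_cassette(800, seed=20)
    modified, truth = simulate_cassette_integration(toy_genome, cassette, n_sites=0, seed=21)
    assert modified.sequences == toy_genome.sequences

    modified, truth = simulate_cassette_integration(toy_genome, cassette, n_sites=2, seed=22)
    assert len(truth.cassette_sites) == 2
    cas = next(iter(cassette.sequences.values()))
    offset = 0
    for contig, pos in truth.cassette_sites:
        got = modified.sequences[contig][pos + offset : pos + offset + len(cas)]
        assert got == cas
        offset += len(cas)


def test_fragment_genome_liftover_maps_core_only(small_world):
    _, donor, _, fragments = small_world
    genome, pm = fragment_genome(fragments)
    frag = fragments[0]
    contig, start, end = frag.origin
    a = frag.core_offset
    assert pm.map_position(frag.fragment_id, a) == (contig, start)
    assert pm.map_position(frag.fragment_id, a + len(frag.core) - 1) == (contig, end - 1)
    assert pm.map_position(frag.fragment_id, 0) is None  # adaptor base
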
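"""End-to-end orchestration: simulate -> call -> intersect -> detect ->
annotate -> enrich -> report.

A run emulates the full coculture experiment: a matched arm (ctDNA and
recipient cell of the same tumor type, where integration happens) and a
smaller mismatched arm (ctDNA from the other tumor type), plus an
optional transgene-cassette scenario. Every stage is also exposed as a
library function / CLI subcommand operating on files, so external tool
output (a real assembler's contigs, a real caller's VCF) can be swapped
in at any stage boundary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import repeats, transgene, transitions, variants
from .genomes import GenomeSequence, PACBIO_ADAPTOR, write_fragments, write_te_library
from .simulate import (
    SimulationConfig,
    TruthTable,
    fragment_genome,
    make_cassette,
    simulate_cassette_integration,
    simulate_coculture,
    simulate_ctdna,
    simulate_genomes,
    simulate_reads,
)

logger = logging.getLogger("ctdna_integrate")


@dataclass
class RunConfig:
    """Full configuration of a pipeline run.

    Defaults are the documented demo conditions: 20 integrated fragments
    (TE-end probability 0.9), 20 non-integrated background fragments
    (TE-end probability 0.2), a 10-fragment mismatched arm, 30x reads,
    proximity bias 0.8 in a 10 kb window, AF threshold 0.01 and the
    100-nt TE window.
    """

    seed: int = 1
    sim: SimulationConfig = field(default_factory=lambda: SimulationConfig(n_fragments=20))
    # arm sizes / TE probabilities (TE-bearing fragments integrate)
    te_end_probability_integrated: float = 0.9
    te_end_probability_background: float = 0.2
    n_background_fragments: int = 20
    n_mismatched_fragments: int = 10
    mismatched_insertion_rate: float = 1.0
    matched_tissue: str = "MM"
    mismatched_tissue: str = "PC"
    # caller
    af_threshold: float = 0.01
    min_depth: int = 8
    # transitions
    anchor_k: int = 31
    max_gap: int = 20
    adaptor: str = PACBIO_ADAPTOR
    adaptor_search_window: int = 30
    contig_flank: int = 600
    # repeats / enrichment
    te_window: int = 100
    require_adaptor: bool = True
    min_score: float = 40.0
    min_identity: float = 0.80
    continuity_correction: bool = False
    min_dup_len: int = 10
    # transgene scenario
    run_transgene: bool = True
    n_cassette_sites: int = 2
    cassette_length: int = 1500
    transgene_min_support: int = 3
    # evaluation
    truth_tolerance: int = 50

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "sim" in d and isinstance(d["sim"], dict):
            d["sim"] = SimulationConfig.from_dict(d["sim"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(payload)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


@dataclass
class RunReport:
    """Consolidated, JSON-serialisable run summary.

    Every number here is recomputable from the stage outputs written to
    the run directory.
    """

    config: dict
    stage_counts: dict
    venn: dict
    soi_count: int
    vaf_shift_mean_delta: float | None
    structural_gain: dict
    enrichment: dict
    tissue_specific: list
    proximity: dict
    tumor_fraction: float | None
    transgene_sites: list
    truth_comparison: dict
    checksums: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1, default=str))


def _seed(base: int, salt: int) -> int:
    return (base * 1_000 + salt) % (2**31 - 1)


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> RunReport:
    """Run the whole analysis on one simulated coculture experiment."""
    sim = config.sim
    seed = config.seed
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        config.to_file(out / "config.yaml")
    stage_counts: dict[str, int] = {}

    # --- simulate -----------------------------------------------------
    cell, donor, library = simulate_genomes(sim, seed)
    logger.info("simulate_genomes: %d contigs, %d TE consensi", sim.n_contigs, len(library))
    # the mismatched arm emulates ctDNA from a different patient: it gets
    # its own donor so matched-arm TE plants cannot leak into its fragments
    donor_mm = donor.copy(name="donor_mm")
    donor_mm.private_snvs = list(donor.private_snvs)  # type: ignore[attr-defined]

    frags_int = simulate_ctdna(
        donor, library, sim.n_fragments,
        size_model=(sim.fragment_median, sim.fragment_sigma),
        te_end_probability=config.te_end_probability_integrated,
        adaptor=sim.adaptor, seed=_seed(seed, 1),
        te_end_window=sim.te_end_window, fragment_min=sim.fragment_min,
        ensure_private_snv=sim.ensure_private_snv,
        tissue=config.matched_tissue, id_prefix="fi",
    )
    frags_bg = simulate_ctdna(
        donor, library, config.n_background_fragments,
        size_model=(sim.fragment_median, sim.fragment_sigma),
        te_end_probability=config.te_end_probability_background,
        adaptor=sim.adaptor, seed=_seed(seed, 2),
        te_end_window=sim.te_end_window, fragment_min=sim.fragment_min,
        ensure_private_snv=sim.ensure_private_snv,
        tissue=config.matched_tissue, id_prefix="fb",
    )
    frags_mm = simulate_ctdna(
        donor_mm, library, config.n_mismatched_fragments,
        size_model=(sim.fragment_median, sim.fragment_sigma),
        te_end_probability=config.te_end_probability_integrated,
        adaptor=sim.adaptor, seed=_seed(seed, 3),
        te_end_window=sim.te_end_window, fragment_min=sim.fragment_min,
        ensure_private_snv=sim.ensure_private_snv,
        tissue=config.mismatched_tissue, id_prefix="fx",
    )
    stage_counts["ctdna_fragments"] = len(frags_int) + len(frags_bg)

    coculture, truth = simulate_coculture(
        cell, frags_int,
        insertion_rate=sim.insertion_rate,
        proximity_bias=sim.proximity_bias,
        proximity_window=sim.proximity_window,
        duplication_rate=sim.duplication_rate,
        seed=_seed(seed, 4),
        duplication_length_range=sim.duplication_length_range,
    )
    coculture_mm, truth_mm = simulate_coculture(
        cell, frags_mm,
        insertion_rate=config.mismatched_insertion_rate,
        proximity_bias=sim.proximity_bias,
        proximity_window=sim.proximity_window,
        duplication_rate=0.0,
        seed=_seed(seed, 5),
    )
    stage_counts["planted_insertions"] = len(truth.planted_insertions)
    stage_counts["planted_duplications"] = len(truth.planted_duplications)

    ctdna_genome, ctdna_map = fragment_genome(frags_int + frags_bg)
    reads_cell = simulate_reads(cell, sim.coverage, sim.read_length,
                                (sim.insert_mean, sim.insert_sd), sim.error_rate, _seed(seed, 6))
    reads_ctdna = simulate_reads(ctdna_genome, sim.coverage, sim.read_length,
                                 (sim.insert_mean, sim.insert_sd), sim.error_rate, _seed(seed, 7))
    reads_cocu = simulate_reads(coculture, sim.coverage, sim.read_length,
                                (sim.insert_mean, sim.insert_sd), sim.error_rate, _seed(seed, 8))
    stage_counts["read_pairs"] = len(reads_cell) + len(reads_ctdna) + len(reads_cocu)

    if out is not None:
        cell.to_fasta(out / "cell.fasta")
        donor.to_fasta(out / "donor.fasta")
        coculture.to_fasta(out / "coculture.fasta")
        write_te_library(library, out / "te_library.fasta")
        write_fragments(frags_int + frags_bg, out / "ctdna_fragments.fasta")
        truth.to_json(out / "truth.json")
        reads_cocu.write_fastq(out / "coculture")

    # --- variant calling and three-way set logic ----------------------
    recs_cell = variants.call_snvs(reads_cell, cell, config.af_threshold,
                                   config.min_depth, "cell")
    recs_ctdna = variants.call_snvs(reads_ctdna, cell, config.af_threshold,
                                    config.min_depth, "ctDNA", liftover=ctdna_map)
    recs_cocu = variants.call_snvs(reads_cocu, cell, config.af_threshold,
                                   config.min_depth, "coculture", liftover=truth.liftover)
    stage_counts["snvs_cell"] = len(recs_cell)
    stage_counts["snvs_ctdna"] = len(recs_ctdna)
    stage_counts["snvs_coculture"] = len(recs_cocu)

    keys_cell = variants.keys_of(recs_cell)
    keys_ctdna = variants.keys_of(recs_ctdna)
    keys_cocu = variants.keys_of(recs_cocu)
    soi, venn = variants.snvs_of_interest(keys_cell, keys_ctdna, keys_cocu)
    ctdna_private = keys_ctdna - keys_cell

    cocu_by_key = {r.key: r for r in recs_cocu}
    cell_by_key = {r.key: r for r in recs_cell}
    shifts = [
        variants.vaf_shift(k, cell_by_key.get(k), cocu_by_key[k])
        for k in sorted(soi)
        if k in cocu_by_key
    ]
    mean_delta = (
        sum(s.delta_af for s in shifts) / len(shifts) if shifts else None
    )

    if out is not None:
        variants.write_vcf(recs_cell, out / "cell.vcf", cell)
        variants.write_vcf(recs_ctdna, out / "ctdna.vcf", cell)
        variants.write_vcf(recs_cocu, out / "coculture.vcf", cell)

    # --- transitions, insertions, duplications ------------------------
    all_frags = frags_int + frags_bg
    contigs = (
        transitions.assemble_or_ingest(
            None, "perfect", truth=truth, genome=coculture,
            fragments=frags_int, flank=config.contig_flank,
        )
        if truth.planted_insertions or truth.planted_duplications
        else []
    )
    detector = transitions.TransitionDetector(
        cell, all_frags, config.adaptor, config.anchor_k,
        config.max_gap, config.adaptor_search_window,
    )
    tps: list[transitions.TransitionPoint] = []
    contigs_with_tp: set[str] = set()
    for contig in contigs:
        found = detector.detect(contig)
        tps.extend(found)
        if found:
            contigs_with_tp.add(contig.contig_id)
    calls = transitions.confirm_and_call(tps, soi, ctdna_private, all_frags)
    stage_counts["transitions"] = len(tps)
    stage_counts["insertion_calls"] = len(calls)

    dup_contigs = [c for c in contigs if c.contig_id not in contigs_with_tp]
    dups = transitions.detect_duplications(
        dup_contigs, cell, config.min_dup_len, anchor_k=config.anchor_k
    )
    stage_counts["duplications"] = len(dups)
    gain = transitions.count_structural_gain(calls, dups, sim.proximity_window)

    # mismatched arm (tissue specificity only)
    contigs_mm = (
        transitions.assemble_or_ingest(
            None, "perfect", truth=truth_mm, genome=coculture_mm,
            fragments=frags_mm, flank=config.contig_flank,
        )
        if truth_mm.planted_insertions
        else []
    )
    detector_mm = transitions.TransitionDetector(
        cell, frags_mm, config.adaptor, config.anchor_k,
        config.max_gap, config.adaptor_search_window,
    )
    tps_mm = [t for c in contigs_mm for t in detector_mm.detect(c)]
    calls_mm = transitions.confirm_and_call(tps_mm, None, set(), frags_mm)

    if out is not None:
        transitions.transitions_to_tsv(tps, out / "transitions.tsv")
        transitions.calls_to_tsv(calls, out / "insertions.tsv")
        transitions.duplications_to_bed(dups, out / "duplications.bed")

    # --- repeats, enrichment, tissue specificity ----------------------
    te_int = repeats.fragment_te_presence(frags_int, library, config.te_window,
                                          config.min_score, config.min_identity)
    te_bg = repeats.fragment_te_presence(frags_bg, library, config.te_window,
                                         config.min_score, config.min_identity)
    te_mm = repeats.fragment_te_presence(frags_mm, library, config.te_window,
                                         config.min_score, config.min_identity)

    inserted_ids = {c.fragment_id for c in calls}
    integrated_flags = [bool(te_int[f.fragment_id]) for f in frags_int if f.fragment_id in inserted_ids]
    non_integrated_flags = [bool(te_bg[f.fragment_id]) for f in frags_bg]
    try:
        enrich = repeats.enrichment_test(
            integrated_flags, non_integrated_flags, config.continuity_correction
        ).to_dict()
    except ValueError as exc:
        enrich = {"error": str(exc)}

    matched_multiset: dict[str, int] = {}
    for call in calls:
        for hit in te_int.get(call.fragment_id, []):
            matched_multiset[hit.te_name] = matched_multiset.get(hit.te_name, 0) + 1
    mismatched_multiset: dict[str, int] = {}
    for call in calls_mm:
        for hit in te_mm.get(call.fragment_id, []):
            mismatched_multiset[hit.te_name] = mismatched_multiset.get(hit.te_name, 0) + 1
    specific = repeats.tissue_specific_elements(matched_multiset, mismatched_multiset)

    origins = {f.fragment_id: f.origin for f in all_frags}
    prox = repeats.proximity_stats(calls, sim.proximity_window, origins)

    # --- tumor fraction (cfDNA mixture companion analysis) -------------
    from .simulate import simulate_cfdna_mixture

    tumor_keys = {
        variants.VariantKey(c, p, ref, alt) for c, p, ref, alt in donor.private_snvs  # type: ignore[attr-defined]
    }
    tumor_fraction = None
    if tumor_keys:
        mixture = simulate_cfdna_mixture(cell, donor, 0.8, 400,
                                         (sim.fragment_median, sim.fragment_sigma),
                                         _seed(seed, 9), sim.fragment_min)
        try:
            tumor_fraction = variants.estimate_tumor_fraction(mixture, tumor_keys).fraction
        except ValueError:
            tumor_fraction = None

    # --- transgene scenario -------------------------------------------
    transgene_sites: list[dict] = []
    truth_cassette = None
    if config.run_transgene:
        cassette = make_cassette(config.cassette_length, _seed(seed, 10))
        modified, truth_cassette = simulate_cassette_integration(
            cell, cassette, config.n_cassette_sites, _seed(seed, 11)
        )
        reads_tg = simulate_reads(modified, sim.coverage, sim.read_length,
                                  (sim.insert_mean, sim.insert_sd), sim.error_rate, _seed(seed, 12))
        dpairs = transgene.find_discordant_pairs(reads_tg, cell, cassette, config.anchor_k)
        sites = transgene.cluster_sites(
            dpairs, (sim.insert_mean, sim.insert_sd), config.transgene_min_support,
            genome_length=len(cell),
        )
        transgene_sites = [dataclasses.asdict(s) for s in sites]
        stage_counts["discordant_pairs"] = len(dpairs)
        if out is not None:
            transgene.sites_to_tsv(sites, out / "transgene_sites.tsv")

    # --- truth comparison ----------------------------------------------
    comparison = compare_to_truth(
        calls, dups,
        [(s["contig"], (s["start"] + s["end"]) // 2) for s in transgene_sites],
        truth, truth_cassette, tolerance=config.truth_tolerance,
        insert_span=sim.insert_mean + 3 * sim.insert_sd,
    )

    report = RunReport(
        config=config.to_dict(),
        stage_counts=stage_counts,
        venn=venn,
        soi_count=len(soi),
        vaf_shift_mean_delta=mean_delta,
        structural_gain=gain.to_dict(),
        enrichment=enrich,
        tissue_specific=specific,
        proximity=prox.to_dict(),
        tumor_fraction=tumor_fraction,
        transgene_sites=transgene_sites,
        truth_comparison=comparison,
    )
    if out is not None:
        report.checksums = {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "report.json"
        }
        report.to_json(out / "report.json")
    return report


def _greedy_match(
    called: Sequence[tuple[str, int]],
    truth_loci: Sequence[tuple[str, int]],
    tolerance: float,
) -> int:
    """One-to-one greedy matching by distance; returns the number matched."""
    candidates = []
    for i, (c_contig, c_pos) in enumerate(called):
        for j, (t_contig, t_pos) in enumerate(truth_loci):
            if c_contig == t_contig and abs(c_pos - t_pos) <= tolerance:
                candidates.append((abs(c_pos - t_pos), i, j))
    candidates.sort()
    used_c: set[int] = set()
    used_t: set[int] = set()
    matched = 0
    for _dist, i, j in candidates:
        if i in used_c or j in used_t:
            continue
        used_c.add(i)
        used_t.add(j)
        matched += 1
    return matched


def _pr(matched: int, n_called: int, n_truth: int) -> dict:
    return {
        "precision": matched / n_called if n_called else None,
        "recall": matched / n_truth if n_truth else None,
        "n_called": n_called,
        "n_truth": n_truth,
        "matched": matched,
    }


def compare_to_truth(
    insertion_calls: Sequence[transitions.InsertionCall],
    duplication_events: Sequence[transitions.DuplicationEvent],
    transgene_loci: Sequence[tuple[str, int]],
    truth: TruthTable,
    cassette_truth: TruthTable | None = None,
    tolerance: int = 50,
    insert_span: float = 400.0,
) -> dict:
    """Precision/recall per event class against the simulation truth.

    A call matches a truth event when loci lie within ``tolerance`` bp
    (transgene sites within ``insert_span``, the pair-localisation limit);
    matching is one-to-one greedy by distance. Undefined ratios (empty
    denominator) are reported as None (NA in TSV output).
    """
    ins_called = [(c.cell_locus[0], c.cell_locus[1]) for c in insertion_calls]
    ins_truth = [(t.contig, t.position) for t in truth.planted_insertions]
    out = {"insertions": _pr(_greedy_match(ins_called, ins_truth, tolerance), len(ins_called), len(ins_truth))}

    dup_called = [(d.contig, d.start) for d in duplication_events]
    dup_truth = [(d.contig, d.start) for d in truth.planted_duplications]
    out["duplications"] = _pr(_greedy_match(dup_called, dup_truth, tolerance), len(dup_called), len(dup_truth))

    if cassette_truth is not None:
        tg_truth = [(c, p) for c, p in cassette_truth.cassette_sites]
        out["transgene_sites"] = _pr(
            _greedy_match(transgene_loci, tg_truth, insert_span), len(transgene_loci), len(tg_truth)
        )
    return out
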
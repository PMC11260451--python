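"""Synthetic coculture generator.

Emulates the experimental design in which a recipient tumor cell line is
cocultured with patient-derived circulating tumor DNA (ctDNA):

* a haploid recipient ("cell") genome and a "donor" genome differing from
  it only by private single-nucleotide substitutions (the tumor variants
  that mark ctDNA origin),
* a library of synthetic transposable-element (TE) consensi tagged with a
  tumor tissue label,
* adaptor-ligated ctDNA fragments drawn from the donor, with TE copies
  embedded near fragment ends,
* a "coculture" genome equal to the cell genome plus integrated fragment
  cores (with a configurable bias toward insertion near each fragment's
  locus of origin) and coculture-unique tandem duplications >= 10 bp,
* paired-end reads at configurable coverage, and
* a transgene-cassette scenario yielding discordant read pairs.

Every generator is a pure function of (parameters, seed); a machine-
readable truth table records all planted events for downstream
precision/recall evaluation.
"""

from __future__ import annotations

import dataclasses
import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .genomes import (
    ALPHABET,
    PACBIO_ADAPTOR,
    CtDNAFragment,
    GenomeSequence,
    PositionMap,
    TEConsensus,
    random_sequence,
    revcomp,
)

_TE_CLASS_CYCLE = ("SINE", "LINE", "LTR", "ERVL")

# Element names used as synthetic stand-ins; the sequences generated here
# are random and carry no homology to the real Repbase/Dfam consensi.
_TE_NAME_POOL = {
    "MM": ("AluSp", "MER11C", "AluJb", "L2a", "AluSg2", "THE1A"),
    "PC": ("AluSx", "MIRc", "MTL1J", "AluSx1", "L1PA4", "MER41B"),
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic coculture experiment.

    Defaults are the documented desk-scale study conditions: two 150 kb
    contigs, donor SNV rate 5e-4, cfDNA-like lognormal fragment sizes
    (median 170 bp), adaptor ligation on both ends, 80% proximity bias
    within a 10 kb window, and 30x paired-end 2x100 reads.
    """

    n_contigs: int = 2
    contig_length: int = 150_000
    gc_content: float = 0.41
    donor_snv_rate: float = 5e-4
    # TE library
    te_per_tissue: int = 4
    te_length_range: tuple[int, int] = (120, 260)
    tissues: tuple[str, ...] = ("MM", "PC")
    te_scan_score_cutoff: float = 40.0
    # ctDNA fragments
    n_fragments: int = 40
    fragment_median: float = 170.0
    fragment_sigma: float = 0.6
    fragment_min: int = 80
    te_end_probability: float = 0.8
    te_end_window: int = 100
    adaptor: str = PACBIO_ADAPTOR
    ensure_private_snv: bool = True
    # coculture
    insertion_rate: float = 1.0
    proximity_bias: float = 0.8
    proximity_window: int = 10_000
    duplication_rate: float = 2e-5
    duplication_length_range: tuple[int, int] = (10, 60)
    # reads
    coverage: float = 30.0
    read_length: int = 100
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    error_rate: float = 0.0

    def validate(self) -> None:
        for name in ("donor_snv_rate", "te_end_probability", "insertion_rate", "proximity_bias"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_contigs < 1 or self.contig_length < 10_000:
            raise ValueError("need n_contigs >= 1 and contig_length >= 10 kb")
        if not self.adaptor:
            raise ValueError("adaptor must be non-empty")
        if self.error_rate >= 0.1:
            raise ValueError("error_rate must be < 0.1")
        if self.duplication_length_range[0] < 10:
            raise ValueError("duplication lengths are drawn >= 10 bp")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("te_length_range", "tissues", "duplication_length_range"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class PlantedInsertion:
    contig: str            # coculture contig (same namespace as cell)
    position: int          # cell-reference coordinate of the insertion point
    cocu_position: int     # coordinate of the first inserted base in the coculture genome
    fragment_id: str
    distance_to_origin: int | None  # bp, None when inter-contig


@dataclass
class PlantedDuplication:
    contig: str
    start: int             # cell-reference start of the duplicated segment
    length: int            # >= 10
    cocu_position: int = -1  # coordinate of the planted extra copy in the coculture genome


@dataclass
class TruthTable:
    """Record of every planted event; the acceptance oracle."""

    planted_insertions: list[PlantedInsertion] = field(default_factory=list)
    planted_duplications: list[PlantedDuplication] = field(default_factory=list)
    donor_private_snvs: list[tuple[str, int, str, str]] = field(default_factory=list)
    cassette_sites: list[tuple[str, int]] = field(default_factory=list)
    seed: int = 0
    parameters: dict = field(default_factory=dict)
    #: liftover from the edited genome back to cell/donor coordinates
    liftover: PositionMap | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "parameters": self.parameters,
            "planted_insertions": [dataclasses.asdict(x) for x in self.planted_insertions],
            "planted_duplications": [dataclasses.asdict(x) for x in self.planted_duplications],
            "donor_private_snvs": [list(x) for x in self.donor_private_snvs],
            "cassette_sites": [list(x) for x in self.cassette_sites],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        payload = json.loads(Path(path).read_text())
        return cls(
            planted_insertions=[PlantedInsertion(**x) for x in payload["planted_insertions"]],
            planted_duplications=[PlantedDuplication(**x) for x in payload["planted_duplications"]],
            donor_private_snvs=[tuple(x) for x in payload["donor_private_snvs"]],
            cassette_sites=[tuple(x) for x in payload["cassette_sites"]],
            seed=payload["seed"],
            parameters=payload["parameters"],
        )


# ---------------------------------------------------------------------------
# genomes and TE library


def _substitute(base: str, rng: np.random.Generator) -> str:
    choices = [b for b in ALPHABET if b != base]
    return choices[rng.integers(3)]


def simulate_genomes(
    config: SimulationConfig, seed: int
) -> tuple[GenomeSequence, GenomeSequence, list[TEConsensus]]:
    """Generate the recipient cell genome, the donor genome and a TE library.

    The donor differs from the cell only by substitutions at
    ``donor_snv_rate`` (positions recorded on the returned donor object as
    ``donor.private_snvs``: list of (contig, pos, ref, alt)). Deterministic
    under (config, seed).
    """
    config.validate()
    rng = np.random.default_rng(seed)

    cell_seqs: dict[str, str] = {}
    for i in range(config.n_contigs):
        cell_seqs[f"chr{i + 1}"] = random_sequence(config.contig_length, rng, config.gc_content)
    cell = GenomeSequence("cell", cell_seqs, role="cell")

    donor_seqs: dict[str, str] = {}
    private: list[tuple[str, int, str, str]] = []
    for contig, seq in cell_seqs.items():
        n_snv = rng.binomial(len(seq), config.donor_snv_rate)
        positions = np.sort(rng.choice(len(seq), size=n_snv, replace=False))
        arr = list(seq)
        for pos in positions:
            ref = arr[pos]
            alt = _substitute(ref, rng)
            arr[pos] = alt
            private.append((contig, int(pos), ref, alt))
        donor_seqs[contig] = "".join(arr)
    donor = GenomeSequence("donor", donor_seqs, role="donor")
    donor.private_snvs = private  # type: ignore[attr-defined]

    library = _simulate_te_library(config, rng)
    return cell, donor, library


def _simulate_te_library(config: SimulationConfig, rng: np.random.Generator) -> list[TEConsensus]:
    """Random TE consensi, mutually non-homologous above the scan cutoff.

    Random sequences over a 4-letter alphabet essentially never share a
    local-alignment score >= 40 at these lengths; the longest common
    substring check below is a cheap guard that also bounds the local
    alignment score (match +2).
    """
    library: list[TEConsensus] = []
    max_shared = int(config.te_scan_score_cutoff // 2)  # match score +2
    for tissue in config.tissues:
        names = _TE_NAME_POOL.get(tissue)
        for j in range(config.te_per_tissue):
            name = (
                names[j] if names and j < len(names) else f"{tissue}_TE{j + 1}"
            )
            te_class = _TE_CLASS_CYCLE[j % len(_TE_CLASS_CYCLE)]
            for _ in range(50):
                length = int(rng.integers(config.te_length_range[0], config.te_length_range[1] + 1))
                seq = random_sequence(length, rng, config.gc_content)
                if all(
                    _longest_common_substring(seq, other.sequence) < max_shared
                    and _longest_common_substring(seq, revcomp(other.sequence)) < max_shared
                    for other in library
                ):
                    break
            else:  # pragma: no cover - vanishingly unlikely
                raise RuntimeError("could not generate a non-homologous TE consensus")
            library.append(TEConsensus(name=name, te_class=te_class, sequence=seq, tumor_label=tissue))
    return library


def _longest_common_substring(a: str, b: str, k: int = 12) -> int:
    """Length of the longest exact shared substring (k-mer seeded)."""
    kmers = {a[i : i + k]: i for i in range(len(a) - k + 1)}
    best = 0
    for j in range(len(b) - k + 1):
        i = kmers.get(b[j : j + k])
        if i is None:
            continue
        lo, hi = i, j
        while lo > 0 and hi > 0 and a[lo - 1] == b[hi - 1]:
            lo, hi = lo - 1, hi - 1
        length = k
        while i + length < len(a) and j + length < len(b) and a[i + length] == b[j + length]:
            length += 1
        best = max(best, length + (i - lo))
    return best


# ---------------------------------------------------------------------------
# ctDNA fragments


def simulate_ctdna(
    donor: GenomeSequence,
    te_library: Sequence[TEConsensus],
    n_fragments: int,
    size_model: tuple[float, float] = (170.0, 0.6),
    te_end_probability: float = 0.8,
    adaptor: str = PACBIO_ADAPTOR,
    seed: int = 0,
    *,
    te_end_window: int = 100,
    fragment_min: int = 80,
    ensure_private_snv: bool = True,
    tissue: str | None = None,
    id_prefix: str = "frag",
) -> list[CtDNAFragment]:
    """Draw adaptor-ligated ctDNA fragments from the donor genome.

    Fragment lengths follow a lognormal with the given (median, sigma).
    With probability ``te_end_probability`` a TE consensus copy is written
    into the donor at the fragment's origin so that the copy lies within
    ``te_end_window`` nt of a fragment end; the donor genome is therefore
    MUTATED IN PLACE (its recorded private SNVs are pruned where
    overwritten) so that every fragment core remains an exact substring of
    the donor. When ``ensure_private_snv`` is set, a fragment whose core
    contains no donor-private SNV gets one forced substitution (recorded).
    """
    if not 0.0 <= te_end_probability <= 1.0:
        raise ValueError("te_end_probability must be in [0, 1]")
    if not adaptor:
        raise ValueError("adaptor must be non-empty")
    rng = np.random.default_rng(seed)
    median, sigma = size_model
    contigs = donor.contigs()
    lengths = np.array([len(donor.sequences[c]) for c in contigs], dtype=float)
    if fragment_min > lengths.max():
        raise ValueError("fragment size larger than any contig")
    weights = lengths / lengths.sum()
    candidates = [te for te in te_library if tissue is None or te.tumor_label == tissue]
    if te_end_probability > 0 and not candidates:
        raise ValueError(f"no TE consensi available for tissue {tissue!r}")

    private: list[tuple[str, int, str, str]] = getattr(donor, "private_snvs", [])
    private_by_contig: dict[str, dict[int, tuple[str, str]]] = {}
    for contig, pos, ref, alt in private:
        private_by_contig.setdefault(contig, {})[pos] = (ref, alt)

    # pass 1: sample origins, sizes and TE plans
    plans = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in contigs}
    for i in range(n_fragments):
        plant_te = rng.random() < te_end_probability
        te = candidates[rng.integers(len(candidates))] if plant_te else None
        for _ in range(200):
            size = int(np.rint(np.exp(np.log(median) + sigma * rng.standard_normal())))
            size = max(size, fragment_min)
            if te is not None:
                size = max(size, len(te.sequence) + 20)
            contig = contigs[rng.choice(len(contigs), p=weights)]
            limit = len(donor.sequences[contig]) - size
            if limit <= 0:
                continue
            start = int(rng.integers(0, limit))
            span = (start, start + size)
            # keep TE-planting fragments disjoint so plants cannot collide
            if te is not None and any(
                s < span[1] and span[0] < e for s, e in occupied[contig]
            ):
                continue
            break
        else:
            raise RuntimeError("could not place ctDNA fragment; contigs too small")
        if te is not None:
            occupied[contig].append(span)
        plans.append((f"{id_prefix}{i:04d}", contig, start, size, te))

    # pass 2: write TE copies into the donor
    donor_arr = {c: list(s) for c, s in donor.sequences.items()}
    te_placements: dict[str, tuple[str, int, int]] = {}
    for frag_id, contig, start, size, te in plans:
        if te is None:
            continue
        te_len = len(te.sequence)
        slack = min(te_end_window, size - te_len)
        offset_from_end = int(rng.integers(0, slack + 1))
        if rng.random() < 0.5:  # 5' end
            core_start = offset_from_end
        else:  # 3' end
            core_start = size - offset_from_end - te_len
        te_seq = te.sequence if rng.random() < 0.5 else revcomp(te.sequence)
        pos = start + core_start
        donor_arr[contig][pos : pos + te_len] = te_seq
        te_placements[frag_id] = (te.name, core_start, core_start + te_len)
        # drop private SNVs overwritten by the plant
        cmap = private_by_contig.get(contig, {})
        for p in range(pos, pos + te_len):
            cmap.pop(p, None)

    # pass 3: force a private SNV into fragments lacking one
    cell_like = None
    for frag_id, contig, start, size, te in plans:
        cmap = private_by_contig.setdefault(contig, {})
        core_range = range(start, start + size)
        has_snv = any(p in cmap for p in core_range)
        if has_snv or not ensure_private_snv:
            continue
        te_iv = te_placements.get(frag_id)
        for _ in range(100):
            pos = start + int(rng.integers(0, size))
            if te_iv is not None and te_iv[1] <= pos - start < te_iv[2]:
                continue
            ref = donor_arr[contig][pos]
            alt = _substitute(ref, rng)
            donor_arr[contig][pos] = alt
            cmap[pos] = (ref, alt)
            break

    donor.sequences = {c: "".join(arr) for c, arr in donor_arr.items()}
    donor.private_snvs = [  # type: ignore[attr-defined]
        (contig, pos, ref, alt)
        for contig, cmap in sorted(private_by_contig.items())
        for pos, (ref, alt) in sorted(cmap.items())
    ]

    # pass 4: extract fragments
    fragments: list[CtDNAFragment] = []
    for frag_id, contig, start, size, te in plans:
        core = donor.sequences[contig][start : start + size]
        cmap = private_by_contig.get(contig, {})
        snvs = sorted(p for p in cmap if start <= p < start + size)
        te_iv = te_placements.get(frag_id)
        fragments.append(
            CtDNAFragment(
                fragment_id=frag_id,
                sequence=adaptor + core + adaptor,
                origin=(contig, start, start + size),
                adaptor_5=True,
                adaptor_3=True,
                adaptor=adaptor,
                planted_te_names=[te_iv[0]] if te_iv else [],
                private_snvs=snvs,
                te_intervals=[(te_iv[1], te_iv[2])] if te_iv else [],
            )
        )
    return fragments


def fragment_genome(fragments: Sequence[CtDNAFragment], name: str = "ctdna") -> tuple[GenomeSequence, PositionMap]:
    """Fragments as a pseudo-genome (one contig each) plus liftover to donor coords.

    Adaptor bases are unmapped; read pileups over this genome land on
    donor (== cell) coordinates.
    """
    seqs = {f.fragment_id: f.sequence for f in fragments}
    pm = PositionMap()
    for f in fragments:
        contig, start, _end = f.origin
        off = f.core_offset
        pm.add(f.fragment_id, off, off + len(f.core), contig, start)
    return GenomeSequence(name, seqs, role="donor"), pm.finalize()


# ---------------------------------------------------------------------------
# coculture genome


def simulate_coculture(
    cell: GenomeSequence,
    fragments: Sequence[CtDNAFragment],
    insertion_rate: float = 1.0,
    proximity_bias: float = 0.8,
    proximity_window: int = 10_000,
    duplication_rate: float = 0.0,
    seed: int = 0,
    *,
    duplication_length_range: tuple[int, int] = (10, 60),
) -> tuple[GenomeSequence, TruthTable]:
    """Plant fragment cores and coculture-unique duplications into the cell genome.

    Each fragment is inserted with probability ``insertion_rate`` (adaptors
    stripped: the ligated adaptor is a library artifact, not part of the
    integrated molecule). A fraction ``proximity_bias`` of insertions land
    within ``proximity_window`` of the fragment's homologous origin locus;
    the rest land uniformly. Tandem duplications of length >= 10 are planted
    at ``duplication_rate`` per base. Returns the coculture genome and a
    complete truth table (including a coculture -> cell/donor liftover).
    """
    if not 0.0 <= proximity_bias <= 1.0:
        raise ValueError("proximity_bias must be in [0, 1]")
    if duplication_length_range[0] < 10:
        raise ValueError("duplication lengths are drawn >= 10")
    rng = np.random.default_rng(seed)
    contigs = cell.contigs()
    lengths = np.array([len(cell.sequences[c]) for c in contigs], dtype=float)
    weights = lengths / lengths.sum()

    # edits: (contig, cell position, inserted sequence, kind, payload)
    edits: list[tuple[str, int, str, str, object]] = []
    used_positions: dict[str, set[int]] = {c: set() for c in contigs}

    inserted = [f for f in fragments if rng.random() < insertion_rate]
    for frag in inserted:
        o_contig, o_start, _o_end = frag.origin
        for attempt in range(100):
            if rng.random() < proximity_bias and o_contig in cell.sequences:
                contig = o_contig
                lo = max(1, o_start - proximity_window)
                hi = min(len(cell.sequences[contig]) - 1, o_start + proximity_window)
                pos = int(rng.integers(lo, hi + 1))
            else:
                contig = contigs[rng.choice(len(contigs), p=weights)]
                pos = int(rng.integers(1, len(cell.sequences[contig]) - 1))
            if pos not in used_positions[contig]:
                used_positions[contig].add(pos)
                break
        else:
            raise RuntimeError("could not place insertion without collision")
        dist = abs(pos - o_start) if contig == o_contig else None
        edits.append((contig, pos, frag.core, "insertion", (frag, dist)))

    dup_lo, dup_hi = duplication_length_range
    for contig, length in zip(contigs, lengths):
        seq = cell.sequences[contig]
        n_dup = rng.binomial(int(length), duplication_rate)
        for _ in range(n_dup):
            for attempt in range(200):
                dlen = int(rng.integers(dup_lo, dup_hi + 1))
                start = int(rng.integers(1, int(length) - dlen - 1))
                # avoid boundary microhomology so the planted length is
                # unambiguous: the segment's first base must differ from the
                # base following it, and its last base from the one before it
                if seq[start] == seq[start + dlen] or seq[start - 1] == seq[start + dlen - 1]:
                    continue
                # tandem copy inserted at the end of the original segment
                if (start + dlen) not in used_positions[contig]:
                    used_positions[contig].add(start + dlen)
                    break
            else:
                raise RuntimeError("could not place duplication without collision")
            dup_seq = seq[start : start + dlen]
            edits.append((contig, start + dlen, dup_seq, "duplication", (start, dlen)))

    truth = TruthTable(seed=seed)
    pm = PositionMap()
    cocu_seqs: dict[str, str] = {}
    for contig in contigs:
        cell_seq = cell.sequences[contig]
        contig_edits = sorted(
            (e for e in edits if e[0] == contig), key=lambda e: e[1]
        )
        parts: list[str] = []
        cursor = 0
        out_len = 0
        for _c, pos, ins_seq, kind, payload in contig_edits:
            parts.append(cell_seq[cursor:pos])
            out_len += pos - cursor
            pm.add(contig, out_len - (pos - cursor), out_len, contig, cursor)
            ins_start = out_len
            parts.append(ins_seq)
            out_len += len(ins_seq)
            if kind == "insertion":
                frag, dist = payload
                f_contig, f_start, _f_end = frag.origin
                pm.add(contig, ins_start, out_len, f_contig, f_start)
                truth.planted_insertions.append(
                    PlantedInsertion(
                        contig=contig,
                        position=pos,
                        cocu_position=ins_start,
                        fragment_id=frag.fragment_id,
                        distance_to_origin=dist,
                    )
                )
            else:
                start, dlen = payload
                pm.add(contig, ins_start, out_len, contig, start)
                truth.planted_duplications.append(
                    PlantedDuplication(contig=contig, start=start, length=dlen, cocu_position=ins_start)
                )
            cursor = pos
        parts.append(cell_seq[cursor:])
        out_len += len(cell_seq) - cursor
        pm.add(contig, out_len - (len(cell_seq) - cursor), out_len, contig, cursor)
        cocu_seqs[contig] = "".join(parts)

    coculture = GenomeSequence("coculture", cocu_seqs, role="coculture")
    truth.liftover = pm.finalize()
    truth.planted_insertions.sort(key=lambda x: (x.contig, x.position))
    truth.planted_duplications.sort(key=lambda x: (x.contig, x.start))
    return coculture, truth


# ---------------------------------------------------------------------------
# reads


@dataclass
class ReadPair:
    name: str
    r1: str
    r2: str
    contig: str
    start: int         # 0-based leftmost position of the sampled insert
    insert: int

    def genomic_segments(self) -> list[tuple[int, str]]:
        """(start, genomic-orientation bases) for each mate."""
        return [
            (self.start, self.r1),
            (self.start + self.insert - len(self.r2), revcomp(self.r2)),
        ]


@dataclass
class ReadSet:
    pairs: list[ReadPair]
    genome_name: str
    read_length: int

    def __len__(self) -> int:
        return len(self.pairs)

    def write_fastq(self, prefix: str | Path) -> tuple[Path, Path]:
        """Write gzip FASTQ as <prefix>_R1.fastq.gz / <prefix>_R2.fastq.gz."""
        prefix = Path(prefix)
        p1 = prefix.parent / f"{prefix.name}_R1.fastq.gz"
        p2 = prefix.parent / f"{prefix.name}_R2.fastq.gz"
        for path, attr in ((p1, "r1"), (p2, "r2")):
            with gzip.open(path, "wt") as fh:
                for pair in self.pairs:
                    seq = getattr(pair, attr)
                    fh.write(f"@{pair.name}\n{seq}\n+\n{'I' * len(seq)}\n")
        return p1, p2


def simulate_reads(
    genome: GenomeSequence,
    coverage: float,
    read_length: int = 100,
    insert_size: tuple[float, float] = (300.0, 30.0),
    error_rate: float = 0.0,
    seed: int = 0,
) -> ReadSet:
    """Uniform paired-end read sampling with per-base substitution errors.

    Read names encode the true origin (``genome:contig:start:insert:i``) so
    downstream desk-scale tools can pile up without running an aligner.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    mean, sd = insert_size
    if read_length >= mean:
        raise ValueError("read_length must be smaller than the insert mean")
    if error_rate >= 0.1:
        raise ValueError("error_rate must be < 0.1")
    rng = np.random.default_rng(seed)
    pairs: list[ReadPair] = []
    counter = 0
    for contig, seq in genome.sequences.items():
        clen = len(seq)
        if clen < read_length:
            continue  # molecule too short to sequence
        n_pairs = int(np.rint(coverage * clen / (2 * read_length)))
        for _ in range(n_pairs):
            insert = int(np.rint(rng.normal(mean, sd)))
            insert = max(insert, read_length)
            insert = min(insert, clen)
            start = int(rng.integers(0, clen - insert + 1))
            r1 = seq[start : start + read_length]
            r2 = revcomp(seq[start + insert - read_length : start + insert])
            if error_rate > 0:
                r1 = _add_errors(r1, error_rate, rng)
                r2 = _add_errors(r2, error_rate, rng)
            name = f"{genome.name}:{contig}:{start}:{insert}:{counter}"
            pairs.append(ReadPair(name, r1, r2, contig, start, insert))
            counter += 1
    return ReadSet(pairs=pairs, genome_name=genome.name, read_length=read_length)


def _add_errors(read: str, rate: float, rng: np.random.Generator) -> str:
    n_err = rng.binomial(len(read), rate)
    if n_err == 0:
        return read
    arr = list(read)
    for pos in rng.choice(len(read), size=n_err, replace=False):
        arr[pos] = _substitute(arr[pos], rng)
    return "".join(arr)


# ---------------------------------------------------------------------------
# transgene cassette scenario


def simulate_cassette_integration(
    cell: GenomeSequence,
    cassette: GenomeSequence,
    n_sites: int,
    seed: int = 0,
    *,
    min_separation: int = 5_000,
) -> tuple[GenomeSequence, TruthTable]:
    """Plant full cassette copies at ``n_sites`` recorded positions.

    Emulates the transgene scenario (a CMV-mCherry style construct flanked
    by targeting sequences): reads simulated over the modified genome will
    yield discordant pairs spanning each cassette junction.
    """
    cassette_seq = next(iter(cassette.sequences.values()))
    if len(cassette_seq) < 500:
        raise ValueError("cassette must be at least 500 bp")
    rng = np.random.default_rng(seed)
    contigs = cell.contigs()
    lengths = np.array([len(cell.sequences[c]) for c in contigs], dtype=float)
    if n_sites > int(lengths.sum() // max(min_separation, 1)):
        raise ValueError("n_sites exceeds placeable loci")
    weights = lengths / lengths.sum()

    sites: list[tuple[str, int]] = []
    for _ in range(n_sites):
        for attempt in range(200):
            contig = contigs[rng.choice(len(contigs), p=weights)]
            pos = int(rng.integers(1000, len(cell.sequences[contig]) - 1000))
            if all(c != contig or abs(p - pos) >= min_separation for c, p in sites):
                sites.append((contig, pos))
                break
        else:
            raise ValueError("n_sites exceeds placeable loci")
    sites.sort()

    modified_seqs: dict[str, str] = {}
    for contig, seq in cell.sequences.items():
        parts, cursor = [], 0
        for c, pos in sites:
            if c != contig:
                continue
            parts.append(seq[cursor:pos])
            parts.append(cassette_seq)
            cursor = pos
        parts.append(seq[cursor:])
        modified_seqs[contig] = "".join(parts)

    truth = TruthTable(seed=seed, cassette_sites=sites)
    modified = GenomeSequence("cell+cassette", modified_seqs, role="coculture")
    return modified, truth


def make_cassette(length: int = 1500, seed: int = 7, name: str = "CMV-mCherry") -> GenomeSequence:
    """A synthetic stand-in for a CMV-mCherry cassette (random sequence)."""
    rng = np.random.default_rng(seed)
    return GenomeSequence(name, {name: random_sequence(length, rng, 0.55)}, role="cassette")


# ---------------------------------------------------------------------------
# convenience: mixture cfDNA for tumor-fraction estimation


def simulate_cfdna_mixture(
    cell: GenomeSequence,
    donor: GenomeSequence,
    tumor_fraction: float,
    n_fragments: int,
    size_model: tuple[float, float] = (170.0, 0.6),
    seed: int = 0,
    fragment_min: int = 80,
) -> list[CtDNAFragment]:
    """cfDNA as a donor:cell mixture — a fraction ``tumor_fraction`` of
    fragments derive from the donor (carrying its private SNVs), the rest
    from the cell genome. Origins are donor/cell coordinates (shared)."""
    rng = np.random.default_rng(seed)
    median, sigma = size_model
    contigs = cell.contigs()
    lengths = np.array([len(cell.sequences[c]) for c in contigs], dtype=float)
    weights = lengths / lengths.sum()
    fragments = []
    for i in range(n_fragments):
        from_donor = rng.random() < tumor_fraction
        source = donor if from_donor else cell
        size = max(int(np.rint(np.exp(np.log(median) + sigma * rng.standard_normal()))), fragment_min)
        contig = contigs[rng.choice(len(contigs), p=weights)]
        size = min(size, len(source.sequences[contig]))
        start = int(rng.integers(0, len(source.sequences[contig]) - size + 1))
        fragments.append(
            CtDNAFragment(
                fragment_id=f"cfdna{i:05d}" + ("t" if from_donor else "n"),
                sequence=source.sequences[contig][start : start + size],
                origin=(contig, start, start + size),
            )
        )
    return fragments
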
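"""Core sequence containers and coordinate plumbing.

All coordinates are 0-based half-open unless a file format dictates
otherwise (VCF is 1-based on disk; the shift happens exactly once, in
:mod:`ctdna_integrate.variants`).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: 14-nt oligo ligated to ctDNA 5'/3' ends before library prep; used as the
#: fragment-end marker throughout the pipeline.
PACBIO_ADAPTOR = "GCGCTCTGTGTGCT"


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_sequence(length: int, rng: np.random.Generator, gc: float = 0.41) -> str:
    """Random nucleotide string with the given GC content."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return "".join(ALPHABET[i] for i in idx)


@dataclass
class GenomeSequence:
    """A named haploid sequence set.

    role is one of ``cell`` (recipient reference), ``donor`` (the genome
    the ctDNA derives from), ``coculture`` (recipient genome after
    integration events) or ``cassette`` (a transgene construct).
    """

    name: str
    sequences: dict[str, str]
    role: str = "cell"

    def __post_init__(self) -> None:
        if self.role not in {"cell", "donor", "coculture", "cassette"}:
            raise ValueError(f"unknown genome role {self.role!r}")
        seen: set[str] = set()
        for contig, seq in self.sequences.items():
            if contig in seen:
                raise ValueError(f"duplicate contig name {contig!r}")
            seen.add(contig)
            if not seq:
                raise ValueError(f"contig {contig!r} is empty")

    def __len__(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def contigs(self) -> list[str]:
        return list(self.sequences)

    def fetch(self, contig: str, start: int, end: int) -> str:
        return self.sequences[contig][start:end]

    def copy(self, name: str | None = None, role: str | None = None) -> "GenomeSequence":
        return GenomeSequence(
            name=name or self.name,
            sequences=dict(self.sequences),
            role=role or self.role,
        )

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=contig, description="")
            for contig, seq in self.sequences.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path: str | Path, name: str | None = None, role: str = "cell") -> "GenomeSequence":
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        return cls(name=name or Path(path).stem, sequences=seqs, role=role)


@dataclass
class TEConsensus:
    """A transposable-element consensus sequence with a tissue association.

    The tissue tag (``tumor_label``, e.g. MM or PC) encodes which tumor
    type the element is associated with in the simulated cocultures.
    """

    name: str
    te_class: str
    sequence: str
    tumor_label: str

    CLASSES = ("SINE", "LINE", "LTR", "ERVL", "other")

    def __post_init__(self) -> None:
        if self.te_class not in self.CLASSES:
            raise ValueError(f"unknown TE class {self.te_class!r}")
        if len(self.sequence) < 50:
            raise ValueError("TE consensus must be at least 50 nt")


def write_te_library(library: Iterable[TEConsensus], path: str | Path) -> None:
    """Write a TE library FASTA with ``name|class|tissue`` headers."""
    records = [
        SeqRecord(Seq(te.sequence), id=f"{te.name}|{te.te_class}|{te.tumor_label}", description="")
        for te in library
    ]
    SeqIO.write(records, str(path), "fasta")


def read_te_library(path: str | Path) -> list[TEConsensus]:
    library = []
    for rec in SeqIO.parse(str(path), "fasta"):
        name, te_class, tissue = rec.id.split("|")
        library.append(TEConsensus(name, te_class, str(rec.seq).upper(), tissue))
    return library


@dataclass
class CtDNAFragment:
    """A donor-derived cell-free DNA fragment.

    ``sequence`` is the full library molecule including ligated adaptors;
    ``core`` (the biological fragment) is the sequence with adaptors
    stripped and equals ``donor[origin]`` exactly.
    """

    fragment_id: str
    sequence: str
    origin: tuple[str, int, int]
    adaptor_5: bool = False
    adaptor_3: bool = False
    adaptor: str = PACBIO_ADAPTOR
    planted_te_names: list[str] = field(default_factory=list)
    #: donor-coordinate positions of donor-private SNVs inside the core
    private_snvs: list[int] = field(default_factory=list)
    #: (start, end) of planted TE copies, in core coordinates
    te_intervals: list[tuple[int, int]] = field(default_factory=list)

    @property
    def core(self) -> str:
        start = len(self.adaptor) if self.adaptor_5 else 0
        end = len(self.sequence) - (len(self.adaptor) if self.adaptor_3 else 0)
        return self.sequence[start:end]

    @property
    def core_offset(self) -> int:
        """Offset of the first core base within ``sequence``."""
        return len(self.adaptor) if self.adaptor_5 else 0

    def __post_init__(self) -> None:
        contig, start, end = self.origin
        if end - start != len(self.core):
            raise ValueError(
                f"{self.fragment_id}: origin span {end - start} != core length {len(self.core)}"
            )
        if self.adaptor_5 and not self.sequence.startswith(self.adaptor):
            raise ValueError(f"{self.fragment_id}: 5' adaptor flag set but motif absent")
        if self.adaptor_3 and not self.sequence.endswith(self.adaptor):
            raise ValueError(f"{self.fragment_id}: 3' adaptor flag set but motif absent")


def write_fragments(fragments: Iterable[CtDNAFragment], path: str | Path) -> None:
    """FASTA with ``id|contig:start-end`` headers (full adaptor-ligated molecule)."""
    records = []
    for frag in fragments:
        contig, start, end = frag.origin
        header = f"{frag.fragment_id}|{contig}:{start}-{end}|a5={int(frag.adaptor_5)}|a3={int(frag.adaptor_3)}"
        records.append(SeqRecord(Seq(frag.sequence), id=header, description=""))
    SeqIO.write(records, str(path), "fasta")


def read_fragments(path: str | Path, adaptor: str = PACBIO_ADAPTOR) -> list[CtDNAFragment]:
    fragments = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = rec.id.split("|")
        frag_id, locus = fields[0], fields[1]
        a5 = fields[2] == "a5=1" if len(fields) > 2 else False
        a3 = fields[3] == "a3=1" if len(fields) > 3 else False
        contig, span = locus.rsplit(":", 1)
        start, end = (int(x) for x in span.split("-"))
        fragments.append(
            CtDNAFragment(
                fragment_id=frag_id,
                sequence=str(rec.seq).upper(),
                origin=(contig, start, end),
                adaptor_5=a5,
                adaptor_3=a3,
                adaptor=adaptor,
            )
        )
    return fragments


class PositionMap:
    """Piecewise-linear liftover between two coordinate systems.

    Each segment maps ``src[src_contig][src_start:src_end)`` onto
    ``ref[ref_contig][ref_start:ref_start + (src_end - src_start))``
    (forward strand only — the simulator never plants inversions).
    Positions outside every segment (e.g. ligated adaptor bases) are
    unmapped.
    """

    def __init__(self) -> None:
        self._segments: dict[str, list[tuple[int, int, str, int]]] = {}
        self._arrays: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[str]]] = {}

    def add(self, src_contig: str, src_start: int, src_end: int, ref_contig: str, ref_start: int) -> None:
        if src_end > src_start:
            self._segments.setdefault(src_contig, []).append((src_start, src_end, ref_contig, ref_start))

    def finalize(self) -> "PositionMap":
        self._arrays = {}
        for src, segs in self._segments.items():
            segs.sort()
            names = sorted({s[2] for s in segs})
            code = {n: i for i, n in enumerate(names)}
            self._arrays[src] = (
                np.array([s[0] for s in segs], dtype=np.int64),
                np.array([s[1] for s in segs], dtype=np.int64),
                np.array([s[3] for s in segs], dtype=np.int64),
                np.array([code[s[2]] for s in segs], dtype=np.int64),
                names,
            )
        return self

    @classmethod
    def identity(cls, genome: GenomeSequence) -> "PositionMap":
        pm = cls()
        for contig, seq in genome.sequences.items():
            pm.add(contig, 0, len(seq), contig, 0)
        return pm.finalize()

    def map_position(self, contig: str, pos: int) -> tuple[str, int] | None:
        segs = self._segments.get(contig)
        if not segs:
            return None
        i = bisect.bisect_right(segs, (pos, float("inf"))) - 1
        if i < 0:
            return None
        src_start, src_end, ref_contig, ref_start = segs[i]
        if src_start <= pos < src_end:
            return ref_contig, ref_start + (pos - src_start)
        return None

    def map_array(self, contig: str, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """Vectorised liftover.

        Returns (contig_codes, ref_positions, code_names); unmapped entries
        get code -1 / pos -1.
        """
        arrays = self._arrays.get(contig)
        n = len(positions)
        if arrays is None:
            return np.full(n, -1, dtype=np.int64), np.full(n, -1, dtype=np.int64), []
        starts, ends, ref_starts, codes, names = arrays
        idx = np.searchsorted(starts, positions, side="right") - 1
        idx_clip = np.clip(idx, 0, len(starts) - 1)
        valid = (idx >= 0) & (positions < ends[idx_clip]) & (positions >= starts[idx_clip])
        out_codes = np.where(valid, codes[idx_clip], -1)
        out_pos = np.where(valid, ref_starts[idx_clip] + positions - starts[idx_clip], -1)
        return out_codes, out_pos, names

    def segments(self) -> Iterator[tuple[str, int, int, str, int]]:
        for contig, segs in self._segments.items():
            for src_start, src_end, ref_contig, ref_start in segs:
                yield contig, src_start, src_end, ref_contig, ref_start
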
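"""Transition-point detection in coculture contigs.

A contig assembled from a coculture genome that carries an integrated
ctDNA fragment is chimeric: a prefix (and usually a suffix) matches the
recipient cell reference while the middle matches one ctDNA fragment.
The switch offset — the transition point — is found by seeding with
k-mers unique to exactly one of the two references and extending
ungapped along the seeded diagonal. Insertions are then confirmed by
ctDNA-private SNVs inside the inserted segment, and duplications >= 10 bp
are called from reference intervals covered more than once by a single
contig.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .genomes import CtDNAFragment, GenomeSequence, revcomp
from .simulate import ReadSet, TruthTable
from .variants import VariantKey

_COMP = str.maketrans("ACGTN", "TGCAN")


@dataclass
class Contig:
    contig_id: str
    sequence: str
    source: str = "coculture"  # cell | ctDNA | coculture


@dataclass
class TransitionPoint:
    """A cell -> ctDNA switch inside one contig.

    ``breakpoint`` is the 0-based contig offset of the boundary adjacent
    to the maximally extended cell segment: for a leading (cell_to_ctdna)
    junction it is the first base past the cell prefix; for a trailing
    (ctdna_to_cell) junction it is the first base of the cell suffix.
    """

    contig_id: str
    breakpoint: int
    orientation: str  # cell_to_ctdna | ctdna_to_cell
    cell_segment: tuple[str, int, int, str]       # (ref contig, start, end, strand)
    ctdna_segment: tuple[str, int, int, str]      # (fragment id, start, end, strand)
    adaptor_adjacent: bool
    junction_gap: int


@dataclass
class InsertionCall:
    transitions: list[TransitionPoint]
    cell_locus: tuple[str, int]
    fragment_id: str
    confirming_private_snvs: list[VariantKey]
    distance_to_origin: int | None  # bp; None == inter-contig
    status: str = "unconfirmed"

    def __post_init__(self) -> None:
        self.status = "confirmed" if self.confirming_private_snvs else "unconfirmed"


@dataclass
class DuplicationEvent:
    contig: str            # reference contig
    start: int
    end: int
    copies: int
    source_contig_id: str
    coculture_unique: bool = True

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# assembly / ingestion


def assemble_or_ingest(
    source,
    mode: str = "ingest",
    *,
    source_label: str = "coculture",
    flank: int = 600,
    truth: TruthTable | None = None,
    genome: GenomeSequence | None = None,
    fragments: Sequence[CtDNAFragment] | None = None,
    k: int = 31,
) -> list[Contig]:
    """Produce contigs for transition analysis.

    ``ingest``: a FASTA path or GenomeSequence, sequences passed through.
    ``perfect``: simulator truth is used to emit one contig per planted
    event spanning the junction(s) plus ``flank`` nt of context — the
    stand-in for an assembler with a perfect error profile.
    ``greedy``: a k-mer unitig extender over error-free simulated reads,
    for desk-scale end-to-end runs without an external assembler.
    """
    if mode == "ingest":
        if isinstance(source, (str, Path)):
            genome_in = GenomeSequence.from_fasta(source, role="coculture")
        else:
            genome_in = source
        contigs = [
            Contig(contig_id=name, sequence=seq, source=source_label)
            for name, seq in genome_in.sequences.items()
        ]
        if not contigs:
            raise ValueError("empty contig input")
        return contigs

    if mode == "perfect":
        if truth is None or genome is None:
            raise ValueError("perfect mode needs the simulation truth and the coculture genome")
        frag_len = {f.fragment_id: len(f.core) for f in fragments or []}
        contigs = []
        for ins in truth.planted_insertions:
            seq = genome.sequences[ins.contig]
            core_len = frag_len.get(ins.fragment_id, 0)
            start = max(0, ins.cocu_position - flank)
            end = min(len(seq), ins.cocu_position + core_len + flank)
            contigs.append(
                Contig(
                    contig_id=f"ins_{ins.contig}_{ins.position}_{ins.fragment_id}",
                    sequence=seq[start:end],
                    source=source_label,
                )
            )
        for i, dup in enumerate(truth.planted_duplications):
            seq = genome.sequences[dup.contig]
            start = max(0, dup.cocu_position - flank)
            end = min(len(seq), dup.cocu_position + dup.length + flank)
            contigs.append(
                Contig(
                    contig_id=f"dup_{dup.contig}_{dup.start}_{i}",
                    sequence=seq[start:end],
                    source=source_label,
                )
            )
        if not contigs:
            raise ValueError("empty contig input: no planted events in truth")
        return contigs

    if mode == "greedy":
        return _greedy_assemble(source, k=k, source_label=source_label)

    raise ValueError(f"unknown assembly mode {mode!r}")


def _greedy_assemble(reads: ReadSet, k: int = 31, source_label: str = "coculture") -> list[Contig]:
    """Unitig walker over the de Bruijn graph of genomic-orientation read k-mers.

    Deterministic: start k-mers are processed in sorted order and each
    extension step requires a unique successor.
    """
    kmers: set[str] = set()
    for pair in reads.pairs:
        for _start, bases in pair.genomic_segments():
            for i in range(len(bases) - k + 1):
                km = bases[i : i + k]
                if "N" not in km:
                    kmers.add(km)
    if not kmers:
        raise ValueError("empty input")

    def successors(km: str) -> list[str]:
        return [km[1:] + b for b in "ACGT" if km[1:] + b in kmers]

    def predecessors(km: str) -> list[str]:
        return [b + km[:-1] for b in "ACGT" if b + km[:-1] in kmers]

    starts = sorted(km for km in kmers if len(predecessors(km)) != 1 or len(successors(predecessors(km)[0])) != 1)
    visited: set[str] = set()
    contigs: list[Contig] = []
    for start_km in starts:
        if start_km in visited:
            continue
        path = [start_km]
        visited.add(start_km)
        km = start_km
        while True:
            nxt = successors(km)
            if len(nxt) != 1 or nxt[0] in visited:
                break
            km = nxt[0]
            visited.add(km)
            path.append(km)
        seq = path[0] + "".join(p[-1] for p in path[1:])
        if len(seq) >= 2 * k:
            contigs.append(Contig(contig_id=f"utg{len(contigs):05d}", sequence=seq, source=source_label))
    return contigs


# ---------------------------------------------------------------------------
# k-mer anchoring machinery


def _index_kmers(sequences: Mapping[str, str], k: int) -> dict[str, tuple[str, int] | None]:
    """Forward k-mer -> (contig, pos); repeated k-mers map to None."""
    index: dict[str, tuple[str, int] | None] = {}
    for contig, seq in sequences.items():
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            index[km] = None if km in index else (contig, i)
    return index


@dataclass
class _Block:
    source: str        # cell | ctdna
    ref: str           # reference contig / fragment id
    strand: str        # + | -
    q_start: int
    q_end: int
    r_start: int
    r_end: int
    n_anchors: int = 1

    @property
    def q_len(self) -> int:
        return self.q_end - self.q_start


def _extend_block(
    block: _Block,
    query: str,
    ref_seq: str,
    *,
    mismatch_lookahead: int = 8,
    max_mismatch_per_100: float = 1.0,
) -> _Block:
    """Ungapped extension of a seeded block along its diagonal.

    A mismatch is skipped only when the mismatch budget (``max_mismatch_
    per_100`` per 100 extended nt) allows it AND the next ``mismatch_
    lookahead`` bases match — so extension never creeps past a junction
    into randomly matching sequence. Ends are trimmed back to a match.
    """

    def q2r(q: int) -> int:
        if block.strand == "+":
            return block.r_start + (q - block.q_start)
        return (block.r_end - 1) - (q - block.q_start)

    def ref_base(q: int) -> str | None:
        r = q2r(q)
        if not 0 <= r < len(ref_seq):
            return None
        base = ref_seq[r]
        return base if block.strand == "+" else base.translate(_COMP)

    budget = lambda length: int(length * max_mismatch_per_100 / 100)

    def extend(pos: int, step: int) -> int:
        """Return the new exclusive/inclusive boundary after extension."""
        mismatches = 0
        length = block.q_len
        last_match = pos - step  # last position known to match
        while 0 <= pos < len(query):
            rb = ref_base(pos)
            if rb is None:
                break
            if query[pos] == rb:
                last_match = pos
                pos += step
                length += 1
                continue
            if mismatches + 1 > budget(length + mismatch_lookahead):
                break
            ok = True
            probe = pos + step
            for _ in range(mismatch_lookahead):
                if not 0 <= probe < len(query):
                    ok = False
                    break
                rb2 = ref_base(probe)
                if rb2 is None or query[probe] != rb2:
                    ok = False
                    break
                probe += step
            if not ok:
                break
            mismatches += 1
            pos += step
            length += 1
        return last_match

    right = extend(block.q_end, +1)
    left = extend(block.q_start - 1, -1)
    new_q_start = min(left + 1, block.q_start)
    new_q_end = max(right + 1, block.q_end)
    if block.strand == "+":
        delta_l = block.q_start - new_q_start
        delta_r = new_q_end - block.q_end
        return _Block(block.source, block.ref, "+", new_q_start, new_q_end,
                      block.r_start - delta_l, block.r_end + delta_r, block.n_anchors)
    delta_l = block.q_start - new_q_start
    delta_r = new_q_end - block.q_end
    return _Block(block.source, block.ref, "-", new_q_start, new_q_end,
                  block.r_start - delta_r, block.r_end + delta_l, block.n_anchors)


def _seed_blocks(
    query: str,
    indexes: Mapping[str, dict[str, tuple[str, int] | None]],
    ref_seqs: Mapping[str, Mapping[str, str]],
    k: int,
    *,
    mismatch_lookahead: int = 8,
    max_mismatch_per_100: float = 1.0,
) -> list[_Block]:
    """Seed anchors with source-unique k-mers, group by diagonal, extend.

    ``indexes``/``ref_seqs`` are keyed by source name ("cell", "ctdna");
    k-mers present in more than one source are ambiguous and discarded.
    """
    sources = list(indexes)
    # group key -> (min q, max q, anchor count)
    groups: dict[tuple[str, str, str, int], tuple[int, int, int]] = {}
    for i in range(len(query) - k + 1):
        km = query[i : i + k]
        if "N" in km:
            continue
        hits = []
        for src in sources:
            fwd = indexes[src].get(km)
            rev = indexes[src].get(revcomp(km))
            if fwd is not None:
                hits.append((src, fwd, "+"))
            if rev is not None:
                hits.append((src, rev, "-"))
            if km in indexes[src] and fwd is None:
                hits.append(None)  # repeated within source: poison
            if revcomp(km) in indexes[src] and rev is None and revcomp(km) != km:
                hits.append(None)
        if len(hits) != 1 or hits[0] is None:
            continue
        src, (ref_contig, rpos), strand = hits[0]
        if strand == "+":
            key = (src, ref_contig, "+", rpos - i)
        else:
            key = (src, ref_contig, "-", rpos + i)  # anti-diagonal constant
        lo, hi, n = groups.get(key, (i, i, 0))
        groups[key] = (min(lo, i), max(hi, i), n + 1)

    blocks: list[_Block] = []
    for (src, ref_contig, strand, diag), (lo, hi, n) in groups.items():
        q_start, q_end = lo, hi + k
        if strand == "+":
            r_start, r_end = diag + q_start, diag + q_end
        else:
            r_start, r_end = diag - hi, diag - lo + k
        seed = _Block(src, ref_contig, strand, q_start, q_end, r_start, r_end, n_anchors=n)
        blocks.append(
            _extend_block(
                seed,
                query,
                ref_seqs[src][ref_contig],
                mismatch_lookahead=mismatch_lookahead,
                max_mismatch_per_100=max_mismatch_per_100,
            )
        )
    # suppress blocks mostly covered (on the contig) by a block with more
    # anchor support: chance microhomology at a junction can seed a 1-anchor
    # block onto a homologous region of the wrong reference, and a fragment
    # core with sparse private SNVs also extends along the cell diagonal of
    # its origin locus — the block with the most source-unique seeds wins
    blocks.sort(
        key=lambda b: (-b.n_anchors, -b.q_len, b.source, b.ref, b.strand, b.r_start)
    )
    kept: list[_Block] = []
    for b in blocks:
        shadowed = False
        for o in kept:
            overlap = min(o.q_end, b.q_end) - max(o.q_start, b.q_start)
            if overlap > 0.5 * min(o.q_len, b.q_len):
                shadowed = True
                break
        if not shadowed:
            kept.append(b)
    return kept


# ---------------------------------------------------------------------------
# transition detection


class TransitionDetector:
    """Caches the reference/fragment k-mer indexes across contigs."""

    def __init__(
        self,
        cell_ref: GenomeSequence,
        ctdna_refs: Sequence[CtDNAFragment],
        adaptor: str,
        anchor_k: int = 31,
        max_gap: int = 20,
        adaptor_search_window: int = 30,
        min_block: int = 40,
    ) -> None:
        if anchor_k < 21:
            raise ValueError("anchor_k must be >= 21")
        self.anchor_k = anchor_k
        self.max_gap = max_gap
        self.adaptor = adaptor
        self.adaptor_search_window = adaptor_search_window
        self.min_block = min_block
        self.cell_ref = cell_ref
        self.fragments = {f.fragment_id: f for f in ctdna_refs}
        frag_seqs = {f.fragment_id: f.sequence for f in ctdna_refs}
        self.ref_seqs = {"cell": cell_ref.sequences, "ctdna": frag_seqs}
        self.indexes = {
            "cell": _index_kmers(cell_ref.sequences, anchor_k),
            "ctdna": _index_kmers(frag_seqs, anchor_k),
        }

    def detect(self, contig: Contig) -> list[TransitionPoint]:
        query = contig.sequence
        blocks = [
            b
            for b in _seed_blocks(query, self.indexes, self.ref_seqs, self.anchor_k)
            if b.q_len >= self.min_block
        ]
        cell_blocks = sorted(
            (b for b in blocks if b.source == "cell"), key=lambda b: b.q_start
        )
        ctdna_blocks = sorted(
            (b for b in blocks if b.source == "ctdna"), key=lambda b: b.q_start
        )
        transitions: list[TransitionPoint] = []
        for B in ctdna_blocks:
            lead = self._best_flank(B, cell_blocks, side="lead")
            if lead is not None:
                transitions.append(self._junction(contig, query, "cell_to_ctdna", lead, B))
            trail = self._best_flank(B, cell_blocks, side="trail")
            if trail is not None:
                transitions.append(self._junction(contig, query, "ctdna_to_cell", trail, B))
        transitions.sort(key=lambda t: t.breakpoint)
        return transitions

    def _best_flank(self, B: _Block, cell_blocks: list[_Block], side: str) -> _Block | None:
        """Cell block abutting the ctDNA block within max_gap; when chance
        microhomology offers several, the one with the most anchors wins."""
        candidates = []
        for C in cell_blocks:
            if side == "lead":
                if C.q_start < B.q_start and C.q_end <= B.q_end and B.q_start - C.q_end <= self.max_gap:
                    candidates.append(C)
            else:
                if C.q_end > B.q_end and C.q_start >= B.q_start and C.q_start - B.q_end <= self.max_gap:
                    candidates.append(C)
        if not candidates:
            return None
        return max(candidates, key=lambda c: (c.n_anchors, c.q_len, -c.q_start))

    def _junction(
        self, contig: Contig, query: str, orientation: str, C: _Block, B: _Block
    ) -> TransitionPoint:
        if orientation == "cell_to_ctdna":
            breakpoint_ = C.q_end
            gap = max(0, B.q_start - C.q_end)
        else:
            breakpoint_ = C.q_start
            gap = max(0, C.q_start - B.q_end)
        return TransitionPoint(
            contig_id=contig.contig_id,
            breakpoint=breakpoint_,
            orientation=orientation,
            cell_segment=(C.ref, C.r_start, C.r_end, C.strand),
            ctdna_segment=(B.ref, B.r_start, B.r_end, B.strand),
            adaptor_adjacent=self._adaptor_adjacent(query, orientation, B),
            junction_gap=gap,
        )

    def _adaptor_adjacent(self, query: str, orientation: str, ctdna_b: _Block) -> bool:
        """Adaptor evidence for the ctDNA side of a junction.

        True when the adaptor motif (<= 1 mismatch, either orientation)
        occurs within the search window of the ctDNA-side contig end, or
        when the matched fragment segment reaches within the window of a
        ligated adaptor end of that fragment.
        """
        w = self.adaptor_search_window + len(self.adaptor)
        end_seq = query[-w:] if orientation == "cell_to_ctdna" else query[:w]
        if _motif_near(end_seq, self.adaptor, max_mismatch=1):
            return True
        frag = self.fragments.get(ctdna_b.ref)
        if frag is None:
            return False
        # junction-side fragment coordinate
        if orientation == "cell_to_ctdna":
            b_f = ctdna_b.r_start if ctdna_b.strand == "+" else ctdna_b.r_end
        else:
            b_f = ctdna_b.r_end if ctdna_b.strand == "+" else ctdna_b.r_start
        a = len(frag.adaptor)
        if frag.adaptor_5 and b_f - a <= self.adaptor_search_window:
            return True
        if frag.adaptor_3 and (len(frag.sequence) - a) - b_f <= self.adaptor_search_window:
            return True
        return False


def _motif_near(window: str, motif: str, max_mismatch: int = 1) -> bool:
    for probe in (motif, revcomp(motif)):
        m = len(probe)
        for i in range(len(window) - m + 1):
            mism = sum(1 for a, b in zip(window[i : i + m], probe) if a != b)
            if mism <= max_mismatch:
                return True
    return False


def detect_transitions(
    contig: Contig,
    cell_ref: GenomeSequence,
    ctdna_refs: Sequence[CtDNAFragment],
    adaptor: str,
    anchor_k: int = 31,
    max_gap: int = 20,
    adaptor_search_window: int = 30,
) -> list[TransitionPoint]:
    """One-shot wrapper around :class:`TransitionDetector` (see spec of the
    detector for the algorithm)."""
    det = TransitionDetector(
        cell_ref, ctdna_refs, adaptor, anchor_k, max_gap, adaptor_search_window
    )
    return det.detect(contig)


# ---------------------------------------------------------------------------
# insertion calls


def confirm_and_call(
    transitions: Sequence[TransitionPoint],
    soi: set[VariantKey] | None,
    ctdna_private: set[VariantKey],
    fragments: Mapping[str, CtDNAFragment] | Sequence[CtDNAFragment] = (),
) -> list[InsertionCall]:
    """Turn transitions into insertion calls confirmed by private SNVs.

    Transitions on one contig that bound the same fragment merge into a
    double-junction call. A call is ``confirmed`` when at least one
    ctDNA-private SNV falls inside the inserted fragment segment (lifted
    to donor coordinates through the fragment origin).
    """
    if not isinstance(fragments, Mapping):
        fragments = {f.fragment_id: f for f in fragments}
    by_contig: dict[str, list[TransitionPoint]] = {}
    for t in transitions:
        by_contig.setdefault(t.contig_id, []).append(t)

    calls: list[InsertionCall] = []
    for contig_id in sorted(by_contig):
        tps = sorted(by_contig[contig_id], key=lambda t: t.breakpoint)
        used = [False] * len(tps)
        for i, t in enumerate(tps):
            if used[i]:
                continue
            group = [t]
            used[i] = True
            if t.orientation == "cell_to_ctdna":
                for j in range(i + 1, len(tps)):
                    if (
                        not used[j]
                        and tps[j].orientation == "ctdna_to_cell"
                        and tps[j].ctdna_segment[0] == t.ctdna_segment[0]
                    ):
                        group.append(tps[j])
                        used[j] = True
                        break
            calls.append(_make_call(group, ctdna_private, fragments))

    # merge duplicate views of the same integration event: contigs spanning
    # two nearby insertions each report both, so the same fragment can be
    # called from more than one contig (locus jitter <= microhomology)
    calls.sort(
        key=lambda c: (-len(c.transitions), -len(c.confirming_private_snvs), c.cell_locus)
    )
    deduped: list[InsertionCall] = []
    for call in calls:
        if any(
            other.fragment_id == call.fragment_id
            and other.cell_locus[0] == call.cell_locus[0]
            and abs(other.cell_locus[1] - call.cell_locus[1]) <= 10
            for other in deduped
        ):
            continue
        deduped.append(call)
    deduped.sort(key=lambda c: (c.cell_locus, c.fragment_id))
    return deduped


def _make_call(
    group: list[TransitionPoint],
    ctdna_private: set[VariantKey],
    fragments: Mapping[str, CtDNAFragment],
) -> InsertionCall:
    lead = group[0]
    frag_id = lead.ctdna_segment[0]
    # insertion point on the cell reference: boundary of the cell segment
    ref_contig, r_start, r_end, strand = lead.cell_segment
    if lead.orientation == "cell_to_ctdna":
        cell_pos = r_end if strand == "+" else r_start
    else:
        cell_pos = r_start if strand == "+" else r_end
    # inserted fragment interval (fragment coordinates)
    f_lo = min(t.ctdna_segment[1] for t in group)
    f_hi = max(t.ctdna_segment[2] for t in group)
    frag = fragments.get(frag_id)
    confirming: list[VariantKey] = []
    distance: int | None = None
    if frag is not None:
        o_contig, o_start, o_end = frag.origin
        off = frag.core_offset
        d_lo = max(o_start, o_start + (f_lo - off))
        d_hi = min(o_end, o_start + (f_hi - off))
        confirming = sorted(
            (k for k in ctdna_private if k.contig == o_contig and d_lo <= k.pos < d_hi),
            key=lambda k: (k.contig, k.pos),
        )
        if ref_contig == o_contig:
            distance = abs(cell_pos - o_start)
    return InsertionCall(
        transitions=group,
        cell_locus=(ref_contig, cell_pos),
        fragment_id=frag_id,
        confirming_private_snvs=confirming,
        distance_to_origin=distance,
    )


# ---------------------------------------------------------------------------
# duplications


def detect_duplications(
    coculture_contigs: Sequence[Contig],
    cell_ref: GenomeSequence,
    min_len: int = 10,
    soi_filter: set[VariantKey] | None = None,
    *,
    anchor_k: int = 31,
    cell_contigs: Sequence[Contig] | None = None,
) -> list[DuplicationEvent]:
    """Reference intervals covered more than once by a single contig.

    Extension is exact (no mismatch skipping) so event lengths are sharp;
    events also present in ``cell_contigs`` lose their coculture_unique
    flag. With ``soi_filter``, only events on contigs whose mapped span
    contains a filter SNV position are kept.
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    index = {"cell": _index_kmers(cell_ref.sequences, anchor_k)}
    refs = {"cell": cell_ref.sequences}

    def events_for(contigs: Sequence[Contig]) -> list[DuplicationEvent]:
        out: list[DuplicationEvent] = []
        for contig in contigs:
            blocks = [
                b
                for b in _seed_blocks(
                    contig.sequence, index, refs, anchor_k, max_mismatch_per_100=0.0
                )
                if b.q_len >= anchor_k
            ]
            # depth sweep over reference intervals, per reference contig
            by_ref: dict[str, list[tuple[int, int]]] = {}
            for b in blocks:
                by_ref.setdefault(b.ref, []).append((b.r_start, b.r_end))
            span_contains_soi = (
                soi_filter is None
                or any(
                    k.contig == ref and s <= k.pos < e
                    for ref, ivs in by_ref.items()
                    for s, e in ivs
                    for k in soi_filter
                )
            )
            if not span_contains_soi:
                continue
            for ref, ivs in by_ref.items():
                edges: list[tuple[int, int]] = []
                for s, e in ivs:
                    edges.append((s, +1))
                    edges.append((e, -1))
                edges.sort()
                depth = 0
                run_start = None
                for pos, delta in edges:
                    prev = depth
                    depth += delta
                    if prev < 2 <= depth:
                        run_start = pos
                    elif prev >= 2 > depth and run_start is not None:
                        if pos - run_start >= min_len:
                            max_copies = max(
                                sum(1 for s, e in ivs if s <= p < e)
                                for p in (run_start, pos - 1)
                            )
                            out.append(
                                DuplicationEvent(
                                    contig=ref,
                                    start=run_start,
                                    end=pos,
                                    copies=max_copies,
                                    source_contig_id=contig.contig_id,
                                )
                            )
                        run_start = None
        return out

    events = events_for(coculture_contigs)
    if cell_contigs:
        cell_events = {
            (e.contig, e.start, e.end) for e in events_for(cell_contigs)
        }
        for e in events:
            if (e.contig, e.start, e.end) in cell_events:
                e.coculture_unique = False
    events.sort(key=lambda e: (e.contig, e.start, e.end))
    return events


# ---------------------------------------------------------------------------
# summaries and serialisation


@dataclass
class StructuralGainSummary:
    insertions: int
    confirmed_insertions: int
    duplications: int
    coculture_unique_duplications: int
    proximal_insertions: int
    proximity_window: int

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def count_structural_gain(
    calls: Sequence[InsertionCall],
    duplications: Sequence[DuplicationEvent],
    proximity_window: int = 10_000,
) -> StructuralGainSummary:
    """Per-class event counts after locus deduplication."""
    seen: set[tuple[str, int, str]] = set()
    uniq_calls = []
    for c in calls:
        key = (c.cell_locus[0], c.cell_locus[1], c.fragment_id)
        if key not in seen:
            seen.add(key)
            uniq_calls.append(c)
    dup_keys = {(d.contig, d.start, d.end) for d in duplications}
    uniq_dups = []
    taken: set[tuple[str, int, int]] = set()
    for d in duplications:
        key = (d.contig, d.start, d.end)
        if key not in taken:
            taken.add(key)
            uniq_dups.append(d)
    return StructuralGainSummary(
        insertions=len(uniq_calls),
        confirmed_insertions=sum(1 for c in uniq_calls if c.status == "confirmed"),
        duplications=len(uniq_dups),
        coculture_unique_duplications=sum(1 for d in uniq_dups if d.coculture_unique),
        proximal_insertions=sum(
            1
            for c in uniq_calls
            if c.distance_to_origin is not None and c.distance_to_origin <= proximity_window
        ),
        proximity_window=proximity_window,
    )


def transitions_to_tsv(transitions: Iterable[TransitionPoint], path: str | Path) -> None:
    """TSV (1-based breakpoint column, per the BED/TSV convention split)."""
    lines = [
        "contig_id\tbreakpoint_1based\torientation\tcell_contig\tcell_start\tcell_end\tcell_strand\t"
        "fragment_id\tfrag_start\tfrag_end\tfrag_strand\tadaptor_adjacent\tjunction_gap"
    ]
    for t in transitions:
        cc, cs, ce, cst = t.cell_segment
        fi, fs, fe, fst = t.ctdna_segment
        lines.append(
            f"{t.contig_id}\t{t.breakpoint + 1}\t{t.orientation}\t{cc}\t{cs}\t{ce}\t{cst}\t"
            f"{fi}\t{fs}\t{fe}\t{fst}\t{int(t.adaptor_adjacent)}\t{t.junction_gap}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def calls_to_tsv(calls: Iterable[InsertionCall], path: str | Path) -> None:
    lines = [
        "cell_contig\tcell_pos\tfragment_id\tstatus\tn_confirming_snvs\tdistance_to_origin\tn_junctions"
    ]
    for c in calls:
        dist = c.distance_to_origin if c.distance_to_origin is not None else "inter-contig"
        lines.append(
            f"{c.cell_locus[0]}\t{c.cell_locus[1]}\t{c.fragment_id}\t{c.status}\t"
            f"{len(c.confirming_private_snvs)}\t{dist}\t{len(c.transitions)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def duplications_to_bed(events: Iterable[DuplicationEvent], path: str | Path) -> None:
    lines = [
        f"{e.contig}\t{e.start}\t{e.end}\tcopies={e.copies};unique={int(e.coculture_unique)};contig={e.source_contig_id}"
        for e in events
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
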
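"""Transgene cassette integration calling from discordant read pairs.

A cassette (e.g. a CMV-mCherry construct) integrated into the host genome
produces read pairs with one mate on the host reference and the other on
the cassette. Pairs are anchored by k-mers unique to one reference,
clustered by genomic position, and each cluster is scored for confidence
(against a Poisson background of stray discordant pairs) and frequency
(support relative to the expected junction-spanning pair coverage).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .genomes import GenomeSequence, revcomp
from .simulate import ReadSet


@dataclass
class DiscordantPair:
    read_id: str
    genome_side: tuple[str, int, str]  # (contig, pos, strand) of the cell-aligned read
    cassette_side: tuple[int, str]     # (pos, strand) on the cassette
    unique_anchor: bool = True


@dataclass
class TransgeneInsertionSite:
    contig: str
    start: int
    end: int
    supporting_pairs: int
    left_support: int
    right_support: int
    confidence: float
    frequency: float


def _kmer_index(sequences: dict[str, str], k: int) -> dict[str, tuple[str, int]]:
    index: dict[str, tuple[str, int] | None] = {}
    for contig, seq in sequences.items():
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            index[km] = None if km in index else (contig, i)
    return {km: hit for km, hit in index.items() if hit is not None}


def _map_read(
    read: str,
    index: dict[str, tuple[str, int]],
    sequences: dict[str, str],
    k: int,
) -> tuple[str, int, str] | None:
    """Unique-anchor mapping with a verification extension.

    Tries a few anchor offsets on both orientations; a hit must extend to
    >= 90% identity over the read to count.
    """
    offsets = (0, max(0, (len(read) - k) // 2), max(0, len(read) - k))
    for strand, seq in (("+", read), ("-", revcomp(read))):
        for off in offsets:
            km = seq[off : off + k]
            hit = index.get(km)
            if hit is None:
                continue
            contig, pos = hit
            start = pos - off
            ref = sequences[contig]
            if start < 0 or start + len(seq) > len(ref):
                continue
            matches = sum(1 for a, b in zip(seq, ref[start : start + len(seq)]) if a == b)
            if matches >= 0.9 * len(seq):
                return contig, start, strand
    return None


def find_discordant_pairs(
    read_pairs: ReadSet,
    cell_ref: GenomeSequence,
    cassette: GenomeSequence,
    anchor_k: int = 31,
) -> list[DiscordantPair]:
    """Pairs with one mate anchored on the host genome and the other on the cassette.

    Hard error when the cassette shares a >= anchor_k exact substring with
    the host reference (the design would be ambiguous). Concordant pairs
    and cassette-internal pairs are discarded.
    """
    cassette_name = next(iter(cassette.sequences))
    cassette_seq = cassette.sequences[cassette_name]
    cell_index = _kmer_index(cell_ref.sequences, anchor_k)
    for i in range(len(cassette_seq) - anchor_k + 1):
        km = cassette_seq[i : i + anchor_k]
        if km in cell_index or revcomp(km) in cell_index:
            raise ValueError(
                f"cassette shares a {anchor_k}-mer with the host reference; ambiguous design"
            )
    cassette_index = _kmer_index(cassette.sequences, anchor_k)

    pairs: list[DiscordantPair] = []
    for pair in read_pairs.pairs:
        maps = []
        for read in (pair.r1, pair.r2):
            cell_hit = _map_read(read, cell_index, cell_ref.sequences, anchor_k)
            cas_hit = _map_read(read, cassette_index, cassette.sequences, anchor_k)
            if cell_hit and cas_hit:
                maps.append(None)  # ambiguous
            elif cell_hit:
                maps.append(("cell", cell_hit))
            elif cas_hit:
                maps.append(("cassette", cas_hit))
            else:
                maps.append(None)
        sides = {m[0] for m in maps if m}
        if sides != {"cell", "cassette"}:
            continue  # concordant, cassette-internal, or unmapped
        (kind1, hit1), (kind2, hit2) = maps  # type: ignore[misc]
        genome_hit = hit1 if kind1 == "cell" else hit2
        cas_hit = hit2 if kind1 == "cell" else hit1
        pairs.append(
            DiscordantPair(
                read_id=pair.name,
                genome_side=genome_hit,
                cassette_side=(cas_hit[1], cas_hit[2]),
            )
        )
    pairs.sort(key=lambda p: (p.genome_side[0], p.genome_side[1]))
    return pairs


def cluster_sites(
    pairs: Sequence[DiscordantPair],
    insert_model: tuple[float, float] = (300.0, 30.0),
    min_support: int = 3,
    *,
    genome_length: int | None = None,
    expected_pair_coverage: float | None = None,
) -> list[TransgeneInsertionSite]:
    """Single-linkage clustering of discordant pairs into insertion sites.

    Clusters with a genomic gap <= insert mean + 3 sd merge; sites below
    ``min_support`` are dropped. Confidence is one minus the Poisson
    probability of observing at least the cluster's support from the
    off-site (background) discordant density; frequency is support divided
    by the expected junction-spanning pair count (estimated from the
    median cluster support when not supplied).
    """
    mean, sd = insert_model
    gap_limit = mean + 3 * sd
    if not pairs:
        return []
    ordered = sorted(pairs, key=lambda p: (p.genome_side[0], p.genome_side[1]))
    clusters: list[list[DiscordantPair]] = [[ordered[0]]]
    for p in ordered[1:]:
        prev = clusters[-1][-1]
        if (
            p.genome_side[0] == prev.genome_side[0]
            and p.genome_side[1] - prev.genome_side[1] <= gap_limit
        ):
            clusters[-1].append(p)
        else:
            clusters.append([p])

    supported = [c for c in clusters if len(c) >= min_support]
    n_background = sum(len(c) for c in clusters if len(c) < min_support)
    if genome_length is None:
        genome_length = max(
            (p.genome_side[1] for p in ordered), default=1
        ) + int(gap_limit)
    bg_rate = max(n_background / genome_length, 1e-9)  # pairs per bp
    window = 2 * gap_limit

    if expected_pair_coverage is None:
        expected_pair_coverage = float(np.median([len(c) for c in supported])) if supported else 1.0

    sites: list[TransgeneInsertionSite] = []
    for cluster in supported:
        positions = [p.genome_side[1] for p in cluster]
        start, end = min(positions), max(positions)
        left = sum(1 for p in cluster if p.genome_side[2] == "+")
        right = len(cluster) - left
        lam = bg_rate * window
        # 1 - P(background alone yields >= this support)
        confidence = float(stats.poisson.cdf(len(cluster) - 1, lam))
        sites.append(
            TransgeneInsertionSite(
                contig=cluster[0].genome_side[0],
                start=start,
                end=end,
                supporting_pairs=len(cluster),
                left_support=left,
                right_support=right,
                confidence=confidence,
                frequency=len(cluster) / expected_pair_coverage,
            )
        )
    sites.sort(key=lambda s: (s.contig, s.start))
    return sites


def sites_to_tsv(sites: Iterable[TransgeneInsertionSite], path: str | Path) -> None:
    lines = ["contig\tstart\tend\tsupporting_pairs\tleft\tright\tconfidence\tfrequency"]
    for s in sites:
        lines.append(
            f"{s.contig}\t{s.start}\t{s.end}\t{s.supporting_pairs}\t{s.left_support}\t"
            f"{s.right_support}\t{s.confidence:.4f}\t{s.frequency:.3f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
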
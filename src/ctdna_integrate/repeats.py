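"""Transposable-element annotation and enrichment statistics.

Sequences (ctDNA fragments or contigs) are scanned against a TE consensus
library by Smith-Waterman local alignment on both strands. Hits are then
filtered to the 100-nt window around cell -> ctDNA transition points that
also carry adaptor evidence, tested for integrated-vs-non-integrated
enrichment with a 1-df chi-square, and reduced to tissue-specific
elements (present in matched cocultures, absent from mismatched ones).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align
from scipy import stats

from .genomes import TEConsensus, revcomp
from .transitions import InsertionCall, TransitionPoint


@dataclass
class RepeatAnnotation:
    subject_id: str
    te_name: str
    te_class: str
    start: int          # 0-based half-open on the subject
    end: int
    strand: str
    score: float
    percent_identity: float

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class EnrichmentResult:
    """2x2 chi-square summary over TE+/TE- fragment classes."""

    table: tuple[tuple[int, int], tuple[int, int]]  # [[TE+, TE-] integrated, [TE+, TE-] non-integrated]
    chi_square: float
    dof: int
    p_value: float
    odds_ratio: float
    expected_warning: bool = False
    fisher_p: float | None = None

    def to_dict(self) -> dict:
        return {
            "table": [list(self.table[0]), list(self.table[1])],
            "chi_square": self.chi_square,
            "dof": self.dof,
            "p_value": self.p_value,
            "odds_ratio": self.odds_ratio,
            "expected_warning": self.expected_warning,
            "fisher_p": self.fisher_p,
        }


def _make_aligner(match: float, mismatch: float, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def scan_repeats(
    subject: str,
    library: Sequence[TEConsensus],
    min_score: float = 40.0,
    min_identity: float = 0.80,
    subject_id: str = "subject",
    *,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
) -> list[RepeatAnnotation]:
    """Best local alignment of each library consensus on both strands.

    Hits with score >= ``min_score`` and identity >= ``min_identity`` are
    reported; overlapping hits to different elements are resolved by
    score, then alignment length, then element name. Deterministic.
    """
    if not library:
        raise ValueError("TE library must be non-empty")
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend)
    raw: list[RepeatAnnotation] = []
    for te in library:
        for strand, query in (("+", te.sequence), ("-", revcomp(te.sequence))):
            alignments = aligner.align(subject, query)
            if alignments.score < min_score:
                continue
            aln = alignments[0]
            blocks = aln.aligned[0]
            start, end = int(blocks[0][0]), int(blocks[-1][1])
            matches = sum(
                1
                for (ts, te_), (qs, qe) in zip(aln.aligned[0], aln.aligned[1])
                for a, b in zip(subject[ts:te_], query[qs:qe])
                if a == b
            )
            columns = aln.length
            identity = matches / columns if columns else 0.0
            if identity < min_identity:
                continue
            raw.append(
                RepeatAnnotation(
                    subject_id=subject_id,
                    te_name=te.name,
                    te_class=te.te_class,
                    start=start,
                    end=end,
                    strand=strand,
                    score=float(alignments.score),
                    percent_identity=100.0 * identity,
                )
            )
    raw.sort(key=lambda h: (-h.score, -(h.end - h.start), h.te_name, h.strand))
    kept: list[RepeatAnnotation] = []
    for hit in raw:
        if any(
            other.te_name != hit.te_name and other.start < hit.end and hit.start < other.end
            for other in kept
        ):
            continue
        if any(other.te_name == hit.te_name and other.strand != hit.strand
               and other.start < hit.end and hit.start < other.end for other in kept):
            continue
        kept.append(hit)
    kept.sort(key=lambda h: (h.start, h.te_name))
    return kept


def filter_transition_proximal(
    annotations: Sequence[RepeatAnnotation],
    transition: TransitionPoint,
    window: int = 100,
    require_adaptor: bool = True,
) -> list[RepeatAnnotation]:
    """Keep TE hits whose nearest edge is within ``window`` nt (inclusive)
    of the transition breakpoint, on the ctDNA side.

    With ``require_adaptor``, a transition lacking adaptor evidence
    contributes nothing — mirroring the selection of TE sequences close to
    the transition point and next to the ligated adaptor.
    """
    if require_adaptor and not transition.adaptor_adjacent:
        return []
    b = transition.breakpoint
    ctdna_right = transition.orientation == "cell_to_ctdna"
    kept = []
    for hit in annotations:
        if ctdna_right:
            if hit.end <= b:          # entirely on the cell side
                continue
            distance = max(0, hit.start - b)
        else:
            if hit.start >= b:
                continue
            distance = max(0, b - hit.end)
        if distance <= window:
            kept.append(hit)
    return kept


def enrichment_test(
    integrated: Sequence[bool] | tuple[int, int],
    non_integrated: Sequence[bool] | tuple[int, int],
    continuity_correction: bool = False,
) -> EnrichmentResult:
    """Pearson chi-square (1 df) on the TE+/TE- x integrated/non-integrated table.

    Inputs are per-fragment TE presence labels, or precomputed
    (TE+, TE-) count pairs. Odds ratio uses the Haldane correction when a
    zero cell exists; with any expected count < 5 a warning is raised and
    the exact (Fisher) p-value is reported alongside.
    """
    def to_counts(arm) -> tuple[int, int]:
        if isinstance(arm, tuple) and len(arm) == 2 and all(isinstance(x, (int, np.integer)) for x in arm):
            return int(arm[0]), int(arm[1])
        flags = [bool(x) for x in arm]
        return sum(flags), len(flags) - sum(flags)

    a, b = to_counts(integrated)
    c, d = to_counts(non_integrated)
    table = np.array([[a, b], [c, d]], dtype=float)
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        raise ValueError("zero margin: chi-square statistic undefined")
    chi2, p, dof, expected = stats.chi2_contingency(table, correction=continuity_correction)
    exp_warn = bool((expected < 5).any())
    fisher_p = None
    if exp_warn:
        warnings.warn("expected count < 5 in the 2x2 table; exact test also reported")
        _, fisher_p = stats.fisher_exact([[a, b], [c, d]])
        fisher_p = float(fisher_p)
    if 0 in (a, b, c, d):
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return EnrichmentResult(
        table=((a, b), (c, d)),
        chi_square=float(chi2),
        dof=int(dof),
        p_value=float(p),
        odds_ratio=float(odds),
        expected_warning=exp_warn,
        fisher_p=fisher_p,
    )


def tissue_specific_elements(
    matched_insertion_tes: Mapping[str, int] | Iterable[str],
    mismatched_insertion_tes: Mapping[str, int] | Iterable[str],
) -> list[str]:
    """Elements observed at matched-coculture insertions and never at
    mismatched ones, ranked by matched occurrence count (ties by name)."""
    matched = Counter(matched_insertion_tes) if not isinstance(matched_insertion_tes, Mapping) else Counter(dict(matched_insertion_tes))
    mismatched = Counter(mismatched_insertion_tes) if not isinstance(mismatched_insertion_tes, Mapping) else Counter(dict(mismatched_insertion_tes))
    exclusive = [name for name, n in matched.items() if n > 0 and mismatched.get(name, 0) == 0]
    return sorted(exclusive, key=lambda name: (-matched[name], name))


@dataclass
class ProximitySummary:
    proximal_fraction: float
    n_calls: int
    n_proximal: int
    n_inter_contig: int
    window: int
    origin_contig_counts: dict[str, int]

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def proximity_stats(
    calls: Sequence[InsertionCall],
    window: int = 10_000,
    origins: Mapping[str, tuple[str, int, int]] | None = None,
) -> ProximitySummary:
    """Fraction of insertion calls landing within ``window`` of their
    fragment's locus of origin, plus a per-origin-contig histogram.

    Inter-contig insertions count against the proximal fraction. Origin
    contigs come from ``origins`` (fragment_id -> origin) when given, else
    from each call's own cell locus.
    """
    n_proximal = 0
    n_inter = 0
    contig_counts: Counter[str] = Counter()
    for call in calls:
        if call.distance_to_origin is None:
            n_inter += 1
        elif call.distance_to_origin <= window:
            n_proximal += 1
        if origins is not None and call.fragment_id in origins:
            contig_counts[origins[call.fragment_id][0]] += 1
        else:
            contig_counts[call.cell_locus[0]] += 1
    n = len(calls)
    return ProximitySummary(
        proximal_fraction=n_proximal / n if n else float("nan"),
        n_calls=n,
        n_proximal=n_proximal,
        n_inter_contig=n_inter,
        window=window,
        origin_contig_counts=dict(sorted(contig_counts.items())),
    )


def annotations_to_tsv(annotations: Iterable[RepeatAnnotation], path: str | Path) -> None:
    lines = ["subject_id\tte_name\tte_class\tstart\tend\tstrand\tscore\tpercent_identity"]
    for a in annotations:
        lines.append(
            f"{a.subject_id}\t{a.te_name}\t{a.te_class}\t{a.start}\t{a.end}\t{a.strand}\t"
            f"{a.score:.1f}\t{a.percent_identity:.1f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def fragment_te_presence(
    fragments,
    library: Sequence[TEConsensus],
    window: int = 100,
    min_score: float = 40.0,
    min_identity: float = 0.80,
) -> dict[str, list[RepeatAnnotation]]:
    """Per-fragment TE hits with an edge within ``window`` nt of a core end.

    The fragment ends are where the ligated adaptor marks the molecule
    boundary, so this is the fragment-level analogue of the transition-
    proximal filter: a fragment is TE+ when the returned list is non-empty.
    """
    out: dict[str, list[RepeatAnnotation]] = {}
    for frag in fragments:
        core = frag.core
        hits = scan_repeats(core, library, min_score, min_identity, subject_id=frag.fragment_id)
        near_end = [
            h
            for h in hits
            if h.start <= window or (len(core) - h.end) <= window
        ]
        out[frag.fragment_id] = near_end
    return out
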
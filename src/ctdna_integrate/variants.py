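"""Desk-scale SNV calling and three-way variant-set logic.

The comparison at the heart of the analysis is between three samples —
the recipient cell line, the patient ctDNA, and the coculture (cell +
ctDNA) — each called against the same cell reference. "SNVs of interest"
are variants shared by ctDNA and coculture but absent from the cell
genome: the sequence-level evidence that ctDNA entered the recipient
genome.

Calling is a transparent pileup over reads with known origins (the
simulator's perfect-mapping stand-in for an aligner); externally called
VCFs or pileup TSVs can be ingested instead at the same module surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genomes import ALPHABET, CtDNAFragment, GenomeSequence, PositionMap
from .simulate import ReadSet

_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_BASE_LUT = np.full(256, -1, dtype=np.int64)
for _b, _i in _BASE_INDEX.items():
    _BASE_LUT[ord(_b)] = _i


def _encode(bases: str) -> np.ndarray:
    return _BASE_LUT[np.frombuffer(bases.encode("ascii"), dtype=np.uint8)]


class VariantKey(NamedTuple):
    """Hashable atom of the set operations: (contig, pos, ref, alt)."""

    contig: str
    pos: int
    ref_allele: str
    alt_allele: str


@dataclass
class SNVRecord:
    """A single-nucleotide variant with allele depths.

    ``af`` = depth_alt / (depth_ref + depth_alt); positions are 0-based in
    memory and shifted to 1-based only on VCF I/O.
    """

    contig: str
    pos: int
    ref_allele: str
    alt_allele: str
    depth_ref: int
    depth_alt: int
    sample_label: str = "cell"

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        if self.depth_ref < 0 or self.depth_alt < 0:
            raise ValueError("allele depths must be non-negative")

    @property
    def af(self) -> float:
        total = self.depth_ref + self.depth_alt
        return self.depth_alt / total if total else float("nan")

    @property
    def key(self) -> VariantKey:
        return VariantKey(self.contig, self.pos, self.ref_allele, self.alt_allele)


# ---------------------------------------------------------------------------
# pileup + calling


def pileup_from_reads(
    reads: ReadSet,
    reference: GenomeSequence,
    liftover: PositionMap | None = None,
) -> dict[str, np.ndarray]:
    """Per-contig (length, 4) base-count arrays on reference coordinates.

    Reads carry their true origin in the genome they were simulated from;
    ``liftover`` maps those coordinates onto the reference (identity when
    omitted). Bases that lift outside the reference (adaptors, junction
    overhangs) are dropped; reads naming an unknown contig are skipped and
    counted in the returned array's ``.skipped`` attribute-free fashion —
    a warning summarises them.
    """
    counts = {
        contig: np.zeros((len(seq), 4), dtype=np.int32)
        for contig, seq in reference.sequences.items()
    }
    # batch all segments per source contig, then lift and accumulate once
    seg_pos: dict[str, list[np.ndarray]] = {}
    seg_bases: dict[str, list[str]] = {}
    skipped = 0
    for pair in reads.pairs:
        for start, bases in pair.genomic_segments():
            seg_pos.setdefault(pair.contig, []).append(np.arange(start, start + len(bases)))
            seg_bases.setdefault(pair.contig, []).append(bases)

    def accumulate(name: str, pos: np.ndarray, base: np.ndarray) -> None:
        arr = counts[name]
        flat = np.bincount(pos * 4 + base, minlength=arr.size)
        counts[name] = arr + flat.reshape(arr.shape).astype(arr.dtype)

    for src_contig in seg_pos:
        positions = np.concatenate(seg_pos[src_contig])
        base_idx = _encode("".join(seg_bases[src_contig]))
        if liftover is None:
            if src_contig not in counts:
                skipped += len(seg_pos[src_contig])
                continue
            valid = base_idx >= 0
            accumulate(src_contig, positions[valid], base_idx[valid])
        else:
            codes, ref_pos, names = liftover.map_array(src_contig, positions)
            if not names:
                skipped += len(seg_pos[src_contig])
                continue
            for code, name in enumerate(names):
                if name not in counts:
                    continue
                valid = (codes == code) & (base_idx >= 0)
                if valid.any():
                    accumulate(name, ref_pos[valid], base_idx[valid])
    if skipped:
        warnings.warn(f"{skipped} read segments skipped (contig absent from reference)")
    return counts


def call_snvs(
    reads: ReadSet | Mapping[str, np.ndarray],
    reference: GenomeSequence,
    af_threshold: float = 0.01,
    min_depth: int = 8,
    sample_label: str = "cell",
    liftover: PositionMap | None = None,
) -> list[SNVRecord]:
    """Pileup SNV caller with an inclusive allele-frequency threshold.

    One record per site/alt-allele with af >= ``af_threshold`` and total
    site depth >= ``min_depth``; multi-allelic sites decompose into one
    record per alt. Accepts a ReadSet or precomputed pileup arrays.
    """
    if not 0.0 < af_threshold <= 1.0:
        raise ValueError("af_threshold must be in (0, 1]")
    counts = (
        pileup_from_reads(reads, reference, liftover)
        if isinstance(reads, ReadSet)
        else reads
    )
    records: list[SNVRecord] = []
    for contig in sorted(counts):
        arr = counts[contig]
        ref_len = len(reference.sequences[contig])
        if arr.shape[0] > ref_len:
            raise ValueError(f"pileup for {contig} longer than the reference contig")
        if arr.shape[0] < ref_len:  # ingested pileups may omit trailing sites
            arr = np.vstack([arr, np.zeros((ref_len - arr.shape[0], 4), dtype=arr.dtype)])
        ref_codes = _encode(reference.sequences[contig])
        depth = arr.sum(axis=1)
        deep = depth >= min_depth
        for ai in range(4):
            d_alt = arr[:, ai]
            cand = np.nonzero(deep & (d_alt > 0) & (ref_codes != ai))[0]
            if len(cand) == 0:
                continue
            d_ref = arr[cand, ref_codes[cand]]
            af = d_alt[cand] / (d_ref + d_alt[cand])
            for p, dr, da in zip(cand[af >= af_threshold], d_ref[af >= af_threshold], d_alt[cand][af >= af_threshold]):
                records.append(
                    SNVRecord(
                        contig=contig,
                        pos=int(p),
                        ref_allele=ALPHABET[ref_codes[p]],
                        alt_allele=ALPHABET[ai],
                        depth_ref=int(dr),
                        depth_alt=int(da),
                        sample_label=sample_label,
                    )
                )
    records.sort(key=lambda r: (r.contig, r.pos, r.alt_allele))
    return records


def read_pileup_tsv(path: str | Path) -> dict[str, np.ndarray]:
    """Ingest a pileup TSV with columns contig, pos (0-based), A, C, G, T."""
    df = pd.read_csv(path, sep="\t")
    counts: dict[str, np.ndarray] = {}
    for contig, group in df.groupby("contig"):
        size = int(group["pos"].max()) + 1
        arr = np.zeros((size, 4), dtype=np.int32)
        arr[group["pos"].to_numpy()] = group[list(ALPHABET)].to_numpy()
        counts[str(contig)] = arr
    return counts


# ---------------------------------------------------------------------------
# three-way set logic


VENN_REGIONS = ("100", "010", "001", "110", "101", "011", "111")


def venn_partition(
    cell: set[VariantKey], ctdna: set[VariantKey], coculture: set[VariantKey]
) -> dict[str, int]:
    """7-region Venn partition; digits are membership in (cell, ctdna, coculture)."""
    out = {region: 0 for region in VENN_REGIONS}
    for key in cell | ctdna | coculture:
        region = f"{int(key in cell)}{int(key in ctdna)}{int(key in coculture)}"
        out[region] += 1
    return out


def snvs_of_interest(
    cell: set[VariantKey], ctdna: set[VariantKey], coculture: set[VariantKey]
) -> tuple[set[VariantKey], dict[str, int]]:
    """Variants shared by ctDNA and coculture but absent from the cell genome.

    Returns the set (ctdna ∩ coculture) \\ cell together with the full
    Venn partition for reporting.
    """
    soi = (ctdna & coculture) - cell
    return soi, venn_partition(cell, ctdna, coculture)


# ---------------------------------------------------------------------------
# VAF shift


@dataclass
class VAFShift:
    key: VariantKey
    af_cell: float
    af_coculture: float
    delta_af: float
    p_value: float
    table: tuple[tuple[int, int], tuple[int, int]]
    flagged: bool = False


def vaf_shift(
    key: VariantKey,
    cell_record: SNVRecord | None,
    coculture_record: SNVRecord,
    cell_site_depth: int | None = None,
) -> VAFShift:
    """Allele-frequency shift between cell and coculture at one site.

    An absent cell record is treated as homozygous reference at the site
    (depth_ref = ``cell_site_depth``, default the coculture total depth;
    depth_alt = 0). Significance is a two-sided exact conditional test on
    the 2x2 allele-depth table.
    """
    cocu_total = coculture_record.depth_ref + coculture_record.depth_alt
    if cocu_total == 0:
        return VAFShift(key, float("nan"), float("nan"), float("nan"), float("nan"),
                        ((0, 0), (0, 0)), flagged=True)
    if cell_record is None:
        ref_c = cell_site_depth if cell_site_depth is not None else cocu_total
        alt_c = 0
    else:
        ref_c, alt_c = cell_record.depth_ref, cell_record.depth_alt
    af_cell = alt_c / (ref_c + alt_c) if (ref_c + alt_c) else 0.0
    af_cocu = coculture_record.af
    table = ((ref_c, alt_c), (coculture_record.depth_ref, coculture_record.depth_alt))
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return VAFShift(
        key=key,
        af_cell=af_cell,
        af_coculture=af_cocu,
        delta_af=af_cocu - af_cell,
        p_value=float(p),
        table=table,
    )


# ---------------------------------------------------------------------------
# tumor fraction


@dataclass
class TumorFractionEstimate:
    fraction: float
    n_informative: int
    n_alt: int
    per_site: pd.DataFrame = field(repr=False, default=None)


def estimate_tumor_fraction(
    cfdna_fragments: Sequence[CtDNAFragment],
    tumor_snvs: set[VariantKey],
) -> TumorFractionEstimate:
    """Fraction of informative cfDNA fragments carrying a tumor alt allele.

    A fragment is informative when it overlaps at least one tumor-SNV
    site; it counts as tumor-derived when its base at any overlapped site
    equals the tumor alt allele. This fragment-level definition mirrors
    estimating the tumor-origin share of cfDNA from the presence of tumor
    SNVs in the fragment sequences.
    """
    by_contig: dict[str, list[VariantKey]] = {}
    for key in tumor_snvs:
        by_contig.setdefault(key.contig, []).append(key)
    for keys in by_contig.values():
        keys.sort(key=lambda k: k.pos)

    n_informative = 0
    n_alt = 0
    site_rows: dict[VariantKey, list[int]] = {}
    for frag in cfdna_fragments:
        contig, start, end = frag.origin
        keys = by_contig.get(contig, [])
        overlapped = [k for k in keys if start <= k.pos < end]
        if not overlapped:
            continue
        n_informative += 1
        core = frag.core
        carries = False
        for k in overlapped:
            base = core[k.pos - start]
            hit = int(base == k.alt_allele)
            site_rows.setdefault(k, [0, 0])
            site_rows[k][0] += 1
            site_rows[k][1] += hit
            carries = carries or bool(hit)
        n_alt += int(carries)
    if n_informative == 0:
        raise ValueError("no cfDNA fragment overlaps a tumor SNV site")
    per_site = pd.DataFrame(
        [
            {"contig": k.contig, "pos": k.pos, "ref": k.ref_allele, "alt": k.alt_allele,
             "fragments": n, "alt_fragments": a}
            for k, (n, a) in sorted(site_rows.items())
        ]
    )
    return TumorFractionEstimate(
        fraction=n_alt / n_informative,
        n_informative=n_informative,
        n_alt=n_alt,
        per_site=per_site,
    )


# ---------------------------------------------------------------------------
# VCF I/O (v4.2; 1-based on disk, 0-based in memory)


_VCF_HEADER = """##fileformat=VCFv4.2
##source=ctdna-integrate
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths (ref,alt)">
##FORMAT=<ID=AF,Number=A,Type=Float,Description="Alt allele frequency">
"""


def write_vcf(records: Sequence[SNVRecord], path: str | Path, reference: GenomeSequence | None = None) -> None:
    sample = records[0].sample_label if records else "sample"
    lines = [_VCF_HEADER.rstrip("\n")]
    if reference is not None:
        for contig, seq in reference.sequences.items():
            lines.append(f"##contig=<ID={contig},length={len(seq)}>")
    lines.append(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}")
    for rec in sorted(records, key=lambda r: (r.contig, r.pos, r.alt_allele)):
        lines.append(
            f"{rec.contig}\t{rec.pos + 1}\t.\t{rec.ref_allele}\t{rec.alt_allele}\t.\tPASS\t.\t"
            f"GT:AD:AF\t0/1:{rec.depth_ref},{rec.depth_alt}:{rec.af:.6g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path, sample_label: str | None = None) -> list[SNVRecord]:
    """Read SNV records (one per alt allele) from a VCF via pysam."""
    import pysam

    records: list[SNVRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        label = sample_label or (samples[0] if samples else "sample")
        for rec in vf:
            for i, alt in enumerate(rec.alts or ()):
                if len(rec.ref) != 1 or len(alt) != 1:
                    continue  # SNVs only
                d_ref, d_alt = 0, 0
                if samples:
                    ad = rec.samples[samples[0]].get("AD")
                    if ad is not None:
                        d_ref = int(ad[0]) if ad[0] is not None else 0
                        d_alt = int(ad[i + 1]) if len(ad) > i + 1 and ad[i + 1] is not None else 0
                records.append(
                    SNVRecord(
                        contig=rec.contig,
                        pos=rec.pos - 1,
                        ref_allele=rec.ref,
                        alt_allele=alt,
                        depth_ref=d_ref,
                        depth_alt=d_alt,
                        sample_label=label,
                    )
                )
    records.sort(key=lambda r: (r.contig, r.pos, r.alt_allele))
    return records


def keys_of(records: Iterable[SNVRecord]) -> set[VariantKey]:
    return {r.key for r in records}
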
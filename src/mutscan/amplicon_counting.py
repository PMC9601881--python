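"""Codon-variant counting from pooled amplicon sequencing reads.

The amplicons are fixed-length PCR products over one mutagenized pool
region, so reads are compared to the pool reference ungapped after being
located by exact-match flank anchors; anything that does not fit (length
change, failed anchors) is classified as ``indel_or_unaligned`` rather than
force-aligned.  Classification of a located read:

* 0 mismatched codons            -> ``wild_type``
* any mismatched base under the quality floor, or an N in a mismatched
  codon                          -> ``low_quality``
* exactly 1 mismatched codon     -> ``single_variant``
* 2+ mismatched codons           -> ``multi_variant``

Single variants whose codon is outside the design's degenerate set (and not
the reference codon) are tallied separately as ``off_design`` — they are
mostly sequencing/PCR errors and are reported but never scored.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd
import yaml

from .library_spec import (
    MutagenesisDesign,
    PoolRegion,
    VariantId,
    expand_degenerate,
    translate_codon,
)

__all__ = [
    "CONDITIONS",
    "ManifestEntry",
    "SampleManifest",
    "Read",
    "merge_read_pair",
    "AmpliconRef",
    "pool_amplicon",
    "CodonCallResult",
    "call_codon_variant",
    "CountTable",
    "tally",
    "tally_fastq",
    "read_fastq",
]

CONDITIONS = ("t0", "selected", "unselected")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

REJECT_CLASSES = ("multi_variant", "indel_or_unaligned", "low_quality")


class CountingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# manifest


@dataclass(frozen=True)
class ManifestEntry:
    """One sequenced sample: a (pool, condition, replicate) cell."""

    sample_id: str
    pool_id: str
    condition: str
    replicate: int
    sources: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise CountingError(
                f"condition {self.condition!r} not in {CONDITIONS}"
            )
        if self.replicate < 1:
            raise CountingError("replicate numbers are positive (1-based)")


@dataclass
class SampleManifest:
    entries: list[ManifestEntry]

    def __post_init__(self) -> None:
        keys = [(e.pool_id, e.condition, e.replicate) for e in self.entries]
        if len(set(keys)) != len(keys):
            raise CountingError("duplicate (pool, condition, replicate) in manifest")
        ids = [e.sample_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise CountingError("duplicate sample_id in manifest")

    def __iter__(self) -> Iterator[ManifestEntry]:
        return iter(self.entries)

    def get(self, pool_id: str, condition: str, replicate: int) -> ManifestEntry:
        for e in self.entries:
            if (e.pool_id, e.condition, e.replicate) == (pool_id, condition, replicate):
                return e
        raise CountingError(f"no manifest entry for {(pool_id, condition, replicate)}")

    def replicates(self, pool_id: str) -> list[int]:
        return sorted({e.replicate for e in self.entries if e.pool_id == pool_id})

    def save(self, path: str | Path) -> None:
        doc = [
            {
                "sample_id": e.sample_id,
                "pool_id": e.pool_id,
                "condition": e.condition,
                "replicate": e.replicate,
                "sources": list(e.sources),
            }
            for e in self.entries
        ]
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "SampleManifest":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(
            [
                ManifestEntry(
                    sample_id=d["sample_id"],
                    pool_id=d["pool_id"],
                    condition=d["condition"],
                    replicate=int(d["replicate"]),
                    sources=tuple(d.get("sources", ())),
                )
                for d in doc
            ]
        )


# ---------------------------------------------------------------------------
# reads and pair merging


@dataclass(frozen=True)
class Read:
    """A sequencing read with per-base Phred qualities."""

    seq: str
    qual: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise CountingError("sequence and quality lengths differ")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def merge_read_pair(
    fwd: Read,
    rev: Read,
    min_overlap: int = 20,
    max_overlap_mismatch_frac: float = 0.1,
) -> Optional[Read]:
    """Merge a read pair by its best ungapped 3' overlap, or return None.

    ``rev`` is given in sequencer orientation and is reverse-complemented
    here.  Candidate overlaps of length >= ``min_overlap`` are scored by
    matched bases; the best candidate must have a mismatch fraction at or
    under the threshold.  Disagreeing overlap bases resolve to the
    higher-quality base; quality ties become N.
    """
    rc = _revcomp(rev.seq)
    rq = rev.qual[::-1]
    best: tuple[int, int] | None = None  # (matches, overlap_len)
    max_o = min(len(fwd.seq), len(rc))
    for o in range(min_overlap, max_o + 1):
        a = fwd.seq[-o:]
        b = rc[:o]
        mism = sum(1 for x, y in zip(a, b) if x != y)
        if mism / o > max_overlap_mismatch_frac:
            continue
        score = o - mism
        if best is None or score > best[0] or (score == best[0] and o > best[1]):
            best = (score, o)
    if best is None:
        return None
    o = best[1]
    head_seq, head_q = fwd.seq[:-o], fwd.qual[:-o]
    tail_seq, tail_q = rc[o:], rq[o:]
    mid_seq = []
    mid_q = []
    for i in range(o):
        fb, fq = fwd.seq[len(fwd.seq) - o + i], fwd.qual[len(fwd.qual) - o + i]
        rb, rqual = rc[i], rq[i]
        if fb == rb:
            mid_seq.append(fb)
            mid_q.append(max(fq, rqual))
        elif fq > rqual:
            mid_seq.append(fb)
            mid_q.append(fq)
        elif rqual > fq:
            mid_seq.append(rb)
            mid_q.append(rqual)
        else:
            mid_seq.append("N")
            mid_q.append(2)
    return Read(head_seq + "".join(mid_seq) + tail_seq, tuple(head_q) + tuple(mid_q) + tuple(tail_q))


# ---------------------------------------------------------------------------
# amplicon reference and per-read codon calling


@dataclass(frozen=True)
class AmpliconRef:
    """The fixed amplicon over one pool: flank + mutagenized region + flank.

    Flanks come from the CDS context around the region and double as the
    exact-match anchors that locate a read.
    """

    pool: PoolRegion
    seq: str
    region_start: int  # 0-based offset of the region within seq
    first_codon: int  # 1-based codon index of the first region codon

    @property
    def region_len(self) -> int:
        return 3 * (self.pool.last_codon - self.pool.first_codon + 1)


def pool_amplicon(design: MutagenesisDesign, pool_id: str, flank: int = 18) -> AmpliconRef:
    """Build the amplicon reference for one pool with up to ``flank`` nt of
    CDS context on each side (truncated at the CDS ends)."""
    pool = design.pool(pool_id)
    region_lo = 3 * (pool.first_codon - 1)
    region_hi = 3 * pool.last_codon
    lo = max(0, region_lo - flank)
    hi = min(len(design.reference_cds), region_hi + flank)
    return AmpliconRef(
        pool=pool,
        seq=design.reference_cds[lo:hi],
        region_start=region_lo - lo,
        first_codon=pool.first_codon,
    )


@dataclass(frozen=True)
class CodonCallResult:
    classification: str  # wild_type | single_variant | multi_variant | indel_or_unaligned | low_quality
    variant: Optional[VariantId] = None
    n_mismatched_codons: int = 0


def call_codon_variant(
    read: Read,
    amplicon: AmpliconRef,
    quality_floor: int = 30,
    anchor_len: int = 12,
) -> CodonCallResult:
    """Classify one merged read against the pool amplicon (ungapped).

    The read must contain the amplicon's first and last ``anchor_len`` bases
    by exact match, at a spacing equal to the amplicon length; otherwise it
    is ``indel_or_unaligned``.
    """
    if not read.seq or not amplicon.seq:
        raise CountingError("empty read or amplicon reference")
    ref = amplicon.seq
    # anchors must stay within the constant flanks so edge-codon variants
    # still align; degenerate designs with no flank fall back to 1 nt
    left_len = max(1, min(anchor_len, amplicon.region_start))
    right_flank = len(ref) - (amplicon.region_start + amplicon.region_len)
    right_len = max(1, min(anchor_len, right_flank))
    left = ref[:left_len]
    start = read.seq.find(left)
    if start < 0 or start + len(ref) > len(read.seq):
        return CodonCallResult("indel_or_unaligned")
    if read.seq[start + len(ref) - right_len : start + len(ref)] != ref[-right_len:]:
        return CodonCallResult("indel_or_unaligned")
    aligned = read.seq[start : start + len(ref)]
    quals = read.qual[start : start + len(ref)]

    # low-quality screen on mismatched bases
    mismatch_positions = [i for i in range(len(ref)) if aligned[i] != ref[i]]
    for i in mismatch_positions:
        if quals[i] < quality_floor or aligned[i] == "N":
            return CodonCallResult("low_quality")

    # group mismatches by region codon; mismatches in flanks (between anchor
    # and region) count as unexpected -> treat as a mismatched "codon" slot
    region_lo = amplicon.region_start
    region_hi = amplicon.region_start + amplicon.region_len
    flank_hit = any(i < region_lo or i >= region_hi for i in mismatch_positions)
    codon_slots: set[int] = set()
    for i in mismatch_positions:
        if region_lo <= i < region_hi:
            codon_slots.add((i - region_lo) // 3)
    n_bad = len(codon_slots) + (1 if flank_hit else 0)
    if n_bad == 0:
        return CodonCallResult("wild_type")
    if n_bad > 1 or flank_hit:
        return CodonCallResult("multi_variant", n_mismatched_codons=n_bad)
    slot = codon_slots.pop()
    codon_index = amplicon.first_codon + slot
    codon = aligned[region_lo + 3 * slot : region_lo + 3 * slot + 3]
    ref_codon = ref[region_lo + 3 * slot : region_lo + 3 * slot + 3]
    aa = translate_codon(codon)
    variant = VariantId(
        codon_index=codon_index,
        codon=codon,
        aa_class=aa,
        is_wt_codon=False,
        is_wt_synonymous=aa == translate_codon(ref_codon),
    )
    return CodonCallResult("single_variant", variant=variant, n_mismatched_codons=1)


# ---------------------------------------------------------------------------
# count tables


@dataclass
class CountTable:
    """Per-sample codon-variant counts with conservation accounting.

    ``counts`` maps (codon_index, codon) -> reads; ``wt_count`` holds reads
    identical to the reference (including molecules whose NNS draw equals
    the reference codon); ``off_design`` holds single-codon variants outside
    the degenerate set.  Invariant:
    wt + sum(counts) + off_design + sum(rejected) == total_reads.
    """

    pool_id: str
    sample_id: str
    counts: dict[tuple[int, str], float] = field(default_factory=dict)
    wt_count: float = 0
    off_design: float = 0
    rejected: dict[str, float] = field(default_factory=lambda: {c: 0 for c in REJECT_CLASSES})
    total_reads: float = 0

    def validate(self) -> None:
        total = self.wt_count + sum(self.counts.values()) + self.off_design + sum(
            self.rejected.values()
        )
        if abs(total - self.total_reads) > 1e-6:
            raise CountingError(
                f"count conservation violated for {self.sample_id}: "
                f"{total} != {self.total_reads}"
            )
        if self.wt_count < 0 or any(v < 0 for v in self.counts.values()):
            raise CountingError("negative counts")

    def variant_count(self, codon_index: int, codon: str) -> float:
        return self.counts.get((codon_index, codon), 0)

    # -- TSV I/O ----------------------------------------------------------

    def to_frame(self, design: MutagenesisDesign) -> pd.DataFrame:
        rows = [
            {
                "pool_id": self.pool_id,
                "sample_id": self.sample_id,
                "codon_index": idx,
                "residue_number": idx + design.numbering_offset,
                "codon": codon,
                "aa_class": translate_codon(codon),
                "count": count,
            }
            for (idx, codon), count in sorted(self.counts.items())
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "pool_id",
                "sample_id",
                "codon_index",
                "residue_number",
                "codon",
                "aa_class",
                "count",
            ],
        )

    def summary_frame(self) -> pd.DataFrame:
        row = {
            "pool_id": self.pool_id,
            "sample_id": self.sample_id,
            "wild_type": self.wt_count,
            "off_design": self.off_design,
            **self.rejected,
            "total_reads": self.total_reads,
        }
        return pd.DataFrame([row])

    def write_tsv(self, counts_path: str | Path, summary_path: str | Path, design: MutagenesisDesign) -> None:
        self.to_frame(design).to_csv(counts_path, sep="\t", index=False)
        self.summary_frame().to_csv(summary_path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, counts_path: str | Path, summary_path: str | Path) -> "CountTable":
        cf = pd.read_csv(counts_path, sep="\t")
        sf = pd.read_csv(summary_path, sep="\t").iloc[0]
        table = cls(
            pool_id=str(sf["pool_id"]),
            sample_id=str(sf["sample_id"]),
            counts={
                (int(r.codon_index), str(r.codon)): r.count for r in cf.itertuples()
            },
            wt_count=sf["wild_type"],
            off_design=sf["off_design"],
            rejected={c: sf[c] for c in REJECT_CLASSES},
            total_reads=sf["total_reads"],
        )
        table.validate()
        return table


def load_count_tables(
    directory: str | Path, manifest: SampleManifest
) -> dict[tuple[str, str, int], CountTable]:
    """Load ``{sample_id}.counts.tsv`` / ``{sample_id}.summary.tsv`` pairs
    for every manifest entry, keyed by (pool, condition, replicate)."""
    directory = Path(directory)
    out: dict[tuple[str, str, int], CountTable] = {}
    for e in manifest:
        table = CountTable.read_tsv(
            directory / f"{e.sample_id}.counts.tsv",
            directory / f"{e.sample_id}.summary.tsv",
        )
        out[(e.pool_id, e.condition, e.replicate)] = table
    return out


def tally(
    reads: Iterable[Read],
    entry: ManifestEntry,
    design: MutagenesisDesign,
    quality_floor: int = 30,
    anchor_len: int = 12,
    flank: int = 18,
) -> CountTable:
    """Tally a stream of merged reads for one sample into a CountTable.

    A read pair that failed merging should be passed as None; it is counted
    as ``indel_or_unaligned``.
    """
    amplicon = pool_amplicon(design, entry.pool_id, flank=flank)
    pattern_codons = expand_degenerate(design.pattern)
    table = CountTable(pool_id=entry.pool_id, sample_id=entry.sample_id)
    n = 0
    for read in reads:
        n += 1
        if read is None:
            table.rejected["indel_or_unaligned"] += 1
            continue
        call = call_codon_variant(read, amplicon, quality_floor=quality_floor, anchor_len=anchor_len)
        if call.classification == "wild_type":
            table.wt_count += 1
        elif call.classification == "single_variant":
            v = call.variant
            assert v is not None
            if v.codon in pattern_codons:
                key = (v.codon_index, v.codon)
                table.counts[key] = table.counts.get(key, 0) + 1
            else:
                table.off_design += 1
        else:
            table.rejected[call.classification] += 1
    table.total_reads = n
    table.validate()
    return table


def _open_maybe_gz(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fastq(path: str | Path) -> Iterator[Read]:
    """Stream a FASTQ file (gzip-transparent) as Read objects."""
    with _open_maybe_gz(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().strip()
            fh.readline()  # +
            qual = fh.readline().strip()
            yield Read(seq, tuple(ord(c) - 33 for c in qual))


def tally_fastq(
    entry: ManifestEntry,
    design: MutagenesisDesign,
    quality_floor: int = 30,
    min_overlap: int = 20,
    max_overlap_mismatch_frac: float = 0.1,
    anchor_len: int = 12,
    flank: int = 18,
) -> CountTable:
    """Tally one manifest entry from its FASTQ source(s).

    One source file means pre-merged reads; two means a paired run that is
    overlap-merged first.
    """
    if len(entry.sources) == 1:
        stream: Iterable[Optional[Read]] = read_fastq(entry.sources[0])
    elif len(entry.sources) == 2:
        fwd_reads = read_fastq(entry.sources[0])
        rev_reads = read_fastq(entry.sources[1])
        stream = (
            merge_read_pair(f, r, min_overlap=min_overlap, max_overlap_mismatch_frac=max_overlap_mismatch_frac)
            for f, r in zip(fwd_reads, rev_reads)
        )
    else:
        raise CountingError(
            f"sample {entry.sample_id}: expected 1 (merged) or 2 (paired) FASTQ sources, "
            f"got {len(entry.sources)}"
        )
    return tally(stream, entry, design, quality_floor=quality_floor, anchor_len=anchor_len, flank=flank)
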
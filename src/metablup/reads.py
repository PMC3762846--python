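"""Read-level preprocessing: quality trimming, deduplication and k-mer counting.

Shotgun reads are quality-trimmed from the 3' end, length/quality filtered,
de-duplicated on exact sequence identity, and optionally summarised as k-mer
count profiles.  The k-mer path is an alternative to alignment-based contig
counting: every k-mer observed in the first ``max_reads`` reads of each sample
is counted, and only k-mers seen in *every* sample enter the count table.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .profiles import CountTable

__all__ = [
    "ReadRecord",
    "KmerCounts",
    "qc_read",
    "remove_duplicates",
    "count_kmers",
    "build_kmer_count_table",
    "read_fastq",
    "write_fastq",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class ReadRecord:
    """A sequencing read: bases over {A,C,G,T,N} plus per-base Phred scores."""

    id: str
    bases: str
    quals: list[int]

    def validate(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality scores"
            )
        if any(q < 0 for q in self.quals):
            raise ValueError(f"read {self.id!r}: negative Phred score")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class KmerCounts:
    """Per-sample k-mer tallies from the first ``reads_used`` reads."""

    sample_id: str
    K: int
    counts: dict[str, int] = field(default_factory=dict)
    reads_used: int = 0

    def total(self) -> int:
        return sum(self.counts.values())


def qc_read(
    read: ReadRecord,
    low_q: int = 15,
    max_low: int = 3,
    min_len: int = 50,
    min_mean_q: int = 30,
) -> tuple[ReadRecord, bool]:
    """Trim a read from the 3' end and decide whether to keep it.

    Bases are removed one at a time from the 3' end until at most ``max_low``
    bases with Phred quality below ``low_q`` remain (equivalently: the longest
    prefix with no more than ``max_low`` low-quality bases is kept).  The read
    is then discarded when shorter than ``min_len`` or when the arithmetic
    mean Phred quality of the *trimmed* read is below ``min_mean_q``.

    Returns
    -------
    (trimmed, keep)
        ``trimmed`` is always a prefix of the input read; ``keep`` is False
        for reads failing the length or mean-quality filter.
    """
    read.validate()
    quals = np.asarray(read.quals, dtype=np.int64)
    # low_cum is nondecreasing, so the longest acceptable prefix ends at the
    # last position whose cumulative low-quality count is still <= max_low
    low_cum = np.cumsum(quals < low_q)
    ok = np.nonzero(low_cum <= max_low)[0]
    length = int(ok[-1]) + 1 if ok.size else 0
    trimmed = ReadRecord(read.id, read.bases[:length], list(read.quals[:length]))
    if length < min_len or length == 0:
        return trimmed, False
    if float(np.mean(quals[:length])) < min_mean_q:
        return trimmed, False
    return trimmed, True


def remove_duplicates(reads: Iterable[ReadRecord]) -> Iterator[ReadRecord]:
    """Drop exact sequence duplicates, keeping the first occurrence.

    The key is the forward-orientation base string only: identical bases with
    different ids or qualities are duplicates.  This is a deliberately simple
    stand-in for dedicated read-decloning tools and does not collapse
    reverse complements.
    """
    seen: set[str] = set()
    for read in reads:
        if read.bases not in seen:
            seen.add(read.bases)
            yield read


def _canonical(kmer: str) -> str:
    rc = kmer.translate(_COMPLEMENT)[::-1]
    return kmer if kmer <= rc else rc


def count_kmers(
    reads: Iterable[ReadRecord],
    K: int,
    max_reads: int = 1_000_000,
    sample_id: str = "",
    canonical: bool = False,
) -> KmerCounts:
    """Count every k-mer in the first ``max_reads`` reads of a sample.

    Substrings containing ``N`` are skipped; reads shorter than ``K``
    contribute nothing.  With ``canonical=True`` each k-mer is collapsed with
    its reverse complement (lexicographically smaller form kept).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if max_reads < 1:
        raise ValueError("max_reads must be >= 1")
    counts: Counter[str] = Counter()
    used = 0
    for read in reads:
        if used >= max_reads:
            break
        used += 1
        bases = read.bases
        for i in range(len(bases) - K + 1):
            kmer = bases[i : i + K]
            if "N" in kmer:
                continue
            counts[_canonical(kmer) if canonical else kmer] += 1
    return KmerCounts(sample_id=sample_id, K=K, counts=dict(counts), reads_used=used)


def build_kmer_count_table(samples: list[KmerCounts]) -> CountTable:
    """Assemble per-sample k-mer counts into a samples x k-mers count table.

    Only k-mers observed (count >= 1) in *every* sample are retained, so the
    resulting table has no zero entries by construction.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    ks = {s.K for s in samples}
    if len(ks) != 1:
        raise ValueError(f"samples counted with different K: {sorted(ks)}")
    shared = set(samples[0].counts)
    for s in samples[1:]:
        shared &= set(s.counts)
    features = sorted(shared)
    counts = np.array(
        [[s.counts[k] for k in features] for s in samples], dtype=np.int64
    ).reshape(len(samples), len(features))
    return CountTable(
        sample_ids=[s.sample_id for s in samples],
        feature_ids=features,
        counts=counts,
    )


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream reads from a (possibly gzipped) Sanger Phred+33 FASTQ file."""
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fastq"):
            yield ReadRecord(
                id=rec.id,
                bases=str(rec.seq).upper(),
                quals=list(rec.letter_annotations["phred_quality"]),
            )


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> int:
    """Write reads to a (possibly gzipped) FASTQ file; returns count written."""
    n = 0
    with _open_text(path, "wt") as handle:
        for read in reads:
            rec = SeqRecord(Seq(read.bases), id=read.id, description="")
            rec.letter_annotations["phred_quality"] = list(read.quals)
            SeqIO.write(rec, handle, "fastq")
            n += 1
    return n
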
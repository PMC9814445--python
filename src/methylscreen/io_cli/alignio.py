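"""FASTA and SAM readers/writers.

Simulated reads are written as plain-text SAM with the origin strand in the
``XG`` tag (``CT`` Watson / ``GA`` Crick, matching the de-facto converted-read
convention), the methylation call string in ``XM`` when available, and the
simulator's compromised flag in ``XC``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pysam
from Bio import SeqIO

from ..context_qc import CRICK, WATSON, ConvertedRead


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load all records of a FASTA file as {name: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: Iterable[tuple[str, str]] | Mapping[str, str], path: str | Path) -> None:
    items = records.items() if isinstance(records, Mapping) else records
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_sam(
    reads: Iterable[ConvertedRead],
    ref_lengths: Mapping[str, int],
    path: str | Path,
    compromised: Mapping[str, bool] | None = None,
) -> None:
    """Write reads as coordinate-unsorted text SAM."""
    names = list(ref_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": int(ref_lengths[n])} for n in names],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for read in reads:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = read.read_id
            seg.reference_name = read.reference
            seg.reference_start = read.start
            seg.query_sequence = read.sequence
            seg.cigarstring = f"{len(read.sequence)}M"
            seg.mapping_quality = 60
            seg.flag = 16 if read.strand == CRICK else 0
            tags = [("XG", "GA" if read.strand == CRICK else "CT")]
            if read.call_string is not None:
                tags.append(("XM", read.call_string))
            if compromised is not None and read.read_id in compromised:
                tags.append(("XC", int(compromised[read.read_id])))
            seg.set_tags(tags)
            out.write(seg)


def read_alignments(
    path: str | Path,
    refs: Mapping[str, str] | None = None,
    trust_calls: bool = False,
) -> Iterator[ConvertedRead]:
    """Stream aligned reads from SAM/BAM as :class:`ConvertedRead`.

    Origin strand comes from the ``XG`` tag when present, else from the
    reverse flag.  With ``trust_calls`` an embedded ``XM`` call string is
    carried over instead of being recomputed later.  A read mapped to a
    contig absent from ``refs`` (when provided) is an error naming the contig.
    """
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for i, seg in enumerate(fh):
            try:
                if seg.is_unmapped:
                    continue
                contig = seg.reference_name
                if refs is not None and contig not in refs:
                    raise KeyError(f"reference contig {contig!r} not found (record {i})")
                if seg.has_tag("XG"):
                    strand = CRICK if seg.get_tag("XG") == "GA" else WATSON
                else:
                    strand = CRICK if seg.is_reverse else WATSON
                calls = None
                if trust_calls and seg.has_tag("XM"):
                    calls = str(seg.get_tag("XM"))
                mate = "R1" if seg.is_read1 else "R2" if seg.is_read2 else "single"
                yield ConvertedRead(
                    read_id=seg.query_name,
                    reference=contig,
                    start=seg.reference_start,
                    sequence=seg.query_sequence,
                    strand=strand,
                    mate=mate,
                    call_string=calls,
                )
            except KeyError:
                raise
            except Exception as exc:  # malformed record: report its index
                raise ValueError(f"malformed alignment record {i}: {exc}") from exc
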
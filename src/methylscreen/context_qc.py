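"""Per-read methylation-context calling, unconverted-CH counting and filtering.

Reads produced by enzymatic or chemical C->T conversion retain a C only where
the original molecule was methylated -- or where conversion failed.  Calls are
made against the reference strand the molecule originated from, one symbol per
read base:

======  ==================================================
symbol  meaning
======  ==================================================
Z / z   methylated / unmethylated CpG
X / x   methylated / unmethylated CHG
H / h   methylated / unmethylated CHH
.       no cytosine on the origin strand, or context
        unresolvable (N, reference edge, read-base error)
======  ==================================================

Unconverted CH calls (uppercase ``X`` + ``H``) flag conversion failure: non-CpG
methylation is rare in human DNA, so a retained C outside CpG context is
almost always an artefact.  Failures come in two flavours -- sporadic single
sites, and clusters concentrated in one molecule.  The clustered mode is what
the read-level filter targets: reads carrying ``ch_threshold`` (default 3) or
more unconverted CH calls are removed before quantification.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

WATSON = "+"
CRICK = "-"

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMP)[::-1]


@dataclass
class ConvertedRead:
    """One aligned (or simulated) post-conversion read.

    The sequence is stored in forward-reference orientation regardless of the
    origin strand; ``strand`` records which strand the molecule came from
    ("+" Watson, "-" Crick).  No indel support: the alignment span is exactly
    ``len(sequence)`` bases starting at ``start`` (0-based).
    """

    read_id: str
    reference: str
    start: int
    sequence: str
    strand: str = WATSON
    mate: str = "single"  # single / R1 / R2
    call_string: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative alignment start: {self.start}")
        if self.strand not in (WATSON, CRICK):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def end(self) -> int:
        return self.start + len(self.sequence)


@dataclass(frozen=True)
class FilterConfig:
    """Read-filtering knobs. ``ch_threshold`` is the minimum unconverted-CH
    count that marks a read as incompletely converted."""

    ch_threshold: int = 3
    min_base_quality: int = 0
    paired_overlap_policy: str = "higher-quality"

    def __post_init__(self) -> None:
        if self.ch_threshold < 1:
            raise ValueError("ch_threshold must be >= 1")
        if self.min_base_quality < 0:
            raise ValueError("min_base_quality must be >= 0")


@dataclass(frozen=True)
class ReadCHProfile:
    """Per-read tally of context calls and the derived CH category."""

    read_id: str
    n_unconverted_ch: int
    n_converted_ch: int
    n_cpg_meth: int
    n_cpg_unmeth: int
    category: str

    def __post_init__(self) -> None:
        for name in ("n_unconverted_ch", "n_converted_ch", "n_cpg_meth", "n_cpg_unmeth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def ch_category(n_unconverted_ch: int, threshold: int = 3) -> str:
    """Category label: "0", "1", ... below the threshold, "<t>+" at/above it."""
    if n_unconverted_ch < threshold:
        return str(n_unconverted_ch)
    return f"{threshold}+"


def call_read_contexts(read: ConvertedRead, ref_seq: str) -> str:
    """Call the methylation context of every read base against the reference.

    Context is taken from the reference on the strand of origin, using up to
    two reference bases downstream of each cytosine (so read-terminal Cs are
    still classifiable).  A position yields '.' when the origin strand has no
    C there, when the context involves N or runs off the reference, or when
    the read base is neither the retained C nor its converted product.
    """
    n_ref = len(ref_seq)
    if read.start < 0 or read.end > n_ref:
        raise ValueError(
            f"read {read.read_id} spans [{read.start},{read.end}) beyond "
            f"reference of length {n_ref}"
        )
    seq = read.sequence
    out = []
    if read.strand == WATSON:
        for i, base in enumerate(seq):
            p = read.start + i
            if ref_seq[p] != "C":
                out.append(".")
                continue
            nxt = ref_seq[p + 1] if p + 1 < n_ref else "N"
            nxt2 = ref_seq[p + 2] if p + 2 < n_ref else "N"
            out.append(_symbol(base, "C", "T", nxt, nxt2))
    else:
        # Crick-origin molecule: its cytosines sit at reference Gs, and its
        # downstream direction runs towards lower forward coordinates.
        for i, base in enumerate(seq):
            p = read.start + i
            if ref_seq[p] != "G":
                out.append(".")
                continue
            nxt = _complement(ref_seq[p - 1]) if p - 1 >= 0 else "N"
            nxt2 = _complement(ref_seq[p - 2]) if p - 2 >= 0 else "N"
            out.append(_symbol(base, "G", "A", nxt, nxt2))
    return "".join(out)


def _complement(base: str) -> str:
    return base.translate(_COMP)


def _symbol(read_base: str, retained: str, converted: str, nxt: str, nxt2: str) -> str:
    """Resolve one call symbol given the origin-strand downstream context."""
    if nxt == "G":
        ctx = "Z"
    elif nxt == "N":
        return "."
    elif nxt2 == "G":
        ctx = "X"
    elif nxt2 == "N":
        return "."
    else:
        ctx = "H"
    if read_base == retained:
        return ctx
    if read_base == converted:
        return ctx.lower()
    return "."  # sequencing error or mismatch: no call


def count_unconverted_ch(calls: str) -> int:
    """Number of unconverted (uppercase) CH calls in a call string."""
    return calls.count("X") + calls.count("H")


def profile_read(read: ConvertedRead, calls: str, config: FilterConfig | None = None) -> ReadCHProfile:
    """Tally a call string into a :class:`ReadCHProfile`."""
    config = config or FilterConfig()
    c = Counter(calls)
    n_unconv = c["X"] + c["H"]
    return ReadCHProfile(
        read_id=read.read_id,
        n_unconverted_ch=n_unconv,
        n_converted_ch=c["x"] + c["h"],
        n_cpg_meth=c["Z"],
        n_cpg_unmeth=c["z"],
        category=ch_category(n_unconv, config.ch_threshold),
    )


def classify_read_ch(profile: ReadCHProfile, config: FilterConfig | None = None) -> tuple[str, bool]:
    """Return ``(category, keep)``: a read is removed iff its unconverted-CH
    count reaches the threshold."""
    config = config or FilterConfig()
    cat = ch_category(profile.n_unconverted_ch, config.ch_threshold)
    return cat, profile.n_unconverted_ch < config.ch_threshold


def dedup_reads(reads: Iterable[ConvertedRead]) -> tuple[list[ConvertedRead], int]:
    """Keep the first read per (reference, start, end, origin strand) key.

    Returns the retained reads (input order) and the number removed.
    """
    seen: set[tuple[str, int, int, str]] = set()
    kept: list[ConvertedRead] = []
    removed = 0
    for read in reads:
        key = (read.reference, read.start, read.end, read.strand)
        if key in seen:
            removed += 1
        else:
            seen.add(key)
            kept.append(read)
    return kept, removed


@dataclass
class FilterResult:
    kept: list[ConvertedRead]
    removed: list[ConvertedRead]
    profiles: list[ReadCHProfile]
    summary: dict = field(default_factory=dict)


def filter_reads(
    reads: Sequence[ConvertedRead],
    refs: Mapping[str, str],
    config: FilterConfig | None = None,
    trust_calls: bool = False,
) -> FilterResult:
    """Call contexts, profile and partition reads into kept/removed.

    The partition is exhaustive and disjoint, and kept reads' call strings are
    never altered (pure selection).  Each read's computed call string is
    attached to ``read.call_string`` for downstream aggregation.
    """
    config = config or FilterConfig()
    kept: list[ConvertedRead] = []
    removed: list[ConvertedRead] = []
    profiles: list[ReadCHProfile] = []
    category_counts: Counter[str] = Counter()
    for read in reads:
        if trust_calls and read.call_string is not None:
            calls = read.call_string
        else:
            if read.reference not in refs:
                raise KeyError(f"reference {read.reference!r} not provided")
            calls = call_read_contexts(read, refs[read.reference])
            read.call_string = calls
        prof = profile_read(read, calls, config)
        profiles.append(prof)
        category_counts[prof.category] += 1
        _, keep = classify_read_ch(prof, config)
        (kept if keep else removed).append(read)
    n_total = len(kept) + len(removed)
    summary = {
        "n_total": n_total,
        "n_kept": len(kept),
        "n_removed": len(removed),
        "removal_fraction": (len(removed) / n_total) if n_total else 0.0,
        "category_counts": dict(category_counts),
        "ch_threshold": config.ch_threshold,
    }
    return FilterResult(kept=kept, removed=removed, profiles=profiles, summary=summary)


def ch_read_report(
    reads: Sequence[ConvertedRead],
    refs: Mapping[str, str],
    config: FilterConfig | None = None,
    trust_calls: bool = False,
) -> dict:
    """Category proportions over all reads plus the share of "3+" reads among
    reads that contain at least one unconverted CH."""
    if len(reads) == 0:
        raise ValueError("ch_read_report requires at least one read")
    config = config or FilterConfig()
    result = filter_reads(reads, refs, config, trust_calls=trust_calls)
    counts = result.summary["category_counts"]
    n = result.summary["n_total"]
    categories = [str(i) for i in range(config.ch_threshold)] + [f"{config.ch_threshold}+"]
    proportions = {cat: counts.get(cat, 0) / n for cat in categories}
    n_ch_reads = sum(counts.get(cat, 0) for cat in categories[1:])
    top = counts.get(categories[-1], 0)
    if n_ch_reads == 0:
        logger.warning("no CH-containing reads; share of %s reads set to 0", categories[-1])
        share = 0.0
    else:
        share = top / n_ch_reads
    return {
        "n_reads": n,
        "category_counts": {cat: counts.get(cat, 0) for cat in categories},
        "category_proportions": proportions,
        "share_top_among_ch_reads": share,
    }
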
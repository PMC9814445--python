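"""Aggregation of context calls into per-site methylation levels.

Sites are keyed by (reference, 0-based position, strand, context); the beta
value of a site is meth/(meth+unmeth) over all calls covering it.  Besides
plain quantification this module classifies control sites into hypo/hyper
classes, estimates conversion efficiency on truth-unmethylated controls, and
flags incomplete-conversion hotspots: CpGs with residual signal that is
corroborated by signal at nearby CH sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .context_qc import ConvertedRead

_CONTEXT = {"Z": "CpG", "X": "CHG", "H": "CHH"}

SITE_COLUMNS = ["reference", "pos", "strand", "context", "meth", "unmeth", "beta"]


@dataclass(frozen=True)
class SiteClassConfig:
    """Beta thresholds for labelling control sites (strict inequalities)."""

    hypo: float = 0.01
    hyper: float = 0.80

    def __post_init__(self) -> None:
        if not 0.0 < self.hypo < self.hyper < 1.0:
            raise ValueError("need 0 < hypo < hyper < 1")


@dataclass(frozen=True)
class HotspotRecord:
    reference: str
    pos: int
    strand: str
    beta: float
    supporting_ch: tuple[tuple[int, float], ...]
    window: int


@dataclass(frozen=True)
class ConversionEfficiency:
    estimate: float
    ci_low: float
    ci_high: float
    n_calls: int


def aggregate_calls(reads: Iterable[ConvertedRead]) -> pd.DataFrame:
    """Tally call strings into per-site counts and betas.

    Every read must carry a ``call_string`` (as attached by
    :func:`methylscreen.context_qc.filter_reads`).  Sites with zero coverage
    are simply absent.  Watson and Crick calls of one CpG dyad are reported as
    separate rows; see :func:`cpg_records` with ``merge_strands=True``.
    """
    counts: dict[tuple[str, int, str, str], list[int]] = {}
    for read in reads:
        calls = read.call_string
        if calls is None:
            raise ValueError(f"read {read.read_id} has no call string")
        ref, start, strand = read.reference, read.start, read.strand
        for i, sym in enumerate(calls):
            if sym == ".":
                continue
            key = (ref, start + i, strand, _CONTEXT[sym.upper()])
            slot = counts.setdefault(key, [0, 0])
            slot[0 if sym.isupper() else 1] += 1
    rows = [
        (ref, pos, strand, ctx, m, u, m / (m + u))
        for (ref, pos, strand, ctx), (m, u) in counts.items()
    ]
    df = pd.DataFrame(rows, columns=SITE_COLUMNS)
    return df.sort_values(["reference", "pos", "strand"], ignore_index=True)


def cpg_records(sites: pd.DataFrame, merge_strands: bool = False) -> pd.DataFrame:
    """CpG-context subset; optionally sum Watson+Crick counts onto the Watson
    C position of each dyad (merged rows get strand '*')."""
    cpg = sites[sites["context"] == "CpG"].copy()
    if not merge_strands:
        return cpg.reset_index(drop=True)
    cpg["dyad_pos"] = np.where(cpg["strand"] == "-", cpg["pos"] - 1, cpg["pos"])
    merged = (
        cpg.groupby(["reference", "dyad_pos"], as_index=False)[["meth", "unmeth"]]
        .sum()
        .rename(columns={"dyad_pos": "pos"})
    )
    merged["strand"] = "*"
    merged["context"] = "CpG"
    merged["beta"] = merged["meth"] / (merged["meth"] + merged["unmeth"])
    return merged[SITE_COLUMNS]


def ch_records(sites: pd.DataFrame) -> pd.DataFrame:
    """CHG+CHH subset (the pooled CH class)."""
    return sites[sites["context"].isin(["CHG", "CHH"])].reset_index(drop=True)


def classify_sites(sites: pd.DataFrame, config: SiteClassConfig | None = None) -> pd.DataFrame:
    """Add a ``site_class`` column: hypo (beta < hypo threshold), hyper
    (beta > hyper threshold) or intermediate.  Boundary values are
    intermediate (strict inequalities)."""
    config = config or SiteClassConfig()
    out = sites.copy()
    out["site_class"] = np.select(
        [out["beta"] < config.hypo, out["beta"] > config.hyper],
        ["hypo", "hyper"],
        default="intermediate",
    )
    return out


def conversion_efficiency(sites: pd.DataFrame) -> ConversionEfficiency:
    """Efficiency on a truth-unmethylated control: 1 - unconverted fraction
    over all cytosine contexts, with a normal-approximation 95% CI."""
    meth = int(sites["meth"].sum())
    total = meth + int(sites["unmeth"].sum())
    if total == 0:
        raise ValueError("no calls: conversion efficiency undefined")
    q = meth / total
    eff = 1.0 - q
    half = 1.96 * np.sqrt(q * (1 - q) / total)
    return ConversionEfficiency(
        estimate=eff,
        ci_low=max(0.0, eff - half),
        ci_high=min(1.0, eff + half),
        n_calls=total,
    )


def detect_incomplete_conversion_hotspots(
    cpg_sites: pd.DataFrame,
    ch_sites: pd.DataFrame,
    signal_thresh: float = 0.01,
    window: int = 50,
) -> list[HotspotRecord]:
    """CpGs on an unmethylated control with beta above ``signal_thresh`` that
    are supported by at least one CH site above the same threshold within
    +/- ``window`` bp, sorted by CpG beta descending."""
    hot_ch = ch_sites[ch_sites["beta"] > signal_thresh]
    records: list[HotspotRecord] = []
    for row in cpg_sites.itertuples():
        if row.beta <= signal_thresh:
            continue
        near = hot_ch[
            (hot_ch["reference"] == row.reference)
            & ((hot_ch["pos"] - row.pos).abs() <= window)
        ].sort_values("pos")
        if near.empty:
            continue
        support = tuple(
            (int(p), float(b)) for p, b in zip(near["pos"], near["beta"])
        )
        records.append(
            HotspotRecord(
                reference=row.reference,
                pos=int(row.pos),
                strand=str(row.strand),
                beta=float(row.beta),
                supporting_ch=support,
                window=window,
            )
        )
    records.sort(key=lambda r: r.beta, reverse=True)
    return records


def compare_filtering_effect(
    before: pd.DataFrame,
    after: pd.DataFrame,
    site_classes: pd.DataFrame,
) -> pd.DataFrame:
    """Per-class paired comparison of site betas before vs after filtering.

    ``site_classes`` maps sites (reference, pos, strand) to a ``site_class``
    label.  Only sites present in all three tables are compared (paired by
    site).  Returns one row per class with mean betas, the mean paired delta
    and a paired Student's t; a class where every delta is identical has an
    undefined t, flagged via ``degenerate``.
    """
    keys = ["reference", "pos", "strand"]
    merged = before.merge(after, on=keys, suffixes=("_before", "_after"))
    if merged.empty:
        raise ValueError("no common sites between before and after tables")
    merged = merged.merge(site_classes[keys + ["site_class"]], on=keys)
    if merged.empty:
        raise ValueError("no classified sites in the matched set")
    rows = []
    for cls, grp in merged.groupby("site_class"):
        delta = grp["beta_after"] - grp["beta_before"]
        degenerate = bool(np.allclose(delta.var(ddof=0), 0.0)) or len(grp) < 2
        if degenerate:
            t_stat, p_val = float("nan"), float("nan")
        else:
            t_stat, p_val = stats.ttest_rel(grp["beta_after"], grp["beta_before"])
        rows.append(
            {
                "site_class": cls,
                "n_sites": len(grp),
                "mean_before": grp["beta_before"].mean(),
                "mean_after": grp["beta_after"].mean(),
                "mean_delta": delta.mean(),
                "t_stat": float(t_stat),
                "p_value": float(p_val),
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows).set_index("site_class")
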
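"""Marker selection and five-probe capture panel design.

Selection keeps CpGs that are hypermethylated in tumour tissue while their
linked gene is downregulated, then drops CpGs whose background blood
methylation would swamp the plasma signal.  For every surviving CpG a set of
five 120-bp probes is designed: the original sequence plus the four in-silico
converted strand x methylation-assumption combinations, so capture efficiency
does not depend on the methylation state of the captured molecule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .context_qc import revcomp

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionThresholds:
    fdr_expr: float = 0.05
    abs_log2fc: float = 1.0
    fdr_meth: float = 0.05
    abs_delta_beta: float = 0.2
    blood_delta: float = 0.1

    def __post_init__(self) -> None:
        for name in ("fdr_expr", "fdr_meth"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0,1)")
        for name in ("abs_log2fc", "abs_delta_beta", "blood_delta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _two_group_t(values: pd.DataFrame, is_case: np.ndarray) -> pd.DataFrame:
    """Row-wise equal-variance two-sample t with BH-FDR correction.

    Rows with zero variance in both groups get p = 1 and a flag.
    """
    is_case = np.asarray(is_case, dtype=bool)
    if is_case.sum() < 2 or (~is_case).sum() < 2:
        raise ValueError("need at least 2 samples per group")
    case = values.loc[:, is_case].to_numpy(dtype=float)
    ctrl = values.loc[:, ~is_case].to_numpy(dtype=float)
    zero_var = (case.var(axis=1) == 0) & (ctrl.var(axis=1) == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat, p_val = stats.ttest_ind(case, ctrl, axis=1, equal_var=True)
    t_stat = np.where(zero_var, 0.0, t_stat)
    p_val = np.where(zero_var | ~np.isfinite(p_val), 1.0, p_val)
    fdr = multipletests(p_val, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "effect": case.mean(axis=1) - ctrl.mean(axis=1),
            "t_stat": t_stat,
            "p_value": p_val,
            "fdr": fdr,
            "zero_variance": zero_var,
        },
        index=values.index,
    )


def differential_expression(
    expr: pd.DataFrame,
    is_case: np.ndarray,
    *,
    log_transform: bool = True,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene log2 fold change (case minus control group mean on the log2
    scale), equal-variance t-test p and BH FDR.  ``expr`` is genes x samples
    on the linear scale unless ``log_transform`` is disabled."""
    values = np.log2(expr + pseudocount) if log_transform else expr
    out = _two_group_t(values, is_case)
    return out.rename(columns={"effect": "log2fc"})


def differential_methylation(beta: pd.DataFrame, is_case: np.ndarray) -> pd.DataFrame:
    """Per-CpG group-mean beta difference (case minus control), t-test p and
    BH FDR.  ``beta`` is CpGs x samples on the raw beta scale."""
    out = _two_group_t(beta, is_case)
    return out.rename(columns={"effect": "delta_beta"})


def select_hcc_markers(
    de: pd.DataFrame,
    dm: pd.DataFrame,
    mapping: pd.DataFrame,
    thresholds: SelectionThresholds | None = None,
) -> pd.DataFrame:
    """Join methylation and expression screens via the CpG->gene map and keep
    CpGs hypermethylated in tumour whose gene is downregulated.

    Keeps a CpG iff delta_beta > abs_delta_beta with FDR_meth < fdr_meth and
    its gene has log2fc < -abs_log2fc with FDR_expr < fdr_expr.  CpGs without
    a mapped gene are skipped (count logged).  Returns one row per mapped CpG
    with per-rule flags and a ``selected`` column.
    """
    th = thresholds or SelectionThresholds()
    n_unmapped = (~dm.index.isin(mapping["cpg_id"])).sum()
    if n_unmapped:
        logger.info("skipping %d CpGs with no gene mapping", n_unmapped)
    table = (
        mapping.merge(dm, left_on="cpg_id", right_index=True)
        .merge(de, left_on="gene", right_index=True, suffixes=("_meth", "_expr"))
        .set_index("cpg_id")
    )
    table["pass_meth"] = (table["delta_beta"] > th.abs_delta_beta) & (
        table["fdr_meth"] < th.fdr_meth
    )
    table["pass_expr"] = (table["log2fc"] < -th.abs_log2fc) & (
        table["fdr_expr"] < th.fdr_expr
    )
    table["selected"] = table["pass_meth"] & table["pass_expr"]
    return table


def blood_filter(
    candidates: pd.DataFrame,
    blood_beta: pd.DataFrame,
    hcc_beta: pd.DataFrame,
    blood_delta: float = 0.1,
) -> tuple[pd.DataFrame, list[str]]:
    """Drop candidate CpGs whose mean blood beta exceeds the mean tumour-tissue
    beta by more than ``blood_delta``.  Candidates missing from the blood
    matrix are retained with a warning.  Returns (kept, removed ids)."""
    blood_mean = blood_beta.mean(axis=1)
    hcc_mean = hcc_beta.mean(axis=1)
    removed: list[str] = []
    keep_mask = []
    for cpg in candidates.index:
        if cpg not in blood_mean.index:
            logger.warning("CpG %s absent from blood matrix; retained", cpg)
            keep_mask.append(True)
            continue
        excess = blood_mean[cpg] - hcc_mean.get(cpg, np.nan)
        drop = bool(np.isfinite(excess) and excess > blood_delta)
        if drop:
            removed.append(cpg)
        keep_mask.append(not drop)
    return candidates.loc[keep_mask], removed


def in_silico_convert(sequence: str, strand: str = "watson", assumption: str = "unmethylated") -> str:
    """Deterministically convert a sequence as complete chemistry would.

    Watson: every C becomes T, except -- under the CpG-methylated assumption --
    a C immediately followed by G.  Crick: the same rules applied to the
    reverse complement of the input.  N bases are preserved untouched; a C
    followed by N is treated as non-CpG.
    """
    strand = strand.lower().lstrip("+-") or ("watson" if strand == "+" else "crick")
    if strand not in ("watson", "crick"):
        raise ValueError(f"strand must be watson or crick, got {strand!r}")
    if assumption not in ("unmethylated", "cpg_methylated"):
        raise ValueError(f"unknown assumption {assumption!r}")
    s = sequence if strand == "watson" else revcomp(sequence)
    out = list(s)
    for i, b in enumerate(out):
        if b != "C":
            continue
        if assumption == "cpg_methylated" and i + 1 < len(s) and s[i + 1] == "G":
            continue
        out[i] = "T"
    return "".join(out)


PROBE_SUFFIXES = ("orig", "mW", "mC", "uW", "uC")


@dataclass(frozen=True)
class ProbeSet:
    """Five capture probes for one CpG: original, converted methylated
    Watson/Crick, converted unmethylated Watson/Crick."""

    cpg_id: str
    reference: str
    window_start: int
    probes: Mapping[str, str]

    def __post_init__(self) -> None:
        if set(self.probes) != set(PROBE_SUFFIXES):
            raise ValueError(f"probe set must have exactly {PROBE_SUFFIXES}")
        lengths = {len(p) for p in self.probes.values()}
        if len(lengths) != 1:
            raise ValueError("all probes must share one length")

    def to_fasta_records(self) -> list[tuple[str, str]]:
        return [(f"{self.cpg_id}_{sfx}", self.probes[sfx]) for sfx in PROBE_SUFFIXES]


def design_probe_set(
    ref_seq: str,
    cpg_pos: int,
    probe_length: int = 120,
    *,
    cpg_id: str | None = None,
    reference: str = "ref",
) -> ProbeSet:
    """Design the five-probe set for the CpG whose C sits at ``cpg_pos``.

    The window is centred on the CpG and shifted (with a log message) when the
    CpG lies within half a probe length of a reference end.
    """
    L = len(ref_seq)
    if L < probe_length:
        raise ValueError(f"reference length {L} shorter than probe length {probe_length}")
    if not (0 <= cpg_pos < L - 1 and ref_seq[cpg_pos : cpg_pos + 2] == "CG"):
        raise ValueError(f"position {cpg_pos} is not the C of a CpG dyad")
    start = cpg_pos - probe_length // 2 + 1
    shifted = min(max(start, 0), L - probe_length)
    if shifted != start:
        logger.info("probe window for %s:%d shifted by %d bp to fit reference",
                    reference, cpg_pos, shifted - start)
    window = ref_seq[shifted : shifted + probe_length]
    probes = {
        "orig": window,
        "mW": in_silico_convert(window, "watson", "cpg_methylated"),
        "mC": in_silico_convert(window, "crick", "cpg_methylated"),
        "uW": in_silico_convert(window, "watson", "unmethylated"),
        "uC": in_silico_convert(window, "crick", "unmethylated"),
    }
    return ProbeSet(
        cpg_id=cpg_id or f"{reference}:{cpg_pos}",
        reference=reference,
        window_start=shifted,
        probes=probes,
    )
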
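"""Simulators for conversion-treated control DNA and cfDNA-like fragments.

Two failure modes are modelled explicitly.  Sporadic failures arise from the
per-site conversion probability ``eff`` being below 1 in an otherwise normal
molecule.  Clustered failures arise from whole molecules drawn as
conversion-compromised (probability ``rho_fail``) whose sites convert at the
much lower ``eff_fail``; these produce reads with many unconverted CH calls.
Every simulated read carries a truth record so downstream QC can be scored.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .context_qc import CRICK, WATSON, ConvertedRead

logger = logging.getLogger(__name__)

_BASES = (b"A", b"C", b"G", b"T")


class MethylomeSpec:
    """Per-reference map of (cytosine position, strand) -> methylation probability.

    Positions are 0-based forward coordinates; strand "+" marks a C on the
    Watson strand, "-" a C on the Crick strand (a G in forward sequence).
    Unlisted positions are unmethylated (probability 0).
    """

    def __init__(self, levels: Mapping[str, Mapping[tuple[int, str], float]]):
        for ref, sites in levels.items():
            for (pos, strand), p in sites.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"methylation probability out of [0,1] at {ref}:{pos}{strand}")
                if strand not in (WATSON, CRICK):
                    raise ValueError(f"bad strand {strand!r} at {ref}:{pos}")
        self.levels = {ref: dict(sites) for ref, sites in levels.items()}

    def prob(self, reference: str, pos: int, strand: str) -> float:
        return self.levels.get(reference, {}).get((pos, strand), 0.0)

    def validate(self, refs: Mapping[str, str]) -> None:
        """Check every keyed position really is a cytosine on its stated strand."""
        for ref, sites in self.levels.items():
            seq = refs[ref]
            for pos, strand in sites:
                expected = "C" if strand == WATSON else "G"
                if not (0 <= pos < len(seq)) or seq[pos] != expected:
                    raise ValueError(
                        f"{ref}:{pos} ({strand}) is not a cytosine on that strand"
                    )

    @classmethod
    def all_unmethylated(cls, refs: Mapping[str, str]) -> "MethylomeSpec":
        return cls({name: {} for name in refs})

    @classmethod
    def cpg_methylated(cls, refs: Mapping[str, str], prob: float = 1.0) -> "MethylomeSpec":
        """Both cytosines of every CpG dyad methylated with probability ``prob``."""
        levels: dict[str, dict[tuple[int, str], float]] = {}
        for name, seq in refs.items():
            sites: dict[tuple[int, str], float] = {}
            for i in range(len(seq) - 1):
                if seq[i] == "C" and seq[i + 1] == "G":
                    sites[(i, WATSON)] = prob
                    sites[(i + 1, CRICK)] = prob
            levels[name] = sites
        return cls(levels)


@dataclass(frozen=True)
class ConversionParams:
    """Per-molecule conversion behaviour.

    eff       -- per-site conversion probability of an unmethylated C in a
                 normal molecule
    rho_fail  -- probability a molecule is conversion-compromised
    eff_fail  -- per-site conversion probability within a compromised molecule
    err       -- per-base sequencing error rate, applied after conversion
    """

    eff: float = 0.998
    rho_fail: float = 0.01
    eff_fail: float = 0.5
    err: float = 0.001
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("eff", "rho_fail", "eff_fail", "err"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.eff_fail > self.eff:
            raise ValueError("eff_fail must not exceed eff")


@dataclass(frozen=True)
class FragmentParams:
    """cfDNA-like fragment length model: a modal Gaussian (default 167 +/- 10)
    plus optional sub-peaks spaced ``subpeak_spacing`` bp below the mode."""

    n_fragments: int = 10000
    mean_length: float = 167.0
    sd_length: float = 10.0
    periodic_weight: float = 0.0
    n_subpeaks: int = 3
    subpeak_spacing: float = 10.0
    subpeak_sd: float = 2.0
    min_length: int = 60
    max_length: int = 400
    p_watson: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_fragments < 0:
            raise ValueError("n_fragments must be >= 0")
        if not 0 < self.min_length <= self.max_length:
            raise ValueError("need 0 < min_length <= max_length")
        if not 0.0 <= self.p_watson <= 1.0:
            raise ValueError("p_watson outside [0,1]")
        if not 0.0 <= self.periodic_weight <= 1.0:
            raise ValueError("periodic_weight outside [0,1]")


@dataclass(frozen=True)
class Fragment:
    """Half-open fragment interval on a reference, with strand of origin."""

    reference: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad fragment interval [{self.start},{self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MoleculeTruth:
    compromised: bool
    n_conversion_failures: int


def simulate_fragments(
    ref_seq: str,
    params: FragmentParams,
    *,
    reference: str = "ref",
    rng: np.random.Generator | None = None,
) -> list[Fragment]:
    """Draw fragments with mixture-model lengths and uniform placement."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if params.n_fragments == 0:
        return []
    L = len(ref_seq)
    if L < params.min_length:
        raise ValueError(
            f"reference length {L} shorter than minimum fragment length {params.min_length}"
        )
    n = params.n_fragments
    sub = rng.random(n) < params.periodic_weight
    k = rng.integers(1, params.n_subpeaks + 1, size=n)
    means = np.where(sub, params.mean_length - k * params.subpeak_spacing, params.mean_length)
    sds = np.where(sub, params.subpeak_sd, params.sd_length)
    lengths = np.rint(rng.normal(means, sds)).astype(int)
    lengths = np.clip(lengths, params.min_length, min(params.max_length, L))
    starts = rng.integers(0, L - lengths + 1)
    strands = np.where(rng.random(n) < params.p_watson, WATSON, CRICK)
    return [
        Fragment(reference, int(s), int(s + l), str(st))
        for s, l, st in zip(starts, lengths, strands)
    ]


def convert_molecule(
    sequence: str,
    methylome: MethylomeSpec,
    params: ConversionParams,
    rng: np.random.Generator,
    *,
    reference: str = "ref",
    start: int = 0,
    strand: str = WATSON,
    read_id: str = "read",
) -> tuple[ConvertedRead, MoleculeTruth]:
    """Apply conversion chemistry to one molecule and emit its read.

    ``sequence`` is given in forward-reference orientation; for Crick-origin
    molecules the cytosines are the forward-sequence Gs and convert G->A.
    Methylated cytosines (per the methylome probabilities) never convert; N
    bases never convert.  Sequencing errors are applied last.
    """
    arr = np.frombuffer(sequence.encode("ascii"), dtype="S1").copy()
    target, product = (b"C", b"T") if strand == WATSON else (b"G", b"A")
    idx = np.flatnonzero(arr == target)
    compromised = bool(rng.random() < params.rho_fail)
    p_conv = params.eff_fail if compromised else params.eff
    n_failed = 0
    if idx.size:
        sites = methylome.levels.get(reference, {})
        if sites:
            probs = np.fromiter(
                (sites.get((start + int(i), strand), 0.0) for i in idx), float, count=idx.size
            )
            meth = rng.random(idx.size) < probs
        else:
            meth = np.zeros(idx.size, dtype=bool)
        converted = ~meth & (rng.random(idx.size) < p_conv)
        n_failed = int((~meth & ~converted).sum())
        arr[idx[converted]] = product
    if params.err > 0:
        hits = np.flatnonzero(rng.random(arr.size) < params.err)
        for i in hits:
            cur = arr[i]
            choices = [b for b in _BASES if b != cur]
            arr[i] = choices[rng.integers(len(choices))]
    read = ConvertedRead(
        read_id=read_id,
        reference=reference,
        start=start,
        sequence=arr.tobytes().decode("ascii"),
        strand=strand,
    )
    return read, MoleculeTruth(compromised=compromised, n_conversion_failures=n_failed)


@dataclass
class SimulatedRun:
    reads: list[ConvertedRead]
    truth: pd.DataFrame = field(default_factory=pd.DataFrame)


def simulate_control_run(
    refs: Mapping[str, str],
    methylomes: Mapping[str, MethylomeSpec],
    frag_params: FragmentParams,
    conv_params: ConversionParams,
    *,
    seed: int | None = None,
) -> SimulatedRun:
    """Simulate a mixed control run over one or more reference molecules.

    Fragment counts are split across references in proportion to length.  The
    truth table records origin reference, coordinates, strand, the compromised
    flag and the realised number of conversion failures per read.
    """
    if not refs:
        raise ValueError("at least one reference required")
    for name in refs:
        if name not in methylomes:
            raise KeyError(f"no methylome spec for reference {name!r}")
    if seed is None:
        seed = conv_params.seed if conv_params.seed is not None else frag_params.seed
    rng = np.random.default_rng(seed)
    n_total = frag_params.n_fragments
    if n_total == 0:
        logger.warning("zero fragments requested; returning empty run")
        return SimulatedRun(reads=[], truth=_empty_truth())
    names = sorted(refs)
    weights = np.array([len(refs[n]) for n in names], dtype=float)
    counts = rng.multinomial(n_total, weights / weights.sum())
    reads: list[ConvertedRead] = []
    rows = []
    for name, n_frag in zip(names, counts):
        if n_frag == 0:
            continue
        per_ref = dataclasses.replace(frag_params, n_fragments=int(n_frag), seed=None)
        fragments = simulate_fragments(refs[name], per_ref, reference=name, rng=rng)
        for i, frag in enumerate(fragments):
            read, truth = convert_molecule(
                refs[name][frag.start : frag.end],
                methylomes[name],
                conv_params,
                rng,
                reference=name,
                start=frag.start,
                strand=frag.strand,
                read_id=f"{name}|{i:06d}",
            )
            reads.append(read)
            rows.append(
                (read.read_id, name, frag.start, frag.end, frag.strand,
                 truth.compromised, truth.n_conversion_failures)
            )
    truth_df = pd.DataFrame(
        rows,
        columns=[
            "read_id", "reference", "start", "end", "strand",
            "compromised", "n_conversion_failures",
        ],
    )
    return SimulatedRun(reads=reads, truth=truth_df)


def _empty_truth() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "read_id", "reference", "start", "end", "strand",
            "compromised", "n_conversion_failures",
        ]
    )
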
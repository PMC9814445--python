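"""Synthetic plasma cohort generator.

Produces three-class cohorts (normal / liver disease / HCC with stages) with
marker-level beta values under the standard ctDNA dilution assumption: the
observed methylation of a tumour marker is a mixture of a low background
level and a high tumour level, weighted by the sample's tumour fraction
theta.  Liver-disease samples get a small additive shift on a marker subset.
Sampling noise is beta-binomial at a configurable sequencing depth.

The stage-specific theta ranges are implementer defaults, not measured
values; they are chosen so signal intensity increases stage I < II < III-IV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

CLASSES = ("normal", "liver", "HCC")
STAGES = ("I", "II", "III-IV")

AFP_CUTOFF = 20.0  # ng/mL
PIVKA_CUTOFF = 40.0  # mAU/mL-style cutoff at 40


@dataclass(frozen=True)
class CohortParams:
    """Class sizes default to a 195/54/168 training and 84/22/73 test split
    (normal / liver disease / HCC) with 283 markers at depth 800."""

    n_train: tuple[int, int, int] = (195, 54, 168)
    n_test: tuple[int, int, int] = (84, 22, 73)
    n_markers: int = 283
    background_beta: tuple[float, float] = (2.0, 60.0)  # Beta(a,b), mean ~0.032
    tumor_beta: tuple[float, float] = (8.0, 4.0)  # Beta(a,b), mean ~0.67
    liver_delta: float = 0.02
    liver_marker_frac: float = 0.2
    stage_theta: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "I": (0.005, 0.03),
            "II": (0.01, 0.06),
            "III-IV": (0.03, 0.20),
        }
    )
    stage_probs: dict[str, float] = field(
        default_factory=lambda: {"I": 0.55, "II": 0.12, "III-IV": 0.33}
    )
    depth: int = 800
    overdispersion: float = 0.01
    noiseless: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_markers <= 0:
            raise ValueError("n_markers must be positive")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if any(n < 0 for n in (*self.n_train, *self.n_test)):
            raise ValueError("class sizes must be >= 0")
        for stage, (lo, hi) in self.stage_theta.items():
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"theta range for stage {stage} outside [0,1]")
        if not 0.0 < self.overdispersion < 1.0:
            raise ValueError("overdispersion must be in (0,1)")

    @classmethod
    def null(cls, **overrides) -> "CohortParams":
        """A no-signal cohort: every tumour fraction zero, no liver shift."""
        base = cls(
            stage_theta={s: (0.0, 0.0) for s in STAGES},
            liver_delta=0.0,
        )
        return replace(base, **overrides)


@dataclass
class SampleProfile:
    sample_id: str
    label: str  # normal / liver / HCC
    stage: str | None  # I / II / III-IV for HCC, None otherwise
    betas: np.ndarray
    theta: float
    afp: float
    pivka: float

    def __post_init__(self) -> None:
        if self.label not in CLASSES:
            raise ValueError(f"unknown class {self.label!r}")
        if (self.stage is not None) != (self.label == "HCC"):
            raise ValueError("stage must be set exactly for HCC samples")
        if np.any((self.betas < 0) | (self.betas > 1)):
            raise ValueError("betas outside [0,1]")


@dataclass
class Cohort:
    train: list[SampleProfile]
    test: list[SampleProfile]
    marker_names: list[str]
    marker_truth: pd.DataFrame


def _observe(true_beta: np.ndarray, params: CohortParams, rng: np.random.Generator) -> np.ndarray:
    """Beta-binomial read-sampling noise around the true marker betas."""
    if params.noiseless:
        return true_beta.copy()
    c = (1.0 - params.overdispersion) / params.overdispersion
    m = np.empty_like(true_beta)
    interior = (true_beta > 0) & (true_beta < 1)
    m[~interior] = true_beta[~interior]
    if interior.any():
        tb = true_beta[interior]
        m[interior] = rng.beta(tb * c, (1.0 - tb) * c)
    counts = rng.binomial(params.depth, m)
    return counts / params.depth


def _serology(label: str, theta: float, rng: np.random.Generator) -> tuple[float, float]:
    """Lognormal AFP / PIVKA-II draws whose scale grows with tumour fraction,
    so AFP-negative (and PIVKA-negative) HCC samples occur at low theta."""
    if label == "normal":
        return rng.lognormal(math.log(3.0), 0.7), rng.lognormal(math.log(18.0), 0.5)
    if label == "liver":
        return rng.lognormal(math.log(6.0), 0.9), rng.lognormal(math.log(22.0), 0.6)
    return (
        rng.lognormal(math.log(6.0) + 28.0 * theta, 1.0),
        rng.lognormal(math.log(25.0) + 35.0 * theta, 0.9),
    )


def simulate_cohort(params: CohortParams | None = None) -> Cohort:
    """Generate a full train/test cohort; fixed seed gives an identical cohort."""
    params = params or CohortParams()
    rng = np.random.default_rng(params.seed)
    M = params.n_markers
    bg = rng.beta(*params.background_beta, size=M)
    tum = rng.beta(*params.tumor_beta, size=M)
    n_liver_markers = int(round(params.liver_marker_frac * M))
    liver_idx = rng.choice(M, size=n_liver_markers, replace=False)
    liver_mask = np.zeros(M, dtype=bool)
    liver_mask[liver_idx] = True
    marker_names = [f"m{i:04d}" for i in range(M)]
    marker_truth = pd.DataFrame(
        {
            "marker": marker_names,
            "background_beta": bg,
            "tumor_beta": tum,
            "liver_shifted": liver_mask,
        }
    ).set_index("marker")

    stage_names = list(params.stage_probs)
    stage_p = np.array([params.stage_probs[s] for s in stage_names], dtype=float)
    stage_p = stage_p / stage_p.sum()

    def make_samples(split: str, sizes: Sequence[int]) -> list[SampleProfile]:
        samples: list[SampleProfile] = []
        for label, n in zip(CLASSES, sizes):
            for i in range(n):
                stage = None
                theta = 0.0
                if label == "HCC":
                    stage = stage_names[rng.choice(len(stage_names), p=stage_p)]
                    lo, hi = params.stage_theta[stage]
                    theta = float(rng.uniform(lo, hi))
                true = (1.0 - theta) * bg + theta * tum
                if label == "liver":
                    true = np.clip(true + params.liver_delta * liver_mask, 0.0, 1.0)
                betas = _observe(true, params, rng)
                afp, pivka = _serology(label, theta, rng)
                samples.append(
                    SampleProfile(
                        sample_id=f"{split}_{label}_{i:03d}",
                        label=label,
                        stage=stage,
                        betas=betas,
                        theta=theta,
                        afp=afp,
                        pivka=pivka,
                    )
                )
        return samples

    return Cohort(
        train=make_samples("train", params.n_train),
        test=make_samples("test", params.n_test),
        marker_names=marker_names,
        marker_truth=marker_truth,
    )


def feature_frame(samples: Sequence[SampleProfile], marker_names: Sequence[str]) -> pd.DataFrame:
    """Samples x markers beta matrix."""
    return pd.DataFrame(
        np.vstack([s.betas for s in samples]),
        index=[s.sample_id for s in samples],
        columns=list(marker_names),
    )


def label_series(samples: Sequence[SampleProfile]) -> pd.Series:
    return pd.Series([s.label for s in samples], index=[s.sample_id for s in samples], name="label")


def sample_sheet(samples: Sequence[SampleProfile]) -> pd.DataFrame:
    """Sample metadata table: class, stage, truth theta and serology with
    positivity flags at the 20 ng/mL (AFP) and 40 (PIVKA-II) cutoffs."""
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "label": [s.label for s in samples],
            "stage": [s.stage if s.stage is not None else "NA" for s in samples],
            "theta": [s.theta for s in samples],
            "afp": [s.afp for s in samples],
            "pivka": [s.pivka for s in samples],
            "afp_pos": [s.afp >= AFP_CUTOFF for s in samples],
            "pivka_pos": [s.pivka >= PIVKA_CUTOFF for s in samples],
        }
    ).set_index("sample_id")
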
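import numpy as np
import pytest

from methylscreen.context_qc import FilterConfig, filter_reads
from methylscreen.conversion_sim import (
    ConversionParams,
    FragmentParams,
    MethylomeSpec,
    simulate_control_run,
)


def random_sequence(length: int, seed: int, gc: float = 0.5) -> str:
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


@pytest.fixture(scope="session")
def lambda_like() -> str:
    """Unmethylated control reference (random 20 kb, 50% GC)."""
    return random_sequence(20000, seed=101)


@pytest.fixture(scope="session")
def puc19_like() -> str:
    """CpG-methylated control reference (random 2.7 kb)."""
    return random_sequence(2700, seed=202)


@pytest.fixture(scope="session")
def control_refs(lambda_like, puc19_like) -> dict:
    return {"lambda_like": lambda_like, "puc19_like": puc19_like}


@pytest.fixture(scope="session")
def control_methylomes(control_refs) -> dict:
    return {
        "lambda_like": MethylomeSpec.all_unmethylated(
            {"lambda_like": control_refs["lambda_like"]}
        ),
        "puc19_like": MethylomeSpec.cpg_methylated(
            {"puc19_like": control_refs["puc19_like"]}
        ),
    }


QC_CONV_PARAMS = ConversionParams(eff=0.998, rho_fail=0.01, eff_fail=0.5, err=0.0)
QC_SEED = 7


@pytest.fixture(scope="session")
def control_sim(control_refs, control_methylomes):
    """50k-read mixed control run at the conversion-QC reference settings."""
    return simulate_control_run(
        control_refs,
        control_methylomes,
        FragmentParams(n_fragments=50000),
        QC_CONV_PARAMS,
        seed=QC_SEED,
    )


@pytest.fixture(scope="session")
def control_filtered(control_sim, control_refs):
    """Filter result over the full control run (attaches call strings)."""
    return filter_reads(control_sim.reads, control_refs, FilterConfig())
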
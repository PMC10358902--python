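import numpy as np
import pytest

from tgscore.genotype_io import AlleleCall, GenotypePanel, SNPMeta
from tgscore.simulate import SimulationConfig, simulate_cohort


def make_panel(genotypes: dict[str, dict[str, str]], meta: dict[str, SNPMeta]) -> GenotypePanel:
    """Build a panel from {rsid: {participant: genotype}} for toy cases."""
    participants: list[str] = []
    calls = {}
    for rsid, per_pid in genotypes.items():
        for pid, geno in per_pid.items():
            if pid not in participants:
                participants.append(pid)
            calls[(pid, rsid)] = AlleleCall(pid, rsid, geno)
    return GenotypePanel(calls=calls, meta=meta, participants=participants)


def snp(rsid: str, ref: str, alt: str, **kw) -> SNPMeta:
    kw.setdefault("gene", "GENE")
    return SNPMeta(rsid=rsid, ref_allele=ref, alt_allele=alt, **kw)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced synthetic cohort that runs the full pipeline quickly."""
    cfg = SimulationConfig(n_snps=120, monomorphic_fraction=0.25, n_causal=10, seed=7)
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
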
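import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from msikit import (
    SimParams,
    cohort_feature_matrix,
    default_panel,
    simulate_cohort,
    train_kmeans,
)

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def panel():
    return default_panel(29)


@pytest.fixture(scope="session")
def sim_params():
    return SimParams()


@pytest.fixture(scope="session")
def training_cohort(tmp_path_factory, sim_params):
    """Default 94-sample training-like cohort (22 MSI-H, 25 MSS, 47 normal)."""
    out = tmp_path_factory.mktemp("training_cohort")
    return simulate_cohort(sim_params, 22, 25, 47, out, seed=17)


@pytest.fixture(scope="session")
def training_matrix(training_cohort):
    return cohort_feature_matrix(training_cohort)


@pytest.fixture(scope="session")
def trained_model(training_cohort, training_matrix):
    labels = [training_cohort.truth[s] for s in training_matrix.sample_ids]
    return train_kmeans(training_matrix, labels, seed=0)


def write_vcf_text(path, body_lines, contigs=("chr1",)):
    """Tiny hand-rolled VCF for parser tests."""
    header = ["##fileformat=VCFv4.2",
              '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
              '##FILTER=<ID=PASS,Description="All filters passed">',
              '##FILTER=<ID=LowQual,Description="Low quality">']
    header += [f"##contig=<ID={c},length=1000000>" for c in contigs]
    header.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    path.write_text("\n".join(header + list(body_lines)) + "\n")
    return path
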
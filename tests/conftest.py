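import numpy as np
import pandas as pd
import pytest

from riftkin import ChaseDesign
from riftkin.synthetic import TrueKinetics, simulate_genome, simulate_operon

GRID = np.array([0.0, 2.5, 5.0, 10.0, 20.0, 40.0, 60.0])


@pytest.fixture(scope="session")
def design_clean():
    """Noise-free single-replicate design on the chase grid."""
    return ChaseDesign(seed=101, noise_sigma=0.0, replicates=1)


@pytest.fixture(scope="session")
def design_noisy():
    """Triplicate design with the default multiplicative noise."""
    return ChaseDesign(seed=202, noise_sigma=0.1, replicates=3)


@pytest.fixture(scope="session")
def genome_fixture():
    """Small genome-scale fixture shared across read-only tests."""
    design = ChaseDesign(seed=303, noise_sigma=0.1, replicates=3)
    truth, series, annotation, categories = simulate_genome(
        design, n_genes=250, n_operons=20, n_type2=4,
        low_expression_fraction=0.2)
    return design, truth, series, annotation, categories


@pytest.fixture()
def pure_exponential():
    """A pure exponential transcript (t1/2 = 5 min) and its grid series."""
    k = TrueKinetics("pure", E0=800.0, onset_delay=0.0, fast_half_life=5.0,
                     slow_half_life=5.0, phase_break=30.0)
    signal = 800.0 * 2.0 ** (-GRID / 5.0)
    return k, GRID, signal


def operon_annotation(truth):
    """Plus-strand annotation frame matching an operon truth table."""
    rows = []
    for k in truth.kinetics:
        start = 1 + int(k.distance_from_operon_start)
        rows.append({
            "gene_id": k.gene_id, "start": start,
            "end": start + k.gene_length - 1, "strand": "+",
            "length_nt": k.gene_length, "category": "unknown",
            "operon_id": k.operon_id or "", "operon_position": k.operon_position,
            "dist_to_operon_start_nt": k.distance_from_operon_start,
        })
    return pd.DataFrame(rows).set_index("gene_id")
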
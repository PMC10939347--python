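import numpy as np
import pandas as pd
import pytest

from clonescan.core import GenotypeMatrix


def make_matrix(gt_rows, samples=None, chrom="chr1", start_pos=100, spacing=100,
                vtype="SNP", qd=25.0, dp=16, positions=None, vtypes=None):
    """Build a small GenotypeMatrix from genotype-code rows (sites x samples)."""
    gt = np.array(gt_rows, dtype=np.int8)
    n_sites, n_samples = gt.shape
    samples = samples or [f"S{i + 1}" for i in range(n_samples)]
    if positions is None:
        positions = [start_pos + i * spacing for i in range(n_sites)]
    if vtypes is None:
        vtypes = [vtype] * n_sites
    rows = []
    for pos, vt in zip(positions, vtypes):
        if vt == "SNP":
            ref, alt = "A", "T"
        else:
            ref, alt = "AT", "A"
        rows.append({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt, "vtype": vt, "qd": qd})
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "vtype", "qd"])
    dp_arr = np.full((n_sites, n_samples), dp, dtype=np.int32)
    return GenotypeMatrix(samples=samples, sites=sites, gt=gt, dp=dp_arr)


@pytest.fixture(scope="session")
def small_sim():
    """A fast small simulated panel with outgroup, shared across tests."""
    from clonescan.clonesim import SimConfig, simulate_population

    cfg = SimConfig(
        seed=11,
        chrom_lengths={"chr1": 400_000, "chr2": 400_000},
        outgroup=True,
        te_counts_by_sharing={1: 30, 2: 12, 3: 6, 8: 2},
    )
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def default_sim():
    """The default study-condition simulation (6 Mbp, 8 clones, outgroup)."""
    from clonescan.clonesim import SimConfig, simulate_population

    return simulate_population(SimConfig(seed=2024, outgroup=True))
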
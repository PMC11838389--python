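import numpy as np
import pandas as pd
import pytest

from lumenstrain.io import SNVTable, SampleMeta
from lumenstrain.simulate import build_scenario


def make_table(depth, alt, species_id="spX", site_types=None):
    """Small SNVTable from site x sample arrays (columns auto-named)."""
    depth = np.atleast_2d(np.asarray(depth))
    alt = np.atleast_2d(np.asarray(alt))
    n_sites, n_samp = depth.shape
    idx = pd.Index([f"{species_id}|s{i:04d}" for i in range(n_sites)], name="site_id")
    cols = [f"smp{j}" for j in range(n_samp)]
    sites = pd.DataFrame(
        {
            "contig": "contig_1",
            "position": np.arange(1, n_sites + 1),
            "ref_allele": "A",
            "alt_allele": "G",
            "gene_id": "gene_0001",
            "site_type": site_types if site_types is not None else "syn",
        },
        index=idx,
    )
    return SNVTable(
        species_id,
        sites,
        pd.DataFrame(depth, index=idx, columns=cols),
        pd.DataFrame(alt, index=idx, columns=cols),
    )


def eight_mouse_meta():
    """The caged-mouse design: 8 mice in cages of (3, 2, 3), 5 regions each."""
    from lumenstrain.simulate import ColonizationConfig, make_sample_sheet

    return make_sample_sheet(ColonizationConfig())


@pytest.fixture(scope="session")
def two_strain_build():
    return build_scenario("two_strain_uniform", seed=11)


@pytest.fixture(scope="session")
def three_strain_build():
    return build_scenario("three_strain", seed=11)


@pytest.fixture(scope="session")
def single_strain_build():
    return build_scenario("single_strain", seed=11)


@pytest.fixture(scope="session")
def planted_sweeps_build():
    return build_scenario("planted_sweeps", seed=11)
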
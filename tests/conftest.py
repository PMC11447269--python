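import logging

import pytest

from karstpop.simulate import SimConfig, simulate_dataset

logging.getLogger("karstpop").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def base_bundle():
    """One medium synthetic bundle exercising every feature."""
    cfg = SimConfig(
        seed=11,
        genome=[("chr1", 400_000), ("chr2", 200_000)],
        mutation_density=3.0,
        n_genes=25,
        missing_rate=0.02,
        deleterious_hom_bias=0.3,
        n_private_nonsyn=3,
        n_stop_gained=1,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def written_bundle(tmp_path_factory, base_bundle):
    """The base bundle written to disk, returning (bundle, paths)."""
    outdir = tmp_path_factory.mktemp("bundle")
    paths = base_bundle.write(outdir)
    return base_bundle, paths
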
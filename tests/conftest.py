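"""Shared fixtures: a small synthetic study generated once per session."""

import pytest

from divscan.models import MODELS, DemographicParams
from divscan import simdata


#: the scaled secondary-contact-with-stop history used across tests
SCS_TRUTH = DemographicParams(
    n_anc=500,
    n_pma=500,
    n_pja=500,
    t_split=3000,
    t_contact=300,
    t_stop=10,
    m_mj=0.0005,
    m_jm=0.005,
)


def make_landscape_config(seed: int, **kw) -> simdata.SimulationConfig:
    """A compact multi-chromosome layout with two planted divergent regions."""
    layout = simdata.default_layout(
        n_chromosomes=kw.pop("n_chromosomes", 4),
        chrom_length=kw.pop("chrom_length", 400_000),
        n_loci=kw.pop("n_loci", 160),
        locus_length=kw.pop("locus_length", 150),
        n_divergent=kw.pop("n_divergent", 2),
        region_length=kw.pop("region_length", 80_000),
        seed=kw.pop("layout_seed", 1),
    )
    return simdata.SimulationConfig(
        layout=layout,
        model=MODELS["SCS"],
        truth=SCS_TRUTH,
        samples_per_deme=kw.pop("samples_per_deme", (20, 10)),
        theta_per_locus=kw.pop("theta_per_locus", 4.0),
        seed=seed,
        **kw,
    )


@pytest.fixture(scope="session")
def landscape_dataset():
    """One simulated study used by many read-only tests."""
    return simdata.simulate_dataset(make_landscape_config(seed=3))


@pytest.fixture(scope="session")
def study_bundle(tmp_path_factory):
    """A written study bundle (VCF/FASTA/GFF/GO/popmap/truth) on disk."""
    outdir = tmp_path_factory.mktemp("bundle")
    cfg = make_landscape_config(seed=11, n_chromosomes=3, n_loci=90,
                                chrom_length=300_000, n_divergent=1,
                                region_length=60_000, samples_per_deme=(12, 8))
    paths = simdata.write_dataset(cfg, outdir)
    return cfg, paths
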
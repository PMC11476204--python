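import numpy as np
import pandas as pd
import pytest

from cardiosplice import GeneModel, JunctionCountSet, SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A reduced cohort that keeps the default class structure but runs in
    about a second."""
    return SimConfig(
        seed=7, n_case_samples=30, n_control_samples=40, n_genes=60,
        variants_per_sample=40, synonymous_rate=5,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture
def toy_gene() -> GeneModel:
    """Three exons -> two junctions: (200,301) and (400,501)."""
    return GeneModel(
        gene_id="GX", chrom="chr1",
        exons=[(100, 200), (301, 400), (501, 600)],
        tier=1, inheritance="AD", pli=0.95, median_tpm=5.0,
    )


def make_theta_counts(
    theta_rows: np.ndarray,
    gene_ids: list[str] | None = None,
    positions: list[int] | None = None,
    samples: list[str] | None = None,
    depth: int = 100,
) -> JunctionCountSet:
    """Site-level count set with exact splicing fractions per (sample, site).

    ``theta_rows`` is samples x sites of intended θ values; counts are
    deterministic (split = round(θ · depth)).
    """
    theta_rows = np.atleast_2d(np.asarray(theta_rows, float))
    n_s, n_sites = theta_rows.shape
    samples = samples or [f"S{i:02d}" for i in range(n_s)]
    site_ids = [f"site{j}" for j in range(n_sites)]
    gene_ids = gene_ids or [f"G{j}" for j in range(n_sites)]
    positions = positions or [1000 * (j + 1) for j in range(n_sites)]
    split = np.round(theta_rows * depth).astype(int)
    nonsplit = depth - split
    sites = pd.DataFrame({"gene_id": gene_ids, "pos": positions},
                         index=pd.Index(site_ids, name="site_id"))
    junctions = pd.DataFrame(
        {"gene_id": ["G_dummy"], "donor": [10], "acceptor": [20]},
        index=pd.Index(["jdummy"], name="junction_id"),
    )
    jsplit = pd.DataFrame(depth, index=samples, columns=junctions.index)
    return JunctionCountSet(
        junctions=junctions, split_counts=jsplit, sites=sites,
        site_split=pd.DataFrame(split, index=samples, columns=site_ids),
        site_nonsplit=pd.DataFrame(nonsplit, index=samples, columns=site_ids),
    )
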
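import numpy as np
import pytest

from intromap import GenotypeMatrix, PopulationMap


def build_matrix(
    codes,
    chrom="chr1",
    positions=None,
    samples=None,
    ploidy=None,
    depth=None,
    ref=None,
    alt=None,
    chroms=None,
):
    """Construct a GenotypeMatrix from plain lists for toy examples."""
    codes = np.asarray(codes, dtype=np.int16)
    n_sites, n_hap = codes.shape
    if positions is None:
        positions = list(range(1, n_sites + 1))
    if chroms is None:
        chroms = [chrom] * n_sites
    if ploidy is None:
        assert n_hap % 2 == 0
        ploidy = [2] * (n_hap // 2)
    if samples is None:
        samples = [f"s{i}" for i in range(len(ploidy))]
    if ref is None:
        ref = ["A"] * n_sites
    if alt is None:
        alt = [("T",)] * n_sites
    return GenotypeMatrix(chroms, positions, ref, alt, codes, depth, samples, ploidy)


def four_group_popmap(samples_per_group=1, ploidy=2, prefix=("p1", "p2", "p3", "o")):
    """Population map with one group per role; sample ids <prefix>_<i>."""
    assignment = {}
    for g, pre in zip(("g1", "g2", "g3", "g4"), prefix):
        for i in range(samples_per_group):
            assignment[f"{pre}_{i}"] = g
    return PopulationMap(
        assignment=assignment, roles={"P1": "g1", "P2": "g2", "P3": "g3", "O": "g4"}
    )


def random_four_group_matrix(rng, n_sites=None, haps_per_group=3, missing_p=0.15):
    """Random biallelic matrix over four groups with missingness.

    Guarantees at least one called haplotype per group at one site so the
    statistics are defined somewhere.
    """
    if n_sites is None:
        n_sites = int(rng.integers(5, 51))
    n_hap = 4 * haps_per_group
    codes = rng.integers(0, 2, size=(n_sites, n_hap)).astype(np.int16)
    miss = rng.random((n_sites, n_hap)) < missing_p
    codes[miss] = -1
    codes[0] = np.abs(codes[0])  # keep site 0 fully called
    samples, ploidy, assignment = [], [], {}
    for g in range(4):
        for i in range(haps_per_group):
            name = f"g{g}_{i}"
            samples.append(name)
            ploidy.append(1)
            assignment[name] = f"grp{g}"
    pm = PopulationMap(
        assignment=assignment,
        roles={"P1": "grp0", "P2": "grp1", "P3": "grp2", "O": "grp3"},
    )
    gm = build_matrix(codes, samples=samples, ploidy=ploidy)
    return gm, pm


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete simulated dataset (two 1 Mb chromosomes)."""
    from intromap.simulate import SimConfig, simulate_dataset

    cfg = SimConfig(
        seed=42,
        chrom_lengths={"chr1": 1_000_000, "chr2": 1_000_000},
        wp_locus=("chr2", 500_000),
        # per-chromosome crossover rate scaled to the shorter chromosomes so
        # the per-bp recombination density matches the full-size design
        crossover_rate=0.15,
    )
    return simulate_dataset(cfg)
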
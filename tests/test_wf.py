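"""Wright-Fisher engine: determinism, conservation, mutation model,
neutral expectations against coalescent oracles, and rescaling."""


import msprime
import numpy as np
import pandas as pd
import pytest

from ldrepulsion import (
    DemographyModel,
    DFEModel,
    ForwardSimulator,
    SimulationConfig,
    simulate,
    summarize_selection_by_frequency,
)

from conftest import make_sample


def _cfg(**kw):
    base = dict(
        length=200_000,
        r=1e-8,
        rescale_factor=20,
        seed=5,
        demography=DemographyModel.model1(),
        dfe=DFEModel(),
        track_noncoding=False,
    )
    base.update(kw)
    return SimulationConfig(**base)


# --------------------------- basic invariants ---------------------------- #
def test_identical_seed_gives_identical_sample():
    a = simulate(_cfg())
    b = simulate(_cfg())
    np.testing.assert_array_equal(a.haplotypes, b.haplotypes)
    pd.testing.assert_frame_equal(a.sites, b.sites)
    c = simulate(_cfg(seed=6))
    assert not a.sites.equals(c.sites)


def test_sample_is_segregating_sorted_binary(small_dfe_sample):
    s = small_dfe_sample
    H = s.haplotypes
    assert set(np.unique(H)) <= {0, 1}
    counts = H.sum(axis=0)
    assert ((counts > 0) & (counts < H.shape[0])).all()
    pos = s.sites["position"].to_numpy()
    assert (np.diff(pos) > 0).all()
    np.testing.assert_array_equal(counts, s.sites["derived_count"].to_numpy())
    assert H.shape[0] == 100  # 50 diploids


def test_population_sizes_follow_demography():
    cfg = _cfg(length=50_000, seed=9)
    sim = ForwardSimulator(cfg)
    sim.initialize()
    expected = sim.demog.sizes["pop0"]
    for _ in range(3):
        sim.step()
        assert sim.pops["pop0"].shape[0] == 2 * expected[sim.generation]


def test_mutations_respect_genome_annotation(small_neutral_sample):
    """NS and S only inside exons; noncoding only outside."""
    s = small_neutral_sample
    g = s.config.resolved_genome()
    kinds = g.classify(s.sites["position"].to_numpy())
    ann = s.sites["annotation"].to_numpy()
    assert (kinds[ann == "NS"] == "exon").all()
    assert (kinds[ann == "S"] == "exon").all()
    assert (kinds[ann == "NC"] != "exon").all()


def test_selection_coefficients_only_on_ns(small_dfe_sample):
    sites = small_dfe_sample.sites
    assert (sites.loc[sites["annotation"] == "NS", "s"] < 0).all()
    assert (sites.loc[sites["annotation"] != "NS", "s"] == 0).all()


def test_exonic_ns_to_s_input_ratio():
    """Mutation-class assignment reproduces the 2.31:1 exonic NS:S ratio."""
    cfg = _cfg(seed=21)
    sim = ForwardSimulator(cfg)
    rng_positions = np.random.default_rng(0)
    exons = cfg.resolved_genome().exons
    # draw 1e5 positions uniformly over exonic bases
    lens = exons[:, 1] - exons[:, 0]
    cum = np.concatenate([[0], np.cumsum(lens)])
    u = rng_positions.integers(0, cum[-1], size=100_000)
    iv = np.searchsorted(cum, u, side="right") - 1
    pos = exons[iv, 0] + (u - cum[iv])
    ann, s, h = sim.annotate_mutation_positions(pos)
    n_ns = int((ann == 0).sum())
    n_s = int((ann == 1).sum())
    ratio = n_ns / n_s
    p = 2.31 / 3.31
    se = np.sqrt(p * (1 - p) / 100_000)
    assert abs(n_ns / 100_000 - p) < 4 * se
    assert ratio == pytest.approx(2.31, rel=0.05)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        _cfg(rescale_factor=0.5)
    with pytest.raises(ValueError):
        _cfg(initialization="magic")
    with pytest.raises(ValueError):
        simulate(_cfg(rescale_factor=20_000))  # N would drop below 2


# ------------------------ neutral oracle checks -------------------------- #
def test_neutral_sfs_singleton_doubleton_ratio():
    """Forward-only run (empty start, 10N burn) reproduces the neutral SFS
    expectation xi_i ~ 1/i: singletons are twice as common as doubletons."""
    counts = {1: 0, 2: 0}
    total = 0
    for seed in (31, 32):
        cfg = SimulationConfig(
            length=150_000,
            r=1e-8,
            rescale_factor=20,
            seed=seed,
            demography=DemographyModel.model1(),
            dfe=DFEModel.neutral(),
            track_noncoding=True,
            initialization="empty",
        )
        s = simulate(cfg)
        vc = s.sites["derived_count"].value_counts()
        counts[1] += int(vc.get(1, 0))
        counts[2] += int(vc.get(2, 0))
        total += s.n_sites
    ratio = counts[1] / counts[2]
    # Poisson sampling error on the ratio
    se = ratio * np.sqrt(1 / counts[1] + 1 / counts[2])
    assert abs(ratio - 2.0) < 3 * se
    # and the coalescent oracle at the same scaled parameters agrees
    ts = msprime.sim_ancestry(
        samples=50, population_size=500, sequence_length=150_000 * 2,
        recombination_rate=2e-7, discrete_genome=True, random_seed=1,
    )
    ts = msprime.sim_mutations(ts, rate=3e-7, random_seed=2,
                               model=msprime.BinaryMutationModel())
    G = ts.genotype_matrix()
    cnt = (G != 0).sum(axis=1)
    oracle = (cnt == 1).sum() / (cnt == 2).sum()
    assert abs(oracle - 2.0) < 3 * se + 0.4


def test_neutral_fixation_probability_matches_initial_frequency():
    """A neutral allele at frequency p fixes with probability p (tiny N)."""
    n_fix = 0
    n_rep = 400
    N = 10
    for rep in range(n_rep):
        cfg = SimulationConfig(
            length=1000, mu=0.0, r=0.0, seed=1000 + rep,
            demography=DemographyModel.constant(N),
            dfe=DFEModel.neutral(), initialization="empty",
            burn_in_factor=50.0,  # 500 generations >> absorption time
        )
        sim = ForwardSimulator(cfg)
        sim.initialize()
        # inject one neutral site at frequency 0.3
        sim.positions = np.array([500], dtype=np.int64)
        sim.ann = np.array([1], dtype=np.int8)
        sim.s_unscaled = np.array([0.0])
        sim.h = np.array([0.5])
        sim.origin = np.array([0], dtype=np.int32)
        sim._pos_set = {500}
        H = np.zeros((2 * N, 1), dtype=np.uint8)
        H[: int(0.3 * 2 * N), 0] = 1
        sim.pops["pop0"] = H
        sim.config.purge_interval = 0  # keep the column observable
        absorbed = False
        while sim.generation < sim.demog.T:
            sim.step()
            c = int(sim.pops["pop0"][:, 0].sum())
            if c in (0, 2 * N):
                absorbed = True
                n_fix += c == 2 * N
                break
        assert absorbed
    p_hat = n_fix / n_rep
    se = np.sqrt(0.3 * 0.7 / n_rep)
    assert abs(p_hat - 0.3) < 3 * se


def test_heterozygosity_near_four_N_mu(small_neutral_sample):
    """Pairwise diversity per bp within a loose factor of theta = 4*N*mu."""
    s = small_neutral_sample
    n = s.haplotypes.shape[0]
    p = s.sites["derived_count"].to_numpy() / n
    pi = float(np.sum(2 * p * (1 - p) * n / (n - 1))) / s.config.length
    theta = 4 * 10_000 * 1.5e-8
    assert 0.5 * theta < pi < 1.7 * theta


def test_rescaling_invariance_of_diversity():
    """Scaled parameter sets (N/Q, Q*mu, Q*r) give compatible diversity."""
    sites = {}
    for Q in (10, 20):
        tot = 0
        for seed in (41, 42, 43):
            s = simulate(_cfg(length=150_000, rescale_factor=Q, seed=seed,
                              dfe=DFEModel.neutral(), track_noncoding=True))
            tot += s.n_sites
        sites[Q] = tot / 3
    assert 0.75 < sites[10] / sites[20] < 1.33


# ----------------------- selection summaries ----------------------------- #
def test_selection_by_frequency_trivial_cases():
    H = np.zeros((100, 1), dtype=np.uint8)
    H[:2, 0] = 1
    samp = make_sample(H, [10], ["NS"], s=[-0.01])
    tab = summarize_selection_by_frequency(samp)
    assert tab.values.tolist() == [[2, -0.01, 1]]
    neutral = make_sample(H, [10], ["S"])
    assert summarize_selection_by_frequency(neutral).empty


def test_rare_ns_variants_are_more_deleterious():
    """Mean |s| declines from singletons toward higher allele counts."""
    rows = []
    for seed in range(61, 69):
        s = simulate(_cfg(length=300_000, seed=seed))
        rows.append(s.sites[s.sites["annotation"] == "NS"])
    ns = pd.concat(rows)
    singles = ns.loc[ns["derived_count"] == 1, "s"]
    high = ns.loc[ns["derived_count"] >= 10, "s"]
    assert len(singles) > 30 and len(high) > 30
    assert singles.mean() < high.mean()  # more negative for singletons


def test_model2_samples_from_african_population():
    cfg = _cfg(length=100_000, demography=DemographyModel.model2(), seed=71)
    sim = ForwardSimulator(cfg)
    sim.run()
    assert set(sim.pops) == {"AF", "EU", "AS"}
    s = sim.sample()
    assert s.n == 50
    assert sim.demog.sample_population == "AF"
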
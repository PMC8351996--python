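"""Forward-in-time Wright-Fisher simulation with selection and recombination.

The engine simulates diploid individuals with discrete generations:

* **fitness** — multiplicative across sites; per-site genotype fitness is
  ``1``, ``1 + h*s``, ``1 + s`` for 0/1/2 copies of the derived allele.
  Parents are sampled with probability proportional to fitness.
* **recombination** — each gamete is a mosaic of its parent's two haplotypes
  with ``Poisson(r * L)`` crossovers placed uniformly.
* **mutation** — Poisson at rate ``mu`` per bp per gamete, infinite-sites at
  base-pair resolution (a second hit at an occupied position is re-drawn).
  Exonic mutations are nonsynonymous with probability 2.31/3.31 and draw a
  selection coefficient from the configured DFE; synonymous and noncoding
  mutations are neutral.
* **rescaling** — a factor ``Q`` divides population sizes and event times and
  multiplies ``mu``, ``r``, ``|s|``, growth and migration rates, preserving
  ``N*mu``, ``N*r`` and ``N*s``.  Scaled selection coefficients are clipped
  at -1 (lethal).

Two initialization modes are available.  ``"coalescent"`` (default) starts
the forward phase from a neutral mutation-drift equilibrium sample generated
by ``msprime`` at the root population size, followed by a short forward burn
(default ``2 * N_root`` generations) during which selection purges the
deleterious class toward selection-drift balance.  ``"empty"`` starts from a
mutation-free population and burns forward for ``10 * N_root`` generations,
the convention of running a constant population ten times its size in
generations before any demographic event.

Because synonymous and noncoding variants never affect fitness, restricting
mutation tracking to exons (``track_noncoding=False``) yields samples whose
exonic variation is identical in distribution to a full-genome run at a
fraction of the cost; analyses that only touch NS/S variants use this mode.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import msprime
import numpy as np
import pandas as pd

from .demography import CompiledDemography, DemographyModel
from .dfe import DFEModel, draw_selection_coefficients
from .genome import EXON, GenomeStructure, build_genome_structure


ANN_NS, ANN_S, ANN_NC = 0, 1, 2
ANN_LABELS = np.array(["NS", "S", "NC"])


@dataclass
class SimulationConfig:
    """Parameters of one forward simulation replicate.

    Defaults follow the study conditions: a ~5 Mb chromosome with gene
    structure, ``mu = 1.5e-8`` per bp per generation, uniform recombination,
    a gamma DFE for NS mutations at a 2.31:1 NS:S ratio, and a sample of 50
    diploids from the (African, for structured models) focal population.
    """

    length: int = 5_000_000
    mu: float = 1.5e-8
    r: float = 1e-8
    dfe: DFEModel = field(default_factory=DFEModel)
    demography: DemographyModel = field(default_factory=DemographyModel.model1)
    ns_to_s_ratio: float = 2.31
    rescale_factor: float = 1.0
    sample_size: int = 50
    seed: int = 1
    genome: GenomeStructure | None = None
    track_noncoding: bool = True
    initialization: str = "coalescent"
    burn_in_factor: float | None = None
    purge_interval: int = 5

    def __post_init__(self) -> None:
        if self.rescale_factor < 1:
            raise ValueError("rescale_factor must be >= 1")
        if self.mu < 0 or self.r < 0:
            raise ValueError("rates must be non-negative")
        if self.initialization not in ("coalescent", "empty"):
            raise ValueError("initialization must be 'coalescent' or 'empty'")
        if self.sample_size < 1:
            raise ValueError("sample_size must be >= 1")

    def resolved_genome(self) -> GenomeStructure:
        return self.genome or build_genome_structure(self.seed, self.length)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["demography"] = self.demography.model_id
        d["dfe"] = dataclasses.asdict(self.dfe)
        d.pop("genome")
        return d


@dataclass
class HaplotypeSample:
    """A phased sample of ``n`` diploids at segregating sites.

    ``haplotypes`` is a ``(2n, m)`` 0/1 matrix (1 = derived allele), columns
    sorted by position; ``sites`` carries per-site metadata (``position``,
    ``annotation`` in {NS, S, NC}, ``s``, ``h``, ``origin_generation``,
    ``derived_count``).
    """

    haplotypes: np.ndarray
    sites: pd.DataFrame
    chrom: str = "1"
    config: SimulationConfig | None = None

    def __post_init__(self) -> None:
        counts = self.haplotypes.sum(axis=0)
        if "derived_count" not in self.sites.columns:
            self.sites = self.sites.assign(derived_count=counts)

    @property
    def n(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def genotypes(self):
        """Collapse phased haplotypes into an unphased genotype matrix."""
        from .hr import GenotypeMatrix

        g = (self.haplotypes[0::2] + self.haplotypes[1::2]).astype(np.int8)
        return GenotypeMatrix(matrix=g, sites=self.sites.copy(), chrom=self.chrom)


class ForwardSimulator:
    """Stateful Wright-Fisher engine; :func:`simulate` is the one-shot API."""

    def __init__(self, config: SimulationConfig):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.Q = float(config.rescale_factor)
        self.genome = config.resolved_genome()
        self.mu_scaled = config.mu * self.Q
        self.r_scaled = config.r * self.Q
        # tracked intervals for mutation placement
        if config.track_noncoding:
            self.tracked = np.array([[0, self.genome.total_length]], dtype=np.int64)
        else:
            self.tracked = self.genome.exons
        self.tracked_cum = np.concatenate(
            [[0], np.cumsum(self.tracked[:, 1] - self.tracked[:, 0])]
        )
        self.tracked_length = int(self.tracked_cum[-1])
        # exon lookup for annotation assignment
        starts = np.asarray([s for s, _, _ in self.genome.elements], dtype=np.int64)
        kinds = np.asarray(
            [ANN_NC if k != EXON else ANN_NS for _, _, k in self.genome.elements],
            dtype=np.int8,
        )
        self._elem_starts, self._elem_is_exon = starts, kinds == ANN_NS
        self.p_ns = config.ns_to_s_ratio / (1.0 + config.ns_to_s_ratio)

        root_n = round(config.demography.root_size / self.Q)
        factor = config.burn_in_factor
        if factor is None:
            factor = 2.0 if config.initialization == "coalescent" else 10.0
        self.demog: CompiledDemography = config.demography.compile(
            Q=self.Q, burn_generations=int(round(factor * root_n))
        )
        self.root_n = root_n
        # site registry
        self.positions = np.empty(0, dtype=np.int64)
        self.ann = np.empty(0, dtype=np.int8)
        self.s_unscaled = np.empty(0, dtype=np.float64)
        self.h = np.empty(0, dtype=np.float64)
        self.origin = np.empty(0, dtype=np.int32)
        self._pos_set: set[int] = set()
        self.pops: dict[str, np.ndarray] = {}
        self.generation = 0
        self.fixed_count = 0
        # mutation-input tally by class (before any selection acts)
        self.mutation_input_counts = {"NS": 0, "S": 0, "NC": 0}

    # -------------------------------------------------------------- #
    @property
    def n_sites(self) -> int:
        return self.positions.shape[0]

    def _scaled_s(self, s: np.ndarray) -> np.ndarray:
        return np.clip(s * self.Q, -1.0, None)

    def _selection_arrays(self):
        s = self._scaled_s(self.s_unscaled)
        any_sel = bool((s < 0).any())
        with np.errstate(divide="ignore"):
            log_het = np.log1p(self.h * s).astype(np.float32)
            log_hom = np.log1p(s).astype(np.float32)
        # keep -inf (lethal genotypes) out of the matmul: 0 * -inf = nan
        np.maximum(log_het, np.float32(-700.0), out=log_het)
        np.maximum(log_hom, np.float32(-700.0), out=log_hom)
        # dosage @ log_het counts a homozygote as 2*log_het; the correction
        # coefficient fixes it to log_hom (zero at neutral sites)
        return any_sel, log_het, log_hom - 2.0 * log_het

    def annotate_mutation_positions(self, pos: np.ndarray):
        """Assign NS/S/NC classes and selection coefficients to mutation
        positions, exactly as the engine does for new mutations: exonic
        positions are NS with probability 2.31/3.31 (drawing ``s`` from the
        DFE) and S otherwise; intron/intergenic positions are noncoding."""
        idx = np.searchsorted(self._elem_starts, pos, side="right") - 1
        exonic = self._elem_is_exon[idx]
        ann = np.full(pos.shape, ANN_NC, dtype=np.int8)
        is_ns = exonic & (self.rng.random(pos.shape) < self.p_ns)
        ann[exonic] = ANN_S
        ann[is_ns] = ANN_NS
        s = np.zeros(pos.shape, dtype=np.float64)
        n_ns = int(is_ns.sum())
        if n_ns:
            s[is_ns] = draw_selection_coefficients(self.config.dfe, n_ns, self.rng)
        h = np.full(pos.shape, self.config.dfe.h, dtype=np.float64)
        self.mutation_input_counts["NS"] += int((ann == ANN_NS).sum())
        self.mutation_input_counts["S"] += int((ann == ANN_S).sum())
        self.mutation_input_counts["NC"] += int((ann == ANN_NC).sum())
        return ann, s, h

    # -------------------------------------------------------------- #
    def initialize(self) -> None:
        cfg = self.config
        root = self.demog.root
        if cfg.initialization == "empty":
            self.pops = {
                root: np.zeros((2 * self.demog.sizes[root][0], 0), dtype=np.uint8)
            }
            self.positions = np.empty(0, dtype=np.int64)
            return
        # neutral equilibrium from the coalescent at the root size
        anc_seed = int(self.rng.integers(1, 2**31 - 1))
        mut_seed = int(self.rng.integers(1, 2**31 - 1))
        n0 = self.demog.sizes[root][0]
        ts = msprime.sim_ancestry(
            samples=n0,
            population_size=n0,
            sequence_length=self.genome.total_length,
            recombination_rate=self.r_scaled,
            discrete_genome=True,
            random_seed=anc_seed,
        )
        breakpoints, rate_vals = [0.0], []
        for a, b in self.tracked:
            if a > breakpoints[-1]:
                rate_vals.append(0.0)
                breakpoints.append(float(a))
            rate_vals.append(self.mu_scaled)
            breakpoints.append(float(b))
        if breakpoints[-1] < self.genome.total_length:
            rate_vals.append(0.0)
            breakpoints.append(float(self.genome.total_length))
        rate_map = msprime.RateMap(position=breakpoints, rate=rate_vals)
        ts = msprime.sim_mutations(
            ts, rate=rate_map, model=msprime.BinaryMutationModel(), random_seed=mut_seed
        )
        if ts.num_sites:
            G = ts.genotype_matrix()  # sites x haplotypes
            pos = ts.sites_position.astype(np.int64)
            H = (G.T != 0).astype(np.uint8)
            counts = H.sum(axis=0)
            seg = (counts > 0) & (counts < H.shape[0])
            H, pos = H[:, seg], pos[seg]
        else:
            H = np.zeros((2 * n0, 0), dtype=np.uint8)
            pos = np.empty(0, dtype=np.int64)
        ann, s, h = self.annotate_mutation_positions(pos)
        self.positions = pos
        self.ann = ann
        self.s_unscaled = s
        self.h = h
        self.origin = np.zeros(pos.shape, dtype=np.int32)
        self._pos_set = set(int(p) for p in pos)
        self.pops = {root: np.ascontiguousarray(H)}

    # -------------------------------------------------------------- #
    def _fitness_weights(self, H: np.ndarray, any_sel, log_het, hom_corr
                         ) -> np.ndarray:
        n = H.shape[0] // 2
        if not any_sel or H.shape[1] == 0:
            return np.ones(n)
        # dense genotype dosage over all columns; neutral columns carry
        # zero log-fitness coefficients, so no column subsetting is needed
        G = H[0::2] + H[1::2]
        logw = (G @ log_het).astype(np.float64)
        logw += (G >> 1) @ hom_corr  # G >> 1 == 1 exactly at homozygotes
        logw -= logw.max()
        return np.exp(logw)

    def _make_gametes(self, Hp: np.ndarray, parents: np.ndarray, n_extra_cols: int):
        """Build one gamete per entry of ``parents`` (indices of diploids)."""
        rng = self.rng
        k = parents.shape[0]
        S = self.n_sites
        phase = rng.integers(0, 2, size=k)
        rows0 = 2 * parents + phase
        rows1 = 2 * parents + 1 - phase
        out = np.zeros((k, S + n_extra_cols), dtype=np.uint8)
        if S == 0:
            return out
        n_cross = rng.poisson(self.r_scaled * self.genome.total_length, size=k)
        pos = self.positions
        total_bps = int(n_cross.sum())
        bps_flat = rng.uniform(0, self.genome.total_length, size=total_bps)
        bp_off = np.zeros(k + 1, dtype=np.int64)
        np.cumsum(n_cross, out=bp_off[1:])
        out[:, :S] = Hp[rows0]
        one = np.flatnonzero(n_cross == 1)
        if one.size:
            bps = bps_flat[bp_off[one]]
            mask = pos[None, :] >= bps[:, None]
            out[one, :S] = np.where(mask, Hp[rows1[one]], Hp[rows0[one]])
        many = np.flatnonzero(n_cross >= 2)
        for g in many:
            bps = np.sort(bps_flat[bp_off[g] : bp_off[g + 1]])
            parity = np.searchsorted(bps, pos, side="right") % 2
            out[g, :S] = np.where(parity == 1, Hp[rows1[g], :S], Hp[rows0[g], :S])
        return out

    def step(self) -> None:
        """Advance all populations by one generation."""
        g_next = self.generation + 1
        demog = self.demog
        rng = self.rng
        any_sel, log_het, log_hom = self._selection_arrays()
        weights = {
            name: self._fitness_weights(H, any_sel, log_het, log_hom)
            for name, H in self.pops.items()
        }
        cum = {name: np.cumsum(w) for name, w in weights.items()}
        splits_now = {
            child[0]: (parent, child)
            for (g, parent, children, _surv) in demog.splits
            if g == g_next
            for child in children
        }
        # plan offspring: per destination pop, counts per source pop
        plans: dict[str, list[tuple[str, int]]] = {}
        for name, sizes in demog.sizes.items():
            n_new = int(sizes[g_next]) if g_next < len(sizes) else 0
            if n_new <= 0:
                continue
            if name in splits_now:
                plans[name] = [(splits_now[name][0], n_new)]
                continue
            if name not in self.pops:
                continue  # not yet founded
            rates = {
                src: arr[g_next]
                for (dest, src), arr in demog.migration.items()
                if dest == name and src in self.pops and arr[g_next] > 0
            }
            if rates:
                srcs = list(rates)
                p = np.array([rates[s] for s in srcs])
                home = 1.0 - p.sum()
                counts = rng.multinomial(n_new, np.append(p, max(home, 0.0)))
                plan = [(s, int(c)) for s, c in zip(srcs, counts[:-1]) if c > 0]
                if counts[-1] > 0:
                    plan.append((name, int(counts[-1])))
                plans[name] = plan
            else:
                plans[name] = [(name, n_new)]

        # mutation counts per destination
        exp_mut = self.mu_scaled * self.tracked_length
        new_pops: dict[str, np.ndarray] = {}
        n_mut_by_pop = {
            name: int(rng.poisson(exp_mut * 2 * sum(c for _, c in plan)))
            for name, plan in plans.items()
        }
        total_new = sum(n_mut_by_pop.values())
        for name, plan in plans.items():
            gametes = []
            for src, count in plan:
                w = weights[src]
                c = cum[src]
                par = np.searchsorted(c, rng.random(2 * count) * c[-1])
                par = np.minimum(par, len(w) - 1)
                gametes.append(self._make_gametes(self.pops[src], par, total_new))
            new_pops[name] = gametes[0] if len(gametes) == 1 else np.vstack(gametes)

        # place new mutations
        if total_new:
            S = self.n_sites
            new_pos = np.empty(total_new, dtype=np.int64)
            filled = 0
            while filled < total_new:
                need = total_new - filled
                u = rng.integers(0, self.tracked_length, size=need)
                iv = np.searchsorted(self.tracked_cum, u, side="right") - 1
                cand = self.tracked[iv, 0] + (u - self.tracked_cum[iv])
                for p in cand:
                    p = int(p)
                    if p not in self._pos_set:
                        self._pos_set.add(p)
                        new_pos[filled] = p
                        filled += 1
                        if filled == total_new:
                            break
            ann, s, h = self.annotate_mutation_positions(new_pos)
            self.positions = np.concatenate([self.positions, new_pos])
            self.ann = np.concatenate([self.ann, ann])
            self.s_unscaled = np.concatenate([self.s_unscaled, s])
            self.h = np.concatenate([self.h, h])
            self.origin = np.concatenate(
                [self.origin, np.full(total_new, g_next, dtype=np.int32)]
            )
            col = S
            for name in plans:
                k = n_mut_by_pop[name]
                if k:
                    rows = rng.integers(0, new_pops[name].shape[0], size=k)
                    new_pops[name][rows, np.arange(col, col + k)] = 1
                    col += k
        self.pops = new_pops
        self.generation = g_next
        if self.config.purge_interval and g_next % self.config.purge_interval == 0:
            self.purge()

    def purge(self) -> None:
        """Drop globally lost and globally fixed sites."""
        if self.n_sites == 0:
            return
        tot = np.zeros(self.n_sites, dtype=np.int64)
        denom = 0
        for H in self.pops.values():
            tot += H.sum(axis=0, dtype=np.int64)
            denom += H.shape[0]
        keep = (tot > 0) & (tot < denom)
        self.fixed_count += int((tot == denom).sum())
        if keep.all():
            return
        self.positions = self.positions[keep]
        self.ann = self.ann[keep]
        self.s_unscaled = self.s_unscaled[keep]
        self.h = self.h[keep]
        self.origin = self.origin[keep]
        self._pos_set = set(int(p) for p in self.positions)
        self.pops = {n: np.ascontiguousarray(H[:, keep]) for n, H in self.pops.items()}

    # -------------------------------------------------------------- #
    def run(self) -> None:
        self.initialize()
        while self.generation < self.demog.T:
            self.step()
        self.purge()

    def sample(self, n: int | None = None, population: str | None = None
               ) -> HaplotypeSample:
        """Draw ``n`` diploids from the focal population at the present."""
        n = n or self.config.sample_size
        population = population or self.demog.sample_population
        H = self.pops[population]
        n_avail = H.shape[0] // 2
        if n > n_avail:
            raise ValueError(f"cannot sample {n} diploids from {n_avail}")
        ind = np.sort(self.rng.choice(n_avail, size=n, replace=False))
        rows = np.empty(2 * n, dtype=np.int64)
        rows[0::2], rows[1::2] = 2 * ind, 2 * ind + 1
        Hs = H[rows]
        counts = Hs.sum(axis=0)
        seg = (counts > 0) & (counts < 2 * n)
        order = np.argsort(self.positions[seg], kind="stable")
        Hs = np.ascontiguousarray(Hs[:, seg][:, order])
        idx = np.flatnonzero(seg)[order]
        sites = pd.DataFrame(
            {
                "position": self.positions[idx],
                "annotation": ANN_LABELS[self.ann[idx]],
                "s": self.s_unscaled[idx],
                "h": self.h[idx],
                "origin_generation": self.origin[idx],
                "derived_count": Hs.sum(axis=0).astype(np.int64),
            }
        )
        return HaplotypeSample(
            haplotypes=Hs, sites=sites, chrom=f"sim_seed{self.config.seed}",
            config=self.config,
        )


def simulate(config: SimulationConfig) -> HaplotypeSample:
    """Run one forward replicate and return a sample of diploids."""
    sim = ForwardSimulator(config)
    sim.run()
    return sim.sample()


def summarize_selection_by_frequency(sample: HaplotypeSample) -> pd.DataFrame:
    """Mean selection coefficient of NS sites per derived allele count.

    Deleterious DFE runs show the attenuation of mean ``|s|`` with allele
    count: rare variants are the most deleterious, higher-frequency variants
    are nearly neutral.
    """
    ns = sample.sites[sample.sites["annotation"] == "NS"]
    if ns.empty:
        return pd.DataFrame(columns=["derived_count", "mean_s", "n_sites"])
    grouped = ns.groupby("derived_count")["s"].agg(["mean", "size"]).reset_index()
    grouped.columns = ["derived_count", "mean_s", "n_sites"]
    return grouped
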
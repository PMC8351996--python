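"""Demographic models for the forward simulator.

Three named models are provided:

* **Model 1** — a single panmictic population of 10,000 diploids.
* **Model 2** — the three-population out-of-Africa model of human demography
  estimated by Gravel et al. (2011): an ancestral African population of 7,310
  that expands to 14,474 at 5,920 generations ago, an out-of-Africa bottleneck
  population of 1,861 splitting off 2,040 generations ago, and a European /
  East-Asian split 920 generations ago with exponential growth, with symmetric
  migration between extant populations.  Parameter values are taken from
  Gravel et al. (2011), Table 2 (the model itself does not originate here).
* **Model 3** — Model 2 with all migration rates set to zero.

A :class:`DemographyModel` is a declarative event list; :meth:`compile`
resolves it (optionally rescaled by a factor ``Q``) into per-generation
population sizes, split events, and migration rates that the Wright-Fisher
engine consumes.  Rescaling divides population sizes and event times by
``Q`` and multiplies growth and migration rates by ``Q``, preserving the
population-scaled parameters ``N*m`` and ``N*g``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class SizeChange:
    """At ``time_ago`` generations before present, ``population`` assumes
    ``size`` diploids and thereafter grows exponentially at ``growth_rate``
    per generation (toward the present)."""

    time_ago: float
    population: str
    size: float
    growth_rate: float = 0.0


@dataclass(frozen=True)
class PopulationSplit:
    """At ``time_ago``, ``children`` populations are founded by parents drawn
    from ``parent``.  Each child is ``(name, size, growth_rate)``.  If
    ``parent_survives`` is false the parent ceases to exist."""

    time_ago: float
    parent: str
    children: tuple
    parent_survives: bool = True


@dataclass(frozen=True)
class MigrationChange:
    """From ``time_ago`` onward, a fraction ``rate`` of offspring born into
    ``dest`` each generation have parents drawn from ``source``."""

    time_ago: float
    dest: str
    source: str
    rate: float


@dataclass(frozen=True)
class DemographyModel:
    model_id: str
    root_population: str
    root_size: float
    events: tuple = ()
    sample_population: str = ""

    @property
    def structured_duration(self) -> float:
        """Generations from the earliest demographic event to the present."""
        return max((e.time_ago for e in self.events), default=0.0)

    # ------------------------------------------------------------------ #
    @classmethod
    def model1(cls, size: float = 10_000.0) -> "DemographyModel":
        """Constant-size panmictic population (default 10,000 diploids)."""
        return cls(
            model_id="model1",
            root_population="pop0",
            root_size=size,
            events=(),
            sample_population="pop0",
        )

    @classmethod
    def constant(cls, size: float) -> "DemographyModel":
        return cls.model1(size)

    @classmethod
    def model2(cls) -> "DemographyModel":
        """Gravel et al. (2011) out-of-Africa model with migration."""
        m_af_b = 15e-5
        m_af_eu = 2.5e-5
        m_af_as = 0.78e-5
        m_eu_as = 3.11e-5
        events = (
            SizeChange(5920, "AF", 14474),
            PopulationSplit(2040, "AF", (("B", 1861, 0.0),), parent_survives=True),
            MigrationChange(2040, "AF", "B", m_af_b),
            MigrationChange(2040, "B", "AF", m_af_b),
            PopulationSplit(
                920, "B", (("EU", 1032, 0.0038), ("AS", 554, 0.0048)),
                parent_survives=False,
            ),
            MigrationChange(920, "AF", "B", 0.0),
            MigrationChange(920, "B", "AF", 0.0),
            MigrationChange(920, "AF", "EU", m_af_eu),
            MigrationChange(920, "EU", "AF", m_af_eu),
            MigrationChange(920, "AF", "AS", m_af_as),
            MigrationChange(920, "AS", "AF", m_af_as),
            MigrationChange(920, "EU", "AS", m_eu_as),
            MigrationChange(920, "AS", "EU", m_eu_as),
        )
        return cls(
            model_id="model2",
            root_population="AF",
            root_size=7310,
            events=events,
            sample_population="AF",
        )

    @classmethod
    def model3(cls) -> "DemographyModel":
        """Model 2 without migration."""
        m2 = cls.model2()
        events = tuple(e for e in m2.events if not isinstance(e, MigrationChange))
        return cls(
            model_id="model3",
            root_population="AF",
            root_size=7310,
            events=events,
            sample_population="AF",
        )

    @classmethod
    def by_id(cls, model_id: int | str) -> "DemographyModel":
        key = str(model_id).lstrip("model")
        return {"1": cls.model1, "2": cls.model2, "3": cls.model3}[key]()

    # ------------------------------------------------------------------ #
    def compile(self, Q: float = 1.0, burn_generations: int | None = None
                ) -> "CompiledDemography":
        """Resolve the model into a generation-indexed plan.

        ``burn_generations`` is the number of forward generations (already on
        the rescaled clock) run at the root size before the first demographic
        event; default ``10 * root_size / Q``.
        """
        if Q < 1:
            raise ValueError("rescaling factor Q must be >= 1")
        root_n = round(self.root_size / Q)
        if root_n < 2:
            raise ValueError("rescaling factor Q leaves fewer than 2 diploids")
        if burn_generations is None:
            burn_generations = 10 * root_n
        duration = math.ceil(self.structured_duration / Q)
        T = int(burn_generations) + duration
        names = {self.root_population}
        for e in self.events:
            if isinstance(e, PopulationSplit):
                names.update(c[0] for c in e.children)
        names = sorted(names)

        sizes = {name: np.zeros(T + 1, dtype=np.int64) for name in names}
        growth: dict[str, list] = {name: [] for name in names}

        def gen_of(time_ago: float) -> int:
            return T - int(round(time_ago / Q))

        # piecewise size trajectories: (start_gen, size, growth_rate) per pop
        traj: dict[str, list] = {name: [] for name in names}
        traj[self.root_population].append((0, root_n, 0.0))
        splits: list[tuple[int, str, tuple, bool]] = []
        deaths: dict[str, int] = {}
        for e in self.events:
            g = gen_of(e.time_ago)
            if isinstance(e, SizeChange):
                traj[e.population].append((g, max(2, round(e.size / Q)), e.growth_rate * Q))
            elif isinstance(e, PopulationSplit):
                kids = tuple(
                    (name, max(2, round(size / Q)), gr * Q) for name, size, gr in e.children
                )
                splits.append((g, e.parent, kids, e.parent_survives))
                for name, size, gr in kids:
                    traj[name].append((g, size, gr))
                if not e.parent_survives:
                    deaths[e.parent] = g

        for name in names:
            segs = sorted(traj[name])
            if not segs:
                continue
            for i, (g0, n0, gr) in enumerate(segs):
                g1 = segs[i + 1][0] if i + 1 < len(segs) else T
                t = np.arange(g0, g1 + 1)
                sizes[name][g0 : g1 + 1] = np.maximum(
                    2, np.round(n0 * np.exp(gr * (t - g0)))
                ).astype(np.int64)
            # a population that splits into daughters leaves the model at the
            # split generation: its last reproducing cohort is g_death - 1
            if name in deaths:
                sizes[name][deaths[name] :] = 0
        # migration rate arrays
        mig: dict[tuple[str, str], np.ndarray] = {}
        mig_events = sorted(
            (e for e in self.events if isinstance(e, MigrationChange)),
            key=lambda e: -e.time_ago,
        )
        for e in mig_events:
            key = (e.dest, e.source)
            if key not in mig:
                mig[key] = np.zeros(T + 1, dtype=np.float64)
            mig[key][gen_of(e.time_ago) :] = min(1.0, e.rate * Q)
        mig = {k: v for k, v in mig.items() if v.any()}

        return CompiledDemography(
            T=T,
            root=self.root_population,
            sample_population=self.sample_population or self.root_population,
            sizes=sizes,
            splits=sorted(splits),
            migration=mig,
            burn_generations=int(burn_generations),
        )


@dataclass
class CompiledDemography:
    """Generation-indexed demographic plan (rescaled clock).

    ``sizes[name][g]`` is the diploid size of ``name`` at generation ``g``
    (0 = founding generation, ``T`` = present; 0 means not extant).
    """

    T: int
    root: str
    sample_population: str
    sizes: dict
    splits: list
    migration: dict = field(default_factory=dict)
    burn_generations: int = 0

    def alive_at(self, g: int) -> list:
        return [name for name, arr in self.sizes.items() if arr[g] > 0]
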
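"""Demographic model catalogue: piecewise-constant single-population
histories and two-population split models with asymmetric migration.

All models are described forward in time.  Population sizes are numbers of
diploids; times are generations.  Migration rates are the fraction of the
*receiving* population that are new migrants each generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np


@dataclass
class ScalingContext:
    """Physical scaling constants anchoring scaled parameters.

    theta = 4 * N_ANC * mu * L links the composite-likelihood scale to an
    ancestral diploid size.
    """

    mu: float = 2.77e-8          # per-bp per-generation mutation rate
    L: float = 1.0               # callable sequence length, bp
    generation_time: float = 25.9  # years per generation

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.L <= 0 or self.generation_time <= 0:
            raise ValueError("scaling constants must be positive")

    def n_anc_from_theta(self, theta: float) -> float:
        if theta <= 0:
            raise ValueError("theta must be positive")
        return theta / (4.0 * self.mu * self.L)


@dataclass
class EpochModel:
    """Piecewise-constant size history.

    ``sizes`` are ordered past -> present; ``durations`` (one fewer) give
    the length in generations of every epoch after the first.  The first
    (ancestral) epoch extends indefinitely into the past, the last epoch
    ends at the present.
    """

    sizes: list[float]
    durations: list[float] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.durations) != len(self.sizes) - 1:
            raise ValueError("need exactly len(sizes)-1 durations")
        if any(s <= 0 for s in self.sizes):
            raise ValueError("population sizes must be positive")
        if any(t < 0 for t in self.durations):
            raise ValueError("durations must be non-negative")

    # -- constructors matching the catalogue names ----------------------

    @classmethod
    def one_epoch(cls, n_anc: float) -> "EpochModel":
        return cls([n_anc], [], name="1Epoch")

    @classmethod
    def two_epoch(cls, n_anc: float, n_cur: float, t: float) -> "EpochModel":
        return cls([n_anc, n_cur], [t], name="2Epoch")

    @classmethod
    def three_epoch(
        cls, n_anc: float, n_bot: float, n_cur: float, t_bot: float, t_cur: float
    ) -> "EpochModel":
        return cls([n_anc, n_bot, n_cur], [t_bot, t_cur], name="3Epoch")

    @classmethod
    def four_epoch(
        cls,
        n_anc: float,
        n_bot: float,
        n_rec: float,
        n_cur: float,
        t_bot: float,
        t_rec: float,
        t_cur: float,
    ) -> "EpochModel":
        return cls([n_anc, n_bot, n_rec, n_cur], [t_bot, t_rec, t_cur], name="4Epoch")

    # -- views -----------------------------------------------------------

    @property
    def n_epochs(self) -> int:
        return len(self.sizes)

    def change_times(self) -> list[float]:
        """Generations before present of each size change (past -> present)."""
        out = []
        total = sum(self.durations)
        acc = 0.0
        for d in self.durations:
            out.append(total - acc)
            acc += d
        return out

    def size_at(self, t_before_present: float) -> float:
        """Diploid size t generations before the present."""
        t_edges = self.change_times()[::-1]  # ascending times before present
        for size, edge in zip(self.sizes[::-1], t_edges + [np.inf]):
            if t_before_present < edge:
                return size
        return self.sizes[0]

    def to_msprime(self, name: str = "pop") -> msprime.Demography:
        dem = msprime.Demography()
        dem.add_population(name=name, initial_size=self.sizes[-1])
        t = 0.0
        for size, dur in zip(self.sizes[-2::-1], self.durations[::-1]):
            t += dur
            dem.add_population_parameters_change(
                time=t, initial_size=size, population=name
            )
        return dem


#: two-population catalogue names
TWO_POP_MODELS = (
    "Split-NoMigration",
    "Split-SymmetricMigration",
    "Split-AsymmetricMigration",
    "Split-AsymmetricMigration-ENPChangeTw2",
    "AncestralSizeChange-Split-AsymmetricMigration",
    "AncestralSizeChange-Split-Isolation-AsymmetricMigration",
    "AncestralSizeChange-Split-AsymmetricMigration-GOCChange",
)


@dataclass
class TwoPopModel:
    """Ancestral (optionally two-epoch) population splitting into two demes.

    Forward in time: the ancestral population of size ``n_anc`` changes to
    ``n_anc2`` lasting ``t_a`` generations (if set), then splits ``t_split``
    generations before the present into demes 1 and 2 with asymmetric
    per-generation migrant fractions.  Optional recent events model a
    whaling-era size change in deme 1 (``n1_recent`` at ``t_w``), an
    isolation window (migration only during the last ``t_contact``
    generations), or a size change in deme 2 (``n2_recent`` at
    ``t_contact``).
    """

    n_anc: float
    n1: float
    n2: float
    t_split: float
    m_1_to_2: float = 0.0   # fraction of deme 2 that are new migrants from deme 1
    m_2_to_1: float = 0.0
    n_anc2: float | None = None
    t_a: float = 0.0
    n1_recent: float | None = None
    t_w: float = 0.0
    isolation: bool = False
    t_contact: float = 0.0
    n2_recent: float | None = None
    ghost_size: float | None = None   # diploids (paper fixed 30,000 haploids)
    ghost_t_split: float = 0.0
    pop_names: tuple[str, str] = ("ENP", "GOC")
    name: str = ""

    def __post_init__(self) -> None:
        for v in (self.n_anc, self.n1, self.n2):
            if v <= 0:
                raise ValueError("population sizes must be positive")
        for m in (self.m_1_to_2, self.m_2_to_1):
            if not 0.0 <= m < 1.0:
                raise ValueError("migrant fractions must be in [0, 1)")
        if self.t_split < 0 or self.t_a < 0:
            raise ValueError("times must be non-negative")

    def to_msprime(self) -> msprime.Demography:
        """msprime demography (backwards-time events mirror the forward story).

        Forward migration "fraction m of deme j are migrants from deme i"
        corresponds to backwards lineage movement j -> i at rate m.
        """
        p1, p2 = self.pop_names
        dem = msprime.Demography()
        dem.add_population(
            name=p1,
            initial_size=self.n1_recent if self.n1_recent is not None else self.n1,
        )
        dem.add_population(name=p2, initial_size=self.n2_recent
                           if self.n2_recent is not None else self.n2)
        anc_size = self.n_anc2 if self.n_anc2 is not None else self.n_anc
        dem.add_population(name="ANC", initial_size=anc_size)
        if not self.isolation:
            if self.m_1_to_2 > 0:
                dem.set_migration_rate(source=p2, dest=p1, rate=self.m_1_to_2)
            if self.m_2_to_1 > 0:
                dem.set_migration_rate(source=p1, dest=p2, rate=self.m_2_to_1)
        events = []
        if self.n1_recent is not None and self.t_w > 0:
            events.append((self.t_w, "size", p1, self.n1))
        if self.n2_recent is not None and self.t_contact > 0:
            events.append((self.t_contact, "size", p2, self.n2))
        if self.isolation and self.t_contact > 0:
            events.append((self.t_contact, "stop_migration", None, None))
        events.append((self.t_split, "split", None, None))
        if self.n_anc2 is not None and self.t_a > 0:
            events.append((self.t_split + self.t_a, "size", "ANC", self.n_anc))
        if self.ghost_size is not None:
            dem.add_population(name="GHOST", initial_size=self.ghost_size)
            events.append((self.ghost_t_split, "ghost_split", None, None))
        for t, kind, pop, size in sorted(events, key=lambda e: e[0]):
            if kind == "size":
                dem.add_population_parameters_change(
                    time=t, initial_size=size, population=pop
                )
            elif kind == "stop_migration":
                dem.add_migration_rate_change(time=t, rate=0.0)
            elif kind == "split":
                dem.add_population_split(
                    time=t, derived=[p1, p2], ancestral="ANC"
                )
        dem.sort_events()
        return dem


def effective_migrants(m: float, n_receiving: float) -> float:
    """Migrants per generation: migrant fraction x receiving diploid size."""
    if not 0.0 <= m < 1.0:
        raise ValueError("migrant fraction must be in [0, 1)")
    if n_receiving <= 0:
        raise ValueError("receiving population size must be positive")
    return m * n_receiving


def fin_whale_enp_3epoch() -> EpochModel:
    """Best-fit single-population history of the large Pacific deme:
    expansion 16,479 -> 23,913 diploids 4,424 generations ago followed by a
    whaling crash to 305 diploids two generations ago."""
    return EpochModel.three_epoch(16479, 23913, 305, 4424 - 2, 2)


def fin_whale_two_pop(migration: bool = True) -> TwoPopModel:
    """Best-fit two-deme history: ancestral expansion ~16,000 -> ~25,000
    diploids 4,322 generations ago, split 616 generations ago into a large
    (17,386) and a small (114) deme with asymmetric migration."""
    return TwoPopModel(
        n_anc=16000,
        n_anc2=25000,
        t_a=4322 - 616,
        t_split=616,
        n1=17386,
        n2=114,
        m_1_to_2=3.42e-3 if migration else 0.0,
        m_2_to_1=9.24e-5 if migration else 0.0,
        name="AncestralSizeChange-Split-AsymmetricMigration"
        if migration
        else "AncestralSizeChange-Split-NoMigration",
    )
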
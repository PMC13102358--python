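"""Two-population piecewise demographic histories.

A :class:`DemographicModel` describes a pair of populations with two epochs
before their split and three after it, per-epoch directional migration, and
constant or exponential size change within each epoch.  Six representative
fitted models (three per population pair, with divergence at roughly 150, 600
and 800 kya at a 5-year generation time) ship as fixtures.  Models convert to
an :class:`msprime.Demography` for coalescent simulation and round-trip
through a JSON schema.

Conventions
-----------
* Epoch lists are stored in forward-time order: index 0 is the oldest epoch.
* Migration rates are forward-time "sink from source" probabilities, keyed
  ``(source, dest)``: the probability that a lineage in ``dest`` descends
  from a lineage in ``source`` in the previous generation.  This equals the
  backward-time rate at which lineages in ``dest`` jump to ``source``, which
  is the msprime matrix convention.
* Times are generations before present unless explicitly converted.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import msprime

PAIRS = ("ILa-ELw", "ILa-ELs")


def generations_to_years(g: float, generation_time: float = 5.0) -> float:
    """Convert a duration in generations to years.

    >>> generations_to_years(30_000)
    150000.0
    """
    if g < 0:
        raise ValueError(f"generations must be non-negative, got {g}")
    if generation_time <= 0:
        raise ValueError("generation_time must be positive")
    return g * generation_time


@dataclass
class Epoch:
    """One constant- or exponential-size time slice of the history.

    ``size_start`` is the diploid effective size at the (forward-time) start
    of the epoch, ``size_end`` at its end; both are keyed by population name.
    ``migration[(source, dest)]`` is the forward-time directional rate.
    """

    duration: float
    size_start: dict[str, float]
    size_end: dict[str, float]
    change_mode: str = "constant"
    migration: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("epoch duration must be > 0")
        if self.change_mode not in ("constant", "exponential"):
            raise ValueError(f"unknown change_mode {self.change_mode!r}")
        if set(self.size_start) != set(self.size_end):
            raise ValueError("size_start and size_end must cover the same populations")
        for pops in (self.size_start, self.size_end):
            for name, n in pops.items():
                if n <= 0:
                    raise ValueError(f"effective size of {name} must be > 0")
        if self.change_mode == "constant":
            for name in self.size_start:
                if self.size_start[name] != self.size_end[name]:
                    raise ValueError(
                        "constant epochs require size_start == size_end "
                        f"(population {name})"
                    )
        for key, m in self.migration.items():
            if not (0 <= m < 1):
                raise ValueError(f"migration rate {key} must be in [0, 1), got {m}")


@dataclass
class DemographicModel:
    """Piecewise two-population history: 2 ancestral + 3 post-split epochs."""

    populations: tuple[str, str]
    ancestral_epochs: list[Epoch]
    post_split_epochs: list[Epoch]
    divergence_time: float
    mutation_rate: float = 6e-9
    generation_time: float = 5.0
    name: str = ""

    #: population name used for the common ancestor
    ANCESTRAL = "ANC"

    def __post_init__(self) -> None:
        if len(self.ancestral_epochs) != 2:
            raise ValueError("expected exactly 2 ancestral epochs")
        if len(self.post_split_epochs) != 3:
            raise ValueError("expected exactly 3 post-split epochs")
        if self.divergence_time < 20_000:
            raise ValueError("divergence_time must be at least 20,000 generations")
        total = sum(e.duration for e in self.post_split_epochs)
        if not math.isclose(total, self.divergence_time, rel_tol=1e-9):
            raise ValueError(
                f"post-split epoch durations sum to {total}, expected "
                f"divergence_time {self.divergence_time}"
            )
        for e in self.ancestral_epochs:
            if e.migration:
                raise ValueError("ancestral epochs cannot have migration")
            if set(e.size_start) != {self.ANCESTRAL}:
                raise ValueError("ancestral epochs must size the ANC population only")
        for e in self.post_split_epochs:
            if set(e.size_start) != set(self.populations):
                raise ValueError("post-split epochs must size both populations")

    # ------------------------------------------------------------------
    # epoch boundary times (generations before present)
    # ------------------------------------------------------------------
    def epoch_start_times(self) -> list[float]:
        """Backward-time start (younger boundary) of each post-split epoch.

        Returned in forward-time order, i.e. the first entry belongs to the
        oldest epoch.  The last entry is always 0.
        """
        times = []
        t = self.divergence_time
        for e in self.post_split_epochs:
            t -= e.duration
            times.append(max(t, 0.0))
        times[-1] = 0.0
        return times

    # ------------------------------------------------------------------
    # serialization
    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        def epoch_dict(e: Epoch) -> dict:
            return {
                "duration": e.duration,
                "size_start": dict(e.size_start),
                "size_end": dict(e.size_end),
                "change_mode": e.change_mode,
                "migration": [
                    {"source": s, "dest": d, "rate": r}
                    for (s, d), r in sorted(e.migration.items())
                ],
            }

        return {
            "name": self.name,
            "populations": list(self.populations),
            "divergence_time": self.divergence_time,
            "mutation_rate": self.mutation_rate,
            "generation_time": self.generation_time,
            "ancestral_epochs": [epoch_dict(e) for e in self.ancestral_epochs],
            "post_split_epochs": [epoch_dict(e) for e in self.post_split_epochs],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DemographicModel":
        def epoch(e: Mapping) -> Epoch:
            return Epoch(
                duration=e["duration"],
                size_start=dict(e["size_start"]),
                size_end=dict(e["size_end"]),
                change_mode=e["change_mode"],
                migration={
                    (m["source"], m["dest"]): m["rate"] for m in e["migration"]
                },
            )

        return cls(
            populations=tuple(d["populations"]),
            ancestral_epochs=[epoch(e) for e in d["ancestral_epochs"]],
            post_split_epochs=[epoch(e) for e in d["post_split_epochs"]],
            divergence_time=d["divergence_time"],
            mutation_rate=d.get("mutation_rate", 6e-9),
            generation_time=d.get("generation_time", 5.0),
            name=d.get("name", ""),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "DemographicModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ----------------------------------------------------------------------
# simulator configuration
# ----------------------------------------------------------------------

def to_simulator_config(model: DemographicModel) -> dict:
    """Expand a model into a backward-time event list.

    The returned dict has ``populations`` (name -> present-day size and
    growth rate) and ``events``, a time-sorted list of size-change,
    migration-change and split events.  Exponential epochs become growth-rate
    specifications.  :func:`from_simulator_config` inverts the expansion.
    """
    p1, p2 = model.populations
    starts = model.epoch_start_times()
    if any(b > a for a, b in zip(starts, starts[1:])):
        raise ValueError("non-monotone epoch times")

    def growth(e: Epoch, pop: str) -> float:
        # backward-time growth rate g: N(t) = size_end * exp(-g * (t - t_young))
        if e.change_mode == "constant":
            return 0.0
        return math.log(e.size_end[pop] / e.size_start[pop]) / e.duration

    events: list[dict] = []
    recent = model.post_split_epochs[-1]
    populations = {
        pop: {"initial_size": recent.size_end[pop], "growth_rate": growth(recent, pop)}
        for pop in (p1, p2)
    }
    populations[model.ANCESTRAL] = {
        "initial_size": model.ancestral_epochs[-1].size_end[model.ANCESTRAL],
        "growth_rate": 0.0,
    }
    events.append(
        {
            "kind": "migration",
            "time": 0.0,
            "rates": [
                {"source": s, "dest": d, "rate": r}
                for (s, d), r in sorted(recent.migration.items())
            ],
        }
    )
    # older post-split epochs, walking backwards in time
    for e, t_young in zip(model.post_split_epochs[-2::-1], starts[-2::-1]):
        for pop in (p1, p2):
            events.append(
                {
                    "kind": "size",
                    "time": t_young,
                    "population": pop,
                    "size": e.size_end[pop],
                    "growth_rate": growth(e, pop),
                }
            )
        events.append(
            {
                "kind": "migration",
                "time": t_young,
                "rates": [
                    {"source": s, "dest": d, "rate": r}
                    for (s, d), r in sorted(e.migration.items())
                ],
            }
        )
    events.append(
        {
            "kind": "split",
            "time": model.divergence_time,
            "derived": [p1, p2],
            "ancestral": model.ANCESTRAL,
        }
    )
    anc_recent, anc_old = model.ancestral_epochs[-1], model.ancestral_epochs[0]
    events.append(
        {
            "kind": "size",
            "time": model.divergence_time + anc_recent.duration,
            "population": model.ANCESTRAL,
            "size": anc_old.size_end[model.ANCESTRAL],
            "growth_rate": growth(anc_old, model.ANCESTRAL),
        }
    )
    events.sort(key=lambda ev: ev["time"])
    return {
        "populations": populations,
        "events": events,
        "meta": {
            "name": model.name,
            "pair": [p1, p2],
            "mutation_rate": model.mutation_rate,
            "generation_time": model.generation_time,
            "divergence_time": model.divergence_time,
            "epoch_durations": {
                "ancestral": [e.duration for e in model.ancestral_epochs],
                "post_split": [e.duration for e in model.post_split_epochs],
            },
            "change_modes": {
                "ancestral": [e.change_mode for e in model.ancestral_epochs],
                "post_split": [e.change_mode for e in model.post_split_epochs],
            },
        },
    }


def from_simulator_config(config: Mapping) -> DemographicModel:
    """Inverse of :func:`to_simulator_config` (exact round trip)."""
    meta = config["meta"]
    p1, p2 = meta["pair"]
    div = meta["divergence_time"]
    durations = meta["epoch_durations"]["post_split"]
    modes = meta["change_modes"]["post_split"]
    anc_durations = meta["epoch_durations"]["ancestral"]
    anc_modes = meta["change_modes"]["ancestral"]

    sizes: dict[float, dict[str, tuple[float, float]]] = {}
    migrations: dict[float, dict[tuple[str, str], float]] = {}
    for ev in config["events"]:
        if ev["kind"] == "size":
            sizes.setdefault(ev["time"], {})[ev["population"]] = (
                ev["size"],
                ev["growth_rate"],
            )
        elif ev["kind"] == "migration":
            migrations[ev["time"]] = {
                (m["source"], m["dest"]): m["rate"] for m in ev["rates"] if m["rate"]
            }
    for pop, cfg in config["populations"].items():
        sizes.setdefault(0.0, {})[pop] = (cfg["initial_size"], cfg["growth_rate"])

    def epoch_at(t_young: float, duration: float, mode: str, pops: tuple[str, ...]) -> Epoch:
        size_start, size_end = {}, {}
        for pop in pops:
            size, g = sizes[t_young][pop]
            size_end[pop] = size
            size_start[pop] = size if g == 0 else size / math.exp(g * duration)
            if mode == "constant":
                size_start[pop] = size_end[pop]
        return Epoch(
            duration=duration,
            size_start=size_start,
            size_end=size_end,
            change_mode=mode,
            migration=migrations.get(t_young, {}),
        )

    starts = []
    t = div
    for d in durations:
        t -= d
        starts.append(max(t, 0.0))
    starts[-1] = 0.0
    post = [
        epoch_at(t_young, d, mode, (p1, p2))
        for t_young, d, mode in zip(starts, durations, modes)
    ]
    anc_name = DemographicModel.ANCESTRAL
    # the recent ancestral epoch's size is carried by the population entry
    anc_recent = epoch_at(0.0, anc_durations[1], anc_modes[1], (anc_name,))
    anc_recent.migration = {}
    old_t = div + anc_durations[1]
    anc_old = epoch_at(old_t, anc_durations[0], anc_modes[0], (anc_name,))
    anc_old.migration = {}
    return DemographicModel(
        populations=(p1, p2),
        ancestral_epochs=[anc_old, anc_recent],
        post_split_epochs=post,
        divergence_time=div,
        mutation_rate=meta["mutation_rate"],
        generation_time=meta["generation_time"],
        name=meta.get("name", ""),
    )


def to_msprime(model: DemographicModel) -> msprime.Demography:
    """Build the :class:`msprime.Demography` for a model.

    Forward-time "sink from source" rates map directly onto msprime's
    backward-time migration matrix entries ``[dest, source]``.
    """
    config = to_simulator_config(model)
    dem = msprime.Demography()
    p1, p2 = model.populations
    for pop in (p1, p2, model.ANCESTRAL):
        cfg = config["populations"][pop]
        dem.add_population(
            name=pop,
            initial_size=cfg["initial_size"],
            growth_rate=cfg["growth_rate"],
        )
    for ev in config["events"]:
        if ev["kind"] == "migration" and ev["time"] == 0.0:
            for m in ev["rates"]:
                if m["rate"]:
                    # lineages in the forward-time dest jump (backward) to source
                    dem.set_migration_rate(source=m["dest"], dest=m["source"], rate=m["rate"])
        elif ev["kind"] == "migration":
            # reset both directions, then apply the epoch's rates
            for a, b in ((p1, p2), (p2, p1)):
                rate = 0.0
                for m in ev["rates"]:
                    if (m["source"], m["dest"]) == (b, a):
                        rate = m["rate"]
                dem.add_migration_rate_change(time=ev["time"], source=a, dest=b, rate=rate)
        elif ev["kind"] == "size":
            dem.add_population_parameters_change(
                time=ev["time"],
                population=ev["population"],
                initial_size=ev["size"],
                growth_rate=ev["growth_rate"],
            )
        elif ev["kind"] == "split":
            dem.add_population_split(
                time=ev["time"], derived=ev["derived"], ancestral=ev["ancestral"]
            )
    dem.sort_events()
    return dem


# ----------------------------------------------------------------------
# fixture models
# ----------------------------------------------------------------------
# Representative parameter magnitudes: divergence at ~150/600/800 kya
# (generation time 5 years), ILa declining from ~6k to <3k, ELw from ~15k
# to ~5k recently, ELs roughly constant near 10k, and recent migration
# consistently higher in the ILa-ELw pair than in ILa-ELs.

_FIXTURES: dict[tuple[str, int], dict] = {}


def _build_fixtures() -> None:
    specs = {
        # pair -> (EL population name, EL ancient size, EL recent size, recent migration)
        "ILa-ELw": ("ELw", 15_000.0, 5_000.0, 2.0e-6),
        "ILa-ELs": ("ELs", 10_000.0, 10_000.0, 5.0e-7),
    }
    div_gens = {1: 30_000.0, 2: 120_000.0, 3: 160_000.0}
    for pair, (el, el_old, el_new, m_recent) in specs.items():
        for idx, div in div_gens.items():
            ila_old, ila_new = 6_000.0, 2_500.0
            d3 = 2_000.0  # recent epoch with the declines
            d2 = 8_000.0
            d1 = div - d2 - d3
            m_old = m_recent / 3
            anc = DemographicModel.ANCESTRAL
            e1 = Epoch(
                duration=d1,
                size_start={"ILa": ila_old, el: el_old},
                size_end={"ILa": ila_old, el: el_old},
                migration={("ILa", el): m_old, (el, "ILa"): m_old},
            )
            e2 = Epoch(
                duration=d2,
                size_start={"ILa": ila_old, el: el_old},
                size_end={"ILa": ila_old, el: el_old},
                migration={("ILa", el): m_recent / 2, (el, "ILa"): m_recent / 2},
            )
            e3 = Epoch(
                duration=d3,
                size_start={"ILa": ila_old, el: el_old},
                size_end={"ILa": ila_new, el: el_new},
                change_mode="exponential",
                migration={("ILa", el): m_recent, (el, "ILa"): m_recent},
            )
            anc_old = Epoch(
                duration=100_000.0,
                size_start={anc: 10_000.0},
                size_end={anc: 10_000.0},
            )
            anc_recent = Epoch(
                duration=50_000.0,
                size_start={anc: 8_000.0},
                size_end={anc: 8_000.0},
            )
            _FIXTURES[(pair, idx)] = DemographicModel(
                populations=("ILa", el),
                ancestral_epochs=[anc_old, anc_recent],
                post_split_epochs=[e1, e2, e3],
                divergence_time=div,
                name=f"{pair}-model{idx}",
            ).to_dict()


_build_fixtures()


def to_demes_yaml(model: DemographicModel, path: str | Path) -> None:
    """Export the model in the demes YAML interchange convention."""
    import demes

    graph = to_msprime(model).to_demes()
    demes.dump(graph, path)


def load_fixture_model(pair: str, model_index: int) -> DemographicModel:
    """Return one of the six representative fitted models.

    ``pair`` is ``"ILa-ELw"`` or ``"ILa-ELs"``; ``model_index`` in 1..3
    selects divergence at roughly 150, 600 or 800 kya respectively.
    """
    if pair not in PAIRS:
        raise ValueError(f"unknown pair {pair!r}; expected one of {PAIRS}")
    if model_index not in (1, 2, 3):
        raise ValueError(f"model_index must be 1, 2 or 3, got {model_index}")
    return DemographicModel.from_dict(_FIXTURES[(pair, model_index)])
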
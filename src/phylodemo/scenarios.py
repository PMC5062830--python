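"""Demographic scenario definitions for glacial-cycle hypothesis testing.

Four competing demographic histories are expressed for a subdivided
population of ``D`` demes observed at present and traced backward to a
horizon at the Last Glacial Maximum (LGM):

``PLAH``
    Pleistocene Arc: every deme persists to the horizon and was smaller
    there (forward-time expansion since the LGM).
``PPPH``
    Amazon dry-forest shift: backward in time all lineages funnel into a
    single source deme; every other deme shrinks to extinction before the
    horizon.
``BOTH``
    Combination: half of the non-source demes persist (arc expansion),
    half go extinct backward into the source (Amazon shift).
``RETRACTION``
    Range retraction: non-source demes vanish backward while the source
    deme was *larger* at the horizon than today.

Deme sizes follow an exponential interpolation between the present size
``N0`` and the horizon size ``N1``; the growth rate is
``g = ln(N1/N0) / t`` so that ``N(tau) = N0 * exp(g * tau)`` for ``tau``
generations before present.  In backward-time simulators a negative ``g``
means the population is larger now than in the past (a forward-time
expansion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import yaml

HYPOTHESES = ("PLAH", "PPPH", "BOTH", "RETRACTION")

#: Schema identifier written into serialized scenario files.
SCENARIO_SCHEMA = "phylodemo-scenario-v1"

#: Default N1/N0 ratio for forward-time expansion scenarios (deme smaller
#: at the LGM horizon than at present).  The source study never prints the
#: horizon sizes, so these ratios are explicit, documented configuration.
EXPANSION_RATIO = 0.1
#: Default N1/N0 ratio for the range-retraction scenario.
RETRACTION_RATIO = 10.0


class InvalidParameterError(ValueError):
    """A scenario or conversion parameter is outside its valid domain."""


class InvalidHypothesisError(ValueError):
    """Unknown demographic hypothesis label."""


@dataclass(frozen=True)
class DemeTrajectory:
    """Size trajectory of one deme from the present back to the horizon.

    Parameters
    ----------
    deme_id:
        1-based deme index.
    N0:
        Effective size (lineage copies) at present.
    N1:
        Effective size at the horizon.  Ignored when
        ``extinct_before_horizon`` is set.
    t_span:
        Horizon, in generations before present.
    extinct_before_horizon:
        If true the deme shrinks linearly to a single lineage copy at the
        horizon and contributes no resident lineages there.
    """

    deme_id: int
    N0: float
    N1: float
    t_span: int
    extinct_before_horizon: bool = False

    def __post_init__(self) -> None:
        if self.N0 <= 0:
            raise InvalidParameterError(f"deme {self.deme_id}: N0 must be > 0")
        if self.N1 < 0:
            raise InvalidParameterError(f"deme {self.deme_id}: N1 must be >= 0")
        if self.t_span <= 0:
            raise InvalidParameterError(f"deme {self.deme_id}: t_span must be > 0")
        if self.N1 == 0 and not self.extinct_before_horizon:
            raise InvalidParameterError(
                f"deme {self.deme_id}: N1 = 0 must be expressed via "
                "extinct_before_horizon"
            )


@dataclass(frozen=True)
class Scenario:
    """A complete demographic hypothesis over ``D`` demes.

    Backward in time each lineage outside ``source_deme`` migrates into it
    with probability ``migration_prob`` per generation; at
    ``horizon_generations`` all surviving lineages are placed in the
    source deme, which persists at its horizon size until the MRCA.
    """

    name: str
    demes: tuple[DemeTrajectory, ...]
    source_deme: int = 1
    migration_prob: float = 0.01
    horizon_generations: int = 1400
    generation_time_years: float = 15.0

    def __post_init__(self) -> None:
        ids = [d.deme_id for d in self.demes]
        if self.source_deme not in ids:
            raise InvalidParameterError(
                f"source_deme {self.source_deme} not among deme ids"
            )
        if not 0.0 <= self.migration_prob <= 1.0:
            raise InvalidParameterError("migration_prob must lie in [0, 1]")
        if self.horizon_generations <= 0:
            raise InvalidParameterError("horizon_generations must be > 0")

    @property
    def n_demes(self) -> int:
        return len(self.demes)

    def deme(self, deme_id: int) -> DemeTrajectory:
        for d in self.demes:
            if d.deme_id == deme_id:
                return d
        raise KeyError(deme_id)

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema": SCENARIO_SCHEMA,
            "name": self.name,
            "source_deme": self.source_deme,
            "migration_prob": self.migration_prob,
            "horizon_generations": self.horizon_generations,
            "generation_time_years": self.generation_time_years,
            "demes": [asdict(d) for d in self.demes],
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_dict(cls, data: dict) -> "Scenario":
        schema = data.get("schema", SCENARIO_SCHEMA)
        if schema != SCENARIO_SCHEMA:
            raise InvalidParameterError(f"unsupported scenario schema: {schema!r}")
        demes = tuple(DemeTrajectory(**d) for d in data["demes"])
        return cls(
            name=data["name"],
            demes=demes,
            source_deme=data["source_deme"],
            migration_prob=data["migration_prob"],
            horizon_generations=data["horizon_generations"],
            generation_time_years=data["generation_time_years"],
        )

    @classmethod
    def from_yaml(cls, text: str) -> "Scenario":
        return cls.from_dict(yaml.safe_load(text))


@dataclass(frozen=True)
class ThetaConversion:
    """Conversion between the mutation parameter theta and Ne.

    theta = 2*mu*Ne for haploid-transmitted loci (chloroplast) and
    4*mu*Ne for diploid nuclear loci; ``ploidy_factor`` is 2 or 4.
    """

    theta: float
    mu: float
    ploidy_factor: int = 2

    def __post_init__(self) -> None:
        if self.theta < 0:
            raise InvalidParameterError("theta must be >= 0")
        if self.mu <= 0:
            raise InvalidParameterError("mu must be > 0")
        if self.ploidy_factor not in (2, 4):
            raise InvalidParameterError("ploidy_factor must be 2 or 4")


def generations_from_years(age_years: float, generation_time_years: float) -> int:
    """Convert an age in years to generations, rounding half away from zero.

    With the default 15-year generation time the 21 kyr BP glacial
    maximum maps to 1,400 generations.
    """
    if generation_time_years <= 0:
        raise InvalidParameterError("generation time must be > 0")
    if age_years < 0:
        raise InvalidParameterError("age must be >= 0")
    x = age_years / generation_time_years
    return int(math.floor(x + 0.5))


def growth_rate(N0: float, N1: float, t_span: float) -> float:
    """Per-generation exponential rate ``g = ln(N1/N0)/t``.

    Positive ``g`` means the deme was larger at the horizon than at
    present; in a backward-time simulation the matching forward-time
    reading is a population decline since the horizon.
    """
    if N0 <= 0 or N1 <= 0:
        raise InvalidParameterError(
            "growth_rate requires N0, N1 > 0; extinction is expressed via "
            "extinct_before_horizon"
        )
    if t_span <= 0:
        raise InvalidParameterError("t_span must be > 0")
    return math.log(N1 / N0) / t_span


def deme_size_at(traj: DemeTrajectory, tau: float) -> float:
    """Deme size ``tau`` generations before present.

    Exponential interpolation between N0 (tau=0) and N1 (tau=t_span) for
    persistent demes; linear shrink from N0 to one lineage copy at the
    horizon for demes flagged extinct.
    """
    if not 0 <= tau <= traj.t_span:
        raise InvalidParameterError(
            f"tau={tau} outside [0, {traj.t_span}] for deme {traj.deme_id}"
        )
    if traj.extinct_before_horizon:
        frac = tau / traj.t_span
        return traj.N0 + (1.0 - traj.N0) * frac
    g = growth_rate(traj.N0, traj.N1, traj.t_span)
    return traj.N0 * math.exp(g * tau)


def theta_to_ne(conv: ThetaConversion) -> float:
    """Effective size ``Ne = theta / (ploidy_factor * mu)``."""
    return conv.theta / (conv.ploidy_factor * conv.mu)


def build_hypothesis_scenario(
    name: str,
    n_demes: int = 17,
    N0: float = 10_000.0,
    expansion_ratio: float = EXPANSION_RATIO,
    retraction_ratio: float = RETRACTION_RATIO,
    source_deme: int = 1,
    migration_prob: float = 0.01,
    horizon_generations: int = 1400,
    generation_time_years: float = 15.0,
) -> Scenario:
    """Construct the named demographic hypothesis.

    All demes share the present size ``N0``.  Horizon sizes follow the
    hypothesis geometry (module docstring); the N1/N0 ratios are explicit
    configuration because the source study never prints them.
    """
    name = name.upper()
    if name not in HYPOTHESES:
        raise InvalidHypothesisError(
            f"unknown hypothesis {name!r}; expected one of {HYPOTHESES}"
        )
    if n_demes < 1:
        raise InvalidParameterError("n_demes must be >= 1")

    def traj(i: int, ratio: float, extinct: bool) -> DemeTrajectory:
        return DemeTrajectory(
            deme_id=i,
            N0=N0,
            N1=0.0 if extinct else N0 * ratio,
            t_span=horizon_generations,
            extinct_before_horizon=extinct,
        )

    # The source deme's horizon size carries the total ancestral (LGM)
    # population each hypothesis implies, because after the horizon all
    # lineages coalesce inside it: a widespread glacial arc (PLAH) is a
    # large connected ancestral pool, a pure range shift into the source
    # (PPPH) concentrates ancestry in one ordinary-sized deme, and a
    # glacial retraction (RETRACTION) means a large pre-decline deme.
    others = [i for i in range(1, n_demes + 1) if i != source_deme]
    demes: list[DemeTrajectory] = []
    if name == "PLAH":
        demes = [traj(source_deme, n_demes * expansion_ratio, False)]
        demes += [traj(i, expansion_ratio, False) for i in others]
    elif name == "PPPH":
        demes = [traj(source_deme, expansion_ratio, False)]
        demes += [traj(i, expansion_ratio, True) for i in others]
    elif name == "BOTH":
        # Arc half persists, Amazon half funnels into the source deme.
        half = len(others) // 2
        demes = [traj(source_deme, (1 + half) * expansion_ratio, False)]
        demes += [traj(i, expansion_ratio, False) for i in others[:half]]
        demes += [traj(i, expansion_ratio, True) for i in others[half:]]
    elif name == "RETRACTION":
        demes = [traj(source_deme, retraction_ratio, False)]
        demes += [traj(i, retraction_ratio, True) for i in others]
    demes.sort(key=lambda d: d.deme_id)
    return Scenario(
        name=name,
        demes=tuple(demes),
        source_deme=source_deme,
        migration_prob=migration_prob,
        horizon_generations=horizon_generations,
        generation_time_years=generation_time_years,
    )
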
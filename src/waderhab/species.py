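"""Species profiles for the modeled wading birds.

The foraging depth range bounds habitat availability (a cell is available
only while its depth lies inside the closed interval). Fledge age is the
posthatching age at which a nest is scored successful (14 days for the
quickly developing White Ibis, 21 for the Great Egret); the nest cycle
length is incubation plus that age and sets the exponent of the Mayfield
period-success extrapolation. Incubation lengths are package defaults, not
field-estimated values.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class SpeciesProfile:
    name: str
    depth_min_cm: float
    depth_max_cm: float
    fledge_age_days: int
    incubation_days: int
    candidate_set: str = "default"

    def __post_init__(self) -> None:
        if not self.depth_min_cm < self.depth_max_cm:
            raise ValueError("foraging depth range requires min < max")
        if self.nest_cycle_days <= self.fledge_age_days:
            raise ValueError("nest cycle must exceed fledge age")

    @property
    def nest_cycle_days(self) -> int:
        """Mayfield period length T: incubation + posthatching success age."""
        return self.incubation_days + self.fledge_age_days

    @property
    def depth_range(self) -> tuple[float, float]:
        return (self.depth_min_cm, self.depth_max_cm)


GREAT_EGRET = SpeciesProfile("great_egret", 0.0, 28.0, fledge_age_days=21,
                             incubation_days=26)
WHITE_IBIS = SpeciesProfile("white_ibis", 0.0, 18.0, fledge_age_days=14,
                            incubation_days=21)
WOOD_STORK = SpeciesProfile("wood_stork", 0.0, 30.0, fledge_age_days=21,
                            incubation_days=30)

DEFAULT_SPECIES = {p.name: p for p in (GREAT_EGRET, WHITE_IBIS, WOOD_STORK)}


def get_profile(name: str) -> SpeciesProfile:
    try:
        return DEFAULT_SPECIES[name]
    except KeyError:
        raise KeyError(f"unknown species profile: {name!r}") from None
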
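"""Population-level mortality and sublethality for a region x species scenario.

A square maize field of C hectares with a margin D metres wide has a margin
area of about 400*D*sqrt(C) m^2, so the exposed host plants number
10000*C*e within the crop and 400*D*f*sqrt(C) in the margin (e, f plant
densities per m^2).  The plant-count-weighted mean of within-crop mortality h
and margin-average mortality mu(D) simplifies to

    (25*e*h*sqrt(C) + f*D*mu) / (25*e*sqrt(C) + f*D).

Regions where some fields have no margin at all are handled by a bimodal
mixture: with probability q the field exposes only within-crop plants (h),
with probability 1-q it contributes the weighted mean above.  The population
mortality rate is then scaled by the retained-exposure proportions x
(physical effects) and a (temporal coincidence) and by the demographic chain
y*z*v (host plant in arable habitat, maize share of arable fields, MON810
share of maize).  Sublethality is four times mortality, capped at 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .exposure import (
    ExposureProfile,
    crop_mortality_h,
    margin_average_mu,
    margin_mortality_g,
    sublethality,
)

__all__ = [
    "RegionScenario",
    "RiskEstimate",
    "exposed_weight_split",
    "field_level_mortality",
    "population_mortality",
    "project_decline",
]

_PROPORTIONS = ("x", "a", "z", "v", "y", "q")


@dataclass(frozen=True)
class RegionScenario:
    """Demographic and agronomic parameters for one region.

    x, a : retained-exposure proportions (physical effects, temporal coincidence)
    z, v, y : demographic proportions (maize share of arable, MON810 share of
        maize, host-plant share in arable habitat)
    e, f : host-plant densities, plants m^-2, within crop and in margin
    C : mean field size, ha (fields assumed square); D : margin width, m
    q : probability that a field has no margin at all (bimodal margins)
    """

    region: str
    x: float
    a: float
    z: float
    v: float
    y: float
    e: float
    f: float
    C: float
    D: float
    q: float = 0.0

    def __post_init__(self) -> None:
        for name in _PROPORTIONS:
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be a proportion in [0, 1], got {val}")
        if self.e < 0 or self.f < 0:
            raise ValueError("host-plant densities e, f must be non-negative")
        if self.C <= 0:
            raise ValueError(f"field size C must be positive, got {self.C}")
        if self.D < 0:
            raise ValueError(f"margin width D must be non-negative, got {self.D}")
        if self.e == 0 and self.f * self.D == 0:
            raise ValueError(
                "scenario exposes no host plants at all (e = 0 and f*D = 0); "
                "encode a no-host region via y = 0 or a tiny margin density instead"
            )


@dataclass(frozen=True)
class RiskEstimate:
    """Mortality/sublethality rates for one scenario, worst-case and adjusted."""

    region: str
    species: str
    worst_case_within_crop: float  # h
    worst_case_margin_avg: float  # mu(D)
    adjusted_individual_crop: float  # x*a*h
    adjusted_individual_margin: float  # x*a*mu(D)
    population_mortality: float
    population_sublethality: float


def exposed_weight_split(C: float, D: float, e: float, f: float) -> tuple[float, float]:
    """Expected numbers of exposed host plants (within crop, in margin).

    crop = 10000*C*e; margin = 400*D*f*sqrt(C) (square-field perimeter scaling).
    """
    return 10000.0 * C * e, 400.0 * D * f * math.sqrt(C)


def field_level_mortality(
    h: float, mu: float, C: float, D: float, e: float, f: float
) -> float:
    """Plant-count-weighted mean of within-crop and margin mortality.

    Uses the simplified form (25*e*h*sqrt(C) + f*D*mu)/(25*e*sqrt(C) + f*D),
    algebraically identical to weighting h and mu by the exposed plant counts.
    """
    w_crop = 25.0 * e * math.sqrt(C)
    w_margin = f * D
    denom = w_crop + w_margin
    if denom == 0:
        raise ValueError("no exposed host plants: both crop and margin weights are zero")
    return (w_crop * h + w_margin * mu) / denom


def population_mortality(s: RegionScenario, profile: ExposureProfile) -> RiskEstimate:
    """Full population-level risk estimate for one region x species scenario.

    base = (1-q) * field_level_mortality + q * h (fields with no margin expose
    only within-crop plants); population mortality = x*a*y*z*v * base.
    """
    h = crop_mortality_h(profile)
    if s.f > 0 and s.D > 0:
        mu = margin_average_mu(profile, s.D)
        with_margin = field_level_mortality(h, mu, s.C, s.D, s.e, s.f)
    else:
        # no margin plants anywhere: the mixture degenerates to within-crop only;
        # report the margin average as its D -> 0 limit g(0) when D = 0
        mu = margin_average_mu(profile, s.D) if s.D > 0 else float(margin_mortality_g(profile, 0.0))
        with_margin = h
    base = (1.0 - s.q) * with_margin + s.q * h
    xa = s.x * s.a
    mort = xa * s.y * s.z * s.v * base
    return RiskEstimate(
        region=s.region,
        species=profile.species,
        worst_case_within_crop=h,
        worst_case_margin_avg=mu,
        adjusted_individual_crop=xa * h,
        adjusted_individual_margin=xa * mu,
        population_mortality=mort,
        population_sublethality=sublethality(mort),
    )


def project_decline(annual_added_mortality: float, years: int, compounded: bool = True) -> float:
    """Expected population decline after ``years`` of added annual mortality.

    Compounded: 1 - (1 - m)^years; linear approximation (m * years) with
    ``compounded=False``.  Added mortality per year may combine per-generation
    mortality across the generations coincident with pollen shed.
    """
    if not 0.0 <= annual_added_mortality <= 1.0:
        raise ValueError("annual_added_mortality must be a proportion in [0, 1]")
    if years < 0:
        raise ValueError("years must be non-negative")
    if compounded:
        return 1.0 - (1.0 - annual_added_mortality) ** years
    return min(annual_added_mortality * years, 1.0)
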
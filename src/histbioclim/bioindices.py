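"""Cold-climate biometeorological indices and their categorical classifiers.

Two indices are computed from air temperature and wind alone (the only
variables early-instrumental registers provide):

Wind chill temperature (WCT), degC::

    WCT = 13.12 + 0.6215 t - 11.37 v10**0.16 + 0.3965 t v10**0.16

with t the air temperature (degC) and v10 the wind speed in m/s at 10 m.
WCT expresses the cooling of exposed skin and maps onto frostbite-risk
categories.  The formula's conventional validity domain is t <= 10 degC and
v10 >= 1.34 m/s (about 4.8 km/h); outside it the value is still computed
but flagged, since year-round series are routinely summarized.

Insulation predicted (Iclp), clo (1 clo = 0.155 K m^-2 W^-1)::

    Iclp = 0.082 (91.4 - (1.8 t + 32)) / (0.01724 M) - 1 / (0.61 + (1.9 v)**0.5)

the clothing insulation required for heat balance at metabolic rate M
(W/m^2; 135 ~ walking 4 km/h, 70 ~ standing), minus the insulation of the
boundary air layer, which shrinks with wind.  By convention Iclp uses the
wind at chest height (1.2 m).
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .conversions import StandardObservation

__all__ = [
    "BioRecord",
    "CategoryScheme",
    "FROSTBITE_SCHEME",
    "FROSTBITE_SCHEME_4LEVEL",
    "CLOTHING_SCHEME",
    "M_MOVING",
    "M_STANDING",
    "WCT_T_VALID_MAX_C",
    "WCT_V_VALID_MIN_MS",
    "wct",
    "wct_in_validity_domain",
    "iclp",
    "frostbite_category",
    "clothing_band",
    "compute_bio_series",
]

#: metabolic rates (W/m^2): person moving at 4 km/h, and standing
M_MOVING = 135.0
M_STANDING = 70.0

#: conventional validity domain of the wind-chill formula
WCT_T_VALID_MAX_C = 10.0
WCT_V_VALID_MIN_MS = 1.34


def wct(t_c: float, v10: float) -> float:
    """Wind chill temperature (degC); v10 is wind at 10 m in m/s, > 0."""
    if v10 <= 0:
        raise ValueError(f"wind speed at 10 m must be > 0, got {v10}")
    p = v10 ** 0.16
    return 13.12 + 0.6215 * t_c - 11.37 * p + 0.3965 * t_c * p


def wct_in_validity_domain(t_c: float, v10: float) -> bool:
    """Whether (t, v10) lies in the conventional WCT validity domain."""
    return t_c <= WCT_T_VALID_MAX_C and v10 >= WCT_V_VALID_MIN_MS


def iclp(t_c: float, v: float, M: float) -> float:
    """Insulation predicted (clo) at metabolic rate M; v is the 1.2 m wind.

    The first term is the total insulation required for heat balance, the
    second the insulation of the near-surface air layer.
    """
    if M <= 0:
        raise ValueError(f"metabolic rate must be > 0, got {M}")
    if v < 0:
        raise ValueError(f"wind speed must be >= 0, got {v}")
    total = 0.082 * (91.4 - (1.8 * t_c + 32.0)) / (0.01724 * M)
    air_layer = 1.0 / (0.61 + math.sqrt(1.9 * v))
    return total - air_layer


# ---------------------------------------------------------------------------
# categorical schemes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CategoryScheme:
    """Ordered, exhaustive partition of the real line into labelled intervals.

    ``intervals`` lists ``(upper_bound, upper_inclusive, label)`` from lowest
    to highest; the last upper bound must be +inf.  A value belongs to the
    first interval whose upper bound it does not exceed (strictly, or weakly
    when the bound is inclusive).
    """

    name: str
    intervals: tuple[tuple[float, bool, str], ...]

    def __post_init__(self) -> None:
        uppers = [u for u, _, _ in self.intervals]
        if any(b <= a for a, b in zip(uppers, uppers[1:])):
            raise ValueError(f"scheme {self.name!r}: bounds must strictly increase")
        if not math.isinf(uppers[-1]):
            raise ValueError(f"scheme {self.name!r}: last bound must be +inf")

    def classify(self, value: float) -> str:
        if not math.isfinite(value):
            raise ValueError(f"cannot classify non-finite value {value}")
        for upper, inclusive, label in self.intervals:
            if value < upper or (inclusive and value == upper):
                return label
        raise AssertionError("unreachable: last bound is +inf")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for _, _, label in self.intervals)


#: frostbite risk from WCT.  Very high risk (exposed skin can freeze in
#: 10-30 min) from -30 degC down; no risk above 0 degC.
FROSTBITE_SCHEME = CategoryScheme(
    name="frostbite_5level",
    intervals=(
        (-30.0, True, "very high"),
        (-25.0, True, "high"),
        (-10.0, True, "moderate"),
        (0.0, True, "low"),
        (math.inf, True, "lack"),
    ),
)

#: 4-level variant merging "very high" into "high" (figure-legend style)
FROSTBITE_SCHEME_4LEVEL = CategoryScheme(
    name="frostbite_4level",
    intervals=(
        (-25.0, True, "high"),
        (-10.0, True, "moderate"),
        (0.0, True, "low"),
        (math.inf, True, "lack"),
    ),
)

#: Krawczyk clothing-demand bands over Iclp (clo)
CLOTHING_SCHEME = CategoryScheme(
    name="clothing_krawczyk",
    intervals=(
        (0.5, False, "very light summer clothing"),
        (1.0, False, "light summer clothing"),
        (1.5, False, "summer clothing with accessories"),
        (2.5, False, "spring/autumn clothing"),
        (3.0, False, "spring/autumn clothing with increased insulation"),
        (4.0, True, "normal winter clothing"),
        (math.inf, True, "heavy winter (arctic) clothing"),
    ),
)


def frostbite_category(wct_value: float,
                       scheme: CategoryScheme = FROSTBITE_SCHEME) -> str:
    """Frostbite-risk label for a WCT value."""
    return scheme.classify(wct_value)


def clothing_band(clo_value: float,
                  scheme: CategoryScheme = CLOTHING_SCHEME) -> str:
    """Clothing-demand label for an Iclp value (clo)."""
    return scheme.classify(clo_value)


# ---------------------------------------------------------------------------
# per-observation records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BioRecord:
    """Biometeorological indices for one standardized observation.

    ``wct_valid`` is False when the inputs fall outside the conventional
    wind-chill validity domain (the value is still reported).  Missing
    inputs yield ``None`` fields with the reason in ``missing_reason``.
    """

    date: dt.date
    hour_lt: str
    wct: Optional[float]
    iclp_move: Optional[float]
    iclp_stand: Optional[float]
    frostbite: Optional[str]
    clothing: Optional[str]
    wct_valid: bool = True
    missing_reason: Optional[str] = None


def compute_bio_series(
    obs: Sequence[StandardObservation],
    frostbite_scheme: CategoryScheme = FROSTBITE_SCHEME,
    clothing_scheme: CategoryScheme = CLOTHING_SCHEME,
) -> list[BioRecord]:
    """One BioRecord per standardized observation.

    WCT uses the 10 m wind, Iclp the 1.2 m (chest-height) wind; the clothing
    band is assigned from the moving-person Iclp (M = 135 W/m^2).
    """
    out: list[BioRecord] = []
    for o in obs:
        if o.t_c is None or o.v10 is None or o.v12 is None or o.v10 <= 0:
            reason = ("temperature missing" if o.t_c is None
                      else "wind missing" if o.v10 is None or o.v12 is None
                      else "zero wind outside WCT domain")
            out.append(BioRecord(o.date, o.hour_lt, None, None, None, None, None,
                                 wct_valid=False, missing_reason=reason))
            continue
        w = wct(o.t_c, o.v10)
        im = iclp(o.t_c, o.v12, M_MOVING)
        ist = iclp(o.t_c, o.v12, M_STANDING)
        out.append(BioRecord(
            date=o.date,
            hour_lt=o.hour_lt,
            wct=w,
            iclp_move=im,
            iclp_stand=ist,
            frostbite=frostbite_scheme.classify(w),
            clothing=clothing_scheme.classify(im),
            wct_valid=wct_in_validity_domain(o.t_c, o.v10),
        ))
    return out
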
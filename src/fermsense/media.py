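"""Media recipes and exponential feed policies.

The campaign emulates a ten-run *Lactobacillus rhamnosus* study: six batch
runs on four dairy substrates (lactose, whey permeate, demineralised whey,
skim milk powder) and four fed-batch runs on a fixed skim-milk-powder medium
(37 g/L SMP, 14 g/L yeast extract) fed exponentially with a 100 g/L-lactose
skim-milk feed at growth-rate setpoints 0.14, 0.19, 0.24 and 0.34 h⁻¹.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields


#: approximate fermentable-lactose mass fraction of each carbohydrate-bearing
#: medium component (skim milk powder is ~52% lactose, wheys are enriched).
LACTOSE_CONTENT = {
    "lactose": 1.0,
    "whey_permeate": 0.80,
    "demineralised_whey": 0.70,
    "skim_milk_powder": 0.52,
}

_CARBON_FIELDS = tuple(LACTOSE_CONTENT)


@dataclass(frozen=True)
class MediaComposition:
    """One medium recipe, all concentrations in g/L."""

    lactose: float = 0.0
    whey_permeate: float = 0.0
    demineralised_whey: float = 0.0
    skim_milk_powder: float = 0.0
    yeast_extract: float = 0.0
    peptone: float = 0.0
    tween80: float = 1.0
    sodium_acetate: float = 5.0
    ammonium_citrate: float = 2.0
    kh2po4: float = 2.0
    mgso4: float = 0.2
    mnso4: float = 0.04
    inoculum_size: float = 0.1

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"media field {f.name!r} is not finite")
            if v < 0:
                raise ValueError(f"media field {f.name!r} must be >= 0, got {v}")

    @property
    def total_carbon_solids(self) -> float:
        """Sum of the carbohydrate-bearing components (g/L)."""
        return sum(getattr(self, f) for f in _CARBON_FIELDS)

    @property
    def total_solids(self) -> float:
        """Sum of all dissolved components except the inoculum (g/L)."""
        return sum(
            getattr(self, f.name) for f in fields(self) if f.name != "inoculum_size"
        )

    @property
    def fermentable_lactose(self) -> float:
        """Fermentable lactose equivalent of the carbohydrate components (g/L)."""
        return sum(getattr(self, f) * c for f, c in LACTOSE_CONTENT.items())


def _batch(run: int, **kw: float) -> MediaComposition:
    return MediaComposition(**kw)


#: the ten-run campaign recipe table; keys are run numbers (1–6 batch,
#: 7–10 fed-batch).  Fed-batch media fix skim_milk_powder=37, yeast_extract=14.
CAMPAIGN_MEDIA: dict[int, MediaComposition] = {
    1: MediaComposition(lactose=20, yeast_extract=4, peptone=10, inoculum_size=0.2),
    2: MediaComposition(whey_permeate=20.60, yeast_extract=4.15, peptone=2.44, inoculum_size=0.08),
    3: MediaComposition(skim_milk_powder=28.67, yeast_extract=4.15, peptone=4.15, inoculum_size=0.04),
    4: MediaComposition(lactose=15.23, yeast_extract=4.15, peptone=4.15, inoculum_size=0.06),
    5: MediaComposition(demineralised_whey=20.79, yeast_extract=4.15, peptone=3.34, inoculum_size=0.11),
    6: MediaComposition(skim_milk_powder=37, yeast_extract=14, inoculum_size=0.4),
    7: MediaComposition(skim_milk_powder=37, yeast_extract=14, inoculum_size=0.39),
    8: MediaComposition(skim_milk_powder=37, yeast_extract=14, inoculum_size=0.45),
    9: MediaComposition(skim_milk_powder=37, yeast_extract=14, inoculum_size=0.48),
    10: MediaComposition(skim_milk_powder=37, yeast_extract=14, inoculum_size=0.4),
}

BATCH_RUNS = (1, 2, 3, 4, 5, 6)
FEDBATCH_RUNS = (7, 8, 9, 10)
MU_SETPOINTS = (0.14, 0.19, 0.24, 0.34)


def initial_feed_rate(
    mu_set: float, si: float, yxs: float, x0: float, v0: float
) -> float:
    """Initial exponential feed rate F0 in ml/h.

    F0 = mu·X0·V0 / (Si·Yxs): the feed of substrate (concentration ``si``
    g/L) that sustains growth of the standing biomass ``x0·v0`` (g) at
    specific rate ``mu_set`` (h⁻¹) given a maintenance-inclusive yield
    ``yxs`` (g biomass per g substrate).
    """
    if si <= 0 or yxs <= 0:
        raise ValueError("si and yxs must be positive")
    return 1000.0 * mu_set * x0 * v0 / (si * yxs)


@dataclass(frozen=True)
class FeedPolicy:
    """Exponential feeding F(t) = F0·exp(mu_set·(t − t_start)), ml/h."""

    mu_set: float          # growth-rate setpoint, h⁻¹
    f0: float              # initial feed rate, ml/h
    si: float              # limiting-substrate concentration in feed, g/L
    yxs: float             # biomass yield on substrate incl. maintenance, g/g
    x0: float              # biomass concentration at feed start, g/L
    v0: float              # broth volume at feed start, L
    t_start: float         # feed start, h process time
    t_end: float           # feed end, h process time

    def __post_init__(self) -> None:
        if self.mu_set <= 0:
            raise ValueError("mu_set must be positive")
        if self.t_start >= self.t_end:
            raise ValueError("t_start must precede t_end")
        expected = initial_feed_rate(self.mu_set, self.si, self.yxs, self.x0, self.v0)
        if not math.isclose(self.f0, expected, rel_tol=1e-6):
            raise ValueError(
                f"f0={self.f0:.6g} ml/h inconsistent with policy state "
                f"(expected {expected:.6g} ml/h)"
            )

    @classmethod
    def from_state(
        cls,
        mu_set: float,
        si: float,
        yxs: float,
        x0: float,
        v0: float,
        t_start: float,
        t_end: float,
    ) -> "FeedPolicy":
        f0 = initial_feed_rate(mu_set, si, yxs, x0, v0)
        return cls(mu_set, f0, si, yxs, x0, v0, t_start, t_end)

    def rate(self, t_since_start: float) -> float:
        """Feed rate (ml/h) at ``t_since_start`` hours after feed start."""
        if t_since_start < 0:
            raise ValueError("time since feed start must be >= 0")
        return self.f0 * math.exp(self.mu_set * t_since_start)

    def duration_for_added_volume(self, dv_l: float) -> float:
        """Feed duration (h) after which the integrated feed equals dv_l litres."""
        f0_l = self.f0 / 1000.0
        return math.log1p(self.mu_set * dv_l / f0_l) / self.mu_set


def exponential_feed_rate(policy: FeedPolicy, t_since_start) -> object:
    """Vector-friendly F(t) = F0·exp(mu_set·t); t is hours since feed start."""
    import numpy as np

    t = np.asarray(t_since_start, dtype=float)
    if np.any(t < 0):
        raise ValueError("time since feed start must be >= 0")
    out = policy.f0 * np.exp(policy.mu_set * t)
    return float(out) if out.ndim == 0 else out
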
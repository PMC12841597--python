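"""Cross-species representation of chronological age.

Human and mouse timepoints are aligned by expressing each donor's age as a
fraction of the species' maximum lifespan and applying the negative log-log
transform

    scaled = -ln(-ln(age / max_lifespan))

which stretches early development and compresses late life symmetrically in
both species, so that equal *relative* ages map to equal scaled ages. The
natural logarithm is used throughout; the inverse transform
``age = lifespan * exp(-exp(-scaled))`` returns values in years.
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)

#: Species maximum lifespans in years.
DEFAULT_LIFESPANS = {"human": 120.0, "mouse": 4.0}

#: Clamp margin for boundary ages (newborns, centenarian-of-record): one day.
CLAMP_EPS_YEARS = 1.0 / 365.25


class LifespanRegistry:
    """Mapping species -> maximum lifespan in years; extensible via config."""

    def __init__(self, lifespans: dict[str, float] | None = None):
        self.lifespans = dict(DEFAULT_LIFESPANS if lifespans is None else lifespans)
        for sp, ls in self.lifespans.items():
            if not ls > 0:
                raise ValueError(f"non-positive lifespan for {sp!r}: {ls}")

    def __getitem__(self, species: str) -> float:
        try:
            return self.lifespans[species]
        except KeyError:
            raise KeyError(f"no maximum lifespan registered for species {species!r}") from None

    def __contains__(self, species: str) -> bool:
        return species in self.lifespans


_DEFAULT_REGISTRY = LifespanRegistry()


def _clamped_relative_age(age_years, lifespan: float, clamp: bool):
    age = np.asarray(age_years, dtype=float)
    if np.any(age < 0) or np.any(age > lifespan):
        raise ValueError(
            f"age outside [0, {lifespan}] years; cannot scale (got "
            f"{age[(age < 0) | (age > lifespan)][:3]})"
        )
    lo, hi = CLAMP_EPS_YEARS, lifespan - CLAMP_EPS_YEARS
    if clamp:
        n_clamped = int(np.sum((age < lo) | (age > hi)))
        if n_clamped:
            logger.warning("clamped %d boundary age(s) to [1 day, lifespan - 1 day]", n_clamped)
        age = np.clip(age, lo, hi)
    elif np.any(age <= 0) or np.any(age >= lifespan):
        raise ValueError("age must be strictly inside (0, lifespan) when clamp=False")
    return age / lifespan


def scale_age(age_years, species: str, registry: LifespanRegistry | None = None, clamp: bool = True):
    """Map age in years to the lifespan-relative -log(-log(.)) scale.

    Strictly increasing on (0, lifespan). Ages of exactly 0 or the maximum
    lifespan are clamped inward by one day (and logged); ages outside
    [0, lifespan] raise ``ValueError``.
    """
    registry = registry or _DEFAULT_REGISTRY
    rel = _clamped_relative_age(age_years, registry[species], clamp)
    out = -np.log(-np.log(rel))
    return float(out) if np.isscalar(age_years) else out


def unscale_age(scaled, species: str, registry: LifespanRegistry | None = None):
    """Exact inverse of :func:`scale_age`: ``lifespan * exp(-exp(-scaled))``."""
    registry = registry or _DEFAULT_REGISTRY
    lifespan = registry[species]
    out = lifespan * np.exp(-np.exp(-np.asarray(scaled, dtype=float)))
    return float(out) if np.isscalar(scaled) else out


def scale_ages_by_species(age_years, species, registry: LifespanRegistry | None = None):
    """Vectorized :func:`scale_age` for per-sample species labels."""
    registry = registry or _DEFAULT_REGISTRY
    age = np.asarray(age_years, dtype=float)
    sp = np.asarray(species)
    out = np.empty_like(age)
    for s in np.unique(sp):
        m = sp == s
        out[m] = scale_age(age[m], str(s), registry)
    return out


def unscale_ages_by_species(scaled, species, registry: LifespanRegistry | None = None):
    registry = registry or _DEFAULT_REGISTRY
    sc = np.asarray(scaled, dtype=float)
    sp = np.asarray(species)
    out = np.empty_like(sc)
    for s in np.unique(sp):
        m = sp == s
        out[m] = unscale_age(sc[m], str(s), registry)
    return out
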
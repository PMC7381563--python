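"""Random but valid synthetic life histories for testing every stage.

Generated records follow the same structure as the packaged fixtures:
an age of first reproduction, a three-rate survival schedule with
per-rate SDs, a fledgling rate, and a breeding-participation schedule
(a linear ramp for later-maturing life histories).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .demography_io import FixtureCatalog, SurvivalRate, VitalRateSet
from .errors import GenerationError


@dataclass(frozen=True)
class SynthesisSpec:
    """Sampling ranges for synthetic life histories."""

    seed: int = 0
    afr_range: tuple[int, int] = (1, 6)
    adult_survival_range: tuple[float, float] = (0.55, 0.95)
    first_year_survival_range: tuple[float, float] = (0.05, 0.75)
    fledglings_range: tuple[float, float] = (0.3, 4.5)
    relative_sd_range: tuple[float, float] = (0.0, 0.2)
    breeding_prob_range: tuple[float, float] = (0.4, 1.0)

    def validate(self) -> "SynthesisSpec":
        lo, hi = self.afr_range
        if not (1 <= lo <= hi):
            raise GenerationError(f"afr_range must satisfy 1 <= lo <= hi, got {self.afr_range}")
        for name in (
            "adult_survival_range",
            "first_year_survival_range",
            "breeding_prob_range",
        ):
            a, b = getattr(self, name)
            if not (0.0 < a <= b <= 1.0):
                raise GenerationError(f"{name} must lie in (0, 1] with lo <= hi, got {(a, b)}")
        a, b = self.fledglings_range
        if not (0.0 <= a <= b):
            raise GenerationError(f"fledglings_range must be non-negative, got {(a, b)}")
        a, b = self.relative_sd_range
        if not (0.0 <= a <= b):
            raise GenerationError(f"relative_sd_range must be non-negative, got {(a, b)}")
        return self


def _one_record(spec: SynthesisSpec, rng: np.random.Generator, index: int) -> VitalRateSet:
    afr = int(rng.integers(spec.afr_range[0], spec.afr_range[1] + 1))
    s_adult = float(rng.uniform(*spec.adult_survival_range))
    s_second = float(rng.uniform(*spec.adult_survival_range))
    s_first = float(rng.uniform(*spec.first_year_survival_range))
    fledglings = float(rng.uniform(*spec.fledglings_range))
    rel = rng.uniform(*spec.relative_sd_range, size=4)
    b_full = float(rng.uniform(*spec.breeding_prob_range))
    # later-maturing histories get a linear participation ramp, like the
    # packaged Spoonbill/Stork records
    if afr >= 3:
        ramp_years = int(rng.integers(0, 3))
        b_start = float(rng.uniform(spec.breeding_prob_range[0], b_full))
        ages = range(afr, afr + ramp_years + 1)
        probs = np.linspace(b_start, b_full, ramp_years + 1)
        schedule = tuple((a, float(p)) for a, p in zip(ages, probs))
    else:
        schedule = ((afr, b_full),)
    return VitalRateSet(
        species=f"Synthetic {index:03d}",
        population="synthetic",
        period="NA",
        afr=afr,
        fledglings_mean=fledglings,
        fledglings_sd=fledglings * float(rel[3]),
        survival=(
            SurvivalRate("first_year", s_first, s_first * float(rel[0])),
            SurvivalRate("second_year", s_second, s_second * float(rel[1])),
            SurvivalRate("older", s_adult, s_adult * float(rel[2])),
        ),
        breeding_prob=schedule,
    )


def generate(spec: SynthesisSpec, n: int) -> FixtureCatalog:
    """``n`` validated synthetic records, deterministic given ``spec.seed``."""
    if n < 1:
        raise GenerationError(f"n must be >= 1, got {n}")
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    return FixtureCatalog(_one_record(spec, rng, i) for i in range(n))
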
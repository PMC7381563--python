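"""Potential-biological-removal quotas and their effect on DD models.

The annual removable quota is ``0.5 * N * r0 * Fr`` (equivalently a
constant removal fraction ``Fp = 0.5 * r0 * Fr``), with ``r0`` the
low-density growth rate and ``Fr`` a recovery factor in (0, 1].  In the
simulations the fraction is removed from every age class each year after
the matrix transition, with ``r0`` held at its calibration value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .demography_io import VitalRateSet
from .density_dependence import (
    DDModel,
    ResponseSummary,
    response_summary,
)
from .errors import PolicyUndefinedError

RESPONSE_COLUMNS = [
    "species",
    "population",
    "period",
    "lambda0",
    "fr",
    "r0_response_pct",
    "nstar_response_pct",
]


@dataclass(frozen=True)
class PBRPolicy:
    """A removal policy: recovery factor and the reference growth rate."""

    fr: float
    r0_reference: float

    def validate(self) -> "PBRPolicy":
        if not 0.0 < self.fr <= 1.0:
            raise PolicyUndefinedError(f"recovery factor must be in (0, 1], got {self.fr}")
        if self.r0_reference <= 0:
            raise PolicyUndefinedError(
                f"PBR is undefined for non-growing stocks: r0 = {self.r0_reference}"
            )
        return self

    @property
    def harvest_fraction(self) -> float:
        return harvest_fraction(self.r0_reference, self.fr)


def pbr_quota(stock_size: float, r0: float, fr: float) -> float:
    """Removable individuals per year: ``0.5 * N * r0 * Fr``."""
    if stock_size < 0:
        raise ValueError(f"stock size must be >= 0, got {stock_size}")
    PBRPolicy(fr=fr, r0_reference=r0).validate()
    return 0.5 * stock_size * r0 * fr


def harvest_fraction(r0: float, fr: float) -> float:
    """Removable population fraction per year: ``Fp = 0.5 * r0 * Fr``."""
    PBRPolicy(fr=fr, r0_reference=r0).validate()
    return 0.5 * r0 * fr


def simulate_pbr(
    model: DDModel,
    policy: PBRPolicy,
    *,
    n_reps: int = 1000,
    seed: int = 0,
    burn_in: int | None = None,
    window: int | None = None,
    zero_sd: bool = False,
) -> ResponseSummary:
    """Responses of r0 and N* under constant PBR removal vs no removal.

    Each year, after the matrix transition, every age class loses the
    fraction ``0.5 * r0_ref * Fr`` of its count.  Requires a calibrated
    model with ``lambda0 > 1``.
    """
    policy.validate()
    if model.lambda0 <= 1.0:
        raise PolicyUndefinedError(
            f"PBR harvesting needs lambda0 > 1, got {model.lambda0}"
        )
    kwargs: dict = dict(n_reps=n_reps, seed=seed, zero_sd=zero_sd)
    if burn_in is not None:
        kwargs["burn_in"] = burn_in
    if window is not None:
        kwargs["window"] = window
    return response_summary(
        model,
        model,
        treated_harvest_fraction=policy.harvest_fraction,
        **kwargs,
    )


def fr_sweep(
    fixtures: Iterable[VitalRateSet],
    lambda0_grid: Sequence[float],
    fr_grid: Sequence[float],
    *,
    n_reps: int = 200,
    seed: int = 0,
    burn_in: int | None = None,
    window: int | None = None,
    zero_sd: bool = False,
) -> pd.DataFrame:
    """Response table over the fixtures x lambda0 x Fr cross-product.

    One row per combination with both response percentages.  The
    deviation of the whole table from the ``-Fr/2`` approximation is
    available via :func:`minus_fr_half_deviation`.
    """
    if not lambda0_grid or not fr_grid:
        raise ValueError("lambda0_grid and fr_grid must be non-empty")
    from .density_dependence import equilibrium_profile, leftover_r0

    kwargs: dict = dict(n_reps=n_reps, seed=seed, zero_sd=zero_sd)
    if burn_in is not None:
        kwargs["burn_in"] = burn_in
    if window is not None:
        kwargs["window"] = window
    rows = []
    for v in fixtures:
        for lam0 in lambda0_grid:
            model = DDModel.build(v, lam0)
            policies = [
                PBRPolicy(fr=fr, r0_reference=lam0 - 1.0).validate() for fr in fr_grid
            ]
            if model.lambda0 <= 1.0:
                raise PolicyUndefinedError(
                    f"PBR harvesting needs lambda0 > 1, got {model.lambda0}"
                )
            fps = [p.harvest_fraction for p in policies]
            # one batched run: baseline plus every harvest level, paired draws
            nstars = equilibrium_profile(
                model, x_levels=0.0, harvest_levels=[0.0] + fps, **kwargs
            )
            r0_base = leftover_r0(model)
            for fr, fp, nstar in zip(fr_grid, fps, nstars[1:]):
                r0_treated = leftover_r0(model, harvest_fraction=fp)
                if nstars[0] > 0:
                    nstar_resp = max(-100.0, 100.0 * (nstar - nstars[0]) / nstars[0])
                else:  # baseline itself extinct: response undefined
                    nstar_resp = float("nan")
                rows.append(
                    (
                        v.species,
                        v.population,
                        v.period,
                        lam0,
                        fr,
                        100.0 * (r0_treated - r0_base) / r0_base,
                        nstar_resp,
                    )
                )
    return pd.DataFrame(rows, columns=RESPONSE_COLUMNS)


def minus_fr_half_deviation(table: pd.DataFrame) -> float:
    """Max absolute gap (fraction scale) between responses and ``-Fr/2``."""
    if table.empty:
        return 0.0
    gaps = [
        np.nanmax(np.abs(table[col] / 100.0 + table["fr"] / 2.0))
        for col in ("r0_response_pct", "nstar_response_pct")
    ]
    return float(max(gaps))
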
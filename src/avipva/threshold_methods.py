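"""Scalar allowable-mortality rule and its comparison to full matrix models.

The rule: with low-density growth rate ``r0`` and an acceptable
proportional reduction ``R`` of the equilibrium density, the annual kill
fraction ``Fp ~= r0 * R`` keeps the reduction near ``R``.  It coincides
with the PBR fraction at recovery factor ``Fr = 2R``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .demography_io import VitalRateSet
from .density_dependence import DDModel, equilibrium_profile
from .errors import PolicyUndefinedError, UndefinedStatisticError
from .leslie_model import apply_extra_mortality, build_matrix, dominant_eigen

COMPARISON_COLUMNS = [
    "species",
    "population",
    "period",
    "lambda0",
    "mortality_pct",
    "matrix_response",
    "minimodel_response",
    "extinct",
]


@dataclass(frozen=True)
class AllowableMortalityQuery:
    """Inputs of the scalar rule: r0 > 0 and acceptable reduction R in [0, 1)."""

    r0: float
    r_nstar: float

    def validate(self) -> "AllowableMortalityQuery":
        if self.r0 <= 0:
            raise PolicyUndefinedError(
                f"the allowable-mortality rule needs r0 > 0, got {self.r0}"
            )
        if not 0.0 <= self.r_nstar < 1.0:
            raise ValueError(f"acceptable reduction must be in [0, 1), got {self.r_nstar}")
        return self


def allowable_fraction(query: AllowableMortalityQuery) -> float:
    """Allowable annual kill fraction ``Fp = r0 * R``."""
    query.validate()
    return query.r0 * query.r_nstar


def ornis_criterion_mortality(v: VitalRateSet, pct: float) -> float:
    """Extra-mortality fraction x for a %-of-natural-mortality criterion.

    A criterion of ``pct`` percent scales every cohort's mortality by
    ``1 + pct/100``; the returned x feeds the projection scenarios.
    ``v`` identifies the population the criterion is applied to (the
    mapping itself is rate-independent).
    """
    if pct < 0:
        raise ValueError(f"pct must be >= 0, got {pct}")
    return pct / 100.0


def implied_kill_fraction(
    model: DDModel, x: float, method: str = "lambda_drop"
) -> float:
    """Scalar per-year kill fraction equivalent to extra mortality ``x``.

    The %-criterion scales each cohort's mortality; the scalar rule needs
    a single fraction.  The default ``'lambda_drop'`` uses the exact
    proportional drop of the calibrated growth rate,
    ``1 - lambda(x)/lambda(0)`` — the uniform removal fraction with the
    same demographic effect.  ``'stable_age'`` instead returns ``x``
    times the mean natural mortality across classes weighted by the
    stable age distribution (the fraction of standing individuals killed
    per year, which ignores which classes the deaths fall on).
    """
    v = model.vital
    if method == "lambda_drop":
        lam0 = dominant_eigen(
            build_matrix(v, fecundity_scale=model.recruitment_scalar)
        )[0]
        lam_x = dominant_eigen(
            build_matrix(
                apply_extra_mortality(v, x),
                fecundity_scale=model.recruitment_scalar,
            )
        )[0]
        return float(1.0 - lam_x / lam0)
    if method != "stable_age":
        raise ValueError(f"unknown method {method!r}")
    _, w = dominant_eigen(
        build_matrix(v, fecundity_scale=model.recruitment_scalar)
    )
    mortality = np.array(
        [1.0 - v.survival_for_class(j).mean for j in range(v.n_classes)]
    )
    return float(x * (w * mortality).sum())


def compare_minimodel_vs_matrix(
    fixtures: Iterable[VitalRateSet],
    lambda0_grid: Sequence[float] = (1.01, 1.03, 1.1),
    mortality_pcts: Sequence[float] = (1.0, 2.0, 5.0, 10.0),
    *,
    n_reps: int = 200,
    seed: int = 0,
    burn_in: int | None = None,
    window: int | None = None,
    zero_sd: bool = False,
) -> pd.DataFrame:
    """Pair matrix-model N* responses with the scalar-rule prediction.

    One row per fixture x lambda0 x mortality level (fractions, signed;
    matrix responses floored at -1).  Rows at the extinction floor are
    flagged; they censor the linear relation and are excluded from the
    regression summary.
    """
    rows = []
    kwargs: dict = dict(n_reps=n_reps, seed=seed, zero_sd=zero_sd)
    if burn_in is not None:
        kwargs["burn_in"] = burn_in
    if window is not None:
        kwargs["window"] = window
    for v in fixtures:
        for lam0 in lambda0_grid:
            model = DDModel.build(v, lam0)
            xs = [ornis_criterion_mortality(v, pct) for pct in mortality_pcts]
            nstars = equilibrium_profile(model, x_levels=[0.0] + xs, **kwargs)
            nstar_base = nstars[0]
            for pct, x, nstar_treated in zip(mortality_pcts, xs, nstars[1:]):
                if nstar_base > 0:
                    matrix_resp = max(-1.0, (nstar_treated - nstar_base) / nstar_base)
                else:  # baseline itself extinct: comparison undefined
                    matrix_resp = float("nan")
                mini_resp = -implied_kill_fraction(model, x) / (lam0 - 1.0)
                censored = not nstar_base > 0 or matrix_resp <= -1.0 + 1e-9
                rows.append(
                    (
                        v.species,
                        v.population,
                        v.period,
                        lam0,
                        pct,
                        matrix_resp,
                        mini_resp,
                        censored,
                    )
                )
    return pd.DataFrame(rows, columns=COMPARISON_COLUMNS)


def minimodel_regression(
    table: pd.DataFrame, max_abs_response: float | None = None
) -> tuple[float, float]:
    """Least-squares slope and intercept of matrix vs scalar-rule responses.

    Uses the non-extinct rows; ``max_abs_response`` optionally restricts
    to small responses where the linearization is meaningful.
    """
    sub = table[~table["extinct"]].dropna(subset=["matrix_response"])
    if max_abs_response is not None:
        sub = sub[sub["minimodel_response"].abs() <= max_abs_response]
        sub = sub[sub["matrix_response"].abs() <= max_abs_response]
    if len(sub) < 2:
        raise UndefinedStatisticError("not enough non-extinct rows for a regression")
    slope, intercept = np.polyfit(
        sub["minimodel_response"].to_numpy(), sub["matrix_response"].to_numpy(), 1
    )
    return float(slope), float(intercept)
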
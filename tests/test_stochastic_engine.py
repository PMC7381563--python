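import numpy as np
import pytest
from scipy.stats import norm

from avipva.errors import UndefinedStatisticError
from avipva.leslie_model import apply_extra_mortality, growth_rate
from avipva.stochastic_engine import (
    ProjectionConfig,
    decline_after_10_years,
    draw_annual_rates,
    project,
)

from .conftest import scale_sds, strip_sds


def clipped_normal_mean(mu, sigma, lo=0.0, hi=1.0):
    """Closed-form mean of a normal draw clamped to [lo, hi]."""
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return (
        lo * norm.cdf(a)
        + hi * norm.sf(b)
        + mu * (norm.cdf(b) - norm.cdf(a))
        - sigma * (norm.pdf(b) - norm.pdf(a))
    )


def deterministic_decline(v, x, years=10):
    lam = growth_rate(v)
    lam_x = growth_rate(apply_extra_mortality(v, x))
    return 100.0 * (1.0 - (lam_x / lam) ** years)


# ---------------------------------------------------------------------------
# draw_annual_rates
# ---------------------------------------------------------------------------


def test_draws_degenerate_at_zero_sd(starling1):
    v = strip_sds(starling1)
    out = draw_annual_rates(v, np.random.default_rng(0))
    assert out == v


def test_draws_stay_in_bounds_and_unbiased(starling1):
    rng = np.random.default_rng(42)
    fy = np.array(
        [
            draw_annual_rates(starling1, rng).survival_by_label["first_year"].mean
            for _ in range(20_000)
        ]
    )
    assert fy.min() >= 0.0 and fy.max() <= 1.0
    se = 0.035 / np.sqrt(len(fy))
    assert abs(fy.mean() - 0.331) < 3 * se


def test_draw_clipping_matches_analytic_mean(starling3):
    # older-bird survival 0.607 +- 0.151 clips visibly at the unit bound
    rng = np.random.default_rng(7)
    draws = np.array(
        [
            draw_annual_rates(starling3, rng).survival_by_label["older"].mean
            for _ in range(100_000)
        ]
    )
    assert draws.min() >= 0.0 and draws.max() <= 1.0
    assert draws.mean() == pytest.approx(clipped_normal_mean(0.607, 0.151), abs=0.005)


def test_fledgling_draws_non_negative(catalog):
    tern = catalog.get("Common Tern")  # m 1.294 +- 1.024: clips at zero often
    rng = np.random.default_rng(1)
    ms = np.array([draw_annual_rates(tern, rng).fledglings_mean for _ in range(5000)])
    assert ms.min() >= 0.0
    assert (ms == 0.0).any()  # the clip is actually exercised


# ---------------------------------------------------------------------------
# project
# ---------------------------------------------------------------------------


def test_deterministic_limit_matches_matrix_power(catalog):
    for rec in catalog:
        v = strip_sds(rec)
        res = project(v, ProjectionConfig(years=10, n_reps=3, seed=0))
        expected = 1000.0 * growth_rate(v) ** 10
        assert res.mean_total_at(10) == pytest.approx(expected, rel=1e-9), rec.key


def test_starling_decline_scalar_power_oracle(starling3):
    v = strip_sds(starling3)
    res = project(v, ProjectionConfig(years=10, n_reps=1, seed=0))
    lam = 0.607 + 0.102 * 3.73 / 2.0  # 0.79723
    assert res.mean_total_at(10) == pytest.approx(1000.0 * lam**10, rel=1e-9)
    assert res.mean_total_at(10) == pytest.approx(103.7, abs=0.2)


def test_year_zero_total_is_initial_population(starling1):
    res = project(starling1, ProjectionConfig(years=3, n_reps=10, seed=0))
    np.testing.assert_allclose(res.totals[0], 1000.0, rtol=1e-12)


def test_same_seed_is_bit_identical(starling2):
    cfg = ProjectionConfig(years=20, n_reps=50, seed=123, extra_mortality_x=0.02)
    a = project(starling2, cfg)
    b = project(starling2, cfg)
    assert (a.totals == b.totals).all()
    assert (a.state_at_10 == b.state_at_10).all()


def test_config_validation():
    with pytest.raises(ValueError):
        ProjectionConfig(years=0).validate()
    with pytest.raises(ValueError):
        ProjectionConfig(n_reps=0).validate()
    with pytest.raises(ValueError):
        ProjectionConfig(extra_mortality_x=-0.1).validate()


# ---------------------------------------------------------------------------
# decline_after_10_years
# ---------------------------------------------------------------------------


def test_decline_zero_for_identical_runs(starling1):
    cfg = ProjectionConfig(years=10, n_reps=20, seed=5)
    res = project(starling1, cfg)
    assert decline_after_10_years(res, res) == 0.0


def test_decline_deterministic_oracle(starling3):
    v = strip_sds(starling3)
    base = project(v, ProjectionConfig(years=10, n_reps=1, seed=0))
    treated = project(
        v, ProjectionConfig(years=10, n_reps=1, seed=0, extra_mortality_x=0.01)
    )
    # arithmetic oracle from the closed-form two-class growth rates
    lam = 0.607 + 0.102 * 1.865
    lam_x = (1 - 0.393 * 1.01) + (1 - 0.898 * 1.01) * 1.865
    expected = 100.0 * (1.0 - (lam_x / lam) ** 10)
    assert decline_after_10_years(base, treated) == pytest.approx(expected, rel=1e-9)
    assert expected == pytest.approx(23.1, abs=0.1)


def test_decline_stochastic_near_paper_range(starling3):
    base = project(starling3, ProjectionConfig(years=10, n_reps=10_000, seed=2))
    treated = project(
        starling3,
        ProjectionConfig(years=10, n_reps=10_000, seed=2, extra_mortality_x=0.01),
    )
    assert decline_after_10_years(base, treated) == pytest.approx(23.5, abs=1.5)


def test_decline_invariant_to_initial_population(starling2):
    declines = []
    for n0 in (100.0, 1000.0):
        base = project(
            starling2,
            ProjectionConfig(years=10, n_reps=500, seed=9, initial_population=n0),
        )
        treated = project(
            starling2,
            ProjectionConfig(
                years=10, n_reps=500, seed=9, initial_population=n0,
                extra_mortality_x=0.05,
            ),
        )
        declines.append(decline_after_10_years(base, treated))
    # the model is linear in the state, so the statistic is exactly invariant
    assert declines[0] == pytest.approx(declines[1], rel=1e-9)


def test_decline_monotone_in_extra_mortality(catalog):
    for rec in catalog:
        base = project(rec, ProjectionConfig(years=10, n_reps=2000, seed=3))
        declines = [
            decline_after_10_years(
                base,
                project(
                    rec,
                    ProjectionConfig(
                        years=10, n_reps=2000, seed=3, extra_mortality_x=x
                    ),
                ),
            )
            for x in (0.0, 0.01, 0.02, 0.05, 0.10)
        ]
        assert declines[0] == 0.0
        assert all(a <= b + 1e-9 for a, b in zip(declines, declines[1:])), rec.key


def test_slow_species_decline_band(catalog):
    """1% extra mortality: declines of the late-maturing species.

    The Marsh Harrier, Spoonbill, Stork and Eagle records sit in the
    2-3% band; the Godwit records, whose first-year mortality is very
    large (0.831), respond by ~7% under the stated construction — the
    value is frozen from the deterministic oracle rather than the 2-3%
    band the source narrative claims for them.
    """
    slow = {
        "Marsh Harrier": (1.5, 4.0),
        "Eurasian Spoonbill": (1.5, 4.0),
        "White Stork": (1.5, 4.0),
        "White-tailed Eagle": (1.5, 4.0),
        "Black-tailed Godwit": (6.0, 8.5),
    }
    for rec in catalog:
        if rec.species not in slow:
            continue
        lo, hi = slow[rec.species]
        base = project(rec, ProjectionConfig(years=10, n_reps=3000, seed=4))
        treated = project(
            rec,
            ProjectionConfig(years=10, n_reps=3000, seed=4, extra_mortality_x=0.01),
        )
        d = decline_after_10_years(base, treated)
        assert lo <= d <= hi, (rec.key, d)
        assert d == pytest.approx(deterministic_decline(rec, 0.01), abs=1.0)


def test_mean_matches_deterministic_at_small_noise(starling2):
    v = scale_sds(starling2, 0.1)
    res = project(v, ProjectionConfig(years=10, n_reps=4000, seed=6))
    expected = 1000.0 * growth_rate(v) ** 10
    assert res.mean_total_at(10) == pytest.approx(expected, rel=0.01)


def test_decline_requires_ten_years(starling1):
    short = project(starling1, ProjectionConfig(years=5, n_reps=5, seed=0))
    with pytest.raises(ValueError):
        decline_after_10_years(short, short)


def test_decline_undefined_for_zero_baseline(starling1):
    res = project(starling1, ProjectionConfig(years=10, n_reps=5, seed=0))
    dead = project(starling1, ProjectionConfig(years=10, n_reps=5, seed=0))
    dead.totals[:] = 0.0
    with pytest.raises(UndefinedStatisticError):
        decline_after_10_years(dead, res)
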
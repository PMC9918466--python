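"""Saturating growth-curve fitting for carbon accumulation chronosequences.

Three classic stand-growth families are supported, each giving carbon density
C (Mg C ha^-1) as a function of stand age (years):

* Von Bertalanffy:      C = Asym * (1 - exp(-b * (Age - c)))
* Gompertz:             C = Asym * exp(-b * c**Age)
* Chapman-Richards:     C = Asym * (1 - exp(-b * Age))**c

``Asym`` is the asymptotic carbon density the stand approaches; ``b`` and
``c`` set the shape and position of the approach. For carbon pools that are
non-zero before restoration (sediment carbon, and hence total ecosystem
carbon) an additive baseline is added: C(age) = baseline + f(age). The
Chapman-Richards family forces zero density at age 0 and therefore does not
admit a baseline pool.

Carbon-density scatter in chronosequences is multiplicative: the spread at
100 Mg C ha^-1 dwarfs the spread at 5 Mg C ha^-1. Fits therefore default to
least squares on log densities (a lognormal error model with constant
coefficient of variation), which weights young, low-density stands properly;
``error_model="gaussian"`` gives classical constant-variance least squares
on the raw scale. Model comparison uses AIC from the Gaussian log-likelihood
on the fitting scale with the residual variance profiled out,
k = (#curve parameters) + 1 for the variance; AICs are only comparable
between fits sharing the error model. Uncertainty bands are percentile
bootstrap over sites (resampling sites with replacement and refitting).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .data_io import Pathway, SiteRecord

POOLS = ("agc", "bgc", "scs", "tecs")

#: pools that carry a pre-restoration (non-zero) baseline stock
BASELINE_POOLS = ("scs", "tecs")

#: convention pairing control sites to a pathway via their prior land use
CONTROL_PRIOR_USE = {"reforestation": "abandoned_pond", "afforestation": "mudflat"}


class GrowthFamily(str, Enum):
    von_bertalanffy = "von_bertalanffy"
    gompertz = "gompertz"
    chapman_richards = "chapman_richards"


#: tie-break order for AIC selection (after preferring fewer parameters)
FAMILY_ORDER = [GrowthFamily.von_bertalanffy, GrowthFamily.gompertz,
                GrowthFamily.chapman_richards]

SUPPORTS_BASELINE = {
    GrowthFamily.von_bertalanffy: True,
    GrowthFamily.gompertz: True,
    GrowthFamily.chapman_richards: False,
}


class FitError(RuntimeError):
    pass


class InsufficientDataError(FitError):
    pass


def _f_von_bertalanffy(age, asym, b, c):
    return asym * (1.0 - np.exp(-b * (age - c)))


def _f_gompertz(age, asym, b, c):
    return asym * np.exp(-b * np.power(c, age))


def _f_chapman_richards(age, asym, b, c):
    return asym * np.power(1.0 - np.exp(-b * age), c)


_CURVES = {
    GrowthFamily.von_bertalanffy: _f_von_bertalanffy,
    GrowthFamily.gompertz: _f_gompertz,
    GrowthFamily.chapman_richards: _f_chapman_richards,
}


def _validate_params(family: GrowthFamily, asym: float, b: float, c: float) -> None:
    if asym <= 0:
        raise ValueError(f"asym must be > 0, got {asym}")
    if b <= 0:
        raise ValueError(f"b must be > 0, got {b}")
    if family is GrowthFamily.gompertz and not 0 < c < 1:
        raise ValueError(f"gompertz c must be in (0, 1) for an increasing curve, got {c}")
    if family is GrowthFamily.chapman_richards and c <= 0:
        raise ValueError(f"chapman_richards c must be > 0, got {c}")


def eval_growth(family: GrowthFamily, asym: float, b: float, c: float,
                baseline: float = 0.0, age: float | np.ndarray = 0.0):
    """Evaluate a growth curve (with additive baseline) at the given age(s)."""
    family = GrowthFamily(family)
    _validate_params(family, asym, b, c)
    if baseline != 0.0 and not SUPPORTS_BASELINE[family]:
        raise ValueError(f"{family.value} does not admit a non-zero baseline")
    age = np.asarray(age, dtype=float)
    if np.any(age < 0):
        raise ValueError("age must be >= 0")
    out = baseline + _CURVES[family](age, asym, b, c)
    return float(out) if out.ndim == 0 else out


@dataclass
class GrowthFit:
    """A fitted growth curve for one carbon pool x restoration pathway.

    ``residual_sd`` is on the fitting scale: Mg C ha^-1 for the gaussian
    error model, log units (approximately the CV) for the lognormal one.
    """

    family: GrowthFamily
    asym: float
    b: float
    c: float
    baseline: float = 0.0
    baseline_fitted: bool = False
    n_obs: int = 0
    aic: float = math.nan
    residual_sd: float = math.nan
    converged: bool = False
    error_model: str = "lognormal"
    pool: str = ""
    pathway: str = ""
    message: str = ""

    @property
    def n_params(self) -> int:
        return 3 + (1 if self.baseline_fitted else 0)

    def predict(self, age):
        return eval_growth(self.family, self.asym, self.b, self.c, self.baseline, age)

    def increment(self, age):
        """Carbon density increment since the year-0 baseline condition."""
        return increment_since_baseline(self, age)

    def to_json(self) -> str:
        d = asdict(self)
        d["family"] = self.family.value
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GrowthFit":
        d = json.loads(text)
        d["family"] = GrowthFamily(d["family"])
        return cls(**d)


@dataclass
class PredictionBand:
    """Bootstrap percentile band for a fitted curve on an age grid."""

    ages: np.ndarray
    point: np.ndarray
    lo2p5: np.ndarray
    hi97p5: np.ndarray
    n_boot: int
    seed: int
    family: GrowthFamily = GrowthFamily.gompertz
    n_failed: int = 0

    def curve(self, which: str):
        """Interpolator for the 'point', 'lo2p5' or 'hi97p5' curve."""
        values = getattr(self, which)
        return lambda age: np.interp(age, self.ages, values)


def _usable_pairs(records: Iterable[SiteRecord], pool: str, pathway: str):
    ages, values = [], []
    for r in records:
        if r.pathway.value != pathway:
            continue
        v = getattr(r, pool)
        if v is None or not math.isfinite(r.age_years):
            continue
        ages.append(r.age_years)
        values.append(v)
    return np.asarray(ages, float), np.asarray(values, float)


def control_baseline(records: Iterable[SiteRecord], pool: str, pathway: str) -> Optional[float]:
    """Mean pool density over paired control sites for a pathway, or None.

    Control rows are matched to a pathway through their ``prior_land_use``
    (abandoned_pond -> reforestation, mudflat -> afforestation by default).
    """
    want = CONTROL_PRIOR_USE.get(pathway)
    vals = [
        getattr(r, pool)
        for r in records
        if r.pathway is Pathway.control
        and getattr(r, pool) is not None
        and (want is None or r.prior_land_use == want)
    ]
    return float(np.mean(vals)) if vals else None


# multi-start grids; asym always starts at 1.2 x max observed density
_B_STARTS = (0.1, 0.5, 1.0, 2.0)
_C_STARTS = {
    GrowthFamily.gompertz: (0.3, 0.6, 0.9),
    GrowthFamily.von_bertalanffy: (-5.0, 0.0, 5.0),
    GrowthFamily.chapman_richards: (0.5, 1.0, 2.0),
}

_EPS = 1e-8


def _bounds(family: GrowthFamily, fit_baseline: bool, y_max: float):
    lo = [_EPS, _EPS, {"gompertz": _EPS, "von_bertalanffy": -np.inf,
                       "chapman_richards": _EPS}[family.value]]
    hi = [np.inf, np.inf, {"gompertz": 1 - _EPS, "von_bertalanffy": np.inf,
                           "chapman_richards": np.inf}[family.value]]
    if fit_baseline:
        lo.append(0.0)
        hi.append(np.inf)
    return lo, hi


def fit_curve(
    ages: np.ndarray,
    values: np.ndarray,
    family: GrowthFamily,
    *,
    with_baseline: bool = False,
    baseline: Optional[float] = None,
    error_model: str = "lognormal",
    starts: Optional[Sequence[Sequence[float]]] = None,
) -> GrowthFit:
    """Nonlinear least-squares fit of one family to (age, density) pairs.

    ``with_baseline`` adds the additive year-0 offset; if ``baseline`` is
    given it is held fixed, otherwise it is a free parameter. The default
    ``error_model="lognormal"`` minimises squared residuals of log density
    (constant-CV noise); ``"gaussian"`` minimises them on the raw scale.
    Multi-start initialisation guards against local minima; non-convergence
    is reported on the returned fit, never silently.
    """
    family = GrowthFamily(family)
    ages = np.asarray(ages, float)
    values = np.asarray(values, float)
    if with_baseline and not SUPPORTS_BASELINE[family]:
        raise ValueError(f"{family.value} defines zero density at age 0; no baseline pool")
    if error_model not in ("lognormal", "gaussian"):
        raise ValueError(f"error_model must be 'lognormal' or 'gaussian', got {error_model!r}")
    n = len(ages)
    fit_baseline = with_baseline and baseline is None
    n_params = 3 + (1 if fit_baseline else 0)
    if n < n_params + 1:
        raise InsufficientDataError(f"need >= {n_params + 1} (age, density) pairs, got {n}")
    if np.ptp(ages) == 0:
        raise InsufficientDataError("all ages identical; cannot fit a growth curve")

    offset = baseline if (with_baseline and baseline is not None) else 0.0
    base_f = _CURVES[family]
    if fit_baseline:
        def density(age, asym, b, c, base):
            return base + base_f(age, asym, b, c)
    else:
        def density(age, asym, b, c):
            return offset + base_f(age, asym, b, c)

    if error_model == "lognormal":
        if np.any(values <= 0):
            raise ValueError(
                "lognormal error model needs strictly positive densities; "
                "use error_model='gaussian' or drop zero rows"
            )
        target = np.log(values)

        def model(age, *p):
            return np.log(np.maximum(density(age, *p), 1e-12))
    else:
        target = values
        model = density

    spread = max(float(np.max(values)) - offset, _EPS)
    asym0 = max(1.2 * spread, _EPS)
    if starts is None:
        starts = []
        for b0 in _B_STARTS:
            for c0 in _C_STARTS[family]:
                p0 = [asym0, b0, c0]
                if fit_baseline:
                    p0.append(max(float(np.min(values)), _EPS))
                starts.append(p0)
    bounds = _bounds(family, fit_baseline, float(np.max(values)))

    best_popt, best_rss = None, np.inf
    for p0 in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(model, ages, target, p0=p0, bounds=bounds,
                                    method="trf", maxfev=5000)
            rss = float(np.sum((target - model(ages, *popt)) ** 2))
            if math.isfinite(rss) and rss < best_rss:
                best_rss, best_popt = rss, popt
        except (RuntimeError, ValueError):
            continue

    if best_popt is None:
        return GrowthFit(family=family, asym=math.nan, b=math.nan, c=math.nan,
                         baseline=offset, baseline_fitted=fit_baseline, n_obs=n,
                         converged=False, error_model=error_model,
                         message="no start converged")

    asym, b, c = (float(v) for v in best_popt[:3])
    base_val = float(best_popt[3]) if fit_baseline else offset
    rss = max(best_rss, _EPS)  # guard log(0) on noise-free data
    k = n_params + 1  # + residual variance
    aic = n * math.log(2 * math.pi * rss / n) + n + 2 * k
    dof = max(n - n_params, 1)
    return GrowthFit(
        family=family, asym=asym, b=b, c=c, baseline=base_val,
        baseline_fitted=fit_baseline, n_obs=n, aic=aic,
        residual_sd=math.sqrt(best_rss / dof), converged=True,
        error_model=error_model,
    )


def fit_growth_model(
    records: Iterable[SiteRecord],
    pool: str,
    pathway: str,
    family: GrowthFamily,
    *,
    with_baseline: Optional[bool] = None,
    baseline: Optional[float] = None,
    error_model: str = "lognormal",
) -> GrowthFit:
    """Fit one growth family to a pool x pathway slice of the site table.

    For baseline pools (scs, tecs) the year-0 offset defaults to the mean of
    the paired control sites when such sites exist, otherwise it is fitted as
    a free parameter.
    """
    records = list(records)
    if pool not in POOLS:
        raise ValueError(f"pool must be one of {POOLS}, got {pool!r}")
    if with_baseline is None:
        with_baseline = pool in BASELINE_POOLS
    if with_baseline and baseline is None:
        baseline = control_baseline(records, pool, pathway)
    ages, values = _usable_pairs(records, pool, pathway)
    fit = fit_curve(ages, values, family, with_baseline=with_baseline,
                    baseline=baseline, error_model=error_model)
    fit.pool, fit.pathway = pool, pathway
    return fit


def select_by_aic(fits: Sequence[GrowthFit]) -> GrowthFit:
    """Minimum-AIC converged fit; ties to fewer parameters, then family order."""
    converged = [f for f in fits if f.converged and math.isfinite(f.aic)]
    if not converged:
        raise FitError("no converged fit to select from")
    if len({f.error_model for f in converged}) > 1:
        raise ValueError("AICs are not comparable across error models")
    return min(
        converged,
        key=lambda f: (f.aic, f.n_params, FAMILY_ORDER.index(f.family)),
    )


def increment_since_baseline(fit: GrowthFit, age) -> float | np.ndarray:
    """Density increment relative to the age-0 condition: C(age) - C(0)."""
    return fit.predict(age) - fit.predict(0.0)


def bootstrap_prediction_band(
    records: Iterable[SiteRecord],
    pool: str,
    pathway: str,
    family: GrowthFamily,
    n_boot: int,
    seed: int,
    ages: Optional[np.ndarray] = None,
    *,
    with_baseline: Optional[bool] = None,
    baseline: Optional[float] = None,
    error_model: str = "lognormal",
) -> PredictionBand:
    """Site-resampling percentile bootstrap band (2.5/97.5) on an age grid.

    Each replicate resamples sites with replacement and refits, started from
    the full-data estimates. More than 50% replicate failures aborts.
    """
    records = list(records)
    if ages is None:
        ages = np.arange(0.0, 41.0)
    ages = np.asarray(ages, float)
    full = fit_growth_model(records, pool, pathway, family,
                            with_baseline=with_baseline, baseline=baseline,
                            error_model=error_model)
    if not full.converged:
        raise FitError(f"full-data fit did not converge: {full.message}")
    xs, ys = _usable_pairs(records, pool, pathway)
    rng = np.random.default_rng(seed)
    p0 = [full.asym, full.b, full.c]
    if full.baseline_fitted:
        p0.append(full.baseline)
    fixed_baseline = None if full.baseline_fitted else (
        full.baseline if full.baseline != 0.0 or pool in BASELINE_POOLS else None
    )
    with_base = full.baseline_fitted or fixed_baseline is not None
    curves, n_failed = [], 0
    n = len(xs)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            rep = fit_curve(xs[idx], ys[idx], family,
                            with_baseline=with_base, baseline=fixed_baseline,
                            error_model=error_model, starts=[p0])
            if not rep.converged:
                raise FitError(rep.message)
            curves.append(rep.predict(ages))
        except (FitError, InsufficientDataError):
            n_failed += 1
    if n_boot > 0 and n_failed > 0.5 * n_boot:
        raise FitError(
            f"{n_failed}/{n_boot} bootstrap replicates failed to converge; "
            "consider a smaller model or more data"
        )
    stack = np.vstack(curves) if curves else np.empty((0, len(ages)))
    lo = np.percentile(stack, 2.5, axis=0)
    hi = np.percentile(stack, 97.5, axis=0)
    return PredictionBand(ages=ages, point=np.asarray(full.predict(ages)),
                          lo2p5=lo, hi97p5=hi, n_boot=n_boot, seed=seed,
                          family=family, n_failed=n_failed)


@dataclass
class LogAgeModelResult:
    """OLS fit of density ~ log(age) x pathway + region indicators."""

    table: pd.DataFrame
    interaction_coef: float
    interaction_p: float
    n_obs: int
    n_dropped_age0: int = 0


def log_age_pathway_model(records: Iterable[SiteRecord], pool: str) -> LogAgeModelResult:
    """Test whether carbon-accumulation trajectories differ between pathways.

    Fixed-effects least squares of pool density on log(age), pathway, their
    interaction, and region indicators; the interaction coefficient measures
    the pathway difference in log-age slope. Age-0 rows are excluded (log
    domain) with a notice.
    """
    import statsmodels.formula.api as smf

    rows = []
    n_zero = 0
    for r in records:
        if r.pathway is Pathway.control:
            continue
        v = getattr(r, pool)
        if v is None:
            continue
        if r.age_years <= 0:
            n_zero += 1
            continue
        rows.append({"density": v, "age": r.age_years,
                     "pathway": r.pathway.value, "region": r.region or "unknown"})
    if n_zero:
        warnings.warn(f"excluded {n_zero} age-0 rows from log-age model", stacklevel=2)
    df = pd.DataFrame(rows)
    if df.empty or df["pathway"].nunique() < 2:
        raise ValueError("both restoration pathways are required for the interaction model")
    formula = "density ~ np.log(age) * C(pathway, Treatment('afforestation'))"
    if df["region"].nunique() > 1:
        formula += " + C(region)"
    res = smf.ols(formula, data=df).fit()
    table = pd.DataFrame({"coef": res.params, "se": res.bse,
                          "t": res.tvalues, "p": res.pvalues})
    inter = [ix for ix in table.index if ix.startswith("np.log(age):")]
    if len(inter) != 1:
        raise RuntimeError(f"expected one interaction term, found {inter}")
    return LogAgeModelResult(
        table=table,
        interaction_coef=float(table.loc[inter[0], "coef"]),
        interaction_p=float(table.loc[inter[0], "p"]),
        n_obs=int(res.nobs),
        n_dropped_age0=n_zero,
    )
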
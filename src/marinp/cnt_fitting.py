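"""Maximum-likelihood estimation of CNT contact-angle-distribution parameters.

Fits (mu_theta, sigma_theta, log10 n_max) of :class:`~marinp.cnt_model.CNTParams`
to one or more droplet-freezing assays of the same sample, typically a
dilution series.  The objective is the exact censored-data likelihood of the
observed freezing temperatures: on a descending grid T_0 > T_1 > ... each
droplet contributes the probability of freezing in its interval,
f(T_i) - f(T_{i-1}), or of staying liquid to the end, 1 - f(T_end), with
f(T) the CNT forward model.  This handles f -> 0 and censored f -> 1 bins
without ad hoc weighting.

The likelihood is multi-modal in (mu_theta, sigma_theta); a documented
multi-start grid with seeded jitter guards against local optima.  Optimization
runs over (mu_theta, log sigma_theta, log10 n_max) so positivity is built in.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import minimize

from .assay_spectra import FreezingAssay, SampleChemistry, Spectrum, default_grid
from .cnt_model import (
    ActivationTable,
    CNTParams,
    ThermoParams,
    WATER_ICE_DEFAULT,
    site_density_curve,
)

__all__ = ["FitResult", "fit_cnt", "ensemble_spread"]

#: multi-start grid over the mean contact angle [rad]
MU_STARTS = (1.2, 1.6, 2.0, 2.4)
#: multi-start offsets added to the data-driven log10 n_max guess
LGN_OFFSETS = (0.3, 1.0)
#: optimizer box (mu_theta [rad], ln sigma_theta, log10 n_max around guess)
MU_BOUNDS = (0.2, 3.0)
SIGMA_BOUNDS = (0.03, 1.2)


@dataclass
class FitResult:
    """Outcome of one CNT fit."""

    params: CNTParams
    loglik: float
    n_obs: int
    converged: bool
    covariance_proxy: dict          # per-parameter bootstrap (or empty) sd
    fit_basis: str
    sample_id: str
    thermo_name: str = WATER_ICE_DEFAULT.name

    def site_density(self, temperature_grid,
                     thermo: ThermoParams = WATER_ICE_DEFAULT) -> np.ndarray:
        return site_density_curve(self.params, thermo, temperature_grid)


def _interval_counts(assay: FreezingAssay, grid: np.ndarray) -> np.ndarray:
    """Per-interval freeze counts: bin i collects droplets with
    grid[i] <= T_freeze (< grid[i-1] for i > 0)."""
    temps = assay.freezing_temperatures
    if temps.size and temps.min() < grid[-1]:
        raise ValueError(
            "assay contains freezing temperatures below the fit grid; extend the grid"
        )
    cum = np.array([(temps >= t).sum() for t in grid], dtype=int)
    return np.diff(np.concatenate([[0], cum]))


def _basis_concentration(chemistry, sample_id: str, basis: str) -> float:
    if basis == "per_volume":
        return 1.0
    if isinstance(chemistry, dict):
        chem = chemistry[sample_id]
    else:
        chem = chemistry
    conc = chem.basis_concentration(basis)
    if conc is None or conc <= 0:
        raise ValueError(f"sample {sample_id!r}: no usable {basis!r} concentration")
    return conc


def _neg_loglik(x, table: ActivationTable, coef, counts, n_unfrozen):
    mu, log_sig, lgn = x
    p_site = table.p_site(mu, math.exp(log_sig))
    n_max = 10.0 ** lgn
    nll = 0.0
    for c, k, n_cens in zip(coef, counts, n_unfrozen):
        lam = n_max * c * p_site
        f = -np.expm1(-lam)
        q = np.diff(np.concatenate([[0.0], f]))
        nll -= np.sum(k * np.log(np.maximum(q, 1e-300)))
        nll -= n_cens * math.log(max(1.0 - f[-1], 1e-300))
    return nll


def fit_cnt(
    assays: Sequence[FreezingAssay],
    chemistry: Union[SampleChemistry, dict, None],
    thermo: ThermoParams = WATER_ICE_DEFAULT,
    basis: str = "per_c_tccho",
    temperature_grid=None,
    init: Optional[CNTParams] = None,
    bounds: Optional[dict] = None,
    seed: int = 0,
    n_boot: int = 0,
    a_site: float = 1.0e-14,
    delta_t: float = 60.0,
) -> FitResult:
    """Fit CNT contact-angle-distribution parameters to freezing assays.

    Parameters
    ----------
    assays:
        Assays of one sample (e.g. a dilution series).  At least one frozen
        and one unfrozen droplet are required overall.
    chemistry:
        :class:`SampleChemistry` (or mapping sample_id -> chemistry) supplying
        the basis concentration; may be ``None`` for ``basis="per_volume"``.
    basis:
        Normalization basis of the fitted ``n_max``.
    init:
        Optional single starting point; replaces the multi-start grid.
    seed:
        Seeds the jitter of the multi-start grid and the bootstrap.
    n_boot:
        Number of parametric-bootstrap replicates for the uncertainty proxy
        (0 disables; 200 is the recommended production setting).

    Returns the best converged :class:`FitResult`; a non-converged result is
    returned flagged (``converged=False``) rather than raised.
    """
    if len(assays) == 0:
        raise ValueError("need at least one assay")
    sample_id = assays[0].sample_id
    grid = np.asarray(default_grid() if temperature_grid is None else temperature_grid,
                      dtype=float)
    counts = [_interval_counts(a, grid) for a in assays]
    n_frozen = sum(int(k.sum()) for k in counts)
    n_total = sum(a.n_droplets_total for a in assays)
    # no information if nothing froze, or everything froze warmer than the
    # grid start (flat f = 1 everywhere); a fully frozen ramp with spread-out
    # freezing temperatures is still informative
    all_above = all(
        a.freezing_temperatures.size == a.n_droplets_total
        and np.all(a.freezing_temperatures > grid[0])
        for a in assays
    )
    if n_frozen == 0 or all_above:
        raise ValueError("spectrum uninformative: all or no droplets froze")
    n_unfrozen = [a.n_droplets_total - int(k.sum()) for a, k in zip(assays, counts)]
    conc = _basis_concentration(chemistry, sample_id, basis)
    coef = [conc * a.droplet_volume / a.dilution_factor for a in assays]

    table = ActivationTable(grid, thermo, a_site, delta_t)
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 0x5EED])

    # data-driven n_max guess: Vali estimate at the coldest informative bin
    lgn_guess = []
    for a, k, c in zip(assays, counts, coef):
        cum = np.cumsum(k)
        frac = cum / a.n_droplets_total
        ok = (frac > 0) & (frac < 1)
        if ok.any():
            i = np.flatnonzero(ok)[-1]
            lgn_guess.append(math.log10(-math.log1p(-frac[i]) / c))
    lgn0 = max(lgn_guess) if lgn_guess else math.log10(1.0 / min(coef))

    if init is not None:
        starts = [(init.mu_theta, math.log(init.sigma_theta),
                   math.log10(init.n_max))]
    else:
        starts = [
            (mu + rng.normal(0.0, 0.02),
             math.log(0.25) + rng.normal(0.0, 0.05),
             lgn0 + off + rng.normal(0.0, 0.05))
            for mu in MU_STARTS
            for off in LGN_OFFSETS
        ]
    box = [
        (bounds or {}).get("mu_theta", MU_BOUNDS),
        tuple(np.log((bounds or {}).get("sigma_theta", SIGMA_BOUNDS))),
        (bounds or {}).get("log10_n_max", (lgn0 - 4.0, lgn0 + 6.0)),
    ]

    best = None
    for x0 in starts:
        res = minimize(
            _neg_loglik,
            np.clip(x0, [b[0] for b in box], [b[1] for b in box]),
            args=(table, coef, counts, n_unfrozen),
            method="L-BFGS-B",
            bounds=box,
            options={"maxiter": 300},
        )
        if best is None or res.fun < best.fun:
            best = res
    converged = bool(best.success and np.isfinite(best.fun))
    mu, log_sig, lgn = best.x
    params = CNTParams(
        mu_theta=float(mu),
        sigma_theta=float(math.exp(log_sig)),
        n_max=float(10.0 ** lgn),
        a_site=a_site,
        delta_t=delta_t,
        basis=basis,
    )

    cov: dict = {}
    if n_boot > 0 and converged:
        draws = _bootstrap(params, table, coef,
                           [a.n_droplets_total for a in assays],
                           box, rng, n_boot)
        if draws.size:
            cov = {
                "mu_theta": float(np.std(draws[:, 0])),
                "sigma_theta": float(np.std(np.exp(draws[:, 1]))),
                "log10_n_max": float(np.std(draws[:, 2])),
            }

    return FitResult(
        params=params,
        loglik=float(-best.fun),
        n_obs=n_total,
        converged=converged,
        covariance_proxy=cov,
        fit_basis=basis,
        sample_id=sample_id,
        thermo_name=thermo.name,
    )


def _bootstrap(params, table, coef, n_droplets, box, rng, n_boot):
    """Parametric bootstrap: resample interval counts from the fitted model,
    refit from the fitted point, collect parameter draws."""
    p_site = table.p_site(params.mu_theta, params.sigma_theta)
    x_hat = (params.mu_theta, math.log(params.sigma_theta),
             math.log10(params.n_max))
    draws = []
    for _ in range(n_boot):
        counts_b, unfrozen_b = [], []
        for c, n in zip(coef, n_droplets):
            f = -np.expm1(-params.n_max * c * p_site)
            q = np.diff(np.concatenate([[0.0], f, [1.0]]))  # last: never froze
            sample = rng.multinomial(n, np.maximum(q, 0.0) / max(q.sum(), 1e-300))
            counts_b.append(sample[:-1])
            unfrozen_b.append(int(sample[-1]))
        res = minimize(
            _neg_loglik, x_hat, args=(table, coef, counts_b, unfrozen_b),
            method="L-BFGS-B", bounds=box, options={"maxiter": 200},
        )
        if res.success:
            draws.append(res.x)
    return np.asarray(draws)


def ensemble_spread(fits: Sequence[Union[FitResult, Spectrum]], T: float,
                    thermo: ThermoParams = WATER_ICE_DEFAULT) -> float:
    """Orders-of-magnitude spread, log10(max/min), of site density at T.

    Accepts fitted models (evaluated through the CNT curve) and measured
    spectra (nearest grid point; ``n_m`` if normalized, else the per-volume
    concentration).  Entries with zero or missing density at T are excluded
    with a warning.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits or spectra")
    values = []
    for obj in fits:
        if isinstance(obj, FitResult):
            v = float(obj.site_density(np.array([T]), thermo)[0])
        else:
            curve = obj.n_m if obj.n_m is not None else obj.n_inm_per_volume
            if curve is None:
                warnings.warn(f"spectrum {obj.sample_id!r} has no density; excluded")
                continue
            i = int(np.argmin(np.abs(obj.temperature_grid - T)))
            v = float(curve[i])
        if v <= 0 or not np.isfinite(v):
            warnings.warn(f"zero/invalid site density at {T} K; entry excluded")
            continue
        values.append(v)
    if len(values) < 2:
        raise ValueError("fewer than two usable densities at the requested T")
    return math.log10(max(values) / min(values))
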
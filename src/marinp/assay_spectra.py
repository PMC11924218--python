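"""Droplet-freezing assays and cumulative ice-nucleating-macromolecule spectra.

A freezing assay cools an array of droplets of a (possibly diluted) sample at
a constant ramp and records the temperature at which each droplet freezes.
With ice-nucleating macromolecules (INMs) distributed over droplets following
Poisson statistics, the frozen fraction f(T) maps to the cumulative INM
number concentration of the original sample by the Vali transform

    n(T) = -ln(1 - f(T)) / V_droplet * dilution   [INM per litre sample],

which is nondecreasing with cooling.  Dividing by a per-sample chemical
concentration (e.g. the carbohydrate carbon mass C-TCCHO) turns n(T) into a
site density n_m(T) [INM per gram of basis], the quantity on which different
organisms' spectra collapse when the same macromolecule class carries the
activity.

Temperatures are kelvin internally; Celsius appears only in CSV columns with
explicit unit suffixes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import beta

from .cnt_model import T_MELT

__all__ = [
    "TREATMENTS",
    "FreezingAssay",
    "SampleChemistry",
    "Spectrum",
    "ReductionResult",
    "default_grid",
    "frozen_fraction_curve",
    "cumulative_inm_concentration",
    "normalize_spectrum",
    "subtract_background",
    "treatment_reduction",
    "pooled_dilution_spectrum",
    "read_assay_csv",
    "read_chemistry_csv",
    "spectrum_frame",
    "write_spectrum_csv",
]

TREATMENTS = (
    "none",
    "filtered_0.2um",
    "heated_95C_1h",
    "filtered_then_heated",
    "acid_hydrolysis",
    "cacl2",
    "cacl2_then_filtered",
)

BASES = ("per_volume", "per_c_tccho", "per_toc", "per_dry_mass")


def default_grid() -> np.ndarray:
    """Default spectrum grid: 0.5-K bins from 272.15 K down to 238.15 K."""
    return np.arange(272.15, 238.15 - 1e-9, -0.5)


@dataclass
class FreezingAssay:
    """One droplet-freezing experiment.

    ``freezing_temperatures`` lists the freezing temperature [K] of every
    droplet that froze; droplets missing from the list stayed liquid to the
    end of the ramp (censored).
    """

    sample_id: str
    droplet_volume: float          # litre
    dilution_factor: float         # >= 1
    freezing_temperatures: np.ndarray  # kelvin, one entry per frozen droplet
    n_droplets_total: int
    background_id: Optional[str] = None
    treatment: str = "none"

    def __post_init__(self):
        self.freezing_temperatures = np.asarray(
            self.freezing_temperatures, dtype=float
        )
        if self.droplet_volume <= 0:
            raise ValueError("droplet_volume must be > 0")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")
        if self.n_droplets_total <= 0:
            raise ValueError("n_droplets_total must be > 0")
        if self.freezing_temperatures.size > self.n_droplets_total:
            raise ValueError("more freezing temperatures than droplets")
        if np.any(self.freezing_temperatures >= T_MELT):
            raise ValueError("freezing temperatures must be below 273.15 K")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")


@dataclass(frozen=True)
class SampleChemistry:
    """Per-sample chemical concentrations in the original (undiluted) sample."""

    sample_id: str
    c_tccho: float                  # g carbohydrate carbon per litre
    toc: float                      # g carbon per litre
    dry_mass: Optional[float] = None  # g per litre

    def __post_init__(self):
        for name in ("c_tccho", "toc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.dry_mass is not None and self.dry_mass < 0:
            raise ValueError("dry_mass must be >= 0")
        if self.c_tccho > self.toc > 0:
            raise ValueError("c_tccho cannot exceed toc")

    def basis_concentration(self, basis: str) -> Optional[float]:
        return {
            "per_volume": 1.0,
            "per_c_tccho": self.c_tccho,
            "per_toc": self.toc,
            "per_dry_mass": self.dry_mass,
        }[basis]


@dataclass
class Spectrum:
    """Temperature-gridded frozen fraction and cumulative INM spectrum."""

    sample_id: str
    temperature_grid: np.ndarray        # kelvin, strictly descending
    frozen_fraction: np.ndarray
    n_frozen: np.ndarray                # integer counts behind frozen_fraction
    n_total: int
    droplet_volume: float
    dilution_factor: float
    n_inm_per_volume: Optional[np.ndarray] = None  # INM per litre sample
    ci_low: Optional[np.ndarray] = None
    ci_high: Optional[np.ndarray] = None
    censored: Optional[np.ndarray] = None          # bool: f = 1 lower bounds
    normalization_basis: str = "per_volume"
    n_m: Optional[np.ndarray] = None               # INM per gram of basis
    basis_concentration: Optional[float] = None
    treatment: str = "none"


def _check_grid(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("temperature grid must be a non-empty 1-D array")
    if grid.size > 1 and not np.all(np.diff(grid) < 0):
        raise ValueError("temperature grid must be strictly descending")
    return grid


def frozen_fraction_curve(assay: FreezingAssay, temperature_grid=None) -> Spectrum:
    """Cumulative frozen fraction on a descending temperature grid.

    A droplet whose freezing temperature is exactly a grid temperature counts
    as frozen at that grid point ("frozen by the time the ramp reaches T").
    """
    grid = _check_grid(default_grid() if temperature_grid is None else temperature_grid)
    temps = assay.freezing_temperatures
    counts = np.array([(temps >= t).sum() for t in grid], dtype=int)
    return Spectrum(
        sample_id=assay.sample_id,
        temperature_grid=grid,
        frozen_fraction=counts / assay.n_droplets_total,
        n_frozen=counts,
        n_total=assay.n_droplets_total,
        droplet_volume=assay.droplet_volume,
        dilution_factor=assay.dilution_factor,
        treatment=assay.treatment,
    )


def _clopper_pearson(k: np.ndarray, n: int, alpha: float):
    """Exact binomial confidence bounds on the frozen fraction."""
    k = np.asarray(k, dtype=float)
    lo = np.where(k > 0, beta.ppf(alpha / 2.0, k, n - k + 1.0), 0.0)
    hi = np.where(k < n, beta.ppf(1.0 - alpha / 2.0, k + 1.0, n - k), 1.0)
    return lo, hi


def _vali(f, volume: float, dilution: float):
    """-ln(1 - f) / V * dilution, with f = 1 mapped to +inf."""
    f = np.asarray(f, dtype=float)
    with np.errstate(divide="ignore"):
        return np.where(f < 1.0, -np.log1p(-np.clip(f, 0.0, 1.0 - 1e-300)), np.inf) \
            / volume * dilution


def cumulative_inm_concentration(spectrum: Spectrum, assay: FreezingAssay,
                                 alpha: float = 0.05) -> Spectrum:
    """Fill the Vali cumulative INM concentration and its confidence bounds.

    Clopper-Pearson bounds on the frozen fraction are pushed through the same
    transform (exact at the small droplet counts typical of assays).  Grid
    points with all droplets frozen are censored: the reported value uses
    f = (k - 1/2)/k as a lower bound and the upper confidence bound is +inf.
    """
    f = spectrum.frozen_fraction
    if np.any(f < 0) or np.any(f > 1):
        raise ValueError("frozen fraction outside [0, 1]")
    n = spectrum.n_total
    k = spectrum.n_frozen
    censored = k == n
    f_eff = np.where(censored, (n - 0.5) / n, f)
    value = _vali(f_eff, assay.droplet_volume, assay.dilution_factor)
    f_lo, f_hi = _clopper_pearson(k, n, alpha)
    ci_low = _vali(f_lo, assay.droplet_volume, assay.dilution_factor)
    ci_high = _vali(f_hi, assay.droplet_volume, assay.dilution_factor)
    ci_low = np.minimum(ci_low, value)
    return replace(
        spectrum,
        n_inm_per_volume=value,
        ci_low=ci_low,
        ci_high=ci_high,
        censored=censored,
    )


def normalize_spectrum(spectrum: Spectrum, chemistry: SampleChemistry,
                       basis: str) -> Spectrum:
    """Divide the cumulative concentration by a chemical basis concentration.

    ``basis="per_c_tccho"`` yields n_m,C-TCCHO in INM per gram carbohydrate
    carbon; ``"per_volume"`` returns the spectrum unchanged.
    """
    if basis not in BASES:
        raise ValueError(f"unknown basis {basis!r}; expected one of {BASES}")
    if basis == "per_volume":
        return replace(spectrum, normalization_basis="per_volume", n_m=None,
                       basis_concentration=None)
    if spectrum.n_inm_per_volume is None:
        raise ValueError("cumulative concentration must be filled before normalizing")
    conc = chemistry.basis_concentration(basis)
    if conc is None or conc <= 0:
        raise ValueError(
            f"sample {chemistry.sample_id!r}: basis {basis!r} concentration "
            "is zero or missing"
        )
    return replace(
        spectrum,
        normalization_basis=basis,
        n_m=spectrum.n_inm_per_volume / conc,
        basis_concentration=conc,
    )


def subtract_background(spectrum: Spectrum, background: Spectrum) -> Spectrum:
    """Subtract a paired pure-water spectrum in concentration space, floored at 0.

    Off by default in the pipeline; the grids must match.
    """
    if not np.array_equal(spectrum.temperature_grid, background.temperature_grid):
        raise ValueError("spectrum and background grids differ")
    if spectrum.n_inm_per_volume is None or background.n_inm_per_volume is None:
        raise ValueError("both spectra need cumulative concentrations")
    value = np.maximum(spectrum.n_inm_per_volume - background.n_inm_per_volume, 0.0)
    ci_low = None if spectrum.ci_low is None else np.maximum(
        spectrum.ci_low - background.n_inm_per_volume, 0.0)
    ci_high = None if spectrum.ci_high is None else np.maximum(
        spectrum.ci_high - background.n_inm_per_volume, 0.0)
    return replace(spectrum, n_inm_per_volume=value, ci_low=ci_low, ci_high=ci_high)


@dataclass(frozen=True)
class ReductionResult:
    """Percent reduction of INM concentration by a treatment, with bounds."""

    percent: float
    ci_low: float
    ci_high: float
    flagged: bool = False


def treatment_reduction(reference: Spectrum, treated: Spectrum,
                        T: float) -> ReductionResult:
    """Percent reduction 100 (1 - n_treated / n_reference) at grid temperature T.

    Negative values mean enhancement.  The confidence interval combines the
    Clopper-Pearson bounds of both spectra conservatively; the result is
    flagged when the reference value is zero (undefined) or either value is
    censored.
    """
    for s in (reference, treated):
        if s.n_inm_per_volume is None:
            raise ValueError("both spectra need cumulative concentrations")
    idx_r = np.flatnonzero(np.isclose(reference.temperature_grid, T))
    idx_t = np.flatnonzero(np.isclose(treated.temperature_grid, T))
    if idx_r.size == 0 or idx_t.size == 0:
        raise ValueError(f"temperature {T} K not on both spectrum grids")
    i, j = idx_r[0], idx_t[0]
    n_ref = reference.n_inm_per_volume[i]
    n_tr = treated.n_inm_per_volume[j]
    if n_ref <= 0:
        return ReductionResult(np.nan, np.nan, np.nan, flagged=True)
    value = 100.0 * (1.0 - n_tr / n_ref)
    flagged = bool(
        (reference.censored is not None and reference.censored[i])
        or (treated.censored is not None and treated.censored[j])
    )
    if reference.ci_low is None or treated.ci_low is None:
        return ReductionResult(value, np.nan, np.nan, flagged=True)
    ref_lo = max(reference.ci_low[i], 0.0)
    with np.errstate(divide="ignore"):
        lo = 100.0 * (1.0 - treated.ci_high[j] / ref_lo) if ref_lo > 0 else -np.inf
        hi = 100.0 * (1.0 - treated.ci_low[j] / reference.ci_high[i])
    return ReductionResult(value, lo, hi, flagged=flagged)


def pooled_dilution_spectrum(assays: Sequence[FreezingAssay],
                             temperature_grid=None,
                             alpha: float = 0.05) -> Spectrum:
    """Maximum-likelihood cumulative spectrum pooled across a dilution series.

    At each grid temperature the per-assay frozen counts k_d of n_d droplets
    follow Binomial(n_d, 1 - exp(-n V / dilution_d)); the pooled estimate
    maximizes the joint likelihood over the sample concentration n.  A
    normal-approximation interval in log n supplements the point estimate
    (the exact per-assay Clopper-Pearson machinery remains available through
    the single-assay path).
    """
    if len(assays) == 0:
        raise ValueError("need at least one assay")
    sample_id = assays[0].sample_id
    if any(a.sample_id != sample_id for a in assays):
        raise ValueError("pooled assays must share a sample_id")
    grid = _check_grid(default_grid() if temperature_grid is None else temperature_grid)
    specs = [frozen_fraction_curve(a, grid) for a in assays]
    lam_coef = np.array([a.droplet_volume / a.dilution_factor for a in assays])
    ks = np.stack([s.n_frozen for s in specs])            # (n_assay, n_T)
    ns = np.array([a.n_droplets_total for a in assays])

    def score(log_n, k, n):
        lam = np.exp(log_n) * lam_coef
        p = -np.expm1(-lam)
        with np.errstate(divide="ignore", invalid="ignore"):
            dll = np.where(
                k > 0, k * lam * np.exp(-lam) / np.maximum(p, 1e-300), 0.0
            ) - (n - k) * lam
        return dll.sum()

    value = np.zeros(grid.size)
    ci_lo = np.zeros(grid.size)
    ci_hi = np.zeros(grid.size)
    censored = np.zeros(grid.size, dtype=bool)
    for t in range(grid.size):
        k = ks[:, t]
        if k.sum() == 0:
            value[t] = 0.0
            ci_hi[t] = min(
                _vali(_clopper_pearson(np.array([0]), int(n), alpha)[1], 1.0, 1.0)[0]
                / c for n, c in zip(ns, lam_coef)
            )
            continue
        if np.all(k == ns):
            censored[t] = True
            k = np.minimum(k, ns - 0.5)  # lower-bound convention
        lo_b, hi_b = -10.0, 60.0
        if score(lo_b, k, ns) < 0:
            value[t] = 0.0
            continue
        value[t] = np.exp(brentq(score, lo_b, hi_b, args=(k, ns)))
        # expected-information interval in log n:
        # I = sum_d n_d lam_d^2 exp(-lam_d) / p_d  for binomial(n_d, p_d)
        lam = value[t] * lam_coef
        p = np.maximum(-np.expm1(-lam), 1e-300)
        info = np.sum(ns * lam**2 * np.exp(-lam) / p)
        se = 1.0 / np.sqrt(max(info, 1e-12))
        z = 1.959963984540054
        ci_lo[t] = value[t] * np.exp(-z * se)
        ci_hi[t] = value[t] * np.exp(z * se) if not censored[t] else np.inf
    # report pooled counts of the least-diluted assay for bookkeeping
    ref = int(np.argmin([a.dilution_factor for a in assays]))
    return Spectrum(
        sample_id=sample_id,
        temperature_grid=grid,
        frozen_fraction=ks[ref] / ns[ref],
        n_frozen=ks[ref],
        n_total=int(ns[ref]),
        droplet_volume=assays[ref].droplet_volume,
        dilution_factor=assays[ref].dilution_factor,
        n_inm_per_volume=value,
        ci_low=ci_lo,
        ci_high=ci_hi,
        censored=censored,
        treatment=assays[ref].treatment,
    )


# ---------------------------------------------------------------------------
# CSV interfaces (Celsius at the boundary, kelvin inside)
# ---------------------------------------------------------------------------

def read_assay_csv(path) -> list[FreezingAssay]:
    """Read per-droplet assay records.

    Columns: sample_id, droplet_id, droplet_volume_uL, dilution_factor,
    freeze_temp_C (empty if the droplet never froze), treatment,
    background_id.  One assay per (sample_id, dilution_factor, treatment).
    """
    df = pd.read_csv(path)
    assays = []
    for (sid, dil, treat), grp in df.groupby(
        ["sample_id", "dilution_factor", "treatment"], sort=False
    ):
        frozen = grp["freeze_temp_C"].dropna()
        bg = grp["background_id"].dropna()
        assays.append(
            FreezingAssay(
                sample_id=str(sid),
                droplet_volume=float(grp["droplet_volume_uL"].iloc[0]) * 1e-6,
                dilution_factor=float(dil),
                freezing_temperatures=frozen.to_numpy(dtype=float) + T_MELT,
                n_droplets_total=len(grp),
                background_id=str(bg.iloc[0]) if len(bg) else None,
                treatment=str(treat),
            )
        )
    return assays


def write_assay_csv(assays: Sequence[FreezingAssay], path) -> None:
    rows = []
    for a in assays:
        n_frozen = a.freezing_temperatures.size
        for d in range(a.n_droplets_total):
            rows.append(
                {
                    "sample_id": a.sample_id,
                    "droplet_id": d,
                    "droplet_volume_uL": a.droplet_volume * 1e6,
                    "dilution_factor": a.dilution_factor,
                    "freeze_temp_C": (a.freezing_temperatures[d] - T_MELT)
                    if d < n_frozen else np.nan,
                    "treatment": a.treatment,
                    "background_id": a.background_id or "",
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_chemistry_csv(path) -> dict[str, SampleChemistry]:
    """Columns: sample_id, c_tccho_gC_per_L, toc_gC_per_L, dry_mass_g_per_L."""
    df = pd.read_csv(path)
    out = {}
    for _, row in df.iterrows():
        dm = row.get("dry_mass_g_per_L", np.nan)
        out[str(row["sample_id"])] = SampleChemistry(
            sample_id=str(row["sample_id"]),
            c_tccho=float(row["c_tccho_gC_per_L"]),
            toc=float(row["toc_gC_per_L"]),
            dry_mass=None if pd.isna(dm) else float(dm),
        )
    return out


def write_chemistry_csv(chem: Sequence[SampleChemistry], path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "c_tccho_gC_per_L": c.c_tccho,
                "toc_gC_per_L": c.toc,
                "dry_mass_g_per_L": np.nan if c.dry_mass is None else c.dry_mass,
            }
            for c in chem
        ]
    ).to_csv(path, index=False)


def spectrum_frame(spectrum: Spectrum) -> pd.DataFrame:
    """Tidy per-grid-point view of a spectrum (Celsius at the boundary)."""
    n = spectrum.temperature_grid.size
    return pd.DataFrame(
        {
            "sample_id": [spectrum.sample_id] * n,
            "temp_C": spectrum.temperature_grid - T_MELT,
            "frozen_fraction": spectrum.frozen_fraction,
            "n_inm_per_L": spectrum.n_inm_per_volume
            if spectrum.n_inm_per_volume is not None else np.nan,
            "ci_low": spectrum.ci_low if spectrum.ci_low is not None else np.nan,
            "ci_high": spectrum.ci_high if spectrum.ci_high is not None else np.nan,
            "n_m": spectrum.n_m if spectrum.n_m is not None else np.nan,
            "basis": [spectrum.normalization_basis] * n,
            "censored_flag": spectrum.censored
            if spectrum.censored is not None else False,
        }
    )


def write_spectrum_csv(spectra: Sequence[Spectrum], path) -> None:
    pd.concat([spectrum_frame(s) for s in spectra], ignore_index=True).to_csv(
        path, index=False
    )
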
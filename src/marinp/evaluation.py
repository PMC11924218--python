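"""Model-observation evaluation: FAC2/FAC10 agreement and improvement fraction.

Observed INP concentrations (point measurements with an activation
temperature) are paired with annual-mean modeled INP at the nearest grid
cell (great-circle distance) and the nearest evaluated activation
temperature within 0.5 K.  Agreement is summarized by the fraction of pairs
within a factor N (symmetric ratio), and the added value of the
polysaccharide scheme is the fraction of the factor-10 improvement over
dust-only that it reproduces relative to the sea-spray-surface scheme:

    F = (FAC10_{N15+HSZ25} - FAC10_{N15}) / (FAC10_{N15+M18} - FAC10_{N15}),

which may exceed 1 and is undefined (flagged) when the sea-spray scheme adds
no agreement.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .cnt_model import T_MELT

__all__ = [
    "VARIANTS",
    "EvalReport",
    "read_observations_csv",
    "write_observations_csv",
    "match_pairs",
    "fac_fraction",
    "improvement_fraction",
    "evaluate",
]

#: model variants evaluated against observations
VARIANTS = {
    "N15": ("inp_dust",),
    "N15+M18": ("inp_dust", "inp_m18"),
    "N15+HSZ25": ("inp_dust", "inp_poly"),
}

EARTH_RADIUS_KM = 6371.0


def great_circle_km(lat1, lon1, lat2, lon2):
    """Haversine distance [km]; broadcasts."""
    la1, lo1, la2, lo2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = (
        np.sin((la2 - la1) / 2.0) ** 2
        + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2.0) ** 2
    )
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def read_observations_csv(path) -> pd.DataFrame:
    """Columns: campaign, lat, lon, time_iso, activation_temp_C, inp_per_L,
    marine_flag.  Temperatures converted to kelvin internally."""
    df = pd.read_csv(path)
    df["activation_temperature"] = df["activation_temp_C"] + T_MELT
    return df


def write_observations_csv(df: pd.DataFrame, path) -> None:
    out = df.copy()
    if "activation_temp_C" not in out and "activation_temperature" in out:
        out["activation_temp_C"] = out["activation_temperature"] - T_MELT
    cols = ["campaign", "lat", "lon", "time_iso", "activation_temp_C",
            "inp_per_L", "marine_flag"]
    out[cols].to_csv(path, index=False)


def match_pairs(
    observations: pd.DataFrame,
    inp: xr.Dataset,
    t_window: tuple = (T_MELT - 20.0, T_MELT - 15.0),
    temp_tol: float = 0.5,
) -> tuple[pd.DataFrame, dict]:
    """Pair observations with modeled INP at the nearest cell and temperature.

    Observations outside the activation-temperature window, farther than
    ``temp_tol`` from any evaluated temperature, are skipped and counted.
    Returns (pairs, skipped) where pairs carries the observed value, the
    model value of every INP variable, and pairing metadata.
    """
    lat = inp["lat"].values
    lon = inp["lon"].values
    temps = inp["temperature"].values
    lat2, lon2 = np.meshgrid(lat, lon, indexing="ij")
    lo, hi = min(t_window), max(t_window)

    rows = []
    skipped = {"outside_window": 0, "no_temperature_level": 0}
    for _, obs in observations.iterrows():
        t_act = float(obs["activation_temperature"])
        if not (lo <= t_act <= hi):
            skipped["outside_window"] += 1
            continue
        k = int(np.argmin(np.abs(temps - t_act)))
        if abs(temps[k] - t_act) > temp_tol:
            skipped["no_temperature_level"] += 1
            continue
        d = great_circle_km(obs["lat"], obs["lon"], lat2, lon2)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        row = {
            "campaign": obs.get("campaign", ""),
            "observed": float(obs["inp_per_L"]),
            "activation_temperature": t_act,
            "model_temperature": float(temps[k]),
            "lat": float(lat[i]),
            "lon": float(lon[j]),
            "distance_km": float(d[i, j]),
        }
        for var in inp.data_vars:
            row[var] = float(inp[var].values[k, i, j])
        rows.append(row)
    pairs = pd.DataFrame(rows)
    return pairs, skipped


def fac_fraction(observed, modeled, factor: float) -> tuple[float, int, int]:
    """Fraction of pairs with max(model/obs, obs/model) <= factor.

    Pairs where either value is zero (ratio undefined) are excluded and
    counted separately.  Returns (fraction, n_valid, n_excluded); the
    fraction is NaN when no valid pair remains.
    """
    if factor <= 1.0:
        raise ValueError("factor must be > 1")
    obs = np.asarray(observed, dtype=float)
    mod = np.asarray(modeled, dtype=float)
    valid = (obs > 0) & (mod > 0)
    n_excluded = int((~valid).sum())
    if valid.sum() == 0:
        warnings.warn("no valid pairs for the factor metric")
        return math.nan, 0, n_excluded
    ratio = np.maximum(mod[valid] / obs[valid], obs[valid] / mod[valid])
    return float((ratio <= factor).mean()), int(valid.sum()), n_excluded


def improvement_fraction(fac10_n15: float, fac10_n15_m18: float,
                         fac10_n15_hsz25: float) -> float:
    """Fraction of the M18 factor-10 improvement reproduced by polysaccharides.

    NaN (with a warning) when the denominator is <= 0, i.e. the sea-spray
    scheme added no factor-10 agreement over dust alone.
    """
    for f in (fac10_n15, fac10_n15_m18, fac10_n15_hsz25):
        if not (0.0 <= f <= 1.0):
            raise ValueError("FAC fractions must lie in [0, 1]")
    denom = fac10_n15_m18 - fac10_n15
    if denom <= 0.0:
        warnings.warn("M18 added no factor-10 agreement; improvement undefined")
        return math.nan
    return (fac10_n15_hsz25 - fac10_n15) / denom


@dataclass
class EvalReport:
    """FAC metrics per model variant plus the improvement fraction."""

    n_pairs: int
    fac2: dict
    fac10: dict
    excluded: dict
    improvement_fraction: float
    t_window: tuple
    scenario_tag: str = ""
    skipped: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant": list(self.fac2),
                "fac2": [self.fac2[v] for v in self.fac2],
                "fac10": [self.fac10[v] for v in self.fac2],
                "n_excluded": [self.excluded[v] for v in self.fac2],
            }
        )

    def summary(self) -> str:
        lines = [
            f"pairs: {self.n_pairs} in window "
            f"[{self.t_window[0] - T_MELT:+.1f}, {self.t_window[1] - T_MELT:+.1f}] C "
            f"(scenario {self.scenario_tag or 'n/a'})"
        ]
        for v in self.fac2:
            lines.append(
                f"  {v:10s} FAC2 = {self.fac2[v]:.3f}  FAC10 = {self.fac10[v]:.3f}"
            )
        f = self.improvement_fraction
        lines.append(
            "  improvement fraction (polysaccharide share of the M18 FAC10 gain): "
            + ("undefined" if math.isnan(f) else f"{f:.3f}")
        )
        return "\n".join(lines)


def evaluate(
    observations: pd.DataFrame,
    inp: xr.Dataset,
    t_window: tuple = (T_MELT - 20.0, T_MELT - 15.0),
    temp_tol: float = 0.5,
    scenario_tag: str = "",
) -> EvalReport:
    """Full evaluation: pair, score FAC2/FAC10 per variant, compute Eq.-style
    improvement fraction of the polysaccharide scheme."""
    pairs, skipped = match_pairs(observations, inp, t_window, temp_tol)
    fac2, fac10, excl = {}, {}, {}
    for variant, parts in VARIANTS.items():
        if len(pairs) == 0:
            fac2[variant], fac10[variant], excl[variant] = math.nan, math.nan, 0
            continue
        if any(p not in pairs.columns for p in parts):
            continue
        model = sum(pairs[p] for p in parts)
        fac2[variant], _, excl[variant] = fac_fraction(pairs["observed"], model, 2.0)
        fac10[variant], _, _ = fac_fraction(pairs["observed"], model, 10.0)
    if {"N15", "N15+M18", "N15+HSZ25"} <= fac10.keys() and len(pairs):
        improvement = improvement_fraction(
            fac10["N15"], fac10["N15+M18"], fac10["N15+HSZ25"]
        )
    else:
        improvement = math.nan
    return EvalReport(
        n_pairs=len(pairs),
        fac2=fac2,
        fac10=fac10,
        excluded=excl,
        improvement_fraction=improvement,
        t_window=(min(t_window), max(t_window)),
        scenario_tag=scenario_tag,
        skipped=skipped,
    )
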
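"""Ancestry-vs-distance clines and trend statistics.

Populations are summarised by their mean Holarctic ancestry (a membership
coefficient for nuclear layers, an observed lineage/allele frequency for mt
and Z layers) and plotted against great-circle ("as-the-crow-flies")
distance from an anchor locality — by convention San Diego, California.
Trend is quantified by a Spearman rank correlation and, optionally, a
bounded least-squares logistic cline fit returning centre and width.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

EARTH_RADIUS_KM = 6371.0
SAN_DIEGO = (32.7157, -117.1611)


class ClineError(ValueError):
    pass


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance on a spherical Earth (radius 6371.0 km)."""
    for lat, lon in ((lat1, lon1), (lat2, lon2)):
        if not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 180.0):
            raise ClineError(f"coordinates out of bounds: ({lat}, {lon})")
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2 - lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


@dataclasses.dataclass
class ClineSeries:
    """Per-population distance/ancestry series."""

    table: pd.DataFrame       # population, distance_km, mean_ancestry, n
    anchor: tuple[float, float]

    def __len__(self) -> int:
        return len(self.table)


def ancestry_cline_series(
    metadata: pd.DataFrame,
    ancestry: Mapping[str, float] | pd.Series,
    anchor: tuple[float, float] = SAN_DIEGO,
    exclude_pops: Sequence[str] = (),
) -> ClineSeries:
    """Per-population mean ancestry vs distance from the anchor.

    ``ancestry`` maps sample id -> HOL ancestry quantity (membership
    coefficient for nuclear layers; a 0/1 lineage indicator for mt, giving
    an observed lineage frequency per population). Populations listed in
    ``exclude_pops``, and populations with zero usable samples, are dropped.
    """
    ancestry = pd.Series(dict(ancestry), dtype=float)
    rows = []
    for pop, grp in metadata.groupby("population", sort=False):
        if pop in exclude_pops:
            continue
        vals = ancestry.reindex(grp["sample"]).dropna()
        if vals.empty:
            continue
        lat, lon = grp["latitude"].mean(), grp["longitude"].mean()
        rows.append(
            {
                "population": pop,
                "distance_km": haversine_km(anchor[0], anchor[1], lat, lon),
                "mean_ancestry": float(vals.mean()),
                "n": int(len(vals)),
            }
        )
    if not rows:
        raise ClineError("no populations left after exclusions")
    table = pd.DataFrame(rows).sort_values("distance_km").reset_index(drop=True)
    return ClineSeries(table=table, anchor=anchor)


@dataclasses.dataclass
class ClineTrend:
    spearman_rho: float
    p_value: float
    logistic_center_km: float | None = None
    logistic_width_km: float | None = None
    fit_converged: bool = False


def _logistic(d, center, width):
    return 1.0 / (1.0 + np.exp(-4.0 * (d - center) / width))


def cline_trend(series: ClineSeries, fit_logistic: bool = True) -> ClineTrend:
    """Spearman rank trend of ancestry vs distance, plus an optional
    bounded least-squares logistic fit (centre, width; width is the inverse
    maximum slope). The fit is reported only when the optimiser converges.
    """
    t = series.table
    if len(t) < 4:
        raise ClineError("need >= 4 populations")
    y = t["mean_ancestry"].to_numpy()
    d = t["distance_km"].to_numpy()
    if np.ptp(y) == 0:
        raise ClineError("constant ancestry series: trend undefined")
    rho, p = stats.spearmanr(d, y)
    trend = ClineTrend(spearman_rho=float(rho), p_value=float(p))
    if fit_logistic:
        span = max(d.max() - d.min(), 1.0)
        try:
            popt, _ = optimize.curve_fit(
                _logistic, d, y,
                p0=[d.mean(), span / 2.0],
                bounds=([d.min() - span, 1e-3], [d.max() + span, 20.0 * span]),
                maxfev=10000,
            )
            trend.logistic_center_km = float(popt[0])
            trend.logistic_width_km = float(popt[1])
            trend.fit_converged = True
        except RuntimeError:
            trend.fit_converged = False
    return trend
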
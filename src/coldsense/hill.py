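"""Modified Hill-equation fitting of cGMP concentration-response data.

The ligand dependence of cyclic nucleotide-gated current is modelled as

    I([cGMP]) = I_min + (I_max - I_min) / (1 + (EC50 / [cGMP])^H)

with EC50 the half-maximal effective concentration (uM) and H the Hill slope.
Fits are performed patch by patch, never pooled, and a patch's series at a
second temperature is normalized to its fitted 22 degC maximum before
comparison. Paired per-patch EC50 and Imax changes on cooling are summarized
with paired t statistics (mean +/- SEM throughout).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from coldsense import stats as cstats

__all__ = [
    "ConcResponseSeries",
    "HillParams",
    "hill_eval",
    "fit_hill",
    "normalize_pair",
    "paired_temperature_summary",
]


@dataclass
class ConcResponseSeries:
    """Per-patch current vs ligand-concentration points at one temperature."""

    patch_id: str
    temperature_C: float
    conc_uM: np.ndarray
    current: np.ndarray
    normalization_reference: float | None = None
    condition: str = ""

    def __post_init__(self) -> None:
        self.conc_uM = np.asarray(self.conc_uM, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.conc_uM.shape != self.current.shape or self.conc_uM.ndim != 1:
            raise ValueError("conc_uM and current must be 1-D arrays of equal length")
        if np.any(self.conc_uM <= 0):
            raise ValueError("concentrations must be > 0")
        if np.unique(self.conc_uM).size != self.conc_uM.size:
            raise ValueError("concentrations must be distinct")


@dataclass
class HillParams:
    i_min: float
    i_max: float
    ec50: float
    h: float
    residual_norm: float = 0.0
    converged: bool = True
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.ec50 <= 0 or self.h <= 0:
            raise ValueError("ec50 and h must be > 0")
        if self.i_max < self.i_min:
            raise ValueError("i_max must be >= i_min")


def hill_eval(params: HillParams, conc_uM) -> np.ndarray | float:
    """Evaluate the modified Hill equation at the given concentration(s)."""
    conc = np.asarray(conc_uM, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("conc_uM must be > 0")
    out = params.i_min + (params.i_max - params.i_min) / (1.0 + (params.ec50 / conc) ** params.h)
    return float(out) if np.ndim(conc_uM) == 0 else out


def _hill(conc, i_min, i_max, ec50, h):
    return i_min + (i_max - i_min) / (1.0 + (ec50 / conc) ** h)


def fit_hill(series: ConcResponseSeries, pin_imin: bool = False) -> HillParams:
    """Least-squares fit of (I_min, I_max, EC50, H) to one series.

    Deterministic multi-start: EC50 seeded at the geometric mean of the
    concentrations and at the concentration nearest the half-maximal response,
    H at 1 and 2; best residual wins. With ``pin_imin`` the floor is fixed at
    zero. The convergence flag is honest: degenerate (flat) series and fits
    whose EC50 falls outside the tested concentration range are reported
    non-converged rather than extrapolated.
    """
    conc = series.conc_uM
    resp = series.current
    n = conc.size
    if n < 4:
        raise ValueError("need >= 4 concentrations to fit the Hill equation")

    span = float(np.ptp(resp))
    scale = max(float(np.max(np.abs(resp))), 1e-30)
    if span <= 1e-9 * scale:
        return HillParams(
            i_min=float(np.min(resp)), i_max=float(np.max(resp)) + 1e-30,
            ec50=float(np.exp(np.mean(np.log(conc)))), h=1.0,
            residual_norm=0.0, converged=False, n_points=n,
        )

    half = (np.min(resp) + np.max(resp)) / 2.0
    ec50_starts = [
        float(np.exp(np.mean(np.log(conc)))),
        float(conc[np.argmin(np.abs(resp - half))]),
    ]
    h_starts = [1.0, 2.0]
    imin0 = 0.0 if pin_imin else float(np.min(resp))
    imax0 = float(np.max(resp))

    big = 1e12 * max(scale, 1.0)
    best = None
    for ec50_0, h0 in product(ec50_starts, h_starts):
        if pin_imin:
            def resid(p, conc=conc, resp=resp):
                return _hill(conc, 0.0, p[0], p[1], p[2]) - resp

            x0 = [imax0, ec50_0, h0]
            lb = [1e-30, 1e-12, 0.05]
            ub = [big, 1e12, 20.0]
        else:
            def resid(p, conc=conc, resp=resp):
                return _hill(conc, p[0], p[1], p[2], p[3]) - resp

            x0 = [max(imin0, 0.0), imax0, ec50_0, h0]
            lb = [0.0, 1e-30, 1e-12, 0.05]
            ub = [big, big, 1e12, 20.0]
        sol = least_squares(resid, x0, bounds=(lb, ub), xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if best is None or sol.cost < best.cost:
            best = sol

    if pin_imin:
        i_min, (i_max, ec50, h) = 0.0, best.x
    else:
        i_min, i_max, ec50, h = best.x
    if i_max < i_min:  # guard; bounds make this unlikely
        i_min, i_max = i_max, i_min
    bracketing = float(np.min(conc)) <= ec50 <= float(np.max(conc))
    return HillParams(
        i_min=float(i_min),
        i_max=float(max(i_max, i_min + 1e-30)),
        ec50=float(ec50),
        h=float(h),
        residual_norm=float(np.sqrt(2.0 * best.cost)),
        converged=bool(best.success and bracketing),
        n_points=n,
    )


def normalize_pair(
    series_warm: ConcResponseSeries,
    series_cold: ConcResponseSeries,
    fit_warm: HillParams | None = None,
    pin_imin: bool = False,
):
    """Normalize a patch's paired series to its fitted warm-temperature maximum.

    Returns ``(norm_warm, norm_cold, fit_warm)``; both series are divided by
    the warm fitted I_max so the warm maximum is 1 by construction. EC50 and H
    are unaffected by the scaling.
    """
    if series_warm.patch_id != series_cold.patch_id:
        raise ValueError("normalize_pair requires series from the same patch")
    if fit_warm is None:
        fit_warm = fit_hill(series_warm, pin_imin=pin_imin)
    if not fit_warm.converged:
        raise ValueError(
            f"patch {series_warm.patch_id}: warm-temperature fit did not converge; "
            "cannot normalize"
        )
    ref = fit_warm.i_max
    out = []
    for s in (series_warm, series_cold):
        out.append(
            ConcResponseSeries(
                patch_id=s.patch_id,
                temperature_C=s.temperature_C,
                conc_uM=s.conc_uM.copy(),
                current=s.current / ref,
                normalization_reference=ref,
                condition=s.condition,
            )
        )
    return out[0], out[1], fit_warm


def paired_temperature_summary(
    fits: dict[str, dict[float, HillParams]],
    warm_C: float = 22.0,
    cold_C: float = 12.0,
):
    """Per-patch paired EC50/Imax comparison across two temperatures.

    ``fits`` maps patch_id -> {temperature_C: HillParams}. Patches lacking a
    converged fit at either temperature are excluded with a warning. Returns
    ``(table, tests)`` where ``table`` has one row per patch
    (ec50_warm, ec50_cold, ec50_ratio, imax_warm, imax_cold, imax_ratio) plus
    group mean/SEM, and ``tests`` holds paired-t comparisons of EC50 and Imax.
    """
    rows = []
    for patch_id, by_temp in fits.items():
        fw, fc = by_temp.get(warm_C), by_temp.get(cold_C)
        if fw is None or fc is None or not (fw.converged and fc.converged):
            warnings.warn(f"patch {patch_id}: unpaired or non-converged; excluded", stacklevel=2)
            continue
        rows.append(
            {
                "patch_id": patch_id,
                "ec50_warm": fw.ec50,
                "ec50_cold": fc.ec50,
                "ec50_ratio": fc.ec50 / fw.ec50,
                "imax_warm": fw.i_max,
                "imax_cold": fc.i_max,
                "imax_ratio": fc.i_max / fw.i_max,
            }
        )
    if len(rows) < 2:
        raise ValueError("need >= 2 patches with converged paired fits")
    table = pd.DataFrame(rows)
    tests = {
        "ec50": cstats.compare_groups(
            table["ec50_warm"].to_numpy(),
            table["ec50_cold"].to_numpy(),
            paired=True,
            forced_test="paired_t",
        ),
        "imax": cstats.compare_groups(
            table["imax_warm"].to_numpy(),
            table["imax_cold"].to_numpy(),
            paired=True,
            forced_test="paired_t",
        ),
    }
    summary = {}
    for col in ("ec50_warm", "ec50_cold", "ec50_ratio", "imax_ratio"):
        ms = cstats.mean_sem(table[col].to_numpy())
        summary[col] = {"mean": ms.mean, "sem": ms.sem, "n": ms.n}
    return table, tests, summary
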
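"""Temperature dependence of channel currents.

The core quantification follows the classical Arrhenius treatment of
cold-activated cyclic nucleotide-gated currents. The current trace is mapped
to (1/T_K, ln|I|) axes, binned onto a temperature grid to de-weight dwell-time
imbalance, and fitted with a continuous two-segment line whose interior
breakpoint is the apparent thermal activation threshold. Segment slopes are
converted to the 10-degree activation coefficient

    Q10 = exp(slope * (1/T_K(Tref - 10) - 1/T_K(Tref)))

evaluated at the segment midpoint temperature Tref, with the convention that
Q10 > 1 means the current grows on cooling (positive Arrhenius slope).

Fold activation by cold and the percent inhibition by a blocker are simple
ratio quantities defined on matched-voltage currents and annotated gap-free
traces respectively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CurrentTrace",
    "ArrheniusFit",
    "FoldActivation",
    "KELVIN_OFFSET",
    "arrhenius_transform",
    "fit_threshold",
    "compute_q10",
    "q10_to_slope",
    "compute_fold_activation",
    "compute_inhibition",
    "extract_current_at_voltage",
]

KELVIN_OFFSET = 273.15


@dataclass
class CurrentTrace:
    """Current vs time with synchronized temperature and voltage channels."""

    times: np.ndarray
    current: np.ndarray
    temperature: np.ndarray
    voltage: np.ndarray | float = -80.0
    cgmp_uM: float = 0.0
    cell_id: str = "cell0"
    condition: dict[str, str] = field(default_factory=dict)
    annotations: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        self.temperature = np.asarray(self.temperature, dtype=float)
        if not (self.times.shape == self.current.shape == self.temperature.shape):
            raise ValueError("times, current and temperature must have equal length")
        if np.any(self.temperature < 0.0) or np.any(self.temperature > 50.0):
            raise ValueError("temperature channel outside [0, 50] degC")
        if np.ndim(self.voltage) > 0:
            self.voltage = np.asarray(self.voltage, dtype=float)
            if self.voltage.shape != self.times.shape:
                raise ValueError("voltage channel length mismatch")


@dataclass
class ArrheniusFit:
    """Two-segment Arrhenius fit: apparent threshold and per-segment Q10."""

    threshold_T: float
    q10_below: float
    q10_above: float
    slope_below: float
    slope_above: float
    has_threshold: bool
    sse_two_segment: float
    sse_single_line: float
    f_ratio: float
    n_below: int
    n_above: int
    t_range: tuple[float, float]


@dataclass
class FoldActivation:
    fold: float
    voltage_mV: float
    i_cold: float
    i_warm: float
    leak_corrected: bool
    defined: bool = True


def _inv_tk(temp_c):
    return 1.0 / (np.asarray(temp_c, dtype=float) + KELVIN_OFFSET)


def q10_to_slope(q10: float, t_ref_c: float) -> float:
    """Arrhenius-axis slope producing the given Q10 at reference temperature."""
    dx = _inv_tk(t_ref_c - 10.0) - _inv_tk(t_ref_c)
    return float(np.log(q10) / dx)


def compute_q10(segment_slope: float, t_ref_c: float) -> float:
    """Convert an Arrhenius-axis slope to Q10 at the reference temperature.

    ``segment_slope`` is d(ln I)/d(1/T_K); a positive slope (current growing on
    cooling) yields Q10 > 1.
    """
    dx = _inv_tk(t_ref_c - 10.0) - _inv_tk(t_ref_c)
    return float(np.exp(segment_slope * dx))


def arrhenius_transform(
    trace: CurrentTrace,
    bin_width_C: float = 0.5,
    baseline_current: float = 0.0,
    analysis_interval: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Map a current trace to Arrhenius axes.

    Subtracts ``baseline_current``, requires the remaining current to be of
    uniform sign, then bins points to a ``bin_width_C`` temperature grid by
    median so slowly-swept temperature ranges do not dominate the fit.

    Returns a DataFrame with columns ``temp_C``, ``inv_TK``, ``ln_I`` sorted by
    descending temperature.
    """
    mask = np.ones_like(trace.times, dtype=bool)
    if analysis_interval is not None:
        a0, a1 = analysis_interval
        mask = (trace.times >= a0) & (trace.times <= a1)
    current = trace.current[mask] - baseline_current
    temp = trace.temperature[mask]
    nz = np.abs(current) > 0
    if not np.any(nz):
        raise ValueError("no nonzero currents in the analysis range")
    signs = np.sign(current[nz])
    if signs.max() != signs.min():
        raise ValueError(
            "current changes sign over the analysis range; "
            "subtract a baseline/leak current first"
        )
    current, temp = current[nz], temp[nz]

    bins = np.round(temp / bin_width_C) * bin_width_C
    df = pd.DataFrame({"bin": bins, "temp_C": temp, "ln_I": np.log(np.abs(current))})
    out = (
        df.groupby("bin", sort=True)
        .agg(temp_C=("temp_C", "median"), ln_I=("ln_I", "median"))
        .reset_index(drop=True)
    )
    out["inv_TK"] = _inv_tk(out["temp_C"])
    return out.sort_values("temp_C", ascending=False, ignore_index=True)[
        ["temp_C", "inv_TK", "ln_I"]
    ]


def _piecewise_sse(x, y, xb):
    """SSE of the continuous two-segment line with breakpoint at xb (1/T_K)."""
    design = np.column_stack([np.ones_like(x), x, np.maximum(0.0, x - xb)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return float(resid @ resid), coef


def fit_threshold(
    arr: pd.DataFrame,
    grid_step_C: float = 0.1,
    edge_margin_C: float = 1.0,
    f_ratio_min: float = 4.0,
) -> ArrheniusFit:
    """Fit the biphasic Arrhenius relation and locate its breakpoint.

    A continuous piecewise-linear model on (1/T_K, ln I) axes is fitted for
    every interior candidate breakpoint on a ``grid_step_C`` grid, the best
    candidate is polished by bounded scalar minimization, and the improvement
    over a single straight line is gated by an F-ratio: below ``f_ratio_min``
    the trace is reported as monophasic (``has_threshold=False``) with a single
    Q10 at the overall midpoint.
    """
    x = arr["inv_TK"].to_numpy(float)
    y = arr["ln_I"].to_numpy(float)
    t = arr["temp_C"].to_numpy(float)
    n = x.size
    t_min, t_max = float(t.min()), float(t.max())
    if n < 8 or (t_max - t_min) < 10.0:
        raise ValueError("need >= 8 Arrhenius points spanning >= 10 degC")

    # single straight line
    d1 = np.column_stack([np.ones_like(x), x])
    coef1, *_ = np.linalg.lstsq(d1, y, rcond=None)
    resid1 = y - d1 @ coef1
    sse1 = float(resid1 @ resid1)

    lo, hi = t_min + edge_margin_C, t_max - edge_margin_C
    candidates = np.arange(np.ceil(lo / grid_step_C), np.floor(hi / grid_step_C) + 1)
    candidates = candidates * grid_step_C
    best_tb, best_sse = None, np.inf
    for tb in candidates:
        sse, _ = _piecewise_sse(x, y, _inv_tk(tb))
        if sse < best_sse:
            best_sse, best_tb = sse, float(tb)

    from scipy.optimize import minimize_scalar

    span = max(grid_step_C, 2 * grid_step_C)
    res = minimize_scalar(
        lambda tb: _piecewise_sse(x, y, _inv_tk(tb))[0],
        bounds=(max(lo, best_tb - span), min(hi, best_tb + span)),
        method="bounded",
        options={"xatol": 1e-4},
    )
    if res.fun < best_sse:
        best_tb, best_sse = float(res.x), float(res.fun)
    sse2, coef = _piecewise_sse(x, y, _inv_tk(best_tb))

    # F-ratio for the 2 extra parameters of the segmented model
    y_var = float(np.var(y)) * n
    dof2 = max(n - 4, 1)
    improvement = max(sse1 - sse2, 0.0)
    if y_var <= 0 or sse1 <= 1e-12 * y_var:
        f_ratio = 0.0  # already a perfect single line
    elif sse2 <= 0:
        f_ratio = np.inf
    else:
        f_ratio = (improvement / 2.0) / (sse2 / dof2)

    slope_above = float(coef[1])                # warm side (x <= xb)
    slope_below = float(coef[1] + coef[2])      # cold side (x > xb)
    mid_below = (t_min + best_tb) / 2.0
    mid_above = (best_tb + t_max) / 2.0
    has_threshold = bool(f_ratio >= f_ratio_min)
    if not has_threshold:
        mid = (t_min + t_max) / 2.0
        q10 = compute_q10(float(coef1[1]), mid)
        return ArrheniusFit(
            threshold_T=float("nan"),
            q10_below=q10,
            q10_above=q10,
            slope_below=float(coef1[1]),
            slope_above=float(coef1[1]),
            has_threshold=False,
            sse_two_segment=sse2,
            sse_single_line=sse1,
            f_ratio=float(f_ratio),
            n_below=int(np.sum(t <= best_tb)),
            n_above=int(np.sum(t > best_tb)),
            t_range=(t_min, t_max),
        )
    return ArrheniusFit(
        threshold_T=best_tb,
        q10_below=compute_q10(slope_below, mid_below),
        q10_above=compute_q10(slope_above, mid_above),
        slope_below=slope_below,
        slope_above=slope_above,
        has_threshold=True,
        sse_two_segment=sse2,
        sse_single_line=sse1,
        f_ratio=float(f_ratio),
        n_below=int(np.sum(t <= best_tb)),
        n_above=int(np.sum(t > best_tb)),
        t_range=(t_min, t_max),
    )


def extract_current_at_voltage(ramp_trace: CurrentTrace, voltage_mV: float) -> float:
    """Linearly interpolate the current of a voltage-ramp trace at a command voltage."""
    v = np.asarray(ramp_trace.voltage, dtype=float)
    if v.ndim == 0 or v.size != ramp_trace.current.size:
        raise ValueError("trace does not carry a per-sample voltage ramp")
    if not (v.min() <= voltage_mV <= v.max()):
        raise ValueError(
            f"requested voltage {voltage_mV} mV outside ramp range "
            f"[{v.min():.1f}, {v.max():.1f}] mV"
        )
    order = np.argsort(v, kind="stable")
    return float(np.interp(voltage_mV, v[order], ramp_trace.current[order]))


def compute_fold_activation(
    i_cold: float,
    i_warm: float,
    voltage_mV: float = 60.0,
    leak_cold: float = 0.0,
    leak_warm: float = 0.0,
    resolution: float = 1e-9,
) -> FoldActivation:
    """Fold activation by cooling: I_cold / I_warm at matched voltage.

    Optionally subtracts matched no-ligand leak currents first. When the warm
    current is below ``resolution`` the fold is undefined and flagged.
    """
    ic = i_cold - leak_cold
    iw = i_warm - leak_warm
    leak_corrected = (leak_cold != 0.0) or (leak_warm != 0.0)
    if abs(iw) < resolution:
        return FoldActivation(
            fold=float("nan"), voltage_mV=voltage_mV, i_cold=ic, i_warm=iw,
            leak_corrected=leak_corrected, defined=False,
        )
    return FoldActivation(
        fold=float(ic / iw), voltage_mV=voltage_mV, i_cold=ic, i_warm=iw,
        leak_corrected=leak_corrected,
    )


def fold_from_ramp_pair(
    ramp_cold: CurrentTrace,
    ramp_warm: CurrentTrace,
    voltage_mV: float = 60.0,
    leak_cold: CurrentTrace | None = None,
    leak_warm: CurrentTrace | None = None,
) -> FoldActivation:
    """Fold activation from a pair of voltage-ramp traces at two temperatures."""
    lc = extract_current_at_voltage(leak_cold, voltage_mV) if leak_cold is not None else 0.0
    lw = extract_current_at_voltage(leak_warm, voltage_mV) if leak_warm is not None else 0.0
    return compute_fold_activation(
        extract_current_at_voltage(ramp_cold, voltage_mV),
        extract_current_at_voltage(ramp_warm, voltage_mV),
        voltage_mV=voltage_mV,
        leak_cold=lc,
        leak_warm=lw,
    )


def compute_inhibition(trace: CurrentTrace) -> tuple[float, bool]:
    """Maximum percent inhibition of the cold-activated current by a drug.

    Requires ``pre_cold``, ``cold`` and ``drug`` interval annotations on a
    gap-free trace. The pre-cold mean defines the baseline; the peak deviation
    from baseline during the cold epoch defines the cold-activated current;
    inhibition is how far the drug pushes the deviation back toward baseline:

        inhibition% = 100 * (d_peak_cold - d_min_drug) / d_peak_cold

    Returns ``(percent, in_range)``; values are clamped to [0, 100] and
    ``in_range`` is False when the raw value fell outside.
    """
    for name in ("pre_cold", "cold", "drug"):
        if name not in trace.annotations:
            raise ValueError(f"missing '{name}' annotation")
    t = trace.times

    def window(name):
        a0, a1 = trace.annotations[name]
        return trace.current[(t >= a0) & (t <= a1)]

    baseline = float(np.mean(window("pre_cold")))
    d_cold = np.abs(window("cold") - baseline)
    d_drug = np.abs(window("drug") - baseline)
    peak = float(np.max(d_cold))
    if peak <= 0:
        raise ValueError("no cold-activated current above baseline")
    raw = 100.0 * (peak - float(np.min(d_drug))) / peak
    in_range = 0.0 <= raw <= 100.0
    return float(np.clip(raw, 0.0, 100.0)), in_range
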
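"""Synthetic-data generators with known ground truth.

Three generators emulate the statistical structure the analysis assumes:

* ``simulate_coverslip`` — a dish of Fura-2-loaded neurons: baseline ratio
  levels with iid noise, a specified fraction of thermoresponsive cells whose
  response waveform peaks shortly after the ramp, a terminal High-K+
  depolarization response in every healthy cell, and an optional fraction of
  cells that each violate exactly one named QC criterion by a >= 20% margin.
* ``simulate_current_trace`` — cold-activated channel current along a
  temperature protocol. The thermal gain is piecewise log-linear in inverse
  absolute temperature (true Arrhenius segments) with a breakpoint at the
  apparent activation threshold; segment slopes are anchored at the segment
  midpoints so the realized fold-change per 10 degC equals the requested Q10
  exactly at the reference cGMP concentration. Ligand dependence enters
  through the Hill equation; the implied EC50(T) is recoverable from the
  realized open probability by exact Hill inversion.
* ``simulate_conc_response`` — paired per-patch Hill concentration-response
  series at a warm and a cold temperature sharing a patch-level scale factor.

Every generator draws all randomness from a single ``numpy`` Generator seeded
by the spec/params seed, so identical inputs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from coldsense.caimg import RatioTrace
from coldsense.protocols import TemperatureProtocol
from coldsense.thermo import KELVIN_OFFSET, CurrentTrace, q10_to_slope

__all__ = [
    "PopulationSpec",
    "ChannelModelParams",
    "QC_FAIL_MODES",
    "simulate_coverslip",
    "simulate_current_trace",
    "simulate_conc_response",
]

QC_FAIL_MODES = ("high_baseline", "noisy_baseline", "no_recovery", "weak_high_k")

# injected violations exceed the corresponding QC threshold by >= 20%
_FAIL_BASELINE_LEVEL = 0.90      # vs mean <= 0.7
_FAIL_BASELINE_NOISE_SD = 0.10   # vs sd <= 0.05
_FAIL_RECOVERY_OFFSET = 0.75     # vs |drift| <= 0.5
_FAIL_HIGH_K_AMPLITUDE = 0.20    # vs amplitude >= 0.5


def _round_half_even(x: float) -> int:
    return int(np.rint(x))


@dataclass
class PopulationSpec:
    """Composition of one simulated coverslip population.

    Defaults describe a mouse-like preparation: ~10% of neurons respond to the
    thermal ramp with amplitudes well above the 0.575 classification
    threshold, nonresponders fluctuate far below it, and every healthy cell
    produces a robust High-K+ response.
    """

    n_cells: int = 200
    frac_responsive: float = 0.10
    responsive_amplitude_dist: tuple[float, float] = (1.2, 0.15)
    nonresponsive_amplitude_dist: tuple[float, float] = (0.10, 0.05)
    baseline_level_dist: tuple[float, float] = (0.45, 0.05)
    baseline_noise_sd: float = 0.01
    high_k_amplitude_dist: tuple[float, float] = (1.5, 0.25)
    frac_qc_fail: float = 0.0
    qc_fail_modes: dict[str, float] = field(
        default_factory=lambda: {m: 1.0 for m in QC_FAIL_MODES}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for name in ("frac_responsive", "frac_qc_fail"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in (
            "responsive_amplitude_dist",
            "nonresponsive_amplitude_dist",
            "baseline_level_dist",
            "high_k_amplitude_dist",
        ):
            if getattr(self, name)[1] < 0:
                raise ValueError(f"{name} sd must be >= 0")
        if self.baseline_noise_sd < 0:
            raise ValueError("baseline_noise_sd must be >= 0")
        unknown = set(self.qc_fail_modes) - set(QC_FAIL_MODES)
        if unknown:
            raise ValueError(f"unknown qc_fail_modes {sorted(unknown)}")


def _response_shape(t, peak_t, rise_sigma=6.0, decay_tau=18.0):
    """Half-Gaussian rise to a peak followed by exponential recovery."""
    rise = np.exp(-0.5 * ((t - peak_t) / rise_sigma) ** 2)
    fall = np.exp(-(t - peak_t) / decay_tau)
    return np.where(t <= peak_t, rise, fall)


def _high_k_shape(t, h0, h1):
    """Fast rise at High-K+ onset, sustained through the epoch, then decay."""
    rise = np.clip((t - h0) / 4.0, 0.0, 1.0)
    fall = np.where(t > h1, np.exp(-(t - h1) / 10.0), 1.0)
    return rise * fall


def simulate_coverslip(
    spec: PopulationSpec,
    protocol: TemperatureProtocol,
    coverslip_id: str = "cs0",
):
    """Generate one coverslip of ratio traces plus a ground-truth table.

    Responder counts follow round-half-to-even of ``frac_responsive * n``;
    QC-failing cells (round-half-even of ``frac_qc_fail * n``) are drawn
    uniformly across responders and nonresponders so exclusion is independent
    of class, and each violates exactly one criterion. Ground truth records
    each cell's class (``sensitive``/``insensitive``/``excluded``), underlying
    responsiveness, injected amplitudes and failure mode.
    """
    for name in ("baseline", "ramp", "high_k"):
        if name not in protocol.annotations:
            raise ValueError(f"protocol lacks required annotation {name!r}")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cells
    t = protocol.times
    r0, r1 = protocol.annotations["ramp"]
    h0, h1 = protocol.annotations["high_k"]

    n_resp = _round_half_even(spec.frac_responsive * n)
    n_fail = _round_half_even(spec.frac_qc_fail * n)
    responsive = np.zeros(n, dtype=bool)
    responsive[:n_resp] = True
    fail_idx = rng.choice(n, size=n_fail, replace=False)
    modes = np.array(list(spec.qc_fail_modes))
    weights = np.array([spec.qc_fail_modes[m] for m in modes], dtype=float)
    weights = weights / weights.sum()
    fail_mode = np.full(n, "", dtype=object)
    if n_fail:
        fail_mode[fail_idx] = rng.choice(modes, size=n_fail, p=weights)

    traces: list[RatioTrace] = []
    truth_rows = []
    for i in range(n):
        mode = fail_mode[i]
        level = rng.normal(*spec.baseline_level_dist)
        level = float(np.clip(level, 0.05, 0.65))
        noise_sd = spec.baseline_noise_sd
        if responsive[i]:
            amp = float(max(rng.normal(*spec.responsive_amplitude_dist), 0.0))
        else:
            amp = float(max(rng.normal(*spec.nonresponsive_amplitude_dist), 0.0))
        hk_amp = float(max(rng.normal(*spec.high_k_amplitude_dist), 0.65))

        if mode == "high_baseline":
            level = _FAIL_BASELINE_LEVEL
        elif mode == "noisy_baseline":
            noise_sd = _FAIL_BASELINE_NOISE_SD
        elif mode == "weak_high_k":
            hk_amp = _FAIL_HIGH_K_AMPLITUDE

        peak_t = (r0 + r1) / 2.0 + rng.uniform(5.0, 10.0)
        fr = level + amp * _response_shape(t, peak_t) + hk_amp * _high_k_shape(t, h0, h1)
        if mode == "no_recovery":
            # persistent drift starting after the response window closes
            fr = fr + _FAIL_RECOVERY_OFFSET * np.clip((t - (r1 + 12.0)) / 8.0, 0.0, 1.0)
        fr = fr + rng.normal(0.0, noise_sd, size=t.shape)
        fr = np.clip(fr, 0.0, None)

        cell_id = f"{coverslip_id}_c{i:04d}"
        traces.append(
            RatioTrace(
                cell_id=cell_id,
                times=t.copy(),
                fr=fr,
                coverslip_id=coverslip_id,
                annotations=dict(protocol.annotations),
            )
        )
        if mode:
            true_class = "excluded"
        elif responsive[i]:
            true_class = "sensitive"
        else:
            true_class = "insensitive"
        truth_rows.append(
            {
                "cell_id": cell_id,
                "coverslip_id": coverslip_id,
                "true_class": true_class,
                "underlying_responsive": bool(responsive[i]),
                "true_amplitude": amp,
                "true_high_k_amplitude": hk_amp,
                "baseline_level": level,
                "fail_mode": mode or None,
            }
        )
    return traces, pd.DataFrame(truth_rows)


@dataclass
class ChannelModelParams:
    """Generative parameters of the cold-potentiated channel model.

    Defaults match the characterized mouse channel: EC50 falling from 21.8 uM
    at 22 degC to 3.5 uM at 12 degC, maximal current inhibited by 25% on
    cooling, apparent activation threshold 22.4 degC, and a below-threshold
    Q10 of 6.5 (current grows ~6.5-fold per 10 degC of cooling).
    """

    ec50_warm: float = 21.8
    ec50_cold: float = 3.5
    hill_h: float = 2.0
    imax_warm: float = 2.0          # maximal current magnitude at -80 mV, nA
    imax_cold_fraction: float = 0.75
    threshold_T: float = 22.4
    q10_below: float = 6.5
    q10_above: float = 1.3
    leak_conductance: float = 0.0   # nA per mV
    reversal_V: float = 0.0
    noise_sd: float = 0.0           # current units
    patch_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ec50_warm <= 0 or self.ec50_cold <= 0:
            raise ValueError("EC50 values must be > 0")
        if self.hill_h <= 0:
            raise ValueError("hill_h must be > 0")
        if not 0.0 < self.imax_cold_fraction <= 1.0:
            raise ValueError("imax_cold_fraction must lie in (0, 1]")
        if self.q10_below < 1.0 or self.q10_above < 1.0:
            raise ValueError("Q10 values must be >= 1")
        if not 0.0 <= self.patch_cv < 1.0:
            raise ValueError("patch_cv must lie in [0, 1)")


def _hill_fraction(conc, ec50, h):
    conc = np.asarray(conc, dtype=float)
    out = np.zeros_like(conc, dtype=float)
    pos = conc > 0
    out[pos] = 1.0 / (1.0 + (ec50 / conc[pos]) ** h)
    return out if out.ndim else float(out)


def _lognormal_scale(rng, cv):
    if cv <= 0:
        return 1.0
    sigma2 = np.log(1.0 + cv**2)
    return float(rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2)))


def simulate_current_trace(
    params: ChannelModelParams,
    protocol: TemperatureProtocol,
    cgmp_uM: float = 1.0,
    hold_mV: float = -80.0,
):
    """Channel current along a temperature protocol; returns (trace, truth).

    The noiseless current is

        I(t) = Gmax * p(T(t)) * (V - Vrev) + g_leak * (V - Vrev)

    with Gmax calibrated so the saturating current magnitude at -80 mV equals
    ``imax_warm``, and open fraction p(T) = p_warm * F(T) where p_warm is the
    Hill fraction at the reference cGMP and warm EC50, and ln F is continuous
    piecewise-linear in 1/T_K, breaking at ``threshold_T``, with segment
    slopes chosen so the midpoint-referenced Q10 of each segment equals the
    requested value exactly. ``truth`` carries the injected threshold, Q10s,
    Arrhenius slopes, and the implied EC50 at the protocol's extreme
    temperatures (exact Hill inversion of p).
    """
    if cgmp_uM < 0:
        raise ValueError("cgmp_uM must be >= 0")
    rng = np.random.default_rng(params.seed)
    t = protocol.times
    temp = protocol.temperatures
    t_min, t_max = float(temp.min()), float(temp.max())
    tb = float(np.clip(params.threshold_T, t_min, t_max))

    mid_below = (t_min + tb) / 2.0
    mid_above = (tb + t_max) / 2.0
    s_below = q10_to_slope(params.q10_below, mid_below) if tb > t_min else 0.0
    s_above = q10_to_slope(params.q10_above, mid_above) if tb < t_max else 0.0

    x = 1.0 / (temp + KELVIN_OFFSET)
    x0 = 1.0 / (t_max + KELVIN_OFFSET)
    xb = 1.0 / (tb + KELVIN_OFFSET)
    ln_f = s_above * (np.minimum(x, xb) - x0) + s_below * np.maximum(0.0, x - xb)

    p_warm = _hill_fraction(np.asarray([cgmp_uM]), params.ec50_warm, params.hill_h)[0]
    p = np.clip(p_warm * np.exp(ln_f), 0.0, 1.0)

    scale = _lognormal_scale(rng, params.patch_cv)
    g_max = params.imax_warm / abs(-80.0 - params.reversal_V)
    driving = hold_mV - params.reversal_V
    current = scale * g_max * p * driving + params.leak_conductance * driving
    if params.noise_sd > 0:
        current = current + rng.normal(0.0, params.noise_sd, size=t.shape)

    trace = CurrentTrace(
        times=t.copy(),
        current=current,
        temperature=temp.copy(),
        voltage=hold_mV,
        cgmp_uM=cgmp_uM,
        condition={"model": "synthetic"},
        annotations=dict(protocol.annotations),
    )

    def implied_ec50(temp_c: float) -> float:
        xq = 1.0 / (temp_c + KELVIN_OFFSET)
        lf = s_above * (min(xq, xb) - x0) + s_below * max(0.0, xq - xb)
        pq = min(p_warm * np.exp(lf), 1.0 - 1e-12)
        if pq <= 0:
            return float("inf")
        return float(cgmp_uM * (1.0 / pq - 1.0) ** (1.0 / params.hill_h))

    truth = {
        "threshold_T": tb,
        "q10_below": params.q10_below,
        "q10_above": params.q10_above,
        "slope_below": s_below,
        "slope_above": s_above,
        "p_warm": p_warm,
        "patch_scale": scale,
        "ec50_at_t_min": implied_ec50(t_min),
        "ec50_at_t_max": implied_ec50(t_max),
    }
    return trace, truth


def simulate_conc_response(
    params: ChannelModelParams,
    concs_uM,
    temps_C: tuple[float, float] = (22.0, 12.0),
    n_patches: int = 4,
):
    """Paired per-patch concentration-response series at two temperatures.

    The warmer member of ``temps_C`` uses (ec50_warm, imax_warm); the colder
    uses (ec50_cold, imax_warm * imax_cold_fraction). Each patch draws two
    log-normal factors of CV ``patch_cv``, both shared by its two
    temperatures: an amplitude scale on Imax and a ligand-sensitivity factor
    multiplying both EC50s (patch-to-patch EC50 spread preserves the paired
    cold/warm ratio, as patch-level variation in apparent ligand sensitivity
    does). Points get iid Gaussian noise of SD ``noise_sd``. Returns
    (list of ConcResponseSeries, ground-truth DataFrame).
    """
    concs = np.asarray(sorted(concs_uM), dtype=float)
    if concs.size < 4 or np.unique(concs).size != concs.size:
        raise ValueError("need >= 4 distinct concentrations")
    if not (concs.min() < params.ec50_warm < concs.max()):
        raise ValueError("concentrations must span the warm EC50")
    rng = np.random.default_rng(params.seed)
    warm, cold = (max(temps_C), min(temps_C))
    per_temp = {
        warm: (params.ec50_warm, params.imax_warm),
        cold: (params.ec50_cold, params.imax_warm * params.imax_cold_fraction),
    }
    series: list = []
    truth_rows = []
    from coldsense.hill import ConcResponseSeries

    for k in range(n_patches):
        patch_id = f"patch{k:02d}"
        scale = _lognormal_scale(rng, params.patch_cv)
        sens = _lognormal_scale(rng, params.patch_cv)
        for temp_c in (warm, cold):
            base_ec50, imax = per_temp[temp_c]
            ec50 = base_ec50 * sens
            ideal = scale * imax * _hill_fraction(concs, ec50, params.hill_h)
            noisy = ideal + (
                rng.normal(0.0, params.noise_sd, size=concs.shape)
                if params.noise_sd > 0
                else 0.0
            )
            series.append(
                ConcResponseSeries(
                    patch_id=patch_id,
                    temperature_C=temp_c,
                    conc_uM=concs.copy(),
                    current=noisy,
                )
            )
            truth_rows.append(
                {
                    "patch_id": patch_id,
                    "temperature_C": temp_c,
                    "scale": scale,
                    "ec50_true": ec50,
                    "imax_true": scale * imax,
                    "hill_h": params.hill_h,
                }
            )
    return series, pd.DataFrame(truth_rows)
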
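"""Tabular readers/writers and run configuration.

All on-disk formats are plain CSV/TSV with explicit schemas; times are seconds
from recording start and temperatures degC (Kelvin appears only inside the
Arrhenius math). Validation errors name the offending column or row.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from coldsense.caimg import CellAssessment, CoverslipSummary, RatioTrace
from coldsense.hill import ConcResponseSeries, HillParams
from coldsense.thermo import CurrentTrace

__all__ = [
    "RunConfig",
    "read_trace_table",
    "read_current_table",
    "read_conc_response_table",
    "write_assessments",
    "write_summaries",
    "write_hill_params",
]

TRACE_COLUMNS = ("cell_id", "coverslip_id", "time_s", "fr")
ANNOTATION_COLUMNS = ("coverslip_id", "epoch", "start_s", "end_s")
CURRENT_COLUMNS = ("cell_id", "time_s", "current", "temp_C")
CONC_COLUMNS = ("patch_id", "temp_C", "cgmp_uM", "current_pA")


class PopulationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_cells: int = 200
    frac_responsive: float = 0.10
    responsive_amplitude_mean: float = 1.2
    responsive_amplitude_sd: float = 0.15
    nonresponsive_amplitude_mean: float = 0.10
    nonresponsive_amplitude_sd: float = 0.05
    baseline_level_mean: float = 0.45
    baseline_level_sd: float = 0.05
    baseline_noise_sd: float = 0.01
    high_k_amplitude_mean: float = 1.5
    high_k_amplitude_sd: float = 0.25
    frac_qc_fail: float = 0.0


class QCConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    baseline_mean_max: float = 0.7
    baseline_sd_max: float = 0.05
    recovery_diff_max: float = 0.5
    high_k_amplitude_min: float = 0.5
    baseline_window_s: float = 45.0
    pre_high_k_window_s: float = 20.0


class ChannelConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    ec50_warm: float = 21.8
    ec50_cold: float = 3.5
    hill_h: float = 2.0
    imax_warm: float = 2.0
    imax_cold_fraction: float = 0.75
    threshold_T: float = 22.4
    q10_below: float = 6.5
    q10_above: float = 1.3
    noise_sd: float = 0.0
    patch_cv: float = 0.0


class RunConfig(BaseModel):
    """End-to-end report configuration; round-trips losslessly through YAML."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    n_coverslips: int = 6
    mode: str = "cold"
    classification_threshold_fr: float = 0.575
    warm_C: float = 22.0
    cold_C: float = 12.0
    n_patches: int = 4
    n_thermo_cells: int = 5
    concs_uM: list[float] = Field(
        default_factory=lambda: [0.5, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0, 1000.0]
    )
    pin_imin: bool = False
    population: PopulationConfig = Field(default_factory=PopulationConfig)
    qc: QCConfig = Field(default_factory=QCConfig)
    channel: ChannelConfig = Field(default_factory=ChannelConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing required column(s) {missing}")


def _check_finite(df: pd.DataFrame, col: str, what: str) -> None:
    bad = df.index[~np.isfinite(df[col].to_numpy(dtype=float))]
    if len(bad):
        raise ValueError(f"{what}: non-finite {col!r} at row(s) {list(bad[:5])}")


def read_trace_table(
    traces_path, annotations_path, metadata_path=None
) -> tuple[list[RatioTrace], pd.DataFrame | None]:
    """Read long-format ratio traces plus per-coverslip epoch annotations.

    Rows may arrive in any order; they are grouped by cell and sorted by time.
    Duplicate timestamps within a cell, NaN ratios and missing columns raise
    named validation errors.
    """
    df = pd.read_csv(traces_path)
    _require_columns(df, TRACE_COLUMNS, "trace table")
    _check_finite(df, "fr", "trace table")
    _check_finite(df, "time_s", "trace table")
    ann = pd.read_csv(annotations_path)
    _require_columns(ann, ANNOTATION_COLUMNS, "annotation table")
    ann_by_cs = {
        cs: {r.epoch: (float(r.start_s), float(r.end_s)) for r in g.itertuples()}
        for cs, g in ann.groupby("coverslip_id")
    }
    traces = []
    for (cell_id, cs_id), g in df.groupby(["cell_id", "coverslip_id"], sort=True):
        g = g.sort_values("time_s", kind="stable")
        t = g["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            dup = g.index[1:][np.diff(t) <= 0]
            raise ValueError(
                f"trace table: non-increasing time for cell {cell_id} at row(s) {list(dup[:5])}"
            )
        if cs_id not in ann_by_cs:
            raise ValueError(f"annotation table: no epochs for coverslip {cs_id}")
        traces.append(
            RatioTrace(
                cell_id=str(cell_id),
                times=t,
                fr=g["fr"].to_numpy(dtype=float),
                coverslip_id=str(cs_id),
                annotations=ann_by_cs[cs_id],
            )
        )
    meta = pd.read_csv(metadata_path) if metadata_path else None
    return traces, meta


def read_current_table(path) -> list[CurrentTrace]:
    """Read long-format current traces (cell_id, time_s, current, temp_C
    [, voltage_mV, cgmp_uM])."""
    df = pd.read_csv(path)
    _require_columns(df, CURRENT_COLUMNS, "current table")
    for col in ("current", "temp_C", "time_s"):
        _check_finite(df, col, "current table")
    out = []
    for cell_id, g in df.groupby("cell_id", sort=True):
        g = g.sort_values("time_s", kind="stable")
        t = g["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"current table: non-increasing time for cell {cell_id}")
        voltage = (
            g["voltage_mV"].to_numpy(dtype=float) if "voltage_mV" in g.columns else -80.0
        )
        if np.ndim(voltage) and np.ptp(voltage) == 0:
            voltage = float(voltage[0])
        out.append(
            CurrentTrace(
                times=t,
                current=g["current"].to_numpy(dtype=float),
                temperature=g["temp_C"].to_numpy(dtype=float),
                voltage=voltage,
                cgmp_uM=float(g["cgmp_uM"].iloc[0]) if "cgmp_uM" in g.columns else 0.0,
                cell_id=str(cell_id),
            )
        )
    return out


def read_conc_response_table(path) -> list[ConcResponseSeries]:
    """Read per-patch concentration-response points
    (patch_id, temp_C, cgmp_uM, current_pA [, construct])."""
    df = pd.read_csv(path)
    _require_columns(df, CONC_COLUMNS, "concentration-response table")
    for col in ("cgmp_uM", "current_pA", "temp_C"):
        _check_finite(df, col, "concentration-response table")
    out = []
    for (patch_id, temp_c), g in df.groupby(["patch_id", "temp_C"], sort=True):
        g = g.sort_values("cgmp_uM", kind="stable")
        out.append(
            ConcResponseSeries(
                patch_id=str(patch_id),
                temperature_C=float(temp_c),
                conc_uM=g["cgmp_uM"].to_numpy(dtype=float),
                current=g["current_pA"].to_numpy(dtype=float),
                condition=str(g["construct"].iloc[0]) if "construct" in g.columns else "",
            )
        )
    return out


def assessments_frame(assessments: list[CellAssessment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_id": a.cell_id,
                "coverslip_id": a.coverslip_id,
                "baseline_mean": a.baseline_mean,
                "baseline_sd": a.baseline_sd,
                "response_amplitude": a.response_amplitude,
                "high_k_amplitude": a.high_k_amplitude,
                "recovery_diff": a.recovery_diff,
                "qc_pass": a.qc_pass,
                "qc_failures": ";".join(a.qc_failures),
                "cell_class": a.cell_class,
            }
            for a in assessments
        ]
    )


def write_assessments(assessments: list[CellAssessment], path) -> None:
    assessments_frame(assessments).to_csv(path, sep="\t", index=False)


def summaries_frame(summaries: list[CoverslipSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {
            "coverslip_id": s.coverslip_id,
            "n_total": s.n_total,
            "n_pass_qc": s.n_pass_qc,
            "n_sensitive": s.n_sensitive,
            "pct_sensitive": s.pct_sensitive,
            "mean_high_k_amplitude": s.mean_high_k_amplitude,
        }
        row.update(s.group_labels)
        rows.append(row)
    return pd.DataFrame(rows)


def write_summaries(summaries: list[CoverslipSummary], path) -> None:
    summaries_frame(summaries).to_csv(path, sep="\t", index=False)


def hill_params_frame(fits: dict[str, dict[float, HillParams]]) -> pd.DataFrame:
    rows = []
    for patch_id, by_temp in fits.items():
        for temp_c, p in sorted(by_temp.items(), reverse=True):
            rows.append(
                {
                    "patch_id": patch_id,
                    "temp_C": temp_c,
                    "i_min": p.i_min,
                    "i_max": p.i_max,
                    "ec50_uM": p.ec50,
                    "hill_h": p.h,
                    "residual_norm": p.residual_norm,
                    "converged": p.converged,
                    "n_points": p.n_points,
                }
            )
    return pd.DataFrame(rows)


def write_hill_params(fits: dict[str, dict[float, HillParams]], path) -> None:
    hill_params_frame(fits).to_csv(path, sep="\t", index=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
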
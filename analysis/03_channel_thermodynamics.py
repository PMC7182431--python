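"""Quantify the temperature dependence of the cold-potentiated channel.

Fits biphasic Arrhenius relations to replicate simulated temperature-ramp
recordings (apparent activation threshold and segmental Q10), measures cold
fold-activation on warm/cold/rewarm step protocols (including its
reversibility), and quantifies maximum drug inhibition of cold-activated
current for homomer-like vs heteromer-like block depths.

Writes: results/arrhenius_fits.tsv, results/fold_activation.tsv,
        results/inhibition.tsv
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from cohort import channel_params, seeds

from coldsense import stats as cs
from coldsense.protocols import make_temperature_protocol
from coldsense.synth import simulate_current_trace
from coldsense.thermo import (
    CurrentTrace,
    arrhenius_transform,
    compute_fold_activation,
    compute_inhibition,
    fit_threshold,
)


def main() -> None:
    out_dir = Path(__file__).resolve().parents[1] / "results"
    out_dir.mkdir(exist_ok=True)

    # --- Arrhenius threshold and Q10 over replicate cells -----------------
    broad = make_temperature_protocol("broad_ramp", duration_s=300.0)
    rows = []
    for k, seed in enumerate(seeds("arrhenius", 20)):
        params = channel_params("mouse", seed, noise_sd=5e-4, patch_cv=0.25)
        trace, _ = simulate_current_trace(params, broad, cgmp_uM=1.0)
        fit = fit_threshold(arrhenius_transform(trace))
        rows.append(
            {
                "cell_id": f"cell{k:02d}",
                "threshold_C": fit.threshold_T,
                "q10_below": fit.q10_below,
                "q10_above": fit.q10_above,
                "has_threshold": fit.has_threshold,
                "f_ratio": fit.f_ratio,
            }
        )
    arr = pd.DataFrame(rows)
    arr.to_csv(out_dir / "arrhenius_fits.tsv", sep="\t", index=False)
    thr, q10 = cs.mean_sem(arr["threshold_C"]), cs.mean_sem(arr["q10_below"])
    print(
        f"Apparent activation threshold {thr.mean:.1f} +/- {thr.sem:.1f} C, "
        f"Q10 below threshold {q10.mean:.1f} +/- {q10.sem:.1f} (n={thr.n} cells)"
    )

    # --- cold fold-activation and its reversibility -----------------------
    step = make_temperature_protocol("step_pair", duration_s=300.0)
    fold_rows = []
    for k, seed in enumerate(seeds("fold", 10)):
        params = channel_params("mouse", seed, noise_sd=5e-4, patch_cv=0.25)
        trace, _ = simulate_current_trace(params, step, cgmp_uM=1.0)
        t = trace.times

        def level(name):
            a0, a1 = trace.annotations[name]
            return float(np.mean(trace.current[(t >= a0) & (t <= a1)]))

        cool = compute_fold_activation(level("cold"), level("warm"), voltage_mV=-80.0)
        rewarm = compute_fold_activation(level("cold"), level("rewarm"), voltage_mV=-80.0)
        fold_rows.append(
            {"cell_id": f"cell{k:02d}", "fold_cooling": cool.fold, "fold_vs_rewarm": rewarm.fold}
        )
    folds = pd.DataFrame(fold_rows)
    folds.to_csv(out_dir / "fold_activation.tsv", sep="\t", index=False)
    fm = cs.mean_sem(folds["fold_cooling"])
    rev = float(np.max(np.abs(folds["fold_cooling"] / folds["fold_vs_rewarm"] - 1.0)))
    print(
        f"Cold fold-activation at -80 mV: {fm.mean:.2f} +/- {fm.sem:.2f} (n={fm.n}); "
        f"cooling vs rewarm limbs agree within {100 * rev:.2f}%"
    )

    # --- maximum drug inhibition: homomer-like vs heteromer-like ----------
    rng = np.random.default_rng(seeds("inhibition", 1)[0])
    tt = np.arange(0.0, 100.0, 0.1)

    def drug_trace(depth_fraction):
        cur = np.zeros_like(tt)
        cur[tt >= 20.0] = -2.0
        cur[(tt >= 50.0) & (tt < 70.0)] = -2.0 * (1.0 - depth_fraction)
        cur += rng.normal(0.0, 0.01, size=tt.shape)
        return CurrentTrace(
            times=tt, current=cur, temperature=np.full_like(tt, 12.0),
            annotations={"pre_cold": (0.0, 19.0), "cold": (20.0, 49.0), "drug": (50.0, 69.0)},
        )

    inh_rows = []
    for construct, depth in (("homomer", 0.35), ("heteromer", 0.70)):
        for k in range(6):
            pct, in_range = compute_inhibition(drug_trace(depth))
            inh_rows.append({"construct": construct, "cell": k, "inhibition_pct": pct,
                             "in_range": in_range})
    inh = pd.DataFrame(inh_rows)
    inh.to_csv(out_dir / "inhibition.tsv", sep="\t", index=False)
    means = inh.groupby("construct")["inhibition_pct"].mean()
    res = cs.compare_groups(
        inh.loc[inh["construct"] == "heteromer", "inhibition_pct"].to_numpy(),
        inh.loc[inh["construct"] == "homomer", "inhibition_pct"].to_numpy(),
        forced_test="welch_t",
    )
    print(
        f"Maximum inhibition: homomer {means['homomer']:.1f}%, heteromer "
        f"{means['heteromer']:.1f}% ({means['heteromer'] / means['homomer']:.2f}-fold; "
        f"Welch p={res.p_value:.2g} {res.significance_label})"
    )


if __name__ == "__main__":
    main()
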
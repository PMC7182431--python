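"""Classify thermosensitive neurons per coverslip and compare conditions.

Runs the full imaging pipeline (QC, response amplitudes, 0.575-unit
classification, per-coverslip aggregation) on the simulated cohort, then
compares per-coverslip percentages of cold-sensitive neurons across
conditions the way the coverslip is the unit of analysis: Mann-Whitney for
the species contrast, Welch's t for the drug contrast, after the normality
gate's audit.

Writes: results/coverslip_summaries.tsv, results/group_comparisons.tsv
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from cohort import CONDITIONS, population_spec, seeds

from coldsense import stats as cs
from coldsense.caimg import assess_cell, summarize_coverslip
from coldsense.protocols import make_temperature_protocol
from coldsense.synth import simulate_coverslip


def main() -> None:
    out_dir = Path(__file__).resolve().parents[1] / "results"
    out_dir.mkdir(exist_ok=True)
    protocol = make_temperature_protocol("cooling_ramp")

    rows = []
    for condition, cond in CONDITIONS.items():
        for k, seed in enumerate(seeds(condition, cond["n_coverslips"])):
            spec = population_spec(condition, seed)
            traces, _ = simulate_coverslip(spec, protocol, coverslip_id=f"{condition}_cs{k:02d}")
            assessments = [assess_cell(tr) for tr in traces]
            s = summarize_coverslip(assessments, group_labels={"condition": condition})
            rows.append(
                {
                    "coverslip_id": s.coverslip_id,
                    "condition": condition,
                    "n_total": s.n_total,
                    "n_pass_qc": s.n_pass_qc,
                    "n_sensitive": s.n_sensitive,
                    "pct_sensitive": s.pct_sensitive,
                    "mean_high_k_amplitude": s.mean_high_k_amplitude,
                }
            )
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "coverslip_summaries.tsv", sep="\t", index=False)

    def pcts(condition):
        return table.loc[table["condition"] == condition, "pct_sensitive"].to_numpy()

    comparisons = [
        ("mouse_vs_squirrel", pcts("mouse"), pcts("squirrel"), "mann_whitney"),
        ("mouse_ctrl_vs_diltiazem", pcts("mouse"), pcts("mouse_diltiazem"), "welch_t"),
    ]
    comp_rows = []
    for name, a, b, forced in comparisons:
        res = cs.compare_groups(a, b, forced_test=forced)
        ma, mb = cs.mean_sem(a), cs.mean_sem(b)
        comp_rows.append(
            {
                "comparison": name,
                "test": res.test_name,
                "mean_a": ma.mean, "sem_a": ma.sem, "n_a": ma.n,
                "mean_b": mb.mean, "sem_b": mb.sem, "n_b": mb.n,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "label": res.significance_label,
            }
        )
        print(
            f"{name}: {ma.mean:.1f} +/- {ma.sem:.1f}% (n={ma.n}) vs "
            f"{mb.mean:.1f} +/- {mb.sem:.1f}% (n={mb.n}); "
            f"{res.test_name} p={res.p_value:.4g} ({res.significance_label})"
        )
    pd.DataFrame(comp_rows).to_csv(out_dir / "group_comparisons.tsv", sep="\t", index=False)

    print("\nPer-coverslip mean High-K+ amplitudes by condition:")
    print(table.groupby("condition")["mean_high_k_amplitude"].mean().round(3).to_string())


if __name__ == "__main__":
    main()
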
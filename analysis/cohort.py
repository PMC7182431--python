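"""Shared synthetic study cohort for the numbered analysis scripts.

Defines the simulated experimental conditions once so every stage draws the
same deterministic cohort: mouse-like and squirrel-like coverslip populations
(differing in their cold-responsive fraction), a drug-treated condition with
cold responses suppressed, channel-model parameter sets for the two species
orthologues, and the seed policy. Scripts regenerate data on demand — the
generators are deterministic, so stages agree without large intermediates.
"""

from __future__ import annotations

import numpy as np

from coldsense.synth import ChannelModelParams, PopulationSpec

BASE_SEED = 2026

# per-coverslip population conditions (cold-responsive fractions as observed
# per species; drug condition suppresses nearly all cold responders)
CONDITIONS = {
    "mouse": {"frac_responsive": 0.100, "n_coverslips": 12},
    "squirrel": {"frac_responsive": 0.068, "n_coverslips": 12},
    "mouse_diltiazem": {"frac_responsive": 0.010, "n_coverslips": 5},
}

# channel-model parameter sets: the mouse orthologue is cold-potentiated
# (EC50 falls steeply on cooling), the squirrel orthologue is not, and its
# maximal activity is inhibited more strongly by cold
CHANNELS = {
    "mouse": dict(ec50_warm=21.8, ec50_cold=3.5, imax_cold_fraction=0.75),
    "squirrel": dict(ec50_warm=26.4, ec50_cold=20.4, imax_cold_fraction=0.40),
}

CONCS_UM = [0.5, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0, 1000.0]
N_PATCHES = {"mouse": 4, "squirrel": 5}


def seeds(tag: str, n: int) -> list[int]:
    """Deterministic per-stage seed stream derived from the cohort base seed."""
    tag_offset = sum(ord(c) for c in tag)
    ss = np.random.SeedSequence([BASE_SEED, tag_offset])
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def population_spec(condition: str, seed: int) -> PopulationSpec:
    cond = CONDITIONS[condition]
    return PopulationSpec(
        n_cells=200,
        frac_responsive=cond["frac_responsive"],
        frac_qc_fail=0.05,
        seed=seed,
    )


def channel_params(species: str, seed: int, noise_sd=0.02, patch_cv=0.25) -> ChannelModelParams:
    return ChannelModelParams(seed=seed, noise_sd=noise_sd, patch_cv=patch_cv, **CHANNELS[species])
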
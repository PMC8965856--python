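"""Recomputable headline quantities of the analysis.

Helpers that regenerate, from scratch, the quantities the package is
designed to reproduce: the worked-example statistics that follow directly
from printed cohort tables, and the Monte-Carlo recovery of the planted
synthetic-cohort effects (alpha-suppression ratios, group detection rate,
regression-coefficient recovery). Used by the acceptance script and the
acceptance test suite.
"""

from __future__ import annotations

import numpy as np

from .pipeline import RunConfig, run_pipeline, select_clean_epoch
from .simulate import CohortSimParams, EegSimParams, simulate_participant_pair
from .spectral import alpha_ratio, compute_welch_psd

#: EEG synthesis restricted to the three analyzed midline electrodes:
#: channels are statistically independent, so this changes only run time.
MIDLINE_CHANNELS = ("Fz", "Cz", "Pz")


def mean_recovered_ratio(group: str, suppression: float, n_seeds: int,
                         base_seed: int) -> float:
    """Mean raw-mode Cz attention-to-resting alpha ratio over seeded
    session pairs with a fixed planted suppression."""
    params = EegSimParams(channels=("Cz",))
    vals = []
    for i in range(n_seeds):
        rest, task, _ = simulate_participant_pair(
            group, params, base_seed + i, suppression=suppression)
        sr = compute_welch_psd(select_clean_epoch(rest))
        st = compute_welch_psd(select_clean_epoch(task))
        vals.append(alpha_ratio(st, sr)[0])
    return float(np.mean(vals))


def cohort_recovery(n_detect: int, n_slope: int, base_seed: int) -> dict:
    """End-to-end cohort Monte Carlo.

    Runs the full pipeline (simulate -> epoch selection -> Welch ->
    ratios -> statistics) on ``n_slope`` seeded default cohorts in raw
    ratio mode. Returns the fraction of the first ``n_detect`` runs whose
    Cz alpha-ratio group difference reaches p < 0.05 (Mann-Whitney), and
    the mean full-entry-model commission-on-ratio coefficient across all
    ``n_slope`` runs.
    """
    detect = 0
    slopes = []
    for i in range(n_slope):
        cfg = RunConfig(
            seed=base_seed + i, ratio_mode="raw",
            sim=CohortSimParams(eeg=EegSimParams(channels=MIDLINE_CHANNELS)),
        )
        bundle = run_pipeline(cfg)
        if i < n_detect:
            p = bundle.alpha_ratio_comparison.set_index("channel").loc["Cz", "p"]
            detect += p < 0.05
        full = bundle.regression_commission.full_model.set_index("name")
        slopes.append(full.loc["cz_alpha_ratio", "B"])
    return {
        "detection_rate": detect / min(n_detect, n_slope),
        "mean_commission_slope": float(np.mean(slopes)),
        "n_detect": min(n_detect, n_slope),
        "n_slope": n_slope,
    }


def omission_slope_recovery(n_seeds: int, base_seed: int) -> float:
    """Mean full-entry-model coefficient of intelligence on the omission
    T-score over seeded default cohorts (EEG-free: the coupling involves
    no spectral quantity)."""
    import pandas as pd

    from .regression import stepwise_regression
    from .simulate import simulate_cohort

    coefs = []
    params = CohortSimParams(eeg=EegSimParams(channels=MIDLINE_CHANNELS))
    for i in range(n_seeds):
        cohort, _, man = simulate_cohort(params, seed=base_seed + i,
                                         include_eeg=False)
        cand = pd.DataFrame({
            "cz_alpha_ratio": [man["participants"][p]["planted_raw_cz_alpha_ratio"]
                               for p in cohort.participant_id],
            "genotype_group": (cohort.group == "PWS").astype(float).to_numpy(),
            "age": cohort.age.to_numpy(),
            "intelligence": cohort.intelligence.astype(float).to_numpy(),
            "bmi_z": cohort.bmi_z.to_numpy(),
        })
        tab = stepwise_regression(cohort.cpt_omission, cand)
        coefs.append(tab.full_model.set_index("name").loc["intelligence", "B"])
    return float(np.mean(coefs))
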
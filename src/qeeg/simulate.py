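"""Synthetic EEG sessions and behavioral cohorts.

Generates data with the statistical structure the analysis assumes, so the
full pipeline is testable end to end without any recordings:

* **EEG sessions** — a 1/f^beta Gaussian background (spectral-shaping
  construction) plus band-limited stochastic oscillators (narrow-band
  filtered noise, not pure sinusoids, so alpha power varies naturally across
  1-s Welch blocks). Eyes-closed rest has a prominent ~10 Hz alpha rhythm;
  the attention (go/no-go task) session multiplies the alpha oscillator
  amplitude by sqrt(1 - s), planting a fractional alpha POWER suppression
  ``s`` — drawn Uniform[0.60, 0.70] for controls and centered on 0.30 for
  the patient group — and, for controls only, boosts delta + theta power.
* **Cohorts** — two groups of 10 with demographics, genotype, intelligence
  category, BMI (z-scored against the bundled synthetic reference) and nine
  go/no-go T-scores; commission-error T-scores are linearly coupled to each
  participant's planted attention-to-resting Cz alpha ratio and omission
  T-scores to the intelligence category. A manifest records every planted
  ground-truth value for recovery testing.

Everything is bit-reproducible under a seed at every level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .recording import TEN_TWENTY_19, EegRecording
from .stats import BmiNormTable, bmi_zscore, classify_weight, synthetic_norm_table

# ---------------------------------------------------------------------------
# EEG session simulation
# ---------------------------------------------------------------------------

#: Default oscillators: name -> (center Hz, bandwidth Hz, RMS amplitude uV).
#: Bandwidth is 2 sigma of the Gaussian spectral envelope, so >= 95% of an
#: oscillator's power stays inside center +/- bandwidth.
DEFAULT_OSCILLATORS: dict[str, tuple[float, float, float]] = {
    "delta": (2.0, 1.5, 5.0),
    "theta": (6.0, 2.0, 8.0),
    "alpha": (10.0, 2.0, 20.0),
    "beta": (20.0, 6.0, 5.0),
}


@dataclass
class EegSimParams:
    """Parameters of the synthetic EEG session generator."""

    fs: float = 200.0
    duration: float = 60.0                    # seconds, >= 60 for a full epoch
    background_exponent: float = 1.0          # beta of the 1/f^beta background
    background_scale: float = 7.0             # total background RMS, uV
    background_f_floor: float = 0.5           # flatten the 1/f shape below this
    oscillators: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_OSCILLATORS)
    )
    # alpha POWER suppression s in the attention session (amplitude x sqrt(1-s))
    control_suppression_range: tuple[float, float] = (0.60, 0.70)
    pws_suppression_mean: float = 0.30
    pws_suppression_sd: float = 0.12
    pws_suppression_bounds: tuple[float, float] = (0.0, 0.60)
    # multiplicative delta+theta POWER gain, controls' attention session only
    attention_low_freq_boost: float = 1.5
    artifact_rate: float = 0.0                # transients per minute
    artifact_amplitude: float = 300.0         # uV
    artifact_duration: float = 0.5            # seconds
    channels: tuple[str, ...] = TEN_TWENTY_19

    def __post_init__(self) -> None:
        if any(amp < 0 for _, _, amp in self.oscillators.values()):
            raise ValueError("oscillator amplitudes must be non-negative")
        lo, hi = self.control_suppression_range
        if not (0 <= lo <= hi < 1):
            raise ValueError("suppression fractions must lie in [0, 1)")


def _rfft_freqs(n: int, fs: float) -> np.ndarray:
    return np.fft.rfftfreq(n, d=1.0 / fs)


def _background_weights(n: int, params: EegSimParams) -> np.ndarray:
    """Amplitude weights of the 1/f^beta background over rfft bins (DC = 0)."""
    f = _rfft_freqs(n, params.fs)
    w = np.zeros_like(f)
    eff = np.maximum(f, params.background_f_floor)
    w[1:] = eff[1:] ** (-params.background_exponent / 2.0)
    return w


def _oscillator_weights(n: int, fs: float, center: float, bandwidth: float) -> np.ndarray:
    """Gaussian spectral envelope; bandwidth = 2 sigma of the amplitude profile."""
    f = _rfft_freqs(n, fs)
    sigma = bandwidth / 2.0
    w = np.exp(-((f - center) ** 2) / (2.0 * sigma**2))
    w[0] = 0.0
    return w


def _weight_variance(w: np.ndarray, n: int) -> np.ndarray:
    """Expected variance of irfft(w * rfft(unit white noise)), per unit weight."""
    mult = np.full(w.shape, 2.0)
    mult[0] = 1.0
    if n % 2 == 0:
        mult[-1] = 1.0
    return (mult * w**2).sum() / n


def _shaped_noise(rng: np.random.Generator, n_ch: int, n: int, w: np.ndarray,
                  target_rms: float) -> np.ndarray:
    """Gaussian noise with amplitude spectrum ``w``, scaled to ``target_rms``."""
    if target_rms == 0:
        return np.zeros((n_ch, n))
    white = rng.standard_normal((n_ch, n))
    shaped = np.fft.irfft(np.fft.rfft(white, axis=1) * w, n=n, axis=1)
    scale = target_rms / np.sqrt(_weight_variance(w, n))
    return shaped * scale


def _component_band_power(w: np.ndarray, n: int, fs: float, rms: float,
                          band: tuple[float, float]) -> float:
    """Expected power (uV^2) of a component inside ``[lo - 0.5, hi + 0.5)`` Hz,
    the support of the inclusive integer Welch bins ``lo..hi``."""
    if rms == 0:
        return 0.0
    f = _rfft_freqs(n, fs)
    mult = np.full(w.shape, 2.0)
    mult[0] = 1.0
    if n % 2 == 0:
        mult[-1] = 1.0
    var_per_unit = (mult * w**2) / n
    total = var_per_unit.sum()
    lo, hi = band
    mask = (f >= lo - 0.5) & (f < hi + 0.5)
    return rms**2 * var_per_unit[mask].sum() / total


def _session_scales(group: str, session_tag: str, params: EegSimParams,
                    suppression: float) -> dict[str, float]:
    """Per-oscillator amplitude multipliers for a session."""
    scales = {name: 1.0 for name in params.oscillators}
    if session_tag in ("cpt_task", "noise_cpt"):
        scales["alpha"] = float(np.sqrt(1.0 - suppression))
        if group == "control":
            boost = float(np.sqrt(params.attention_low_freq_boost))
            for name in ("delta", "theta"):
                if name in scales:
                    scales[name] = boost
    return scales


def expected_band_power(params: EegSimParams, band: tuple[float, float],
                        scales: dict[str, float] | None = None) -> float:
    """Analytic expected power (uV^2) in a Welch band for given oscillator
    amplitude multipliers (1.0 everywhere = resting session)."""
    n = int(round(params.duration * params.fs))
    scales = scales or {}
    total = _component_band_power(
        _background_weights(n, params), n, params.fs, params.background_scale, band
    )
    for name, (center, bw, amp) in params.oscillators.items():
        w = _oscillator_weights(n, params.fs, center, bw)
        total += _component_band_power(w, n, params.fs, amp * scales.get(name, 1.0), band)
    return total


def expected_alpha_ratio(params: EegSimParams, group: str, suppression: float) -> float:
    """Analytic raw-mode attention-to-resting alpha (8-12 Hz) power ratio for a
    planted suppression, including background leakage into the alpha band."""
    rest = expected_band_power(params, (8, 12))
    task_scales = _session_scales(group, "cpt_task", params, suppression)
    task = expected_band_power(params, (8, 12), task_scales)
    return task / rest


def draw_suppression(group: str, params: EegSimParams, rng: np.random.Generator) -> float:
    """Draw the planted alpha-power suppression fraction for one participant."""
    if group == "control":
        lo, hi = params.control_suppression_range
        return float(rng.uniform(lo, hi))
    if group == "PWS":
        lo, hi = params.pws_suppression_bounds
        while True:  # rejection-sampled truncated normal
            s = rng.normal(params.pws_suppression_mean, params.pws_suppression_sd)
            if lo <= s <= hi:
                return float(s)
    raise ValueError(f"unknown group {group!r}")


def _insert_artifacts(data: np.ndarray, fs: float, params: EegSimParams,
                      rng: np.random.Generator) -> None:
    """Add high-amplitude Hann-shaped transients in place."""
    n = data.shape[1]
    minutes = n / fs / 60.0
    k = rng.poisson(params.artifact_rate * minutes)
    width = int(round(params.artifact_duration * fs))
    bump = params.artifact_amplitude * np.hanning(width)
    for _ in range(k):
        start = int(rng.integers(0, max(1, n - width)))
        data[:, start : start + width] += bump[: n - start]


def _render_session(participant_id: str, group: str, session_tag: str,
                    params: EegSimParams, components: dict[str, np.ndarray],
                    suppression: float, artifact_rng: np.random.Generator) -> EegRecording:
    scales = _session_scales(group, session_tag, params, suppression)
    data = components["background"].copy()
    for name in params.oscillators:
        data += components[name] * scales.get(name, 1.0)
    if params.artifact_rate > 0:
        _insert_artifacts(data, params.fs, params, artifact_rng)
    return EegRecording(
        participant_id=participant_id, session_tag=session_tag,
        fs=params.fs, channel_labels=params.channels, data=data,
    )


def _draw_components(params: EegSimParams, seed_seq: np.random.SeedSequence) -> dict[str, np.ndarray]:
    n = int(round(params.duration * params.fs))
    n_ch = len(params.channels)
    children = seed_seq.spawn(1 + len(params.oscillators))
    comps = {
        "background": _shaped_noise(
            np.random.default_rng(children[0]), n_ch, n,
            _background_weights(n, params), params.background_scale,
        )
    }
    for child, (name, (center, bw, amp)) in zip(children[1:], params.oscillators.items()):
        w = _oscillator_weights(n, params.fs, center, bw)
        comps[name] = _shaped_noise(np.random.default_rng(child), n_ch, n, w, amp)
    return comps


def simulate_eeg_session(group: str, session_tag: str, params: EegSimParams,
                         seed, suppression: float | None = None,
                         participant_id: str = "sim") -> EegRecording:
    """Simulate a single EEG session.

    For attention sessions the planted alpha suppression is drawn from the
    group's distribution unless ``suppression`` is given explicitly.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    comp_ss, aux_ss = ss.spawn(2)
    aux_rng = np.random.default_rng(aux_ss)
    if suppression is None:
        suppression = (
            draw_suppression(group, params, aux_rng)
            if session_tag in ("cpt_task", "noise_cpt") else 0.0
        )
    components = _draw_components(params, comp_ss)
    return _render_session(participant_id, group, session_tag, params,
                           components, suppression, aux_rng)


def simulate_participant_pair(group: str, params: EegSimParams, seed,
                              suppression: float | None = None,
                              participant_id: str = "sim",
                              ) -> tuple[EegRecording, EegRecording, float]:
    """Simulate the resting + attention session pair of one participant.

    Both sessions share the background and oscillator noise realizations;
    only the planted attention modifications (alpha scaling by
    sqrt(1 - s), controls' low-frequency boost) differ. Returns
    ``(resting, attention, s)`` with the drawn suppression for recovery tests.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    comp_ss, aux_ss = ss.spawn(2)
    aux_rng = np.random.default_rng(aux_ss)
    if suppression is None:
        suppression = draw_suppression(group, params, aux_rng)
    components = _draw_components(params, comp_ss)
    rest = _render_session(participant_id, group, "rest_eyes_closed", params,
                           components, suppression, aux_rng)
    task = _render_session(participant_id, group, "cpt_task", params,
                           components, suppression, aux_rng)
    return rest, task, float(suppression)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

#: Nine go/no-go T-score variables: (PWS mean, PWS SD, control mean, control SD).
#: ``omission`` and ``commission`` are generated through the couplings below
#: (their printed means are matched via the intercepts; the listed SDs then
#: describe the observed totals, not the coupling noise).
CPT_TABLE: dict[str, tuple[float, float, float, float]] = {
    "detectability": (67.6, 11.2, 51.4, 8.6),
    "omission": (74.4, 18.9, 49.3, 5.7),
    "commission": (60.9, 18.3, 50.9, 9.5),
    "perseveration": (78.7, 7.3, 48.8, 3.2),
    "hrt": (69.1, 17.1, 48.9, 7.4),
    "hrt_sd": (75.7, 18.4, 46.3, 5.8),
    "variability": (71.3, 16.8, 46.7, 5.3),
    "hrt_block_change": (37.5, 19.3, 52.3, 9.9),
    "hrt_isi_change": (61.1, 15.8, 53.0, 6.0),
}

CPT_VARIABLES = tuple(CPT_TABLE)
_COUPLED = ("omission", "commission")


@dataclass
class CohortSimParams:
    """Parameters of the synthetic behavioral cohort generator.

    Demographic defaults follow the two-group study design this package
    targets (n = 10 per group, PWS age 18.5 +/- 8.0 vs control 19.8 +/- 5.8
    years, sex 4/6 vs 5/5, genotype 6 deletion / 4 non-deletion, 7 of 10 PWS
    with moderate-to-severe intellectual disability). ``None`` count fields
    are allocated proportionally for other group sizes.
    """

    n_per_group: int = 10
    age_pws: tuple[float, float] = (18.5, 8.0)       # mean, SD (years)
    age_control: tuple[float, float] = (19.8, 5.8)
    age_bounds: tuple[float, float] = (6.0, 55.0)    # truncation, > 5 y
    sex_counts_pws: tuple[int, int] | None = None    # (M, F); default 4/6
    sex_counts_control: tuple[int, int] | None = None  # default 5/5
    genotype_deletion_count: int | None = None       # PWS only; default 6/10
    intelligence_counts_pws: tuple[int, int, int] | None = None  # (normal, mild, mod-sev); default 0/3/7
    bmi_pws: tuple[float, float] = (25.7, 5.9)       # kg/m^2
    bmi_control: tuple[float, float] = (23.6, 3.5)
    bmi_min: float = 12.0
    cpt_table: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(CPT_TABLE)
    )
    # commission_T = intercept + slope * (planted raw-mode Cz alpha ratio) + N(0, sd)
    commission_slope: float = 25.04
    commission_intercept: float | None = None  # None: derived so the control
                                               # group mean matches the table
    commission_noise_sd: float = 3.0
    # omission_T = intercept + slope * intelligence_category + N(0, sd)
    omission_slope: float = 14.41
    omission_intercept: float | None = None    # None: control mean from table
    omission_noise_sd: float = 5.0
    eeg: EegSimParams = field(default_factory=EegSimParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need at least 2 participants per group")
        for name in ("sex_counts_pws", "sex_counts_control", "intelligence_counts_pws"):
            val = getattr(self, name)
            if val is not None and sum(val) != self.n_per_group:
                raise ValueError(f"{name} must sum to n_per_group")
        if (self.genotype_deletion_count is not None
                and not 0 <= self.genotype_deletion_count <= self.n_per_group):
            raise ValueError("genotype_deletion_count exceeds n_per_group")
        for _, (_, psd, _, csd) in self.cpt_table.items():
            if psd <= 0 or csd <= 0:
                raise ValueError("T-score SDs must be positive")


def _alloc(n: int, fractions: tuple[float, ...]) -> list[int]:
    """Largest-remainder allocation of n items over fixed fractions."""
    raw = [f * n for f in fractions]
    base = [int(np.floor(r)) for r in raw]
    rem = n - sum(base)
    order = np.argsort([b - r for b, r in zip(base, raw)])
    for i in order[:rem]:
        base[i] += 1
    return base


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = np.empty(size)
    for i in range(size):
        while True:
            v = rng.normal(mean, sd)
            if lo <= v <= hi:
                out[i] = v
                break
    return out


def simulate_cohort(params: CohortSimParams, seed: int | None = None,
                    include_eeg: bool = True, norms: BmiNormTable | None = None):
    """Simulate a full two-group cohort.

    Returns ``(cohort, recordings, manifest)``:

    * ``cohort`` — DataFrame, one row per participant, with demographics,
      BMI (+z, weight class) and the nine ``cpt_*`` T-score columns;
    * ``recordings`` — ``{participant_id: {session_tag: EegRecording}}``
      for the resting and attention sessions (empty if ``include_eeg`` is
      False);
    * ``manifest`` — planted ground truth: per-participant suppression and
      analytic raw-mode Cz alpha ratio, the coupling coefficients used, and
      the seed, for recovery testing.
    """
    seed = params.seed if seed is None else seed
    norms = norms or synthetic_norm_table()
    n = params.n_per_group
    root = np.random.SeedSequence(seed)
    demo_ss, cpt_ss, eeg_ss = root.spawn(3)
    demo_rng = np.random.default_rng(demo_ss)
    cpt_rng = np.random.default_rng(cpt_ss)
    eeg_children = eeg_ss.spawn(2 * n)

    sex_pws = params.sex_counts_pws or tuple(_alloc(n, (0.4, 0.6)))
    sex_ctl = params.sex_counts_control or tuple(_alloc(n, (0.5, 0.5)))
    geno_del = (params.genotype_deletion_count
                if params.genotype_deletion_count is not None else _alloc(n, (0.6, 0.4))[0])
    intel_pws = params.intelligence_counts_pws or tuple(_alloc(n, (0.0, 0.3, 0.7)))

    rows, recordings = [], {}
    manifest: dict = {
        "seed": int(seed),
        "participants": {},
        "couplings": {},
        "eeg_params": {
            "control_suppression_range": list(params.eeg.control_suppression_range),
            "pws_suppression_mean": params.eeg.pws_suppression_mean,
            "pws_suppression_sd": params.eeg.pws_suppression_sd,
            "attention_low_freq_boost": params.eeg.attention_low_freq_boost,
        },
    }

    specs = []
    for gi, group in enumerate(("PWS", "control")):
        age_mu, age_sd = params.age_pws if group == "PWS" else params.age_control
        bmi_mu, bmi_sd = params.bmi_pws if group == "PWS" else params.bmi_control
        ages = _truncated_normal(demo_rng, age_mu, age_sd, *params.age_bounds, size=n)
        bmis = _truncated_normal(demo_rng, bmi_mu, bmi_sd, params.bmi_min, np.inf, size=n)
        sexes = ["M"] * (sex_pws if group == "PWS" else sex_ctl)[0] + \
                ["F"] * (sex_pws if group == "PWS" else sex_ctl)[1]
        demo_rng.shuffle(sexes)
        if group == "PWS":
            genotypes = ["deletion"] * geno_del + ["non_deletion"] * (n - geno_del)
            demo_rng.shuffle(genotypes)
            intel = [0] * intel_pws[0] + [1] * intel_pws[1] + [2] * intel_pws[2]
            demo_rng.shuffle(intel)
        else:
            genotypes = ["NA"] * n
            intel = [0] * n
        for i in range(n):
            pid = f"{'PWS' if group == 'PWS' else 'CTL'}{i + 1:02d}"
            specs.append((pid, group, ages[i], sexes[i], genotypes[i], intel[i],
                          bmis[i], eeg_children[gi * n + i]))

    # planted EEG suppression + analytic ratio (used by the commission coupling)
    planted = {}
    pair_seeds = {}
    for pid, group, *_rest, eeg_child in specs:
        sup_ss, pair_ss = eeg_child.spawn(2)
        pair_seeds[pid] = pair_ss
        s = draw_suppression(group, params.eeg, np.random.default_rng(sup_ss))
        planted[pid] = (s, expected_alpha_ratio(params.eeg, group, s))

    tbl = params.cpt_table
    commission_intercept = params.commission_intercept
    if commission_intercept is None:
        lo, hi = params.eeg.control_suppression_range
        r_ctl = expected_alpha_ratio(params.eeg, "control", (lo + hi) / 2.0)
        commission_intercept = tbl["commission"][2] - params.commission_slope * r_ctl
    omission_intercept = (params.omission_intercept if params.omission_intercept is not None
                          else tbl["omission"][2])
    manifest["couplings"] = {
        "commission": {"slope": params.commission_slope,
                       "intercept": float(commission_intercept),
                       "noise_sd": params.commission_noise_sd,
                       "predictor": "planted_raw_cz_alpha_ratio"},
        "omission": {"slope": params.omission_slope,
                     "intercept": float(omission_intercept),
                     "noise_sd": params.omission_noise_sd,
                     "predictor": "intelligence_category"},
    }

    for pid, group, age, sex, genotype, intel, bmi, eeg_child in specs:
        s, ratio = planted[pid]
        z = bmi_zscore(bmi, age, sex, norms)
        scores = {}
        for var in CPT_VARIABLES:
            pm, psd, cm, csd = tbl[var]
            if var == "commission":
                scores[var] = (commission_intercept + params.commission_slope * ratio
                               + cpt_rng.normal(0.0, params.commission_noise_sd))
            elif var == "omission":
                scores[var] = (omission_intercept + params.omission_slope * intel
                               + cpt_rng.normal(0.0, params.omission_noise_sd))
            else:
                mu, sd = (pm, psd) if group == "PWS" else (cm, csd)
                scores[var] = cpt_rng.normal(mu, sd)
        rows.append({
            "participant_id": pid, "group": group, "age": age, "sex": sex,
            "genotype": genotype, "intelligence": intel, "bmi": bmi,
            "bmi_z": z, "weight_class": classify_weight(z),
            **{f"cpt_{v}": scores[v] for v in CPT_VARIABLES},
        })
        manifest["participants"][pid] = {
            "group": group, "suppression": float(s),
            "planted_raw_cz_alpha_ratio": float(ratio),
        }
        if include_eeg:
            rest, task, _ = simulate_participant_pair(
                group, params.eeg, pair_seeds[pid], suppression=s, participant_id=pid
            )
            recordings[pid] = {"rest_eyes_closed": rest, "cpt_task": task}

    cohort = pd.DataFrame(rows)
    return cohort, recordings, manifest
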
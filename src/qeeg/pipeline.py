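"""End-to-end orchestration: epoch selection, analysis run, report.

``run_pipeline`` takes a :class:`RunConfig` and produces a
:class:`CohortResultBundle` — the full set of cohort tables: demographics
and behavioral comparisons, resting theta/beta-ratio and total-power
comparisons, group-mean normalized spectra with per-frequency t-tests,
per-participant attention-to-resting alpha power ratios with group tests,
ratio-vs-behavior Spearman correlations, and the stepwise regressions of
commission and omission error T-scores.

Input is either a simulated cohort (the synthetic generator) or a
directory of EDF files plus a participant CSV. Only the eyes-closed
resting session and the attention-task session are analyzed; recordings
with other session tags are accepted and ignored. Recordings are analyzed
as recorded: no filtering, re-referencing or montage transformation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .edf import read_eeg_edf, write_eeg_edf
from .recording import MIDLINE_ELECTRODES, CleanEpoch, EegRecording
from .regression import RegressionTable, stepwise_regression
from .simulate import CPT_VARIABLES, CohortSimParams, simulate_cohort
from .spectral import (
    NormalizedSpectrum,
    SpectralConfig,
    alpha_ratio,
    band_power,
    compute_welch_psd,
    normalize_spectrum,
    per_frequency_spectra,
    theta_beta_ratio,
)
from .stats import (
    BmiNormTable,
    bmi_zscore,
    classify_weight,
    cohort_compare,
    mann_whitney,
    per_frequency_ttest,
    spearman,
    synthetic_norm_table,
)

log = logging.getLogger("qeeg")

ANALYZED_SESSIONS = ("rest_eyes_closed", "cpt_task")

REGRESSION_CANDIDATES = ("cz_alpha_ratio", "genotype_group", "age",
                         "intelligence", "bmi_z")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML- or dict-loadable)."""

    mode: str = "simulate"                   # "simulate" | "edf_dir"
    edf_dir: str | None = None
    cohort_csv: str | None = None
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    ratio_mode: str = "normalized"           # "normalized" | "raw"
    electrodes: tuple[str, ...] = MIDLINE_ELECTRODES
    artifact_threshold: float = 100.0        # uV
    max_artifact_fraction: float = 0.1
    epoch_duration: float = 60.0             # seconds
    chi2_correction: bool = False
    ttest_variant: str = "pooled"            # "pooled" | "welch"
    p_enter: float = 0.05
    p_remove: float = 0.10
    bh_annotation: bool = False
    norm_table_path: str | None = None
    seed: int = 0
    out_dir: str | None = None
    write_edf: bool = False
    sim: CohortSimParams = field(default_factory=CohortSimParams)

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "edf_dir"):
            raise ValueError("mode must be 'simulate' or 'edf_dir'")
        if self.mode == "edf_dir" and (self.edf_dir is None or self.cohort_csv is None):
            raise ValueError("edf_dir mode requires edf_dir and cohort_csv paths")
        if self.ratio_mode not in ("normalized", "raw"):
            raise ValueError("ratio_mode must be 'normalized' or 'raw'")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "spectral" in d and isinstance(d["spectral"], dict):
            spec = d["spectral"]
            if "bands" in spec:
                spec["bands"] = {k: tuple(v) for k, v in spec["bands"].items()}
            d["spectral"] = SpectralConfig(**spec)
        if "sim" in d and isinstance(d["sim"], dict):
            sim = dict(d["sim"])
            if "eeg" in sim and isinstance(sim["eeg"], dict):
                eeg = dict(sim["eeg"])
                if "channels" in eeg:
                    eeg["channels"] = tuple(eeg["channels"])
                if "oscillators" in eeg:
                    eeg["oscillators"] = {k: tuple(v)
                                          for k, v in eeg["oscillators"].items()}
                from .simulate import EegSimParams
                sim["eeg"] = EegSimParams(**eeg)
            d["sim"] = CohortSimParams(**sim)
        if "electrodes" in d:
            d["electrodes"] = tuple(d["electrodes"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def select_clean_epoch(recording: EegRecording, duration: float = 60.0,
                       threshold: float = 100.0, max_fraction: float = 0.1,
                       electrodes: tuple[str, ...] | None = None) -> CleanEpoch:
    """Automated stand-in for visual artifact screening.

    Slides a window of ``duration`` seconds over the recording and selects
    the one minimizing the fraction of time samples where any electrode of
    interest exceeds ``threshold`` uV in magnitude (earliest window on
    ties). Fails if even the best window exceeds ``max_fraction``.
    """
    n_win = int(round(duration * recording.fs))
    if recording.n_samples < n_win:
        raise ValueError(
            f"recording too short: {recording.duration:.1f} s < {duration} s"
        )
    probe = recording.pick(electrodes) if electrodes else recording
    exceed = (np.abs(probe.data) > threshold).any(axis=0).astype(int)
    csum = np.concatenate([[0], np.cumsum(exceed)])
    counts = csum[n_win:] - csum[:-n_win]          # one per start sample
    best = int(np.argmin(counts))
    frac = counts[best] / n_win
    if frac > max_fraction:
        raise ValueError(
            f"no acceptable window: best artifact fraction {frac:.3f} "
            f"exceeds {max_fraction}"
        )
    return CleanEpoch(
        recording=recording.slice_seconds(best / recording.fs, duration),
        duration=duration, artifact_fraction=float(frac),
    )


@dataclass
class CohortResultBundle:
    """Every table of a full cohort analysis, plus provenance."""

    demographics: pd.DataFrame           # group comparison of demographics
    cpt: pd.DataFrame                    # nine T-score comparisons
    resting_features: pd.DataFrame       # per participant x channel TBR/powers
    resting_comparison: pd.DataFrame     # per channel TBR & total-power tests
    spectra: pd.DataFrame                # group-mean normalized spectra/session
    per_freq_tests: pd.DataFrame         # per session x channel x bin t-tests
    alpha_ratios: pd.DataFrame           # per participant x channel ratios
    alpha_ratio_comparison: pd.DataFrame # per channel group test of the ratio
    correlations: pd.DataFrame           # Cz ratio vs nine CPT variables
    regression_commission: RegressionTable
    regression_omission: RegressionTable
    provenance: dict

    _TABLES = ("demographics", "cpt", "resting_features", "resting_comparison",
               "spectra", "per_freq_tests", "alpha_ratios",
               "alpha_ratio_comparison", "correlations")

    def tables(self) -> dict[str, pd.DataFrame]:
        out = {name: getattr(self, name) for name in self._TABLES}
        for name, reg in (("regression_commission", self.regression_commission),
                          ("regression_omission", self.regression_omission)):
            out[f"{name}_selected"] = reg.selected
            out[f"{name}_full"] = reg.full_model
        return out


def _regression_frame(reg: RegressionTable) -> dict:
    return {
        "outcome": reg.outcome,
        "r_squared": reg.r_squared,
        "r_squared_full": reg.r_squared_full,
        "trace": [list(t) for t in reg.trace],
    }


def _load_edf_inputs(config: RunConfig):
    cohort = pd.read_csv(config.cohort_csv)
    if "bmi_z" not in cohort.columns:
        norms = (BmiNormTable.from_csv(config.norm_table_path)
                 if config.norm_table_path else synthetic_norm_table())
        cohort["bmi_z"] = [bmi_zscore(r.bmi, r.age, r.sex, norms)
                           for r in cohort.itertuples()]
        cohort["weight_class"] = [classify_weight(z) for z in cohort["bmi_z"]]
    recordings: dict[str, dict[str, EegRecording]] = {}
    edf_dir = Path(config.edf_dir)
    for pid in cohort["participant_id"]:
        recordings[pid] = {}
        for path in sorted(edf_dir.glob(f"{pid}_*.edf")):
            tag = path.stem.removeprefix(f"{pid}_")
            if tag not in ANALYZED_SESSIONS:
                log.info("ignoring session %r of %s (not analyzed)", tag, pid)
                continue
            recordings[pid][tag] = read_eeg_edf(path, participant_id=pid,
                                                session_tag=tag)
        missing = set(ANALYZED_SESSIONS) - set(recordings[pid])
        if missing:
            raise FileNotFoundError(
                f"participant {pid}: missing EDF for session(s) {sorted(missing)}"
            )
    return cohort, recordings, None


def run_pipeline(config: RunConfig) -> CohortResultBundle:
    """Execute the full analysis and return the result bundle.

    Deterministic given (config, seed). Stage errors are re-raised with
    participant/session context; nothing is written unless ``out_dir`` is
    configured, and then only after the bundle is complete.
    """
    if config.mode == "simulate":
        sim = dataclasses.replace(config.sim, seed=config.seed)
        cohort, recordings, manifest = simulate_cohort(sim)
    else:
        cohort, recordings, manifest = _load_edf_inputs(config)

    # --- per-participant spectral analysis -------------------------------
    norm_spectra: dict[str, dict[str, NormalizedSpectrum]] = {}
    raw_spectra: dict[str, dict] = {}
    for pid, sessions in recordings.items():
        norm_spectra[pid], raw_spectra[pid] = {}, {}
        for tag in ANALYZED_SESSIONS:
            try:
                rec = sessions[tag].pick(config.electrodes)
                epoch = select_clean_epoch(
                    rec, duration=config.epoch_duration,
                    threshold=config.artifact_threshold,
                    max_fraction=config.max_artifact_fraction,
                )
                psd = compute_welch_psd(epoch, config.spectral)
            except Exception as exc:
                raise type(exc)(f"participant {pid}, session {tag}: {exc}") from exc
            raw_spectra[pid][tag] = psd
            norm_spectra[pid][tag] = normalize_spectrum(psd)

    group_of = dict(zip(cohort["participant_id"], cohort["group"]))
    pids = list(cohort["participant_id"])

    # --- resting features (TBR, band powers, total power) ----------------
    feat_rows = []
    for pid in pids:
        psd = raw_spectra[pid]["rest_eyes_closed"]
        tbr = theta_beta_ratio(psd)
        for ci, ch in enumerate(psd.channel_labels):
            feat_rows.append({
                "participant_id": pid, "group": group_of[pid], "channel": ch,
                "theta_power": band_power(psd, "theta")[ci],
                "alpha_power": band_power(psd, "alpha")[ci],
                "beta_power": band_power(psd, "beta")[ci],
                "total_power_0_50": band_power(psd, "total")[ci],
                "tbr": tbr[ci],
            })
    resting_features = pd.DataFrame(feat_rows)

    rest_cmp_rows = []
    for ch in config.electrodes:
        sub = resting_features[resting_features["channel"] == ch]
        for var in ("tbr", "total_power_0_50"):
            res = mann_whitney(sub.loc[sub["group"] == "PWS", var],
                               sub.loc[sub["group"] == "control", var])
            rest_cmp_rows.append((ch, var, res.statistic, res.p_value))
    resting_comparison = pd.DataFrame(
        rest_cmp_rows, columns=["channel", "variable", "U", "p"])

    # --- group-mean normalized spectra + per-frequency t-tests -----------
    spectra_frames, pf_frames = [], []
    for tag in ANALYZED_SESSIONS:
        by_group = {
            g: [norm_spectra[p][tag] for p in pids if group_of[p] == g]
            for g in ("PWS", "control")
        }
        frame = per_frequency_spectra(by_group)
        frame.insert(0, "session", tag)
        spectra_frames.append(frame)
        ref = norm_spectra[pids[0]][tag]
        for ci, ch in enumerate(ref.channel_labels):
            a = np.stack([norm_spectra[p][tag].fraction[ci]
                          for p in pids if group_of[p] == "PWS"])
            b = np.stack([norm_spectra[p][tag].fraction[ci]
                          for p in pids if group_of[p] == "control"])
            pf = per_frequency_ttest(a, b, freqs=ref.freqs,
                                     variant=config.ttest_variant,
                                     bh_annotation=config.bh_annotation)
            pf.insert(0, "channel", ch)
            pf.insert(0, "session", tag)
            pf_frames.append(pf)
    spectra = pd.concat(spectra_frames, ignore_index=True)
    per_freq_tests = pd.concat(pf_frames, ignore_index=True)

    # --- attention-to-resting alpha power ratio --------------------------
    ratio_rows = []
    for pid in pids:
        if config.ratio_mode == "normalized":
            ratios = alpha_ratio(norm_spectra[pid]["cpt_task"],
                                 norm_spectra[pid]["rest_eyes_closed"])
            chans = norm_spectra[pid]["cpt_task"].channel_labels
        else:
            ratios = alpha_ratio(raw_spectra[pid]["cpt_task"],
                                 raw_spectra[pid]["rest_eyes_closed"])
            chans = raw_spectra[pid]["cpt_task"].channel_labels
        for ch, r in zip(chans, ratios):
            ratio_rows.append({"participant_id": pid, "group": group_of[pid],
                               "channel": ch, "alpha_ratio": r})
    alpha_ratios = pd.DataFrame(ratio_rows)

    ar_cmp_rows = []
    for ch in config.electrodes:
        sub = alpha_ratios[alpha_ratios["channel"] == ch]
        res = mann_whitney(sub.loc[sub["group"] == "PWS", "alpha_ratio"],
                           sub.loc[sub["group"] == "control", "alpha_ratio"])
        ar_cmp_rows.append((ch, res.statistic, res.p_value))
    alpha_ratio_comparison = pd.DataFrame(ar_cmp_rows, columns=["channel", "U", "p"])

    # --- correlations and regressions (Cz ratio, pooled cohort) ----------
    cz = alpha_ratios[alpha_ratios["channel"] == "Cz"].set_index("participant_id")
    cz_ratio = cz.loc[pids, "alpha_ratio"].to_numpy()
    corr_rows = []
    for var in CPT_VARIABLES:
        res = spearman(cz_ratio, cohort[f"cpt_{var}"].to_numpy())
        corr_rows.append((var, res.statistic, res.p_value))
    correlations = pd.DataFrame(corr_rows, columns=["variable", "rho", "p"])

    candidates = pd.DataFrame({
        "cz_alpha_ratio": cz_ratio,
        # coded Control = 0, PWS = 1 (group indicator)
        "genotype_group": (cohort["group"] == "PWS").astype(float).to_numpy(),
        "age": cohort["age"].to_numpy(),
        "intelligence": cohort["intelligence"].astype(float).to_numpy(),
        "bmi_z": cohort["bmi_z"].to_numpy(),
    })
    regression_commission = stepwise_regression(
        cohort["cpt_commission"], candidates, p_enter=config.p_enter,
        p_remove=config.p_remove, outcome_name="commission_t_score")
    regression_omission = stepwise_regression(
        cohort["cpt_omission"], candidates, p_enter=config.p_enter,
        p_remove=config.p_remove, outcome_name="omission_t_score")

    tables = cohort_compare(cohort, chi2_correction=config.chi2_correction)

    config_dict = config.to_dict()
    config_dict["out_dir"] = None  # output location is not part of the analysis
    provenance = {
        "package": "qeeg-attention",
        "version": __version__,
        "config": config_dict,
        "seed": config.seed,
        "ratio_mode": config.ratio_mode,
        "analyzed_sessions": list(ANALYZED_SESSIONS),
        "reference_note": "signals analyzed as recorded (no re-referencing)",
        "artifact_rule": "minimal-artifact 60-s sliding window, "
                         f"threshold ±{config.artifact_threshold} µV "
                         "(automated stand-in for visual screening)",
        "n_participants": len(pids),
    }
    if manifest is not None:
        provenance["simulation_manifest"] = manifest

    bundle = CohortResultBundle(
        demographics=tables["demographics"], cpt=tables["cpt"],
        resting_features=resting_features, resting_comparison=resting_comparison,
        spectra=spectra, per_freq_tests=per_freq_tests,
        alpha_ratios=alpha_ratios, alpha_ratio_comparison=alpha_ratio_comparison,
        correlations=correlations,
        regression_commission=regression_commission,
        regression_omission=regression_omission,
        provenance=provenance,
    )

    if config.out_dir is not None:
        out = Path(config.out_dir)
        if config.mode == "simulate" and config.write_edf:
            input_dir = out / "input"
            input_dir.mkdir(parents=True, exist_ok=True)
            cohort.to_csv(input_dir / "cohort.csv", index=False)
            for pid, sessions in recordings.items():
                for tag, rec in sessions.items():
                    write_eeg_edf(rec, input_dir / f"{pid}_{tag}.edf")
        render_report(bundle, out / "report")
    return bundle


def render_report(bundle: CohortResultBundle, out_dir: str | Path,
                  formats: tuple[str, ...] = ("csv", "json", "txt"),
                  ) -> list[Path]:
    """Serialize a bundle: one CSV per table, provenance/regression JSON and
    a plain-text summary with 3-decimal p-values and mean ± SD formatting.
    ``formats`` may also include ``"png"`` for figures of the group-mean
    normalized spectra and the per-channel ratio distributions."""
    for name in bundle._TABLES:
        if getattr(bundle, name) is None or len(getattr(bundle, name)) == 0:
            raise ValueError(f"incomplete bundle: missing table {name!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if "csv" in formats:
        for name, df in bundle.tables().items():
            p = out / f"{name}.csv"
            df.to_csv(p, index=False)
            written.append(p)
    if "json" in formats:
        p = out / "provenance.json"
        p.write_text(json.dumps(bundle.provenance, indent=2, sort_keys=True,
                                default=str))
        written.append(p)
        p = out / "regressions.json"
        p.write_text(json.dumps(
            {"commission": _regression_frame(bundle.regression_commission),
             "omission": _regression_frame(bundle.regression_omission)},
            indent=2, sort_keys=True))
        written.append(p)
    if "txt" in formats or "html" in formats:
        text = _summary_text(bundle)
        if "txt" in formats:
            p = out / "summary.txt"
            p.write_text(text)
            written.append(p)
        if "html" in formats:
            p = out / "summary.html"
            p.write_text("<html><body><pre>\n" + text + "</pre></body></html>\n")
            written.append(p)
    if "png" in formats:
        written.extend(_figures(bundle, out))
    return written


def _fmt_p(p: float) -> str:
    if not np.isfinite(p):
        return "NA"
    return "<0.001" if p < 0.0005 else f"{p:.3f}"


def _summary_text(bundle: CohortResultBundle) -> str:
    lines = ["Quantitative EEG attention analysis — cohort summary",
             "=" * 56, ""]
    for title, df in (("Demographics", bundle.demographics),
                      ("CPT-3 T-scores", bundle.cpt)):
        lines += [title, "-" * len(title)]
        for r in df.itertuples():
            lines.append(f"  {r.variable:<28} {r.pws:>14} {r.control:>14}  "
                         f"p = {_fmt_p(r.p)}")
        lines.append("")
    lines += ["Resting-state comparisons (Mann-Whitney)", "-" * 40]
    for r in bundle.resting_comparison.itertuples():
        lines.append(f"  {r.channel} {r.variable:<18} U = {r.U:6.1f}  "
                     f"p = {_fmt_p(r.p)}")
    lines.append("")
    lines += ["Attention-to-resting alpha power ratio", "-" * 38]
    for r in bundle.alpha_ratio_comparison.itertuples():
        sub = bundle.alpha_ratios[bundle.alpha_ratios["channel"] == r.channel]
        for g in ("PWS", "control"):
            v = sub.loc[sub["group"] == g, "alpha_ratio"]
            lines.append(f"  {r.channel} {g:<8} {v.mean():.3f} ± {v.std(ddof=1):.3f}")
        lines.append(f"  {r.channel} group difference: U = {r.U:.1f}, "
                     f"p = {_fmt_p(r.p)}")
    lines.append("")
    lines += ["Spearman correlations (Cz alpha ratio vs CPT-3 T-scores)",
              "-" * 56]
    for r in bundle.correlations.itertuples():
        lines.append(f"  {r.variable:<18} rho = {r.rho:+.3f}  p = {_fmt_p(r.p)}")
    lines.append("")
    for title, reg in (("Stepwise regression — commission errors",
                        bundle.regression_commission),
                       ("Stepwise regression — omission errors",
                        bundle.regression_omission)):
        lines += [title, "-" * len(title)]
        for r in reg.full_model.itertuples():
            mark = "*" if r.selected else " "
            lines.append(f"  {mark}{r.name:<18} B = {r.B:+8.3f}  t = {r.t:+6.2f}  "
                         f"p = {_fmt_p(r.p)}")
        lines.append(f"  selected: {', '.join(n for n in reg.selected.loc[reg.selected['selected'], 'name']) or '(none)'}"
                     f"; R² = {reg.r_squared:.3f}")
        lines.append("")
    return "\n".join(lines) + "\n"


def _figures(bundle: CohortResultBundle, out: Path) -> list[Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    channels = sorted(bundle.spectra["channel"].unique())
    fig, axes = plt.subplots(len(channels), 2, figsize=(9, 3 * len(channels)),
                             squeeze=False, sharex=True)
    for i, ch in enumerate(channels):
        for j, tag in enumerate(ANALYZED_SESSIONS):
            ax = axes[i][j]
            sub = bundle.spectra[(bundle.spectra["channel"] == ch)
                                 & (bundle.spectra["session"] == tag)]
            for g, color in (("control", "tab:blue"), ("PWS", "tab:red")):
                gs = sub[sub["group"] == g].sort_values("freq")
                ax.plot(gs["freq"], gs["mean"], color=color, label=g)
                ax.fill_between(gs["freq"], gs["mean"] - gs["sd"],
                                gs["mean"] + gs["sd"], color=color, alpha=0.2)
            ax.set_title(f"{ch} — {tag}")
            ax.set_xlabel("frequency (Hz)")
            ax.set_ylabel("normalized power")
    axes[0][0].legend()
    fig.tight_layout()
    p = out / "normalized_spectra.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    written.append(p)

    fig, axes = plt.subplots(1, len(channels), figsize=(3 * len(channels), 3),
                             squeeze=False)
    for i, ch in enumerate(channels):
        ax = axes[0][i]
        sub = bundle.alpha_ratios[bundle.alpha_ratios["channel"] == ch]
        data = [sub.loc[sub["group"] == g, "alpha_ratio"] for g in ("control", "PWS")]
        ax.boxplot(data, tick_labels=["control", "PWS"])
        ax.set_title(ch)
        ax.set_ylabel("alpha power ratio")
    fig.tight_layout()
    p = out / "alpha_ratios.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    written.append(p)
    return written
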
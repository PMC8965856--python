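"""Cohort statistics: BMI z-scores, group comparisons and correlations.

All tests are two-sided. The default variants mirror the behaviour of the
classic clinical-statistics packages: Pearson chi-square without continuity
correction, exact Mann-Whitney for small tie-free samples with a
tie-corrected normal approximation otherwise, Spearman correlation with the
t-distribution p-value approximation, and a pooled-variance independent
t-test (a Welch option is available).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sstats

WEIGHT_CLASSES = ("normal", "overweight", "obese")


@dataclass
class StatTestResult:
    """Outcome of a single hypothesis test."""

    method: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


# ---------------------------------------------------------------------------
# BMI z-scores and weight classification
# ---------------------------------------------------------------------------

class BmiNormTable:
    """Age- and sex-specific BMI reference means and SDs.

    Rows are ``(sex, age_lo, age_hi, mean, sd)`` with half-open age bands
    ``[age_lo, age_hi)`` per sex; the highest band is closed at the top.
    The population reference itself is external; this class only stores and
    looks up a user-supplied table (see :func:`synthetic_norm_table` for the
    bundled synthetic stand-in).
    """

    COLUMNS = ("sex", "age_lo", "age_hi", "mean", "sd")

    def __init__(self, table: pd.DataFrame):
        missing = set(self.COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"norm table missing columns {sorted(missing)}")
        if (table["sd"] <= 0).any():
            raise ValueError("norm table SDs must be positive")
        table = table.sort_values(["sex", "age_lo"]).reset_index(drop=True)
        for sex, grp in table.groupby("sex"):
            if (grp["age_hi"].values[:-1] > grp["age_lo"].values[1:]).any():
                raise ValueError(f"overlapping age bands for sex {sex!r}")
        self.table = table

    @classmethod
    def from_csv(cls, path: str | Path) -> "BmiNormTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def lookup(self, sex: str, age: float) -> tuple[float, float]:
        """Return ``(mean, sd)`` of the band covering ``(sex, age)``."""
        sub = self.table[self.table["sex"] == sex]
        hit = sub[(sub["age_lo"] <= age) & (age < sub["age_hi"])]
        if hit.empty:  # allow the top band to be closed
            hit = sub[sub["age_hi"] == age]
        if hit.empty:
            raise ValueError(f"no norm band for sex={sex!r}, age={age}")
        row = hit.iloc[0]
        return float(row["mean"]), float(row["sd"])


def synthetic_norm_table() -> BmiNormTable:
    """Synthetic BMI reference table (stand-in, not a population norm).

    A smooth synthetic reference covering ages 5-80 for both sexes, with
    adult means near 21 kg/m^2 and SDs near 2.4, shaped so that cohorts with
    adult BMIs in the mid-20s map to z-scores in the range the package's
    demographic tables describe. It is NOT the Taiwanese population
    reference the z-score definition was designed around; supply a real
    norm table via :class:`BmiNormTable` for clinical use.
    """
    rows = []
    bands = [(5, 10, 16.5, 2.2), (10, 15, 18.8, 2.6), (15, 20, 21.0, 2.5),
             (20, 30, 21.8, 2.4), (30, 80, 22.2, 2.4)]
    for sex in ("M", "F"):
        for lo, hi, mean, sd in bands:
            # females marginally lighter in the synthetic reference
            shift = -0.4 if sex == "F" else 0.0
            rows.append((sex, lo, hi, mean + shift, sd))
    return BmiNormTable(pd.DataFrame(rows, columns=BmiNormTable.COLUMNS))


def bmi_zscore(bmi: float, age: float, sex: str, norms: BmiNormTable) -> float:
    """Standardize a BMI against the matching age/sex reference band:
    ``z = (bmi - mean) / sd``."""
    mean, sd = norms.lookup(sex, age)
    return (bmi - mean) / sd


def classify_weight(z: float) -> str:
    """Weight class from the BMI z-score: overweight for z > 1, obese for
    z > 2 (strict inequalities), normal otherwise."""
    if not np.isfinite(z):
        raise ValueError("BMI z-score must be finite")
    if z > 2:
        return "obese"
    if z > 1:
        return "overweight"
    return "normal"


# ---------------------------------------------------------------------------
# Group-comparison tests
# ---------------------------------------------------------------------------

def chi_square_2x2(table, correction: bool = False) -> StatTestResult:
    """Pearson chi-square test of independence on a 2x2 count table.

    No continuity correction by default (``correction=True`` applies
    Yates'). df = 1; two-sided p from the chi-square distribution.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: zero margin")
    chi2, p, dof, _ = sstats.chi2_contingency(t, correction=correction)
    return StatTestResult(
        method="chi-square" + (" (Yates)" if correction else ""),
        statistic=float(chi2), p_value=float(p),
        n=(int(t[0].sum()), int(t[1].sum())),
        extra={"df": int(dof), "correction": correction},
    )


def mann_whitney(a, b, mode: str = "auto") -> StatTestResult:
    """Two-sided Mann-Whitney U test.

    ``mode="auto"`` uses exact null enumeration when both samples have
    n <= 10 and there are no ties, and the tie-corrected normal
    approximation (no continuity correction) otherwise; ``"exact"`` and
    ``"asymptotic"`` force a method.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    if mode == "auto":
        method = "exact" if (a.size <= 10 and b.size <= 10 and not has_ties) else "asymptotic"
    elif mode in ("exact", "asymptotic"):
        method = mode
    else:
        raise ValueError("mode must be 'auto', 'exact' or 'asymptotic'")
    res = sstats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=False
    )
    return StatTestResult(
        method=f"mann-whitney ({method})",
        statistic=float(res.statistic), p_value=float(min(res.pvalue, 1.0)),
        n=(a.size, b.size),
        extra={"ties": bool(has_ties)},
    )


def spearman_p_from_rho(rho: float, n: int) -> float:
    """Two-sided p for a Spearman rho via the t approximation,
    ``t = rho * sqrt((n - 2) / (1 - rho^2))`` with n - 2 df."""
    if n < 4:
        raise ValueError("need n >= 4")
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * sstats.t.sf(abs(t), df=n - 2))


def spearman(x, y, method: str = "t") -> StatTestResult:
    """Spearman rank correlation with a two-sided p-value.

    rho is the Pearson correlation of average ranks. ``method="t"`` uses
    the t approximation with n - 2 df; ``"permutation"`` an exact/MC
    permutation null for small samples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    n = x.size
    if n < 4:
        raise ValueError("need n >= 4 pairs")
    rx, ry = sstats.rankdata(x), sstats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("zero rank variance: constant input")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if method == "t":
        p = spearman_p_from_rho(rho, n)
    elif method == "permutation":
        res = sstats.permutation_test(
            (rx,), lambda r: np.corrcoef(r, ry)[0, 1],
            permutation_type="pairings", n_resamples=20000,
            alternative="two-sided", rng=0,
        )
        p = float(res.pvalue)
    else:
        raise ValueError("method must be 't' or 'permutation'")
    return StatTestResult(
        method=f"spearman ({method})", statistic=rho, p_value=p, n=(n,),
        extra={"df": n - 2},
    )


def independent_ttest(a, b, variant: str = "pooled") -> StatTestResult:
    """Two-sided independent two-sample t-test (pooled variance by default,
    ``variant="welch"`` for unequal variances). A zero pooled variance makes
    the statistic undefined: the result is flagged degenerate with p = NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        return StatTestResult(
            method=f"t-test ({variant})", statistic=np.nan, p_value=np.nan,
            n=(a.size, b.size), extra={"degenerate": True},
        )
    res = sstats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return StatTestResult(
        method=f"t-test ({variant})",
        statistic=float(res.statistic), p_value=float(res.pvalue),
        n=(a.size, b.size), extra={"degenerate": False, "df": float(res.df)},
    )


def cohort_compare(cohort: pd.DataFrame, chi2_correction: bool = False
                   ) -> dict[str, pd.DataFrame]:
    """Group-comparison tables for a two-group cohort table.

    ``cohort`` needs a ``group`` column with levels "PWS" and "control",
    the demographic columns ``age, sex, intelligence, bmi, bmi_z,
    weight_class`` and the nine ``cpt_*`` T-score columns. Continuous
    variables are compared with the Mann-Whitney U test (reported as
    mean +/- SD by group), categorical ones with the Pearson chi-square
    test on 2x2 counts.

    Returns ``{"demographics": ..., "cpt": ...}`` DataFrames with columns
    ``variable, pws, control, test, statistic, p``.
    """
    pws = cohort[cohort["group"] == "PWS"]
    ctl = cohort[cohort["group"] == "control"]
    if len(pws) == 0 or len(ctl) == 0:
        raise ValueError("both groups must be non-empty")

    def msd(series) -> str:
        return f"{series.mean():.1f} ± {series.std(ddof=1):.1f}"

    def cont_row(var, col):
        res = mann_whitney(pws[col], ctl[col])
        return (var, msd(pws[col]), msd(ctl[col]), "mann-whitney",
                res.statistic, res.p_value)

    def cat_row(var, pws_yes, ctl_yes, fmt=None):
        t = [[pws_yes, len(pws) - pws_yes], [ctl_yes, len(ctl) - ctl_yes]]
        if min(sum(t[0]), sum(t[1]), t[0][0] + t[1][0], t[0][1] + t[1][1]) == 0:
            return (var, (fmt or "{}/{}").format(*t[0]),
                    (fmt or "{}/{}").format(*t[1]), "chi-square", np.nan, np.nan)
        res = chi_square_2x2(t, correction=chi2_correction)
        return (var, (fmt or "{}/{}").format(*t[0]), (fmt or "{}/{}").format(*t[1]),
                res.method, res.statistic, res.p_value)

    demo = [
        cont_row("Age (years)", "age"),
        cat_row("Sex (M/F)", (pws["sex"] == "M").sum(), (ctl["sex"] == "M").sum()),
        ("Genotype (Del/non-Del)",
         f"{(pws['genotype'] == 'deletion').sum()}/{(pws['genotype'] == 'non_deletion').sum()}",
         "NA", "", np.nan, np.nan),
        cat_row("Moderate-to-severe ID", (pws["intelligence"] == 2).sum(),
                (ctl["intelligence"] == 2).sum()),
        cont_row("BMI", "bmi"),
        cont_row("BMI z-score", "bmi_z"),
        cat_row("Overweight/obesity", (pws["bmi_z"] > 1).sum(), (ctl["bmi_z"] > 1).sum()),
    ]
    cols = ["variable", "pws", "control", "test", "statistic", "p"]
    demo_df = pd.DataFrame(demo, columns=cols)

    cpt_cols = [c for c in cohort.columns if c.startswith("cpt_")]
    cpt_df = pd.DataFrame(
        [cont_row(c.removeprefix("cpt_"), c) for c in cpt_cols], columns=cols
    )
    return {"demographics": demo_df, "cpt": cpt_df}


def per_frequency_ttest(
    group_a: np.ndarray,
    group_b: np.ndarray,
    freqs=None,
    variant: str = "pooled",
    bh_annotation: bool = False,
) -> pd.DataFrame:
    """Independent t-test of normalized power at every frequency bin.

    ``group_a``/``group_b`` are ``(n_subjects, n_bins)`` arrays of per-bin
    normalized power for the two groups. Returns a DataFrame with columns
    ``freq, t, p, degenerate`` (+ ``p_bh`` when ``bh_annotation``, a
    Benjamini-Hochberg adjusted p provided as an extension — the primary
    report is the raw per-bin p).
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 participants per group")
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must share frequency bins")
    if freqs is None:
        freqs = np.arange(a.shape[1])
    rows = []
    for j, f in enumerate(np.asarray(freqs)):
        res = independent_ttest(a[:, j], b[:, j], variant=variant)
        rows.append((int(f), res.statistic, res.p_value, res.extra.get("degenerate", False)))
    df = pd.DataFrame(rows, columns=["freq", "t", "p", "degenerate"])
    if bh_annotation:
        p = df["p"].to_numpy()
        ok = np.isfinite(p)
        adj = np.full_like(p, np.nan)
        if ok.any():
            m = ok.sum()
            order = np.argsort(p[ok])
            ranked = p[ok][order] * m / (np.arange(m) + 1)
            ranked = np.minimum.accumulate(ranked[::-1])[::-1]
            tmp = np.empty(m)
            tmp[order] = np.minimum(ranked, 1.0)
            adj[ok] = tmp
        df["p_bh"] = adj
    return df
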
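"""Precursor-intensity statistics: log10 transform, ANOVA, Tukey-Kramer HSD.

Raw precursor intensities are log-normal over several decades; their base-10
logarithm is approximately normal, which licenses fixed-effects ANOVA across
the 26 treatment groups. The design is unbalanced (9-26 patients per
condition, and each retained PSM contributes one observation), so all-pairs
mean comparisons use the Tukey-Kramer form of the HSD test

    t_ij = |mean_i - mean_j| / sqrt((MS_resid / 2) * (1/n_i + 1/n_j))

referred to the studentized-range distribution q(alpha, k, df_resid), and are
summarized as a compact letter display: groups sharing any letter are not
significantly different.

Published results often survive only as per-group (mean, SD, N) summary
tables. :func:`anova_from_summary` reconstructs the exact one-way ANOVA from
such a table — the between-group stratum from the weighted means, the residual
stratum from Sum (n_i - 1) * sd_i**2 — and agrees with :func:`one_way_anova`
whenever the summaries are exact.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.formula.api import ols

LETTERS = string.ascii_lowercase


class DegenerateDataError(ValueError):
    """All observations identical: the ANOVA decomposition is undefined."""


# ---------------------------------------------------------------------------
# observations

def log10_transform(psms: pd.DataFrame, entity_level: str = "gene_symbol") -> pd.DataFrame:
    """One log10-intensity observation per retained PSM.

    Returns columns ``entity``, ``treatment_id``, ``patient_id``,
    ``log10_intensity``. With the default 1e4 precursor floor every value is
    >= 4.0.
    """
    from .treatments import map_treatment
    if (psms["precursor_intensity"] <= 0).any():
        raise ValueError("precursor intensities must be positive")
    tid = [map_treatment(c, s) for c, s in zip(psms["condition"], psms["search_type"])]
    return pd.DataFrame({
        "entity": psms[entity_level].astype(str).to_numpy(),
        "treatment_id": np.asarray(tid, dtype=np.int64),
        "patient_id": psms["patient_id"].astype(str).to_numpy(),
        "log10_intensity": np.log10(psms["precursor_intensity"].to_numpy(dtype=float)),
    })


def normality_check(observations: pd.DataFrame, cap: int = 5000,
                    seed: int = 0) -> pd.DataFrame:
    """Shapiro-Wilk normality test per treatment group.

    Groups with n < 3 or zero variance are skipped and flagged. Groups larger
    than ``cap`` are subsampled without replacement under a fixed seed, since
    the test is defined for moderate n.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for tid, grp in observations.groupby("treatment_id"):
        x = grp["log10_intensity"].to_numpy(dtype=float)
        if len(x) < 3 or np.ptp(x) == 0:
            rows.append({"treatment_id": tid, "n": len(x), "W": np.nan,
                         "p": np.nan, "skipped": True})
            continue
        if len(x) > cap:
            x = rng.choice(x, size=cap, replace=False)
        W, p = stats.shapiro(x)
        rows.append({"treatment_id": tid, "n": len(grp), "W": W, "p": p,
                     "skipped": False})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ANOVA

@dataclass(frozen=True)
class AnovaResult:
    """One-way fixed-effects decomposition (R-style strata)."""

    df_treatment: int
    ss_treatment: float
    ms_treatment: float
    f_value: float
    p_value: float
    df_residual: int
    ss_residual: float
    ms_residual: float

    def to_frame(self) -> pd.DataFrame:
        """R ``anova()``-shaped table: Df, Sum Sq, Mean Sq, F value, Pr(>F)."""
        return pd.DataFrame(
            {
                "Df": [self.df_treatment, self.df_residual],
                "Sum Sq": [self.ss_treatment, self.ss_residual],
                "Mean Sq": [self.ms_treatment, self.ms_residual],
                "F value": [self.f_value, np.nan],
                "Pr(>F)": [self.p_value, np.nan],
            },
            index=["treatment", "residuals"],
        )


def one_way_anova(values, groups) -> AnovaResult:
    """One-way fixed-effects ANOVA on raw observations.

    Fits an OLS cell-means model and reads the sequential (Type I) table;
    ``df_treatment = k - 1``, ``df_residual = N - k``.
    """
    df = pd.DataFrame({"y": np.asarray(values, dtype=float),
                       "g": np.asarray(groups)})
    k = df["g"].nunique()
    if k < 2:
        raise ValueError("need at least two groups")
    if np.ptp(df["y"].to_numpy()) == 0:
        raise DegenerateDataError("all observations identical (zero total SS)")
    fit = ols("y ~ C(g)", data=df).fit()
    tab = sm.stats.anova_lm(fit, typ=1)
    ss_t, ss_r = float(tab["sum_sq"].iloc[0]), float(tab["sum_sq"].iloc[1])
    df_t, df_r = int(tab["df"].iloc[0]), int(tab["df"].iloc[1])
    ms_t, ms_r = ss_t / df_t, ss_r / df_r
    return AnovaResult(df_t, ss_t, ms_t, float(tab["F"].iloc[0]),
                       float(tab["PR(>F)"].iloc[0]), df_r, ss_r, ms_r)


def anova_from_summary(means, sds, ns) -> AnovaResult:
    """Reconstruct the one-way ANOVA from per-group (mean, sd, n) summaries.

    ``ss_treatment = Sum n_i (mean_i - grand_mean)**2`` with the n-weighted
    grand mean; ``ss_residual = Sum (n_i - 1) sd_i**2``. Equal to
    :func:`one_way_anova` on any raw data having exactly these summaries.
    Groups with n == 1 may omit the sd (NaN); sd missing with n >= 2 is an
    error.
    """
    m = np.asarray(means, dtype=float)
    s = np.asarray(sds, dtype=float)
    n = np.asarray(ns, dtype=float)
    if not (m.shape == s.shape == n.shape):
        raise ValueError("means, sds, ns must have equal length")
    if (n < 1).any():
        raise ValueError("every group needs n >= 1")
    if np.isnan(s[n >= 2]).any():
        raise ValueError("sd required for groups with n >= 2")
    s = np.where(np.isnan(s), 0.0, s)
    k = len(m)
    if k < 2:
        raise ValueError("need at least two groups")
    N = n.sum()
    grand = (n * m).sum() / N
    ss_t = float((n * (m - grand) ** 2).sum())
    ss_r = float(((n - 1) * s ** 2).sum())
    df_t, df_r = k - 1, int(round(N)) - k
    if df_r < 1:
        raise ValueError("no residual degrees of freedom")
    if ss_t == 0 and ss_r == 0:
        raise DegenerateDataError("all summaries identical (zero total SS)")
    ms_t, ms_r = ss_t / df_t, ss_r / df_r
    if ms_r == 0:
        f, p = np.inf, 0.0
    else:
        f = ms_t / ms_r
        p = float(stats.f.sf(f, df_t, df_r))
    return AnovaResult(df_t, ss_t, ms_t, float(f), p, df_r, ss_r, ms_r)


def two_way_anova(values, treatments, peptides) -> pd.DataFrame:
    """Additive two-factor fixed-effects ANOVA (no interaction).

    Type I sequential sums of squares with the treatment factor entered first
    (matching R's default ``aov(y ~ treatment + peptide)`` on an unbalanced
    design, where the order matters). Returns the R-shaped strata table with
    rows ``treatment``, ``peptide``, ``residuals``.

    A factor level confined to a single cell (fully confounded) is reported
    with a warning, not an error.
    """
    df = pd.DataFrame({"y": np.asarray(values, dtype=float),
                       "t": np.asarray(treatments), "pep": np.asarray(peptides)})
    if df["t"].nunique() < 2:
        raise ValueError("treatment factor needs >= 2 levels")
    if df["pep"].nunique() < 2:
        # constant second factor: the model collapses to the one-way layout
        warnings.warn("peptide factor is constant; collapsing to one-way ANOVA",
                      stacklevel=2)
        one = one_way_anova(df["y"], df["t"])
        tab = one.to_frame().rename(index={"residuals": "residuals"})
        pep_row = pd.DataFrame({"Df": [0], "Sum Sq": [0.0], "Mean Sq": [np.nan],
                                "F value": [np.nan], "Pr(>F)": [np.nan]},
                               index=["peptide"])
        return pd.concat([tab.iloc[:1], pep_row, tab.iloc[1:]])[
            ["Df", "Sum Sq", "Mean Sq", "F value", "Pr(>F)"]]
    cells = df.groupby(["t", "pep"]).size()
    for fac in ("t", "pep"):
        lonely = cells.reset_index().groupby(fac).size()
        if (lonely == 1).any():
            warnings.warn(
                f"factor {fac!r} has level(s) observed in a single cell; "
                "its stratum may be partially confounded", stacklevel=2)
            break
    fit = ols("y ~ C(t) + C(pep)", data=df).fit()
    tab = sm.stats.anova_lm(fit, typ=1)
    tab.index = ["treatment", "peptide", "residuals"]
    out = tab.rename(columns={"df": "Df", "sum_sq": "Sum Sq", "F": "F value",
                              "PR(>F)": "Pr(>F)"})
    out["Mean Sq"] = out["Sum Sq"] / out["Df"]
    return out[["Df", "Sum Sq", "Mean Sq", "F value", "Pr(>F)"]]


# ---------------------------------------------------------------------------
# Tukey-Kramer HSD and the compact letter display

@dataclass
class TukeyKramerResult:
    """All-pairs comparison at one alpha.

    ``pairwise`` has one row per unordered pair with the Tukey-Kramer
    statistic, its studentized-range p-value and the significance flag;
    ``letters`` maps group -> letter string (shared letter = not separated).
    """

    pairwise: pd.DataFrame
    letters: dict
    q_critical: float
    alpha: float


def compact_letter_display(groups, significant_pairs) -> dict:
    """Insert-and-absorb compact letter display.

    Parameters
    ----------
    groups : sequence
        Group labels in the order letters should be allocated
        (conventionally descending mean).
    significant_pairs : iterable of 2-tuples
        Pairs judged significantly different.

    Returns
    -------
    dict mapping group -> concatenated letters; two groups share a letter iff
    they are not significantly different.
    """
    groups = list(groups)
    sig = {frozenset(p) for p in significant_pairs}
    columns: list[set] = [set(groups)]
    for pair in sig:
        i, j = tuple(pair)
        for col in [c for c in columns if i in c and j in c]:
            columns.remove(col)
            columns.extend([col - {i}, col - {j}])
        # absorb: drop columns contained in another
        columns = [c for c in columns
                   if not any(c < d for d in columns)]
        # dedupe
        seen, uniq = set(), []
        for c in columns:
            f = frozenset(c)
            if f not in seen:
                seen.add(f)
                uniq.append(c)
        columns = uniq
    rank = {g: i for i, g in enumerate(groups)}
    columns.sort(key=lambda c: min(rank[g] for g in c))
    out = {g: "" for g in groups}
    for li, col in enumerate(columns):
        letter = LETTERS[li % len(LETTERS)] * (1 + li // len(LETTERS))
        for g in groups:
            if g in col:
                out[g] += letter
    return out


def tukey_kramer(summaries: pd.DataFrame, ms_residual: float, df_residual: int,
                 alpha: float = 0.05) -> TukeyKramerResult:
    """Tukey-Kramer HSD from group summaries and the pooled residual variance.

    ``summaries`` needs columns ``treatment_id`` (or ``group``), ``mean``,
    ``n``. The statistic for pair (i, j) is
    ``|mean_i - mean_j| / sqrt((ms_residual/2)(1/n_i + 1/n_j))`` compared with
    the studentized-range quantile q(alpha, k, df_residual).
    """
    if df_residual < 1:
        raise ValueError("df_residual must be >= 1")
    if ms_residual < 0:
        raise ValueError("ms_residual must be >= 0")
    key = "treatment_id" if "treatment_id" in summaries.columns else "group"
    s = summaries.sort_values("mean", ascending=False, kind="mergesort")
    labels = list(s[key])
    means = s["mean"].to_numpy(dtype=float)
    ns = s["n"].to_numpy(dtype=float)
    k = len(labels)
    if k < 2:
        raise ValueError("need >= 2 groups")
    q_crit = float(stats.studentized_range.ppf(1 - alpha, k, df_residual))
    rows, sig_pairs = [], []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt((ms_residual / 2.0) * (1.0 / ns[i] + 1.0 / ns[j]))
            diff = abs(means[i] - means[j])
            stat = np.inf if se == 0 and diff > 0 else (0.0 if se == 0 else diff / se)
            p = float(stats.studentized_range.sf(stat, k, df_residual)) \
                if np.isfinite(stat) else 0.0
            signif = bool(stat > q_crit)
            if signif:
                sig_pairs.append((labels[i], labels[j]))
            rows.append({"group_1": labels[i], "group_2": labels[j],
                         "diff": means[i] - means[j], "stat": stat,
                         "p": p, "significant": signif})
    letters = compact_letter_display(labels, sig_pairs)
    return TukeyKramerResult(pd.DataFrame(rows), letters, q_crit, alpha)


# ---------------------------------------------------------------------------
# per-entity summaries and the model objects

def group_summaries(observations: pd.DataFrame) -> pd.DataFrame:
    """Per-treatment mean, sd (ddof=1; 0 for n == 1) and n of log10 intensity."""
    g = observations.groupby("treatment_id")["log10_intensity"]
    out = pd.DataFrame({
        "treatment_id": g.mean().index,
        "mean": g.mean().to_numpy(),
        "sd": g.std(ddof=1).fillna(0.0).to_numpy(),
        "n": g.size().to_numpy(),
    }).reset_index(drop=True)
    return out


def summarize_entity(observations: pd.DataFrame, entity: str,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Per-treatment summary table for one entity, with Tukey letters.

    Treatments without observations are omitted. With a single observed
    treatment the letters column is empty (no comparison is computable).
    """
    obs = observations[observations["entity"] == entity]
    if len(obs) == 0:
        raise ValueError(f"entity {entity!r} not present")
    summ = group_summaries(obs)
    if len(summ) >= 2 and summ["n"].sum() > len(summ):
        try:
            aov = anova_from_summary(summ["mean"], summ["sd"], summ["n"])
        except DegenerateDataError:
            summ["letters"] = ""
            return summ
        tk = tukey_kramer(summ, aov.ms_residual, aov.df_residual, alpha)
        summ["letters"] = summ["treatment_id"].map(tk.letters)
    else:
        summ["letters"] = ""
    return summ


@dataclass
class IntensityAnovaResults:
    """Fitted intensity model: ANOVA strata, group summaries and Tukey letters."""

    model: "IntensityAnova"
    anova: AnovaResult
    groups: pd.DataFrame
    tukey: TukeyKramerResult | None

    def summary(self) -> str:
        lines = ["Log10 precursor-intensity ANOVA", "=" * 36]
        if self.model.entity is not None:
            lines.append(f"entity: {self.model.entity}")
        lines += ["", "One-way ANOVA:",
                  self.anova.to_frame().to_string(),
                  "", "Group summaries (Tukey-Kramer letters, alpha="
                  f"{self.model.alpha}):",
                  self.groups.to_string(index=False)]
        return "\n".join(lines)


class IntensityAnova:
    """Model: one-way ANOVA of log10 precursor intensity across treatments.

    Construct from raw observations (``observations`` with columns
    ``treatment_id`` and ``log10_intensity``), from filtered PSMs via
    :meth:`from_psms`, or from a published-style per-group summary table via
    :meth:`from_summary`; ``fit`` returns an :class:`IntensityAnovaResults`
    carrying the strata, the per-group summaries and the compact letter
    display.
    """

    def __init__(self, observations: pd.DataFrame | None = None,
                 summaries: pd.DataFrame | None = None,
                 entity: str | None = None, alpha: float = 0.05):
        if (observations is None) == (summaries is None):
            raise ValueError("provide exactly one of observations, summaries")
        self.observations = observations
        self.summaries = summaries
        self.entity = entity
        self.alpha = alpha

    @classmethod
    def from_psms(cls, psms: pd.DataFrame, entity: str,
                  level: str = "gene_symbol", alpha: float = 0.05,
                  per_patient_mean: bool = False) -> "IntensityAnova":
        """Build from best-hit PSMs for one entity.

        By default each retained PSM is one observation; with
        ``per_patient_mean`` the patient-level means are the observations.
        """
        obs = log10_transform(psms, entity_level=level)
        obs = obs[obs["entity"] == entity].reset_index(drop=True)
        if len(obs) == 0:
            raise ValueError(f"entity {entity!r} not present")
        if per_patient_mean:
            obs = (obs.groupby(["treatment_id", "patient_id"], as_index=False)
                   ["log10_intensity"].mean())
            obs["entity"] = entity
        return cls(observations=obs, entity=entity, alpha=alpha)

    @classmethod
    def from_summary(cls, summaries: pd.DataFrame, entity: str | None = None,
                     alpha: float = 0.05) -> "IntensityAnova":
        """Build from a per-group (treatment_id, mean, sd, n) table."""
        required = {"treatment_id", "mean", "sd", "n"}
        if not required <= set(summaries.columns):
            raise ValueError(f"summary table needs columns {sorted(required)}")
        return cls(summaries=summaries.reset_index(drop=True), entity=entity,
                   alpha=alpha)

    def fit(self) -> IntensityAnovaResults:
        if self.observations is not None:
            summ = group_summaries(self.observations)
            aov = one_way_anova(self.observations["log10_intensity"],
                                self.observations["treatment_id"])
        else:
            summ = self.summaries.copy()
            aov = anova_from_summary(summ["mean"], summ["sd"], summ["n"])
        tukey = None
        if len(summ) >= 2 and aov.ms_residual > 0:
            tukey = tukey_kramer(summ, aov.ms_residual, aov.df_residual,
                                 self.alpha)
            summ = summ.copy()
            summ["letters"] = summ["treatment_id"].map(tukey.letters)
        else:
            summ = summ.copy()
            summ["letters"] = ""
        return IntensityAnovaResults(self, aov, summ, tukey)
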
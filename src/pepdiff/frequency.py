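"""Spectral-counting differential analysis between two treatments.

The primary quantification is the *observation frequency*: the number of
filtered (best-hit, intensity-thresholded) MS/MS spectra attributed to an
entity — a peptide sequence, a protein accession, or a gene symbol — within a
treatment. Two treatments A and B are contrasted by

1. rescaling A's raw counts by the ratio of total filtered spectra,
   ``corrected_a = count_a * total_b / total_a``, so both sit on B's sampling
   depth;
2. the pseudo-count one-cell chi-square score

       chi2 = (corrected_a - count_b)**2 / (count_b + 1)

   referred to a chi-square distribution with one degree of freedom, with the
   ``+1`` keeping the score finite when the comparator count is zero;
3. Benjamini-Hochberg FDR correction of the tail p-values within the analysis
   family (one rollup level x one search channel).

The score is intentionally asymmetric in (A, B) and is anticonservative
relative to the classical two-sample proportion chi-square; the classical 2x2
statistic is provided as a calibration cross-check (it is not part of the
published scoring rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import psm
from .treatments import map_treatment

LEVELS = ("peptide_sequence", "accession", "gene_symbol")

#: Reserved entity for records lacking a gene symbol at gene-level rollup.
UNMAPPED = "UNMAPPED"


# ---------------------------------------------------------------------------
# counting

@dataclass
class FrequencyTable:
    """Observation counts at one rollup level.

    Attributes
    ----------
    level : str
        ``peptide_sequence``, ``accession`` or ``gene_symbol``.
    counts : DataFrame
        Entities x treatment ids; integer counts, absent cells zero.
    totals : Series
        Per-treatment total of filtered MS/MS spectra. Because each retained
        spectrum is attributed to exactly one entity, column sums equal totals
        (counts are conserved).
    """

    level: str
    counts: pd.DataFrame
    totals: pd.Series

    def condition_counts(self) -> pd.DataFrame:
        """Pool the TRYP/STYP channels of each condition (columns -> conditions)."""
        from .treatments import unmap_treatment
        cond = {tid: unmap_treatment(tid)[0] for tid in self.counts.columns}
        return self.counts.T.groupby(cond).sum().T


def count_frequencies(psms: pd.DataFrame, level: str = "gene_symbol") -> FrequencyTable:
    """Tally best-hit PSMs into an entity x treatment frequency table.

    Records with an empty entity at gene level are routed to the reserved
    ``UNMAPPED`` entity so that counts stay conserved.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}")
    if len(psms) == 0:
        return FrequencyTable(level, pd.DataFrame(dtype=np.int64),
                              pd.Series(dtype=np.int64))
    entity = psms[level].astype(str)
    entity = entity.where(entity.str.len() > 0, UNMAPPED)
    tid = [map_treatment(c, s) for c, s in zip(psms["condition"], psms["search_type"])]
    counts = (
        pd.DataFrame({"entity": entity.to_numpy(), "treatment_id": tid})
        .groupby(["entity", "treatment_id"], sort=True)
        .size()
        .unstack(fill_value=0)
    )
    counts.index.name = "entity"
    totals = counts.sum(axis=0)
    totals.name = "total"
    return FrequencyTable(level, counts, totals)


# ---------------------------------------------------------------------------
# correction and the chi-square score

@dataclass(frozen=True)
class CorrectionFactors:
    """Sampling-depth totals of the contrasted treatments.

    ``factor = total_b / total_a`` rescales A's raw counts onto B's depth.
    In the breast-vs-ovarian contrast the published totals are 455,426 (A)
    and 498,616 (B) filtered MS/MS spectra.
    """

    total_a: float
    total_b: float

    def __post_init__(self):
        if self.total_a <= 0 or self.total_b <= 0:
            raise ValueError("spectrum totals must be positive")

    @property
    def factor(self) -> float:
        return self.total_b / self.total_a


def correct_counts(count_a, factors: CorrectionFactors):
    """Rescale raw A counts to B's sampling depth: ``count_a * total_b/total_a``."""
    return np.asarray(count_a, dtype=float) * factors.factor


def chi_square_eq1(corrected_a, count_b):
    """Pseudo-count one-cell score ``(corrected_a - count_b)**2 / (count_b + 1)``.

    Zero iff the corrected A count equals the B count; finite at ``count_b = 0``
    by construction. Asymmetric: B is the comparator in the denominator.
    """
    a = np.asarray(corrected_a, dtype=float)
    b = np.asarray(count_b, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("counts must be nonnegative")
    return (a - b) ** 2 / (b + 1.0)


def chi2_pvalue(chi2, df: int = 1):
    """Upper-tail probability of the chi-square distribution with ``df`` dof."""
    if df < 1:
        raise ValueError("df must be >= 1")
    c = np.asarray(chi2, dtype=float)
    if (c < 0).any():
        raise ValueError("chi2 must be >= 0")
    return stats.chi2.sf(c, df)


def classical_chi2(count_a, count_b, total_a: float, total_b: float):
    """Pearson 2x2 proportion chi-square (entity vs rest, A vs B margins).

    Calibration reference only — this is the textbook two-sample statistic,
    not the published pseudo-count score. Computed without continuity
    correction; returns 0 where an entity's pooled count is 0 or equals the
    pooled total.
    """
    a = np.asarray(count_a, dtype=float)
    b = np.asarray(count_b, dtype=float)
    resta, restb = total_a - a, total_b - b
    n = total_a + total_b
    num = n * (a * restb - b * resta) ** 2
    den = (a + b) * (resta + restb) * total_a * total_b
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / den, 0.0)
    return out


def bh_fdr(p_values):
    """Benjamini-Hochberg step-up q-values, returned in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# tables built on the score

def contrast_table(freq: FrequencyTable, treatment_a: int, treatment_b: int,
                   factors: CorrectionFactors | None = None) -> pd.DataFrame:
    """Per-entity contrast rows: counts, corrected count, delta, chi2, p, q.

    ``delta = corrected_a - count_b``; the FDR family is the set of entities in
    this table (one level x one channel).
    """
    if factors is None:
        factors = CorrectionFactors(float(freq.totals.get(treatment_a, 0)),
                                    float(freq.totals.get(treatment_b, 0)))
    count_a = freq.counts.get(treatment_a, pd.Series(0, index=freq.counts.index))
    count_b = freq.counts.get(treatment_b, pd.Series(0, index=freq.counts.index))
    corrected = correct_counts(count_a, factors)
    delta = corrected - count_b.to_numpy(dtype=float)
    chi2 = chi_square_eq1(corrected, count_b)
    p = chi2_pvalue(chi2, df=1)
    out = pd.DataFrame({
        "entity": freq.counts.index,
        "count_a": count_a.to_numpy(dtype=np.int64),
        "count_b": count_b.to_numpy(dtype=np.int64),
        "corrected_a": corrected,
        "delta": delta,
        "chi2": chi2,
        "p": p,
        "q": bh_fdr(p),
    }).reset_index(drop=True)
    return out.sort_values("chi2", ascending=False, kind="mergesort").reset_index(drop=True)


def gene_mean_chi2(accession_rows: pd.DataFrame) -> pd.DataFrame:
    """Roll per-accession chi-square rows up to gene symbols.

    Returns one row per gene symbol with the arithmetic mean chi-square over
    its accessions and ``n_accessions``, sorted by decreasing mean.
    """
    grouped = accession_rows.groupby("gene_symbol")["chi2"]
    out = pd.DataFrame({
        "gene_symbol": grouped.mean().index,
        "mean_chi2": grouped.mean().to_numpy(),
        "n_accessions": grouped.size().to_numpy(),
    })
    return out.sort_values(["mean_chi2", "gene_symbol"],
                           ascending=[False, True]).reset_index(drop=True)


def select_candidates(rows: pd.DataFrame, min_delta: float = 9.0,
                      min_chi2: float = 9.0) -> pd.DataFrame:
    """Retain rows with ``delta > min_delta`` and ``chi2 > min_chi2`` (strict).

    The default (9, 9) is the published gene-list selection rule; (15, 15) is
    the stricter network-figure variant.
    """
    keep = (rows["delta"] > min_delta) & (rows["chi2"] > min_chi2)
    return rows[keep].reset_index(drop=True)


def quantile_difference_table(rows: pd.DataFrame, by: str = "delta") -> pd.DataFrame:
    """Rows sorted by ``by`` with the cumulative fraction, for quantile plots."""
    if len(rows) == 0:
        raise ValueError("empty table")
    out = rows.sort_values(by, kind="mergesort").reset_index(drop=True)
    out["quantile"] = (np.arange(len(out)) + 1) / len(out)
    return out


def export_gene_list(rows: pd.DataFrame, path,
                     column: str = "entity") -> list[str]:
    """Write the deduplicated, sorted gene symbols of selected rows, one per line."""
    symbols = sorted(set(map(str, rows[column])))
    with open(path, "w", encoding="utf-8") as fh:
        for s in symbols:
            fh.write(s + "\n")
    return symbols


# ---------------------------------------------------------------------------
# model / results objects

@dataclass
class FrequencyContrastResults:
    """Fitted frequency contrast between two treatments.

    ``table`` holds per-entity rows (counts, corrected count, delta, chi2, p,
    q) sorted by decreasing chi2; helper methods expose the selection rule,
    the gene-symbol rollup, and quantile-plot data.
    """

    model: "FrequencyContrast"
    table: pd.DataFrame
    factors: CorrectionFactors
    freq: FrequencyTable
    accession_map: pd.Series | None = None
    _gene_rollup: pd.DataFrame | None = field(default=None, repr=False)

    def select(self, min_delta: float = 9.0, min_chi2: float = 9.0) -> pd.DataFrame:
        return select_candidates(self.table, min_delta, min_chi2)

    def gene_summary(self) -> pd.DataFrame:
        """Mean chi-square per gene symbol with accession counts.

        At accession level the rollup averages over accessions sharing a gene
        symbol; at gene level each symbol is its own single "accession".
        """
        rows = self.table.copy()
        if self.model.level == "accession" and self.accession_map is not None:
            rows["gene_symbol"] = rows["entity"].map(self.accession_map).fillna(UNMAPPED)
        else:
            rows["gene_symbol"] = rows["entity"]
        return gene_mean_chi2(rows)

    def quantile_table(self, by: str = "delta") -> pd.DataFrame:
        return quantile_difference_table(self.table, by=by)

    def export_gene_list(self, path, min_delta: float = 9.0,
                         min_chi2: float = 9.0) -> list[str]:
        sel = self.select(min_delta, min_chi2)
        rows = sel.copy()
        if self.model.level == "accession" and self.accession_map is not None:
            rows["entity"] = rows["entity"].map(self.accession_map).fillna(UNMAPPED)
        return export_gene_list(rows, path)

    def summary(self) -> str:
        m = self.model
        sel = self.select()
        lines = [
            "Frequency contrast (pseudo-count chi-square)",
            "=" * 44,
            f"level: {m.level}   channel: {m.search_type}",
            f"A: {m.condition_a} (treatment {m.treatment_a}, "
            f"total {self.factors.total_a:.0f})",
            f"B: {m.condition_b} (treatment {m.treatment_b}, "
            f"total {self.factors.total_b:.0f})",
            f"correction factor total_b/total_a = {self.factors.factor:.6f}",
            f"entities tested: {len(self.table)}",
            f"selected (delta > 9 and chi2 > 9): {len(sel)}",
            "",
            "top entities by chi2:",
            self.table.head(10).to_string(index=False),
        ]
        return "\n".join(lines)


class FrequencyContrast:
    """Model: observation-frequency contrast of two conditions in one channel.

    Parameters
    ----------
    candidates : DataFrame
        Candidate-match table (may be redundant; the fit applies the intensity
        floor and the best-hit collapse first).
    condition_a, condition_b : str
        Contrasted conditions; A is depth-corrected onto B.
    search_type : str
        ``TRYP`` or ``STYP`` — the analysis family for FDR correction.
    level : str
        Rollup level for counting.
    min_intensity : float
        Precursor floor in arbitrary counts (inclusive).
    correction : str
        ``"spectrum_totals"`` (default: totals of filtered spectra) or
        ``"correlation_totals"`` (totals of redundant candidate rows, an
        alternative depth measure that yields similar results).

    Examples
    --------
    >>> res = FrequencyContrast(cands, "breast_cancer", "ovarian_cancer").fit()
    >>> res.table.head()
    """

    def __init__(self, candidates: pd.DataFrame, condition_a: str, condition_b: str,
                 search_type: str = "TRYP", level: str = "gene_symbol",
                 min_intensity: float = psm.DEFAULT_MIN_INTENSITY,
                 correction: str = "spectrum_totals"):
        if condition_a == condition_b:
            raise ValueError("contrast conditions must differ")
        if correction not in ("spectrum_totals", "correlation_totals"):
            raise ValueError(f"unknown correction mode: {correction!r}")
        if level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}")
        self.candidates = candidates
        self.condition_a = condition_a
        self.condition_b = condition_b
        self.search_type = search_type
        self.level = level
        self.min_intensity = min_intensity
        self.correction = correction
        self.treatment_a = map_treatment(condition_a, search_type)
        self.treatment_b = map_treatment(condition_b, search_type)

    def fit(self) -> FrequencyContrastResults:
        cands = self.candidates
        cands = cands[cands["search_type"] == self.search_type]
        cands = cands[cands["condition"].isin([self.condition_a, self.condition_b])]
        thresholded = psm.intensity_threshold(cands, self.min_intensity)
        best = psm.best_hit_filter(thresholded)
        freq = count_frequencies(best, self.level)

        if self.correction == "correlation_totals":
            # depth measured as redundant candidate rows rather than spectra
            per = thresholded.groupby("condition").size()
            factors = CorrectionFactors(float(per.get(self.condition_a, 0)),
                                        float(per.get(self.condition_b, 0)))
        else:
            factors = CorrectionFactors(
                float(freq.totals.get(self.treatment_a, 0)),
                float(freq.totals.get(self.treatment_b, 0)))

        table = contrast_table(freq, self.treatment_a, self.treatment_b, factors)
        accession_map = None
        if self.level == "accession" and len(best):
            accession_map = (best.groupby("accession")["gene_symbol"]
                             .agg(lambda s: s.mode().iloc[0]))
        return FrequencyContrastResults(self, table, factors, freq, accession_map)
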
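"""Seeded simulator of candidate PSM tables with planted effects.

The generator emulates the structure of a multisite plasma peptidomics study:
9-26 patients per disease/control condition, ten organic/water sub-fractions
per patient, overdispersed MS/MS spectrum counts per fraction run, log-normal
precursor intensities with a detection floor at 1e4 counts (log10 = 4), and
redundant candidate correlations per spectrum at roughly 1.2 candidates per
spectrum. Effects can be planted and are returned as ground truth:

* *frequency enrichment* — a gene's observation rate multiplied by a fold
  factor in one condition;
* *intensity shift* — an additive log10-intensity offset for a gene in one
  condition;
* *exclusive peptides* — peptides emitted only in one condition;
* a reduced detectable gene panel in the ice-cold baseline condition.

Every draw flows from one ``numpy`` Generator seeded from ``SimConfig.seed``,
so a fixed config reproduces the dataset byte-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .treatments import CONDITIONS

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: Patient counts per condition (study-scale replication: 9 to 26).
DEFAULT_PATIENTS = {
    "alzheimer_normal": 12,
    "alzheimer_dementia": 13,
    "breast_cancer": 15,
    "cancer_control": 18,
    "ovarian_cancer": 15,
    "ice_cold": 9,
    "heart_attack_arterial": 11,
    "heart_attack_normal_control": 13,
    "heart_attack_venous": 26,
    "multiple_sclerosis_normal_control": 20,
    "multiple_sclerosis": 15,
    "sepsis": 12,
    "sepsis_normal_control": 14,
}


def default_gene_panel(n_genes: int = 200, peptides_per_gene: int = 3,
                       accessions_per_gene: int = 2) -> pd.DataFrame:
    """Deterministic synthetic gene panel with peptides and accessions.

    Peptide sequences are random tryptic-looking strings (ending K/R) drawn
    from a fixed internal seed, so the panel is identical across runs and
    independent of the cohort seed.
    """
    rng = np.random.default_rng(20121986)
    rows = []
    for g in range(n_genes):
        gene = f"GENE{g + 1:04d}"
        accs = [f"NP_{g + 1:06d}.{a + 1}" for a in range(accessions_per_gene)]
        for p in range(peptides_per_gene):
            length = int(rng.integers(8, 15))
            seq = "".join(rng.choice(_AA, size=length - 1)) + \
                  str(rng.choice(["K", "R"]))
            rows.append({"gene_symbol": gene, "peptide_sequence": seq,
                         "accessions": accs})
    return pd.DataFrame(rows)


@dataclass
class SimConfig:
    """Cohort-generator configuration.

    The structural defaults mirror the emulated study design (patients per
    condition, 10 fractions, intensity scale mean 4.6 / sd 0.5 with floor 4.0,
    redundancy ~0.2 extra candidates per spectrum); the per-fraction sampling
    depth is a free parameter kept small enough that a full cohort generates
    in seconds.
    """

    conditions: dict = field(default_factory=lambda: dict(DEFAULT_PATIENTS))
    fractions_per_patient: int = 10
    spectra_per_fraction_mean: float = 150.0
    spectra_per_fraction_dispersion: float = 5.0  # neg-binomial shape (size)
    gene_panel: pd.DataFrame | None = None        # default_gene_panel() if None
    enriched_genes: dict = field(default_factory=dict)   # gene -> (condition, fold)
    shifted_genes: dict = field(default_factory=dict)    # gene -> (condition, delta)
    exclusive_peptides: list = field(default_factory=list)
    # each: (peptide_sequence, gene_symbol, condition, relative_rate)
    intensity_mean: float = 4.6
    intensity_sd: float = 0.5
    intensity_floor: float = 4.0
    styp_fraction: float = 0.35
    redundancy_prob: float = 0.2
    score_mean: float = 3.0
    score_sd: float = 0.6
    score_gap_scale: float = 0.5
    icecold_detect_fraction: float = 0.5
    seed: int = 0

    def panel(self) -> pd.DataFrame:
        return self.gene_panel if self.gene_panel is not None else default_gene_panel()

    def validate(self) -> None:
        if len(self.panel()) == 0:
            raise ValueError("empty gene panel")
        if not 0 <= self.redundancy_prob <= 1:
            raise ValueError("redundancy_prob must be in [0,1]")
        if not 0 <= self.styp_fraction <= 1:
            raise ValueError("styp_fraction must be in [0,1]")
        if not 0 < self.icecold_detect_fraction <= 1:
            raise ValueError("icecold_detect_fraction must be in (0,1]")
        for cond in self.conditions:
            if cond not in CONDITIONS:
                raise ValueError(f"unknown condition {cond!r}")
        for gene, (cond, fold) in self.enriched_genes.items():
            if fold < 0:
                raise ValueError(f"negative fold for {gene}")


@dataclass
class TruthTable:
    """Ground truth accompanying a generated cohort."""

    gene_rates: pd.DataFrame          # gene x condition sampling probability
    enriched_genes: dict              # gene -> (condition, fold)
    shifted_genes: dict               # gene -> (condition, delta)
    exclusive_peptides: list          # (peptide, gene, condition, rate)
    spectra_per_condition: pd.Series  # generated spectrum totals


def _truncated_normal(rng, mu, sd, floor):
    """Redraw values below the floor (truncation, not censoring)."""
    x = rng.normal(mu, sd)
    bad = x < floor
    while bad.any():
        x[bad] = rng.normal(np.asarray(mu)[bad] if np.ndim(mu) else mu,
                            sd, size=int(bad.sum()))
        bad = x < floor
    return x


def generate_cohort(config: SimConfig) -> tuple[pd.DataFrame, TruthTable]:
    """Generate a candidate-match table and its ground truth.

    For every condition x patient x fraction the spectrum count is a negative
    binomial draw; each spectrum is assigned a gene (and one of its peptides
    and accessions) from the condition's rate vector, a charge, a search
    channel, a winner score and a floored log-normal precursor intensity.
    Redundant candidate rows are appended with strictly lower scores, so the
    best-hit filter's expected output is the winner set by construction.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    panel = config.panel()
    genes = panel["gene_symbol"].unique()
    gene_idx = {g: i for i, g in enumerate(genes)}
    peptides_by_gene = panel.groupby("gene_symbol", sort=False)
    gene_peptides = {g: list(df["peptide_sequence"]) for g, df in peptides_by_gene}
    gene_accessions = {g: list(df["accessions"].iloc[0]) for g, df in peptides_by_gene}

    # per-condition sampling rates over genes + planted exclusive peptides
    base = np.ones(len(genes), dtype=float)
    rate_rows = {}
    excl_by_cond: dict[str, list] = {}
    for pep, gene, cond, rate in config.exclusive_peptides:
        excl_by_cond.setdefault(cond, []).append((pep, gene, rate))
    for cond in config.conditions:
        rates = base.copy()
        if cond == "ice_cold":
            cut = max(1, int(round(config.icecold_detect_fraction * len(genes))))
            rates[cut:] = 0.0
        for gene, (ec, fold) in config.enriched_genes.items():
            if ec == cond and gene in gene_idx:
                rates[gene_idx[gene]] *= fold
        rate_rows[cond] = rates

    frames = []
    spectrum_counter = 0
    totals = {}
    nb_size = config.spectra_per_fraction_dispersion
    nb_p = nb_size / (nb_size + config.spectra_per_fraction_mean)
    for cond in config.conditions:                      # fixed insertion order
        n_pat = config.conditions[cond]
        n_runs = n_pat * config.fractions_per_patient
        counts = rng.negative_binomial(nb_size, nb_p, size=n_runs)
        n_spec = int(counts.sum())
        totals[cond] = n_spec
        if n_spec == 0:
            continue
        pat = np.repeat(np.repeat(np.arange(n_pat), config.fractions_per_patient),
                        counts)
        frac = np.repeat(np.tile(np.arange(1, config.fractions_per_patient + 1),
                                 n_pat), counts)

        excl = excl_by_cond.get(cond, [])
        rates = rate_rows[cond]
        weights = np.concatenate([rates, [r for _, _, r in excl]]) if excl else rates
        probs = weights / weights.sum()
        slot = rng.choice(len(probs), size=n_spec, p=probs)

        gene_arr = np.empty(n_spec, dtype=object)
        pep_arr = np.empty(n_spec, dtype=object)
        acc_arr = np.empty(n_spec, dtype=object)
        is_gene = slot < len(genes)
        for i in np.nonzero(is_gene)[0]:
            g = genes[slot[i]]
            peps = gene_peptides[g]
            gene_arr[i] = g
            pep_arr[i] = peps[rng.integers(len(peps))]
            accs = gene_accessions[g]
            acc_arr[i] = accs[rng.integers(len(accs))]
        for i in np.nonzero(~is_gene)[0]:
            pep, g, _ = excl[slot[i] - len(genes)]
            gene_arr[i] = g
            pep_arr[i] = pep
            acc_arr[i] = (gene_accessions.get(g) or [f"NP_X_{g}"])[0]

        mu = np.full(n_spec, config.intensity_mean)
        for gene, (sc, delta) in config.shifted_genes.items():
            if sc == cond:
                mu[gene_arr == gene] += delta
        log10_int = _truncated_normal(rng, mu, config.intensity_sd,
                                      config.intensity_floor)

        charge = rng.choice([2, 3], size=n_spec, p=[0.7, 0.3])
        styp = rng.random(n_spec) < config.styp_fraction
        score = rng.normal(config.score_mean, config.score_sd, size=n_spec)
        sid = np.array([f"S{spectrum_counter + i:09d}" for i in range(n_spec)])
        spectrum_counter += n_spec

        df = pd.DataFrame({
            "spectrum_id": sid,
            "condition": cond,
            "search_type": np.where(styp, "STYP", "TRYP"),
            "patient_id": np.array([f"{cond}_p{p + 1:02d}" for p in pat]),
            "fraction": frac.astype(np.int64),
            "peptide_sequence": pep_arr,
            "charge": charge.astype(np.int64),
            "score": score,
            "precursor_intensity": 10.0 ** log10_int,
            "accession": acc_arr,
            "gene_symbol": gene_arr,
            "modifications": "",
        })

        extra_mask = rng.random(n_spec) < config.redundancy_prob
        if extra_mask.any():
            extra = df[extra_mask].copy()
            gap = rng.exponential(config.score_gap_scale, size=len(extra)) + 1e-6
            extra["score"] = extra["score"].to_numpy() - gap
            flip = rng.random(len(extra)) < 0.5
            extra["charge"] = np.where(flip, 5 - extra["charge"].to_numpy(),
                                       extra["charge"].to_numpy())
            # non-flipped decoys get a different peptide from a random gene
            # drawn from this condition's detectable set
            detectable = genes[rates > 0]
            others = rng.choice(detectable, size=len(extra))
            pep2 = np.array([gene_peptides[g][rng.integers(len(gene_peptides[g]))]
                             for g in others], dtype=object)
            keep_pep = extra["peptide_sequence"].to_numpy(dtype=object)
            extra["peptide_sequence"] = np.where(flip, keep_pep, pep2)
            extra["gene_symbol"] = np.where(flip, extra["gene_symbol"], others)
            df = pd.concat([df, extra], ignore_index=True)
        frames.append(df)

    candidates = (pd.concat(frames, ignore_index=True) if frames
                  else pd.DataFrame())
    rate_df = pd.DataFrame(rate_rows, index=genes)
    rate_df = rate_df / rate_df.sum(axis=0)
    truth = TruthTable(
        gene_rates=rate_df,
        enriched_genes=dict(config.enriched_genes),
        shifted_genes=dict(config.shifted_genes),
        exclusive_peptides=list(config.exclusive_peptides),
        spectra_per_condition=pd.Series(totals, name="spectra"),
    )
    return candidates, truth


def null_cohort(config: SimConfig) -> tuple[pd.DataFrame, TruthTable]:
    """Same generator with every planted effect removed (calibration runs)."""
    cfg = replace(config, enriched_genes={}, shifted_genes={},
                  exclusive_peptides=[])
    return generate_cohort(cfg)


# ---------------------------------------------------------------------------
# recovery metrics

def enrichment_ranks(chi2_table: pd.DataFrame, truth: TruthTable) -> pd.Series:
    """1-based rank of each truly enriched gene in the chi2 ordering."""
    order = (chi2_table.sort_values("chi2", ascending=False, kind="mergesort")
             ["entity"].tolist())
    pos = {e: i + 1 for i, e in enumerate(order)}
    return pd.Series({g: pos.get(g, np.nan) for g in truth.enriched_genes},
                     dtype=float)


def exclusive_recovery(exclusivity: pd.DataFrame, truth: TruthTable) -> dict:
    """Recall/precision of the exclusivity screen against planted peptides."""
    planted = {(p, c) for p, _, c, _ in truth.exclusive_peptides}
    called = set()
    if len(exclusivity):
        hits = exclusivity[exclusivity["exclusive"]]
        called = set(zip(hits["peptide_sequence"], hits["target"]))
    tp = len(planted & called)
    recall = tp / len(planted) if planted else np.nan
    precision = tp / len(called) if called else (1.0 if not planted else 0.0)
    return {"n_planted": len(planted), "n_called": len(called),
            "true_positives": tp, "recall": recall, "precision": precision}


def letters_separated(letters: dict, target, controls) -> bool:
    """True when the target group shares no Tukey letter with any control."""
    t = set(letters.get(target, ""))
    return bool(t) and all(not (t & set(letters.get(c, ""))) for c in controls)


def recovery_report(truth: TruthTable, chi2_table: pd.DataFrame | None = None,
                    exclusivity: pd.DataFrame | None = None,
                    shifted_letters: dict | None = None,
                    top_k: int = 20) -> dict:
    """Collect recovery metrics for whatever pipeline outputs are provided.

    ``shifted_letters`` maps gene -> bool (Tukey letters of the shifted
    condition disjoint from all controls), as computed by the caller from an
    :class:`~pepdiff.intensity.IntensityAnova` fit. With no planted effects
    the report is empty.
    """
    report: dict = {}
    if chi2_table is not None and truth.enriched_genes:
        ranks = enrichment_ranks(chi2_table, truth)
        report["enriched_gene_ranks"] = ranks.to_dict()
        report["enriched_in_top_k"] = int((ranks <= top_k).sum())
        report["top_k"] = top_k
    if exclusivity is not None and truth.exclusive_peptides:
        report["exclusive"] = exclusive_recovery(exclusivity, truth)
    if shifted_letters is not None and truth.shifted_genes:
        report["shifted_gene_separated"] = dict(shifted_letters)
    return report
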
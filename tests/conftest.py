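import numpy as np
import pandas as pd
import pytest

from pepdiff.psm import COLUMNS
from pepdiff.simulate import SimConfig, default_gene_panel, generate_cohort


def make_candidates(rows):
    """Build a candidate table from dicts, filling unset columns with defaults."""
    defaults = {
        "spectrum_id": "S0", "condition": "breast_cancer", "search_type": "TRYP",
        "patient_id": "p01", "fraction": 1, "peptide_sequence": "PEPTIDEK",
        "charge": 2, "score": 1.0, "precursor_intensity": 2.0e4,
        "accession": "NP_000001.1", "gene_symbol": "GENE0001",
        "modifications": "",
    }
    if not rows:
        return pd.DataFrame(columns=list(COLUMNS))
    out = pd.DataFrame([{**defaults, **r} for r in rows])
    return out[list(COLUMNS)]


def random_candidates(rng, n_rows, n_spectra):
    """Random but valid candidate table with redundant spectra."""
    sid = rng.integers(0, n_spectra, size=n_rows)
    genes = [f"GENE{i:04d}" for i in range(1, 21)]
    peps = [f"PEP{i:03d}K" for i in range(40)]
    return make_candidates([
        {
            "spectrum_id": f"S{g:05d}",
            "condition": rng.choice(["breast_cancer", "ovarian_cancer"]),
            "search_type": rng.choice(["TRYP", "STYP"]),
            "patient_id": f"p{rng.integers(1, 10):02d}",
            "fraction": int(rng.integers(1, 11)),
            "peptide_sequence": peps[rng.integers(len(peps))],
            "charge": int(rng.choice([2, 3])),
            "score": float(np.round(rng.normal(3, 1), 6)),
            "precursor_intensity": float(10 ** rng.uniform(3.5, 7)),
            "accession": f"NP_{rng.integers(1, 30):06d}.1",
            "gene_symbol": genes[rng.integers(len(genes))],
        }
        for g in sid
    ])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Two-condition cohort with planted enrichment, reused across tests."""
    cfg = SimConfig(
        conditions={"breast_cancer": 9, "ovarian_cancer": 9},
        gene_panel=default_gene_panel(n_genes=50),
        spectra_per_fraction_mean=25,
        enriched_genes={"GENE0001": ("breast_cancer", 8.0)},
        seed=77,
    )
    candidates, truth = generate_cohort(cfg)
    return cfg, candidates, truth
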
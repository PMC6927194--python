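"""Candidate peptide-spectrum matches: tabular I/O and the two core filters.

A *candidate match* is one proposed correlation of one MS/MS spectrum to one
peptide sequence at one charge state, with a search score and the precursor ion
intensity. Search engines emit several candidates per spectrum (different
charge states or sequences); re-using a spectrum for more than one count would
inflate observation frequencies, so counting is always preceded by

1. an intensity floor (default: precursor >= 1e4 arbitrary counts), and
2. a best-hit collapse retaining exactly one candidate per spectrum.

The canonical on-disk form is a UTF-8 tab-separated table with a header row.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .treatments import SEARCH_TYPES

logger = logging.getLogger(__name__)

#: Canonical column order of the candidate table.
COLUMNS: tuple[str, ...] = (
    "spectrum_id",
    "condition",
    "search_type",
    "patient_id",
    "fraction",
    "peptide_sequence",
    "charge",
    "score",
    "precursor_intensity",
    "accession",
    "gene_symbol",
    "modifications",
)

_STRING_COLS = ("spectrum_id", "condition", "search_type", "patient_id",
                "peptide_sequence", "accession", "gene_symbol", "modifications")
_INT_COLS = ("fraction", "charge")
_FLOAT_COLS = ("score", "precursor_intensity")

#: Columns that must be present (``modifications`` is optional free text).
REQUIRED_COLUMNS = tuple(c for c in COLUMNS if c != "modifications")

#: Charge states accepted by the search configuration.
VALID_CHARGES = (2, 3)

#: Default precursor-intensity inclusion floor in arbitrary counts.
DEFAULT_MIN_INTENSITY = 10_000.0


class MissingColumnError(ValueError):
    """A required column cannot be resolved in the input header."""


def _empty_frame() -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in COLUMNS})
    for c in _INT_COLS:
        df[c] = df[c].astype(np.int64)
    for c in _FLOAT_COLS:
        df[c] = df[c].astype(float)
    return df


def validate_candidates(df: pd.DataFrame) -> None:
    """Raise ``ValueError`` on violation of the candidate-table invariants."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise MissingColumnError(f"missing required column(s): {missing}")
    if len(df) == 0:
        return
    if not df["charge"].isin(VALID_CHARGES).all():
        bad = sorted(set(df["charge"]) - set(VALID_CHARGES))
        raise ValueError(f"charge states outside {VALID_CHARGES}: {bad}")
    if not df["fraction"].between(1, 10).all():
        raise ValueError("fraction outside 1..10")
    if not (df["precursor_intensity"] > 0).all():
        raise ValueError("non-positive precursor intensity")
    if (df["peptide_sequence"].astype(str).str.len() == 0).any():
        raise ValueError("empty peptide sequence")
    if not df["search_type"].isin(SEARCH_TYPES).all():
        raise ValueError("unknown search_type value")


def read_candidates(path, dialect: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a tab-separated candidate table.

    Parameters
    ----------
    path : str or path-like
        File with a header row.
    dialect : mapping, optional
        Maps canonical column names to the names used in the file, to tolerate
        third-party exports (e.g. ``{"charge": "z"}``).

    Returns
    -------
    DataFrame with the canonical columns, original row order preserved. Rows
    whose numeric fields fail to parse, or that violate a row-level invariant,
    are dropped; their count and reasons are logged and recorded in
    ``df.attrs["n_rejected"]`` / ``df.attrs["rejections"]``.

    Raises
    ------
    MissingColumnError
        If a required column is absent after dialect remapping.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if dialect:
        rename = {v: k for k, v in dialect.items()}
        raw = raw.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise MissingColumnError(f"missing required column(s): {missing}")
    if "modifications" not in raw.columns:
        raw["modifications"] = ""
    raw = raw[list(COLUMNS)]

    rejections: list[tuple[int, str]] = []
    df = raw.copy()
    for col in _INT_COLS + _FLOAT_COLS:
        df[col] = pd.to_numeric(df[col], errors="coerce")

    bad_numeric = df[list(_INT_COLS + _FLOAT_COLS)].isna().any(axis=1)
    for i in df.index[bad_numeric]:
        rejections.append((int(i), "unparseable numeric field"))

    ok = ~bad_numeric
    checks = [
        (df["charge"].isin(VALID_CHARGES), "charge not in {2,3}"),
        (df["fraction"].between(1, 10), "fraction outside 1..10"),
        (df["precursor_intensity"] > 0, "non-positive precursor intensity"),
        (df["peptide_sequence"].str.len() > 0, "empty peptide sequence"),
        (df["search_type"].isin(SEARCH_TYPES), "unknown search_type"),
    ]
    for mask, reason in checks:
        newly_bad = ok & ~mask.fillna(False)
        for i in df.index[newly_bad]:
            rejections.append((int(i), reason))
        ok &= mask.fillna(False)

    out = df[ok].copy()
    for c in _INT_COLS:
        out[c] = out[c].astype(np.int64)
    for c in _FLOAT_COLS:
        out[c] = out[c].astype(float)
    out = out.reset_index(drop=True)
    if rejections:
        logger.warning("rejected %d of %d rows while reading %s",
                       len(rejections), len(raw), path)
        for i, reason in rejections:
            logger.debug("row %d rejected: %s", i, reason)
    out.attrs["n_rejected"] = len(rejections)
    out.attrs["rejections"] = rejections
    return out if len(out) else _empty_frame()


def write_candidates(df: pd.DataFrame, path) -> None:
    """Write the canonical tab-separated candidate table (lossless round-trip)."""
    out = df.copy()
    if "modifications" not in out.columns:
        out["modifications"] = ""
    out[list(COLUMNS)].to_csv(path, sep="\t", index=False)


def intensity_threshold(df: pd.DataFrame,
                        min_intensity: float = DEFAULT_MIN_INTENSITY) -> pd.DataFrame:
    """Keep candidates with ``precursor_intensity >= min_intensity`` (inclusive).

    The floor defaults to 1e4 arbitrary counts, the instrument-noise cutoff
    used for all counting statistics.
    """
    if min_intensity < 0:
        raise ValueError("min_intensity must be >= 0")
    return df[df["precursor_intensity"] >= min_intensity].reset_index(drop=True)


def best_hit_filter(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse redundant candidates to the single best fit per spectrum.

    Exactly one row per distinct ``spectrum_id`` survives: the highest score,
    with deterministic tie-breaks (lower charge, then lexicographically smaller
    peptide sequence, then smaller accession). The result is invariant to the
    input row order, so every downstream count is permutation-stable.
    """
    if len(df) == 0:
        return df.reset_index(drop=True)
    order = df.sort_values(
        by=["score", "charge", "peptide_sequence", "accession",
            "spectrum_id", "gene_symbol"],
        ascending=[False, True, True, True, True, True],
        kind="mergesort",
    )
    best = order.drop_duplicates(subset="spectrum_id", keep="first")
    return best.sort_values("spectrum_id", kind="mergesort").reset_index(drop=True)
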
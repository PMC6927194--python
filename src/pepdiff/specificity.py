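"""Treatment-exclusive peptides.

A peptide observed repeatedly in exactly one clinical condition and never in
any other — the pattern shown by the QSER1 peptide QPKVKAEPPPK, seen only in
ovarian cancer plasma — suggests condition-specific proteolysis. The screen
works on a peptide-level frequency table, pooling the TRYP/STYP channels of
each condition by default, and requires a minimum count in the target
condition so that a single spectrum cannot produce a call.
"""

from __future__ import annotations

import pandas as pd

from .frequency import FrequencyTable


def peptide_exclusivity(freq: FrequencyTable, min_count: int = 3,
                        pool_search_types: bool = True,
                        gene_map: pd.Series | dict | None = None,
                        ignore_conditions: tuple = ()) -> pd.DataFrame:
    """Find peptides whose observations are confined to one condition.

    A peptide is *exclusive* to condition t when its count is >= ``min_count``
    in t and 0 in every other (non-ignored) condition. Raising ``min_count``
    can only shrink the exclusive set.

    Parameters
    ----------
    freq : FrequencyTable
        Must be at ``peptide_sequence`` level.
    min_count : int
        Support floor in the target condition.
    pool_search_types : bool
        Pool the two search channels of each condition (default). With
        ``False`` exclusivity is judged at the treatment (channel) level.
    gene_map : optional
        peptide -> gene symbol, carried into the report.
    ignore_conditions : tuple
        Conditions excluded from the "elsewhere" check (e.g. a matched
        control to pool with the target, or the ice-cold baseline).
    """
    if freq.level != "peptide_sequence":
        raise ValueError("exclusivity requires a peptide-level frequency table")
    if len(freq.counts) == 0:
        return pd.DataFrame(columns=["peptide_sequence", "gene_symbol",
                                     "target", "count_in_target",
                                     "count_elsewhere", "exclusive"])
    counts = freq.condition_counts() if pool_search_types else freq.counts
    counts = counts.drop(columns=[c for c in ignore_conditions
                                  if c in counts.columns])
    top = counts.idxmax(axis=1)
    in_target = counts.max(axis=1)
    elsewhere = counts.sum(axis=1) - in_target
    out = pd.DataFrame({
        "peptide_sequence": counts.index,
        "target": top.to_numpy(),
        "count_in_target": in_target.to_numpy(),
        "count_elsewhere": elsewhere.to_numpy(),
    })
    out["exclusive"] = (out["count_in_target"] >= min_count) & \
                       (out["count_elsewhere"] == 0)
    if gene_map is not None:
        gm = pd.Series(gene_map)
        out.insert(1, "gene_symbol", out["peptide_sequence"].map(gm))
    else:
        out.insert(1, "gene_symbol", "")
    return (out.sort_values(["exclusive", "count_in_target", "peptide_sequence"],
                            ascending=[False, False, True], kind="mergesort")
            .reset_index(drop=True))


def patient_support(psms: pd.DataFrame, peptide: str,
                    condition: str | None = None) -> int:
    """Distinct patients contributing observations of ``peptide``.

    Guards exclusivity calls against single-sample artifacts: a peptide seen
    five times in one patient has support 1.
    """
    sel = psms[psms["peptide_sequence"] == peptide]
    if condition is not None:
        sel = sel[sel["condition"] == condition]
    return int(sel["patient_id"].nunique())
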
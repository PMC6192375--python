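"""Bioactivity curation: record filtering, replicate aggregation, p-value
transform, activity class labels and the sorted-cyclic fivefold split.

The raw input emulates a ChEMBL-style activity export: one row per
measurement with columns ``compound_id, endpoint, relation, value, unit``.
Curation keeps only exact ("=") measurements reported in nM, aggregates
replicates by the median, converts to p-units (pKi / pIC50 = -log10 of the
molar value) and labels compounds active at 1 uM or better.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("compound_id", "endpoint", "relation", "value", "unit")
ENDPOINTS = ("Ki", "IC50")

#: curated table columns
CURATED_COLUMNS = ("compound_id", "endpoint", "value_nM", "p_value", "label", "fold")


def filter_records(rows: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep rows with unit nM, relation "=", a known endpoint and value > 0.

    Returns the surviving rows and a per-row rejection report with a reason
    column; a row failing several rules is reported once with the first
    violated rule (unit, relation, endpoint, value — in that order).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in rows.columns]
    if missing:
        raise ValueError(f"activity table missing required columns: {missing}")
    if len(rows) == 0:
        return rows.copy(), pd.DataFrame(columns=["row", "compound_id", "reason"])

    value = pd.to_numeric(rows["value"], errors="coerce")
    reasons = np.full(len(rows), "", dtype=object)
    bad_unit = rows["unit"].astype(str).str.strip() != "nM"
    bad_rel = rows["relation"].astype(str).str.strip() != "="
    bad_end = ~rows["endpoint"].astype(str).str.strip().isin(ENDPOINTS)
    bad_val = ~(value > 0)
    for mask, tag in [
        (bad_unit, "unit_not_nM"),
        (bad_rel, "relation_not_eq"),
        (bad_end, "unknown_endpoint"),
        (bad_val, "non_positive_value"),
    ]:
        reasons[np.asarray(mask) & (reasons == "")] = tag
    keep = reasons == ""
    kept = rows.loc[keep].copy()
    kept["value"] = value[keep]
    report = pd.DataFrame(
        {
            "row": np.flatnonzero(~keep),
            "compound_id": rows.loc[~keep, "compound_id"].to_numpy(),
            "reason": reasons[~keep],
        }
    )
    return kept, report


def aggregate_replicates(records: pd.DataFrame) -> pd.Series:
    """Median activity in nM per compound (single values pass through).

    All records must share one endpoint; the median of an even number of
    replicates is the mean of the two central values.
    """
    if records["endpoint"].nunique() > 1:
        raise ValueError("records mix endpoints; aggregate one endpoint at a time")
    return records.groupby("compound_id", sort=True)["value"].median()


def to_p_value(value_nM):
    """p-value = -log10(value in M) for values given in nM."""
    value_nM = np.asarray(value_nM, dtype=float)
    if np.any(~(value_nM > 0)):
        raise ValueError("activity values must be positive to take -log10")
    return -np.log10(value_nM * 1e-9)


def label_class(p_value, threshold_uM: float = 1.0, boundary_active: bool = True):
    """Active/inactive label from a p-value at a molar concentration threshold.

    At the default 1 uM threshold a compound is active iff p >= 6.0; the
    boundary compound counts as active (configurable).
    """
    p_value = np.asarray(p_value, dtype=float)
    cut = -np.log10(threshold_uM * 1e-6)
    active = p_value >= cut if boundary_active else p_value > cut
    return np.where(active, "active", "inactive")


def fivefold_split(values_nM, compound_ids, n_folds: int = 5) -> np.ndarray:
    """Sorted-cyclic fold assignment, stratified across the activity range.

    Compounds are sorted ascending by activity value (ties broken by
    compound id, so the split is deterministic), then fold numbers 1..5 are
    dealt out cyclically down the sorted list. Fold sizes differ by at most
    one and every fold spans the whole value range by construction.
    """
    values_nM = np.asarray(values_nM, dtype=float)
    ids = np.asarray(compound_ids, dtype=object)
    if len(values_nM) < n_folds:
        raise ValueError(f"need at least {n_folds} compounds, got {len(values_nM)}")
    order = np.lexsort((ids, values_nM))
    folds = np.empty(len(values_nM), dtype=int)
    folds[order] = 1 + np.arange(len(values_nM)) % n_folds
    return folds


def curate(
    rows: pd.DataFrame,
    endpoint: str | None = None,
    threshold_uM: float = 1.0,
    boundary_active: bool = True,
    n_folds: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full curation: filter -> median-aggregate -> p-transform -> label -> split.

    Returns the curated per-compound table (CURATED_COLUMNS) plus the row
    rejection report. With `endpoint` None the table must contain a single
    endpoint.
    """
    kept, report = filter_records(rows)
    if endpoint is not None:
        kept = kept[kept["endpoint"] == endpoint]
    elif kept["endpoint"].nunique() > 1:
        raise ValueError("multiple endpoints present; pass endpoint=")
    if len(kept) == 0:
        empty = pd.DataFrame(columns=list(CURATED_COLUMNS))
        return empty, report
    endpoint = endpoint or kept["endpoint"].iloc[0]
    agg = aggregate_replicates(kept)
    p = to_p_value(agg.to_numpy())
    curated = pd.DataFrame(
        {
            "compound_id": agg.index.to_numpy(),
            "endpoint": endpoint,
            "value_nM": agg.to_numpy(),
            "p_value": p,
            "label": label_class(p, threshold_uM, boundary_active),
            "fold": fivefold_split(agg.to_numpy(), agg.index.to_numpy(), n_folds),
        }
    )
    return curated, report
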
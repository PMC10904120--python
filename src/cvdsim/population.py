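"""Population-level summaries: category means, direct standardization to a
reference population, and deprivation-gradient gaps."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .coefficients import ReferencePopulation
from .errors import ConfigError, PartitionError


def summarize_by_category(per_person: pd.DataFrame,
                          categories: Sequence[str],
                          metrics: Sequence[str] = ("life_years", "qalys"),
                          category_masks: dict = None) -> pd.DataFrame:
    """Mean outcomes per category with counts.

    `categories` are column names partitioning the cohort (groupby).
    Alternatively pass `category_masks` (name -> boolean mask); these are
    checked to be a partition: overlapping or non-covering masks raise.
    """
    for m in metrics:
        if m not in per_person.columns:
            raise ConfigError(f"metric column {m!r} not in results")
    if category_masks is not None:
        cover = np.zeros(len(per_person), dtype=int)
        for mask in category_masks.values():
            cover += np.asarray(mask, dtype=int)
        if (cover > 1).any():
            raise PartitionError("categories overlap: some person falls in "
                                 "more than one category")
        if (cover == 0).any():
            raise PartitionError("categories do not cover the cohort")
        rows = []
        for name, mask in category_masks.items():
            sub = per_person[np.asarray(mask, dtype=bool)]
            row = {"category": name, "n": len(sub)}
            for m in metrics:
                row[m] = float(sub[m].mean()) if len(sub) else float("nan")
            rows.append(row)
        return pd.DataFrame(rows)
    for col in categories:
        if col not in per_person.columns:
            raise ConfigError(f"category column {col!r} not in results")
    grouped = per_person.groupby(list(categories), observed=True)
    out = grouped[list(metrics)].mean()
    out["n"] = grouped.size()
    return out.reset_index()


def standardize(category_means: pd.DataFrame, reference: ReferencePopulation,
                metrics: Sequence[str] = ("life_years", "qalys"),
                margins: Optional[Sequence[str]] = None,
                missing_policy: str = "error") -> pd.DataFrame:
    """Directly standardize cell means to the reference weights.

    `category_means` must have columns sex, age_band, quintile plus the
    metric columns (one row per cell). `margins` selects which reference
    dimensions to keep (e.g. ["quintile"] averages over sex and age with
    reference weights); None collapses to a single overall row.
    A positive-weight reference cell with no estimate raises unless
    missing_policy='drop' (drop and renormalize).
    """
    if missing_policy not in ("error", "drop"):
        raise ConfigError("missing_policy must be 'error' or 'drop'")
    ref = reference.to_frame()
    ref["age_band"] = ref["age_band"].astype(str)
    cells = category_means.copy()
    if "quintile" not in cells.columns and "townsend_quintile" in cells.columns:
        cells = cells.rename(columns={"townsend_quintile": "quintile"})
    needed = {"sex", "age_band", "quintile"}
    if not needed.issubset(cells.columns):
        raise ConfigError(f"category means must have columns {sorted(needed)}")
    cells["age_band"] = cells["age_band"].astype(str)
    merged = ref.merge(cells, on=["sex", "age_band", "quintile"], how="left")
    missing = merged[merged[metrics[0]].isna() & (merged["weight"] > 0)]
    if len(missing):
        if missing_policy == "error":
            cells_str = [f"({r.sex},{r.age_band},{r.quintile})"
                         for r in missing.itertuples()]
            raise ConfigError(
                f"positive-weight reference cells without estimates: "
                f"{cells_str[:8]}{'...' if len(cells_str) > 8 else ''} "
                f"(use missing_policy='drop' to renormalize)")
        merged = merged[~merged[metrics[0]].isna()]
    group_cols = list(margins) if margins else []

    def weighted(df):
        w = df["weight"].to_numpy()
        total = w.sum()
        if total <= 0:
            return pd.Series({m: float("nan") for m in metrics})
        return pd.Series({m: float((df[m].to_numpy() * w).sum() / total)
                          for m in metrics})

    if group_cols:
        out = merged.groupby(group_cols, observed=True)[
            list(metrics) + ["weight"]].apply(weighted).reset_index()
    else:
        out = weighted(merged).to_frame().T
    return out


def gradient_gap(standardized_by_quintile: pd.DataFrame,
                 metrics: Sequence[str] = ("life_years", "qalys"),
                 by: Sequence[str] = ()) -> pd.DataFrame:
    """Least-minus-most-deprived gap: quintile 1 value - quintile 5 value.

    Input is standardized means with a `quintile` column (and optionally
    extra margin columns in `by`, e.g. sex and age band). All five
    quintiles must be present in every margin cell.
    """
    df = standardized_by_quintile
    if "quintile" not in df.columns:
        raise ConfigError("input must have a quintile column")
    groups = df.groupby(list(by), observed=True) if by else [((), df)]
    rows = []
    for key, g in groups:
        present = set(int(q) for q in g["quintile"])
        if present != {1, 2, 3, 4, 5}:
            raise ConfigError(f"all five quintiles required, found "
                              f"{sorted(present)} in {key!r}")
        q1 = g[g["quintile"] == 1].iloc[0]
        q5 = g[g["quintile"] == 5].iloc[0]
        row = dict(zip(by, key if isinstance(key, tuple) else (key,)))
        for m in metrics:
            row[f"{m}_gap"] = float(q1[m] - q5[m])
        rows.append(row)
    return pd.DataFrame(rows)
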
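"""Subset-by-tissue composition statistics.

Builds the observed subset x origin contingency table, the expected table
from its margins, Pearson residuals ``(O - E) / sqrt(E)`` and the
observed/expected ratio (tissue-preference score), plus per-sample immune
proportions within the non-epithelial compartment and group t-tests on them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from scatlas._errors import ValidationError
from scatlas.io_core import CellAnnotation


@dataclass
class ContingencyStats:
    observed: pd.DataFrame
    expected: pd.DataFrame
    pearson_residual: pd.DataFrame
    roe: pd.DataFrame
    chi2: float
    dof: int
    p_value: float


def contingency(
    annotation: CellAnnotation,
    subset_field: str = "subset",
    origin_field: str = "tissue_origin",
) -> ContingencyStats:
    """Chi-square statistics of the subset x origin cell-count table.

    Zero-margin rows/columns are dropped with a warning. Cells with
    ``E = 0`` cannot occur after that, so residual and ratio are defined
    everywhere.
    """
    observed = pd.crosstab(
        annotation.table[subset_field], annotation.table[origin_field]
    )
    zero_rows = observed.sum(axis=1) == 0
    zero_cols = observed.sum(axis=0) == 0
    if zero_rows.any() or zero_cols.any():
        warnings.warn("dropping zero-margin rows/columns", stacklevel=2)
        observed = observed.loc[~zero_rows, ~zero_cols]
    if observed.shape[0] < 2 or observed.shape[1] < 2:
        raise ValidationError("need >= 2 subsets and >= 2 origins")

    obs = observed.to_numpy(dtype=float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    expected = row @ col / total
    residual = (obs - expected) / np.sqrt(expected)
    roe_table = obs / expected
    chi2 = float((residual**2).sum())
    dof = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p_value = float(stats.chi2.sf(chi2, dof))

    wrap = lambda a: pd.DataFrame(a, index=observed.index, columns=observed.columns)
    return ContingencyStats(
        observed=observed,
        expected=wrap(expected),
        pearson_residual=wrap(residual),
        roe=wrap(roe_table),
        chi2=chi2,
        dof=dof,
        p_value=p_value,
    )


def roe(stats_: ContingencyStats) -> pd.DataFrame:
    """Observed/expected ratio table (> 1 means tissue preference)."""
    return stats_.roe


def immune_proportions(
    annotation: CellAnnotation,
    exclude_lineages: tuple[str, ...] = ("Epithelial",),
    subset_field: str = "subset",
) -> pd.DataFrame:
    """Per-sample subset fractions within the non-excluded compartment.

    ``exclude_lineages`` defaults to epithelial only; pass
    ``("Epithelial", "Fibroblast", "Endothelial")`` to also drop stroma.
    Samples with no qualifying cells are omitted with a warning. Fractions
    sum to 1 per retained sample.
    """
    table = annotation.table
    kept = table[~table["lineage"].isin(exclude_lineages)]
    dropped = set(table["sample_id"]) - set(kept["sample_id"])
    if dropped:
        warnings.warn(f"samples with no qualifying cells omitted: {sorted(dropped)}", stacklevel=2)
    counts = pd.crosstab(kept["sample_id"], kept[subset_field])
    return counts.div(counts.sum(axis=1), axis=0)


def group_comparison(
    fractions: pd.DataFrame,
    sample_groups: pd.Series,
    group_a: str,
    group_b: str,
) -> pd.DataFrame:
    """Two-sided Student's t-test per subset between two sample groups.

    ``sample_groups`` maps sample id -> group label (e.g. tissue origin).
    """
    groups = sample_groups.loc[fractions.index]
    a = fractions[groups == group_a]
    b = fractions[groups == group_b]
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each compared group needs >= 2 samples")
    t, p = stats.ttest_ind(a.to_numpy(), b.to_numpy(), axis=0, equal_var=True)
    return pd.DataFrame(
        {
            "subset": fractions.columns,
            "mean_a": a.mean(axis=0).to_numpy(),
            "mean_b": b.mean(axis=0).to_numpy(),
            "t": t,
            "p": p,
        }
    )


def export_table(stats_: ContingencyStats) -> pd.DataFrame:
    """Long-format table: subset, origin, observed, expected, residual, roe."""
    rows = []
    for subset in stats_.observed.index:
        for origin in stats_.observed.columns:
            rows.append(
                {
                    "subset": subset,
                    "origin": origin,
                    "observed": int(stats_.observed.loc[subset, origin]),
                    "expected": float(stats_.expected.loc[subset, origin]),
                    "residual": float(stats_.pearson_residual.loc[subset, origin]),
                    "roe": float(stats_.roe.loc[subset, origin]),
                }
            )
    return pd.DataFrame(rows)
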
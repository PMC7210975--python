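"""Threshold-based marker statistics, signature scoring and survival strata.

Marker selection between two cell groups applies four gates to each gene:
expressing-cell fraction above ``min_pct`` in at least one group (the tested
set), |log2 fold change| above a cutoff, equal-variance two-sided Student's
t-test p below ``max_p``, and Bonferroni-adjusted p (over the tested set)
below ``max_adj_p``. Log2 fold change is the difference of group means in
log2 space. Also provides the dispersion-based variable-gene selector, the
PC1 two-way stromal partition, percentile survival stratification with
10-year censoring, and the log-rank test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test
from scipy import stats

from scatlas._errors import ValidationError
from scatlas.io_core import CellAnnotation, ExpressionMatrix


@dataclass
class MarkerThresholds:
    min_abs_log2fc: float = 1.0
    max_p: float = 0.01
    max_adj_p: float = 0.01
    min_pct: float = 0.25
    direction: str = "up"  # "up": log2fc must exceed +cutoff; "both": |log2fc|

    def __post_init__(self) -> None:
        if self.direction not in ("up", "both"):
            raise ValidationError("direction must be 'up' or 'both'")
        for name in ("min_abs_log2fc", "max_p", "max_adj_p", "min_pct"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")


STAGE_COMPARISON_THRESHOLDS = MarkerThresholds(min_abs_log2fc=0.585, direction="both")


def percent_expressing(matrix: ExpressionMatrix, cells: Sequence[str]) -> pd.Series:
    """Fraction of the given cells with lognorm > 0, per gene."""
    cells = list(cells)
    if not cells:
        raise ValidationError("empty cell set")
    idx = matrix.cell_index(cells)
    sub = matrix.lognorm[idx] if matrix.lognorm is not None else None
    if sub is None:
        raise ValidationError("lognorm layer not computed")
    frac = np.asarray((sub > 0).sum(axis=0)).ravel() / len(cells)
    return pd.Series(frac, index=matrix.gene_ids, name="pct")


def log2_fold_change(
    matrix: ExpressionMatrix, group_a: Sequence[str], group_b: Sequence[str]
) -> pd.Series:
    """Difference of group mean lognorm values (already in log2 space)."""
    a, b = set(group_a), set(group_b)
    if not a or not b:
        raise ValidationError("both groups must be non-empty")
    if a & b:
        raise ValidationError("groups overlap")
    dense = matrix.lognorm_dense()
    mean_a = dense[matrix.cell_index(sorted(a))].mean(axis=0)
    mean_b = dense[matrix.cell_index(sorted(b))].mean(axis=0)
    return pd.Series(mean_a - mean_b, index=matrix.gene_ids, name="log2fc")


def differential_markers(
    matrix: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    thresholds: MarkerThresholds | None = None,
) -> pd.DataFrame:
    """Per-gene marker statistics between two disjoint cell groups.

    Only genes passing the expressing-fraction gate in at least one group are
    tested; Bonferroni uses the tested-set size. Genes with zero variance in
    both groups and equal means get ``p = 1`` and ``degenerate = True``.
    Returns a frame sorted by log2fc descending with columns
    ``gene, log2fc, p, adj_p, pct1, pct2, passed, tested, degenerate``.
    """
    thresholds = thresholds or MarkerThresholds()
    a, b = sorted(set(group_a)), sorted(set(group_b))
    if len(a) < 3 or len(b) < 3:
        raise ValidationError("each group needs >= 3 cells")
    if set(a) & set(b):
        raise ValidationError("groups overlap")

    dense = matrix.lognorm_dense()
    xa = dense[matrix.cell_index(a)]
    xb = dense[matrix.cell_index(b)]
    pct1 = (xa > 0).mean(axis=0)
    pct2 = (xb > 0).mean(axis=0)
    log2fc = xa.mean(axis=0) - xb.mean(axis=0)

    tested = (pct1 > thresholds.min_pct) | (pct2 > thresholds.min_pct)
    n_tested = int(tested.sum())

    p = np.ones(matrix.n_genes)
    degenerate = np.zeros(matrix.n_genes, dtype=bool)
    if n_tested:
        with np.errstate(invalid="ignore", divide="ignore"):
            _, p_tested = stats.ttest_ind(
                xa[:, tested], xb[:, tested], axis=0, equal_var=True
            )
        bad = ~np.isfinite(p_tested)
        p_tested = np.where(bad, 1.0, p_tested)
        p[tested] = p_tested
        degenerate[np.flatnonzero(tested)[bad]] = True

    adj_p = np.minimum(1.0, p * max(n_tested, 1))
    if thresholds.direction == "up":
        fc_ok = log2fc > thresholds.min_abs_log2fc
    else:
        fc_ok = np.abs(log2fc) > thresholds.min_abs_log2fc
    passed = tested & fc_ok & (p < thresholds.max_p) & (adj_p < thresholds.max_adj_p)

    frame = pd.DataFrame(
        {
            "gene": matrix.gene_ids,
            "log2fc": log2fc,
            "p": p,
            "adj_p": adj_p,
            "pct1": pct1,
            "pct2": pct2,
            "passed": passed,
            "tested": tested,
            "degenerate": degenerate,
        }
    )
    return frame.sort_values("log2fc", ascending=False, kind="stable").reset_index(drop=True)


def stage_comparison_markers(
    matrix: ExpressionMatrix, group_a: Sequence[str], group_b: Sequence[str]
) -> pd.DataFrame:
    """Marker selection for stage contrasts: |log2FC| > 0.585, both directions."""
    return differential_markers(matrix, group_a, group_b, STAGE_COMPARISON_THRESHOLDS)


def signature_score(
    matrix: ExpressionMatrix,
    gene_set: Sequence[str],
    cells: Sequence[str] | None = None,
) -> pd.Series:
    """Per-cell mean lognorm over the genes of the set present in the matrix."""
    present = [g for g in gene_set if g in set(matrix.gene_ids)]
    missing = sorted(set(gene_set) - set(present))
    if not present:
        raise ValidationError(f"no signature genes found in matrix; missing: {missing}")
    if missing:
        warnings.warn(f"signature genes absent from matrix: {missing}", stacklevel=2)
    dense = matrix.lognorm_dense()[:, matrix.gene_index(present)]
    scores = pd.Series(dense.mean(axis=1), index=matrix.cell_ids, name="score")
    if cells is not None:
        scores = scores.loc[list(cells)]
    return scores


def sample_signature_score(
    matrix: ExpressionMatrix, gene_set: Sequence[str], annotation: CellAnnotation
) -> pd.Series:
    """Per-sample mean of the per-cell signature score."""
    per_cell = signature_score(matrix, gene_set)
    samples = annotation.table.set_index("cell_id")["sample_id"]
    return per_cell.groupby(samples.loc[per_cell.index]).mean().rename("score")


def stratify_percentiles(
    scores: pd.Series, low_q: float = 0.25, high_q: float = 0.75
) -> pd.Series:
    """Label samples low (<= low quantile), high (>= high quantile) or excluded.

    Quantiles use linear (type-7) interpolation.
    """
    if len(scores) < 8:
        raise ValidationError("need >= 8 samples to stratify")
    if scores.nunique() == 1:
        raise ValidationError("all scores identical; stratification impossible")
    lo = float(np.quantile(scores.to_numpy(), low_q))
    hi = float(np.quantile(scores.to_numpy(), high_q))
    labels = pd.Series("excluded", index=scores.index, name="stratum")
    labels[scores <= lo] = "low"
    labels[scores >= hi] = "high"
    return labels


def censor_survival(
    times_days: pd.Series, events: pd.Series, censor_years: float = 10.0
) -> pd.DataFrame:
    """Cap follow-up at ``censor_years``; deaths beyond the cap become censored."""
    cap = censor_years * 365.25
    times = times_days.astype(float).clip(upper=cap)
    ev = events.astype(int).where(times_days.astype(float) <= cap, 0)
    return pd.DataFrame({"time_days": times, "event": ev})


def survival_logrank(
    table: pd.DataFrame,
    strata: pd.Series,
    censor_years: float = 10.0,
) -> float:
    """Two-sided log-rank p between the low and high strata.

    ``table`` carries ``time_days`` and ``event`` indexed by sample.
    """
    censored = censor_survival(table["time_days"], table["event"], censor_years)
    low = strata[strata == "low"].index
    high = strata[strata == "high"].index
    if len(low) == 0 or len(high) == 0:
        raise ValidationError("both strata must be non-empty")
    result = logrank_test(
        censored.loc[low, "time_days"],
        censored.loc[high, "time_days"],
        event_observed_A=censored.loc[low, "event"],
        event_observed_B=censored.loc[high, "event"],
    )
    return float(result.p_value)


def select_variable_genes(
    matrix: ExpressionMatrix,
    mean_range: tuple[float, float] = (0.0125, 3.0),
    min_dispersion_z: float = 0.5,
    n_bins: int = 20,
) -> list[str]:
    """Genes with mean lognorm inside ``mean_range`` (exclusive) and
    mean-binned dispersion z-score above ``min_dispersion_z``.

    Dispersion is variance/mean of lognorm; z-scores are computed within
    ``n_bins`` equal-width bins of the mean.
    """
    dense = matrix.lognorm_dense()
    means = dense.mean(axis=0)
    var = dense.var(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        dispersion = np.where(means > 0, var / np.maximum(means, 1e-300), 0.0)

    bins = pd.cut(means, bins=n_bins, labels=False)
    z = np.full(matrix.n_genes, -np.inf)
    for b in np.unique(bins[~np.isnan(bins)]):
        in_bin = bins == b
        d = dispersion[in_bin]
        sd = d.std()
        z[in_bin] = (d - d.mean()) / sd if sd > 0 else 0.0

    keep = (means > mean_range[0]) & (means < mean_range[1]) & (z > min_dispersion_z)
    return [g for g, k in zip(matrix.gene_ids, keep) if k]


def pc1_partition(
    matrix: ExpressionMatrix,
    markers_a: Sequence[str],
    markers_b: Sequence[str],
    variable_genes: Sequence[str] | None = None,
    marker_min: float = 1.0,
) -> pd.Series:
    """Split cells by the sign of PC1, labels gated by marker expression.

    PC1 of the per-gene-centered (variable-gene) matrix is oriented so cells
    with high ``markers_a`` expression score positive. A positive cell is
    labeled ``A`` only if its mean lognorm over ``markers_a`` exceeds
    ``marker_min`` (symmetrically for ``B``); otherwise ``undetermined``.
    """
    if matrix.n_cells < 2:
        raise ValidationError("need >= 2 cells")
    for name, ms in (("markers_a", markers_a), ("markers_b", markers_b)):
        if not set(ms) & set(matrix.gene_ids):
            raise ValidationError(f"{name} absent from matrix")
    genes = list(variable_genes) if variable_genes is not None else select_variable_genes(matrix)
    if not genes:
        raise ValidationError("no variable genes to compute PC1 on")
    dense = matrix.lognorm_dense()[:, matrix.gene_index(genes)]
    centered = dense - dense.mean(axis=0, keepdims=True)
    # PC1 scores via SVD of the centered matrix
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    pc1 = u[:, 0] * s[0]

    score_a = signature_score(matrix, list(markers_a))
    score_b = signature_score(matrix, list(markers_b))
    # orient: markers_a-high side positive
    orientation = np.corrcoef(pc1, score_a.to_numpy())[0, 1]
    if orientation < 0:
        pc1 = -pc1

    labels = pd.Series("undetermined", index=matrix.cell_ids, name="label")
    labels[(pc1 > 0) & (score_a > marker_min)] = "A"
    labels[(pc1 <= 0) & (score_b > marker_min)] = "B"
    return labels
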
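"""Malignancy calling from expression-inferred copy-number perturbation.

The procedure works on log-normalized expression of epithelial cells from a
tumor sample, diluted with normal-tissue cells so that putative malignant
cells stay a minority:

1. spike in normal reference cells until putative malignant cells are at most
   ``max_malignant_fraction`` of the mix,
2. drop genes expressed in fewer than ``min_cells_per_gene`` cells or with
   mean log2 expression below ``min_mean_expression``,
3. per-gene Z-score (population sd) clipped to ``±z_clip``,
4. moving average over ``window_size`` genes ordered by chromosome position,
   within chromosomes,
5. per-cell centering of the genome-wide window profile,
6. per-cell statistics: ``ms`` (mean squared window value) and ``corr``
   (Pearson correlation with the mean profile of the top
   ``top_reference_fraction`` of cells ranked by ``ms``); a cell is called
   malignant when ``ms > ms_threshold`` or ``corr > corr_threshold``
   (strict).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from scatlas._errors import ValidationError
from scatlas.io_core import CellAnnotation, ExpressionMatrix, GeneAnnotation

MIN_CELLS_FOR_SCORING = 20


@dataclass
class CnvParams:
    """Constants of the CNV-inference procedure."""

    max_malignant_fraction: float = 0.20
    min_cells_per_gene: int = 10
    min_mean_expression: float = 0.1
    z_clip: float = 3.0
    window_size: int = 100
    top_reference_fraction: float = 0.05
    ms_threshold: float = 0.02
    corr_threshold: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_size < 2:
            raise ValidationError("window_size must be >= 2")
        for name in ("max_malignant_fraction", "top_reference_fraction"):
            value = getattr(self, name)
            if not 0.0 < value < 1.0:
                raise ValidationError(f"{name} must be in (0, 1)")
        for name in ("min_mean_expression", "z_clip", "ms_threshold", "corr_threshold"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")


@dataclass
class CnvScore:
    """Per-cell CNV summary and malignancy call."""

    cell_id: str
    ms: float
    corr: float  # NaN when the cell's window profile has zero variance
    malignant: bool


def assemble_reference_mix(
    tumor_cells: Sequence[str],
    normal_pool: Sequence[str],
    params: CnvParams,
) -> set[str]:
    """Tumor cells plus enough seeded-sampled normals to dilute them.

    Adds ``ceil(n_tumor * (1/f - 1))`` normals (``f`` the maximum malignant
    fraction), sampled without replacement. An undersized pool is used in
    full with a warning.
    """
    tumor = set(map(str, tumor_cells))
    pool = set(map(str, normal_pool))
    if not tumor:
        raise ValidationError("tumor_cells is empty")
    if tumor & pool:
        raise ValidationError("tumor cells and normal pool overlap")
    f = params.max_malignant_fraction
    needed = math.ceil(len(tumor) * (1.0 / f - 1.0) - 1e-9)
    if needed >= len(pool):
        if len(pool) < needed:
            warnings.warn(
                f"normal pool ({len(pool)}) smaller than the {needed} cells needed "
                f"to dilute {len(tumor)} tumor cells below {f:.0%}",
                stacklevel=2,
            )
        return tumor | pool
    rng = np.random.default_rng(params.seed)
    sampled = rng.choice(sorted(pool), size=needed, replace=False)
    return tumor | set(sampled.tolist())


def cnv_gene_filter(matrix: ExpressionMatrix, params: CnvParams) -> ExpressionMatrix:
    """Keep genes expressed in >= ``min_cells_per_gene`` cells with mean
    lognorm >= ``min_mean_expression`` (both bounds non-strict)."""
    lognorm = matrix.lognorm_dense()
    expressing = (lognorm > 0).sum(axis=0)
    means = lognorm.mean(axis=0)
    keep = (expressing >= params.min_cells_per_gene) & (means >= params.min_mean_expression)
    return matrix.subset_genes(keep)


def zscore_clip(
    matrix: ExpressionMatrix, params: CnvParams
) -> tuple[np.ndarray, list[str]]:
    """Per-gene Z-score (population sd) clipped to ``±z_clip``.

    Zero-variance genes are dropped with a warning; returns the clipped
    matrix and surviving gene ids.
    """
    lognorm = matrix.lognorm_dense()
    means = lognorm.mean(axis=0)
    sds = lognorm.std(axis=0)  # population sd
    keep = sds > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance genes", stacklevel=2)
    z = (lognorm[:, keep] - means[keep]) / sds[keep]
    genes = [g for g, k in zip(matrix.gene_ids, keep) if k]
    return np.clip(z, -params.z_clip, params.z_clip), genes


def windowed_smooth(
    z: np.ndarray,
    gene_ids: Sequence[str],
    gene_annotation: GeneAnnotation,
    params: CnvParams,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Moving average of Z over chromosome-ordered gene windows.

    Genes are sorted by (chromosome, start). A chromosome with ``n`` genes
    contributes ``n - window_size + 1`` stride-1 windows when
    ``n >= window_size``; otherwise a single window over all its genes,
    flagged ``short=True``. Returns the cells-by-windows matrix and a table
    with the chromosome and flag of every window.
    """
    positions = gene_annotation.positions_for(list(gene_ids))
    order = np.lexsort((positions["start"].to_numpy(), positions["chromosome"].to_numpy()))
    z_sorted = z[:, order]
    chroms = positions["chromosome"].to_numpy()[order]

    blocks: list[np.ndarray] = []
    window_info: list[tuple[str, bool]] = []
    w = params.window_size
    for chrom in pd.unique(chroms):
        cols = np.flatnonzero(chroms == chrom)
        block = z_sorted[:, cols]
        n = block.shape[1]
        if n < w:
            blocks.append(block.mean(axis=1, keepdims=True))
            window_info.append((chrom, True))
            continue
        cumsum = np.cumsum(block, axis=1)
        sums = cumsum[:, w - 1 :].copy()
        sums[:, 1:] -= cumsum[:, : n - w]
        blocks.append(sums / w)
        window_info.extend((chrom, False) for _ in range(n - w + 1))
    windows = np.hstack(blocks)
    info = pd.DataFrame(window_info, columns=["chromosome", "short"])
    return windows, info


def center_cells(windows: np.ndarray) -> np.ndarray:
    """Subtract each cell's own mean from its window profile."""
    return windows - windows.mean(axis=1, keepdims=True)


def score_cells(
    windows: np.ndarray, cell_ids: Sequence[str], params: CnvParams
) -> list[CnvScore]:
    """Per-cell mean-squares and top-fraction reference correlation.

    The reference profile is the element-wise mean over the top
    ``ceil(top_reference_fraction * n)`` cells ranked by ``ms``. Cells whose
    centered profile (or the reference) has zero variance get ``corr = NaN``,
    which never satisfies the correlation threshold.
    """
    n_cells = windows.shape[0]
    if n_cells < MIN_CELLS_FOR_SCORING:
        raise ValidationError(
            f"need >= {MIN_CELLS_FOR_SCORING} cells to score (got {n_cells}); "
            "enlarge the reference mix"
        )
    ms = (windows**2).mean(axis=1)
    n_top = math.ceil(params.top_reference_fraction * n_cells - 1e-9)
    top = np.argsort(-ms, kind="stable")[:n_top]
    reference = windows[top].mean(axis=0)

    centered = windows - windows.mean(axis=1, keepdims=True)
    ref_centered = reference - reference.mean()
    ref_norm = np.sqrt((ref_centered**2).sum())
    cell_norms = np.sqrt((centered**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (centered @ ref_centered) / (cell_norms * ref_norm)
    corr[(cell_norms == 0) | (ref_norm == 0)] = np.nan

    scores = [
        CnvScore(cell_id=str(c), ms=float(m), corr=float(r), malignant=False)
        for c, m, r in zip(cell_ids, ms, corr)
    ]
    return classify_malignant(scores, params)


def classify_malignant(scores: list[CnvScore], params: CnvParams) -> list[CnvScore]:
    """Apply the strict ms/correlation thresholds to each score in place."""
    for s in scores:
        corr_hit = (not math.isnan(s.corr)) and s.corr > params.corr_threshold
        s.malignant = s.ms > params.ms_threshold or corr_hit
    return scores


def run_cnv_pipeline(
    matrix: ExpressionMatrix,
    gene_annotation: GeneAnnotation,
    params: CnvParams,
    tumor_cells: Sequence[str],
    normal_pool: Sequence[str] = (),
) -> pd.DataFrame:
    """Full chain: reference mix, gene filter, Z-clip, window, center, score.

    Returns one row per scored cell: ``cell_id, ms, corr, malignant,
    is_spike_in, n_windows``. Spike-in normals are scored but flagged so the
    malignancy tally can exclude them.
    """
    mix = assemble_reference_mix(tumor_cells, normal_pool, params) if normal_pool else set(
        map(str, tumor_cells)
    )
    sub = matrix.subset_cells(matrix.cell_index([c for c in matrix.cell_ids if c in mix]))
    sub = cnv_gene_filter(sub, params)
    z, genes = zscore_clip(sub, params)
    windows, _info = windowed_smooth(z, genes, gene_annotation, params)
    centered = center_cells(windows)
    scores = score_cells(centered, sub.cell_ids, params)
    tumor = set(map(str, tumor_cells))
    return pd.DataFrame(
        {
            "cell_id": [s.cell_id for s in scores],
            "ms": [s.ms for s in scores],
            "corr": [s.corr for s in scores],
            "malignant": [s.malignant for s in scores],
            "is_spike_in": [s.cell_id not in tumor for s in scores],
            "n_windows": windows.shape[1],
        }
    )
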
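"""Receptor-ligand cell-cell interaction inference with a permutation null.

For each (ligand, receptor) pair and ordered cluster pair (A -> B) the score
is the average of the ligand's mean lognorm in A and the receptor's mean
lognorm in B, defined only when both genes are expressed in more than
``min_pct`` of the corresponding cluster's cells. Significance comes from a
one-sided permutation test: cluster labels are shuffled ``n_perm`` times
(the same seeded permutation stream for every pair) and
``p = #(permuted score >= observed) / n_perm``; undefined observed scores
get ``p = 1``. Four filters then apply: no collagen genes, no
within-lineage cluster pairs, a 0.1% subset-size floor over the
immune+stromal compartment, and ``p < alpha``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from scatlas._errors import FormatError, ValidationError
from scatlas.io_core import CellAnnotation, ExpressionMatrix

COLLAGEN_PATTERN = re.compile(r"^COL\d", re.IGNORECASE)


@dataclass
class LrPair:
    pair_id: str
    ligand: str
    receptor: str
    annotation: str = ""


def load_lr_pairs(path: str | Path, gene_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Read a ligand-receptor pair table (TSV with ligand, receptor columns).

    Duplicate (ligand, receptor) rows are collapsed with a warning. When
    ``gene_ids`` is given, pairs whose genes are absent are kept but flagged
    ``usable = False``.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("ligand", "receptor"):
        if col not in frame.columns:
            raise FormatError(f"pair table missing column {col!r}")
    if frame.empty:
        raise FormatError("pair table is empty")
    if "pair_id" not in frame.columns:
        frame["pair_id"] = frame["ligand"] + "_" + frame["receptor"]
    before = len(frame)
    frame = frame.drop_duplicates(subset=["ligand", "receptor"]).reset_index(drop=True)
    if len(frame) < before:
        warnings.warn(f"dropped {before - len(frame)} duplicate pairs", stacklevel=2)
    if gene_ids is not None:
        known = set(gene_ids)
        frame["usable"] = frame["ligand"].isin(known) & frame["receptor"].isin(known)
    return frame


def interaction_score(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    ligand: str,
    receptor: str,
    cluster_a: str,
    cluster_b: str,
    min_pct: float = 0.25,
) -> float:
    """Mean-expression score for one pair and cluster pair; NaN when gated."""
    for cluster in (cluster_a, cluster_b):
        if cluster not in set(labels):
            raise ValidationError(f"unknown cluster {cluster!r}")
    dense = matrix.lognorm_dense()
    gi = matrix.gene_index([ligand, receptor])
    cells_a = matrix.cell_index(labels.index[labels == cluster_a])
    cells_b = matrix.cell_index(labels.index[labels == cluster_b])
    lig = dense[cells_a, gi[0]]
    rec = dense[cells_b, gi[1]]
    if (lig > 0).mean() <= min_pct or (rec > 0).mean() <= min_pct:
        return float("nan")
    return float((lig.mean() + rec.mean()) / 2.0)


def permutation_test(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    pairs: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    min_pct: float = 0.25,
    pseudocount: bool = False,
) -> pd.DataFrame:
    """Permutation p-values for every usable pair and ordered cluster pair.

    ``labels`` is indexed by cell id. Permuted scores ignore the
    expressing-fraction gate (the gate decides only whether the observed
    score is defined). With ``pseudocount`` the estimator is
    ``(k + 1)/(n + 1)`` instead of ``k/n``.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm = {n_perm} is low; p-values will be coarse", stacklevel=2)
    labels = labels.loc[list(matrix.cell_ids)]
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise ValidationError("need >= 2 clusters")

    known = set(matrix.gene_ids)
    usable = pairs[pairs["ligand"].isin(known) & pairs["receptor"].isin(known)]
    genes = sorted(set(usable["ligand"]) | set(usable["receptor"]))
    if not genes:
        raise ValidationError("no pair gene present in the matrix")
    dense = matrix.lognorm_dense()[:, matrix.gene_index(genes)]
    gene_pos = {g: i for i, g in enumerate(genes)}

    # cluster membership (k x cells), rows normalized to cluster means
    member = np.stack([(labels == c).to_numpy(float) for c in clusters])
    sizes = member.sum(axis=1, keepdims=True)
    weights = member / sizes

    obs_mean = weights @ dense  # k x g
    obs_pct = weights @ (dense > 0)  # k x g

    rng = np.random.default_rng(seed)
    perm_means = np.empty((n_perm, len(clusters), len(genes)))
    n_cells = dense.shape[0]
    for i in range(n_perm):
        perm = rng.permutation(n_cells)
        perm_means[i] = weights @ dense[perm]

    records = []
    ci = {c: i for i, c in enumerate(clusters)}
    for _, pair in usable.iterrows():
        li, ri = gene_pos[pair["ligand"]], gene_pos[pair["receptor"]]
        for a in clusters:
            for b in clusters:
                gated = obs_pct[ci[a], li] <= min_pct or obs_pct[ci[b], ri] <= min_pct
                score = float("nan") if gated else float(
                    (obs_mean[ci[a], li] + obs_mean[ci[b], ri]) / 2.0
                )
                if np.isnan(score):
                    p = 1.0
                else:
                    null = (perm_means[:, ci[a], li] + perm_means[:, ci[b], ri]) / 2.0
                    k = int((null >= score - 1e-12).sum())
                    p = (k + 1) / (n_perm + 1) if pseudocount else k / n_perm
                records.append(
                    {
                        "pair_id": pair["pair_id"],
                        "ligand": pair["ligand"],
                        "receptor": pair["receptor"],
                        "cluster_a": a,
                        "cluster_b": b,
                        "score": score,
                        "p": p,
                    }
                )
    return pd.DataFrame(records)


def filter_interactions(
    results: pd.DataFrame,
    annotation: CellAnnotation,
    min_subset_fraction: float = 0.001,
    alpha: float = 0.05,
    epithelial_lineages: tuple[str, ...] = ("Epithelial",),
    subset_field: str = "subset",
) -> pd.DataFrame:
    """Apply the four interaction filters.

    1. drop pairs where either gene symbol is a collagen (``^COL`` + digit),
    2. drop cluster pairs within one lineage (includes self-pairs),
    3. drop immune/stromal clusters below ``min_subset_fraction`` of the
       immune+stromal cell total (epithelial clusters are exempt),
    4. keep ``p < alpha``.
    """
    table = annotation.table
    lineage_of = table.drop_duplicates(subset_field).set_index(subset_field)["lineage"]
    needed = set(results["cluster_a"]) | set(results["cluster_b"])
    missing = needed - set(lineage_of.index)
    if missing:
        raise ValidationError(f"clusters without lineage annotation: {sorted(missing)}")

    out = results.copy()
    out = out[
        ~out["ligand"].str.match(COLLAGEN_PATTERN)
        & ~out["receptor"].str.match(COLLAGEN_PATTERN)
    ]
    out = out[
        lineage_of.loc[out["cluster_a"]].to_numpy()
        != lineage_of.loc[out["cluster_b"]].to_numpy()
    ]

    non_epi = table[~table["lineage"].isin(epithelial_lineages)]
    total = len(non_epi)
    subset_counts = non_epi[subset_field].value_counts()

    def big_enough(cluster: str) -> bool:
        if lineage_of.loc[cluster] in epithelial_lineages:
            return True
        return subset_counts.get(cluster, 0) / max(total, 1) > min_subset_fraction

    ok = out["cluster_a"].map(big_enough) & out["cluster_b"].map(big_enough)
    out = out[ok]
    out = out[out["p"] < alpha]
    return out.assign(significant=True).reset_index(drop=True)


def count_significant(results: pd.DataFrame) -> pd.DataFrame:
    """Clusters x clusters matrix of significant ligand->receptor pair counts."""
    if results.empty:
        return pd.DataFrame()
    return pd.crosstab(results["cluster_a"], results["cluster_b"])
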
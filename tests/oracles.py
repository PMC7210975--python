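"""Independent brute-force reference implementations used as test oracles.

Everything here is written with plain loops and textbook formulas, sharing
no code path with the package, so agreement is evidence of correctness.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def brute_force_cnv_scores(
    lognorm: np.ndarray,
    chromosomes: list[str],
    starts: list[int],
    window_size: int = 100,
    z_clip: float = 3.0,
    top_fraction: float = 0.05,
):
    """Naive re-implementation of the Z -> window -> center -> score chain.

    ``lognorm`` is cells x genes, already gene-filtered. Returns (ms, corr)
    arrays.
    """
    n_cells, n_genes = lognorm.shape

    # per-gene population z-score, clipped; drop zero-variance genes
    z_cols = []
    keep = []
    for g in range(n_genes):
        col = lognorm[:, g]
        mu = sum(col) / n_cells
        var = sum((x - mu) ** 2 for x in col) / n_cells
        if var == 0:
            continue
        sd = math.sqrt(var)
        z_cols.append([min(max((x - mu) / sd, -z_clip), z_clip) for x in col])
        keep.append(g)

    # sort retained genes by chromosome then start
    order = sorted(range(len(keep)), key=lambda i: (chromosomes[keep[i]], starts[keep[i]]))
    sorted_chroms = [chromosomes[keep[i]] for i in order]
    z = [[z_cols[i][c] for i in order] for c in range(n_cells)]

    # windows within chromosomes
    window_cols: list[list[float]] = []
    chrom_list = []
    for ch in dict.fromkeys(sorted_chroms):  # preserves first-appearance order
        idx = [j for j, c in enumerate(sorted_chroms) if c == ch]
        n = len(idx)
        if n < window_size:
            spans = [idx]
        else:
            spans = [idx[s : s + window_size] for s in range(n - window_size + 1)]
        for span in spans:
            window_cols.append([sum(z[c][j] for j in span) / len(span) for c in range(n_cells)])
            chrom_list.append(ch)

    # per-cell centering
    profiles = []
    n_windows = len(window_cols)
    for c in range(n_cells):
        vec = [window_cols[wi][c] for wi in range(n_windows)]
        mean = sum(vec) / n_windows
        profiles.append([v - mean for v in vec])

    ms = [sum(v * v for v in p) / n_windows for p in profiles]

    n_top = math.ceil(top_fraction * n_cells - 1e-9)
    ranked = sorted(range(n_cells), key=lambda c: -ms[c])
    top = ranked[:n_top]
    reference = [sum(profiles[c][wi] for c in top) / n_top for wi in range(n_windows)]

    ref_mean = sum(reference) / n_windows
    ref_c = [r - ref_mean for r in reference]
    ref_norm = math.sqrt(sum(r * r for r in ref_c))
    corr = []
    for p in profiles:
        p_mean = sum(p) / n_windows
        p_c = [v - p_mean for v in p]
        p_norm = math.sqrt(sum(v * v for v in p_c))
        if p_norm == 0 or ref_norm == 0:
            corr.append(float("nan"))
        else:
            corr.append(sum(a * b for a, b in zip(p_c, ref_c)) / (p_norm * ref_norm))
    return np.array(ms), np.array(corr)


def student_t_pvalue(a: np.ndarray, b: np.ndarray) -> float:
    """Textbook equal-variance two-sided Student's t-test."""
    from scipy.stats import t as t_dist

    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    sp = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    if sp == 0:
        return 1.0 if ma == mb else 0.0
    t = (ma - mb) / math.sqrt(sp * (1 / na + 1 / nb))
    return 2 * t_dist.sf(abs(t), na + nb - 2)


def naive_marker_table(xa: np.ndarray, xb: np.ndarray, min_pct: float = 0.25):
    """Per-gene loop version of the marker statistics (no thresholds applied).

    Returns list of dicts with log2fc, p, pct1, pct2, tested; Bonferroni over
    the tested set.
    """
    n_genes = xa.shape[1]
    rows = []
    for g in range(n_genes):
        a, b = xa[:, g], xb[:, g]
        pct1 = sum(v > 0 for v in a) / len(a)
        pct2 = sum(v > 0 for v in b) / len(b)
        tested = pct1 > min_pct or pct2 > min_pct
        rows.append(
            {
                "log2fc": sum(a) / len(a) - sum(b) / len(b),
                "p": student_t_pvalue(a, b) if tested else 1.0,
                "pct1": pct1,
                "pct2": pct2,
                "tested": tested,
            }
        )
    n_tested = sum(r["tested"] for r in rows)
    for r in rows:
        r["adj_p"] = min(1.0, r["p"] * max(n_tested, 1))
    return rows


def exact_permutation_p(
    expr_ligand: np.ndarray,
    expr_receptor: np.ndarray,
    labels: list[str],
    cluster_a: str,
    cluster_b: str,
) -> float:
    """Exact one-sided permutation p by enumerating all label assignments.

    Enumerates every distinct way of distributing the observed multiset of
    labels over the cells; p = fraction of assignments whose score is >= the
    observed score (the identity assignment counts itself in).
    """
    n = len(labels)
    idx_a = [i for i, l in enumerate(labels) if l == cluster_a]
    obs = _pair_score(expr_ligand, expr_receptor, labels, cluster_a, cluster_b)

    positions = list(range(n))
    n_a = labels.count(cluster_a)
    count = 0
    total = 0
    for chosen in combinations(positions, n_a):
        # two-cluster case: remaining cells take the other label
        perm = [cluster_b] * n
        for i in chosen:
            perm[i] = cluster_a
        score = _pair_score(expr_ligand, expr_receptor, perm, cluster_a, cluster_b)
        total += 1
        if score >= obs - 1e-12:
            count += 1
    return count / total


def _pair_score(lig, rec, labels, a, b):
    la = [lig[i] for i, l in enumerate(labels) if l == a]
    rb = [rec[i] for i, l in enumerate(labels) if l == b]
    return (sum(la) / len(la) + sum(rb) / len(rb)) / 2.0


def pairwise_jaccard_edges(term_sets: dict[str, set], threshold: float):
    """Exhaustive pairwise Jaccard enumeration over all unordered pairs."""
    edges = {}
    names = sorted(term_sets)
    for i, g1 in enumerate(names):
        for g2 in names[i + 1 :]:
            s1, s2 = term_sets[g1], term_sets[g2]
            union = s1 | s2
            j = len(s1 & s2) / len(union)
            if j > threshold:
                edges[(g1, g2)] = j
    return edges
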
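"""Selection of stably expressed reference genes.

Two complementary information-theoretic criteria identify candidate
normalizer genes from a multi-region expression matrix:

1. **Entropy flatness** — an expression vector (per-region means, or one
   region's per-subject values) is normalized into a discrete
   distribution; its Shannon entropy is maximal exactly when expression
   is uniform.  Well-expressed genes (>3 FPKM) whose normalized entropy
   approaches 1 have flat profiles.

2. **I-index reproducibility** — for each gene, random subsets of k
   subjects (k = 2..9) yield a regions x k contingency table of that
   gene's expression.  The I-index, an overlap measure built from the
   mutual information between the row and column variables of the table,

       I = 1 - MI(row; col) / min(H(row), H(col)),

   equals 1 exactly when the columns are linearly dependent (all
   subjects share one profile up to scale) and decreases as subjects
   disagree.  The minimum I-index over many resampled subsets is a
   robust per-gene reproducibility score.

The exact functional form of the I-index is a reconstruction from its
stated properties (positive, bounded by 1, maximal under linear
dependence of columns); see the methods document.
"""

from __future__ import annotations

import math
from itertools import combinations
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .models import ExpressionMatrix

_MI_TOL = 1e-10


class DegenerateColumnError(ValueError):
    """A contingency-table column with zero total has no defined overlap."""


class UndefinedEntropyError(ValueError):
    """An all-zero vector induces no distribution, hence no entropy."""


def shannon_entropy(vector: Sequence[float]) -> Tuple[float, float]:
    """Entropy (bits) and normalized entropy of a non-negative vector.

    The vector is normalized to a probability distribution p_i = x_i / sum(x);
    H = -sum p_i log2 p_i with 0*log 0 = 0, and normalized entropy
    H / log2(n) lies in [0, 1], reaching 1 only on the uniform vector.
    """
    x = np.asarray(vector, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("entropy requires a 1-d vector of length >= 2")
    if (x < 0).any():
        raise ValueError("entropy requires non-negative values")
    total = x.sum()
    if total == 0:
        raise UndefinedEntropyError("all-zero vector has undefined entropy")
    p = x / total
    nz = p[p > 0]
    h = float(-(nz * np.log2(nz)).sum())
    h = max(h, 0.0)
    return h, h / math.log2(x.size)


def flat_across_regions(
    matrix: ExpressionMatrix,
    min_fpkm: float = 3.0,
    entropy_threshold: float = 0.99,
) -> pd.DataFrame:
    """Rank well-expressed genes by entropy flatness of per-region means.

    A gene qualifies for ranking when its mean FPKM exceeds ``min_fpkm``
    (strictly) in *every* region; ``selected`` additionally requires the
    normalized entropy of its per-region mean vector to reach
    ``entropy_threshold``.  Rows are sorted by entropy, descending.
    """
    region_means = matrix.region_means()
    if region_means.shape[1] < 2:
        raise ValueError("at least two regions are required")
    expressed = (region_means > min_fpkm).all(axis=1)
    sub = region_means.loc[expressed]
    norm_h = pd.Series(
        [shannon_entropy(row)[1] for row in sub.to_numpy()],
        index=sub.index, name="norm_entropy",
    )
    out = pd.DataFrame(
        {
            "mean_fpkm": matrix.values.loc[sub.index].mean(axis=1),
            "norm_entropy": norm_h,
            "selected": norm_h >= entropy_threshold,
        }
    )
    return out.sort_values(
        ["norm_entropy", "mean_fpkm"], ascending=[False, False], kind="mergesort"
    )


def stable_within_region(
    matrix: ExpressionMatrix,
    region: str,
    min_fpkm: float = 3.0,
    entropy_threshold: float = 0.99,
) -> pd.DataFrame:
    """Entropy flatness of each gene's across-subject vector in one region."""
    mask = matrix.samples["region"] == region
    if not mask.any():
        raise KeyError(f"unknown region {region!r}")
    if mask.sum() < 2:
        raise ValueError(f"region {region!r} has fewer than two subjects")
    sub = matrix.values.loc[:, mask.to_numpy()]
    expressed = sub.mean(axis=1) > min_fpkm
    rows = sub.loc[expressed]
    norm_h = pd.Series(
        [
            shannon_entropy(r)[1] if r.sum() > 0 else 0.0
            for r in rows.to_numpy()
        ],
        index=rows.index, name="norm_entropy",
    )
    out = pd.DataFrame(
        {
            "mean_fpkm": rows.mean(axis=1),
            "norm_entropy": norm_h,
            "selected": norm_h >= entropy_threshold,
        }
    )
    return out.sort_values(
        ["norm_entropy", "mean_fpkm"], ascending=[False, False], kind="mergesort"
    )


def i_index(table, column_normalize: bool = True) -> float:
    """Mutual-information overlap index of a non-negative contingency table.

    ``table`` is an (r x k) array, r, k >= 2.  Cells are used as weights
    directly (continuous values allowed).  With ``column_normalize``
    (default) every column is first scaled to unit sum, so the index
    compares expression *patterns* and is exactly invariant to rescaling
    any column by a positive constant (a subject's sequencing depth must
    not affect overlap); the joint distribution is then
    p_ij = c_ij / (colsum_j * k).  Without it, p_ij = c_ij / N.  With MI
    the row-column mutual information and MI_max = min(H(row), H(col)),

        I = 1 - MI / MI_max  in [0, 1].

    Proportional (linearly dependent) columns give MI = 0 and hence
    I = 1 exactly; MI below 1e-10 bits is clamped to zero so that exact
    proportionality is not lost to floating-point rounding.
    """
    c = np.asarray(table, dtype=float)
    if c.ndim != 2 or c.shape[0] < 2 or c.shape[1] < 2:
        raise ValueError("contingency table must be 2-d with >=2 rows and columns")
    if (c < 0).any():
        raise ValueError("contingency table must be non-negative")
    col_tot = c.sum(axis=0)
    if (col_tot == 0).any():
        j = int(np.argmin(col_tot))
        raise DegenerateColumnError(f"column {j} of the table sums to zero")
    if column_normalize:
        c = c / col_tot
    n = c.sum()
    p = c / n
    pr = p.sum(axis=1)
    pc = p.sum(axis=0)
    mask = p > 0
    outer = np.outer(pr, pc)
    mi = float((p[mask] * np.log2(p[mask] / outer[mask])).sum())
    if mi < _MI_TOL:
        mi = 0.0
    h_row = float(-(pr[pr > 0] * np.log2(pr[pr > 0])).sum())
    h_col = float(-(pc[pc > 0] * np.log2(pc[pc > 0])).sum())
    mi_max = min(h_row, h_col)
    if mi_max <= _MI_TOL:
        # a point-mass marginal forces MI = 0: trivially maximal overlap
        return 1.0
    return float(np.clip(1.0 - mi / mi_max, 0.0, 1.0))


def _subject_subsets(
    subjects: List[str], k: int, m: int, rng: np.random.Generator
) -> List[Tuple[str, ...]]:
    """Up to m distinct subject subsets of size k, sampled without replacement."""
    n_choose_k = math.comb(len(subjects), k)
    if n_choose_k <= m:
        return list(combinations(subjects, k))
    picked: set = set()
    out = []
    while len(out) < m:
        idx = tuple(sorted(rng.choice(len(subjects), size=k, replace=False)))
        if idx in picked:
            continue
        picked.add(idx)
        out.append(tuple(subjects[i] for i in idx))
    return out


def reproducibility_resample(
    matrix: ExpressionMatrix,
    k_values: Iterable[int] = range(2, 10),
    m_per_k: Dict[int, int] | None = None,
    seed: int = 0,
    min_fpkm: float = 3.0,
) -> pd.DataFrame:
    """Per-gene minimum I-index over resampled subject subsets.

    For each gene and each subset of k subjects, the regions x k table of
    that gene's FPKM is scored with :func:`i_index`; the reported value
    is the minimum over all subsets and all k.  The number of subsets per
    k defaults to min(50, max(10, C(n_subjects, k))).  Genes whose mean
    FPKM does not exceed ``min_fpkm`` are excluded; subsets containing a
    subject with all-zero expression for a gene are skipped for that gene.
    Output is sorted by min I-index, descending.
    """
    subjects = matrix.subjects
    k_values = sorted(set(int(k) for k in k_values))
    if not k_values or k_values[0] < 2:
        raise ValueError("k values must be >= 2")
    if k_values[-1] > len(subjects) - 1:
        raise ValueError(
            f"k={k_values[-1]} requires at least {k_values[-1] + 1} subjects"
        )
    rng = np.random.default_rng(seed)
    subsets: List[Tuple[str, ...]] = []
    for k in k_values:
        m = (m_per_k or {}).get(k) or min(50, max(10, math.comb(len(subjects), k)))
        subsets.extend(_subject_subsets(subjects, k, m, rng))

    keep = matrix.values.mean(axis=1) > min_fpkm
    result = {}
    # per-gene regions x subjects pivot, built once
    for gid in matrix.values.index[keep]:
        pivot = matrix.region_values(gid)
        arr = pivot.to_numpy()
        col_of = {s: j for j, s in enumerate(pivot.columns)}
        best = np.inf
        for subset in subsets:
            tab = arr[:, [col_of[s] for s in subset]]
            if (tab.sum(axis=0) == 0).any():
                continue
            best = min(best, i_index(tab))
            if best == 0.0:
                break
        result[gid] = best if np.isfinite(best) else np.nan
    out = pd.DataFrame({"min_i_index": pd.Series(result)})
    out.index.name = "gene_id"
    return out.sort_values("min_i_index", ascending=False, kind="mergesort")


def stability_report(
    matrix: ExpressionMatrix,
    min_fpkm: float = 3.0,
    entropy_threshold: float = 0.99,
    k_values: Iterable[int] = range(2, 10),
    seed: int = 0,
    i_index_threshold: float | None = None,
) -> pd.DataFrame:
    """Combined per-gene stability report.

    Columns: mean FPKM, across-region normalized entropy, flatness flag,
    per-region stability flags, and the resampled minimum I-index with a
    reproducibility flag (threshold optional; ranking is always emitted
    so any cutoff choice stays transparent).
    """
    flat = flat_across_regions(matrix, min_fpkm, entropy_threshold)
    rep = reproducibility_resample(matrix, k_values=k_values, seed=seed,
                                   min_fpkm=min_fpkm)
    out = pd.DataFrame(index=matrix.values.index)
    out["mean_fpkm"] = matrix.values.mean(axis=1)
    out["norm_entropy"] = flat["norm_entropy"]
    out["flat_across_regions"] = flat["selected"].reindex(out.index, fill_value=False)
    for region in matrix.regions:
        sel = stable_within_region(matrix, region, min_fpkm, entropy_threshold)
        out[f"stable_in_{region}"] = sel["selected"].reindex(
            out.index, fill_value=False
        )
    out["min_i_index"] = rep["min_i_index"]
    if i_index_threshold is not None:
        out["reproducible"] = out["min_i_index"] >= i_index_threshold
    return out.sort_values(
        ["norm_entropy", "mean_fpkm"], ascending=[False, False],
        kind="mergesort", na_position="last",
    )
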
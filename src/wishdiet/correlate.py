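"""Spearman correlation analysis among component scores, sub-scores and total.

Reports the pairwise Spearman rank correlation (average-rank tie handling)
across the 13 component scores, the four sub-scores and the total score,
with two-sided p-values. Components that are constant across the population
(common here, since piecewise-linear scores pile up at 0 or 10) carry no
rank information and are excluded with a stated reason rather than
producing undefined coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .aggregate import ScoreResult

__all__ = ["CorrelationMatrix", "spearman_matrix"]


@dataclass
class CorrelationMatrix:
    labels: list[str]
    rho: pd.DataFrame
    pvalues: pd.DataFrame
    alpha: float
    excluded: list[dict[str, str]] = field(default_factory=list)

    def significant(self) -> pd.DataFrame:
        """Boolean mask of cells with p <= alpha (diagonal included)."""
        return self.pvalues <= self.alpha

    def to_csv(self, rho_path: str | Path, p_path: str | Path) -> None:
        self.rho.to_csv(rho_path)
        self.pvalues.to_csv(p_path)


def _scores_frame(results: Iterable[ScoreResult], leave_one_out: bool) -> pd.DataFrame:
    rows = []
    for r in results:
        row = dict(r.component_scores)
        row.update(
            healthy=r.healthy,
            less_healthy=r.less_healthy,
            low_env=r.low_env,
            high_env=r.high_env,
            total=r.total,
        )
        rows.append(row)
    df = pd.DataFrame(rows)
    if leave_one_out:
        # methodological variant: remove each component from the total before
        # correlating it, avoiding the part-whole artefact
        for cid in df.columns[:-5]:
            df[f"total_minus_{cid}"] = df["total"] - df[cid]
    return df


def _exact_permutation_p(x: np.ndarray, y: np.ndarray, observed: float) -> float:
    """Two-sided exact p over all permutations of one variable (tiny n only)."""
    from itertools import permutations

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    count = 0
    total = 0
    for perm in permutations(range(n)):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        if abs(r) >= abs(observed) - 1e-12:
            count += 1
        total += 1
    return count / total


def spearman_matrix(
    results: Iterable[ScoreResult],
    alpha: float = 0.05,
    constant_tol: float = 0.0,
    exact_p_max_n: int = 0,
    bh_correction: bool = False,
    leave_one_out: bool = False,
) -> CorrelationMatrix:
    """Pairwise Spearman correlations across scores, with exclusions.

    Parameters
    ----------
    results
        Scored subjects; at least 3 are required for a meaningful rank
        correlation.
    alpha
        Significance level used by :meth:`CorrelationMatrix.significant`.
    constant_tol
        A score column whose range is <= this tolerance is excluded as
        "constant score". The default 0 uses exact equality, appropriate
        because piecewise-linear scores are often exactly 0 or 10 for
        everyone.
    exact_p_max_n
        If n <= this bound, p-values are computed by full permutation
        enumeration instead of the t-distribution approximation.
    bh_correction
        Apply Benjamini-Hochberg FDR correction across the upper triangle.
    leave_one_out
        Additionally include, for each component, the total with that
        component removed.
    """
    df = _scores_frame(results, leave_one_out)
    n = len(df)
    if n < 3:
        raise ValueError(f"need at least 3 subjects for a correlation, got {n}")

    excluded: list[dict[str, str]] = []
    keep: list[str] = []
    for col in df.columns:
        vals = df[col].to_numpy()
        if float(vals.max() - vals.min()) <= constant_tol:
            excluded.append({"label": col, "reason": "constant score"})
        else:
            keep.append(col)
    if not keep:
        raise ValueError("all score columns are constant; no correlation can be made")

    data = df[keep]
    rho_arr, p_arr = stats.spearmanr(data.to_numpy(), axis=0)
    rho_arr = np.atleast_2d(rho_arr)
    p_arr = np.atleast_2d(p_arr)
    np.fill_diagonal(p_arr, 0.0)

    if exact_p_max_n and n <= exact_p_max_n:
        for i, j in combinations(range(len(keep)), 2):
            p = _exact_permutation_p(
                data.iloc[:, i].to_numpy(), data.iloc[:, j].to_numpy(), rho_arr[i, j]
            )
            p_arr[i, j] = p_arr[j, i] = p

    if bh_correction:
        iu = np.triu_indices(len(keep), k=1)
        flat = p_arr[iu]
        order = np.argsort(flat)
        m = len(flat)
        adj = np.empty(m)
        prev = 1.0
        for rank_pos in range(m - 1, -1, -1):
            idx = order[rank_pos]
            prev = min(prev, flat[idx] * m / (rank_pos + 1))
            adj[idx] = prev
        p_arr[iu] = adj
        p_arr[(iu[1], iu[0])] = adj

    rho = pd.DataFrame(rho_arr, index=keep, columns=keep)
    pvalues = pd.DataFrame(p_arr, index=keep, columns=keep)
    return CorrelationMatrix(labels=keep, rho=rho, pvalues=pvalues, alpha=alpha, excluded=excluded)


def plot_heatmap(matrix: CorrelationMatrix, path: str | Path) -> None:
    """Correlation heatmap; insignificant cells are crossed out."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    k = len(matrix.labels)
    fig, ax = plt.subplots(figsize=(0.5 * k + 2, 0.5 * k + 2))
    im = ax.imshow(matrix.rho.to_numpy(), vmin=-1, vmax=1, cmap="RdBu")
    sig = matrix.significant().to_numpy()
    for i in range(k):
        for j in range(k):
            if not sig[i, j]:
                ax.text(j, i, "x", ha="center", va="center", fontsize=8)
    ax.set_xticks(range(k), matrix.labels, rotation=90, fontsize=7)
    ax.set_yticks(range(k), matrix.labels, fontsize=7)
    fig.colorbar(im, ax=ax, label="Spearman rho")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
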
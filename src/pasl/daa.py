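"""Differential activation analysis on pathway activity scores.

Per-atom Welch two-sample t-statistics with permutation p-values: label
shuffles are shared across atoms (one shuffle evaluated on every column),
which is both faster and keeps the per-atom null distributions comparable.
The add-one estimator ``p = (1 + #{|t*| >= |t|}) / (B + 1)`` avoids p = 0;
an exact mode enumerates all distinct label assignments instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .model import ScoreMatrix


@dataclass
class DaaResult:
    """Sorted per-atom test results.

    ``table`` columns: atom, geneset, t, p, rank (and q when FDR was
    requested), sorted ascending by p with ties broken by |t| descending.
    """

    table: pd.DataFrame
    n_perm: int
    seed: int | None
    exact: bool = False


def _welch_t(scores: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Vectorized Welch t-statistic per column; mask selects group 1."""
    a = scores[mask]
    b = scores[~mask]
    na, nb = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1) / na
    vb = b.var(axis=0, ddof=1) / nb
    denom = np.sqrt(va + vb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=0) - b.mean(axis=0)) / denom
    return np.where(denom > 0, t, 0.0)


def _binary_mask(labels: np.ndarray) -> np.ndarray:
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"labels must have exactly 2 classes, got {classes.size}")
    mask = labels == classes[0]
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValueError("both classes need at least 2 samples")
    return mask


def differential_activation(
    L: ScoreMatrix,
    labels,
    n_perm: int = 10000,
    seed: int | None = None,
    exact: bool = False,
    fdr: bool = False,
) -> DaaResult:
    """Two-sided permutation t-tests on every score column.

    ``labels`` may be a sequence aligned with ``L.sample_ids`` or a pandas
    Series indexed by sample id. With ``exact=True`` all distinct
    assignments of samples to the two group sizes are enumerated and the
    p-value is the exact tail fraction (the identity assignment included);
    otherwise ``n_perm`` seeded shuffles feed the add-one estimator.
    """
    if isinstance(labels, pd.Series):
        labels = labels.reindex(L.sample_ids)
        if labels.isna().any():
            raise ValueError("labels missing for some samples in the score matrix")
        labels = labels.to_numpy()
    labels = np.asarray(labels)
    if labels.shape[0] != len(L.sample_ids):
        raise ValueError("labels length does not match the score matrix")
    mask = _binary_mask(labels)
    scores = L.values
    t_obs = _welch_t(scores, mask)
    abs_obs = np.abs(t_obs)

    n = mask.size
    n1 = int(mask.sum())
    if exact:
        exceed = np.zeros_like(abs_obs, dtype=int)
        count = 0
        for idx in combinations(range(n), n1):
            perm_mask = np.zeros(n, dtype=bool)
            perm_mask[list(idx)] = True
            exceed += np.abs(_welch_t(scores, perm_mask)) >= abs_obs
            count += 1
        p = exceed / count
        n_perm_used = count
    else:
        rng = np.random.default_rng(seed)
        exceed = np.zeros_like(abs_obs, dtype=int)
        for _ in range(n_perm):
            perm_mask = rng.permutation(mask)
            exceed += np.abs(_welch_t(scores, perm_mask)) >= abs_obs
        p = (1 + exceed) / (n_perm + 1)
        n_perm_used = n_perm

    table = pd.DataFrame(
        {
            "atom": L.atom_names,
            "t": t_obs,
            "p": p,
        }
    )
    table = table.sort_values(
        ["p", "t"], key=lambda c: -c.abs() if c.name == "t" else c
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    if fdr:
        table["q"] = _benjamini_hochberg(table["p"].to_numpy())
    return DaaResult(table=table, n_perm=n_perm_used, seed=seed, exact=exact)


def _benjamini_hochberg(p_sorted: np.ndarray) -> np.ndarray:
    """BH adjusted q-values for p-values already sorted ascending."""
    m = p_sorted.size
    q = p_sorted * m / np.arange(1, m + 1)
    return np.minimum.accumulate(q[::-1])[::-1]


def topk_overlap_curve(p_method_a: pd.Series, p_method_b: pd.Series) -> pd.DataFrame:
    """Count each method's findings among the pooled top-x genesets.

    Genesets from both rankings are pooled, ranked by their best (smallest)
    p-value across the two methods; for each cutoff ``x`` the curve reports
    how many of the pooled top-x each method identifies at least as
    significantly as the other (ties credit both). A method compared with
    itself therefore yields the diagonal y = x; methods with disjoint top
    lists yield curves summing to x.
    """
    if len(p_method_a) == 0 and len(p_method_b) == 0:
        return pd.DataFrame(columns=["x", "count_a", "count_b"])
    universe = sorted(set(p_method_a.index) | set(p_method_b.index))
    pa = p_method_a.reindex(universe).fillna(np.inf)
    pb = p_method_b.reindex(universe).fillna(np.inf)
    best = np.minimum(pa.to_numpy(), pb.to_numpy())
    order = np.lexsort((np.asarray(universe, dtype=object), best))
    a_wins = (pa.to_numpy() <= pb.to_numpy())[order]
    b_wins = (pb.to_numpy() <= pa.to_numpy())[order]
    return pd.DataFrame(
        {
            "x": np.arange(1, len(universe) + 1),
            "count_a": np.cumsum(a_wins),
            "count_b": np.cumsum(b_wins),
        }
    )
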
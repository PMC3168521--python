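"""Model selection over the (order, K) grid.

With a uniform prior over model structures, the posterior over models is
proportional to the marginal likelihood, so the model with the largest
variational lower bound L is selected; cross-validated predictive
log-likelihood on held-out bouts is reported alongside as an independent
check.  Per-bird grids are z-scored before averaging across birds so birds
with different bout lengths are commensurable.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .hmm import VBHyperparams, vb_fit
from .pomm import SongDataset

logger = logging.getLogger(__name__)

__all__ = ["grid_search", "select_best", "normalize_across_birds"]

GRID_COLUMNS = [
    "bird_id", "order", "n_states", "lower_bound",
    "predictive_loglik", "pred_ll_per_syllable", "seed", "converged", "error",
]


def grid_search(
    train: SongDataset,
    test: SongDataset | None,
    orders=(0, 1, 2),
    K_range=range(2, 17),
    hyper: VBHyperparams | None = None,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_restarts: int = 5,
    keep_fits: bool = False,
):
    """Fit every (order, K) cell with shared priors and restart policy.

    Returns a DataFrame with one row per cell (columns
    :data:`GRID_COLUMNS`); individual fit failures are recorded in the
    ``error`` column and the grid continues.  If ``keep_fits`` is true the
    fitted results objects are returned as a second value keyed by
    ``(order, K)``.
    """
    orders = sorted(set(int(r) for r in orders))
    Ks = sorted(set(int(k) for k in K_range))
    if not orders or not Ks:
        raise ValueError("orders and K_range must be non-empty")
    rows, fits = [], {}
    for cell_i, (r, K) in enumerate((r, K) for r in orders for K in Ks):
        cell_seed = seed + 1000 * cell_i
        row = {"bird_id": train.bird_id, "order": r, "n_states": K, "seed": cell_seed,
               "lower_bound": np.nan, "predictive_loglik": np.nan,
               "pred_ll_per_syllable": np.nan, "converged": False, "error": ""}
        try:
            res = vb_fit(train, r, K, hyper=hyper, seed=cell_seed, tol=tol,
                         max_iter=max_iter, n_restarts=n_restarts)
            row["lower_bound"] = res.lower_bound
            row["converged"] = res.converged
            if test is not None and len(test):
                pred = res.predictive_loglik(test)
                row["predictive_loglik"] = pred.total
                row["pred_ll_per_syllable"] = pred.per_syllable
            if keep_fits:
                fits[(r, K)] = res
        except Exception as exc:  # keep scanning the grid
            logger.warning("fit failed for order=%d K=%d: %s", r, K, exc)
            row["error"] = str(exc)
        rows.append(row)
    df = pd.DataFrame(rows, columns=GRID_COLUMNS)
    return (df, fits) if keep_fits else df


def select_best(grid: pd.DataFrame, metric: str = "lower_bound"):
    """(order, K) of the grid cell maximizing ``metric``.

    Ties are broken toward smaller K, then smaller order — the simpler
    model, consistent with the Occam preference the bound itself encodes.
    """
    if grid.empty:
        raise ValueError("grid is empty")
    ok = grid[np.isfinite(grid[metric])]
    if ok.empty:
        raise ValueError("no grid cell produced a finite score")
    ranked = ok.sort_values([metric, "n_states", "order"], ascending=[False, True, True],
                            kind="mergesort")
    top = ranked.iloc[0]
    return int(top["order"]), int(top["n_states"])


def normalize_across_birds(grids, metric: str = "lower_bound") -> pd.DataFrame:
    """Average per-cell curves across birds after per-bird z-scoring.

    Each bird's grid is z-scored over all its (order, K) cells, making the
    metric scale-free; the returned frame has per-cell ``mean`` and ``sd``
    across birds.  Birds whose grid is constant carry no ordering
    information and are excluded with a warning.
    """
    grids = list(grids)
    if len(grids) < 2:
        raise ValueError("need grids from at least two birds")
    shapes = {tuple(map(tuple, g[["order", "n_states"]].values)) for g in grids}
    if len(shapes) != 1:
        raise ValueError("all birds must share an identical (order, K) grid")
    normed = []
    for g in grids:
        vals = g[metric].to_numpy(dtype=float)
        sd = np.nanstd(vals)
        if not np.isfinite(sd) or sd == 0:
            logger.warning("bird %s has a degenerate (constant) grid; excluded",
                           g["bird_id"].iloc[0] if len(g) else "?")
            continue
        z = (vals - np.nanmean(vals)) / sd
        normed.append(g.assign(**{metric + "_z": z}))
    if not normed:
        raise ValueError("all bird grids were degenerate")
    allg = pd.concat(normed, ignore_index=True)
    out = (
        allg.groupby(["order", "n_states"])[metric + "_z"]
        .agg(mean="mean", sd=lambda x: float(np.std(x, ddof=0)))
        .reset_index()
    )
    return out
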
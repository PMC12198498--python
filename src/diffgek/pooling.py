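"""Pooling of per-cell spliced/unspliced values into fixed pseudotime bins.

Per-cell counts are too noisy to fit the kinetics ODE directly.  Cells of one
condition (and lineage) are therefore sorted by pseudotime and collapsed into
a fixed number of consecutive, equally sized pools (20 by default).  Each
pool contributes the arithmetic mean of its cells' unspliced values, spliced
values and pseudotimes; pool size is ``floor(N / n_pools)`` cells, and the
``N mod n_pools`` remainder cells are excluded (from the high-pseudotime end
by default).

Averaging over many cells per pool is also what justifies the Gaussian
likelihood used downstream in the fitting module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "N_POOLS",
    "InsufficientCellsError",
    "CellData",
    "GeneTimeCourse",
    "pool_cells",
    "courses_to_frame",
]

#: Default number of pseudotime pools per condition.
N_POOLS = 20


class InsufficientCellsError(ValueError):
    """Fewer cells than pools after lineage/condition filtering."""


@dataclass(frozen=True)
class CellData:
    """Per-cell values of one gene in one condition.

    ``lineage_mask`` (optional) marks the cells hard-assigned to the lineage
    under study; only those enter pooling.  ``sample`` is an optional
    replicate label carried through for samples-mode fitting.
    """

    u: np.ndarray
    s: np.ndarray
    pseudotime: np.ndarray
    condition: str = ""
    sample: str | None = None
    lineage_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        u = np.asarray(self.u, dtype=float)
        s = np.asarray(self.s, dtype=float)
        t = np.asarray(self.pseudotime, dtype=float)
        if not (u.shape == s.shape == t.shape) or u.ndim != 1:
            raise ValueError("u, s and pseudotime must be 1-D arrays of equal length")
        if np.any(~np.isfinite(t)):
            raise ValueError("pseudotime must be finite for all cells")
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "s", s)
        object.__setattr__(self, "pseudotime", t)
        if self.lineage_mask is not None:
            m = np.asarray(self.lineage_mask, dtype=bool)
            if m.shape != t.shape:
                raise ValueError("lineage_mask must match the cell vectors")
            object.__setattr__(self, "lineage_mask", m)

    @property
    def n_cells(self) -> int:
        if self.lineage_mask is not None:
            return int(self.lineage_mask.sum())
        return int(self.pseudotime.size)


@dataclass(frozen=True)
class GeneTimeCourse:
    """Pooled time course of one gene in one condition.

    ``pooled_times`` are non-decreasing pool-mean pseudotimes; ``u_obs`` and
    ``s_obs`` the pool-mean unspliced/spliced values; ``n_cells_per_pool``
    the (equal) number of cells averaged in each pool.
    """

    pooled_times: np.ndarray
    u_obs: np.ndarray
    s_obs: np.ndarray
    condition: str = ""
    sample: str | None = None
    n_cells_per_pool: int = 0
    layer: str | None = None  # provenance of the count layer pooled

    def __post_init__(self) -> None:
        t = np.asarray(self.pooled_times, dtype=float)
        u = np.asarray(self.u_obs, dtype=float)
        s = np.asarray(self.s_obs, dtype=float)
        if not (t.shape == u.shape == s.shape) or t.ndim != 1:
            raise ValueError("pooled arrays must be 1-D and of equal length")
        if np.any(np.diff(t) < -1e-12):
            raise ValueError("pooled_times must be non-decreasing")
        object.__setattr__(self, "pooled_times", t)
        object.__setattr__(self, "u_obs", u)
        object.__setattr__(self, "s_obs", s)

    @property
    def n_pools(self) -> int:
        return int(self.pooled_times.size)


def pool_cells(
    cells: CellData,
    n_pools: int = N_POOLS,
    drop: str = "high",
) -> GeneTimeCourse:
    """Collapse one condition's cells into ``n_pools`` pseudotime pools.

    Cells are sorted by pseudotime (stable sort, so ties keep input order),
    the first ``floor(N / n_pools) * n_pools`` of them are partitioned into
    ``n_pools`` consecutive blocks of equal size, and each block is averaged.

    Parameters
    ----------
    cells
        Per-cell values; if a ``lineage_mask`` is present only masked cells
        are pooled.
    n_pools
        Number of pools (20 by default).
    drop
        Where remainder cells are excluded: ``"high"`` drops them from the
        high-pseudotime end, ``"both"`` splits the exclusion between the two
        ends.

    Raises
    ------
    InsufficientCellsError
        If fewer than ``n_pools`` cells remain after filtering.
    """
    if n_pools < 1:
        raise ValueError("n_pools must be >= 1")
    if drop not in ("high", "both"):
        raise ValueError("drop must be 'high' or 'both'")

    u, s, t = cells.u, cells.s, cells.pseudotime
    if cells.lineage_mask is not None:
        u, s, t = u[cells.lineage_mask], s[cells.lineage_mask], t[cells.lineage_mask]

    n = t.size
    if n < n_pools:
        raise InsufficientCellsError(
            f"{n} cells < {n_pools} pools for condition "
            f"'{cells.condition}' (after lineage filtering)"
        )

    order = np.argsort(t, kind="stable")
    size = n // n_pools
    kept = size * n_pools
    if drop == "high":
        idx = order[:kept]
    else:
        lo = (n - kept) // 2
        idx = order[lo : lo + kept]

    shape = (n_pools, size)
    return GeneTimeCourse(
        pooled_times=t[idx].reshape(shape).mean(axis=1),
        u_obs=u[idx].reshape(shape).mean(axis=1),
        s_obs=s[idx].reshape(shape).mean(axis=1),
        condition=cells.condition,
        sample=cells.sample,
        n_cells_per_pool=size,
    )


def courses_to_frame(courses: dict, gene: str = "") -> pd.DataFrame:
    """Tidy table of pooled courses keyed by condition label."""
    rows = []
    for cond, course in courses.items():
        for i in range(course.n_pools):
            rows.append(
                {
                    "gene": gene,
                    "condition": cond,
                    "sample": course.sample,
                    "pool": i,
                    "pooled_time": course.pooled_times[i],
                    "u_obs": course.u_obs[i],
                    "s_obs": course.s_obs[i],
                    "n_cells": course.n_cells_per_pool,
                }
            )
    return pd.DataFrame(rows)
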
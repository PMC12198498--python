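"""End-to-end orchestration: pool, fit the eight models, select, report.

For every analysed gene the pipeline pools each condition's lineage cells
into 20 pseudotime bins, fits the eight rate-sharing models by penalized
maximum likelihood, ranks them by the weighted corrected Akaike index and
reports the per-rate differential-kinetics calls together with fitted rate
curves and per-rate log2 fold-change curves (second condition over first)
on a dense pseudotime grid.  Genes that fail are flagged and never abort
the batch; per-gene work is independent, so results do not depend on how
genes are partitioned into batches.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .core import RATE_MAX
from .fitting import FitResult, fit_gene
from .io import DatasetBundle
from .models import MODEL_ORDER, MODELS, RATES
from .pooling import CellData, GeneTimeCourse, pool_cells
from .selection import SelectionResult, select_model

__all__ = [
    "GeneReport",
    "normalize_pseudotime",
    "pool_bundle_gene",
    "log2fc_rates",
    "run_diffgek",
    "summary_table",
]


@dataclass
class GeneReport:
    """Full per-gene outcome: calls, curves and diagnostics."""

    gene: str
    selection: SelectionResult | None
    fits: dict[str, FitResult] = field(default_factory=dict)
    grid: np.ndarray | None = None
    #: rate -> condition -> curve on ``grid``
    rate_curves: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    #: rate -> log2(cond2 / cond1) curve on ``grid``
    log2fc: dict[str, np.ndarray] = field(default_factory=dict)
    error: str | None = None
    seconds: float = 0.0

    @property
    def failed(self) -> bool:
        return self.error is not None

    def to_dict(self) -> dict:
        out = {"gene": self.gene, "error": self.error, "seconds": self.seconds}
        if self.selection is not None:
            out["best_model"] = self.selection.best_name
            out["rate_calls"] = self.selection.rate_calls
            out["aicc"] = self.selection.aicc_per_model
            out["ssr"] = self.selection.ssr_per_model
        if self.grid is not None:
            out["grid"] = self.grid.tolist()
            out["rate_curves"] = {
                r: {c: v.tolist() for c, v in d.items()}
                for r, d in self.rate_curves.items()
            }
            out["log2fc"] = {r: v.tolist() for r, v in self.log2fc.items()}
        return out


def normalize_pseudotime(meta: pd.DataFrame) -> pd.DataFrame:
    """Min-max rescale pseudotime to [0, 1] over the lineage cells.

    Rescaling is done jointly over both conditions of the lineage so the
    two share one trajectory domain; rates are then "per unit of normalised
    pseudotime" and the box bound on them is transferable between datasets.
    """
    meta = meta.copy()
    mask = meta["lineage"].astype(bool).to_numpy()
    pt = pd.to_numeric(meta["pseudotime"], errors="coerce").to_numpy(dtype=float)
    lo = np.nanmin(pt[mask])
    hi = np.nanmax(pt[mask])
    if hi <= lo:
        raise ValueError("pseudotime is constant on the lineage; cannot normalise")
    meta["pseudotime"] = (pt - lo) / (hi - lo)
    return meta


def pool_bundle_gene(
    bundle: DatasetBundle,
    gene: str,
    config: PipelineConfig,
    conditions: tuple[str, ...],
):
    """Pooled course(s) per condition for one gene.

    In samples mode each (condition, sample) pair is pooled separately and
    the result maps condition -> list of replicate courses.
    """
    u, s = bundle.gene_vectors(gene)
    meta = bundle.cell_meta
    lineage = bundle.lineage_mask
    pt = pd.to_numeric(meta["pseudotime"], errors="coerce").to_numpy(dtype=float)
    cond_labels = meta["condition"].astype(str).to_numpy()
    out = {}
    for cond in conditions:
        mask = lineage & (cond_labels == cond)
        if config.samples_mode:
            if "sample" not in meta.columns:
                raise ValueError("samples mode requires a 'sample' metadata column")
            samples = pd.unique(meta.loc[mask, "sample"].astype(str))
            reps = []
            for smp in samples:
                m = mask & (meta["sample"].astype(str).to_numpy() == smp)
                cells = CellData(u[m], s[m], pt[m], condition=cond, sample=smp)
                reps.append(pool_cells(cells, config.n_pools, config.pool_drop))
            out[cond] = reps
        else:
            cells = CellData(u[mask], s[mask], pt[mask], condition=cond)
            out[cond] = pool_cells(cells, config.n_pools, config.pool_drop)
    return out


def log2fc_rates(
    curves: dict[str, dict[str, np.ndarray]],
    eps: float | None = None,
) -> dict[str, np.ndarray]:
    """Per-rate log2 fold-change curves (second condition over first).

    Both conditions' curves must share the grid; values are floored at
    ``eps`` (default: 1e-3 of the rate bound) before the ratio so a rate
    sitting on its zero bound cannot produce infinities.
    """
    eps = 1e-3 * RATE_MAX if eps is None else float(eps)
    out = {}
    for rate, per_cond in curves.items():
        conds = list(per_cond)
        if len(conds) != 2:
            raise ValueError("log2 fold changes need exactly two conditions")
        ref, alt = per_cond[conds[0]], per_cond[conds[1]]
        if ref.shape != alt.shape:
            raise ValueError("condition curves must share the evaluation grid")
        out[rate] = np.log2(np.maximum(alt, eps) / np.maximum(ref, eps))
    return out


def _report_curves(report: GeneReport, config: PipelineConfig) -> None:
    """Dense rate curves of the best model plus log2 fold changes."""
    sel = report.selection
    best_fit = report.fits[sel.best_name]
    params = best_fit.best_params
    grid = np.linspace(0.0, 1.0, config.dense_grid_size)
    curves: dict[str, dict[str, np.ndarray]] = {}
    for rate in RATES:
        curves[rate] = {
            cond: getattr(params.kinetics[cond], rate)(grid)
            for cond in params.conditions
        }
    report.grid = grid
    report.rate_curves = curves
    report.log2fc = log2fc_rates(curves, eps=config.log2fc_eps_frac * RATE_MAX)


def run_diffgek(
    bundle: DatasetBundle,
    config: PipelineConfig | None = None,
    genes: list[str] | None = None,
    progress: bool = False,
):
    """Run the full differential-kinetics analysis on a dataset bundle.

    Returns ``(reports, summary, manifest)``: one :class:`GeneReport` per
    analysed gene, a tidy per-gene summary table and a reproducibility
    manifest (config, seed, version, conditions, layer provenance).

    Raises
    ------
    ValueError
        If the lineage does not carry exactly two condition labels.
    """
    config = config or PipelineConfig()
    conditions = bundle.conditions
    if len(conditions) != 2:
        raise ValueError(
            f"two-condition comparison requires exactly 2 condition labels on "
            f"the lineage, found {list(conditions)}"
        )
    bundle = DatasetBundle(
        spliced=bundle.spliced,
        unspliced=bundle.unspliced,
        genes=bundle.genes,
        cells=bundle.cells,
        cell_meta=normalize_pseudotime(bundle.cell_meta),
        gene_list=bundle.gene_list,
        layer_name=bundle.layer_name,
    )
    genes = bundle.analysis_genes() if genes is None else list(genes)

    ss = np.random.SeedSequence(config.seed)
    reports = []
    for gi, gene in enumerate(genes):
        t0 = time.perf_counter()
        gene_ss = ss.spawn(1)[0]
        seeds = gene_ss.generate_state(len(MODEL_ORDER))
        try:
            courses = pool_bundle_gene(bundle, gene, config, conditions)
            fits = {}
            for mi, mname in enumerate(MODEL_ORDER):
                fits[mname] = fit_gene(
                    courses,
                    MODELS[mname],
                    seed=int(seeds[mi] % (2**31)),
                    config=config.fit,
                )
            sel = select_model(fits, courses, gene=gene, config=config.selection)
            report = GeneReport(gene=gene, selection=sel, fits=fits)
            _report_curves(report, config)
        except Exception as exc:
            report = GeneReport(gene=gene, selection=None, error=str(exc))
        report.seconds = time.perf_counter() - t0
        reports.append(report)
        if progress:
            status = report.selection.best_name if report.selection else "FAILED"
            print(f"[{gi + 1}/{len(genes)}] {gene}: {status} ({report.seconds:.1f}s)")

    summary = summary_table(reports)
    manifest = {
        "diffgek_version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "conditions": list(conditions),
        "layer": bundle.layer_name,
        "n_genes": len(genes),
        "n_failed": int(sum(r.failed for r in reports)),
    }
    return reports, summary, manifest


def summary_table(reports) -> pd.DataFrame:
    """One row per gene: best model, per-rate calls, AICc and SSR values."""
    rows = []
    for r in reports:
        if r.selection is None:
            rows.append({"gene": r.gene, "best_model": None, "error": r.error})
        else:
            rows.append({**r.selection.to_row(), "error": None})
    return pd.DataFrame(rows)
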
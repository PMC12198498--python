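"""Run configuration: fitting, selection and pipeline knobs.

All numerical settings of the method live here so that a run is fully
described by (data, config, seed).  Configs can be loaded from YAML and are
serialised into run manifests for reproducibility.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

__all__ = ["FitConfig", "SelectionConfig", "PipelineConfig", "load_config"]


@dataclass
class FitConfig:
    """Settings of the penalized-likelihood multi-start fit.

    rho
        Weight of the spline-wobbliness penalty (sum of squared successive
        node differences); 10 is the simulation-calibrated default.
    n_starts, n_polish, n_final, stage1_maxiter
        Multi-start schedule: all ``n_starts`` random within-bounds points
        are scored, the best ``n_polish`` get a short bounded L-BFGS-B run
        (``stage1_maxiter`` iterations), and the best ``n_final`` of those
        are optimized to convergence.
    maxiter, ftol, gtol
        Local-optimizer budget and convergence tolerances.
    msub
        Quadrature substeps per pooled-time interval of the fitting-internal
        forward model.
    rate_max
        Upper bound of every spline node (rates in [0, rate_max] per unit of
        normalised pseudotime).
    ic_lo, ic_hi
        Initial-condition bounds as fractions of the measured initial pooled
        value (10%..300%).
    sd_lo, sd_hi
        Error-term bounds: standard deviation as a fraction of the maximum
        of the corresponding pooled course (1%..10%).
    """

    rho: float = 10.0
    n_starts: int = 300
    n_polish: int = 10
    n_final: int = 3
    stage1_maxiter: int = 60
    maxiter: int = 600
    ftol: float = 1e-10
    gtol: float = 1e-6
    msub: int = 12
    rate_max: float = 6.7
    ic_lo: float = 0.10
    ic_hi: float = 3.00
    sd_lo: float = 0.01
    sd_hi: float = 0.10


@dataclass
class SelectionConfig:
    """Settings of AICc model ranking.

    mu
        SSR weight in the corrected Akaike index (0.01 is the
        simulation-calibrated default).
    mu_convention
        ``"divide"``: A = 2k + SSR/mu + corr (default); ``"multiply"``:
        A = 2k + SSR*mu + corr.
    n_override
        If set, forces the data count n in the AICc correction term instead
        of the number of pooled observations actually fit
        (conditions x species x pools).
    """

    mu: float = 0.01
    mu_convention: str = "divide"
    n_override: int | None = None

    def __post_init__(self) -> None:
        if self.mu_convention not in ("divide", "multiply"):
            raise ValueError("mu_convention must be 'divide' or 'multiply'")


@dataclass
class PipelineConfig:
    """End-to-end run settings (pooling + fitting + selection + reports)."""

    fit: FitConfig = field(default_factory=FitConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    n_pools: int = 20
    samples_mode: bool = False
    seed: int = 0
    dense_grid_size: int = 101
    #: epsilon floor for log2 fold changes, as a fraction of the rate bound
    log2fc_eps_frac: float = 1e-3
    #: which end remainder cells are dropped from during pooling
    pool_drop: str = "high"

    def to_dict(self) -> dict:
        return asdict(self)


def _from_dict(cls, data: dict):
    names = {f.name for f in fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


def load_config(path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML file.

    Top-level keys map to :class:`PipelineConfig` fields; ``fit`` and
    ``selection`` are nested mappings.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    fit = _from_dict(FitConfig, raw.pop("fit", {}) or {})
    sel = _from_dict(SelectionConfig, raw.pop("selection", {}) or {})
    cfg = _from_dict(PipelineConfig, {"fit": fit, "selection": sel, **raw})
    return cfg
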
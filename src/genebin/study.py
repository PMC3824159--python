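"""Replicate-level simulation study: empirical type-I error and power.

For a synthetic gene panel, each replicate draws a fresh trait vector
on fixed genotypes (optionally redrawing genotypes), runs all requested
statistics on the requested MAF analysis sets with causal columns
excluded, and records the p-values.  Rejection proportions at the
nominal level over N replicates estimate empirical type I error (null
models) or power (calibrated causal models).  Replicate RNG streams
are derived from (master seed, model, replicate index), so results do
not depend on evaluation order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from . import stats as gstats
from .binning import build_bins
from .data import GenotypeMatrix, Phenotype, partition_by_maf
from .regression import fit_joint, fit_marginals
from .simulate import (
    GenePanelSpec,
    HaplotypePool,
    TraitModelSpec,
    analysis_matrix,
    assign_causals,
    calibrate_sigma,
    generate_genotypes,
    generate_pool,
    generate_trait,
    ldselect_bins,
)

logger = logging.getLogger(__name__)

NULL_MODEL = 0  # pseudo model id: trait independent of genotype


@dataclass
class StudyConfig:
    """Configuration of one simulation study on a single gene panel."""

    panel: GenePanelSpec = field(default_factory=GenePanelSpec)
    n_individuals: int = 5000
    n_replicates: int = 1000
    alpha: float = 0.05
    analysis_sets: tuple[str, ...] = ("all", "common", "low_frequency")
    statistics: tuple[str, ...] = gstats.STATISTIC_NAMES
    model_ids: tuple[int, ...] = (1, 2, 3, 4, 5)
    seed: int = 0
    target_power: float = 0.8
    redraw_genotypes: bool = False
    mixture_method: str = "imhof"

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        unknown = set(self.statistics) - set(gstats.STATISTIC_NAMES)
        if unknown:
            raise ValueError(f"unknown statistics: {sorted(unknown)}")


@dataclass
class CellResult:
    """Aggregated outcome for one (model, analysis set, statistic)."""

    model_id: int
    analysis_set: str
    statistic: str
    n_rejections: int
    n_replicates: int
    sigma: float | None
    sigma_clamped: bool
    skipped: bool = False

    @property
    def rejection_rate(self) -> float:
        return self.n_rejections / self.n_replicates

    def binomial_ci(self, level: float = 0.95) -> tuple[float, float]:
        res = sps.binomtest(self.n_rejections, self.n_replicates)
        ci = res.proportion_ci(confidence_level=level, method="exact")
        return (ci.low, ci.high)


@dataclass
class StudyResult:
    cells: list[CellResult]
    seeds: dict = field(default_factory=dict)

    def rate(self, model_id: int, analysis_set: str, statistic: str) -> float:
        for c in self.cells:
            if (
                c.model_id == model_id
                and c.analysis_set == analysis_set
                and c.statistic == statistic
            ):
                return c.rejection_rate
        raise KeyError((model_id, analysis_set, statistic))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "model": c.model_id,
                    "analysis_set": c.analysis_set,
                    "statistic": c.statistic,
                    "rate": c.rejection_rate,
                    "ci_low": c.binomial_ci()[0],
                    "ci_high": c.binomial_ci()[1],
                    "n_replicates": c.n_replicates,
                    "sigma": c.sigma,
                    "sigma_clamped": c.sigma_clamped,
                    "skipped": c.skipped,
                }
                for c in self.cells
            ]
        )


class _SetContext:
    """Pre-processed state for one analysis set: binned, coding-
    corrected genotypes and the pieces each statistic reuses across
    replicates on fixed genotypes."""

    def __init__(self, gm: GenotypeMatrix, r2_threshold: float):
        self.gm, self.bins = build_bins(gm, r2_threshold)


def _prepare_sets(
    gm_analysis: GenotypeMatrix, analysis_sets, r2_threshold: float
) -> dict[str, "_SetContext | None"]:
    out: dict[str, _SetContext | None] = {}
    for s in analysis_sets:
        try:
            out[s] = _SetContext(partition_by_maf(gm_analysis, s), r2_threshold)
        except ValueError:
            logger.warning("analysis set '%s' is empty for this panel; skipped", s)
            out[s] = None
    return out


def _evaluate_statistics(
    ctx: _SetContext,
    ph: Phenotype,
    statistics,
    analysis_set: str,
    mixture_method: str = "imhof",
    minp_seed: int = 0,
) -> dict[str, float]:
    """All requested p-values for one analysis set and one trait draw."""
    gm = ctx.gm
    out: dict[str, float] = {}
    need_joint = {"wald", "mlc-b", "mlc-z", "lc-b", "lc-z", "minp-j"} & set(statistics)
    need_marg = {"ssb", "ssbw", "minp-m"} & set(statistics)
    jf = fit_joint(gm, ph) if need_joint else None
    mf = fit_marginals(gm, ph) if need_marg else None
    for name in statistics:
        if name == "wald":
            res = gstats.wald(jf, analysis_set)
        elif name in ("mlc-b", "mlc-z"):
            res = gstats.mlc(jf, ctx.bins, name[-1].upper(), analysis_set)
        elif name in ("lc-b", "lc-z"):
            res = gstats.lc(jf, name[-1].upper(), analysis_set)
        elif name == "minp-j":
            res = gstats.minp(jf, seed=minp_seed, analysis_set=analysis_set)
        elif name == "minp-m":
            res = gstats.minp(mf, seed=minp_seed, analysis_set=analysis_set)
        elif name == "pc80":
            res = gstats.pc80(gm, ph, analysis_set=analysis_set)
        elif name == "ssb":
            res = gstats.ssb(mf, weighted=False, analysis_set=analysis_set, method=mixture_method)
        elif name == "ssbw":
            res = gstats.ssb(mf, weighted=True, analysis_set=analysis_set, method=mixture_method)
        elif name == "skat":
            res = gstats.skat(gm, ph, analysis_set=analysis_set, method=mixture_method)
        elif name == "skat-c":
            lf = common = None
            lf_idx = [j for j, s in enumerate(gm.snps) if s.freq_class == "low_frequency"]
            c_idx = [j for j, s in enumerate(gm.snps) if s.freq_class == "common"]
            if lf_idx:
                lf = gm.subset_snps(lf_idx)
            if c_idx:
                common = gm.subset_snps(c_idx)
            res = gstats.skat_c(lf, common, ph, analysis_set=analysis_set, method=mixture_method)
        else:  # pragma: no cover - guarded by StudyConfig validation
            raise ValueError(name)
        out[name] = res.p_value
    return out


def _replicate_seed(master: int, model_id: int, replicate: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master, spawn_key=(model_id, replicate))
    )


def run_replicate(
    gm_full: GenotypeMatrix,
    tm: TraitModelSpec | None,
    cfg: StudyConfig,
    replicate_seed,
) -> dict[tuple[str, str], float]:
    """One trait draw and one full evaluation pass.

    ``tm`` is ``None`` for the null model (trait is pure standard
    normal noise).  Returns {(statistic, analysis_set): p-value};
    skipped (empty) analysis sets are absent from the map.
    """
    rng = (
        replicate_seed
        if isinstance(replicate_seed, np.random.Generator)
        else np.random.default_rng(replicate_seed)
    )
    if tm is None:
        ph = Phenotype(list(gm_full.samples), rng.standard_normal(gm_full.n_samples))
        gm_analysis = gm_full
    else:
        ph = generate_trait(gm_full, tm, rng)
        gm_analysis = analysis_matrix(gm_full, tm)
    contexts = _prepare_sets(gm_analysis, cfg.analysis_sets, cfg.panel.r2_threshold)
    out: dict[tuple[str, str], float] = {}
    for set_name, ctx in contexts.items():
        if ctx is None:
            continue
        pmap = _evaluate_statistics(
            ctx, ph, cfg.statistics, set_name, cfg.mixture_method,
            minp_seed=int(rng.integers(2**31)),
        )
        for stat, p in pmap.items():
            out[(stat, set_name)] = p
    return out


def run_study(cfg: StudyConfig, pool: HaplotypePool | None = None) -> StudyResult:
    """Run the full design: for each trait model, fresh genotypes,
    sigma calibration (causal models), N replicate trait draws, and
    rejection proportions at the nominal level.

    ``model_ids`` may include 0 for the null model (type-I error).
    Genotypes are fixed within a model's replicate batch unless
    ``cfg.redraw_genotypes`` is set.
    """
    if pool is None:
        pool = generate_pool(cfg.panel)
    pool_bins = ldselect_bins(pool.correlation_matrix(), cfg.panel.r2_threshold)
    cells: list[CellResult] = []
    seeds = {"master": cfg.seed, "panel": cfg.panel.seed}
    for model_id in cfg.model_ids:
        model_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=cfg.seed, spawn_key=(model_id,))
        )
        gm_full = generate_genotypes(pool, cfg.n_individuals, model_rng)
        if model_id == NULL_MODEL:
            tm = None
            sigma, clamped = None, False
        else:
            tm = assign_causals(pool, pool_bins, model_id, model_rng)
            tm = calibrate_sigma(
                analysis_matrix(gm_full, tm), gm_full, tm,
                target_power=cfg.target_power, alpha=cfg.alpha,
            )
            sigma, clamped = tm.error_sd, tm.sigma_clamped
            if clamped:
                logger.warning(
                    "model %d: calibrated sigma clamped to %.4g", model_id, sigma
                )
        counts: dict[tuple[str, str], int] = {}
        present: dict[tuple[str, str], int] = {}
        gm_analysis = gm_full if tm is None else analysis_matrix(gm_full, tm)
        contexts = _prepare_sets(gm_analysis, cfg.analysis_sets, cfg.panel.r2_threshold)
        for rep in range(cfg.n_replicates):
            rng = _replicate_seed(cfg.seed, model_id, rep)
            if cfg.redraw_genotypes and rep > 0:
                gm_full = generate_genotypes(pool, cfg.n_individuals, rng)
                gm_analysis = gm_full if tm is None else analysis_matrix(gm_full, tm)
                contexts = _prepare_sets(gm_analysis, cfg.analysis_sets, cfg.panel.r2_threshold)
            if tm is None:
                ph = Phenotype(list(gm_full.samples), rng.standard_normal(gm_full.n_samples))
            else:
                ph = generate_trait(gm_full, tm, rng)
            pmap: dict[tuple[str, str], float] = {}
            for set_name, ctx in contexts.items():
                if ctx is None:
                    continue
                stat_p = _evaluate_statistics(
                    ctx, ph, cfg.statistics, set_name, cfg.mixture_method,
                    minp_seed=int(rng.integers(2**31)),
                )
                for stat, p in stat_p.items():
                    pmap[(stat, set_name)] = p
            for key, p in pmap.items():
                present[key] = present.get(key, 0) + 1
                if p < cfg.alpha:
                    counts[key] = counts.get(key, 0) + 1
        for set_name in cfg.analysis_sets:
            for stat in cfg.statistics:
                key = (stat, set_name)
                n_rep = present.get(key, 0)
                cells.append(
                    CellResult(
                        model_id=model_id,
                        analysis_set=set_name,
                        statistic=stat,
                        n_rejections=counts.get(key, 0),
                        n_replicates=max(n_rep, 1),
                        sigma=sigma,
                        sigma_clamped=clamped,
                        skipped=n_rep == 0,
                    )
                )
    return StudyResult(cells=cells, seeds=seeds)
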
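"""Seeded validation studies of the pipeline's operating characteristics.

Each function runs one self-contained simulation experiment against the
package's own stages and returns the measured quantity: the exact binomial
null of the concerted-change classifier and its Monte-Carlo call rate under
an iid sign-symmetric null, Benjamini-Hochberg agreement with the literal
step-up definition, recovery of a planted Spearman correlation at panel
size, type-I error of the correlation screen, null calibration and power of
the LS/KS permutation enrichment, and byte-level determinism of the whole
pipeline.  Problem sizes default to desk scale; every function takes a seed.
"""

from __future__ import annotations

import filecmp
import tempfile
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .association import bh_adjust, correlate
from .concerted import amplitude_tier, call_directions, null_probability
from .config import PipelineConfig
from .enrichment import gene_level_pvalues, permutation_test
from .pipeline import run_pipeline
from .preprocess import collapse_probes, compute_log2fc, tensor_condition
from .simulate import SimulationConfig, generate_panel, simulate_inputs

# the three-line worked example: per-cell-line log2FC after high-dose
# treatment at 24 h and the matching log10(GI50) values
MICRO_LOG2FC = (2.437, 0.648, -0.696)
MICRO_LOG_GI50 = (-8.0, -7.728, -4.952)


def exact_null_tail(n: int = 60, threshold: int = 15) -> float:
    """Exact Binomial(n, 1/2) tail P(X <= threshold) by integer summation."""
    return null_probability(n, threshold)


def null_call_rate_mc(n_genes: int = 1_000_000, n_lines: int = 60,
                      threshold: int = 15, seed: int = 0,
                      chunk: int = 50_000) -> float:
    """Concerted-call rate (either direction) for iid sign-symmetric
    fold-change vectors, via the vectorized direction rule."""
    rng = np.random.default_rng(seed)
    calls = 0
    done = 0
    while done < n_genes:
        m = min(chunk, n_genes - done)
        fc = rng.standard_normal((m, n_lines))
        n_pos = (fc > 0).sum(axis=1)
        n_neg = (fc < 0).sum(axis=1)
        calls += int((call_directions(n_pos, n_neg, threshold) != "none").sum())
        done += m
    return calls / n_genes


def bh_step_up_reference(p_values) -> np.ndarray:
    """Literal double-loop BH step-up: adjusted_(i) = min_{j >= i} of
    m p_(j) / j, capped at 1, in original order."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    for rank_i in range(1, m + 1):
        best = 1.0
        for rank_j in range(rank_i, m + 1):
            best = min(best, m * p[order[rank_j - 1]] / rank_j)
        adjusted[order[rank_i - 1]] = best
    return adjusted


def bh_max_deviation(n_vectors: int = 1000, max_size: int = 12,
                     seed: int = 0) -> float:
    """Largest absolute difference between the screen's BH adjustment and
    the double-loop reference over random small p-value families."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_vectors):
        m = int(rng.integers(1, max_size + 1))
        p = rng.uniform(size=m)
        worst = max(worst, float(np.max(np.abs(
            bh_adjust(p) - bh_step_up_reference(p)))))
    return worst


def _recovery_config(rep_seed: int, n_assoc: int = 5,
                     n_null: int = 1) -> SimulationConfig:
    return SimulationConfig(seed=rep_seed, agents=("dasatinib",),
                            times_hr=(24,), effect_times_hr=(24,),
                            n_null_genes=n_null, n_concerted_genes=0,
                            n_assoc_genes=n_assoc)


def spearman_recovery(n_reps: int = 200, seed: int = 0) -> float:
    """Mean estimated Spearman rho over seeded replicate panels with a
    planted rho = -0.8 link at 60 cell lines."""
    seeds = np.random.default_rng(seed).integers(2 ** 31, size=n_reps)
    rhos = []
    for s in seeds:
        cfg = _recovery_config(int(s))
        expression, sheet, probe_map, response, truth = generate_panel(cfg)
        tensor = compute_log2fc(collapse_probes(expression, probe_map), sheet)
        mat = tensor_condition(tensor, "dasatinib", "high", 24)
        y = response.xs("dasatinib", level="agent")
        for gene in truth.genes_of_class("associated"):
            res = correlate(mat.loc[gene, y.index], y.to_numpy(), "spearman")
            rhos.append(res.rho)
    return float(np.mean(rhos))


def null_p0_rate(n_genes: int = 2000, alpha: float = 0.05,
                 seed: int = 0) -> float:
    """Fraction of null genes with p0 < alpha when the response labels are
    permuted (type-I error of the correlation screen)."""
    cfg = SimulationConfig(seed=seed, agents=("dasatinib",), times_hr=(24,),
                           effect_times_hr=(24,), n_null_genes=n_genes,
                           n_concerted_genes=0, n_assoc_genes=0)
    expression, sheet, probe_map, response, _ = generate_panel(cfg)
    tensor = compute_log2fc(collapse_probes(expression, probe_map), sheet)
    rng = np.random.default_rng(seed + 1)
    permuted = response.copy()
    permuted[:] = rng.permutation(response.to_numpy())
    pvals = gene_level_pvalues(tensor, permuted, "dasatinib", "high", 24)
    return float((pvals < alpha).mean())


def enrichment_null_rejection_rate(n_reps: int = 500, universe_size: int = 400,
                                   set_size: int = 20, n_perm: int = 10_000,
                                   alpha: float = 0.05,
                                   seed: int = 0) -> float:
    """Rejection rate of the LS permutation test at ``alpha`` for random
    sets drawn from a null universe (uniform gene-level p-values)."""
    root = np.random.SeedSequence(seed)
    rejections = 0
    for child in root.spawn(n_reps):
        rng = np.random.default_rng(child)
        universe = pd.Series(rng.uniform(size=universe_size),
                             index=[f"G{i}" for i in range(universe_size)])
        members = rng.choice(universe.index, size=set_size, replace=False)
        out = permutation_test(universe, list(members), n_perm,
                               seed=child.spawn(1)[0],
                               min_set_size=set_size, max_set_size=set_size)
        if out.p_ls < alpha:
            rejections += 1
    return rejections / n_reps


def enrichment_power(n_reps: int = 100, n_perm: int = 10_000,
                     alpha: float = 0.05, seed: int = 0) -> float:
    """Fraction of seeded replicates in which a fully planted set (all
    members carrying the planted gene-response correlation) reaches
    p_ls < alpha, with the universe built end-to-end from a simulated
    panel."""
    seeds = np.random.default_rng(seed).integers(2 ** 31, size=n_reps)
    hits = 0
    for s in seeds:
        cfg = _recovery_config(int(s), n_assoc=20, n_null=180)
        expression, sheet, probe_map, response, truth = generate_panel(cfg)
        tensor = compute_log2fc(collapse_probes(expression, probe_map), sheet)
        universe = gene_level_pvalues(tensor, response, "dasatinib", "high", 24)
        out = permutation_test(universe, truth.genes_of_class("associated"),
                               n_perm, seed=int(s))
        if out.p_ls < alpha:
            hits += 1
    return hits / n_reps


def micro_example() -> dict:
    """The three-cell-line worked example: Spearman correlation of the
    printed fold changes against log10(GI50), and the amplitude tier of an
    upregulated call with maximum log2FC 2.437."""
    res = correlate(MICRO_LOG2FC, MICRO_LOG_GI50, "spearman", min_pairs=3)
    tier = amplitude_tier(MICRO_LOG2FC, "up")
    return {"spearman_rho": res.rho, "n_pairs": res.n_pairs,
            "amplitude_tier": tier}


def pipeline_determinism(seed: int = 0,
                         workdir: Optional[str | Path] = None) -> dict:
    """Simulate a scaled-down panel, run the full pipeline twice with the
    same config and seed, and compare every output file byte for byte."""
    sim = SimulationConfig(seed=seed, agents=("dasatinib", "vorinostat"),
                           n_null_genes=30, n_concerted_genes=6,
                           n_assoc_genes=8, n_gene_sets=4,
                           n_enriched_sets=2, set_size=6)
    cfg = PipelineConfig(rng_seed=seed, n_perm=1000)

    def _run_all(base: Path) -> dict:
        inputs = simulate_inputs(sim, base / "inputs")
        outs = []
        for name in ("run1", "run2"):
            out = run_pipeline(
                cfg, inputs, base / name,
                enrichment_conditions=[("dasatinib", "high", 24)],
                concordance_condition=("dasatinib", "high", 24))
            outs.append(out)
        files = sorted(p.name for p in outs[0].iterdir())
        identical = all(filecmp.cmp(outs[0] / f, outs[1] / f, shallow=False)
                        for f in files)
        return {"identical": identical, "n_files": len(files)}

    if workdir is not None:
        return _run_all(Path(workdir))
    with tempfile.TemporaryDirectory() as tmp:
        return _run_all(Path(tmp))
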
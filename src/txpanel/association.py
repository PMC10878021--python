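"""Correlation screen of expression measures against drug sensitivity.

Per (gene, agent, condition), Spearman and/or Pearson correlation of a
per-cell-line quantity — the log2 fold change at one (concentration, time)
or the untreated baseline expression — against log10(GI50).  Raw two-sided
p-values (p0) are adjusted with Benjamini-Hochberg step-up over a pooled
family: by default a single family per method spanning all genes, agents,
treatment conditions *and* the baseline rows (p_fdr).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .errors import InsufficientDataError, ValidationError

logger = logging.getLogger(__name__)

BASELINE = "baseline"

ASSOC_COLUMNS = ("gene", "agent", "condition", "concentration", "time_hr",
                 "method", "n_pairs", "rho", "p0", "p_fdr", "degenerate")


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p0: float
    n_pairs: int
    degenerate: bool = False


def correlate(x: Sequence[float], y: Sequence[float], method: str = "spearman",
              min_pairs: int = 10) -> CorrelationResult:
    """Correlate two per-cell-line vectors after dropping incomplete pairs.

    Spearman is the Pearson correlation of average-ranked values (ties
    averaged); both p-values are two-sided via the t statistic with n-2
    degrees of freedom.  Zero-variance input yields a degenerate result
    with undefined rho rather than a silent zero.
    """
    if method not in ("spearman", "pearson"):
        raise ValidationError(f"unknown correlation method {method!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < min_pairs:
        raise InsufficientDataError(
            f"only {n} complete pairs; {min_pairs} required"
        )
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(np.nan, np.nan, n, degenerate=True)
    if method == "spearman":
        rho, p0 = stats.spearmanr(x, y)
    else:
        rho, p0 = stats.pearsonr(x, y)
    return CorrelationResult(float(rho), float(p0), n)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment of one p-value family."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def pool_fdr(results: pd.DataFrame, family: str = "global") -> pd.DataFrame:
    """Fill ``p_fdr`` by BH within pooled families.

    global: one family per method across all genes, agents, conditions and
    baseline.  per_agent: one family per (method, agent).  Rows with
    undefined p0 (degenerate correlations) are left out of the family and
    keep p_fdr = NaN.
    """
    if family not in ("global", "per_agent"):
        raise ValidationError(f"unknown FDR family {family!r}")
    out = results.copy()
    out["p_fdr"] = np.nan
    keys = ["method"] if family == "global" else ["method", "agent"]
    valid = out["p0"].notna()
    for _, idx in out[valid].groupby(keys).groups.items():
        out.loc[idx, "p_fdr"] = bh_adjust(out.loc[idx, "p0"].to_numpy())
    return out


def _condition_frames(tensor: pd.DataFrame, baseline: Optional[pd.DataFrame],
                      agent: str):
    """Yield (condition label, concentration, time_hr, gene x cell_line
    frame) for every treatment condition of one agent, plus baseline."""
    sub = tensor[tensor["agent"] == agent]
    conds = sub[["concentration", "time_hr"]].drop_duplicates()
    conds = conds.sort_values(["concentration", "time_hr"])
    for conc, t in conds.itertuples(index=False):
        block = sub[(sub["concentration"] == conc) & (sub["time_hr"] == t)]
        frame = block.pivot(index="gene", columns="cell_line", values="log2fc")
        yield f"{conc}@{t}h", conc, int(t), frame
    if baseline is not None and len(baseline):
        yield BASELINE, BASELINE, None, baseline


def associate_panel(tensor: pd.DataFrame, baseline: Optional[pd.DataFrame],
                    response: pd.Series, config: PipelineConfig,
                    genes: Optional[Sequence[str]] = None,
                    y_gene: Optional[str] = None) -> pd.DataFrame:
    """Run the correlation screen over the whole panel.

    One row per (gene, agent, condition, method) with enough complete
    pairs; conditions are every (concentration, time) present in the
    tensor plus the baseline.  ``genes`` restricts the screen to a gene
    list; ``y_gene`` switches the response vector from log10(GI50) to that
    gene's own values at the same condition (gene-vs-gene correlation of
    expression changes).  FDR is pooled per ``config.fdr_family`` and the
    output is sorted by p_fdr within agent.
    """
    if not len(tensor):
        raise ValidationError("fold-change tensor is empty")
    agents = sorted(tensor["agent"].unique())
    rows = []
    for agent in agents:
        if y_gene is None:
            try:
                y_all = response.xs(agent, level="agent")
            except KeyError:
                logger.warning("agent %r absent from drug-response table; "
                               "skipped", agent)
                continue
        for label, conc, t, frame in _condition_frames(tensor, baseline, agent):
            if frame.empty:
                continue
            if y_gene is not None:
                if y_gene not in frame.index:
                    logger.warning("y-gene %r absent at %s/%s; skipped",
                                   y_gene, agent, label)
                    continue
                y_vec = frame.loc[y_gene]
            else:
                y_vec = y_all
            cells = frame.columns.intersection(y_vec.index)
            if not len(cells):
                logger.warning("no overlapping cell lines for agent %r at %s",
                               agent, label)
                continue
            y = y_vec.reindex(cells).to_numpy(dtype=float)
            use = frame.index if genes is None else frame.index.intersection(genes)
            if y_gene is not None:
                use = use.difference([y_gene])
            sub = frame.loc[use, cells]
            for gene, x in zip(sub.index, sub.to_numpy(dtype=float)):
                for method in config.correlation_methods:
                    try:
                        res = correlate(x, y, method, config.min_pairs)
                    except InsufficientDataError:
                        continue
                    rows.append((gene, agent, label, conc, t, method,
                                 res.n_pairs, res.rho, res.p0, np.nan,
                                 res.degenerate))
    result = pd.DataFrame(rows, columns=ASSOC_COLUMNS)
    if genes is not None:
        missing = set(genes) - set(result["gene"])
        if missing:
            logger.warning("genes absent from the panel: %s", sorted(missing))
    if not len(result):
        return result
    result = pool_fdr(result, config.fdr_family)
    result = result.sort_values(["agent", "p_fdr", "p0"], kind="mergesort",
                                na_position="last", ignore_index=True)
    return result
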
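"""Gene-set enrichment of correlation evidence: LS and KS permutation tests.

The universe is the map gene -> two-sided Spearman p-value of that gene's
expression change against log10(GI50) at one treatment condition.  For a
gene set S intersected with the universe:

* LS ("log score") = mean over S of -ln(p);
* KS = one-sided supremum of the set's empirical p-value CDF above the
  uniform CDF, max_i (i/n - p_(i)) with p_(1) <= ... <= p_(n).

The null draws ``n_perm`` random gene subsets of the same size uniformly
without replacement from the universe; p = (1 + #{null >= observed}) /
(1 + n_perm), so permutation p-values are never zero.  No multiplicity
adjustment is applied across sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .association import correlate
from .config import PipelineConfig
from .errors import InsufficientDataError, ValidationError
from .io import GeneSetCollection

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300  # keeps -ln(p) finite

ENRICH_COLUMNS = ("set_name", "agent", "concentration", "time_hr",
                  "n_genes_in_universe", "n_set_used", "ls_stat", "ks_stat",
                  "p_ls", "p_ks", "n_perm", "seed")


def ls_stat(p_values: Sequence[float]) -> float:
    """Mean of -ln(p) over a set; larger means more small p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValidationError("LS statistic undefined for an empty set")
    return float(np.mean(-np.log(np.clip(p, P_FLOOR, None))))


def ks_stat(p_values: Sequence[float]) -> float:
    """One-sided sup of the empirical CDF of the set's p-values above the
    uniform CDF: max_i (i/n - p_(i))."""
    p = np.sort(np.asarray(p_values, dtype=float))
    if p.size == 0:
        raise ValidationError("KS statistic undefined for an empty set")
    grid = np.arange(1, p.size + 1) / p.size
    return float(np.max(grid - p))


def gene_level_pvalues(tensor: pd.DataFrame, response: pd.Series, agent: str,
                       concentration: str, time_hr: int,
                       min_pairs: int = 10) -> pd.Series:
    """Two-sided Spearman p0 per gene for one condition; this is the
    enrichment universe.  Genes with too few pairs or degenerate input are
    absent."""
    sub = tensor[(tensor["agent"] == agent)
                 & (tensor["concentration"] == concentration)
                 & (tensor["time_hr"] == time_hr)]
    if not len(sub):
        raise ValidationError(
            f"condition ({agent}, {concentration}, {time_hr}h) absent from tensor"
        )
    frame = sub.pivot(index="gene", columns="cell_line", values="log2fc")
    try:
        y_all = response.xs(agent, level="agent")
    except KeyError:
        raise ValidationError(f"agent {agent!r} absent from drug response") from None
    cells = frame.columns.intersection(y_all.index)
    y = y_all.reindex(cells).to_numpy(dtype=float)
    out = {}
    for gene, x in zip(frame.index, frame[cells].to_numpy(dtype=float)):
        try:
            res = correlate(x, y, "spearman", min_pairs)
        except InsufficientDataError:
            continue
        if not res.degenerate:
            out[gene] = res.p0
    return pd.Series(out, name="p0").rename_axis("gene")


@dataclass(frozen=True)
class PermutationOutcome:
    ls: float
    ks: float
    p_ls: float
    p_ks: float
    n_set_used: int
    n_universe: int
    n_perm: int


def _null_stats(p_universe: np.ndarray, k: int, n_perm: int,
                rng: np.random.Generator,
                chunk: int = 2048) -> tuple[np.ndarray, np.ndarray]:
    """LS and KS over ``n_perm`` uniform size-k subsets of the universe.

    Subsets are drawn without replacement by ranking random keys; work is
    chunked to bound memory at ~chunk x universe doubles.
    """
    u = p_universe.size
    neglog = -np.log(np.clip(p_universe, P_FLOOR, None))
    grid = np.arange(1, k + 1) / k
    ls_null = np.empty(n_perm)
    ks_null = np.empty(n_perm)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        keys = rng.random((m, u))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k] if k < u else \
            np.broadcast_to(np.arange(u), (m, u))
        ls_null[done:done + m] = neglog[idx].mean(axis=1)
        ks_null[done:done + m] = (grid - np.sort(p_universe[idx], axis=1)).max(axis=1)
        done += m
    return ls_null, ks_null


def permutation_test(universe: Mapping[str, float] | pd.Series,
                     set_genes: Sequence[str], n_perm: int = 10_000,
                     seed: int | np.random.SeedSequence = 0,
                     min_set_size: int = 5,
                     max_set_size: int = 500) -> PermutationOutcome:
    """LS/KS permutation test of one gene set against the universe."""
    universe = pd.Series(universe, dtype=float)
    members = universe.index.intersection(pd.Index(set_genes).unique())
    k = len(members)
    if not (min_set_size <= k <= max_set_size):
        raise ValidationError(
            f"set intersects universe in {k} genes, outside "
            f"[{min_set_size}, {max_set_size}]"
        )
    obs_p = universe.loc[members].to_numpy()
    obs_ls = ls_stat(obs_p)
    obs_ks = ks_stat(obs_p)
    rng = np.random.default_rng(seed)
    ls_null, ks_null = _null_stats(universe.to_numpy(), k, n_perm, rng)
    p_ls = (1 + int((ls_null >= obs_ls).sum())) / (1 + n_perm)
    p_ks = (1 + int((ks_null >= obs_ks).sum())) / (1 + n_perm)
    return PermutationOutcome(obs_ls, obs_ks, p_ls, p_ks, k, universe.size,
                              n_perm)


def enrich_collection(universe: Mapping[str, float] | pd.Series,
                      collection: GeneSetCollection, config: PipelineConfig,
                      agent: Optional[str] = None,
                      concentration: Optional[str] = None,
                      time_hr: Optional[int] = None) -> pd.DataFrame:
    """Run the permutation test over every admissible set of a collection.

    Per-set RNG streams are spawned deterministically from
    ``config.rng_seed`` in collection order, so results are reproducible
    and independent of which other sets are present is *not* guaranteed —
    the stream index follows collection order.
    """
    universe = pd.Series(universe, dtype=float)
    if not len(universe):
        raise ValidationError("enrichment universe is empty")
    root = np.random.SeedSequence(config.rng_seed)
    streams = root.spawn(len(collection))
    rows = []
    for gene_set, stream in zip(collection, streams):
        try:
            out = permutation_test(universe, gene_set.members, config.n_perm,
                                   stream, config.min_set_size,
                                   config.max_set_size)
        except ValidationError as exc:
            logger.info("set %r skipped: %s", gene_set.name, exc)
            continue
        rows.append((gene_set.name, agent, concentration, time_hr,
                     out.n_universe, out.n_set_used, out.ls, out.ks,
                     out.p_ls, out.p_ks, out.n_perm, config.rng_seed))
    return pd.DataFrame(rows, columns=ENRICH_COLUMNS)
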
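"""Concerted transcriptional change calls and their exact binomial null.

An experiment (gene x agent x concentration x time) shows a *concerted*
change when at most ``threshold`` cell lines (default 15 of 60) move in the
direction opposite to the majority.  Under the null that each line moves up
or down independently with probability 1/2, the chance of so few discordant
lines is the exact binomial tail P(X <= threshold), X ~ Binomial(n, 1/2),
computed here by integer summation — no normal approximation.

Amplitude tiers annotate a concerted call by the largest per-cell-line
log2FC in the consensus direction (default tiers >=1, >=2.5, >=4; inclusive
boundaries).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from math import comb
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .errors import InsufficientDataError, ValidationError

CONSENSUS_COLUMNS = ("gene", "agent", "concentration", "time_hr", "n_pos",
                     "n_neg", "n_zero", "n_total", "direction", "tier",
                     "null_p", "sufficient")


@dataclass(frozen=True)
class DirectionCall:
    n_pos: int
    n_neg: int
    n_zero: int
    n_total: int
    direction: str          # "up" | "down" | "none"
    sufficient: bool


@lru_cache(maxsize=4096)
def null_probability(n: int, threshold: int) -> float:
    """Exact one-direction tail P(X <= threshold) for X ~ Binomial(n, 1/2).

    Computed with integer binomial coefficients and an exact rational
    division, then rounded once to float.
    """
    if threshold < 0 or threshold > n:
        raise ValidationError(f"threshold {threshold} outside [0, {n}]")
    total = sum(comb(n, k) for k in range(threshold + 1))
    return float(Fraction(total, 2 ** n))


def call_directions(n_pos: np.ndarray, n_neg: np.ndarray, threshold: int,
                    min_n: int = 0) -> np.ndarray:
    """Vectorized direction rule over discordance counts.

    up   iff n_neg <= threshold and n_pos > n_neg;
    down iff n_pos <= threshold and n_neg > n_pos;
    none otherwise, or when n_pos + n_neg (+ zeros, handled by caller via
    min_n on totals) is below ``min_n``.
    """
    n_pos = np.asarray(n_pos)
    n_neg = np.asarray(n_neg)
    up = (n_neg <= threshold) & (n_pos > n_neg)
    down = (n_pos <= threshold) & (n_neg > n_pos)
    out = np.where(up, "up", np.where(down, "down", "none"))
    if min_n:
        out = np.where((n_pos + n_neg) < min_n, "none", out)
    return out


def classify_concerted(fc: Sequence[float], threshold: int = 15,
                       min_n: int = 40) -> DirectionCall:
    """Classify one experiment's per-cell-line log2FC vector.

    Zeros count as neither direction and are excluded from both counts.
    Experiments with fewer than ``min_n`` lines with data are flagged
    insufficient and receive direction "none".
    """
    values = np.asarray(fc, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise InsufficientDataError("all fold-change values missing")
    n_pos = int((values > 0).sum())
    n_neg = int((values < 0).sum())
    n_zero = int((values == 0).sum())
    n_total = values.size
    sufficient = n_total >= min_n
    if not sufficient:
        direction = "none"
    elif n_neg <= threshold and n_pos > n_neg:
        direction = "up"
    elif n_pos <= threshold and n_neg > n_pos:
        direction = "down"
    else:
        direction = "none"
    return DirectionCall(n_pos, n_neg, n_zero, n_total, direction, sufficient)


def amplitude_tier(fc: Sequence[float], direction: str,
                   tiers: Sequence[float] = (1.0, 2.5, 4.0)) -> Optional[float]:
    """Highest tier t with at least one cell line at log2FC >= t (up) or
    <= -t (down); ``None`` when no line reaches the first tier."""
    if direction not in ("up", "down"):
        raise ValidationError("amplitude tier undefined for direction 'none'")
    values = np.asarray(fc, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise InsufficientDataError("all fold-change values missing")
    extreme = values.max() if direction == "up" else -values.min()
    best: Optional[float] = None
    for t in tiers:
        if extreme >= t:
            best = float(t)
    return best


def build_consensus_table(tensor: pd.DataFrame,
                          config: PipelineConfig) -> pd.DataFrame:
    """One concerted-change call per (gene, agent, concentration, time).

    The attached null probability uses that experiment's directional count
    n = n_pos + n_neg (zeros are directionless).  Experiments with fewer
    than ``config.min_cell_lines`` lines are kept but flagged
    ``sufficient=False`` with direction "none".
    """
    if not len(tensor):
        raise ValidationError("fold-change tensor is empty")
    keys = ["gene", "agent", "concentration", "time_hr"]
    fc = tensor["log2fc"]
    grp = tensor.assign(
        _pos=(fc > 0).astype(int),
        _neg=(fc < 0).astype(int),
        _zero=(fc == 0).astype(int),
    ).groupby(keys, sort=True)
    agg = grp.agg(n_pos=("_pos", "sum"), n_neg=("_neg", "sum"),
                  n_zero=("_zero", "sum"), fc_max=("log2fc", "max"),
                  fc_min=("log2fc", "min")).reset_index()
    agg["n_total"] = agg["n_pos"] + agg["n_neg"] + agg["n_zero"]
    agg["sufficient"] = agg["n_total"] >= config.min_cell_lines
    direction = call_directions(agg["n_pos"].to_numpy(),
                                agg["n_neg"].to_numpy(),
                                config.discordance_threshold)
    direction = np.where(agg["sufficient"], direction, "none")
    agg["direction"] = direction

    n_eff = (agg["n_pos"] + agg["n_neg"]).to_numpy()
    thr = config.discordance_threshold
    agg["null_p"] = [null_probability(int(n), min(thr, int(n))) if n > 0 else 1.0
                     for n in n_eff]

    tiers = config.amplitude_tiers
    tier_col = []
    for d, mx, mn in zip(agg["direction"], agg["fc_max"], agg["fc_min"]):
        if d == "up":
            extreme = mx
        elif d == "down":
            extreme = -mn
        else:
            tier_col.append("none")
            continue
        best = "none"
        for t in tiers:
            if extreme >= t:
                best = f"{t:g}"
        tier_col.append(best)
    agg["tier"] = tier_col
    return agg[list(CONSENSUS_COLUMNS)]


_ARROW = {"up": "↑", "down": "↓"}


def compact_notation(consensus: pd.DataFrame,
                     tiers: Sequence[float] = (1.0, 2.5, 4.0)) -> pd.DataFrame:
    """Render concerted calls per (gene, agent) in compact form, e.g.
    "H24↑*, L24↑": H/L concentration, time in hours, direction arrow, and
    one star per amplitude tier reached."""
    stars = {f"{t:g}": "*" * (i + 1) for i, t in enumerate(tiers)}
    stars["none"] = ""
    rows = []
    calls = consensus[consensus["direction"].isin(("up", "down"))]
    for (gene, agent), grp in calls.groupby(["gene", "agent"], sort=True):
        order = grp["concentration"].map({"high": 0, "low": 1})
        grp = grp.assign(_ord=order).sort_values(["_ord", "time_hr"])
        parts = [
            f"{'H' if r.concentration == 'high' else 'L'}{r.time_hr}"
            f"{_ARROW[r.direction]}{stars.get(str(r.tier), '')}"
            for r in grp.itertuples()
        ]
        rows.append({"gene": gene, "agent": agent, "calls": ",".join(parts)})
    return pd.DataFrame(rows, columns=["gene", "agent", "calls"])
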
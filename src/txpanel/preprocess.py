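"""Probe collapsing, log2 fold changes, and baseline expression.

The fold-change tensor is the pipeline's central quantity: per
(gene, cell line, agent, concentration, time), the difference between the
gene-averaged log2 expression of the treated sample and its time-matched
vehicle control from the same cell line.  Baseline expression is the median
of vehicle-control log2 values across all agents at one time point
(default 6 hr).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import TREATED_ARMS

FC_COLUMNS = ("gene", "cell_line", "agent", "concentration", "time_hr", "log2fc")


def collapse_probes(matrix: pd.DataFrame, probe_map: pd.Series) -> pd.DataFrame:
    """Average probe-level log2 values to gene level.

    Each gene's value in a sample is the arithmetic mean (on the log2
    scale) of its probes' present values; it is missing only when all
    probes are missing.  Every probe in ``matrix`` must be mapped.
    """
    unmapped = matrix.index.difference(probe_map.index)
    if len(unmapped):
        raise ValidationError(f"unmapped probes: {list(unmapped[:10])}")
    genes = probe_map.reindex(matrix.index)
    collapsed = matrix.groupby(genes.to_numpy()).mean()
    collapsed.index.name = "gene"
    return collapsed


def _arm_means(gene_matrix: pd.DataFrame, sheet: pd.DataFrame,
               arms: Sequence[str]) -> pd.DataFrame:
    """Per (cell_line, agent, arm, time_hr): mean over replicate samples.

    Returns a gene x group DataFrame whose columns are a MultiIndex of the
    grouping keys.  Replicate arrays for the same condition are averaged on
    the log2 scale (missing values excluded).
    """
    sub = sheet[sheet["arm"].isin(arms)]
    sub = sub[sub["sample_id"].isin(gene_matrix.columns)]
    if not len(sub):
        return pd.DataFrame(index=gene_matrix.index)
    cols = gene_matrix[sub["sample_id"].to_numpy()]
    keys = pd.MultiIndex.from_frame(sub[["cell_line", "agent", "arm", "time_hr"]])
    return cols.T.groupby(keys).mean().T


def compute_log2fc(gene_matrix: pd.DataFrame, sheet: pd.DataFrame) -> pd.DataFrame:
    """Compute the fold-change tensor as a long table.

    One row per (gene, cell_line, agent, concentration, time_hr) where both
    the treated sample and its time-matched vehicle control have a value:
    log2fc = treated - vehicle.  Replicates on either side are averaged
    first.
    """
    treated = _arm_means(gene_matrix, sheet, TREATED_ARMS)
    vehicle = _arm_means(gene_matrix, sheet, ["vehicle"])
    if treated.empty or vehicle.empty:
        return pd.DataFrame(columns=FC_COLUMNS)
    # align each treated column with the vehicle column for the same
    # (cell_line, agent, time_hr)
    v_lookup = {key[:2] + (key[3],): key for key in vehicle.columns}
    records = []
    for key in treated.columns:
        cell_line, agent, conc, time_hr = key
        v_key = v_lookup.get((cell_line, agent, time_hr))
        if v_key is None:
            continue
        fc = treated[key] - vehicle[v_key]
        fc = fc.dropna()
        if not len(fc):
            continue
        block = pd.DataFrame({
            "gene": fc.index,
            "cell_line": cell_line,
            "agent": agent,
            "concentration": conc,
            "time_hr": time_hr,
            "log2fc": fc.to_numpy(),
        })
        records.append(block)
    if not records:
        return pd.DataFrame(columns=FC_COLUMNS)
    out = pd.concat(records, ignore_index=True)
    return out.sort_values(list(FC_COLUMNS[:5]), kind="mergesort",
                           ignore_index=True)


def compute_baseline(gene_matrix: pd.DataFrame, sheet: pd.DataFrame,
                     time_hr: int = 6) -> pd.DataFrame:
    """Baseline expression: per (gene, cell line), the median of vehicle
    log2 values across all agents at ``time_hr``.

    Missing values are excluded; a (gene, cell line) pair is NaN when no
    vehicle value exists.
    """
    if time_hr not in set(sheet["time_hr"]):
        raise ValidationError(f"time point {time_hr} hr not present in panel")
    vehicles = sheet[(sheet["arm"] == "vehicle") & (sheet["time_hr"] == time_hr)]
    vehicles = vehicles[vehicles["sample_id"].isin(gene_matrix.columns)]
    if not len(vehicles):
        raise ValidationError(f"no vehicle samples at {time_hr} hr")
    cols = gene_matrix[vehicles["sample_id"].to_numpy()]
    baseline = cols.T.groupby(vehicles["cell_line"].to_numpy()).median().T
    baseline.index.name = "gene"
    baseline.columns.name = "cell_line"
    return baseline


def tensor_condition(tensor: pd.DataFrame, agent: str, concentration: str,
                     time_hr: int) -> pd.DataFrame:
    """Slice the long fold-change tensor to one experimental condition and
    pivot it to a gene x cell_line matrix."""
    sub = tensor[(tensor["agent"] == agent)
                 & (tensor["concentration"] == concentration)
                 & (tensor["time_hr"] == time_hr)]
    if not len(sub):
        return pd.DataFrame()
    return sub.pivot(index="gene", columns="cell_line", values="log2fc")
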
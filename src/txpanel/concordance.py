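"""Direction concordance between an external dataset and panel consensus.

External per-probe, per-replicate log2 fold changes are averaged in two
stages (probes within replicate, then replicates), filtered at a strict
|log2FC| > threshold (default 0.1), and their signs compared with the
consensus direction of concerted changes at a matched panel condition.
Genes failing the filter are reported as filtered, not as disagreement.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

EXTERNAL_COLUMNS = ("gene", "cell_line", "probe", "replicate", "log2fc")

RECORD_COLUMNS = ("gene", "cell_line", "external_log2fc", "passes_filter",
                  "consensus_direction", "agrees")


def summarize_external_fc(records: pd.DataFrame) -> pd.Series:
    """Average probe/replicate-level external log2FC per (gene, cell line).

    Two-stage mean: over probes within each replicate, then over
    replicates.  With balanced probe counts this equals the pooled mean.
    """
    missing = [c for c in EXTERNAL_COLUMNS if c not in records.columns]
    if missing:
        raise ValidationError(f"external table missing columns {missing}")
    per_rep = (records.groupby(["gene", "cell_line", "replicate"])["log2fc"]
               .mean())
    return per_rep.groupby(["gene", "cell_line"]).mean().rename("external_log2fc")


def consensus_directions(consensus: pd.DataFrame, agent: str,
                         concentration: str, time_hr: int) -> pd.Series:
    """Gene -> consensus direction at one panel condition, restricted to
    sufficient experiments with a concerted call."""
    sub = consensus[(consensus["agent"] == agent)
                    & (consensus["concentration"] == concentration)
                    & (consensus["time_hr"] == time_hr)]
    sub = sub[sub["sufficient"] & sub["direction"].isin(("up", "down"))]
    if sub["gene"].duplicated().any():
        raise ValidationError("multiple consensus rows per gene at one condition")
    return pd.Series(sub["direction"].to_numpy(), index=sub["gene"],
                     name="consensus_direction")


def direction_agreement(external: pd.Series,
                        consensus_direction: Mapping[str, str] | pd.Series,
                        min_abs_fc: float = 0.1) -> tuple[pd.DataFrame, float]:
    """Compare external fold-change signs with consensus directions.

    ``external`` is the (gene, cell_line)-indexed output of
    :func:`summarize_external_fc`.  A record agrees when it passes the
    strict |log2FC| > min_abs_fc filter and its sign matches the consensus
    direction; agreement is undefined (NA) for filtered genes and genes
    without a concerted consensus.  Returns the per-record table and the
    fraction agreeing among records where agreement is defined (NaN when
    none).
    """
    cons = pd.Series(consensus_direction, dtype=object)
    genes = external.index.get_level_values("gene")
    if not len(set(genes) & set(cons.index)):
        logger.warning("no overlap between external genes and consensus calls")
    rows = []
    for (gene, cell_line), fc in external.items():
        passes = bool(abs(fc) > min_abs_fc)
        direction = cons.get(gene, "none")
        if passes and direction in ("up", "down"):
            agrees: object = bool((fc > 0) == (direction == "up"))
        else:
            agrees = pd.NA
        rows.append((gene, cell_line, fc, passes, direction, agrees))
    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    defined = records["agrees"].notna()
    summary = (float(records.loc[defined, "agrees"].mean())
               if defined.any() else float("nan"))
    return records, summary
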
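"""End-to-end pipeline: inputs on disk -> report directory of TSV tables.

Stage order: read/validate -> probe collapse -> fold changes & baseline ->
concerted consensus -> association screen -> gene-set enrichment ->
external concordance.  Outputs are a pure function of (inputs, config,
seed); re-running with the same arguments reproduces every file byte for
byte.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import concerted as tconcerted
from . import concordance as tconcord
from . import enrichment as tenrich
from . import io as tio
from . import preprocess as tpre
from .association import associate_panel
from .config import PipelineConfig
from .errors import PipelineError, ValidationError

logger = logging.getLogger(__name__)

Condition = tuple[str, str, int]  # (agent, concentration, time_hr)


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def run_pipeline(config: PipelineConfig, inputs: Mapping[str, str | Path],
                 out_dir: str | Path,
                 agents: Optional[Sequence[str]] = None,
                 enrichment_conditions: Optional[Sequence[Condition]] = None,
                 concordance_condition: Optional[Condition] = None) -> Path:
    """Run every stage and write the report directory.

    ``inputs`` maps: expression, sample_sheet, probe_map, drug_response,
    and optionally gene_sets (GMT) and external (long validation table).
    ``agents`` optionally restricts the analysis; unknown names abort
    before any computation.  ``enrichment_conditions`` limits the LS/KS
    stage to specific (agent, concentration, time_hr) triples (default:
    all present).  ``concordance_condition`` names the consensus condition
    the external table is compared against (required when ``external`` is
    given).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sheet = _stage("read_inputs")(tio.read_sample_sheet)(inputs["sample_sheet"])
    expression = _stage("read_inputs")(tio.read_expression_matrix)(
        inputs["expression"])
    probe_map = _stage("read_inputs")(tio.read_probe_map)(inputs["probe_map"])
    response = _stage("read_inputs")(tio.read_drug_response)(
        inputs["drug_response"])

    if agents is not None:
        unknown = set(agents) - set(sheet["agent"])
        if unknown:
            raise PipelineError(
                f"stage 'filter' failed: unknown agents {sorted(unknown)}"
            )
        sheet = sheet[sheet["agent"].isin(agents)].reset_index(drop=True)
        expression = expression[sheet["sample_id"].to_numpy()]
    logger.info("inputs: %d probes, %d samples, %d agents",
                len(expression), expression.shape[1],
                sheet["agent"].nunique())

    gene_matrix = _stage("collapse_probes")(tpre.collapse_probes)(
        expression, probe_map)
    logger.info("collapse_probes: %d genes", len(gene_matrix))

    tensor = _stage("foldchange")(tpre.compute_log2fc)(gene_matrix, sheet)
    logger.info("foldchange: %d entries", len(tensor))
    tio.write_table(tensor, out / "foldchange.tsv")

    baseline = _stage("baseline")(tpre.compute_baseline)(
        gene_matrix, sheet, config.baseline_time_hr)
    baseline_long = (baseline.stack().rename("baseline")
                     .rename_axis(["gene", "cell_line"]).reset_index())
    tio.write_table(baseline_long, out / "baseline.tsv")

    consensus = _stage("concerted")(tconcerted.build_consensus_table)(
        tensor, config)
    logger.info("concerted: %d experiments, %d concerted calls",
                len(consensus),
                int(consensus["direction"].isin(("up", "down")).sum()))
    tio.write_table(consensus, out / "consensus.tsv")

    assoc = _stage("associate")(associate_panel)(
        tensor, baseline, response, config)
    logger.info("associate: %d results", len(assoc))
    tio.write_table(assoc, out / "associations.tsv")

    if "gene_sets" in inputs and inputs["gene_sets"]:
        collection = _stage("enrich")(tio.read_gmt)(inputs["gene_sets"])
        if enrichment_conditions is None:
            conds = (tensor[["agent", "concentration", "time_hr"]]
                     .drop_duplicates().sort_values(
                         ["agent", "concentration", "time_hr"]))
            enrichment_conditions = [tuple(r) for r in
                                     conds.itertuples(index=False)]
        blocks = []
        for agent, conc, t in enrichment_conditions:
            universe = _stage("enrich")(tenrich.gene_level_pvalues)(
                tensor, response, agent, conc, int(t), config.min_pairs)
            blocks.append(_stage("enrich")(tenrich.enrich_collection)(
                universe, collection, config, agent, conc, int(t)))
        enrich = (pd.concat(blocks, ignore_index=True) if blocks
                  else pd.DataFrame(columns=tenrich.ENRICH_COLUMNS))
        logger.info("enrich: %d set results", len(enrich))
        tio.write_table(enrich, out / "enrichment.tsv")

    if "external" in inputs and inputs["external"]:
        if concordance_condition is None:
            raise PipelineError(
                "stage 'concord' failed: external table given without a "
                "concordance_condition (agent, concentration, time_hr)"
            )
        external = _stage("concord")(tio.read_table)(inputs["external"])
        summarized = _stage("concord")(tconcord.summarize_external_fc)(external)
        agent, conc, t = concordance_condition
        directions = _stage("concord")(tconcord.consensus_directions)(
            consensus, agent, conc, int(t))
        records, summary = _stage("concord")(tconcord.direction_agreement)(
            summarized, directions, config.concordance_min_abs_fc)
        logger.info("concord: %d records, agreement fraction %s",
                    len(records), summary)
        tio.write_table(records, out / "concordance.tsv")
        defined = records["agrees"].notna()
        tio.write_table(
            pd.DataFrame([{
                "agent": agent, "concentration": conc, "time_hr": int(t),
                "n_records": len(records),
                "n_defined": int(defined.sum()),
                "fraction_agree": summary,
            }]),
            out / "concordance_summary.tsv",
        )

    config.to_file(out / "config.yaml")
    return out
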
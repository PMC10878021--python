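"""Synthetic cell-line panel with planted, recoverable truth.

The generator emulates the structure of a drug-perturbation screen on a
cancer cell-line panel: 60 cell lines x 15 agents x {low, high}
concentration x {2, 6, 24} hr, each treated sample paired with a
time-matched vehicle control, genes measured by 1-3 probes on the log2
scale, and a log10(GI50) sensitivity table per (cell line, agent).

Three gene classes are planted:

* null genes — vehicle and treated values differ only by iid noise, so
  their log2FC is sign-symmetric;
* concerted genes — at designated conditions every cell line receives an
  additive shift whose sign matches the planted direction with
  probability 1 - discordance_prob;
* associated genes — the shift is coupled, through a Gaussian copula, to a
  latent per-(cell line, agent) sensitivity score that also generates
  log10(GI50), so the planted Spearman correlation between log2FC and
  log(GI50) is controlled (negative by default: upregulation tracks
  sensitivity).

Gene sets (enriched sets drawn from associated genes, control sets from
null genes) and an external-validation fold-change table with a
configurable direction-concordance rate complete the inputs, so every
pipeline stage can be tested against known truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ValidationError
from . import io as tio

DEFAULT_AGENTS = (
    "azacytidine", "bortezomib", "cisplatin", "dasatinib", "doxorubicin",
    "erlotinib", "geldanamycin", "gemcitabine", "lapatinib", "paclitaxel",
    "rapamycin", "sorafenib", "sunitinib", "topotecan", "vorinostat",
)


def spearman_to_pearson(rho: float) -> float:
    """Pearson correlation of a bivariate normal whose population Spearman
    correlation is ``rho``: 2 sin(pi rho / 6)."""
    return 2.0 * math.sin(math.pi * rho / 6.0)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic panel; defaults mirror the screen's design
    (panel geometry) at desk-scale gene counts."""

    n_cell_lines: int = 60
    agents: tuple[str, ...] = DEFAULT_AGENTS
    concentrations: tuple[str, ...] = ("low", "high")
    times_hr: tuple[int, ...] = (2, 6, 24)

    n_null_genes: int = 400
    n_concerted_genes: int = 16
    concerted_direction: str = "mixed"      # up | down | mixed
    concerted_effect_mean: float = 1.5
    concerted_effect_sd: float = 0.5
    discordance_prob: float = 0.1

    n_assoc_genes: int = 30
    assoc_rho: float = -0.8                 # target Spearman(log2FC, log GI50)
    assoc_effect_scale: float = 2.0

    # conditions at which planted effects are switched on
    effect_concentrations: tuple[str, ...] = ("high",)
    effect_times_hr: tuple[int, ...] = (24,)

    probes_per_gene: tuple[int, int] = (1, 3)
    probe_offset_sd: float = 0.3
    baseline_mean: float = 6.0
    baseline_sd: float = 1.5
    cell_line_sd: float = 0.5
    noise_sd: float = 0.25

    gi50_intercept: float = -6.0
    gi50_slope: float = 1.0
    gi50_noise_sd: float = 0.3

    n_gene_sets: int = 10
    n_enriched_sets: int = 3
    set_size: int = 20
    enriched_fraction: float = 1.0

    external_cell_line: str = "EXT1"
    external_n_replicates: int = 3
    external_effect_mean: float = 0.5
    external_effect_sd: float = 0.2
    external_noise_sd: float = 0.05
    external_concordance_rate: float = 1.0

    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_cell_lines < 1 or not self.agents:
            raise ValidationError("need at least one cell line and one agent")
        if min(self.n_null_genes, self.n_concerted_genes,
               self.n_assoc_genes) < 0:
            raise ValidationError("gene counts must be non-negative")
        if self.n_null_genes + self.n_concerted_genes + self.n_assoc_genes == 0:
            raise ValidationError("no genes requested")
        if not (0 <= self.discordance_prob < 0.5):
            raise ValidationError("discordance_prob must lie in [0, 0.5)")
        if not (-1 < self.assoc_rho < 1):
            raise ValidationError("|assoc_rho| must be < 1")
        lo, hi = self.probes_per_gene
        if not (1 <= lo <= hi):
            raise ValidationError("probes_per_gene must satisfy 1 <= lo <= hi")
        if self.concerted_direction not in ("up", "down", "mixed"):
            raise ValidationError("concerted_direction must be up/down/mixed")
        if set(self.effect_concentrations) - set(self.concentrations):
            raise ValidationError("effect_concentrations not in concentrations")
        if set(self.effect_times_hr) - set(self.times_hr):
            raise ValidationError("effect_times_hr not in times_hr")
        if not (0 <= self.n_enriched_sets <= self.n_gene_sets):
            raise ValidationError("n_enriched_sets must be <= n_gene_sets")
        if not (0 <= self.enriched_fraction <= 1):
            raise ValidationError("enriched_fraction must lie in [0, 1]")
        if not (0 <= self.external_concordance_rate <= 1):
            raise ValidationError("external_concordance_rate must lie in [0, 1]")


@dataclass
class PlantedTruth:
    """Ground truth of a simulated panel: per-gene class/direction/target
    correlation, and (after set generation) per-set enrichment flags."""

    genes: pd.DataFrame                       # index gene: klass, direction, rho
    sets: dict[str, bool] = field(default_factory=dict)

    def genes_of_class(self, klass: str) -> list[str]:
        return list(self.genes.index[self.genes["klass"] == klass])


def _streams(seed: int) -> tuple[np.random.SeedSequence, ...]:
    """Independent, deterministic sub-streams for panel / sets / external."""
    return tuple(np.random.SeedSequence(seed).spawn(3))


def _gene_table(config: SimulationConfig) -> pd.DataFrame:
    names, klass, direction, rho = [], [], [], []
    width = len(str(config.n_null_genes + config.n_concerted_genes
                    + config.n_assoc_genes))
    i = 0
    for _ in range(config.n_concerted_genes):
        i += 1
        names.append(f"G{i:0{width}d}")
        klass.append("concerted")
        if config.concerted_direction == "mixed":
            direction.append("up" if i % 2 else "down")
        else:
            direction.append(config.concerted_direction)
        rho.append(np.nan)
    for _ in range(config.n_assoc_genes):
        i += 1
        names.append(f"G{i:0{width}d}")
        klass.append("associated")
        direction.append("none")
        rho.append(config.assoc_rho)
    for _ in range(config.n_null_genes):
        i += 1
        names.append(f"G{i:0{width}d}")
        klass.append("null")
        direction.append("none")
        rho.append(np.nan)
    return pd.DataFrame({"klass": klass, "direction": direction, "rho": rho},
                        index=pd.Index(names, name="gene"))


def generate_panel(config: SimulationConfig):
    """Simulate the full panel.

    Returns ``(expression, sample_sheet, probe_map, drug_response, truth)``
    where expression is the probe-level log2 matrix.  Identical config
    (including seed) gives identical outputs.
    """
    config.validate()
    s_panel, _, _ = _streams(config.seed)
    rng = np.random.default_rng(s_panel)

    genes = _gene_table(config)
    g = len(genes)
    cells = [f"CL{i + 1:02d}" for i in range(config.n_cell_lines)]
    c = len(cells)
    agents = list(config.agents)
    a = len(agents)

    # probes
    lo, hi = config.probes_per_gene
    n_probes = rng.integers(lo, hi + 1, size=g)
    probe_ids, probe_gene_idx = [], []
    for gi, (gene, k) in enumerate(zip(genes.index, n_probes)):
        for j in range(k):
            probe_ids.append(f"{gene}_p{j + 1}")
            probe_gene_idx.append(gi)
    probe_gene_idx = np.asarray(probe_gene_idx)
    probe_map = pd.Series(genes.index.to_numpy()[probe_gene_idx],
                          index=pd.Index(probe_ids, name="probe_id"),
                          name="gene")
    p = len(probe_ids)

    # structural terms
    gene_mean = rng.normal(config.baseline_mean, config.baseline_sd, size=g)
    baseline = gene_mean[:, None] + rng.normal(0.0, config.cell_line_sd,
                                               size=(g, c))
    probe_offset = rng.normal(0.0, config.probe_offset_sd, size=p)

    # latent sensitivity and GI50
    latent = rng.normal(size=(c, a))
    gi50 = (config.gi50_intercept + config.gi50_slope * latent
            + rng.normal(0.0, config.gi50_noise_sd, size=(c, a)))
    response = pd.Series(
        gi50.ravel(),
        index=pd.MultiIndex.from_product([cells, agents],
                                         names=["cell_line", "agent"]),
        name="log_gi50",
    )

    # planted effects per (gene, cell line, agent)
    effect = np.zeros((g, c, a))
    con_idx = np.flatnonzero((genes["klass"] == "concerted").to_numpy())
    if con_idx.size:
        mag = np.abs(rng.normal(config.concerted_effect_mean,
                                config.concerted_effect_sd,
                                size=(con_idx.size, c, a)))
        signs = np.where(rng.random((con_idx.size, c, a))
                         < config.discordance_prob, -1.0, 1.0)
        planted_dir = np.where(
            genes["direction"].to_numpy()[con_idx] == "up", 1.0, -1.0)
        effect[con_idx] = planted_dir[:, None, None] * signs * mag
    asc_idx = np.flatnonzero((genes["klass"] == "associated").to_numpy())
    if asc_idx.size:
        # Copula correlation compensated for measurement-noise attenuation,
        # so the *observed* (log2FC, log GI50) pair hits the target Spearman:
        # everything is jointly Gaussian, hence Spearman = (6/pi) asin(r/2)
        # holds exactly for the noisy observables too.
        r_obs = spearman_to_pearson(config.assoc_rho)
        scale = config.assoc_effect_scale
        ay = config.gi50_slope / math.hypot(config.gi50_slope,
                                            config.gi50_noise_sd)
        sigma2_fc = 2.0 * config.noise_sd ** 2 / n_probes[asc_idx]
        ax = scale / np.sqrt(scale ** 2 + sigma2_fc)
        r_g = r_obs / (ax * ay)
        if np.any(np.abs(r_g) >= 1.0):
            raise ValidationError(
                "assoc_rho unreachable: noise too large relative to "
                "assoc_effect_scale / gi50_slope"
            )
        z = rng.normal(size=(asc_idx.size, c, a))
        u = (r_g[:, None, None] * latent[None, :, :]
             + np.sqrt(1.0 - r_g ** 2)[:, None, None] * z)
        effect[asc_idx] = scale * u

    # samples
    arms = ("vehicle",) + tuple(config.concentrations)
    sheet_rows = []
    col_meta = []
    for agent_i, agent in enumerate(agents):
        for t in config.times_hr:
            for arm in arms:
                for cell_i, cell in enumerate(cells):
                    sid = f"{cell}.{agent}.{arm}.{t}h"
                    sheet_rows.append((sid, cell, "", agent, arm, int(t)))
                    col_meta.append((cell_i, agent_i, arm, t))
    sheet = pd.DataFrame(sheet_rows, columns=["sample_id", "cell_line",
                                              "tissue", "agent", "arm",
                                              "time_hr"])

    values = rng.normal(0.0, config.noise_sd, size=(p, len(col_meta)))
    eff_conc = set(config.effect_concentrations)
    eff_time = set(config.effect_times_hr)
    for j, (cell_i, agent_i, arm, t) in enumerate(col_meta):
        col = baseline[probe_gene_idx, cell_i] + probe_offset
        if arm in eff_conc and t in eff_time:
            col = col + effect[probe_gene_idx, cell_i, agent_i]
        values[:, j] += col
    expression = pd.DataFrame(values,
                              index=pd.Index(probe_ids, name="probe_id"),
                              columns=sheet["sample_id"].to_numpy())

    return expression, sheet, probe_map, response, PlantedTruth(genes=genes)


def generate_gene_sets(truth: PlantedTruth,
                       config: SimulationConfig) -> tio.GeneSetCollection:
    """Build the gene-set collection: the first ``n_enriched_sets`` sets
    draw ``enriched_fraction`` of their members from associated genes (the
    rest from null genes); remaining sets are drawn from null genes only.
    Flags are recorded in ``truth.sets``."""
    _, s_sets, _ = _streams(config.seed)
    rng = np.random.default_rng(s_sets)
    assoc = truth.genes_of_class("associated")
    null = truth.genes_of_class("null")
    collection = tio.GeneSetCollection()
    width = len(str(max(config.n_gene_sets, 1)))
    for i in range(config.n_gene_sets):
        enriched = i < config.n_enriched_sets
        n_assoc = round(config.enriched_fraction * config.set_size) if enriched else 0
        n_null = config.set_size - n_assoc
        if n_assoc > len(assoc) or n_null > len(null):
            raise ValidationError(
                f"set size {config.set_size} exceeds available gene pool"
            )
        members = []
        if n_assoc:
            members += list(rng.choice(assoc, size=n_assoc, replace=False))
        if n_null:
            members += list(rng.choice(null, size=n_null, replace=False))
        name = f"SET{i + 1:0{width}d}"
        desc = "planted-enriched" if enriched else "control"
        collection.add(tio.GeneSet(name, desc, tuple(members)))
        truth.sets[name] = enriched
    return collection


def generate_external_table(truth: PlantedTruth,
                            config: SimulationConfig) -> pd.DataFrame:
    """External-validation long table (gene, cell_line, probe, replicate,
    log2fc): concerted genes carry a shift whose sign matches the planted
    direction with probability ``external_concordance_rate``; null and
    associated genes carry noise only."""
    _, _, s_ext = _streams(config.seed)
    rng = np.random.default_rng(s_ext)
    lo, hi = config.probes_per_gene
    rows = []
    for gene, rec in truth.genes.iterrows():
        if rec["klass"] == "concerted":
            mag = abs(rng.normal(config.external_effect_mean,
                                 config.external_effect_sd))
            sign = 1.0 if rec["direction"] == "up" else -1.0
            if rng.random() >= config.external_concordance_rate:
                sign = -sign
            true_fc = sign * mag
        else:
            true_fc = 0.0
        n_probes = int(rng.integers(lo, hi + 1))
        for rep in range(1, config.external_n_replicates + 1):
            for pr in range(1, n_probes + 1):
                fc = true_fc + rng.normal(0.0, config.external_noise_sd)
                rows.append((gene, config.external_cell_line, f"{gene}_x{pr}",
                             f"rep{rep}", fc))
    return pd.DataFrame(rows, columns=["gene", "cell_line", "probe",
                                       "replicate", "log2fc"])


def simulate_inputs(config: SimulationConfig, out_dir: str | Path) -> dict:
    """Generate and write every pipeline input plus the truth tables.

    Returns the path dictionary expected by
    :func:`txpanel.pipeline.run_pipeline`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expression, sheet, probe_map, response, truth = generate_panel(config)
    sets = generate_gene_sets(truth, config)
    external = generate_external_table(truth, config)

    paths = {
        "expression": out / "expression.tsv",
        "sample_sheet": out / "sample_sheet.tsv",
        "probe_map": out / "probe_map.tsv",
        "drug_response": out / "drug_response.tsv",
        "gene_sets": out / "gene_sets.gmt",
        "external": out / "external.tsv",
    }
    tio.write_expression_matrix(expression, paths["expression"])
    tio.write_sample_sheet(sheet, paths["sample_sheet"])
    tio.write_probe_map(probe_map, paths["probe_map"])
    tio.write_drug_response(response, paths["drug_response"])
    tio.write_gmt(sets, paths["gene_sets"])
    tio.write_table(external, paths["external"])

    truth_genes = truth.genes.reset_index()
    tio.write_table(truth_genes, out / "truth_genes.tsv")
    tio.write_table(
        pd.DataFrame(sorted(truth.sets.items()),
                     columns=["set_name", "enriched"]),
        out / "truth_sets.tsv",
    )
    return {k: str(v) for k, v in paths.items()}
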
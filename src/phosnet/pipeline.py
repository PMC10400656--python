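"""End-to-end orchestration: raw site tables to a signed network.

The pipeline chains ingest -> missingness classification -> normalization
-> per-site mixed models -> site selection -> discretization -> per
condition network inference -> combination, and keeps a stage log of
site counts so every filtering step is accountable.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from . import diffstats, discretize, netinfer, qc
from .ingest import PhosphoTable, apply_site_filters, merge_replicate_tables
from .regulators import RegulatorList

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable parameters with the pipeline's default values."""

    min_localization: float = 0.75
    min_valid: int | None = None  # None -> ceil(0.75 x replicates)
    normalization: str = "vsn"
    statistic: str = "f"
    p_cutoff: float = 0.05
    q_cutoff: float = 0.05
    delta: discretize.DeltaConfig = field(default_factory=discretize.DeltaConfig)
    bdeu: netinfer.BDeuParams = field(default_factory=netinfer.BDeuParams)
    concordance_threshold: float = 0.5
    lapses: tuple = (0, 1)
    max_parents: int = 2

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["lapses"] = list(self.lapses)
        return d


@dataclass
class StageLog:
    """Per-stage input/output site counts with removal reasons."""

    entries: list = field(default_factory=list)

    def add(self, stage: str, n_in: int, n_out: int, **detail) -> None:
        self.entries.append({"stage": stage, "n_in": n_in, "n_out": n_out, **detail})
        logger.info("stage %-22s %5d -> %5d %s", stage, n_in, n_out, detail or "")

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries)


@dataclass
class PipelineResult:
    network: nx.DiGraph
    condition_networks: dict
    stats: pd.DataFrame
    classification: qc.ValidityClassification
    selected_sites: pd.Index
    stage_log: StageLog
    config: PipelineConfig


def run_pipeline(
    tables,
    regulators: RegulatorList,
    config: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    """Run the full inference pipeline.

    ``tables`` is a PhosphoTable or a list of per-replicate tables to be
    merged.  Returns the combined network plus all intermediates.
    """
    log = StageLog()
    if isinstance(tables, PhosphoTable):
        table = tables
    else:
        table = merge_replicate_tables(list(tables))
    log.add("ingest", table.n_sites, table.n_sites)

    filtered = apply_site_filters(table, config.min_localization)
    log.add(
        "site_filters",
        table.n_sites,
        filtered.n_sites,
        removed=table.n_sites - filtered.n_sites,
    )

    cls = classification = qc.classify_missingness(filtered, config.min_valid)
    counts = cls.counts()
    keep = cls.site_class != qc.DISCARDED
    kept = PhosphoTable(
        filtered.intensities.loc[keep],
        filtered.design,
        filtered.meta.loc[keep],
    )
    log.add(
        "missingness",
        filtered.n_sites,
        kept.n_sites,
        quantified=counts[qc.QUANTIFIED],
        absence_presence=counts[qc.ABSENCE_PRESENCE],
        discarded=counts[qc.DISCARDED],
    )
    if kept.n_sites == 0:
        logger.warning("no quantified or absence/presence sites: empty network")
        empty = nx.DiGraph()
        return PipelineResult(
            empty, {}, pd.DataFrame(), classification, pd.Index([]), log, config
        )

    matrix = qc.normalize(kept, config.normalization)
    quantified, _ap = qc.split_subsets(matrix, cls)

    spec = diffstats.select_design(
        kept.design["condition"].nunique(), kept.design["time_min"].nunique()
    )
    results = []
    for site in quantified.values.index:
        results.append(
            diffstats.fit_site_model(
                quantified.values.loc[site],
                kept.design,
                spec,
                statistic=config.statistic,
                site=site,
            )
        )
    if results:
        diffstats.attach_qvalues(results, config.q_cutoff, config.p_cutoff)
        stats = diffstats.results_frame(results)
    else:
        stats = pd.DataFrame(columns=["p_value", "q_value", "significant"])
    selected = diffstats.select_network_sites(
        stats, cls, config.q_cutoff, config.p_cutoff
    ) if len(stats) or len(cls.sites(qc.ABSENCE_PRESENCE)) else pd.Index([])
    log.add("site_selection", kept.n_sites, len(selected))
    if len(selected) == 0:
        logger.warning("no sites selected for network inference: empty network")
        return PipelineResult(
            nx.DiGraph(), {}, stats, classification, selected, log, config
        )

    centered = discretize.median_center(matrix)
    levels = discretize.discretize_levels(centered)
    site_protein = {s: s[0] for s in selected}
    regulator_sites = [s for s in selected if s[0] in regulators]

    nets = {}
    n_edges = 0
    for cond in kept.conditions:
        profiles = discretize.condition_profiles(centered, cond).loc[list(selected)]
        deltas = discretize.delta_series(profiles, config.delta)
        arr, _reps, _times = discretize.level_array(levels, kept.design, cond)
        sel_pos = {s: i for i, s in enumerate(levels.index)}
        level_arrays = {s: arr[sel_pos[s]] for s in selected}
        nets[cond] = netinfer.infer_condition_network(
            deltas,
            level_arrays,
            regulator_sites,
            cond,
            site_protein=site_protein,
            params=config.bdeu,
            threshold=config.concordance_threshold,
            lapses=config.lapses,
            max_parents=config.max_parents,
        )
        n_edges += nets[cond].number_of_edges()

    conds = list(nets)
    if len(conds) == 2:
        network = netinfer.combine_networks(nets[conds[0]], nets[conds[1]])
    elif len(conds) == 1:
        network = nets[conds[0]].copy()
        nx.set_node_attributes(network, "A", "membership")
        nx.set_edge_attributes(network, "A", "membership")
    else:  # >2 conditions: plain union labelled by condition
        network = nx.DiGraph()
        for cond, net in nets.items():
            network = nx.compose(network, net)
    log.add("network_inference", len(selected), network.number_of_nodes(),
            edges=network.number_of_edges())
    return PipelineResult(network, nets, stats, classification, selected, log, config)
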
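"""End-to-end orchestration: network -> census/significance -> composite-FFL
selection -> CFMSN -> topology -> optional expression validation -> optional
drug association, with a machine-readable JSON report.

The pipeline is deterministic given its config and seed: every source of
randomness derives a substream from the global seed, and the report
contains no timestamps, so identical runs produce byte-identical reports.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import network_io
from .drugs import (
    DrugRecord,
    association_table,
    filter_drugs,
    mirna_drug_association,
)
from .expression import ExpressionMatrix, correlate_pairs, differential_expression
from .ffl import CFMSN, CompositeFFLCriteria, select_and_build_cfmsn
from .network import Relation, RegulatoryNetwork
from .significance import MotifStatistics, RandomizationConfig, motif_statistics
from .synthetic import substream_seed
from .topology import compute_node_metrics, fit_degree_power_law

logger = logging.getLogger("ffl_miner")


@dataclass
class PipelineConfig:
    """Inputs and settings for one pipeline run.

    The network is supplied either in memory (``network``) or as TSV paths
    (``node_path`` + ``edge_paths``).  Expression matrices and drug records
    are optional; their stages are skipped (and marked so in the report)
    when absent.
    """

    network: RegulatoryNetwork | None = None
    node_path: str | None = None
    edge_paths: dict[Relation, str] = field(default_factory=dict)

    ks: Sequence[int] = (3, 4, 5)
    #: replicate count for the null model; either one integer for all sizes
    #: or a per-k mapping (the k=5 census is the expensive one)
    n_random: int | dict[int, int] = 1000
    exchanges_per_edge: int = 3
    criteria: CompositeFFLCriteria = field(default_factory=CompositeFFLCriteria)
    strict_ffl: bool = False

    expression_matrices: Sequence[ExpressionMatrix] | None = None
    drug_records: Sequence[DrugRecord] | None = None
    universe_size: int = 20000
    alpha: float = 0.05
    tail: str = "upper"

    out_dir: str | None = None
    seed: int = 0

    def n_random_for(self, k: int) -> int:
        if isinstance(self.n_random, dict):
            return self.n_random[k]
        return self.n_random

    def resolve_network(self) -> RegulatoryNetwork:
        if self.network is not None:
            return self.network
        if self.node_path is None:
            raise ValueError("config must supply a network or node/edge paths")
        net, _ = network_io.load_network_tables(self.node_path, self.edge_paths)
        return net


def _cfmsn_regulatory_pairs(cfmsn: CFMSN) -> list[tuple[str, str]]:
    return sorted({(s, t) for s, t, _ in cfmsn.network.edges})


def run_pipeline(
    config: PipelineConfig,
    stats_by_k: dict[int, MotifStatistics] | None = None,
) -> dict:
    """Execute all requested stages and return the report dict.

    When ``config.out_dir`` is set, every intermediate table is persisted
    as TSV next to a ``report.json``, so each report number can be
    recomputed from the persisted tables.  ``stats_by_k`` may carry motif
    statistics already computed with the config's own substream seeds (the
    caller's shortcut when it needed the CFMSN earlier); any size not
    supplied is computed here.
    """
    net = config.resolve_network()
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
        network_io.write_node_table(net, out / "network_nodes.tsv")
        network_io.write_edge_table(net, out / "network_edges.tsv")

    report: dict = {
        "config": {
            "ks": list(config.ks),
            "n_random": {str(k): config.n_random_for(k) for k in config.ks},
            "exchanges_per_edge": config.exchanges_per_edge,
            "z_min": config.criteria.z_min,
            "p_max": config.criteria.p_max,
            "strict_ffl": config.strict_ffl,
            "universe_size": config.universe_size,
            "alpha": config.alpha,
            "tail": config.tail,
            "seed": config.seed,
        },
        "network": net.summary(),
    }

    # census + significance per size
    stats_by_k = dict(stats_by_k) if stats_by_k else {}
    for k in config.ks:
        if k not in stats_by_k:
            n_rand = config.n_random_for(k)
            logger.info("motif statistics for k=%d (n_random=%d)", k, n_rand)
            cfg = RandomizationConfig(
                n_random=n_rand,
                exchanges_per_edge=config.exchanges_per_edge,
                seed=substream_seed(config.seed, f"significance_k{k}"),
            )
            stats_by_k[k] = motif_statistics(net, k, cfg, keep_instances=True)
        stats = stats_by_k[k]
        if out:
            pd.DataFrame(stats.to_rows()).to_csv(
                out / f"motif_stats_k{k}.tsv", sep="\t", index=False
            )

    cfmsn, selection = select_and_build_cfmsn(
        net, stats_by_k, config.criteria, strict=config.strict_ffl
    )
    report["motifs"] = {
        str(k): {
            "n_classes": selection.per_k[k]["n_classes"],
            "n_significant": selection.per_k[k]["n_significant"],
            "n_qualifying": selection.per_k[k]["n_qualifying"],
            "winning_label": selection.per_k[k].get("winning_label"),
            "z": selection.per_k[k].get("z"),
            "p": selection.per_k[k].get("p"),
            "n_instances": selection.per_k[k].get("n_instances"),
        }
        for k in selection.per_k
    }
    report["cfmsn"] = {
        "composition": cfmsn.composition(),
        "n_nodes": cfmsn.network.n_nodes,
        "n_edges": cfmsn.network.n_edges,
        "warnings": selection.warnings,
    }
    if out:
        network_io.write_node_table(cfmsn.network, out / "cfmsn_nodes.tsv")
        network_io.write_edge_table(cfmsn.network, out / "cfmsn_edges.tsv")

    profile = compute_node_metrics(net)
    fit = fit_degree_power_law(profile)
    report["topology"] = {
        "power_law": {"a": fit.a, "b": fit.b, "r_squared": fit.r_squared},
        "mean_degree": float(profile["degree"].mean()),
    }
    if out:
        profile.to_csv(out / "topology_profile.tsv", sep="\t")

    # expression validation (optional)
    if config.expression_matrices:
        matrices = list(config.expression_matrices)
        cfmsn_mirnas = cfmsn.network.nodes_with_role("miRNA")
        de_flagged: list[str] = []
        de_tables = []
        for i, m in enumerate(matrices):
            de = differential_expression(m)
            de_tables.append(de)
            subset = [f for f in cfmsn_mirnas if f in de.index]
            de_flagged.extend(de.loc[subset].query("is_de").index.tolist())
            if out:
                de.to_csv(out / f"differential_expression_{i}.tsv", sep="\t")
        pairs = _cfmsn_regulatory_pairs(cfmsn)
        corr = correlate_pairs(pairs, matrices)
        report["expression"] = {
            "de_flagged_cfmsn_mirnas": sorted(set(de_flagged)),
            "n_pairs": corr.n_total,
            "n_significant_pairs": corr.n_significant,
            "fraction_significant": corr.fraction_significant,
            "n_skipped_pairs": len(corr.skipped),
        }
        if out:
            corr.table.to_csv(out / "pair_correlations.tsv", sep="\t", index=False)
    else:
        report["expression"] = "skipped"

    # drug association (optional)
    if config.drug_records is not None:
        kept = filter_drugs(config.drug_records)
        cfmsn_mirnas = set(cfmsn.network.nodes_with_role("miRNA"))
        mirna_targets: dict[str, set[str]] = {}
        for s, t, rel in net.edges:
            if rel is Relation.MIRNA_REPRESSES_GENE and s in cfmsn_mirnas:
                mirna_targets.setdefault(s, set()).add(t)
        results = mirna_drug_association(
            mirna_targets,
            list(config.drug_records),
            universe=config.universe_size,
            alpha=config.alpha,
            tail=config.tail,
        )
        sig = [r for r in results if r.is_significant]
        report["drugs"] = {
            "n_drugs": len(config.drug_records),
            "n_drugs_after_curation": len(kept),
            "n_pairs_tested": len(results),
            "n_significant_pairs": len(sig),
            "n_significant_mirnas": len({r.mirna for r in sig}),
            "n_significant_drugs": len({r.drug_id for r in sig}),
        }
        if out:
            association_table(results).to_csv(
                out / "mirna_drug_associations.tsv", sep="\t", index=False
            )
    else:
        report["drugs"] = "skipped"

    if out:
        (out / "report.json").write_bytes(report_bytes(report))
    return report


def _json_safe(obj):
    """Strict-JSON view: non-finite floats become strings ('inf' marks the
    sd=0 Z-score sentinel of a class never seen under the null)."""
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, float) and not math.isfinite(obj):
        return repr(obj)  # 'inf', '-inf', 'nan'
    return obj


def report_bytes(report: dict) -> bytes:
    """Canonical serialization used for the determinism contract."""
    return (
        json.dumps(_json_safe(report), indent=2, sort_keys=True, allow_nan=False)
        + "\n"
    ).encode("utf-8")
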
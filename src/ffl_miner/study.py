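"""The synthetic study scenario: one fully self-contained analogue of the
TF-miRNA-gene analysis, from network assembly to drug association.

Two network scales are used.  The *global* scale mirrors the merged
TF-miRNA-gene network's published composition (16 TFs / 76 miRNAs / 156
genes with per-relation edge counts 60/276/47/39/222/194) and carries the
topology analysis.  The *motif* scale (8 TFs / 20 miRNAs / 40 genes, ~185
edges) carries the 3/4/5-node census and null-model significance runs,
where the 5-node census cost grows steeply with density; composite FFLs of
every size are planted into it so the selection stage has a real signal to
find.  Replicate counts are likewise scaled per size (200/100/30 for
k=3/4/5).

Everything derives from one global seed via per-component substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .drugs import DrugRecord
from .expression import ExpressionMatrix
from .ffl import CFMSN
from .network import Relation, RegulatoryNetwork
from .pipeline import PipelineConfig, run_pipeline
from .synthetic import (
    TMGN_SCALE_CONFIG,
    ExpressionGenConfig,
    NetworkGenConfig,
    PlantedInstance,
    generate_background_network,
    generate_drug_fixture,
    generate_expression_profiles,
    plant_composite_ffls,
    substream_seed,
)

#: background for the motif census / significance stage
MOTIF_SCALE_CONFIG = NetworkGenConfig(
    n_tf=8,
    n_mirna=20,
    n_gene=40,
    edges_per_relation={
        Relation.TF_ACTIVATES_MIRNA: 14,
        Relation.MIRNA_REPRESSES_GENE: 45,
        Relation.TF_REGULATES_GENE: 16,
        Relation.MIRNA_REPRESSES_TF: 12,
        Relation.GENE_GENE: 22,
        Relation.MIRNA_MIRNA: 14,
    },
)

#: planted composite-FFL instances per motif size
PLANTED_PER_K = {3: 6, 4: 4, 5: 3}

#: null-model replicates per motif size (scaled to census cost)
N_RANDOM_PER_K = {3: 200, 4: 100, 5: 30}

#: Pearson correlation planted on matched CFMSN pairs, and the log2
#: fold change planted on one CFMSN miRNA (one clearly DE regulator)
STUDY_PAIR_RHO = 0.75
STUDY_LOGFC = 3.0
STUDY_NOISE_SD = 1.0
N_SAMPLES_PER_GROUP = 8

N_DRUGS = 38
TARGETS_PER_DRUG = (2, 6)


def build_motif_network(
    seed: int,
) -> tuple[RegulatoryNetwork, dict[int, list[PlantedInstance]]]:
    """Motif-scale background with composite FFLs of all three sizes
    planted on (preferentially) edge-free node tuples."""
    net = generate_background_network(
        replace(MOTIF_SCALE_CONFIG, seed=substream_seed(seed, "background"))
    )
    planted: dict[int, list[PlantedInstance]] = {}
    for k, n in PLANTED_PER_K.items():
        net, planted[k] = plant_composite_ffls(
            net, k, n, seed=substream_seed(seed, f"plant_k{k}")
        )
    return net, planted


def matched_pairs(cfmsn: CFMSN) -> list[tuple[str, str]]:
    """A maximal greedy matching of CFMSN regulatory pairs: each feature at
    most once, so pairwise correlations can be planted independently."""
    used: set[str] = set()
    out: list[tuple[str, str]] = []
    for s, t, _ in sorted(cfmsn.network.edges):
        if s not in used and t not in used:
            out.append((s, t))
            used.update((s, t))
    return out


def build_expression(
    net: RegulatoryNetwork, cfmsn: CFMSN, seed: int
) -> tuple[ExpressionMatrix, dict]:
    """Two-group expression over every network feature, with correlation
    planted on a matching of CFMSN pairs and a strong fold change on the
    first CFMSN miRNA (the scenario's single clearly-DE regulator)."""
    features = sorted(net.roles)
    pairs = matched_pairs(cfmsn)
    mirnas = cfmsn.network.nodes_with_role("miRNA")
    logfc = {mirnas[0]: STUDY_LOGFC} if mirnas else {}
    cfg = ExpressionGenConfig(
        n_samples_per_group=N_SAMPLES_PER_GROUP,
        planted_logfc=logfc,
        pair_rho=STUDY_PAIR_RHO,
        noise_sd=STUDY_NOISE_SD,
        seed=substream_seed(seed, "expression"),
    )
    sx = generate_expression_profiles(features, pairs, cfg)
    return sx.matrix, sx.truth


def build_drugs(net: RegulatoryNetwork, seed: int) -> list[DrugRecord]:
    genes = net.nodes_with_role("gene")
    fx = generate_drug_fixture(
        genes,
        N_DRUGS,
        targets_per_drug=TARGETS_PER_DRUG,
        seed=substream_seed(seed, "drugs"),
    )
    return fx.records


@dataclass
class StudyResult:
    report: dict
    network: RegulatoryNetwork
    planted: dict[int, list[PlantedInstance]]
    global_network: RegulatoryNetwork | None = None


def run_study(
    seed: int,
    out_dir: str | None = None,
    ks: tuple[int, ...] = (3, 4, 5),
    with_expression: bool = True,
    with_drugs: bool = True,
) -> StudyResult:
    """Run the full pipeline on the synthetic study scenario."""
    net, planted = build_motif_network(seed)

    # first pass: motif statistics + CFMSN without the optional stages, so
    # expression/drug fixtures can be matched to the CFMSN features
    base_cfg = PipelineConfig(
        network=net,
        ks=ks,
        n_random={k: N_RANDOM_PER_K[k] for k in ks},
        seed=seed,
    )
    expression = None
    drug_records = None
    stats = None
    if with_expression or with_drugs:
        from .ffl import select_and_build_cfmsn
        from .significance import RandomizationConfig, motif_statistics

        # computed once with the pipeline's own substream seeds and handed
        # back to run_pipeline, so the CFMSN features are known before the
        # expression/drug fixtures are generated
        stats = {
            k: motif_statistics(
                net,
                k,
                RandomizationConfig(
                    n_random=N_RANDOM_PER_K[k],
                    seed=substream_seed(seed, f"significance_k{k}"),
                ),
                keep_instances=True,
            )
            for k in ks
        }
        cfmsn, _ = select_and_build_cfmsn(net, stats)
        if with_expression:
            matrix, _ = build_expression(net, cfmsn, seed)
            expression = [matrix]
        if with_drugs:
            drug_records = build_drugs(net, seed)

    cfg = replace(
        base_cfg,
        expression_matrices=expression,
        drug_records=drug_records,
        universe_size=len(net.nodes_with_role("gene")),
        out_dir=out_dir,
    )
    report = run_pipeline(cfg, stats_by_k=stats)
    return StudyResult(report=report, network=net, planted=planted)


def run_global_network_analysis(seed: int) -> dict:
    """Assemble the global-scale network and fit its degree distribution;
    returns summary + power-law numbers."""
    from .topology import compute_node_metrics, fit_degree_power_law

    cfg = replace(TMGN_SCALE_CONFIG, seed=substream_seed(seed, "global"))
    net = generate_background_network(cfg)
    profile = compute_node_metrics(net)
    fit = fit_degree_power_law(profile)
    out = net.summary()
    out["power_law"] = {"a": fit.a, "b": fit.b, "r_squared": fit.r_squared}
    return out
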
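"""Drug-target association by cumulative hypergeometric overlap.

The overlap between a miRNA's target-gene set (size K) and a drug's
target-gene set (size N) within a gene universe of size M is scored with
the hypergeometric distribution.  The lower cumulative form

    F(x | M, K, N) = sum_{i=0}^{x} C(K, i) C(M-K, N-i) / C(M, N)

is computed with exact integer arithmetic (a single correctly-rounded float
division at the end).  Over-representation of an overlap of x genes is the
upper tail P(X >= x) = 1 - F(x-1), the default here; ``tail="lower"``
scores F(x) instead.

A drug-curation filter keeps FDA-approved, marketed, APRD-numbered drugs
that are not carcinogenic, illegal, mixture-only, or vaginally
administered; drugs with fewer than two target genes are excluded from
association testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from statsmodels.stats.multitest import multipletests

FLAG_COLUMNS = (
    "approved",
    "marketed",
    "carcinogenic",
    "illegal",
    "mixture_only",
    "vaginal_route",
    "has_aprd",
)


@dataclass
class DrugRecord:
    drug_id: str
    name: str
    targets: frozenset[str]
    approved: bool = True
    marketed: bool = True
    carcinogenic: bool = False
    illegal: bool = False
    mixture_only: bool = False
    vaginal_route: bool = False
    has_aprd: bool = True


@dataclass
class AssociationResult:
    mirna: str
    drug_id: str
    drug_name: str
    x: int
    K: int
    N: int
    M: int
    p_value: float
    is_significant: bool


def _check_params(M: int, K: int, N: int) -> None:
    if K > M or N > M:
        raise ValueError(f"K={K} and N={N} must not exceed M={M}")
    if min(M, K, N) < 0:
        raise ValueError("M, K, N must be non-negative")


def cumulative_hypergeometric(x: int, M: int, K: int, N: int) -> float:
    """Lower cumulative hypergeometric F(x | M, K, N), exact."""
    _check_params(M, K, N)
    if x < 0:
        return 0.0
    hi = min(K, N)
    x = min(x, hi)
    lo = max(0, N - (M - K))
    num = sum(comb(K, i) * comb(M - K, N - i) for i in range(lo, x + 1) if i >= 0)
    return num / comb(M, N)


def upper_tail_hypergeometric(x: int, M: int, K: int, N: int) -> float:
    """P(X >= x), computed by direct summation (not 1 - cdf) for accuracy."""
    _check_params(M, K, N)
    hi = min(K, N)
    if x <= max(0, N - (M - K)):
        return 1.0
    if x > hi:
        return 0.0
    num = sum(comb(K, i) * comb(M - K, N - i) for i in range(x, hi + 1))
    return num / comb(M, N)


def filter_drugs(drugs: Iterable[DrugRecord]) -> list[DrugRecord]:
    """Curation screen: approved and marketed and APRD-numbered, and none
    of carcinogenic / illegal / mixture-only / vaginal-route."""
    return [
        d
        for d in drugs
        if d.approved
        and d.marketed
        and d.has_aprd
        and not d.carcinogenic
        and not d.illegal
        and not d.mixture_only
        and not d.vaginal_route
    ]


def mirna_drug_association(
    mirna_targets: Mapping[str, Iterable[str]],
    drugs: Sequence[DrugRecord],
    universe: int | Iterable[str] = 20000,
    alpha: float = 0.05,
    tail: str = "upper",
    min_drug_targets: int = 2,
) -> list[AssociationResult]:
    """Score every (miRNA, drug) pair.

    ``universe`` may be a size (M) or an explicit gene universe, in which
    case target sets are intersected with it before counting.  Drugs with
    fewer than ``min_drug_targets`` targets are dropped.
    """
    if tail not in ("upper", "lower"):
        raise ValueError("tail must be 'upper' or 'lower'")
    universe_set: frozenset[str] | None
    if isinstance(universe, int):
        M = universe
        universe_set = None
    else:
        universe_set = frozenset(universe)
        M = len(universe_set)

    def clip(genes: Iterable[str]) -> frozenset[str]:
        gs = frozenset(genes)
        return gs & universe_set if universe_set is not None else gs

    results: list[AssociationResult] = []
    for drug in drugs:
        targets = clip(drug.targets)
        if len(targets) < min_drug_targets:
            continue
        for mirna, mgenes in sorted(mirna_targets.items()):
            mset = clip(mgenes)
            x = len(mset & targets)
            K, N = len(mset), len(targets)
            _check_params(M, K, N)
            if tail == "upper":
                p = upper_tail_hypergeometric(x, M, K, N)
            else:
                p = cumulative_hypergeometric(x, M, K, N)
            results.append(
                AssociationResult(
                    mirna=mirna,
                    drug_id=drug.drug_id,
                    drug_name=drug.name,
                    x=x,
                    K=K,
                    N=N,
                    M=M,
                    p_value=p,
                    is_significant=p < alpha,
                )
            )
    return results


def association_table(results: Sequence[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mirna": r.mirna,
                "drug_id": r.drug_id,
                "drug_name": r.drug_name,
                "x": r.x,
                "K": r.K,
                "N": r.N,
                "M": r.M,
                "p_value": r.p_value,
                "is_significant": r.is_significant,
            }
            for r in results
        ],
        columns=[
            "mirna", "drug_id", "drug_name", "x", "K", "N", "M",
            "p_value", "is_significant",
        ],
    )


def read_gmt(path: str | Path) -> dict[str, frozenset[str]]:
    """GMT gene-set file: name <tab> description <tab> gene1 <tab> ..."""
    sets: dict[str, frozenset[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = frozenset(g for g in parts[2:] if g)
    return sets


def gene_set_enrichment(
    query: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    universe: int | Iterable[str] = 20000,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a query gene list against
    gene sets, with BH fdr, sorted by p."""
    query_set = frozenset(query)
    if not query_set:
        raise ValueError("query gene list is empty")
    if not gene_sets:
        raise ValueError("no gene sets supplied")
    if isinstance(universe, int):
        M = universe
        universe_set = None
    else:
        universe_set = frozenset(universe)
        M = len(universe_set)

    def clip(genes):
        gs = frozenset(genes)
        return gs & universe_set if universe_set is not None else gs

    q = clip(query_set)
    rows = []
    for name, members in gene_sets.items():
        ms = clip(members)
        x = len(q & ms)
        rows.append(
            {
                "gene_set": name,
                "x": x,
                "K": len(q),
                "N": len(ms),
                "M": M,
                "p_value": upper_tail_hypergeometric(x, M, len(q), len(ms)),
            }
        )
    df = pd.DataFrame(rows)
    df["fdr"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df.sort_values(["p_value", "gene_set"]).reset_index(drop=True)


def read_drug_tables(
    target_path: str | Path, metadata_path: str | Path
) -> list[DrugRecord]:
    """Drug-target TSV (drug_id, name, gene) + metadata TSV (drug_id plus
    one boolean column per curation flag)."""
    targets = pd.read_csv(target_path, sep="\t", dtype=str)
    meta = pd.read_csv(metadata_path, sep="\t").set_index("drug_id")
    by_drug: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for _, row in targets.iterrows():
        by_drug.setdefault(row["drug_id"], set()).add(row["gene"])
        names[row["drug_id"]] = row["name"]
    records = []
    for drug_id in sorted(set(by_drug) | set(meta.index.astype(str))):
        flags = (
            {c: bool(meta.loc[drug_id, c]) for c in FLAG_COLUMNS}
            if drug_id in meta.index
            else {}
        )
        records.append(
            DrugRecord(
                drug_id=drug_id,
                name=names.get(drug_id, drug_id),
                targets=frozenset(by_drug.get(drug_id, ())),
                **flags,
            )
        )
    return records
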
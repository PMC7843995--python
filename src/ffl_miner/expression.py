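"""Expression-based validation of the motif subnetwork.

Two operations: (1) two-group differential expression of features (Welch t
with Benjamini-Hochberg FDR; a feature is flagged when raw p < 0.05 and
|logFC| > 1), and (2) Pearson correlation of regulator-target pairs (a pair
is significant when |r| > 0.5 and p < 0.05).  Expression values are assumed
to be on log2 scale, so logFC is a difference of group means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DE_P_MAX = 0.05
DE_LOGFC_MIN = 1.0
COR_R_MIN = 0.5
COR_P_MAX = 0.05


@dataclass
class ExpressionMatrix:
    """features x samples matrix plus a sample -> group map with exactly
    two groups (case-like listed first)."""

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate feature ids")
        missing = set(self.values.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without a group: {sorted(missing)}")
        counts = self.groups.loc[list(self.values.columns)].value_counts()
        if len(counts) != 2:
            raise ValueError("exactly two groups required")
        if (counts < 2).any():
            raise ValueError("each group needs >= 2 samples")

    def group_columns(self) -> tuple[list[str], list[str]]:
        g = self.groups.loc[list(self.values.columns)]
        levels = sorted(g.unique())
        return (
            [c for c in self.values.columns if g[c] == levels[0]],
            [c for c in self.values.columns if g[c] == levels[1]],
        )


def differential_expression(
    matrix: ExpressionMatrix,
    p_max: float = DE_P_MAX,
    logfc_min: float = DE_LOGFC_MIN,
) -> pd.DataFrame:
    """Per-feature logFC (group1 mean minus group2 mean, groups in sorted
    label order), Welch-t p, BH fdr, and the is_de flag."""
    cols1, cols2 = matrix.group_columns()
    a = matrix.values[cols1].to_numpy(dtype=float)
    b = matrix.values[cols2].to_numpy(dtype=float)
    logfc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    # zero variance in both groups: p undefined by the t formula; equal
    # means -> no evidence (p=1), different means -> deterministic shift
    degenerate = np.isnan(p)
    p = np.where(degenerate & (logfc == 0), 1.0, p)
    p = np.where(degenerate & (logfc != 0), 0.0, p)
    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "logFC": logfc,
            "p_value": p,
            "fdr": fdr,
            "is_de": (p < p_max) & (np.abs(logfc) > logfc_min),
        },
        index=matrix.values.index,
    )


@dataclass
class CorrelationSummary:
    table: pd.DataFrame
    n_significant: int
    n_total: int
    skipped: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def fraction_significant(self) -> float:
        return self.n_significant / self.n_total if self.n_total else 0.0


def _locate(feature: str, matrices: Sequence[ExpressionMatrix]) -> ExpressionMatrix | None:
    for m in matrices:
        if feature in m.values.index:
            return m
    return None


def correlate_pairs(
    pairs: Iterable[tuple[str, str]],
    matrices: ExpressionMatrix | Sequence[ExpressionMatrix],
    sample_alignment: Mapping[str, str] | None = None,
    r_min: float = COR_R_MIN,
    p_max: float = COR_P_MAX,
) -> CorrelationSummary:
    """Pearson correlation per pair on shared samples.

    With two matrices (e.g. a miRNA and a gene matrix) samples are matched
    by name, or through ``sample_alignment`` mapping first-matrix sample
    names onto second-matrix names.  Pairs with a missing feature are
    skipped with a reason; constant vectors are flagged not significant.
    """
    if isinstance(matrices, ExpressionMatrix):
        matrices = [matrices]
    rows = []
    skipped: list[tuple[str, str, str]] = []
    for f1, f2 in pairs:
        m1 = _locate(f1, matrices)
        m2 = _locate(f2, matrices)
        if m1 is None or m2 is None:
            missing = f1 if m1 is None else f2
            skipped.append((f1, f2, f"feature {missing!r} not found"))
            continue
        if m1 is m2:
            shared1 = shared2 = list(m1.values.columns)
        else:
            align = sample_alignment or {c: c for c in m1.values.columns}
            shared1 = [c for c in m1.values.columns if align.get(c) in set(m2.values.columns)]
            shared2 = [align[c] for c in shared1]
        if len(shared1) < 3:
            skipped.append((f1, f2, "fewer than 3 shared samples"))
            continue
        x = m1.values.loc[f1, shared1].to_numpy(dtype=float)
        y = m2.values.loc[f2, shared2].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append(
                {
                    "feature_1": f1,
                    "feature_2": f2,
                    "n": len(x),
                    "pearson_r": np.nan,
                    "p_value": np.nan,
                    "is_significant": False,
                    "note": "constant vector",
                }
            )
            continue
        r, p = stats.pearsonr(x, y)
        rows.append(
            {
                "feature_1": f1,
                "feature_2": f2,
                "n": len(x),
                "pearson_r": float(r),
                "p_value": float(p),
                "is_significant": bool(abs(r) > r_min and p < p_max),
                "note": "",
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "feature_1",
            "feature_2",
            "n",
            "pearson_r",
            "p_value",
            "is_significant",
            "note",
        ],
    )
    return CorrelationSummary(
        table=table,
        n_significant=int(table["is_significant"].sum()) if len(table) else 0,
        n_total=len(table),
        skipped=skipped,
    )
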
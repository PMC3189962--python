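"""Integration of binding classes with gene expression.

Rank-based expression categories (default quintiles), percent-bound
curves per category, and Welch two-sample tests of the multi+MYC class
against the other co-binding classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .classes import COBIND_CLASSES, PromoterBindingSummary
from .types import ExpressionRecord

__all__ = [
    "ExpressionCategories",
    "ClassExpressionReport",
    "expression_categories",
    "percent_bound_by_category",
    "class_expression_test",
]

logger = logging.getLogger(__name__)


@dataclass
class ExpressionCategories:
    """Contiguous rank-quantile expression categories (0 = lowest)."""

    n_categories: int
    assignment: Dict[str, int]
    boundaries: List[Tuple[float, float]]   # per category (min, max) expression

    def genes_in(self, category: int) -> List[str]:
        return [g for g, c in self.assignment.items() if c == category]


@dataclass
class ClassExpressionReport:
    """Per-class expression moments and Welch tests vs multi+MYC."""

    dataset_label: str
    class_stats: pd.DataFrame          # index: cobind_class; n, mean, sd
    tests: pd.DataFrame                # other class vs multi+MYC: t, df, p

    def summary(self) -> str:
        lines = [f"Expression by co-binding class [{self.dataset_label}]", ""]
        lines.append(self.class_stats.to_string(float_format=lambda x: f"{x:.3f}"))
        lines.append("")
        lines.append("Welch t-tests: multi+MYC vs ...")
        lines.append(self.tests.to_string(float_format=lambda x: f"{x:.3g}"))
        return "\n".join(lines)


def expression_categories(
    expression: Sequence[ExpressionRecord], n: int = 5
) -> ExpressionCategories:
    """Split genes into ``n`` near-equal rank quantiles of expression.

    Ties keep their stable-sorted position; category sizes differ by at
    most one.
    """
    if n < 2:
        raise ValueError("need at least 2 categories")
    if len(expression) < n:
        raise ValueError(f"need >= {n} genes for {n} categories")
    values = np.asarray([r.expression for r in expression], dtype=float)
    order = np.argsort(values, kind="stable")
    chunks = np.array_split(order, n)
    assignment: Dict[str, int] = {}
    boundaries: List[Tuple[float, float]] = []
    for cat, chunk in enumerate(chunks):
        for i in chunk:
            assignment[expression[i].gene_id] = cat
        vals = values[chunk]
        boundaries.append((float(vals.min()), float(vals.max())))
    return ExpressionCategories(n_categories=n, assignment=assignment, boundaries=boundaries)


def percent_bound_by_category(
    summaries: Sequence[PromoterBindingSummary],
    categories: ExpressionCategories,
    stratify_by: str = "cobind_class",
) -> pd.DataFrame:
    """Percent of promoters bound, per expression category and stratum.

    ``stratify_by="factor"`` gives OTX2 / MYC columns (any binding of
    that factor); ``"cobind_class"`` gives one column per co-binding
    class.  The denominator is all promoters in the category that carry
    a binding summary.  Promoters without an expression category are
    excluded and logged.
    """
    cat_members: Dict[int, List[PromoterBindingSummary]] = {
        c: [] for c in range(categories.n_categories)
    }
    n_dropped = 0
    for s in summaries:
        cat = categories.assignment.get(s.gene_id)
        if cat is None:
            n_dropped += 1
            continue
        cat_members[cat].append(s)
    if n_dropped:
        logger.info("%d promoters without expression category excluded", n_dropped)
    for c, members in cat_members.items():
        if not members:
            raise ValueError(f"expression category {c} contains no promoters")

    if stratify_by == "factor":
        strata = {
            "OTX2": lambda s: s.n_otx2_peaks > 0,
            "MYC": lambda s: s.myc_bound,
        }
    elif stratify_by == "cobind_class":
        strata = {
            name: (lambda s, name=name: s.cobind_class == name)
            for name in COBIND_CLASSES
            if name not in ("unbound",)
        }
    else:
        raise ValueError("stratify_by must be 'factor' or 'cobind_class'")

    rows = {}
    for name, pred in strata.items():
        rows[name] = [
            100.0 * sum(pred(s) for s in cat_members[c]) / len(cat_members[c])
            for c in range(categories.n_categories)
        ]
    df = pd.DataFrame(rows)
    df.index.name = "category"
    return df


def _welch(x: np.ndarray, y: np.ndarray) -> Tuple[float, float, float]:
    """Welch t, degrees of freedom and two-sided p; degenerate variances
    are reported as NaN rather than raising."""
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return 0.0, float(len(x) + len(y) - 2), 1.0
        return float("nan"), float("nan"), float("nan")
    se2 = vx / len(x) + vy / len(y)
    df = se2**2 / ((vx / len(x)) ** 2 / (len(x) - 1) + (vy / len(y)) ** 2 / (len(y) - 1))
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(df), float(p)


def class_expression_test(
    expression: Sequence[ExpressionRecord],
    summaries: Sequence[PromoterBindingSummary],
    dataset_label: str = "",
    reference_class: str = "multi+MYC",
    pooled: bool = False,
    equal_var: bool = False,
) -> ClassExpressionReport:
    """Two-sample tests of ``reference_class`` expression against the
    other co-binding classes.

    ``pooled=True`` tests the reference class against all other genes
    pooled instead of class by class.  Welch's unequal-variance test by
    default; ``equal_var=True`` switches to the pooled-variance test.
    Genes without expression are excluded and logged.
    """
    expr = {r.gene_id: r.expression for r in expression}
    groups: Dict[str, List[float]] = {c: [] for c in COBIND_CLASSES}
    n_missing = 0
    for s in summaries:
        if s.gene_id not in expr:
            n_missing += 1
            continue
        groups[s.cobind_class].append(expr[s.gene_id])
    if n_missing:
        logger.info("%d promoters without expression measurement excluded", n_missing)

    stats_rows = {}
    for c, vals in groups.items():
        arr = np.asarray(vals)
        stats_rows[c] = {
            "n": len(arr),
            "mean": float(arr.mean()) if len(arr) else float("nan"),
            "sd": float(arr.std(ddof=1)) if len(arr) > 1 else float("nan"),
        }
    class_stats = pd.DataFrame(stats_rows).T

    ref = np.asarray(groups[reference_class])
    if len(ref) < 2:
        raise ValueError(f"reference class {reference_class} has fewer than 2 genes")
    test_rows = {}
    if pooled:
        others = np.asarray(
            [v for c, vals in groups.items() if c != reference_class for v in vals]
        )
        if len(others) >= 2:
            if equal_var:
                t, p = stats_ttest(ref, others, equal_var=True)
                df = float(len(ref) + len(others) - 2)
            else:
                t, df, p = _welch(ref, others)
            test_rows["all-others"] = {"t": t, "df": df, "p": p}
    else:
        for c, vals in groups.items():
            if c == reference_class:
                continue
            arr = np.asarray(vals)
            if len(arr) < 2:
                continue
            if equal_var:
                t, p = stats_ttest(ref, arr, equal_var=True)
                df = float(len(ref) + len(arr) - 2)
            else:
                t, df, p = _welch(ref, arr)
            test_rows[c] = {"t": t, "df": df, "p": p}
    tests = pd.DataFrame(test_rows).T
    return ClassExpressionReport(
        dataset_label=dataset_label, class_stats=class_stats, tests=tests
    )


def stats_ttest(x: np.ndarray, y: np.ndarray, equal_var: bool) -> Tuple[float, float]:
    t, p = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(t), float(p)
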
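"""Statistical kernels and summary tables.

Thin, explicit wrappers around scipy's exact/nonparametric machinery with
the conventions fixed once for the whole package: two-sided Fisher p-values
sum the probabilities of all tables as or less likely than the observed one
("minlike"); the rank-sum test is an exact permutation test for small
samples (handling ties by midranks) and a tie-corrected normal
approximation otherwise; the two-proportion test is the chi-square test
with continuity correction.  No multiplicity correction is applied
anywhere; callers see raw p-values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps

log = logging.getLogger(__name__)


@dataclass
class TestResult:
    method: str
    statistic: float
    p_value: float
    alternative: str = "two_sided"
    sizes: tuple = ()
    table: tuple = ()
    flagged: str | None = None

    def __post_init__(self):
        if not 0 <= self.p_value <= 1 + 1e-12:
            raise ValueError("p-value outside [0, 1]")


def fisher_exact(table, alternative: str = "two_sided") -> TestResult:
    """Exact hypergeometric test on a 2x2 table."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("fisher_exact needs a non-negative 2x2 table")
    alt = {"two_sided": "two-sided", "greater": "greater", "less": "less"}[alternative]
    odds, p = sps.fisher_exact(t, alternative=alt)
    return TestResult(
        "fisher_exact", float(odds), float(min(p, 1.0)), alternative,
        table=tuple(map(tuple, t)),
    )


def _midranks(values) -> np.ndarray:
    return sps.rankdata(values)


def wilcoxon_rank_sum(x, y, exact_below: int = 20) -> TestResult:
    """Rank-sum (Mann-Whitney) test.

    Exact permutation p-value when the pooled sample is at most
    ``exact_below`` (ties handled by midranks); otherwise the normal
    approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return TestResult(
            "wilcoxon_rank_sum", 0.0, 1.0, sizes=(len(x), len(y)),
            flagged="degenerate: all observations tied",
        )
    n1, n = len(x), len(pooled)
    ranks = _midranks(pooled)
    w_obs = ranks[:n1].sum()
    if n <= exact_below:
        sums = np.array(
            [ranks[list(ix)].sum() for ix in combinations(range(n), n1)]
        )
        p_low = np.mean(sums <= w_obs + 1e-9)
        p_high = np.mean(sums >= w_obs - 1e-9)
        p = min(1.0, 2 * min(p_low, p_high))
        return TestResult(
            "wilcoxon_rank_sum_exact", float(w_obs), float(p), sizes=(n1, n - n1)
        )
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return TestResult(
        "wilcoxon_rank_sum", float(res.statistic), float(res.pvalue),
        sizes=(n1, n - n1),
    )


def two_proportion_test(k1: int, n1: int, k2: int, n2: int) -> TestResult:
    """Chi-square test (with continuity correction) for p1 = p2."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("successes must lie within sample sizes")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
    if table.sum(axis=0).min() == 0:  # all successes or all failures
        return TestResult(
            "two_proportion", 0.0, 1.0, sizes=(n1, n2),
            table=tuple(map(tuple, table)), flagged="degenerate margin",
        )
    stat, p, _, _ = sps.chi2_contingency(table, correction=True)
    return TestResult(
        "two_proportion", float(stat), float(p), sizes=(n1, n2),
        table=tuple(map(tuple, table)),
    )


def chisq_independence(table) -> TestResult:
    """Pearson chi-square test of independence on an r x c table."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or min(t.shape) < 2:
        raise ValueError("independence test needs at least a 2x2 table")
    if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
        raise ValueError("table has a zero margin")
    stat, p, dof, _ = sps.chi2_contingency(t, correction=False)
    return TestResult(
        "chisq_independence", float(stat), float(p),
        table=tuple(map(tuple, t.tolist())),
    )


# ---------------------------------------------------------------------------
# percentages and summary tables


def round_half_up(v: float, decimals: int = 0) -> float:
    scale = 10**decimals
    return math.floor(v * scale + 0.5) / scale


def percentage(count: int, total: int, decimals: int = 0) -> float:
    """Percentage at the stated printed precision (half-up rounding)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_up(100.0 * count / total, decimals)


def display_percentage(count: int, total: int) -> float:
    """Percentage convention of the class table: integers, except values
    below 1% shown to one decimal."""
    v = 100.0 * count / total
    if 0 < v < 1:
        return round_half_up(v, 1)
    return round_half_up(v, 0)


CLASS_ROWS = (
    "blunt",
    "microhomology",
    "long_identity",  # simple ends with >20 bp of identity (SSA-scale)
    "complex",
    "complex_mh",
)


@dataclass
class SummaryTable:
    rows: list[tuple[str, int, float]]  # (label, count, percentage)
    total: int
    notes: dict = field(default_factory=dict)

    def count(self, label: str) -> int:
        return dict((r[0], r[1]) for r in self.rows)[label]

    def pct(self, label: str) -> float:
        return dict((r[0], r[2]) for r in self.rows)[label]


def class_table_from_counts(counts, total: int | None = None) -> SummaryTable:
    counts = list(counts)
    if len(counts) != len(CLASS_ROWS):
        raise ValueError(f"expected {len(CLASS_ROWS)} class counts")
    if total is None:
        total = sum(counts)
    elif total != sum(counts):
        raise ValueError("class counts do not sum to the stated total")
    rows = [
        (label, c, display_percentage(c, total))
        for label, c in zip(CLASS_ROWS, counts)
    ]
    return SummaryTable(rows, total)


def summarize_breakpoint_classes(classes) -> SummaryTable:
    """Count breakpoints per class row and attach display percentages.

    Rows: blunt; microhomology; simple ends with >20 bp identity;
    inserted/deleted junction bases; inserted/deleted bases plus
    microhomology.
    """
    if not classes:
        raise ValueError("no classified breakpoints")
    counts = dict.fromkeys(CLASS_ROWS, 0)
    for bc in classes:
        if bc.label == "MICROHOMOLOGY" and bc.long_identity:
            counts["long_identity"] += 1
        elif bc.label == "BLUNT":
            counts["blunt"] += 1
        elif bc.label == "MICROHOMOLOGY":
            counts["microhomology"] += 1
        elif bc.label == "COMPLEX":
            counts["complex"] += 1
        elif bc.label == "COMPLEX_MH":
            counts["complex_mh"] += 1
        else:
            raise ValueError(f"unknown class label {bc.label!r}")
    return class_table_from_counts([counts[r] for r in CLASS_ROWS])


# ---------------------------------------------------------------------------
# genomic context


def annotate_context(calls, gene_models) -> tuple[list[str], SummaryTable]:
    """Label each call exonic / exon-intron / intronic / intergenic.

    ``gene_models`` maps chromosome -> {"genes": [(s, e)], "exons": [(s, e)]}.
    Exonic calls are additionally counted as frame-preserving when their
    size is a multiple of three.
    """
    labels = []
    frame_preserving = 0
    if not gene_models:
        log.warning("annotate_context: no gene models; all calls intergenic")
    for c in calls:
        lo, hi = c.start, max(c.end, c.start + 1)
        models = (gene_models or {}).get(c.chrom, {})
        exons = models.get("exons", [])
        genes = models.get("genes", [])
        in_exon = [e for e in exons if e[0] < hi and lo < e[1]]
        in_gene = [g for g in genes if g[0] < hi and lo < g[1]]
        if in_exon:
            if any(e[0] <= lo and hi <= e[1] for e in in_exon):
                labels.append("exonic")
                if c.size % 3 == 0:
                    frame_preserving += 1
            else:
                labels.append("exon_intron")
        elif in_gene:
            labels.append("intronic")
        else:
            labels.append("intergenic")
    total = len(labels)
    order = ("exonic", "exon_intron", "intronic", "intergenic")
    rows = [
        (lab, labels.count(lab), display_percentage(labels.count(lab), total))
        for lab in order
    ]
    table = SummaryTable(rows, total, notes={"frame_preserving": frame_preserving})
    return labels, table


def size_summary(calls) -> dict:
    sizes = [c.size for c in calls]
    if not sizes:
        return {"n": 0}
    return {
        "n": len(sizes),
        "median": float(np.median(sizes)),
        "mean": float(np.mean(sizes)),
        "min": int(min(sizes)),
        "max": int(max(sizes)),
    }
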
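"""Statistics layer: Pearson correlation with significance, Kruskal-Wallis
with pairwise Mann-Whitney post hoc, and assembly of the machine-readable
report that mirrors the per-genome distance and correlation tables.

Distributions of alignment/segment lengths are generally far from normal, so
group comparisons are rank-based throughout.  Pairwise U tests are exact when
both groups are small (n <= 20), normal-approximated otherwise; p-values are
reported both raw and Bonferroni-adjusted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from karyoevo.breakpoints import BreakageModelResult
from karyoevo.rearrange import MCDSummary
from karyoevo.scaffold import ChromosomeAssembly


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int


@dataclass
class DistributionComparison:
    labels: list[str]
    medians: dict[str, float]
    quartiles: dict[str, tuple[float, float]]
    h_statistic: float
    p_kw: float
    pairwise: list[dict]  # label_1, label_2, u, p_raw, p_bonferroni, method


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Product-moment correlation with the two-sided t-transform p-value
    (t = r sqrt(n-2)/sqrt(1-r^2) on n-2 degrees of freedom)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate input: zero variance")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p_value=float(res.pvalue), n=n)


def compare_length_distributions(
    groups: Mapping[str, Sequence[float]],
) -> DistributionComparison:
    """Kruskal-Wallis across all groups plus pairwise Mann-Whitney U tests.

    H carries the tie correction; quartiles use linear interpolation.  For
    identical groups H is ~0 and the omnibus p ~1.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    labels = list(groups)
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 1:
            raise ValueError(f"group {k!r} is empty")

    try:
        h, p_kw = stats.kruskal(*arrays.values())
    except ValueError:
        # all values identical across every group: no variation at all
        h, p_kw = 0.0, 1.0

    medians = {k: float(np.median(v)) for k, v in arrays.items()}
    quartiles = {
        k: (float(np.percentile(v, 25)), float(np.percentile(v, 75)))
        for k, v in arrays.items()
    }
    pairwise = []
    n_tests = len(labels) * (len(labels) - 1) // 2
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            g1, g2 = arrays[labels[i]], arrays[labels[j]]
            method = "exact" if (g1.size <= 20 and g2.size <= 20) else "asymptotic"
            res = stats.mannwhitneyu(g1, g2, alternative="two-sided", method=method)
            pairwise.append(
                {
                    "label_1": labels[i],
                    "label_2": labels[j],
                    "u": float(res.statistic),
                    "p_raw": float(res.pvalue),
                    "p_bonferroni": float(min(1.0, res.pvalue * n_tests)),
                    "method": method,
                }
            )
    return DistributionComparison(
        labels=labels,
        medians=medians,
        quartiles=quartiles,
        h_statistic=float(h),
        p_kw=float(p_kw),
        pairwise=pairwise,
    )


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------


@dataclass
class Report:
    sections: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.sections, indent=2, default=_jsonable)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if hasattr(obj, "__dataclass_fields__"):
        return {k: getattr(obj, k) for k in obj.__dataclass_fields__}
    raise TypeError(f"not serializable: {type(obj)}")


def build_report(
    assemblies: Sequence[ChromosomeAssembly] = (),
    mcd_summaries: Mapping[str, MCDSummary] | None = None,
    breakage_results: Mapping[str, BreakageModelResult] | None = None,
    correlations: Mapping[str, CorrelationResult] | None = None,
    comparisons: Mapping[str, DistributionComparison] | None = None,
) -> Report:
    """Aggregate stage outputs into one machine-readable report.

    MCD rows pass through ``mcd_summary`` outputs unchanged; empty inputs
    produce empty sections.
    """
    report = Report()
    report.sections["assemblies"] = [
        {"name": a.name, "path": [list(step) for step in a.path]}
        for a in assemblies
    ]
    report.sections["mcd"] = {
        name: {
            "n_chromosomes": s.n_chromosomes,
            "all_changes": s.all_changes,
            "gross_changes": s.gross_changes,
            "per_chromosome_all": s.per_chromosome_all,
            "per_chromosome_gross": s.per_chromosome_gross,
            "per_mb_all": s.per_mb_all,
            "per_mb_gross": s.per_mb_gross,
            "gross_over_all_pct": s.gross_over_all_pct,
        }
        for name, s in (mcd_summaries or {}).items()
    }
    report.sections["breakage"] = {
        name: {
            "L": r.L,
            "n_segments": r.n_segments,
            "ks_statistic": r.ks_statistic,
            "p_value": r.p_value,
        }
        for name, r in (breakage_results or {}).items()
    }
    report.sections["correlations"] = {
        name: {"r": c.r, "p_value": c.p_value, "n": c.n}
        for name, c in (correlations or {}).items()
    }
    report.sections["length_distributions"] = {
        name: {
            "labels": d.labels,
            "medians": d.medians,
            "quartiles": {k: list(v) for k, v in d.quartiles.items()},
            "H": d.h_statistic,
            "p_kw": d.p_kw,
            "pairwise": d.pairwise,
        }
        for name, d in (comparisons or {}).items()
    }
    return report


def write_correlation_table(
    rows: Mapping[str, CorrelationResult], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("comparison\tr\tp_value\tn\n")
        for name, c in rows.items():
            fh.write(f"{name}\t{c.r:.4f}\t{c.p_value:.4g}\t{c.n}\n")
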
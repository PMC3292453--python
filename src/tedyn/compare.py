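"""Between-genome comparisons: family partitioning, copy-number tables,
per-Mbp normalization, and the Wilcoxon rank-sum test.

The exact rank-sum p-value is computed by full enumeration of rank splits
when the pooled sample is small and tie-free; otherwise a normal
approximation with midranks, tie correction, and continuity correction is
used.  Two-sided p-values double the smaller one-sided tail (capped at 1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import norm, rankdata

from .errors import ConfigError

__all__ = [
    "FamilySummary",
    "build_family_summaries",
    "partition_families",
    "copy_number_table",
    "wilcoxon_rank_sum",
    "density_normalize",
]

STATUSES = ("shared", "unique_A", "unique_B", "absent")


@dataclass(frozen=True)
class FamilySummary:
    family_id: str
    te_class: str
    count_A: int
    count_B: int
    density_A: float
    density_B: float
    status: str
    avg_age_A: float = math.nan
    avg_age_B: float = math.nan
    avg_age_both: float = math.nan


def _status(count_a: int, count_b: int) -> str:
    if count_a > 0 and count_b > 0:
        return "shared"
    if count_a > 0:
        return "unique_A"
    if count_b > 0:
        return "unique_B"
    return "absent"


def build_family_summaries(
    library,
    hits_a,
    hits_b,
    genome_len_a: int,
    genome_len_b: int,
    family_ages: dict | None = None,
):
    """One FamilySummary per library family from resolved annotation sets.

    ``family_ages`` optionally maps (family_id, scope) -> FamilyAge with
    scope in {"A", "B", "both"}.
    """
    family_ages = family_ages or {}
    counts_a: dict[str, int] = {}
    counts_b: dict[str, int] = {}
    for h in hits_a:
        counts_a[h.family_id] = counts_a.get(h.family_id, 0) + 1
    for h in hits_b:
        counts_b[h.family_id] = counts_b.get(h.family_id, 0) + 1
    out = []
    for fam in library:
        ca = counts_a.get(fam.family_id, 0)
        cb = counts_b.get(fam.family_id, 0)

        def age(scope):
            fa = family_ages.get((fam.family_id, scope))
            return fa.average_insertion_time if fa is not None else math.nan

        out.append(
            FamilySummary(
                family_id=fam.family_id,
                te_class=fam.te_class,
                count_A=ca,
                count_B=cb,
                density_A=density_normalize(ca, genome_len_a),
                density_B=density_normalize(cb, genome_len_b),
                status=_status(ca, cb),
                avg_age_A=age("A"),
                avg_age_B=age("B"),
                avg_age_both=age("both"),
            )
        )
    return out


def partition_families(summaries) -> dict[str, int]:
    """Counts of shared / unique_A / unique_B / absent families (plus total)."""
    seen = set()
    counts = dict.fromkeys(STATUSES, 0)
    for s in summaries:
        if s.family_id in seen:
            raise ConfigError(f"duplicate family_id {s.family_id!r}")
        seen.add(s.family_id)
        counts[s.status] += 1
    counts["total"] = len(seen)
    return counts


def copy_number_table(summaries, by_class: bool = False):
    """Per-genome copy totals, mean copies/family, and maximum family size.

    Means are taken over families with at least one copy in that genome.
    With ``by_class`` the table nests per te_class; a "all" entry always
    aggregates everything.
    """

    def summarize(items):
        row = {}
        for g, attr in (("A", "count_A"), ("B", "count_B")):
            counts = [getattr(s, attr) for s in items if getattr(s, attr) > 0]
            row[f"total_{g}"] = sum(counts)
            row[f"mean_{g}"] = float(np.mean(counts)) if counts else 0.0
            row[f"max_{g}"] = max(counts) if counts else 0
            row[f"n_families_{g}"] = len(counts)
        return row

    table = {"all": summarize(summaries)}
    if by_class:
        for cls in sorted({s.te_class for s in summaries}):
            table[cls] = summarize([s for s in summaries if s.te_class == cls])
    return table


def wilcoxon_rank_sum(x, y, mode: str = "auto"):
    """Two-sample Wilcoxon rank-sum test (two-sided).

    Returns (W, p) where W is the rank sum of ``x`` under midranks.  With
    ``mode="exact"`` (or "auto" on tie-free pooled samples of size <= 20)
    the null distribution of W is enumerated exactly over all C(n, n_x)
    assignments of ranks; otherwise the normal approximation with tie and
    continuity corrections is used.  Two-sided p doubles the smaller
    one-sided tail, capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ConfigError("both samples must be non-empty")
    if mode not in ("auto", "exact", "normal"):
        raise ConfigError(f"unknown mode {mode!r}")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    nx, ny = len(x), len(y)
    n = nx + ny
    w = float(ranks[:nx].sum())
    has_ties = len(np.unique(pooled)) < n
    if np.ptp(pooled) == 0:
        warnings.warn("all pooled values identical; p = 1 by convention")
        return w, 1.0
    exact = mode == "exact" or (mode == "auto" and n <= 20 and not has_ties)
    if exact:
        if has_ties:
            raise ConfigError("exact mode requires a tie-free pooled sample")
        lo = hi = 0
        total = 0
        for comb in combinations(range(1, n + 1), nx):
            s = sum(comb)
            total += 1
            lo += s <= w
            hi += s >= w
        p_one = min(lo, hi) / total
        return w, min(1.0, 2.0 * p_one)
    mean = nx * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    # tie-corrected variance of the rank sum
    var = nx * ny * (n + 1) / 12.0 * (1.0 - (tie_counts**3 - tie_counts).sum() / (n**3 - n))
    if var <= 0:
        warnings.warn("zero variance after tie correction; p = 1 by convention")
        return w, 1.0
    z = (w - mean - 0.5 * np.sign(w - mean)) / math.sqrt(var)
    p_one = norm.sf(abs(z))
    return w, min(1.0, 2.0 * float(p_one))


def density_normalize(count: int, genome_len_bp: int) -> float:
    """Copies per Mbp: count * 1e6 / genome_len_bp."""
    if genome_len_bp <= 0:
        raise ConfigError("genome_len_bp must be > 0")
    if count < 0:
        raise ConfigError("count must be >= 0")
    return count * 1e6 / genome_len_bp
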
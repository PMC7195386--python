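"""Group-level statistics over morphological classes.

Structures are grouped by sub-domain class (1..4) and a measurement
(volume, surface or form factor) is compared across classes with a
Kruskal–Wallis test followed by pairwise two-sided Mann–Whitney tests with
Bonferroni correction.  Pairwise tests use exact enumeration of the
permutation distribution of U when both sides have at most ``exact_max``
observations (ties handled exactly), and the normal approximation with tie
and continuity correction otherwise.

Significance marks follow the usual convention:
ns (p > 0.05), * (p <= 0.05), ** (p <= 0.01), *** (p <= 0.001).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

__all__ = [
    "GroupedMeasurements",
    "PairwiseResult",
    "StatReport",
    "histogram_classes",
    "kruskal_wallis",
    "mann_whitney_exact",
    "mann_whitney_pairs",
    "significance_mark",
    "build_report",
]

logger = logging.getLogger(__name__)

CLASSES = (1, 2, 3, 4)


@dataclass
class GroupedMeasurements:
    """Mapping class -> measurement values for one measure."""

    groups: dict[int, list[float]]
    measure_name: str = ""

    def __post_init__(self) -> None:
        clean: dict[int, list[float]] = {}
        for k, vals in self.groups.items():
            vals = [float(v) for v in vals]
            if any(not math.isfinite(v) for v in vals):
                raise ValueError(f"non-finite value in class {k}")
            clean[int(k)] = vals
        self.groups = clean

    @classmethod
    def from_records(cls, records, measure: str) -> "GroupedMeasurements":
        attr = {"volume": "volume_um3", "surface": "surface_um2",
                "form_factor": "form_factor"}.get(measure, measure)
        groups: dict[int, list[float]] = {c: [] for c in CLASSES}
        for r in records:
            groups.setdefault(r.morph_class, []).append(getattr(r, attr))
        return cls({k: v for k, v in groups.items() if v}, measure)


@dataclass
class PairwiseResult:
    class_a: int
    class_b: int
    U: float
    p_raw: float
    p_bonferroni: float
    mark: str
    method: str


@dataclass
class StatReport:
    histogram: dict[int, tuple[int, float]]
    kw_H: float
    kw_p: float
    pairwise: list[PairwiseResult] = field(default_factory=list)
    measure_name: str = ""


def significance_mark(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def histogram_classes(records) -> dict[int, tuple[int, float]]:
    """Count and fraction of structures per morphological class 1..4.

    Accepts morphometry records (using ``morph_class``) or plain ints.
    """
    items = [r if isinstance(r, int) else r.morph_class for r in records]
    if not items:
        raise ValueError("need at least one record")
    total = len(items)
    return {c: (items.count(c), items.count(c) / total) for c in CLASSES}


def kruskal_wallis(groups: GroupedMeasurements) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H with chi-square (k-1 df) p-value.

    Degenerate input (all values identical) returns H = 0, p = 1.
    """
    samples = [np.asarray(v, dtype=np.float64) for v in groups.groups.values() if len(v)]
    if len(samples) < 2:
        raise ValueError("need at least two non-empty groups")
    if sum(len(s) for s in samples) < 3:
        raise ValueError("need at least three observations in total")
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    H, p = sstats.kruskal(*samples)
    return float(H), float(p)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U of sample x against y via midranks (ties counted half)."""
    pooled = np.concatenate([x, y])
    ranks = sstats.rankdata(pooled)
    r1 = ranks[: len(x)].sum()
    return float(r1 - len(x) * (len(x) + 1) / 2.0)


def mann_whitney_exact(x, y) -> tuple[float, float]:
    """Two-sided exact Mann–Whitney test by full enumeration.

    Enumerates all C(n+m, n) assignments of the pooled values to the two
    samples, computing U for each; ties are therefore handled exactly.  The
    two-sided p-value is the probability, under the permutation null, of a U
    at least as extreme (on either side of the mean n*m/2) as observed.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, mcount = len(x), len(y)
    if n < 1 or mcount < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sstats.rankdata(pooled)
    u_obs = float(ranks[:n].sum() - n * (n + 1) / 2.0)
    mean = n * mcount / 2.0
    dev = abs(u_obs - mean)

    idx = np.fromiter(itertools.chain.from_iterable(
        itertools.combinations(range(n + mcount), n)), dtype=np.int64)
    idx = idx.reshape(-1, n)
    r1 = ranks[idx].sum(axis=1)
    u_all = r1 - n * (n + 1) / 2.0
    extreme = np.abs(u_all - mean) >= dev - 1e-12
    return u_obs, float(extreme.mean())


def mann_whitney_pairs(groups: GroupedMeasurements, exact_max: int = 8
                       ) -> list[PairwiseResult]:
    """All unordered pairwise two-sided Mann–Whitney tests with Bonferroni.

    Classes with fewer than two observations are skipped with a warning.
    The Bonferroni multiplier is the number of pairs actually tested.
    Pairs whose pooled values are all identical report p = 1.
    """
    usable = {}
    for k, v in sorted(groups.groups.items()):
        if len(v) >= 2:
            usable[k] = np.asarray(v, dtype=np.float64)
        else:
            logger.warning("class %s has <2 observations; excluded from pairwise tests", k)
    pairs = list(itertools.combinations(sorted(usable), 2))
    n_tests = len(pairs)
    out: list[PairwiseResult] = []
    for a, b in pairs:
        x, y = usable[a], usable[b]
        pooled = np.concatenate([x, y])
        if np.all(pooled == pooled[0]):
            u, p, method = len(x) * len(y) / 2.0, 1.0, "degenerate"
        elif len(x) <= exact_max and len(y) <= exact_max:
            u, p = mann_whitney_exact(x, y)
            method = "exact"
        else:
            res = sstats.mannwhitneyu(x, y, alternative="two-sided",
                                      method="asymptotic", use_continuity=True)
            u, p, method = float(res.statistic), float(res.pvalue), "asymptotic"
        p_b = min(1.0, p * n_tests)
        out.append(PairwiseResult(a, b, u, p, p_b, significance_mark(p_b), method))
    return out


def build_report(records, measure: str = "volume",
                 exact_max: int = 8) -> StatReport:
    """Histogram + Kruskal–Wallis + Bonferroni-corrected pairwise tests."""
    grouped = GroupedMeasurements.from_records(records, measure)
    hist = histogram_classes(records)
    H, p = kruskal_wallis(grouped)
    pairwise = mann_whitney_pairs(grouped, exact_max=exact_max)
    return StatReport(histogram=hist, kw_H=H, kw_p=p, pairwise=pairwise,
                      measure_name=measure)
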
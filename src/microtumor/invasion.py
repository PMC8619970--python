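"""Quantification of microtumor invasion assays.

Microtumors seeded on an extracellular-matrix gel either deform the gel
surface (depths typically below 50 µm) or actively invade it.  The
*invasive fraction* of a condition is the proportion of microtumors whose
invasion depth exceeds a threshold — 50 µm by definition, a value that a
two-cluster split of the pooled depth distribution reproduces
independently.  In the multilayer (basement-membrane over collagen) assay
each microtumor additionally occupies one of four regions:

    medium–Matrigel interface → within Matrigel →
    Matrigel–collagen interface → within collagen

and the region occupancy distribution is the readout of invasive
progression.  Group comparisons follow the nonparametric battery used for
such assays: Kruskal–Wallis ANOVA on ranks with a Tukey–Kramer post hoc on
the rank-transformed depths, one-tailed Wilcoxon rank-sum for the
co-culture-exceeds-component comparison, and Pearson chi-square on
region-count contingency tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .cluster1d import DegenerateValuesError, two_means_1d

__all__ = [
    "REGIONS",
    "MicrotumorRecord",
    "InvasionSummary",
    "DepthTestReport",
    "RegionTestReport",
    "invasive_fraction",
    "derive_threshold",
    "region_fractions",
    "compare_depths",
    "compare_regions",
    "summarize",
]

#: canonical order of the multilayer-assay regions, shallow to deep
REGIONS = (
    "medium_matrigel_interface",
    "within_matrigel",
    "matrigel_collagen_interface",
    "within_collagen",
)

DEFAULT_THRESHOLD_UM = 50.0


@dataclass(frozen=True)
class MicrotumorRecord:
    """One microtumor: condition label, composition, invasion depth and
    (for multilayer assays) the region it reached."""

    id: str
    condition: str
    composition: str = "homogeneous"
    depth_um: float = 0.0
    region: str | None = None

    def __post_init__(self):
        if self.depth_um < 0:
            raise ValueError("depth_um must be non-negative")
        if self.composition not in ("homogeneous", "heterogeneous"):
            raise ValueError(f"unknown composition {self.composition!r}")
        if self.region is not None and self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")


@dataclass
class InvasionSummary:
    n: int
    median_depth_um: float
    invasive_fraction: float
    threshold_um: float
    region_fractions: np.ndarray | None = None


@dataclass
class DepthTestReport:
    statistic: float
    pvalue: float
    posthoc: pd.DataFrame | None = None
    wilcoxon: pd.DataFrame | None = None


@dataclass
class RegionTestReport:
    statistic: float
    pvalue: float
    dof: int
    observed: pd.DataFrame = None
    expected: pd.DataFrame = None
    dropped_regions: list[str] = field(default_factory=list)
    low_expected: bool = False


def _depths(records) -> np.ndarray:
    if isinstance(records, pd.DataFrame):
        d = records["depth_um"].to_numpy(dtype=float)
    else:
        d = np.asarray(records, dtype=float)
    if d.size == 0:
        raise ValueError("no records")
    return d


def invasive_fraction(records, threshold_um: float = DEFAULT_THRESHOLD_UM) -> float:
    """Proportion of microtumors with depth strictly over the threshold.

    The comparison is strict ("over 50 µm"): a depth exactly at the
    threshold counts as non-invasive.
    """
    d = _depths(records)
    return float(np.count_nonzero(d > threshold_um) / d.size)


def derive_threshold(depths) -> float:
    """Invasion-depth threshold from a two-cluster split of the depths.

    Optimal 1-D 2-means separates the non-invasive (gel deformation) mode
    from the invasive mode; the threshold is the midpoint between the two
    cluster centroids.  Requires at least two distinct depths.
    """
    d = _depths(depths)
    try:
        _, (lo, hi) = two_means_1d(d)
    except DegenerateValuesError:
        raise DegenerateValuesError(
            "all depths identical; no threshold can be derived"
        ) from None
    return (lo + hi) / 2.0


def region_fractions(records) -> np.ndarray:
    """Occupancy proportions over the four regions, in :data:`REGIONS`
    order, summing to 1.  Regions nobody reached are reported as exact 0.
    """
    if isinstance(records, pd.DataFrame):
        regions = records["region"]
    else:
        regions = pd.Series(list(records))
    if len(regions) == 0:
        raise ValueError("no records")
    if regions.isna().any():
        raise ValueError("every record needs a region label")
    unknown = set(regions) - set(REGIONS)
    if unknown:
        raise ValueError(f"unknown region labels: {sorted(unknown)}")
    counts = regions.value_counts()
    return np.array([counts.get(r, 0) for r in REGIONS], dtype=float) / len(regions)


def _group_arrays(groups) -> tuple[list[str], list[np.ndarray]]:
    if isinstance(groups, pd.DataFrame):
        names, arrays = [], []
        for name, sub in groups.groupby("condition", sort=False):
            names.append(str(name))
            arrays.append(sub["depth_um"].to_numpy(dtype=float))
    else:
        names = list(groups.keys())
        arrays = [np.asarray(groups[k], dtype=float) for k in names]
    if len(names) < 2:
        raise ValueError("need at least two groups")
    for name, arr in zip(names, arrays):
        if arr.size < 2:
            raise ValueError(f"group {name!r} has fewer than two records")
    return names, arrays


def compare_depths(
    groups,
    one_tailed_reference: str | None = None,
    alpha: float = 0.05,
    posthoc: bool = True,
) -> DepthTestReport:
    """Kruskal–Wallis ANOVA on ranks over the groups, with a Tukey–Kramer
    post hoc on the rank-transformed depths (the Kramer form handles
    unequal group sizes).

    ``groups`` is either a dict ``{label: depths}`` or a record DataFrame
    grouped by ``condition``.  If ``one_tailed_reference`` names a group
    (e.g. the co-culture condition), a one-tailed Wilcoxon rank-sum test
    of "reference median greater" is run against every other group.
    """
    names, arrays = _group_arrays(groups)
    stat, p = stats.kruskal(*arrays)

    posthoc_table = None
    if posthoc:
        pooled = np.concatenate(arrays)
        ranks = stats.rankdata(pooled)  # mid-ranks resolve ties
        labels = np.repeat(names, [a.size for a in arrays])
        tukey = pairwise_tukeyhsd(ranks, labels, alpha=alpha)
        posthoc_table = pd.DataFrame(
            tukey.summary().data[1:], columns=tukey.summary().data[0]
        )

    wilcoxon = None
    if one_tailed_reference is not None:
        if one_tailed_reference not in names:
            raise ValueError(f"{one_tailed_reference!r} is not a group label")
        ref = arrays[names.index(one_tailed_reference)]
        rows = []
        for name, arr in zip(names, arrays):
            if name == one_tailed_reference:
                continue
            # exact null distribution where feasible, normal approximation
            # with tie correction otherwise
            method = "exact" if (ref.size <= 20 and arr.size <= 20) else "asymptotic"
            try:
                w, wp = stats.mannwhitneyu(ref, arr, alternative="greater", method=method)
            except ValueError:  # ties make the exact method unavailable
                w, wp = stats.mannwhitneyu(ref, arr, alternative="greater",
                                           method="asymptotic")
            rows.append({"group": name, "statistic": float(w), "pvalue": float(wp),
                         "significant": wp < alpha})
        wilcoxon = pd.DataFrame(rows)

    return DepthTestReport(statistic=float(stat), pvalue=float(p),
                           posthoc=posthoc_table, wilcoxon=wilcoxon)


def compare_regions(groups, drop_empty: bool = True) -> RegionTestReport:
    """Pearson chi-square on the groups × regions contingency table.

    ``groups`` is a dict ``{label: region-label sequence}`` or a record
    DataFrame with ``condition`` and ``region`` columns.  Region columns
    that are empty in *every* group carry no information and are dropped
    (with a warning, and the degrees of freedom adjusted); an all-zero row
    is an error.  A warning flag is set when any expected count is < 5.
    """
    if isinstance(groups, pd.DataFrame):
        items = [(str(name), sub["region"]) for name, sub in
                 groups.groupby("condition", sort=False)]
    else:
        items = [(str(k), pd.Series(list(v))) for k, v in groups.items()]
    if len(items) < 2:
        raise ValueError("need at least two groups")

    table = pd.DataFrame(
        {name: [int((regions == r).sum()) for r in REGIONS] for name, regions in items},
        index=list(REGIONS),
    ).T
    zero_rows = table.index[table.sum(axis=1) == 0].tolist()
    if zero_rows:
        raise ValueError(f"groups with no records: {zero_rows}")

    dropped = table.columns[table.sum(axis=0) == 0].tolist()
    if dropped:
        if not drop_empty:
            raise ValueError(f"regions with no records: {dropped}")
        warnings.warn(
            f"dropping empty region columns {dropped}; degrees of freedom adjusted",
            stacklevel=2,
        )
        table = table.drop(columns=dropped)
    if table.shape[1] < 2:
        raise ValueError("fewer than two non-empty regions; chi-square undefined")

    res = stats.chi2_contingency(table.to_numpy(), correction=False)
    expected = pd.DataFrame(res.expected_freq, index=table.index, columns=table.columns)
    low = bool((res.expected_freq < 5).any())
    if low:
        warnings.warn("some expected counts are below 5; chi-square approximation "
                      "may be poor", stacklevel=2)
    return RegionTestReport(
        statistic=float(res.statistic), pvalue=float(res.pvalue), dof=int(res.dof),
        observed=table, expected=expected, dropped_regions=dropped, low_expected=low,
    )


def summarize(records: pd.DataFrame, threshold_um: float = DEFAULT_THRESHOLD_UM) -> InvasionSummary:
    """Per-condition style summary of a record table."""
    d = _depths(records)
    regions = None
    if isinstance(records, pd.DataFrame) and "region" in records and records["region"].notna().all():
        regions = region_fractions(records)
    return InvasionSummary(
        n=int(d.size),
        median_depth_um=float(np.median(d)),
        invasive_fraction=invasive_fraction(d, threshold_um),
        threshold_um=float(threshold_um),
        region_fractions=regions,
    )
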
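"""Compartment phenotype statistics.

Positive-fraction matrices over ROIs, paired/unpaired rank tests with
Benjamini-Hochberg correction, Gini-Simpson diversity of binned fractions,
hierarchical clustering of ROIs, and predominant-subtype contingency tests.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage, leaves_list

from .io_formats import as_cell_frame

__all__ = [
    "MarkerFractionMatrix",
    "bh_adjust",
    "build_fraction_matrix",
    "paired_compartment_test",
    "rank_sum_test",
    "kruskal_dunn",
    "KruskalDunnResult",
    "simpson_diversity",
    "cluster_rois",
    "ClusterResult",
    "subtype_contingency",
    "SubtypeContingencyResult",
]

logger = logging.getLogger(__name__)


@dataclass
class MarkerFractionMatrix:
    """Markers x ROIs matrix of positive-tumor-cell fractions (NA allowed).

    ``values`` has marker rows and ROI-id columns; ``meta`` is indexed by
    ROI id with ``tumor_id`` and ``compartment`` columns.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.meta.index):
            self.meta = self.meta.loc[self.values.columns]
        v = self.values.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(v, initial=0.0) < 0 or np.nanmax(v, initial=0.0) > 1:
                raise ValueError("fractions must lie in [0, 1] or be NA")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaNs are passed through."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        from statsmodels.stats.multitest import multipletests

        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def build_fraction_matrix(
    cells,
    markers,
    thresholds=None,
    all_negative=None,
) -> MarkerFractionMatrix:
    """Per-ROI fraction of marker-positive tumor cells.

    Parameters
    ----------
    cells
        Cell table (frame or CellRecord list) with ``roi_id``, ``compartment``
        and, ideally, a ``tumor_id`` column.
    markers
        Marker names to quantify.
    thresholds
        Per-marker intensity thresholds used when a ``positive_<m>`` column is
        absent.  A marker measured by intensity only and lacking a threshold
        is an error.
    all_negative
        Optional set of (roi_id, marker) pairs declared completely negative;
        those entries are set to fraction 0 instead of NA.
    """
    df = as_cell_frame(cells)
    tumor = df[df["tissue_class"] == "tumor"]
    if tumor.empty:
        raise ValueError("no tumor cells in input")
    roi_ids = sorted(tumor["roi_id"].unique())
    meta_rows = {}
    for roi, grp in tumor.groupby("roi_id"):
        compartments = grp["compartment"].unique()
        if len(compartments) != 1:
            raise ValueError(f"ROI {roi!r} has multiple compartments: {list(compartments)}")
        tumor_id = grp["tumor_id"].iloc[0] if "tumor_id" in grp.columns else roi
        meta_rows[roi] = {"tumor_id": tumor_id, "compartment": compartments[0]}
    meta = pd.DataFrame.from_dict(meta_rows, orient="index").loc[roi_ids]
    meta.index.name = "roi_id"

    all_negative = set(all_negative or [])
    values = pd.DataFrame(index=pd.Index(markers, name="marker"), columns=roi_ids, dtype=float)
    for marker in markers:
        pcol, icol = f"positive_{marker}", f"intensity_{marker}"
        if pcol in tumor.columns:
            pos = tumor[pcol]
        elif icol in tumor.columns:
            thr = (thresholds or {}).get(marker)
            if thr is None:
                raise ValueError(f"threshold missing for marker {marker!r}")
            pos = tumor[icol] >= thr
            pos = pos.where(tumor[icol].notna())
        else:
            pos = pd.Series(np.nan, index=tumor.index)
        for roi in roi_ids:
            sel = pos[tumor["roi_id"] == roi]
            measured = sel.notna()
            if measured.any():
                values.loc[marker, roi] = float(sel[measured].astype(bool).mean())
            elif (roi, marker) in all_negative:
                values.loc[marker, roi] = 0.0
            # else stays NA: not stained is missing, never zero
    return MarkerFractionMatrix(values=values, meta=meta)


def paired_compartment_test(matrix: MarkerFractionMatrix) -> pd.DataFrame:
    """Paired two-tailed Wilcoxon signed-rank test, lobule vs stroma, per marker.

    The pairing unit is the tumor: per tumor and compartment, the mean
    fraction over that tumor's ROIs.  Tumors missing either compartment are
    dropped per marker (logged).  Zero differences are dropped per the
    signed-rank convention; when no nonzero difference remains the p-value is
    NA.  P-values are BH-adjusted across the marker family.
    """
    meta = matrix.meta
    rows = []
    for marker, frac in matrix.values.iterrows():
        per = pd.DataFrame({"fraction": frac, "tumor_id": meta["tumor_id"], "compartment": meta["compartment"]})
        per = per.dropna(subset=["fraction"])
        means = per.groupby(["tumor_id", "compartment"])["fraction"].mean().unstack()
        for comp in ("lobule", "stroma"):
            if comp not in means.columns:
                means[comp] = np.nan
        complete = means.dropna(subset=["lobule", "stroma"])
        dropped = len(means) - len(complete)
        if dropped:
            logger.info("marker %s: dropped %d tumors missing a compartment", marker, dropped)
        n = len(complete)
        stat = p = np.nan
        if n < 2:
            warnings.warn(f"marker {marker}: fewer than 2 complete tumor pairs", stacklevel=2)
        else:
            diff = complete["lobule"] - complete["stroma"]
            if (diff != 0).sum() == 0:
                warnings.warn(
                    f"marker {marker}: all paired differences are zero; p set to NA",
                    stacklevel=2,
                )
            else:
                res = sps.wilcoxon(
                    complete["lobule"], complete["stroma"], zero_method="wilcox",
                    alternative="two-sided",
                )
                stat, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "marker": marker,
                "n_pairs": n,
                "mean_lobule": float(complete["lobule"].mean()) if n else np.nan,
                "mean_stroma": float(complete["stroma"].mean()) if n else np.nan,
                "statistic": stat,
                "pvalue": p,
            }
        )
    out = pd.DataFrame(rows)
    out["pvalue_bh"] = bh_adjust(out["pvalue"])
    return out


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-tailed unpaired Wilcoxon rank-sum (Mann-Whitney) test.

    Returns (statistic, p).  Identical constant groups give p = 1 by the
    normal-approximation convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        return np.nan, np.nan
    if np.ptp(np.concatenate([x, y])) == 0:
        return 0.0, 1.0
    res = sps.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


@dataclass
class KruskalDunnResult:
    statistic: float
    pvalue: float
    pairwise: pd.DataFrame
    groups: list = field(default_factory=list)


def kruskal_dunn(values, groups) -> KruskalDunnResult:
    """Kruskal-Wallis with tie correction plus BH-adjusted Dunn post-hoc tests.

    Empty groups are dropped with a warning; fewer than 2 remaining groups is
    an error.  Dunn z statistics use pooled mean ranks with tie correction;
    pairwise p-values are BH-adjusted within the pairwise family.
    """
    values = np.asarray(values, dtype=float)
    if isinstance(groups, pd.Series):
        groups = groups.array
    if isinstance(groups, (pd.Categorical, pd.arrays.Categorical)):
        labels = list(groups.categories)
        groups = np.asarray(groups)
    else:
        groups = np.asarray(groups)
        labels = list(pd.unique(groups))
    if len(values) != len(groups):
        raise ValueError("values and groups must have equal length")
    by_group = {g: values[groups == g] for g in labels}
    for g in list(by_group):
        if len(by_group[g]) == 0:
            warnings.warn(f"group {g!r} is empty; dropped", stacklevel=2)
            del by_group[g]
    labels = list(by_group)
    if len(labels) < 2:
        raise ValueError("need at least 2 non-empty groups")

    pooled = np.concatenate([by_group[g] for g in labels])
    if np.ptp(pooled) == 0:
        kw_stat, kw_p = 0.0, 1.0
    else:
        kw_stat, kw_p = sps.kruskal(*[by_group[g] for g in labels])

    ranks = sps.rankdata(pooled)
    n_total = len(pooled)
    offsets = np.cumsum([0] + [len(by_group[g]) for g in labels])
    mean_ranks = {
        g: ranks[offsets[i] : offsets[i + 1]].mean() for i, g in enumerate(labels)
    }
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n_total - 1)) if n_total > 1 else 0.0
    sigma2_base = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            gi, gj = labels[i], labels[j]
            ni, nj = len(by_group[gi]), len(by_group[gj])
            se = np.sqrt(sigma2_base * (1.0 / ni + 1.0 / nj))
            z = (mean_ranks[gi] - mean_ranks[gj]) / se if se > 0 else 0.0
            p = 2.0 * sps.norm.sf(abs(z))
            rows.append({"group1": gi, "group2": gj, "z": float(z), "pvalue": float(p)})
    pairwise = pd.DataFrame(rows)
    pairwise["pvalue_bh"] = bh_adjust(pairwise["pvalue"])
    return KruskalDunnResult(statistic=float(kw_stat), pvalue=float(kw_p), pairwise=pairwise, groups=labels)


def simpson_diversity(fractions, n_bins: int = 10, binned: bool = True) -> float:
    """Gini-Simpson index of ROI fraction diversity.

    Probability that two ROIs drawn without replacement fall in different
    equal-width bins of [0, 1]; 0 when all ROIs share a bin, 1 when all
    differ.  With ``binned=False`` the raw fraction values are used as
    categories instead of bins.
    """
    vals = np.asarray(pd.Series(fractions).dropna(), dtype=float)
    if len(vals) < 2:
        return float("nan")
    if binned:
        if n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if np.any((vals < 0) | (vals > 1)):
            raise ValueError("fractions must lie in [0, 1]")
        cats = np.minimum((vals * n_bins).astype(int), n_bins - 1)
    else:
        cats = vals
    _, counts = np.unique(cats, return_counts=True)
    n = len(vals)
    same = (counts * (counts - 1)).sum() / (n * (n - 1))
    return float(1.0 - same)


@dataclass
class ClusterResult:
    order: list
    labels: pd.Series
    linkage_matrix: np.ndarray


def cluster_rois(matrix: MarkerFractionMatrix, k: int = 2) -> ClusterResult:
    """Ward hierarchical clustering of ROI columns on Euclidean distance.

    NA entries are imputed with the marker's median; all-NA marker rows are
    dropped with a warning.  Columns are pre-sorted by ROI id, making the
    dendrogram and labels deterministic under input permutation.
    """
    values = matrix.values.copy()
    if values.shape[1] < 2:
        raise ValueError("need at least 2 ROI columns")
    all_na = values.isna().all(axis=1)
    if all_na.any():
        warnings.warn(
            f"dropped all-NA marker rows: {list(values.index[all_na])}", stacklevel=2
        )
        values = values.loc[~all_na]
    medians = values.median(axis=1)
    values = values.apply(lambda row: row.fillna(medians[row.name]), axis=1)
    values = values[sorted(values.columns, key=str)]  # deterministic tie-break
    X = values.to_numpy(dtype=float).T  # ROIs as observations
    Z = linkage(X, method="ward", metric="euclidean")
    order = [values.columns[i] for i in leaves_list(Z)]
    raw = fcluster(Z, t=k, criterion="maxclust")
    # relabel clusters in order of first appearance for determinism
    remap: dict[int, int] = {}
    labels = []
    for lab in raw:
        if lab not in remap:
            remap[lab] = len(remap) + 1
        labels.append(remap[lab])
    return ClusterResult(
        order=order,
        labels=pd.Series(labels, index=values.columns, name="cluster"),
        linkage_matrix=Z,
    )


@dataclass
class SubtypeContingencyResult:
    labels: pd.Series
    table: pd.DataFrame
    chi2_statistic: float
    chi2_pvalue: float
    fisher_pvalue: float
    n_indeterminate: int


def subtype_contingency(
    roi_fractions: pd.DataFrame,
    basal_col: str = "basal",
    classical_col: str = "classical",
    compartment_col: str = "compartment",
    delta: float = 0.05,
) -> SubtypeContingencyResult:
    """Predominant-subtype call per ROI plus chi-squared and Fisher tests.

    An ROI is labelled basal when the basal fraction exceeds the classical
    fraction by more than ``delta``, classical for the reverse, otherwise
    indeterminate and excluded from the contingency table.  The chi-squared
    statistic is uncorrected; when a table margin is zero it is NA while the
    Fisher exact p is still computed.
    """
    for col in (basal_col, classical_col, compartment_col):
        if col not in roi_fractions.columns:
            raise ValueError(f"missing column {col!r}")
    if roi_fractions[[basal_col, classical_col]].isna().any().any():
        raise ValueError("both marker fractions must be present per ROI")
    diff = roi_fractions[basal_col] - roi_fractions[classical_col]
    labels = pd.Series(
        np.where(diff > delta, "basal", np.where(diff < -delta, "classical", "indeterminate")),
        index=roi_fractions.index,
        name="subtype",
    )
    determinate = labels != "indeterminate"
    sub = pd.DataFrame(
        {"subtype": labels[determinate], "compartment": roi_fractions.loc[determinate, compartment_col]}
    )
    table = pd.crosstab(sub["subtype"], sub["compartment"])
    table = table.reindex(
        index=["basal", "classical"],
        columns=sorted(sub["compartment"].unique()),
        fill_value=0,
    )
    arr = table.to_numpy()
    chi2_stat = chi2_p = np.nan
    fisher_p = np.nan
    if arr.shape == (2, 2):
        margins_ok = arr.sum(axis=0).min() > 0 and arr.sum(axis=1).min() > 0
        if margins_ok:
            chi2_stat, chi2_p, _, _ = sps.chi2_contingency(arr, correction=False)
            chi2_stat, chi2_p = float(chi2_stat), float(chi2_p)
        fisher_p = float(sps.fisher_exact(arr, alternative="two-sided")[1])
    return SubtypeContingencyResult(
        labels=labels,
        table=table,
        chi2_statistic=chi2_stat,
        chi2_pvalue=chi2_p,
        fisher_pvalue=fisher_p,
        n_indeterminate=int((~determinate).sum()),
    )
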
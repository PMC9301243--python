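"""Quantitative analysis of sample x compound intensity matrices.

Family and glycosylation-degree accumulation profiles, leaf/root ratios,
t-test + fold-change differential calling, complete-linkage hierarchical
clustering with Pearson distance, and PCA on autoscaled data.

Fold-change regulation thresholds follow the study's gates: up when
FC > 2.5 and p < 0.05, down when FC < 0.4 and p < 0.05.  The log2
equivalents are *derived* (log2(2.5) = 1.3219...), never hard-coded to the
rounded 1.3 that appears in print.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import leaves_list, linkage, to_tree
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

__all__ = [
    "FC_UP",
    "FC_DOWN",
    "P_CUTOFF",
    "log2_threshold",
    "IntensityMatrix",
    "DifferentialResult",
    "PCAResult",
    "ClusterResult",
    "average_injections",
    "family_relative_abundance",
    "leaf_root_ratio",
    "glyco_profile",
    "differential_test",
    "differential_all",
    "hierarchical_cluster",
    "pca_autoscaled",
]

FC_UP = 2.5
FC_DOWN = 0.4
P_CUTOFF = 0.05

META_COLUMNS = ["cultivar", "tissue", "treatment", "replicate", "injection"]


def log2_threshold(fc: float = FC_UP) -> float:
    """The log2 equivalent of a linear fold-change gate."""
    return math.log2(fc)


@dataclass
class IntensityMatrix:
    """Non-negative sample x compound intensities with sample metadata.

    ``values`` is indexed by sample id (rows) and compound name (columns);
    ``meta`` shares the row index and carries cultivar, tissue, treatment,
    biological replicate and injection for every sample.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("negative intensities")
        if not self.values.index.equals(self.meta.index):
            raise ValueError("values and meta indices differ")
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"missing metadata columns: {missing}")
        if self.meta[META_COLUMNS].isna().any().any():
            raise ValueError("incomplete sample metadata")

    def subset(self, **conditions) -> "IntensityMatrix":
        mask = pd.Series(True, index=self.meta.index)
        for col, val in conditions.items():
            mask &= self.meta[col] == val
        return IntensityMatrix(self.values[mask], self.meta[mask])

    @property
    def compounds(self) -> list[str]:
        return list(self.values.columns)

    def to_csv(self, values_path: str | Path, meta_path: str | Path) -> None:
        self.values.to_csv(values_path, index_label="sample_id")
        self.meta.to_csv(meta_path, index_label="sample_id")

    @classmethod
    def from_csv(cls, values_path: str | Path, meta_path: str | Path) -> "IntensityMatrix":
        values = pd.read_csv(values_path, index_col="sample_id")
        meta = pd.read_csv(meta_path, index_col="sample_id")
        return cls(values, meta)


def average_injections(m: IntensityMatrix) -> IntensityMatrix:
    """Mean over analytical injections, one row per biological replicate."""
    keys = ["cultivar", "tissue", "treatment", "replicate"]
    joined = m.values.join(m.meta[keys])
    grouped = joined.groupby(keys, sort=True).mean(numeric_only=True)
    idx = pd.Index(
        ["_".join(map(str, k)) for k in grouped.index], name="sample_id"
    )
    values = grouped.set_axis(idx)
    meta = pd.DataFrame(
        list(grouped.index), columns=keys, index=idx
    )
    meta["injection"] = 0
    return IntensityMatrix(values, meta)


# ---------------------------------------------------------------------------
# accumulation profiles


def _group_percentages(
    m: IntensityMatrix,
    category_of: dict[str, str],
    categories: Sequence[str],
    treatment: str | None = "control",
) -> pd.DataFrame:
    rows = {}
    sub = m.subset(treatment=treatment) if treatment is not None else m
    for (tissue, cultivar), idx in sub.meta.groupby(["tissue", "cultivar"], sort=True).groups.items():
        vals = sub.values.loc[idx]
        totals = {cat: 0.0 for cat in categories}
        for comp in vals.columns:
            totals[category_of[comp]] += float(vals[comp].sum())
        grand = sum(totals.values())
        if grand <= 0:
            raise ValueError(f"zero total intensity for group {tissue}/{cultivar}")
        rows[(tissue, cultivar)] = {cat: 100.0 * t / grand for cat, t in totals.items()}
    out = pd.DataFrame.from_dict(rows, orient="index")[list(categories)]
    out.index.names = ["tissue", "cultivar"]
    return out


def family_relative_abundance(
    m: IntensityMatrix,
    annotations: dict[str, str],
    treatment: str | None = "control",
) -> pd.DataFrame:
    """Percent of summed intensity per aglycone family, per tissue x cultivar.

    ``annotations`` maps compound name -> family.  Percentages across
    families sum to 100 for every group.
    """
    families = sorted(set(annotations.values()))
    return _group_percentages(m, annotations, families, treatment)


def glyco_profile(
    m: IntensityMatrix,
    glyco_of: dict[str, str],
    acylated: dict[str, bool] | None = None,
    treatment: str | None = "control",
) -> pd.DataFrame:
    """Percentages over glycosylation classes, plus acylated share if given."""
    classes = sorted(set(glyco_of.values()))
    out = _group_percentages(m, glyco_of, classes, treatment)
    if acylated is not None:
        acy_cat = {c: ("Acy" if acylated[c] else "nonAcy") for c in glyco_of}
        acy = _group_percentages(m, acy_cat, ["Acy", "nonAcy"], treatment)
        out["Acy"] = acy["Acy"]
    return out


def leaf_root_ratio(m: IntensityMatrix, treatment: str | None = "control") -> pd.Series:
    """Total leaf intensity / total root intensity, per cultivar."""
    sub = m.subset(treatment=treatment) if treatment is not None else m
    ratios = {}
    for cultivar, idx in sub.meta.groupby("cultivar", sort=True).groups.items():
        meta = sub.meta.loc[idx]
        vals = sub.values.loc[idx]
        leaf = float(vals[meta["tissue"] == "leaf"].values.sum())
        root = float(vals[meta["tissue"] == "root"].values.sum())
        n_leaf = int((meta["tissue"] == "leaf").sum())
        n_root = int((meta["tissue"] == "root").sum())
        if n_leaf == 0 or n_root == 0:
            raise ValueError(f"cultivar {cultivar}: both tissues required")
        if root == 0:
            raise ValueError(f"cultivar {cultivar}: zero root total")
        # per-sample means so unbalanced designs do not bias the ratio
        ratios[cultivar] = (leaf / n_leaf) / (root / n_root)
    return pd.Series(ratios, name="leaf_root_ratio")


# ---------------------------------------------------------------------------
# differential analysis


@dataclass
class DifferentialResult:
    """Per-compound fold change, p-value and regulation call."""

    compound: str
    mean_control: float
    mean_treated: float
    fc: float
    log2fc: float
    p_value: float
    regulation: str  # up | down | unchanged
    zero_offset_used: bool = False


def _welch_or_student(a: np.ndarray, b: np.ndarray, equal_var: bool) -> np.ndarray:
    """Two-sided t-test p-values column-wise; degenerate zero-variance
    columns get p=1 when means are equal and p=0 otherwise."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sps.ttest_ind(a, b, axis=0, equal_var=equal_var)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = (a.std(axis=0) == 0) & (b.std(axis=0) == 0)
    same = np.isclose(a.mean(axis=0), b.mean(axis=0))
    p = np.where(degenerate, np.where(same, 1.0, 0.0), p)
    return p


def differential_test(
    m: IntensityMatrix,
    tissue: str,
    cultivar: str,
    control: str = "control",
    treated: str = "Hg",
    equal_var: bool = False,
    injections_averaged: bool = True,
    fc_up: float = FC_UP,
    fc_down: float = FC_DOWN,
    p_cutoff: float = P_CUTOFF,
) -> list[DifferentialResult]:
    """Control-vs-treated testing within one tissue x cultivar group.

    Analytical injections are averaged per biological replicate first
    (default), the t-test runs on log2 intensities (Welch by default), and
    the fold change is the ratio of linear means.  Compounds with a zero
    mean in either arm get a small-constant offset (half the smallest
    nonzero intensity) before the ratio and are flagged.
    """
    work = average_injections(m) if injections_averaged else m
    ctrl = work.subset(tissue=tissue, cultivar=cultivar, treatment=control)
    trt = work.subset(tissue=tissue, cultivar=cultivar, treatment=treated)
    if len(ctrl.values) < 2 or len(trt.values) < 2:
        raise ValueError(
            f"need >=2 replicates per arm for {tissue}/{cultivar}; got "
            f"{len(ctrl.values)} control, {len(trt.values)} treated"
        )

    a = ctrl.values.to_numpy(float)
    b = trt.values.to_numpy(float)
    nonzero = np.concatenate([a[a > 0], b[b > 0]])
    offset = 0.5 * nonzero.min() if nonzero.size else 1.0

    mean_c = a.mean(axis=0)
    mean_t = b.mean(axis=0)
    needs_offset = (mean_c == 0) | (mean_t == 0)
    safe_c = np.where(needs_offset, mean_c + offset, mean_c)
    safe_t = np.where(needs_offset, mean_t + offset, mean_t)
    fc = safe_t / safe_c
    log2fc = np.log2(fc)

    log_a = np.log2(np.where(a > 0, a, offset))
    log_b = np.log2(np.where(b > 0, b, offset))
    p = _welch_or_student(log_b, log_a, equal_var=equal_var)

    up_gate = log2_threshold(fc_up)
    down_gate = log2_threshold(fc_down)
    out = []
    for i, comp in enumerate(work.compounds):
        if p[i] < p_cutoff and log2fc[i] > up_gate:
            reg = "up"
        elif p[i] < p_cutoff and log2fc[i] < down_gate:
            reg = "down"
        else:
            reg = "unchanged"
        out.append(
            DifferentialResult(
                compound=comp,
                mean_control=float(mean_c[i]),
                mean_treated=float(mean_t[i]),
                fc=float(fc[i]),
                log2fc=float(log2fc[i]),
                p_value=float(p[i]),
                regulation=reg,
                zero_offset_used=bool(needs_offset[i]),
            )
        )
    return out


def differential_all(m: IntensityMatrix, **kwargs) -> pd.DataFrame:
    """differential_test over every tissue x cultivar group, long format."""
    rows = []
    groups = m.meta.groupby(["tissue", "cultivar"], sort=True).groups
    for tissue, cultivar in groups:
        for r in differential_test(m, tissue, cultivar, **kwargs):
            rows.append(
                {
                    "tissue": tissue,
                    "cultivar": cultivar,
                    "compound": r.compound,
                    "mean_control": r.mean_control,
                    "mean_treated": r.mean_treated,
                    "fc": r.fc,
                    "log2fc": r.log2fc,
                    "p_value": r.p_value,
                    "regulation": r.regulation,
                }
            )
    return pd.DataFrame(rows)


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up)."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0, 1)
    return out


# ---------------------------------------------------------------------------
# multivariate


@dataclass
class ClusterResult:
    """Complete-linkage dendrogram over rows of a data table."""

    linkage: np.ndarray
    labels: list[str]
    excluded: list[str] = field(default_factory=list)

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in leaves_list(self.linkage)]

    def to_newick(self) -> str:
        tree = to_tree(self.linkage)

        def walk(node) -> str:
            if node.is_leaf():
                return self.labels[node.id].replace(" ", "_")
            left, right = walk(node.left), walk(node.right)
            ld = node.dist - node.left.dist
            rd = node.dist - node.right.dist
            return f"({left}:{ld:.6f},{right}:{rd:.6f})"

        return walk(tree) + ";"


def pearson_distance(x: np.ndarray, y: np.ndarray) -> float:
    """1 - Pearson correlation; in [0, 2]."""
    r = np.corrcoef(x, y)[0, 1]
    return float(1.0 - r)


def hierarchical_cluster(data: pd.DataFrame) -> ClusterResult:
    """Complete-linkage clustering of rows under Pearson distance.

    Zero-variance rows (Pearson distance undefined) are excluded with a
    warning.  The scipy ``correlation`` metric computes exactly
    1 - Pearson r; merge order is scipy's deterministic ordering.
    """
    variances = data.var(axis=1, ddof=0)
    bad = list(data.index[variances == 0])
    if bad:
        warnings.warn(f"excluding zero-variance rows: {bad}", stacklevel=2)
        data = data.drop(index=bad)
    if len(data) < 2:
        raise ValueError("need >=2 rows with nonzero variance")
    dist = pdist(data.to_numpy(float), metric="correlation")
    z = linkage(dist, method="complete")
    return ClusterResult(z, [str(i) for i in data.index], excluded=[str(b) for b in bad])


@dataclass
class PCAResult:
    """Scores, loadings and explained-variance fractions."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance: np.ndarray
    dropped_variables: list[str] = field(default_factory=list)

    @property
    def scaled_reconstruction(self) -> np.ndarray:
        return self.scores.to_numpy() @ self.loadings.to_numpy().T


def autoscale(data: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Mean-center each variable and divide by its standard deviation."""
    mu = data.mean(axis=0)
    sd = data.std(axis=0, ddof=ddof)
    return (data - mu) / sd


def pca_autoscaled(data: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """PCA of the autoscaled (mean 0, SD 1 per variable) data matrix.

    Implemented by eigendecomposition of the covariance of the autoscaled
    matrix.  Explained-variance fractions are non-increasing; the sign of
    each component is fixed so that its largest-magnitude loading is
    positive.  Zero-variance variables are dropped with a warning.
    """
    if len(data) < 2 or data.shape[1] < 2:
        raise ValueError("need >=2 samples and >=2 variables")
    sd = data.std(axis=0, ddof=1)
    dropped = list(data.columns[sd == 0])
    if dropped:
        warnings.warn(f"dropping zero-variance variables: {dropped}", stacklevel=2)
        data = data.drop(columns=dropped)
    xs = autoscale(data).to_numpy(float)
    n, p = xs.shape
    cov = (xs.T @ xs) / (n - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]

    k = min(n - 1, p)
    if n_components is not None:
        k = min(k, n_components)
    eigval, eigvec = eigval[:k], eigvec[:, :k]

    for j in range(k):  # deterministic sign convention
        i = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[i, j] < 0:
            eigvec[:, j] = -eigvec[:, j]

    scores = xs @ eigvec
    total = np.trace(cov)
    explained = eigval / total if total > 0 else np.zeros(k)
    comp_names = [f"PC{j + 1}" for j in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=data.index, columns=comp_names),
        loadings=pd.DataFrame(eigvec, index=data.columns, columns=comp_names),
        explained_variance=explained,
        dropped_variables=[str(d) for d in dropped],
    )
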
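"""Descriptive outputs: PCA scores, volcano table, heatmap orderings,
phenotype group statistics.

These are data products, not rendered figures: the PCA returns sample
scores with explained-variance percentages, the volcano table pairs log2
fold changes with -log10 adjusted p-values and a strict adjP < alpha flag,
and the heatmap operation returns row/column leaf orders plus the linkage
trees.  Phenotype statistics use the population-SD (divisor n) convention
and a pooled two-sample two-sided Student t-test.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .io_formats import SampleInfo
from .preprocess import NormalizedMatrix


@dataclasses.dataclass
class PcaResult:
    scores: pd.DataFrame  # sample x component
    explained_pct: np.ndarray


@dataclasses.dataclass
class HeatmapOrder:
    row_order: list[str]
    col_order: list[str]
    row_linkage: np.ndarray
    col_linkage: np.ndarray


def pca_scores(
    m: NormalizedMatrix,
    feature_subset: Sequence[str] | None = None,
    n_components: int = 2,
) -> PcaResult:
    """Sample scores from centered (not scaled) PCA over the features.

    Signs follow a deterministic convention: the loading with the largest
    magnitude on each component is made positive.
    """
    X = m.values if feature_subset is None else m.values.loc[list(feature_subset)]
    data = X.to_numpy().T  # samples are observations
    if data.shape[0] < 3:
        raise ValueError("PCA needs at least 3 samples")
    n_components = min(n_components, data.shape[0] - 1, data.shape[1])
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(data)
    # sign convention: dominant loading positive
    for j in range(n_components):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1.0
    cols = [f"PC{j + 1}" for j in range(n_components)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=X.columns, columns=cols),
        explained_pct=pca.explained_variance_ratio_ * 100.0,
    )


def volcano_table(
    diff: pd.DataFrame, alpha: float = 0.05, fc_lines: float = 1.0
) -> pd.DataFrame:
    """Volcano data: logFC vs -log10 adjP with a strict adjP < alpha flag."""
    out = pd.DataFrame(index=diff.index)
    out["logFC"] = diff["logFC"]
    with np.errstate(divide="ignore"):
        out["neg_log10_adjP"] = -np.log10(diff["adjP"])
    out["significant"] = diff["adjP"] < alpha
    out.attrs["alpha"] = alpha
    out.attrs["fc_lines"] = (-fc_lines, fc_lines)
    return out


def cluster_heatmap(values: pd.DataFrame) -> HeatmapOrder:
    """Average-linkage Euclidean clustering of z-scored rows, both axes.

    Rows are standardized per feature; a constant row cannot be
    standardized and raises.  Leaf orders are deterministic (scipy's
    optimal ordering disabled; ties resolved by input order, which is
    itself sorted by id upstream).
    """
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("heatmap clustering needs >= 2 rows and >= 2 columns")
    X = values.to_numpy(dtype=float)
    sd = X.std(axis=1)
    if np.any(sd == 0):
        bad = values.index[sd == 0][0]
        raise ValueError(f"constant row cannot be standardized: {bad!r}")
    Z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    row_link = hierarchy.linkage(pdist(Z, metric="euclidean"), method="average")
    col_link = hierarchy.linkage(pdist(Z.T, metric="euclidean"), method="average")
    row_order = [values.index[i] for i in hierarchy.leaves_list(row_link)]
    col_order = [values.columns[i] for i in hierarchy.leaves_list(col_link)]
    return HeatmapOrder(row_order, col_order, row_link, col_link)


def phenotype_stats(samples: Sequence[SampleInfo]) -> pd.DataFrame:
    """Group means, population SDs and pooled t-test p per phenotype measure.

    SD uses divisor n; the comparison is the classic pooled-variance
    (equal-variance) two-sided Student t-test with n1 + n2 - 2 df.  A
    sample lacking a measurement is excluded from that measurement only.
    """
    measures = sorted({k for s in samples for k in s.phenotype})
    rows = []
    for meas in measures:
        wt = np.array(
            [s.phenotype[meas] for s in samples if s.group == "WT" and meas in s.phenotype]
        )
        ko = np.array(
            [s.phenotype[meas] for s in samples if s.group == "KO" and meas in s.phenotype]
        )
        if len(wt) < 2 or len(ko) < 2:
            raise ValueError(f"measurement {meas!r}: need >= 2 values per group")
        t, p = stats.ttest_ind(ko, wt, equal_var=True)
        rows.append(
            {
                "measurement": meas,
                "wt_mean": wt.mean(),
                "wt_sd": wt.std(ddof=0),
                "ko_mean": ko.mean(),
                "ko_sd": ko.std(ddof=0),
                "n_wt": len(wt),
                "n_ko": len(ko),
                "t": float(t),
                "p": min(1.0, float(p)),
            }
        )
    return pd.DataFrame(rows).set_index("measurement")
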
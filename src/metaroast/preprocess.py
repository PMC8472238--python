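"""Raw intensities to analysis-ready matrix: normalize, log, impute.

The fixed stage order is per-platform median scaling on the raw scale,
then a log transform (base 2 by default, so downstream group-mean
differences are log2 fold changes), then per-feature mean imputation of
missing values.  Applied to its own output the composed map is the
identity.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io_formats import FeatureMatrix, FormatError


class PreprocessError(ValueError):
    pass


@dataclasses.dataclass
class NormalizedMatrix:
    """Complete (imputed) log-scale matrix plus preprocessing provenance."""

    values: pd.DataFrame  # feature x sample, log scale, no NaN
    platform: pd.Series
    norm_factors: pd.DataFrame  # columns: platform, sample_id, factor
    imputed: pd.DataFrame  # boolean mask, True where a cell was imputed

    @property
    def n_imputed(self) -> int:
        return int(self.imputed.to_numpy().sum())


def median_normalize(m: FeatureMatrix) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Scale each sample, within each platform, to the platform's median-of-medians.

    For every platform the median of each sample's present values is taken;
    each sample is then multiplied by (cohort median-of-medians / its own
    median) so that all per-sample medians coincide.  Missing cells are
    untouched.  Returns the scaled matrix and a factor table.
    """
    values = m.values.copy()
    rows = []
    for plat in m.platform.unique():
        sub = values.loc[m.platform == plat]
        medians = sub.median(axis=0, skipna=True)
        if medians.isna().any():
            sid = medians.index[medians.isna()][0]
            raise PreprocessError(
                f"sample {sid!r} has no present values on platform {plat!r}"
            )
        target = float(np.median(medians.to_numpy()))
        factors = target / medians
        values.loc[m.platform == plat] = sub * factors
        for sid in sub.columns:
            rows.append({"platform": plat, "sample_id": sid, "factor": factors[sid]})
    return FeatureMatrix(values, m.platform.copy()), pd.DataFrame(rows)


def log_transform(
    m: FeatureMatrix, base: float = 2.0, pseudocount: float = 0.0
) -> FeatureMatrix:
    """Elementwise log of (value + pseudocount); missing cells preserved."""
    if pseudocount < 0:
        raise PreprocessError("pseudocount must be >= 0")
    vals = m.values + pseudocount
    if (vals <= 0).any().any():
        raise PreprocessError(
            "non-positive value under log transform; supply a pseudocount > 0"
        )
    out = np.log(vals) / np.log(base)
    return FeatureMatrix(out, m.platform.copy())


def impute_missing(
    m: FeatureMatrix, norm_factors: pd.DataFrame | None = None
) -> NormalizedMatrix:
    """Replace each missing cell with the mean of its feature's present values.

    The mean is taken across all samples (both groups), which biases an
    imputed feature toward the null rather than inflating its group effect.
    """
    values = m.values.copy()
    mask = values.isna()
    all_missing = mask.all(axis=1)
    if all_missing.any():
        feats = list(values.index[all_missing])
        raise PreprocessError(f"feature(s) entirely missing: {feats}")
    feature_means = values.mean(axis=1, skipna=True)
    values = values.where(~mask, feature_means, axis=0)
    if norm_factors is None:
        norm_factors = pd.DataFrame(columns=["platform", "sample_id", "factor"])
    return NormalizedMatrix(values, m.platform.copy(), norm_factors, mask)


def preprocess(
    m: FeatureMatrix, log_base: float = 2.0, pseudocount: float = 0.0
) -> NormalizedMatrix:
    """Run the full normalize -> log -> impute chain."""
    normed, factors = median_normalize(m)
    logged = log_transform(normed, base=log_base, pseudocount=pseudocount)
    return impute_missing(logged, factors)


def write_provenance(nm: NormalizedMatrix, path) -> None:
    """Serialize normalization factors and imputed-cell coordinates as TSV."""
    with open(path, "w") as fh:
        fh.write("record\tplatform\tfeature_id\tsample_id\tvalue\n")
        for _, row in nm.norm_factors.iterrows():
            fh.write(
                f"factor\t{row['platform']}\t\t{row['sample_id']}\t{row['factor']:.17g}\n"
            )
        rr, cc = np.nonzero(nm.imputed.to_numpy())
        for r, c in zip(rr, cc):
            fid = nm.imputed.index[r]
            sid = nm.imputed.columns[c]
            fh.write(f"imputed\t{nm.platform[fid]}\t{fid}\t{sid}\t\n")
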
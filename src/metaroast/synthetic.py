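"""Synthetic two-group untargeted-metabolomics datasets and in-study fixtures.

The generator emulates the statistical structure the pipeline assumes: a
feature x sample raw-intensity table from three acquisition platforms, a
partial feature->compound annotation with coeluting (multi-compound)
features, pathway sets over the uniquely identified compounds, and
per-feature log2-scale intensities whose variances follow a scaled
inverse chi-square hierarchy.  Group effects are assigned at the pathway
level (a shared mean log2 shift plus per-metabolite jitter), mirroring the
coherent pathway-level deregulation the analysis is designed to detect.
Missing values are masked completely at random by default.

``load_table1/2/3`` return machine-readable transcriptions of the study's
printed tables (per-mouse phenotypes, per-metabolite results, per-pathway
results), packaged as TSV data.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import AnnotationTable, FeatureMatrix, PathwayDB, SampleInfo

PLATFORM_TAGS = ("uplc_pos", "uplc_neg", "gcms")

PATHWAY_CATEGORIES = (
    "Carbohydrate metabolism",
    "Energy metabolism",
    "Lipid metabolism",
    "Nucleotide metabolism",
    "Amino acid metabolism",
    "Metabolism of other amino acids",
    "Metabolism of cofactors and vitamins",
)


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters; the defaults are the study conditions.

    Feature counts are scaled to 600 (a paper-scale preset exists) with the
    study's annotation and coelution fractions, 6 + 6 samples, log2 grand
    means spanning the observed average-expression range, and a variance
    hierarchy s0_2 * d0 / chi2_d0.
    """

    n1: int = 6
    n2: int = 6
    m_features: int = 600
    frac_annotated: float = 0.28
    frac_coeluting_of_annotated: float = 0.11
    n_pathways: int = 40
    pathway_size_range: tuple[int, int] = (3, 20)
    disjoint_pathways: bool = False
    frac_deregulated_pathways: float = 0.5
    effect_magnitude_range: tuple[float, float] = (0.5, 2.5)
    effect_jitter_sd: float = 0.3
    d0: float = 4.0
    s0_2: float = 0.04
    baseline_mean_range: tuple[float, float] = (11.0, 27.0)
    missing_rate: float = 0.03
    platform_split: tuple[float, float, float] = (0.49, 0.48, 0.03)
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (
            self.frac_annotated,
            self.frac_coeluting_of_annotated,
            self.frac_deregulated_pathways,
            self.missing_rate,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.pathway_size_range[0] < 3:
            raise ValueError("pathway sizes below 3 are discarded by the pipeline")


def paper_scale_spec(seed: int = 0) -> SyntheticSpec:
    """Preset matching the study's feature counts (4143 features, 283 annotated)."""
    return SyntheticSpec(
        m_features=4143,
        frac_annotated=283 / 4143,
        frac_coeluting_of_annotated=32 / 283,
        platform_split=(2037 / 4143, 2003 / 4143, 101 / 4143),
        seed=seed,
    )


@dataclasses.dataclass
class GroundTruth:
    """What the generator actually injected, for power/calibration checks."""

    pathway_shift: dict[str, float]  # pathway -> mean log2 shift (0 if null)
    deregulated: set[str]
    true_logfc: pd.Series  # per feature
    true_var: pd.Series  # per feature
    missing_mask: pd.DataFrame  # True where masked


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[FeatureMatrix, list[SampleInfo], AnnotationTable, PathwayDB, GroundTruth]:
    """Draw one dataset; a pure function of the spec (fixed seed, fixed output)."""
    rng = np.random.default_rng(spec.seed)
    m = spec.m_features
    n1, n2 = spec.n1, spec.n2
    n = n1 + n2
    feature_ids = [f"f{i:05d}" for i in range(m)]
    sample_ids = [f"WT_{i + 1}" for i in range(n1)] + [f"KO_{i + 1}" for i in range(n2)]
    samples = [
        SampleInfo(sid, "WT" if sid.startswith("WT") else "KO") for sid in sample_ids
    ]

    # platforms
    n_pos = int(round(spec.platform_split[0] * m))
    n_neg = int(round(spec.platform_split[1] * m))
    tags = (
        ["uplc_pos"] * n_pos
        + ["uplc_neg"] * n_neg
        + ["gcms"] * (m - n_pos - n_neg)
    )
    platform = pd.Series(
        tags, index=pd.Index(feature_ids, name="feature_id"), name="platform"
    )

    # annotation: unique compounds first, then 2-3-name coeluting features
    n_ann = int(round(spec.frac_annotated * m))
    n_coel = int(round(spec.frac_coeluting_of_annotated * n_ann))
    n_unique = n_ann - n_coel
    ann_features = list(rng.choice(m, size=n_ann, replace=False))
    compounds: dict[str, list[str]] = {}
    for j in range(n_unique):
        compounds[feature_ids[ann_features[j]]] = [f"compound_{j:04d}"]
    extra = n_unique
    for j in range(n_unique, n_ann):
        k = int(rng.integers(2, 4))
        compounds[feature_ids[ann_features[j]]] = [
            f"compound_{extra + i:04d}" for i in range(k)
        ]
        extra += k
    ann = AnnotationTable(compounds)
    unique_fids = [feature_ids[ann_features[j]] for j in range(n_unique)]
    unique_compounds = [compounds[f][0] for f in unique_fids]
    compound_of = dict(zip(unique_fids, unique_compounds))

    # pathways over unique compounds
    lo, hi = spec.pathway_size_range
    sizes = rng.integers(lo, hi + 1, size=spec.n_pathways)
    if spec.disjoint_pathways and sizes.sum() > n_unique:
        raise ValueError(
            f"infeasible spec: {int(sizes.sum())} disjoint pathway slots but only "
            f"{n_unique} unique compounds"
        )
    if max(lo, hi) > n_unique:
        raise ValueError("pathway sizes exceed available unique compounds")
    members: dict[str, set[str]] = {}
    category: dict[str, str] = {}
    pool = list(rng.permutation(unique_compounds))
    offset = 0
    for k in range(spec.n_pathways):
        name = f"pathway_{k:03d}"
        if spec.disjoint_pathways:
            chosen = pool[offset : offset + sizes[k]]
            offset += sizes[k]
        else:
            chosen = list(rng.choice(unique_compounds, size=sizes[k], replace=False))
        members[name] = set(chosen)
        category[name] = PATHWAY_CATEGORIES[k % len(PATHWAY_CATEGORIES)]
    db = PathwayDB(members, category)

    # pathway-level effects with per-metabolite jitter; first assignment wins
    # for compounds shared between overlapping deregulated pathways
    n_dereg = int(round(spec.frac_deregulated_pathways * spec.n_pathways))
    dereg = set(
        f"pathway_{k:03d}"
        for k in rng.choice(spec.n_pathways, size=n_dereg, replace=False)
    )
    pathway_shift = {}
    feature_of_compound = {c: f for f, c in compound_of.items()}
    delta = pd.Series(0.0, index=feature_ids)
    for name in sorted(members):
        if name in dereg:
            mag = rng.uniform(*spec.effect_magnitude_range)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            shift = sign * mag
            for c in sorted(members[name]):
                fid = feature_of_compound[c]
                if delta[fid] == 0.0:
                    delta[fid] = shift + rng.normal(0.0, spec.effect_jitter_sd)
        else:
            shift = 0.0
        pathway_shift[name] = shift

    # hierarchical variances and log2-scale intensities
    sigma2 = spec.s0_2 * spec.d0 / rng.chisquare(spec.d0, size=m)
    mu = rng.uniform(*spec.baseline_mean_range, size=m)
    log_vals = rng.normal(0.0, 1.0, size=(m, n)) * np.sqrt(sigma2)[:, None]
    log_vals += mu[:, None]
    log_vals[:, n1:] += delta.to_numpy()[:, None]
    raw = np.exp2(log_vals)

    # MCAR mask, guarded so no feature loses every value
    mask = rng.random((m, n)) < spec.missing_rate
    full_rows = mask.all(axis=1)
    if full_rows.any():
        keep = rng.integers(0, n, size=int(full_rows.sum()))
        mask[np.nonzero(full_rows)[0], keep] = False
    raw = np.where(mask, np.nan, raw)

    values = pd.DataFrame(raw, index=feature_ids, columns=sample_ids)
    values.index.name = "feature_id"
    truth = GroundTruth(
        pathway_shift=pathway_shift,
        deregulated=dereg,
        true_logfc=delta,
        true_var=pd.Series(sigma2, index=feature_ids),
        missing_mask=pd.DataFrame(mask, index=feature_ids, columns=sample_ids),
    )
    return FeatureMatrix(values, platform), samples, ann, db, truth


# ---------------------------------------------------------------------------
# in-study fixtures (printed tables, transcribed as package data)


def _data_path(name: str):
    return resources.files("metaroast.data").joinpath(name)


def load_table1() -> pd.DataFrame:
    """Per-mouse phenotypes: 6 WT and 6 KO mice x 4 measurements."""
    with resources.as_file(_data_path("table1_phenotypes.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype={"sample_id": str})


def table1_samples() -> list[SampleInfo]:
    df = load_table1()
    measures = [c for c in df.columns if c not in ("sample_id", "group")]
    return [
        SampleInfo(
            str(r["sample_id"]), str(r["group"]), {m: float(r[m]) for m in measures}
        )
        for _, r in df.iterrows()
    ]


def load_table2() -> pd.DataFrame:
    """Published per-metabolite results: 101 significant metabolites."""
    with resources.as_file(_data_path("table2_metabolites.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_table3() -> pd.DataFrame:
    """Published per-pathway results: 41 tested KEGG metabolism pathways."""
    with resources.as_file(_data_path("table3_pathways.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def make_paper_fixtures() -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    return load_table1(), load_table2(), load_table3()
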
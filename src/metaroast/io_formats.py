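"""Readers and writers for every external representation the pipeline touches.

Intensity tables arrive as TSV/CSV with one row per LC-MS/GC-MS feature
(first column the feature id, second the acquisition platform, remaining
columns one per sample); missing measurements are empty cells or a sentinel.
Annotations map features to one or more reference compounds (coeluting
features match several).  Pathway membership uses the standard GMT layout.
Result tables mirror the schema of published per-metabolite and per-pathway
tables.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

PLATFORMS = ("uplc_pos", "uplc_neg", "gcms")

MISSING_SENTINEL = "NA"

#: separator joining coeluting compound names in annotation files
ANNOTATION_SEPARATOR = ";"


class FormatError(ValueError):
    """Raised when an input file violates a format invariant."""


@dataclasses.dataclass
class FeatureMatrix:
    """Feature x sample intensity matrix with per-feature platform tags.

    ``values`` is a float DataFrame indexed by feature id with sample-id
    columns; missing measurements are NaN.  On the raw scale every present
    value must be non-negative.
    """

    values: pd.DataFrame
    platform: pd.Series  # feature id -> tag in PLATFORMS

    def __post_init__(self) -> None:
        idx = self.values.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicate feature id: {dup!r}")
        cols = self.values.columns
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        bad = set(self.platform.unique()) - set(PLATFORMS)
        if bad:
            raise FormatError(f"unknown platform tag(s): {sorted(bad)}")
        if not self.platform.index.equals(idx):
            raise FormatError("platform tags do not align with feature ids")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().sum().sum())

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(self.values.copy(), self.platform.copy())


@dataclasses.dataclass(frozen=True)
class SampleInfo:
    """Group label and optional phenotype measurements for one sample."""

    sample_id: str
    group: str  # "WT" or "KO"
    phenotype: Mapping[str, float] = dataclasses.field(default_factory=dict)


def check_design(samples: Sequence[SampleInfo], sample_ids: Iterable[str]) -> None:
    """Validate that every matrix sample has exactly one record and both groups exist."""
    by_id: dict[str, SampleInfo] = {}
    for s in samples:
        if s.sample_id in by_id:
            raise FormatError(f"duplicate sample record: {s.sample_id!r}")
        by_id[s.sample_id] = s
    missing = [sid for sid in sample_ids if sid not in by_id]
    if missing:
        raise FormatError(f"samples without metadata: {missing}")
    groups = {s.group for s in samples}
    if not {"WT", "KO"} <= groups:
        raise FormatError(f"both group labels WT and KO required, got {sorted(groups)}")


@dataclasses.dataclass
class AnnotationTable:
    """Feature -> compound-name mapping; coeluting features map to several."""

    compounds: dict[str, list[str]]  # feature id -> ordered compound names

    def is_unique(self, feature_id: str) -> bool:
        return len(self.compounds[feature_id]) == 1

    @property
    def unique_features(self) -> dict[str, str]:
        """Uniquely identified features and their single compound name."""
        return {f: c[0] for f, c in self.compounds.items() if len(c) == 1}

    @property
    def n_coeluting(self) -> int:
        return sum(len(c) > 1 for c in self.compounds.values())


@dataclasses.dataclass
class PathwayDB:
    """Named metabolite sets with an optional category per pathway."""

    members: dict[str, set[str]]  # pathway name -> compound names
    category: dict[str, str]  # pathway name -> category ("" if none)


# ---------------------------------------------------------------------------
# readers


def read_feature_matrix(
    path: str | Path,
    dialect: str = "tsv",
    missing_sentinel: str = MISSING_SENTINEL,
) -> FeatureMatrix:
    """Read an intensity table: feature id, platform tag, then one column per sample."""
    sep = {"tsv": "\t", "csv": ","}[dialect]
    # pandas mangles duplicate headers to "x.1"; detect from the raw header
    raw = _raw_header(path, sep)
    seen: set[str] = set()
    for name in raw[2:]:
        if name in seen:
            raise FormatError(f"duplicate sample id: {name!r}")
        seen.add(name)
    df = pd.read_csv(
        path,
        sep=sep,
        na_values=[missing_sentinel, ""],
        keep_default_na=False,
        float_precision="round_trip",
    )
    if df.shape[1] < 3:
        raise FormatError("expected feature id, platform and >=1 sample column")
    feature_col, platform_col = df.columns[0], df.columns[1]
    df[feature_col] = df[feature_col].astype(str)
    df[platform_col] = df[platform_col].astype(str)
    values = df.set_index(feature_col)[df.columns[2:]].apply(
        pd.to_numeric, errors="raise"
    )
    values.index.name = "feature_id"
    if (values < 0).any().any():
        feat = values.index[(values < 0).any(axis=1)][0]
        raise FormatError(f"negative intensity in feature {feat!r}")
    platform = df.set_index(feature_col)[platform_col]
    platform.name = "platform"
    return FeatureMatrix(values, platform)


def _raw_header(path: str | Path, sep: str) -> list[str]:
    with open(path) as fh:
        return fh.readline().rstrip("\n").split(sep)


def write_feature_matrix(
    m: FeatureMatrix,
    path: str | Path,
    dialect: str = "tsv",
    missing_sentinel: str = MISSING_SENTINEL,
) -> None:
    sep = {"tsv": "\t", "csv": ","}[dialect]
    out = m.values.copy()
    out.insert(0, "platform", m.platform)
    # 17 significant digits round-trip an IEEE double bit-identically
    out.to_csv(path, sep=sep, na_rep=missing_sentinel, float_format="%.17g")


def read_sample_info(path: str | Path) -> list[SampleInfo]:
    """Read sample metadata: sample_id, group, then optional phenotype columns."""
    df = pd.read_csv(path, sep="\t")
    df[df.columns[0]] = df[df.columns[0]].astype(str)
    records = []
    pheno_cols = [c for c in df.columns[2:]]
    for _, row in df.iterrows():
        pheno = {c: float(row[c]) for c in pheno_cols if pd.notna(row[c])}
        records.append(SampleInfo(str(row.iloc[0]), str(row.iloc[1]), pheno))
    check_design(records, [r.sample_id for r in records])
    return records


def write_sample_info(samples: Sequence[SampleInfo], path: str | Path) -> None:
    pheno_cols = sorted({k for s in samples for k in s.phenotype})
    rows = [
        {"sample_id": s.sample_id, "group": s.group, **s.phenotype} for s in samples
    ]
    pd.DataFrame(rows, columns=["sample_id", "group", *pheno_cols]).to_csv(
        path, sep="\t", index=False
    )


def read_annotation(
    path: str | Path, separator: str = ANNOTATION_SEPARATOR
) -> AnnotationTable:
    """Read a two-column feature->compound table; coeluting names joined by ``separator``."""
    compounds: dict[str, list[str]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header:
            raise FormatError("empty annotation file")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"line {lineno}: expected 2 columns")
            fid, names = parts
            if fid in compounds:
                raise FormatError(f"duplicate feature id: {fid!r}")
            comp = [c.strip() for c in names.split(separator)]
            if not all(comp) or not comp:
                raise FormatError(f"line {lineno}: empty compound name for {fid!r}")
            compounds[fid] = comp
    return AnnotationTable(compounds)


def write_annotation(
    ann: AnnotationTable, path: str | Path, separator: str = ANNOTATION_SEPARATOR
) -> None:
    with open(path, "w") as fh:
        fh.write("feature_id\tcompounds\n")
        for fid, comp in ann.compounds.items():
            fh.write(f"{fid}\t{separator.join(comp)}\n")


def read_gmt(path: str | Path) -> PathwayDB:
    """Read pathway sets in GMT layout: name, category/description, members."""
    members: dict[str, set[str]] = {}
    category: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"line {lineno}: GMT line needs >= 3 fields")
            name, cat = parts[0], parts[1]
            if name in members:
                raise FormatError(f"duplicate pathway name: {name!r}")
            mem = {p for p in parts[2:] if p}
            if not mem:
                raise FormatError(f"line {lineno}: pathway {name!r} has no members")
            members[name] = mem
            category[name] = cat
    return PathwayDB(members, category)


def write_gmt(db: PathwayDB, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, mem in db.members.items():
            fields = [name, db.category.get(name, ""), *sorted(mem)]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# result tables

DIFF_COLUMNS = ["compound", "logFC", "aveExpr", "p", "adjP"]
DIFF_FULL_COLUMNS = ["compound", "logFC", "aveExpr", "t", "df", "z", "p", "adjP"]
PATHWAY_COLUMNS = [
    "pathway",
    "n_features",
    "n_down",
    "n_up",
    "direction",
    "p",
    "adjP",
    "group",
]


def write_results(
    diff: pd.DataFrame,
    pathways: pd.DataFrame,
    out_dir: str | Path,
    full: bool = False,
    sig_digits: int = 6,
) -> tuple[Path, Path]:
    """Write the per-metabolite and per-pathway result TSVs.

    Column order mirrors the published tables: metabolite results carry
    compound, log2 fold change, average expression, raw and adjusted p;
    pathway results carry the feature and up/down contributor counts, a
    literal "Up"/"Down" direction, raw/adjusted p and the pathway category.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fmt = f"%.{sig_digits}g"
    diff_cols = DIFF_FULL_COLUMNS if full else DIFF_COLUMNS
    diff_path = out_dir / "metabolites.tsv"
    pw_path = out_dir / "pathways.tsv"
    _frame_with_columns(diff, diff_cols).to_csv(
        diff_path, sep="\t", index=False, float_format=fmt
    )
    _frame_with_columns(pathways, PATHWAY_COLUMNS).to_csv(
        pw_path, sep="\t", index=False, float_format=fmt
    )
    return diff_path, pw_path


def _frame_with_columns(df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    if df.empty:
        return pd.DataFrame(columns=columns)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"result table missing columns: {missing}")
    return df[columns]


def read_diff_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_pathway_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "direction" in df.columns and not df.empty:
        bad = set(df["direction"]) - {"Up", "Down"}
        if bad:
            raise FormatError(f"bad direction value(s): {sorted(bad)}")
    return df
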
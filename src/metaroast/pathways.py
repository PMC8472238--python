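"""ROAST-style rotation test for pathway deregulation.

Each pathway is scored by the arithmetic mean of its member metabolites'
standard-normal-equivalent z scores.  Significance comes from a rotation
null: per feature the n-sample vector is reduced to an effect coordinate
u_g = logFC_g / sqrt(1/n1 + 1/n2) plus d = n1 + n2 - 2 residual coordinates
r_g in a fixed orthonormal basis of the residual space, so that
||r_g||^2 / d = s2_g and u_g / sqrt(s2_g) is the unmoderated t.  A rotation
replaces the effect direction by a random unit vector rho on the sphere in
R^(d+1) — shared across all features within one rotation, which preserves
inter-metabolite correlation — giving rotated effects u*_g = rho' y_g and
rotated variances s*2_g = (||y_g||^2 - u*_g^2)/d, which are pushed through
the same moderation and z-transform path with the prior frozen at its
observed-data estimate.  The rotation test stays exact at very small sample
sizes where permutation of 6+6 labels is too coarse.

Only uniquely identified metabolites enter pathway sets, and sets with
fewer than three identified metabolites are discarded before testing.
Metabolites with |z| above sqrt(2) are counted as up/down contributors.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd

from .diffstats import (
    EBayesPrior,
    GroupDesign,
    bh_adjust,
    split_groups,
    t_to_z,
)
from .io_formats import AnnotationTable, PathwayDB, SampleInfo
from .preprocess import NormalizedMatrix

CONTRIBUTOR_THRESHOLD = math.sqrt(2.0)

DEFAULT_ROTATIONS = 9999
MIN_SET_SIZE = 3


class ConfigError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class RotationConfig:
    n_rotations: int = DEFAULT_ROTATIONS
    seed: int = 0
    contributor_threshold: float = CONTRIBUTOR_THRESHOLD
    alternative: str = "directional"  # or "mixed"

    def __post_init__(self) -> None:
        if self.n_rotations < 99:
            raise ConfigError("need at least 99 rotations")
        if self.contributor_threshold <= 0:
            raise ConfigError("contributor threshold must be > 0")
        if self.alternative not in ("directional", "mixed"):
            raise ConfigError(f"unknown alternative {self.alternative!r}")


@dataclasses.dataclass
class PathwaySet:
    """A pathway restricted to uniquely identified, tested metabolites."""

    name: str
    category: str
    metabolite_ids: list[str]  # feature ids, sorted for determinism

    def __len__(self) -> int:
        return len(self.metabolite_ids)


@dataclasses.dataclass
class RotationFrames:
    """Per-feature (effect, residual) coordinates for the whole matrix."""

    Y: np.ndarray  # m x (d+1): column 0 is u_g, the rest residual coords
    feature_ids: list[str]
    design: GroupDesign

    @property
    def u(self) -> np.ndarray:
        return self.Y[:, 0]

    @property
    def s2(self) -> np.ndarray:
        d = self.design.df_residual
        return (self.Y[:, 1:] ** 2).sum(axis=1) / d


def build_pathway_sets(
    db: PathwayDB,
    ann: AnnotationTable,
    tested: set[str] | Sequence[str],
    min_size: int = MIN_SET_SIZE,
) -> tuple[list[PathwaySet], int]:
    """Intersect pathways with uniquely identified, tested compounds.

    ``tested`` is the set of feature ids with a z score.  Returns the
    retained sets (size >= min_size) and the number discarded.
    """
    tested = set(tested)
    unique = ann.unique_features  # feature id -> compound
    compound_to_feature: dict[str, str] = {}
    for fid in sorted(unique):
        if fid in tested:
            # first feature id wins for a duplicated compound name
            compound_to_feature.setdefault(unique[fid], fid)
    sets: list[PathwaySet] = []
    discarded = 0
    for name in sorted(db.members):
        fids = sorted(
            compound_to_feature[c] for c in db.members[name] if c in compound_to_feature
        )
        if len(fids) >= min_size:
            sets.append(PathwaySet(name, db.category.get(name, ""), fids))
        else:
            discarded += 1
    return sets, discarded


def pathway_score(z: pd.Series, pset: PathwaySet) -> float:
    """Mean z over the pathway's members; the deregulation statistic."""
    missing = [f for f in pset.metabolite_ids if f not in z.index]
    if missing:
        raise KeyError(f"members without z score: {missing}")
    return float(z.loc[pset.metabolite_ids].mean())


def count_contributors(
    z: pd.Series, pset: PathwaySet, threshold: float = CONTRIBUTOR_THRESHOLD
) -> tuple[int, int]:
    """(n_up, n_down) with strict |z| > threshold comparisons."""
    zz = z.loc[pset.metabolite_ids].to_numpy()
    return int((zz > threshold).sum()), int((zz < -threshold).sum())


def make_rotation_frames(
    m: NormalizedMatrix, samples: Sequence[SampleInfo]
) -> RotationFrames:
    """Project every feature onto (contrast direction, residual basis).

    The orthonormal residual basis is fixed deterministically per run (QR of
    the complement of the group-means design), so frames and downstream
    rotation p-values are reproducible for a given seed.
    """
    wt, ko = split_groups(m, samples)
    design = GroupDesign(n1=len(wt), n2=len(ko))
    n1, n2 = design.n1, design.n2
    n = n1 + n2
    X = m.values[wt + ko].to_numpy()  # m x n, WT first

    # contrast unit vector: (KO mean - WT mean) scaled to unit norm
    c = np.concatenate([np.full(n1, -1.0 / n1), np.full(n2, 1.0 / n2)])
    c /= np.linalg.norm(c)  # X @ c = logFC / sqrt(1/n1 + 1/n2) = u
    ones = np.ones(n) / math.sqrt(n)
    # deterministic orthonormal basis of the residual space
    basis = np.column_stack([ones, c, np.eye(n)])
    q, _ = np.linalg.qr(basis)
    R = q[:, 2 : n]  # n x d, orthogonal to intercept and contrast
    u = X @ c
    r = X @ R
    Y = np.column_stack([u, r])
    return RotationFrames(Y=Y, feature_ids=list(m.values.index), design=design)


def _rotation_unit_vectors(B: int, dim: int, rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal((B, dim))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def roast_test(
    frames: RotationFrames,
    sets: Sequence[PathwaySet],
    prior: EBayesPrior | None,
    cfg: RotationConfig = RotationConfig(),
) -> pd.DataFrame:
    """Rotation p-values for every pathway set.

    The prior is frozen: it is estimated once from the observed data and
    reused for every rotation.  p_up and p_down use the +1 add-one
    convention (ties count as exceeding), so p >= 1/(B+1); the directional
    two-sided p is 2 * min(p_up, p_down) capped at 1, the mixed alternative
    compares |mean z| instead.
    """
    if len(sets) == 0:
        return pd.DataFrame(
            columns=[
                "pathway", "n_features", "n_down", "n_up",
                "direction", "p", "adjP", "group",
            ]
        )
    d = frames.design.df_residual
    B = cfg.n_rotations
    rng = np.random.default_rng(cfg.seed)

    z_obs = _frame_z(frames.u, frames.s2, frames, prior)
    z_obs_s = pd.Series(z_obs, index=frames.feature_ids)

    # rotated effects for all features under all rotations, in blocks to
    # bound memory at paper scale (m ~ 4000, B ~ 10^4)
    idx = {f: i for i, f in enumerate(frames.feature_ids)}
    member_idx = [np.array([idx[f] for f in s.metabolite_ids]) for s in sets]
    S_obs = np.array([z_obs[mi].mean() for mi in member_idx])

    norm2 = (frames.Y ** 2).sum(axis=1)
    ge = np.zeros(len(sets), dtype=np.int64)  # #{S* >= S_obs}
    le = np.zeros(len(sets), dtype=np.int64)
    ge_abs = np.zeros(len(sets), dtype=np.int64)
    block = max(1, int(5e6 // max(1, frames.Y.shape[0])))
    done = 0
    while done < B:
        nb = min(block, B - done)
        rho = _rotation_unit_vectors(nb, frames.Y.shape[1], rng)  # nb x (d+1)
        u_star = frames.Y @ rho.T  # m x nb
        s2_star = np.maximum(norm2[:, None] - u_star**2, 0.0) / d
        z_star = _frame_z(u_star, s2_star, frames, prior)
        for k, mi in enumerate(member_idx):
            S_star = z_star[mi].mean(axis=0)
            ge[k] += int((S_star >= S_obs[k]).sum())
            le[k] += int((S_star <= S_obs[k]).sum())
            ge_abs[k] += int((np.abs(S_star) >= abs(S_obs[k])).sum())
        done += nb

    p_up = (ge + 1) / (B + 1)
    p_down = (le + 1) / (B + 1)
    if cfg.alternative == "directional":
        p = np.minimum(1.0, 2.0 * np.minimum(p_up, p_down))
    else:
        p = (ge_abs + 1) / (B + 1)
    rows = []
    for k, s in enumerate(sets):
        n_up, n_down = count_contributors(z_obs_s, s, cfg.contributor_threshold)
        rows.append(
            {
                "pathway": s.name,
                "n_features": len(s),
                "n_down": n_down,
                "n_up": n_up,
                "direction": "Up" if S_obs[k] >= 0 else "Down",
                "p": p[k],
                "group": s.category,
            }
        )
    out = pd.DataFrame(rows)
    out["adjP"] = bh_adjust(out["p"].to_numpy())
    return out[
        ["pathway", "n_features", "n_down", "n_up", "direction", "p", "adjP", "group"]
    ]


def _frame_z(
    u: np.ndarray, s2: np.ndarray, frames: RotationFrames, prior: EBayesPrior | None
) -> np.ndarray:
    """Moderated t and z for (possibly rotated) effect/variance arrays."""
    d = frames.design.df_residual
    if prior is None or prior.d0 == 0:
        s2_post, df_total = s2, float(d)
    elif math.isinf(prior.d0):
        s2_post, df_total = np.broadcast_to(prior.s0_2, np.shape(s2)), math.inf
    else:
        s2_post = (prior.d0 * prior.s0_2 + d * s2) / (prior.d0 + d)
        df_total = d + prior.d0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(s2_post > 0, u / np.sqrt(np.where(s2_post > 0, s2_post, 1.0)), 0.0)
    return t_to_z(t, df_total)
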
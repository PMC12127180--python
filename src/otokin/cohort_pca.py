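"""Cross-cohort resampling PCA of morpho-behavioral feature vectors.

Different measurements (oculomotor gains, canal morphometry, swim
statistics) come from different cohorts of animals, so each animal's
feature vector has missing entries. The integration strategy treats each
variable as an independent within-species distribution: missing cells are
imputed by drawing with replacement from the observed values of that
variable in the same species, the completed matrix is z-scored per
variable, and the whole procedure is repeated (10,000 replicates by
default) so the principal components can be averaged across replicates.
A most-representative replicate (minimum elementwise squared distance to
the replicate mean) provides the dataset that is finally projected onto
the averaged components; loadings scaled by explained variance give the
variable-contribution map.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd


class CoverageError(ValueError):
    """A variable has no observed value in one species."""


class RankError(ValueError):
    pass


@dataclasses.dataclass
class FeatureVector:
    """Per-animal named measures with possible missing entries."""

    animal_id: str
    species: str
    measures: dict[str, float]

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("species label required")
        if not any(np.isfinite(v) for v in self.measures.values()):
            raise ValueError("at least one measure must be observed")


def cohort_frame(cohort: Sequence[FeatureVector] | pd.DataFrame) -> pd.DataFrame:
    """Normalize a cohort to a DataFrame with animal_id/species + variables."""
    if isinstance(cohort, pd.DataFrame):
        return cohort.copy()
    rows = [
        {"animal_id": fv.animal_id, "species": fv.species} | fv.measures
        for fv in cohort
    ]
    return pd.DataFrame(rows)


@dataclasses.dataclass
class ResampledDataset:
    """One completed, z-scored replicate of the cohort matrix."""

    data: np.ndarray  # (animals, variables), zero-mean unit-scale columns
    center: np.ndarray  # per-variable mean before scaling
    scale: np.ndarray  # per-variable SD before scaling
    animals: list[str]
    species: list[str]
    variables: list[str]
    replicate_index: int
    seed: int


def _pca(Z: np.ndarray, n_components: int) -> tuple[np.ndarray, np.ndarray]:
    """Principal axes (rows) and explained-variance fractions of Z."""
    Zc = Z - Z.mean(axis=0)
    _, svals, vt = np.linalg.svd(Zc, full_matrices=False)
    var = svals**2
    total = var.sum()
    if total <= 0 or np.linalg.matrix_rank(Zc) < n_components:
        raise RankError("matrix rank below the requested component count")
    return vt[:n_components], var[:n_components] / total


def _align_signs(components: np.ndarray) -> np.ndarray:
    """Fix each component's sign so its largest-magnitude loading is positive."""
    out = components.copy()
    for k in range(len(out)):
        j = int(np.argmax(np.abs(out[k])))
        if out[k, j] < 0:
            out[k] = -out[k]
    return out


# ---------------------------------------------------------------------------
# cross-section shape features


def cs_features(
    profiles: Sequence[np.ndarray], n_components: int = 5, n_interp: int = 200
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unsupervised shape features of canal cross-section profiles.

    Profiles are interpolated to a common length, centered around the
    across-animal mean profile, and decomposed by PCA; the first
    ``n_components`` scores per animal are the canal cross-section
    features. Returns ``(scores, component_shapes, variance_fractions)``
    so the component shapes (mean offset, localized constriction, ...)
    can be inspected.
    """
    if len(profiles) < n_components + 1:
        raise RankError("need more profiles than components")
    grid = np.linspace(0.0, 1.0, n_interp)
    mat = np.stack(
        [
            np.interp(grid, np.linspace(0.0, 1.0, len(p)), np.asarray(p, float))
            for p in profiles
        ]
    )
    centered = mat - mat.mean(axis=0)
    if not centered.any():
        raise RankError("all profiles identical; centered data has rank 0")
    comps, varfrac = _pca(centered, n_components)
    comps = _align_signs(comps)
    scores = centered @ comps.T
    return scores, comps, varfrac


# ---------------------------------------------------------------------------
# resampling


def resample_cohorts(
    cohort: Sequence[FeatureVector] | pd.DataFrame,
    n_reps: int = 10_000,
    seed: int = 0,
    species_restricted: bool = True,
) -> list[ResampledDataset]:
    """Complete the cohort by within-species resampling, ``n_reps`` times.

    Observed entries are preserved exactly in every replicate; each
    missing cell is drawn with replacement from the observed values of
    that variable in the same species (or the whole cohort when
    ``species_restricted`` is off). Each replicate is z-scored per
    variable with its own statistics.
    """
    df = cohort_frame(cohort)
    variables = [c for c in df.columns if c not in ("animal_id", "species")]
    animals = df["animal_id"].astype(str).tolist()
    species = df["species"].astype(str).tolist()
    X = df[variables].to_numpy(dtype=float)
    n, p = X.shape

    donor_pools: dict[tuple[int, int], np.ndarray] = {}
    sp_codes, sp_index = np.unique(species, return_inverse=True)
    for j in range(p):
        for si in range(len(sp_codes)):
            sel = (sp_index == si) & np.isfinite(X[:, j])
            pool = X[sel, j] if species_restricted else X[np.isfinite(X[:, j]), j]
            if pool.size == 0:
                raise CoverageError(
                    f"variable {variables[j]!r} unobserved in species "
                    f"{sp_codes[si]!r}"
                )
            donor_pools[(j, si)] = pool

    missing = ~np.isfinite(X)
    miss_idx = np.argwhere(missing)
    rng = np.random.default_rng(seed)
    reps = []
    for rep in range(n_reps):
        M = X.copy()
        for i, j in miss_idx:
            pool = donor_pools[(j, sp_index[i])]
            M[i, j] = pool[rng.integers(pool.size)]
        center = M.mean(axis=0)
        scale = M.std(axis=0)
        scale = np.where(scale > 0, scale, 1.0)
        reps.append(
            ResampledDataset(
                data=(M - center) / scale,
                center=center,
                scale=scale,
                animals=animals,
                species=species,
                variables=variables,
                replicate_index=rep,
                seed=seed,
            )
        )
    return reps


def average_components(
    replicates: Sequence[ResampledDataset], n_components: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Average per-replicate principal components after sign alignment.

    Each replicate's components are sign-fixed (largest-magnitude loading
    positive), averaged loading-wise across replicates, re-orthonormalized
    (Gram-Schmidt in component order) and sign-fixed again. Returns
    ``(components, mean_variance_fractions)``.
    """
    if len(replicates) < 2:
        raise ValueError("need at least two replicates")
    n_components = min(n_components, len(replicates[0].variables))
    acc = None
    var_acc = None
    for rep in replicates:
        comps, varfrac = _pca(rep.data, n_components)
        comps = _align_signs(comps)
        acc = comps if acc is None else acc + comps
        var_acc = varfrac if var_acc is None else var_acc + varfrac
    mean_comps = acc / len(replicates)
    # Gram-Schmidt re-orthonormalization in component order
    q = []
    for k in range(n_components):
        v = mean_comps[k].copy()
        for u in q:
            v -= (v @ u) * u
        norm = np.linalg.norm(v)
        if norm < 1e-12:
            raise RankError("averaged components collapsed; increase replicates")
        q.append(v / norm)
    comps = _align_signs(np.stack(q))
    return comps, var_acc / len(replicates)


def representative_dataset(
    replicates: Sequence[ResampledDataset],
) -> ResampledDataset:
    """Replicate closest (elementwise sum of squares) to the replicate mean.

    Ties break toward the lowest replicate index.
    """
    if not replicates:
        raise ValueError("empty replicate list")
    stack = np.stack([r.data for r in replicates])
    mean = stack.mean(axis=0)
    dists = ((stack - mean) ** 2).sum(axis=(1, 2))
    return replicates[int(np.argmin(dists))]


def project(dataset: ResampledDataset, components: np.ndarray) -> np.ndarray:
    """Score matrix: normalized data projected onto the components."""
    if dataset.data.shape[1] != components.shape[1]:
        raise ValueError("dimension mismatch between data and components")
    return dataset.data @ components.T


def loading_map(components: np.ndarray, variance_fractions: np.ndarray) -> np.ndarray:
    """Variable-by-component loadings scaled by explained variance.

    Signs are retained: positive entries mark variables that co-vary with
    the component, negative entries anti-vary.
    """
    components = np.asarray(components, float)
    vf = np.asarray(variance_fractions, float)
    return (components * vf[:, None]).T


def run_cohort_pca(
    cohort: Sequence[FeatureVector] | pd.DataFrame,
    n_reps: int = 10_000,
    n_components: int = 5,
    seed: int = 0,
) -> dict:
    """Full integration: resample, average PCs, pick representative, project."""
    reps = resample_cohorts(cohort, n_reps=n_reps, seed=seed)
    comps, varfrac = average_components(reps, n_components=n_components)
    rep = representative_dataset(reps)
    scores = project(rep, comps)
    return {
        "components": comps,
        "variance_fractions": varfrac,
        "representative": rep,
        "scores": scores,
        "loading_map": loading_map(comps, varfrac),
    }
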
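"""Representational similarity analysis.

First-order dissimilarity is 1 - Pearson correlation between items'
multivariate patterns; second-order comparison between RDMs is Spearman's
rho over the strict lower triangle.  Inference covers ROI permutation
tests (item-relabeling nulls with Bonferroni correction), leave-one-
subject-out noise ceilings, a voxel-grid searchlight, group-level
sign-flip permutation with Benjamini-Hochberg FDR, and the composite
best-stage map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .syndata import StageRepresentation, SyntheticBrain

__all__ = [
    "RDM",
    "RSAResult",
    "GroupResult",
    "compute_rdm",
    "compute_rdm_from_patterns",
    "compare_rdms",
    "roi_permutation_test",
    "noise_ceiling_lower",
    "searchlight_map",
    "group_inference",
    "composite_best_stage_map",
]


@dataclass
class RDM:
    """Item x item representational dissimilarity (1 - Pearson)."""

    items: list[str]
    matrix: np.ndarray

    def validate(self) -> None:
        M = self.matrix
        if M.shape[0] != M.shape[1] or M.shape[0] != len(self.items):
            raise ValueError("RDM must be square over the item list")
        if not np.all(np.isfinite(M)):
            raise ValueError("non-finite RDM")
        if not np.allclose(M, M.T):
            raise ValueError("RDM must be symmetric")
        if not np.allclose(np.diag(M), 0.0):
            raise ValueError("RDM diagonal must be zero")
        if M.min() < -1e-9 or M.max() > 2 + 1e-9:
            raise ValueError("1 - Pearson dissimilarities must lie in [0, 2]")

    def triangle(self) -> np.ndarray:
        """Strict lower-triangle entries as a vector."""
        i, j = np.tril_indices(self.matrix.shape[0], k=-1)
        return self.matrix[i, j]


def compute_rdm_from_patterns(patterns: np.ndarray, items: list[str] | None = None) -> RDM:
    """RDM of an item x measurement-channel matrix."""
    X = np.asarray(patterns, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 items for an RDM")
    sd = X.std(axis=1)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        name = items[bad] if items is not None else f"item {bad}"
        raise ValueError(f"constant pattern (zero variance) for {name}")
    if items is None:
        items = [f"item{i}" for i in range(X.shape[0])]
    D = 1.0 - np.corrcoef(X)
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    rdm = RDM(items=list(items), matrix=D)
    rdm.validate()
    return rdm


def compute_rdm(rep: StageRepresentation) -> RDM:
    """RDM of a stage representation (1 - Pearson between item patterns)."""
    return compute_rdm_from_patterns(rep.matrix, items=rep.items)


def compare_rdms(rdm_a: RDM, rdm_b: RDM) -> float:
    """Spearman's rho between two RDMs over the strict lower triangle."""
    if rdm_a.items != rdm_b.items:
        raise ValueError("RDMs are over different item sets or orders")
    rho = stats.spearmanr(rdm_a.triangle(), rdm_b.triangle()).statistic
    return float(rho)


@dataclass
class RSAResult:
    """Per-stage model fit for one unit of analysis (ROI or voxel)."""

    unit: str
    stage_ids: list[str]
    rho: dict[str, float]
    p: dict[str, float] = field(default_factory=dict)
    p_corrected: dict[str, float] = field(default_factory=dict)
    n_comparisons: int = 1

    def best_stage(self) -> str:
        """Stage with the highest rho; exact ties go to the earlier stage."""
        best = max(
            range(len(self.stage_ids)),
            key=lambda i: (self.rho[self.stage_ids[i]], -i),
        )
        return self.stage_ids[best]


def _triangle_ranks(vec: np.ndarray) -> np.ndarray:
    r = stats.rankdata(vec)
    r = r - r.mean()
    norm = np.sqrt(np.sum(r**2))
    return r / norm if norm > 0 else r


def roi_permutation_test(
    neural_rdm: RDM,
    model_rdms: dict[str, RDM],
    n_perm: int = 10_000,
    n_comparisons: int | None = None,
    seed=0,
    unit: str = "roi",
) -> RSAResult:
    """Item-relabeling permutation test of model fits for one region.

    The null distribution permutes item labels of the neural RDM (rows and
    columns jointly) while model RDMs stay fixed; the one-sided p-value
    uses the add-one rule p = (1 + #{null >= observed}) / (1 + n_perm), and
    the Bonferroni-corrected p multiplies by ``n_comparisons`` (default:
    the number of model RDMs), capped at 1.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if n_comparisons is None:
        n_comparisons = len(model_rdms)
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    n = len(neural_rdm.items)
    i, j = np.tril_indices(n, k=-1)
    # a permutation of item labels permutes the triangle entries among
    # themselves, so precompute the rank vector once and re-index it
    pair_index = np.zeros((n, n), dtype=int)
    pair_index[i, j] = pair_index[j, i] = np.arange(len(i))
    neural_ranks = _triangle_ranks(neural_rdm.triangle())
    model_ranks = {}
    for sid, m in model_rdms.items():
        if m.items != neural_rdm.items:
            raise ValueError(f"model RDM {sid} is over a different item set")
        model_ranks[sid] = _triangle_ranks(m.triangle())

    observed = {sid: float(neural_ranks @ model_ranks[sid]) for sid in model_rdms}
    rng = np.random.default_rng(seed)
    exceed = {sid: 0 for sid in model_rdms}
    for _ in range(n_perm):
        perm = rng.permutation(n)
        null_ranks = neural_ranks[pair_index[perm[i], perm[j]]]
        for sid, mr in model_ranks.items():
            if null_ranks @ mr >= observed[sid]:
                exceed[sid] += 1
    p = {sid: (1 + exceed[sid]) / (1 + n_perm) for sid in model_rdms}
    return RSAResult(
        unit=unit,
        stage_ids=list(model_rdms),
        rho={sid: float(np.clip(observed[sid], -1, 1)) for sid in model_rdms},
        p=p,
        p_corrected={sid: min(1.0, v * n_comparisons) for sid, v in p.items()},
        n_comparisons=n_comparisons,
    )


def noise_ceiling_lower(subject_rdms: list[RDM]) -> float:
    """Leave-one-subject-out lower bound of the noise ceiling.

    For each subject, Spearman's rho between that subject's RDM and the
    element-wise mean RDM of the remaining subjects; returns the mean.
    """
    if len(subject_rdms) < 2:
        raise ValueError("need at least 2 subjects for a noise ceiling")
    items = subject_rdms[0].items
    mats = np.stack([r.matrix for r in subject_rdms])
    rhos = []
    for s, r in enumerate(subject_rdms):
        if r.items != items:
            raise ValueError("subject RDMs are over different item sets")
        others = np.delete(mats, s, axis=0).mean(axis=0)
        loso = RDM(items=items, matrix=others)
        rhos.append(compare_rdms(r, loso))
    return float(np.mean(rhos))


def _sphere_offsets(radius: float, grid_shape) -> np.ndarray:
    r = int(np.floor(radius))
    g = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1].reshape(3, -1).T
    return g[np.sum(g**2, axis=1) <= radius**2]


def searchlight_map(
    brain: SyntheticBrain,
    model_rdm: RDM,
    radius: float = 2.0,
    subject: int = 0,
    model_rdms: dict[str, RDM] | None = None,
) -> np.ndarray | dict[str, np.ndarray]:
    """Per-voxel Spearman fit of model RDM(s) in spherical searchlights.

    For each voxel, the multivoxel pattern over all voxels within
    ``radius`` (Euclidean, voxel units) forms a local RDM that is compared
    with the model RDM.  Spheres with fewer than 2 voxels yield NaN.  Pass
    ``model_rdms`` to score several stages in one sweep over the grid
    (the local RDM is computed once per sphere).
    """
    if radius < 1:
        raise ValueError("radius must be >= 1 voxel")
    single = model_rdms is None
    if single:
        model_rdms = {"model": model_rdm}
    ranks = {sid: _triangle_ranks(m.triangle()) for sid, m in model_rdms.items()}
    nx, ny, nz = brain.grid_shape
    P = brain.patterns[subject]
    offsets = _sphere_offsets(radius, brain.grid_shape)
    maps = {sid: np.full(brain.n_voxels, np.nan) for sid in model_rdms}
    coords = np.array(np.unravel_index(np.arange(brain.n_voxels), brain.grid_shape)).T
    for v in range(brain.n_voxels):
        pts = coords[v] + offsets
        ok = (
            (pts[:, 0] >= 0) & (pts[:, 0] < nx)
            & (pts[:, 1] >= 0) & (pts[:, 1] < ny)
            & (pts[:, 2] >= 0) & (pts[:, 2] < nz)
        )
        vox = np.ravel_multi_index(pts[ok].T, brain.grid_shape)
        if len(vox) < 2:
            continue
        X = P[:, vox]
        sd = X.std(axis=1)
        if np.any(sd == 0):
            continue
        local = 1.0 - np.corrcoef(X)
        lr = _triangle_ranks(local[np.tril_indices(local.shape[0], k=-1)])
        for sid in model_rdms:
            maps[sid][v] = float(lr @ ranks[sid])
    return maps["model"] if single else maps


@dataclass
class GroupResult:
    """Group-level inference over subjects' searchlight maps."""

    mask: np.ndarray       # bool, True where FDR-significant
    p: np.ndarray          # uncorrected sign-flip p per voxel (NaN outside)
    p_fdr: np.ndarray      # BH-adjusted p per voxel
    stat: np.ndarray       # pseudo-t (mean / SE of Fisher-z maps)
    mean_z: np.ndarray


def group_inference(
    per_subject_maps: np.ndarray,
    alpha_fdr: float = 0.01,
    n_perm: int = 5000,
    smoothing_fwhm: float = 0.0,
    grid_shape: tuple[int, int, int] | None = None,
    seed=0,
) -> GroupResult:
    """One-sample sign-flip permutation inference with BH-FDR.

    Subject maps (subjects x voxels, Spearman rho) are Fisher-z
    transformed, optionally Gaussian-smoothed on the grid, and tested for
    mean > 0 by randomly flipping subject signs; voxelwise p-values are
    corrected with Benjamini-Hochberg FDR at ``alpha_fdr``.
    """
    from statsmodels.stats.multitest import multipletests

    maps = np.asarray(per_subject_maps, dtype=float)
    n_subj = maps.shape[0]
    if n_subj < 4:
        raise ValueError("need at least 4 subjects for group inference")
    if not (0 < alpha_fdr < 1):
        raise ValueError("alpha_fdr must be in (0, 1)")
    Z = np.arctanh(np.clip(maps, -(1 - 1e-7), 1 - 1e-7))
    if smoothing_fwhm > 0:
        if grid_shape is None:
            raise ValueError("grid_shape is required for smoothing")
        sigma = smoothing_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        sm = np.empty_like(Z)
        for s in range(n_subj):
            vol = Z[s].reshape(grid_shape)
            good = np.isfinite(vol)
            filled = np.where(good, vol, 0.0)
            num = ndimage.gaussian_filter(filled, sigma)
            den = ndimage.gaussian_filter(good.astype(float), sigma)
            with np.errstate(invalid="ignore"):
                vol = np.where(good, num / den, np.nan)
            sm[s] = vol.ravel()
        Z = sm

    valid = np.all(np.isfinite(Z), axis=0)
    n_vox = Z.shape[1]
    p = np.full(n_vox, np.nan)
    stat = np.full(n_vox, np.nan)
    mean_z = np.full(n_vox, np.nan)
    Zv = Z[:, valid]
    mean_obs = Zv.mean(axis=0)
    se = Zv.std(axis=0, ddof=1) / np.sqrt(n_subj)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat[valid] = np.where(se > 0, mean_obs / se, np.inf * np.sign(mean_obs))
    mean_z[valid] = mean_obs

    if 2**n_subj <= n_perm:
        warnings.warn(
            f"only {2**n_subj} distinct sign patterns for {n_subj} subjects; "
            "using exhaustive sign flips",
            stacklevel=2,
        )
        signs = np.array(
            [[1 if (m >> s) & 1 else -1 for s in range(n_subj)] for m in range(2**n_subj)]
        )
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n_subj))
    null_means = (signs @ Zv) / n_subj
    exceed = np.sum(null_means >= mean_obs[None, :], axis=0)
    p[valid] = (1 + exceed) / (1 + signs.shape[0])

    p_fdr = np.full(n_vox, np.nan)
    mask = np.zeros(n_vox, dtype=bool)
    if valid.any():
        rej, p_adj, *_ = multipletests(p[valid], alpha=alpha_fdr, method="fdr_bh")
        p_fdr[valid] = p_adj
        mask[valid] = rej
    return GroupResult(mask=mask, p=p, p_fdr=p_fdr, stat=stat, mean_z=mean_z)


def composite_best_stage_map(
    stage_maps: dict[str, np.ndarray],
    significance_masks: dict[str, np.ndarray],
) -> np.ndarray:
    """Best-fitting stage per voxel, among voxels significant for >= 1 stage.

    Returns a 1-based stage-index array over voxels (0 = unassigned); ties
    in rho go to the earliest stage in the ordering of ``stage_maps``.
    """
    stage_ids = list(stage_maps)
    if set(significance_masks) != set(stage_ids):
        raise ValueError("stage_maps and significance_masks must cover the same stages")
    R = np.stack([stage_maps[s] for s in stage_ids])          # (stages, voxels)
    M = np.stack([significance_masks[s] for s in stage_ids])  # bool
    any_sig = M.any(axis=0)
    Rf = np.where(np.isfinite(R), R, -np.inf)
    best = np.argmax(Rf, axis=0)  # argmax takes the first (earliest) on ties
    out = np.zeros(R.shape[1], dtype=int)
    out[any_sig] = best[any_sig] + 1
    return out
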
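"""Synthetic inputs for the visuo-semantic pipeline.

Everything downstream of data collection is generated here: a binary
concept x feature norms table with category structure and a realistic
spread of feature sharedness, visual embeddings statistically coupled to
the visual-type features, a layered "visual stage" trajectory standing in
for the hierarchy of a visual network, and per-subject multivoxel brain
patterns whose regions carry the representational geometry of designated
model stages.

All generators draw from named substreams of one seed and are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureNorms",
    "StageRepresentation",
    "RegionSpec",
    "SyntheticBrain",
    "gen_feature_norms",
    "gen_visual_embeddings",
    "gen_visual_stage_trajectory",
    "svd_reduce",
    "gen_synthetic_brain",
]

FEATURE_TYPES = ("visual", "nonvisual_perceptual", "functional", "encyclopaedic")

#: default mixture over feature types, visual-heavy as in property-norm corpora
DEFAULT_TYPE_MIXTURE = {
    "visual": 0.40,
    "nonvisual_perceptual": 0.15,
    "functional": 0.25,
    "encyclopaedic": 0.20,
}

#: fractions of each concept's feature budget by sharedness class
DEFAULT_SHAREDNESS_PROFILE = {
    "category": 0.40,       # shared by a whole category (high N)
    "cross_category": 0.25,  # shared across category boundaries (moderate N)
    "distinguishing": 0.35,  # N <= 2
}


def substream(seed, name: str) -> np.random.Generator:
    """Named, independent random substream derived from a top-level seed."""
    import zlib

    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    key = zlib.crc32(name.encode("utf-8"))  # stable across processes
    child = np.random.SeedSequence(entropy=root.entropy, spawn_key=(key,))
    return np.random.default_rng(child)


@dataclass
class FeatureNorms:
    """Binary concept x feature incidence with per-feature metadata."""

    concept_ids: list[str]
    feature_ids: list[str]
    matrix: np.ndarray
    feature_type: list[str]
    category: list[str] | None = None  # per-concept category label

    @property
    def concept_count(self) -> np.ndarray:
        """Per-feature N: number of concepts possessing the feature."""
        return self.matrix.sum(axis=0).astype(int)

    def validate(self) -> None:
        M = self.matrix
        if M.shape != (len(self.concept_ids), len(self.feature_ids)):
            raise ValueError("matrix shape does not match id lists")
        if not np.isin(M, (0, 1)).all():
            raise ValueError("norms matrix must be binary")
        if (M.sum(axis=1) < 1).any():
            raise ValueError("every concept must have at least one feature")
        if (M.sum(axis=0) < 1).any():
            raise ValueError("every feature must occur in at least one concept")
        bad = set(self.feature_type) - set(FEATURE_TYPES)
        if bad:
            raise ValueError(f"unknown feature types: {bad}")

    def visual_submatrix(self) -> np.ndarray:
        """Concept x visual-type-feature slice of the incidence matrix."""
        mask = np.array([t == "visual" for t in self.feature_type])
        return self.matrix[:, mask]

    def to_tsv(self, norms_path, meta_path) -> None:
        pd.DataFrame(
            self.matrix.astype(int), index=self.concept_ids, columns=self.feature_ids
        ).to_csv(norms_path, sep="\t", index_label="concept")
        pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                "type": self.feature_type,
                "N": self.concept_count,
            }
        ).to_csv(meta_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, norms_path, meta_path) -> "FeatureNorms":
        df = pd.read_csv(norms_path, sep="\t", index_col="concept")
        meta = pd.read_csv(meta_path, sep="\t")
        meta = meta.set_index("feature_id").loc[df.columns]
        norms = cls(
            concept_ids=list(df.index),
            feature_ids=list(df.columns),
            matrix=df.to_numpy().astype(float),
            feature_type=list(meta["type"]),
        )
        norms.validate()
        return norms


@dataclass
class StageRepresentation:
    """Item x unit activations at one ordered processing stage."""

    stage_id: str
    items: list[str]
    matrix: np.ndarray

    def validate(self) -> None:
        if self.matrix.shape[0] != len(self.items):
            raise ValueError("matrix rows must match item count")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("non-finite stage representation")


@dataclass
class RegionSpec:
    """One synthetic brain region: its generative model stage and box extent."""

    name: str
    stage_id: str
    snr: float = 2.0
    n_voxels: int | None = None  # default: stage unit count + 1


@dataclass
class SyntheticBrain:
    """Per-subject voxel patterns on a grid with labelled regions.

    ``patterns`` maps subject index -> (n_items, n_voxels) matrix over the
    flattened grid; ``region_map`` is a flat array of region labels with
    "background" for pure-noise voxels; ``truth`` records each region's
    generative stage id.
    """

    n_subjects: int
    grid_shape: tuple[int, int, int]
    region_map: np.ndarray
    patterns: list[np.ndarray]
    truth: dict[str, str]
    snr: dict[str, float]
    items: list[str]

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_shape))

    def region_voxels(self, name: str) -> np.ndarray:
        return np.flatnonzero(self.region_map == name)

    def region_names(self) -> list[str]:
        # ordered by first voxel index: posterior-to-anterior along axis 0
        names = [n for n in np.unique(self.region_map) if n != "background"]
        return sorted(names, key=lambda n: self.region_voxels(n)[0])

    def validate(self) -> None:
        for name in self.region_names():
            if len(self.region_voxels(name)) < 2:
                raise ValueError(f"region {name} has fewer than 2 voxels")
        for P in self.patterns:
            if not np.all(np.isfinite(P)):
                raise ValueError("non-finite brain pattern")


def gen_feature_norms(
    n_concepts: int = 60,
    n_categories: int = 6,
    features_per_concept: int = 14,
    sharedness_profile: dict[str, float] | None = None,
    type_mixture: dict[str, float] | None = None,
    seed=0,
) -> FeatureNorms:
    """Generate category-structured binary feature norms.

    Concepts are split evenly into categories.  Each concept's feature
    budget is divided per ``sharedness_profile`` into category-level
    features shared by all category members, cross-category features shared
    by a moderate number of concepts spanning categories, and
    distinguishing features occurring in one or two concepts.  Feature
    types are drawn from ``type_mixture``, tilted so that visual-type
    features are over-represented among highly shared features (as in
    property-norm corpora, where visual properties such as *is green* tend
    to be true of many concepts).
    """
    if not (n_concepts >= n_categories >= 1):
        raise ValueError("need n_concepts >= n_categories >= 1")
    if features_per_concept < 2:
        raise ValueError("features_per_concept must be >= 2")
    profile = dict(DEFAULT_SHAREDNESS_PROFILE if sharedness_profile is None else sharedness_profile)
    mixture = dict(DEFAULT_TYPE_MIXTURE if type_mixture is None else type_mixture)
    total = sum(profile.values())
    n_cat_f = max(1, round(features_per_concept * profile.get("category", 0) / total))
    n_cross_f = max(1, round(features_per_concept * profile.get("cross_category", 0) / total))
    n_dist_f = features_per_concept - n_cat_f - n_cross_f
    if n_dist_f < 1:
        raise ValueError(
            "sharedness_profile leaves no room for distinguishing features "
            f"within the budget of {features_per_concept} features per concept"
        )

    rng = substream(seed, "norms")
    categories = [f"cat{k}" for k in range(n_categories)]
    concept_cat = [categories[i % n_categories] for i in range(n_concepts)]
    concept_ids = [f"{concept_cat[i]}_c{i}" for i in range(n_concepts)]
    cat_members = {c: [i for i, cc in enumerate(concept_cat) if cc == c] for c in categories}

    cols: list[np.ndarray] = []
    kinds: list[str] = []  # sharedness kind per feature, for type tilting
    # category-level features: one block per category; members carry them
    # with high but imperfect coherence, as real category norms do
    cat_incl = 0.9
    for c in categories:
        members = np.array(cat_members[c])
        for _ in range(n_cat_f):
            col = np.zeros(n_concepts)
            keep = members[rng.random(len(members)) < cat_incl]
            if len(keep) < max(3, len(members) // 2):
                keep = members
            col[keep] = 1.0
            cols.append(col)
            kinds.append("category")
    # cross-category features: superordinate-like properties spanning two
    # or three whole categories (e.g. *is green* spans plants and
    # vegetables).  They come in correlated pools of near-identical
    # features, mirroring the dense inter-feature correlations of highly
    # shared properties in norm corpora
    pool_size = 3
    mean_cross_N = 2.0 * (n_concepts / n_categories)
    n_pools = max(1, round(n_concepts * n_cross_f / (mean_cross_N * pool_size)))
    for _ in range(n_pools):
        k_cats = int(rng.integers(2, min(3, n_categories) + 1))
        chosen = rng.choice(n_categories, size=k_cats, replace=False)
        col = np.zeros(n_concepts)
        for ci in chosen:
            col[cat_members[categories[ci]]] = 1.0
        for _ in range(pool_size):
            cols.append(col.copy())
            kinds.append("cross")
    # distinguishing features: N = 1 singletons, plus an occasional N = 2
    # feature shared with a same-category neighbour
    for i in range(n_concepts):
        for j in range(n_dist_f):
            col = np.zeros(n_concepts)
            col[i] = 1.0
            if j == n_dist_f - 1 and rng.random() < 0.5:
                mates = [m for m in cat_members[concept_cat[i]] if m != i]
                if mates:
                    col[rng.choice(mates)] = 1.0
            cols.append(col)
            kinds.append("distinguishing")

    M = np.column_stack(cols)
    # drop duplicate all-zero safety (cannot occur by construction) and order
    types = _draw_feature_types(kinds, mixture, rng)
    feature_ids = [f"f{j:04d}_{types[j][:3]}" for j in range(M.shape[1])]
    norms = FeatureNorms(
        concept_ids=concept_ids,
        feature_ids=feature_ids,
        matrix=M,
        feature_type=types,
        category=concept_cat,
    )
    norms.validate()
    return norms


def _draw_feature_types(kinds, mixture, rng) -> list[str]:
    """Sample a type per feature; visual tilted toward shared features."""
    base = np.array([mixture.get(t, 0.0) for t in FEATURE_TYPES], dtype=float)
    base = base / base.sum()
    vis = FEATURE_TYPES.index("visual")
    tilt_shared = base.copy()
    tilt_shared[vis] *= 2.5
    tilt_shared /= tilt_shared.sum()
    tilt_dist = base.copy()
    tilt_dist[vis] *= 0.4
    tilt_dist /= tilt_dist.sum()
    out = []
    for kind in kinds:
        p = tilt_shared if kind in ("category", "cross") else tilt_dist
        out.append(FEATURE_TYPES[rng.choice(len(FEATURE_TYPES), p=p)])
    return out


def gen_visual_embeddings(
    norms: FeatureNorms,
    n_dims: int = 20,
    visual_coupling: float = 0.8,
    noise_sd: float = 0.5,
    seed=0,
) -> np.ndarray:
    """High-level visual embeddings coupled to the visual-type features.

    Each concept's embedding is ``visual_coupling`` times a (standardised)
    random linear image of its visual-type feature vector, plus independent
    Gaussian noise with standard deviation ``noise_sd``.  Concepts sharing
    visual-type features therefore have correlated embeddings, planting the
    visual regularities the attractor network learns to exploit.
    """
    if n_dims < 2:
        raise ValueError("n_dims must be >= 2")
    if not (0.0 <= visual_coupling <= 1.0):
        raise ValueError("visual_coupling must be in [0, 1]")
    rng = substream(seed, "embeddings")
    V = norms.visual_submatrix()
    P = rng.normal(size=(V.shape[1], n_dims))
    signal = V @ P
    sd = signal.std()
    if sd > 0:
        signal = signal / sd
    noise = rng.normal(size=(len(norms.concept_ids), n_dims))
    return visual_coupling * signal + noise_sd * noise


def gen_visual_stage_trajectory(
    embeddings: np.ndarray,
    n_layers: int = 7,
    mixing_decay: float = 0.7,
    seed=0,
    items: list[str] | None = None,
) -> list[StageRepresentation]:
    """Layered stand-in for a visual hierarchy, from pixels to embeddings.

    Layer 1 is an item-specific random "pixel-like" representation; layer
    ``n_layers`` is the given embedding matrix; intermediate layers blend
    the two with a weight that increases with depth (shaped by
    ``mixing_decay``), so that each layer's RDM grows monotonically more
    similar to the embedding RDM.
    """
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    E = np.asarray(embeddings, dtype=float)
    n_items = E.shape[0]
    if items is None:
        items = [f"item{i}" for i in range(n_items)]
    rng = substream(seed, "visual_trajectory")
    stages = []
    if n_layers == 1:
        stages.append(StageRepresentation("visual_layer1", list(items), E.copy()))
        return stages
    pixel = rng.normal(size=E.shape) * E.std()
    for layer in range(1, n_layers + 1):
        w = ((layer - 1) / (n_layers - 1)) ** mixing_decay
        rep = (1.0 - w) * pixel + w * E
        stages.append(StageRepresentation(f"visual_layer{layer}", list(items), rep))
    return stages


def svd_reduce(matrix: np.ndarray, k: int) -> tuple[np.ndarray, float]:
    """Rank-k SVD projection of an item x unit matrix.

    Returns the item scores on the top-k left singular vectors scaled by
    the singular values, together with the fraction of total (uncentered)
    variance the k components capture.
    """
    X = np.asarray(matrix, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite input to svd_reduce")
    if not (1 <= k <= min(X.shape)):
        raise ValueError(f"k must be in 1..{min(X.shape)}, got {k}")
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    total = float(np.sum(s**2))
    var_explained = float(np.sum(s[:k] ** 2) / total) if total > 0 else 1.0
    return U[:, :k] * s[:k], var_explained


def _centered_orthonormal_mixing(n_units: int, n_voxels: int, rng) -> np.ndarray:
    """Random units x voxels mixing with orthonormal rows orthogonal to 1.

    Right-multiplying centered item patterns by this matrix preserves their
    pairwise Pearson correlations exactly, so the noiseless region RDM
    equals the generative stage RDM.
    """
    if n_voxels < n_units + 1:
        raise ValueError(
            f"need at least {n_units + 1} voxels to mix {n_units} units; got {n_voxels}"
        )
    G = rng.normal(size=(n_units, n_voxels))
    G = G - G.mean(axis=1, keepdims=True)  # rows orthogonal to the 1 vector
    Q, _ = np.linalg.qr(G.T)  # columns: orthonormal, still orthogonal to 1
    return Q[:, :n_units].T


def gen_synthetic_brain(
    stage_reps: dict[str, StageRepresentation] | list[StageRepresentation],
    region_specs: list[RegionSpec],
    n_subjects: int = 12,
    snr: float | None = None,
    grid_shape: tuple[int, int, int] | None = None,
    seed=0,
    items: list[str] | None = None,
) -> SyntheticBrain:
    """Plant model-stage geometry into regions of a voxel grid.

    Regions are laid out as consecutive boxes along the first grid axis
    (the synthetic posterior-to-anterior axis), separated by background.
    For each subject and region, the region's generative stage patterns are
    passed through a subject-specific random linear mixing into the
    region's voxels, scaled to unit signal variance, and i.i.d. Gaussian
    noise of standard deviation 1/snr is added.  Background voxels are pure
    unit-variance noise.
    """
    if isinstance(stage_reps, list):
        stage_reps = {s.stage_id: s for s in stage_reps}
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    specs = []
    for spec in region_specs:
        if spec.stage_id not in stage_reps:
            raise ValueError(f"region {spec.name} names unknown stage {spec.stage_id}")
        eff_snr = spec.snr if snr is None else snr
        if not (eff_snr > 0):
            raise ValueError(f"region {spec.name}: snr must be > 0, got {eff_snr}")
        n_units = stage_reps[spec.stage_id].matrix.shape[1]
        n_vox = spec.n_voxels if spec.n_voxels is not None else n_units + 1
        specs.append((spec.name, spec.stage_id, eff_snr, n_vox))

    first = next(iter(stage_reps.values()))
    n_items = first.matrix.shape[0]
    if items is None:
        items = list(first.items)

    # lay regions out as multi-plane slabs along axis 0, separated by wide
    # background gaps so searchlight spheres cannot straddle two regions
    auto = grid_shape is None
    gap_planes = 3 if auto else 1
    margin = 2 if auto else 0
    if auto:
        ny = nz = 8
        # every region spans at least 2 planes so spheres have in-region depth
        sizes = [max(n_vox, 2 * ny * nz) for *_, n_vox in specs]
        depth = sum(int(np.ceil(sz / (ny * nz))) for sz in sizes)
        depth += gap_planes * (len(specs) - 1) + 2 * margin
        grid_shape = (depth, ny, nz)
    nx, ny, nz = grid_shape
    n_voxels = nx * ny * nz
    region_map = np.full(n_voxels, "background", dtype=object)
    region_voxel_idx: dict[str, np.ndarray] = {}
    x0 = margin  # posterior edge margin
    for name, _, _, n_vox in specs:
        slab_vox = max(n_vox, 2 * ny * nz) if auto else n_vox
        slab_planes = int(np.ceil(slab_vox / (ny * nz)))
        if x0 + slab_planes > nx:
            raise ValueError(f"grid_shape {grid_shape} too small for the requested regions")
        start = x0 * ny * nz
        idx = np.arange(start, start + n_vox)
        if np.any(region_map[idx] != "background"):
            raise ValueError(f"region {name} overlaps a previously assigned region")
        region_map[idx] = name
        region_voxel_idx[name] = idx
        x0 += slab_planes + gap_planes

    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = substream(root, "brain")
    patterns = []
    for _ in range(n_subjects):
        P = rng.normal(size=(n_items, n_voxels))  # background + noise floor
        for name, stage_id, eff_snr, n_vox in specs:
            S = stage_reps[stage_id].matrix
            Sc = S - S.mean(axis=1, keepdims=True)
            M = _centered_orthonormal_mixing(S.shape[1], n_vox, rng)
            sig = Sc @ M
            sd = sig.std()
            if sd > 0:
                sig = sig / sd
            idx = region_voxel_idx[name]
            P[:, idx] = sig + P[:, idx] / eff_snr
        patterns.append(P)

    brain = SyntheticBrain(
        n_subjects=n_subjects,
        grid_shape=tuple(grid_shape),
        region_map=region_map,
        patterns=patterns,
        truth={name: stage_id for name, stage_id, *_ in specs},
        snr={name: eff_snr for name, _, eff_snr, _ in specs},
        items=list(items),
    )
    brain.validate()
    return brain
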
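"""Feature-level analyses of the trained attractor network.

Covers the sharedness/distinctiveness classification of semantic features
(distinctiveness = 1/N, distinguishing when N <= 2, shared when N >= 3,
with a median split of the shared features), activation time-courses of
feature groups over the network's ticks, and introspection of the learned
visual-to-semantic weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .attractor import AttractorNetwork, Trajectory, external_input_to_feature
from .syndata import FeatureNorms

__all__ = [
    "FeatureClasses",
    "ActivationCurves",
    "classify_features",
    "activation_curves",
    "top_feature_weights",
    "max_driving_items",
]

SHAREDNESS_CLASSES = ("distinguishing", "low_shared", "high_shared")


@dataclass
class FeatureClasses:
    """Per-feature distinctiveness (1/N), sharedness class and type label."""

    distinctiveness: np.ndarray
    class3: np.ndarray  # of SHAREDNESS_CLASSES
    type: np.ndarray
    N: np.ndarray
    median_N_shared: float | None


def classify_features(norms: FeatureNorms) -> FeatureClasses:
    """Classify features by sharedness.

    Distinctiveness is 1/N where N is the number of concepts the feature
    occurs in.  Features with N <= 2 are distinguishing; N >= 3 are shared
    and are split at the median N over shared features, features exactly at
    the median going to the low-sharedness class.
    """
    norms.validate()
    N = norms.concept_count
    distinctiveness = 1.0 / N
    class3 = np.where(N <= 2, "distinguishing", "shared").astype(object)
    shared = N >= 3
    median = float(np.median(N[shared])) if shared.any() else None
    if shared.any():
        class3[shared & (N <= median)] = "low_shared"
        class3[shared & (N > median)] = "high_shared"
    return FeatureClasses(
        distinctiveness=distinctiveness,
        class3=class3.astype(str),
        type=np.asarray(norms.feature_type, dtype=str),
        N=N,
        median_N_shared=median,
    )


@dataclass
class ActivationCurves:
    """Mean activation per tick for groups of (concept, target-feature) pairs."""

    ticks: np.ndarray
    curves: dict[str, np.ndarray]   # group label -> mean activation per tick
    n_pairs: dict[str, int]
    absent: tuple[str, ...] = ()    # requested groups that had no pairs

    def to_frame(self):
        import pandas as pd

        rows = []
        for g, curve in self.curves.items():
            for t, v in zip(self.ticks, curve):
                rows.append({"group": g, "tick": int(t), "mean": v, "n_pairs": self.n_pairs[g]})
        return pd.DataFrame(rows)


def _group_labels(classes: FeatureClasses, group_by: str) -> np.ndarray:
    if group_by == "sharedness3":
        return classes.class3
    if group_by == "feature_type":
        return classes.type
    if group_by == "sharedness_x_type":
        return np.array([f"{c}|{t}" for c, t in zip(classes.class3, classes.type)])
    if group_by == "none":
        return np.full(classes.N.shape, "target")
    raise ValueError(
        "group_by must be one of sharedness3, feature_type, sharedness_x_type, none"
    )


def activation_curves(
    trajectory: Trajectory,
    norms: FeatureNorms,
    classes: FeatureClasses | None = None,
    group_by: str = "sharedness3",
    include_tick1: bool = False,
) -> ActivationCurves:
    """Mean activation time-course per feature group.

    For each concept, its target features are the value-1 entries of the
    norms.  The curve for a group averages over all (concept, target
    feature) pairs whose feature belongs to the group, at every tick; the
    non-target curve averages over all value-0 pairs.  The average is over
    pairs, not per-feature means.  Tick 1 (the random initialisation) is
    excluded unless ``include_tick1``.
    """
    if classes is None:
        classes = classify_features(norms)
    acts = trajectory.acts  # (T, items, features)
    if acts.shape[1] != len(norms.concept_ids) or acts.shape[2] != len(norms.feature_ids):
        raise ValueError("trajectory does not align with the norms")
    t0 = 0 if include_tick1 else 1
    ticks = np.arange(t0 + 1, acts.shape[0] + 1)
    A = acts[t0:]
    target = norms.matrix > 0
    labels = _group_labels(classes, group_by)

    curves: dict[str, np.ndarray] = {}
    n_pairs: dict[str, int] = {}
    absent = []
    for g in sorted(set(labels)):
        mask = target & (labels == g)[None, :]
        n = int(mask.sum())
        if n == 0:
            absent.append(g)
            continue
        curves[g] = A[:, mask].mean(axis=1)
        n_pairs[g] = n
    nt = ~target
    curves["non_target"] = A[:, nt].mean(axis=1)
    n_pairs["non_target"] = int(nt.sum())
    return ActivationCurves(
        ticks=ticks, curves=curves, n_pairs=n_pairs, absent=tuple(absent)
    )


def top_feature_weights(
    net: AttractorNetwork, k: int, feature_ids: list[str] | None = None
) -> list[tuple]:
    """The k largest visual-input connection weights.

    Returns (feature, input_node, weight) triples in descending weight
    order; exact ties are broken by (feature index, node index).
    """
    W = net.W_in
    if not (1 <= k <= W.size):
        raise ValueError(f"k must be in 1..{W.size}")
    flat = W.ravel()
    # stable ordering: descending weight, then row-major (feature, node) index
    order = np.lexsort((np.arange(flat.size), -flat))[:k]
    out = []
    for idx in order:
        f, n = divmod(int(idx), W.shape[1])
        label = feature_ids[f] if feature_ids is not None else f
        out.append((label, n, float(flat[idx])))
    return out


def max_driving_items(
    net: AttractorNetwork,
    embeddings: np.ndarray,
    feature_index: int,
    m: int | None = None,
    items: list[str] | None = None,
) -> list:
    """Items ranked by feed-forward external input to one feature node.

    The drive is the input-layer contribution only (lateral recurrence
    excluded), mirroring a "maximally activating image" analysis.
    """
    drive = external_input_to_feature(net, embeddings, feature_index)
    if m is None:
        m = len(drive)
    if not (1 <= m <= len(drive)):
        raise ValueError(f"m must be in 1..{len(drive)}")
    order = np.argsort(-drive, kind="stable")[:m]
    if items is not None:
        return [items[i] for i in order]
    return [int(i) for i in order]
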
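"""STP profile classification: VSM normalization, PCA, k-means, summaries.

The workflow mirrors the unitary-synapse phenotyping analysis: per-synapse
charge trains are min-max normalized row-wise (vector space model), a PCA is
fitted on the reference (wild-type) cohort only, test (knockout) observations
are projected into the same component space without influencing the
eigendecomposition, and k-means on the reference scores defines the classes;
test observations are assigned to the nearest reference centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

__all__ = [
    "ProfileMatrix",
    "PCAModel",
    "ClassificationResult",
    "vsm_normalize",
    "fit_pca",
    "project",
    "cluster_kmeans",
    "classify_cohort",
    "class_summaries",
]


@dataclass
class ProfileMatrix:
    """Rows are synapses, columns per-stimulus aggregated charges (>= 0)."""

    values: np.ndarray
    ids: list[str]
    cohort: str = "reference"

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.ndim != 2:
            raise ValueError("profile matrix must be 2-D")
        if len(self.ids) != self.values.shape[0]:
            raise ValueError("ids length must match the row count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("profile matrix must not contain missing values")
        if np.any(self.values < 0):
            raise ValueError("charges must be >= 0")


def _as_array(matrix) -> np.ndarray:
    if isinstance(matrix, ProfileMatrix):
        return matrix.values
    return np.atleast_2d(np.asarray(matrix, dtype=float))


def vsm_normalize(matrix, mode: str = "row") -> tuple[np.ndarray, np.ndarray]:
    """Min-max scale profiles to [0, 1].

    ``mode="row"`` (default) scales each observation independently so profiles
    become shape-comparable regardless of absolute charge; ``mode="column"``
    scales each stimulus feature across observations instead.  Constant rows
    (max == min) map to all-0.5 and are flagged, not dropped.

    Returns ``(normalized, constant_flags)``.
    """
    X = _as_array(matrix).copy()
    if mode not in ("row", "column"):
        raise ValueError("mode must be 'row' or 'column'")
    if mode == "column":
        X = X.T
    lo = X.min(axis=1, keepdims=True)
    hi = X.max(axis=1, keepdims=True)
    span = hi - lo
    flat = (span[:, 0] == 0)
    span[flat] = 1.0
    out = (X - lo) / span
    out[flat] = 0.5
    if mode == "column":
        out = out.T
    return out, flat


@dataclass
class PCAModel:
    """Centered principal-axis decomposition of a reference cohort.

    ``components`` rows are orthonormal loading vectors ordered by explained
    variance; the sign convention makes each component's largest-magnitude
    loading positive, so fits are reproducible across runs.
    """

    mean: np.ndarray
    components: np.ndarray
    explained_variance_ratio: np.ndarray

    @property
    def n_features(self) -> int:
        return int(self.mean.size)


def fit_pca(matrix, n_components: int = 2) -> PCAModel:
    """Fit a PCA on the (normalized) reference profiles.

    Raises when fewer than ``n_components + 1`` rows are given, when the total
    variance is zero, or when the data rank is below ``n_components`` (the
    error names the rank).
    """
    X = _as_array(matrix)
    n, p = X.shape
    if n < n_components + 1:
        raise ValueError(f"need at least {n_components + 1} rows, got {n}")
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2 / (n - 1)
    total = float(var.sum())
    if total <= 0:
        raise ValueError("zero total variance: all rows identical")
    rank = int(np.sum(s > s[0] * 1e-10))
    if rank < n_components:
        raise ValueError(f"matrix rank {rank} is below n_components={n_components}")
    comps = Vt[:n_components].copy()
    for row in comps:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    return PCAModel(mean=mean, components=comps,
                    explained_variance_ratio=var[:n_components] / total)


def project(model: PCAModel, matrix) -> np.ndarray:
    """Scores of observations in the model's component space.

    ``scores = (rows - mean) @ components.T``; projecting the reference
    matrix reproduces the fit scores exactly, and the map is affine.
    """
    X = _as_array(matrix)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature mismatch: matrix has {X.shape[1]} columns, "
            f"model expects {model.n_features}")
    return (X - model.mean) @ model.components.T


def cluster_kmeans(scores: np.ndarray, k: int, seed: int = 0,
                   n_restarts: int = 50) -> tuple[np.ndarray, np.ndarray]:
    """Best-of-restarts k-means with canonicalized labels.

    Labels are 1..k ordered by descending cluster mean of the first score
    dimension (depressing profiles come first under the usual sign
    convention).  Deterministic given the seed.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if k < 1:
        raise ValueError("k must be >= 1")
    if scores.shape[0] < k:
        raise ValueError(f"k={k} exceeds the {scores.shape[0]} observations")
    km = KMeans(n_clusters=k, n_init=n_restarts, tol=1e-6,
                random_state=int(seed) % (2**32), algorithm="lloyd")
    raw = km.fit_predict(scores)
    centroids = km.cluster_centers_
    order = np.argsort(-centroids[:, 0], kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    labels = relabel[raw]
    return labels, centroids[order]


def assign_to_centroids(scores: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Nearest-centroid labels (1..k); ties break toward the lowest label."""
    scores = np.atleast_2d(scores)
    d2 = ((scores[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1) + 1


@dataclass
class ClassificationResult:
    """PCA scores, cluster labels and class summaries for one analysis."""

    model: PCAModel
    k: int
    scores: np.ndarray
    labels: np.ndarray
    centroids: np.ndarray
    explained_variance_2: float
    ref_ids: list[str]
    test_ids: list[str] = field(default_factory=list)
    test_scores: np.ndarray | None = None
    test_labels: np.ndarray | None = None
    class_proportions: dict = field(default_factory=dict)
    class_profiles: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


def _proportions(labels: np.ndarray, k: int) -> dict[str, float]:
    n = labels.size
    return {f"C{c}": float(np.sum(labels == c)) / n for c in range(1, k + 1)}


def classify_cohort(
    reference,
    test=None,
    k: int = 4,
    seed: int = 0,
    n_components: int = 2,
    n_restarts: int = 50,
    normalization: str = "row",
    drop_first: bool = False,
) -> ClassificationResult:
    """Full phenotyping pipeline on a reference cohort with optional overlay.

    Normalize -> fit PCA on the reference only -> project both cohorts ->
    k-means on the reference scores -> assign test observations to the nearest
    reference centroid.  ``drop_first`` excludes the first-stimulus charge
    before normalization (the robustness control).
    """
    ref = reference if isinstance(reference, ProfileMatrix) else ProfileMatrix(
        np.atleast_2d(np.asarray(reference, float)),
        [f"ref_{i}" for i in range(np.atleast_2d(reference).shape[0])])
    ref_vals = ref.values[:, 1:] if drop_first else ref.values
    refN, ref_flat = vsm_normalize(ref_vals, mode=normalization)
    model = fit_pca(refN, n_components=n_components)
    scores = project(model, refN)
    labels, centroids = cluster_kmeans(scores[:, :2], k, seed=seed,
                                       n_restarts=n_restarts)
    flags = []
    if np.any(ref_flat):
        flags.append(f"{int(ref_flat.sum())} constant reference profiles")

    profiles = {}
    for c in range(1, k + 1):
        members = refN[labels == c]
        profiles[f"C{c}"] = members.mean(axis=0) if members.size else np.full(
            refN.shape[1], np.nan)

    result = ClassificationResult(
        model=model, k=k, scores=scores, labels=labels, centroids=centroids,
        explained_variance_2=float(model.explained_variance_ratio[:2].sum()),
        ref_ids=list(ref.ids),
        class_proportions={"reference": _proportions(labels, k)},
        class_profiles=profiles, flags=flags,
    )

    if test is not None:
        tst = test if isinstance(test, ProfileMatrix) else ProfileMatrix(
            np.atleast_2d(np.asarray(test, float)),
            [f"test_{i}" for i in range(np.atleast_2d(test).shape[0])],
            cohort="test")
        tst_vals = tst.values[:, 1:] if drop_first else tst.values
        tstN, tst_flat = vsm_normalize(tst_vals, mode=normalization)
        if np.any(tst_flat):
            result.flags.append(f"{int(tst_flat.sum())} constant test profiles")
        t_scores = project(model, tstN)
        t_labels = assign_to_centroids(t_scores[:, :2], centroids)
        result.test_ids = list(tst.ids)
        result.test_scores = t_scores
        result.test_labels = t_labels
        result.class_proportions["test"] = _proportions(t_labels, k)
    return result


def class_summaries(result: ClassificationResult,
                    epsc1_charges: np.ndarray,
                    pprs: np.ndarray) -> tuple[pd.DataFrame, dict]:
    """Per-class descriptive table with ANOVA + Tukey annotations.

    ``epsc1_charges`` and ``pprs`` align with the reference rows of
    ``result``.  The one-way ANOVA and Tukey post-hoc comparisons are
    descriptive reporting only; classes with fewer than 2 members are excluded
    from the tests (and the tests are suppressed entirely when fewer than two
    classes qualify).
    """
    epsc1 = np.asarray(epsc1_charges, dtype=float)
    ppr = np.asarray(pprs, dtype=float)
    labels = result.labels
    if epsc1.size != labels.size or ppr.size != labels.size:
        raise ValueError("feature vectors must align with the labelled synapses")
    rows = []
    groups_charge, groups_ppr, group_names = [], [], []
    for c in range(1, result.k + 1):
        sel = labels == c
        n = int(sel.sum())
        rows.append({
            "class": f"C{c}",
            "n": n,
            "mean_epsc1_fC": float(np.mean(epsc1[sel])) if n else float("nan"),
            "sem_epsc1_fC": float(stats.sem(epsc1[sel])) if n > 1 else float("nan"),
            "mean_ppr": float(np.nanmean(ppr[sel])) if n else float("nan"),
            "sem_ppr": float(stats.sem(ppr[sel], nan_policy="omit")) if n > 1 else float("nan"),
        })
        if n >= 2:
            groups_charge.append(epsc1[sel])
            groups_ppr.append(ppr[sel][np.isfinite(ppr[sel])])
            group_names.append(f"C{c}")
    table = pd.DataFrame(rows)
    tests: dict = {"note": "descriptive only", "suppressed": len(group_names) < 2}
    if len(group_names) >= 2:
        f_c, p_c = stats.f_oneway(*groups_charge)
        tests["anova_epsc1"] = {"F": float(f_c), "p": float(p_c)}
        if all(g.size >= 2 for g in groups_ppr):
            f_p, p_p = stats.f_oneway(*groups_ppr)
            tests["anova_ppr"] = {"F": float(f_p), "p": float(p_p)}
        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        values = np.concatenate(groups_charge)
        names = np.concatenate([[g] * arr.size for g, arr in
                                zip(group_names, groups_charge)])
        tukey = pairwise_tukeyhsd(values, names)
        tests["tukey_epsc1"] = str(tukey.summary())
    return table, tests
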
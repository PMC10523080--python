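"""Point-distribution shape models and PC-score collinearity screening.

Three model variants are supported, mirroring the three bone-surface models
whose PC scores feed the strain regressions: the outer cortical surface of
the tibia alone (``tibia``), the combined tibia + fibula outer surfaces
(``tibia_fibula``), and the combined cortical + trabecular (endosteal)
surfaces (``cortical_trabecular``).

`PointDistributionModel` is a scikit-learn style transformer: generalized
Procrustes alignment of corresponded point sets followed by PCA of the
aligned, flattened coordinates.  Scaling is off by default so that overall
size remains a modelled shape characteristic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

__all__ = [
    "VARIANTS", "variant_nodes", "cohort_point_sets", "align_shapes",
    "procrustes_align", "PointDistributionModel", "fit_ssm", "project",
    "CollinearityScreen", "collinearity_screen", "ScreeningResult",
    "AlignmentError", "ZeroVarianceError",
]

VARIANTS = ("tibia", "tibia_fibula", "cortical_trabecular")


class AlignmentError(ValueError):
    """Degenerate input to Procrustes alignment."""


class ZeroVarianceError(ValueError):
    """All training shapes identical: shape variance is zero."""


def variant_nodes(mesh, variant: str) -> np.ndarray:
    """Template node indices (corner nodes) defining one model variant."""
    meta = mesh.meta
    if variant == "tibia":
        return np.asarray(meta["tibia_outer_nodes"])
    if variant == "tibia_fibula":
        return np.concatenate([meta["tibia_outer_nodes"], meta["fibula_ring_nodes"]])
    if variant == "cortical_trabecular":
        return np.concatenate([meta["tibia_outer_nodes"], meta["tibia_inner_nodes"]])
    raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")


def cohort_point_sets(cohort, variant: str) -> np.ndarray:
    """Stack a cohort's corresponded variant point sets, shape (n, p, 3)."""
    idx = variant_nodes(cohort.template, variant)
    return np.stack([m.nodes[idx] for m in cohort.meshes])


# ---------------------------------------------------------------------------
# Procrustes

def _kabsch(src: np.ndarray, dst: np.ndarray, with_scaling: bool):
    """Optimal rotation (and scale) mapping centered src onto centered dst."""
    h = src.T @ dst
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    if with_scaling:
        denom = np.einsum("ij,ij->", src, src)
        scale = (s @ np.diag(diag)[:3]) / denom
    else:
        scale = 1.0
    return rot, scale


def _align_one(shape: np.ndarray, target: np.ndarray, with_scaling: bool) -> np.ndarray:
    c_s = shape.mean(axis=0)
    c_t = target.mean(axis=0)
    src = shape - c_s
    if np.linalg.norm(src) == 0:
        raise AlignmentError("degenerate shape: all points coincident")
    rot, scale = _kabsch(src, target - c_t, with_scaling)
    return scale * src @ rot.T + c_t


def align_shapes(source: np.ndarray, target: np.ndarray,
                 with_scaling: bool = False) -> np.ndarray:
    """Ordinary (two-shape) Procrustes: superimpose source onto target."""
    return _align_one(np.asarray(source, dtype=float),
                      np.asarray(target, dtype=float), with_scaling)


def procrustes_align(shapes: np.ndarray | Sequence[np.ndarray],
                     with_scaling: bool = False,
                     tol: float = 1e-10, max_iter: int = 200) -> np.ndarray:
    """Generalized Procrustes alignment of corresponded point sets.

    Returns the aligned stack (n, p, 3).  Iterates alignment to the running
    mean until the mean moves by less than ``tol``; at convergence the mean
    is a fixed point and re-aligning any shape changes it negligibly.
    """
    x = np.stack([np.asarray(s, dtype=float) for s in shapes])
    if len(x) < 3:
        raise AlignmentError("generalized alignment needs at least 3 shapes")
    aligned = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(aligned.reshape(len(x), -1), axis=1)
    if np.any(norms == 0):
        raise AlignmentError("degenerate shape: all points coincident")
    # initialising from the raw average makes a converged set a fixed point;
    # fall back to the first shape if the average degenerates
    mean = aligned.mean(axis=0)
    if np.linalg.norm(mean) < 1e-8 * norms.max():
        mean = aligned[0].copy()
    for _ in range(max_iter):
        aligned = np.stack([_align_one(s, mean, with_scaling) for s in aligned])
        new_mean = aligned.mean(axis=0)
        new_mean = new_mean - new_mean.mean(axis=0)
        shift = np.abs(new_mean - mean).max()
        mean = new_mean
        if shift < tol:
            break
    # final consistent pass against the converged mean
    aligned = np.stack([_align_one(s, mean, with_scaling) for s in aligned])
    return aligned


# ---------------------------------------------------------------------------
# Point-distribution model

class PointDistributionModel(BaseEstimator, TransformerMixin):
    """GPA + PCA shape model with sklearn fit/transform semantics.

    Parameters
    ----------
    n_components:
        Number of modes to keep (default: all nonzero, at most n-1).
    with_scaling:
        Remove size in the alignment step.  Off by default: size is itself a
        shape characteristic of interest.
    variant:
        Informational label stored with the model.

    Attributes (after ``fit``)
    --------------------------
    mean_shape_ : (p, 3) aligned mean shape
    components_ : (k, 3p) orthonormal modes
    explained_variance_ : (k,) eigenvalues
    pct_variance_ : (k,) percentage of total shape variance, non-increasing
    scores_ : (n, k) training scores (zero column means)
    """

    def __init__(self, n_components: int | None = None,
                 with_scaling: bool = False, variant: str = "tibia"):
        self.n_components = n_components
        self.with_scaling = with_scaling
        self.variant = variant

    def fit(self, X, y=None) -> "PointDistributionModel":
        shapes = self._as_shapes(X)
        aligned = procrustes_align(shapes, with_scaling=self.with_scaling)
        n, p, _ = aligned.shape
        flat = aligned.reshape(n, -1)
        total_var = flat.var(axis=0, ddof=1).sum()
        if total_var <= 1e-24:
            raise ZeroVarianceError("all training shapes are identical")
        k = self.n_components or min(n - 1, flat.shape[1])
        pca = PCA(n_components=min(k, n - 1), svd_solver="full")
        scores = pca.fit_transform(flat)
        nonzero = pca.explained_variance_ > 1e-18 * pca.explained_variance_[0]
        self.n_points_ = p
        self.mean_shape_ = pca.mean_.reshape(p, 3)
        self.components_ = pca.components_[nonzero]
        self.explained_variance_ = pca.explained_variance_[nonzero]
        self.pct_variance_ = 100.0 * self.explained_variance_ / total_var
        self.scores_ = scores[:, nonzero]
        self.aligned_ = aligned
        return self

    def transform(self, X) -> np.ndarray:
        shapes = self._as_shapes(X)
        out = np.empty((len(shapes), len(self.components_)))
        for i, s in enumerate(shapes):
            if s.shape != self.mean_shape_.shape:
                raise ValueError("node count mismatch with the fitted model")
            a = _align_one(s, self.mean_shape_, self.with_scaling)
            out[i] = self.components_ @ (a.ravel() - self.mean_shape_.ravel())
        return out

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        scores = np.atleast_2d(scores)
        flat = self.mean_shape_.ravel() + scores @ self.components_
        return flat.reshape(len(scores), *self.mean_shape_.shape)

    @staticmethod
    def _as_shapes(X) -> np.ndarray:
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:                      # (n, 3p) flattened
            x = x.reshape(len(x), -1, 3)
        if x.ndim != 3 or x.shape[2] != 3:
            raise ValueError("expected (n, p, 3) point sets or (n, 3p) rows")
        return x


def fit_ssm(aligned_or_shapes, variant: str = "tibia",
            n_components: int | None = None,
            with_scaling: bool = False) -> PointDistributionModel:
    """Functional wrapper over :class:`PointDistributionModel`."""
    return PointDistributionModel(n_components=n_components,
                                  with_scaling=with_scaling,
                                  variant=variant).fit(aligned_or_shapes)


def project(model: PointDistributionModel, shape: np.ndarray) -> np.ndarray:
    """Scores of a single corresponded shape under a fitted model."""
    return model.transform(np.asarray(shape)[None])[0]


# ---------------------------------------------------------------------------
# Collinearity screening

@dataclass
class ScreeningResult:
    """Outcome of the cross-model PC collinearity screen."""

    retained: list[tuple[str, int]]
    removed: list[dict]
    cutoff: float

    def retained_columns(self) -> list[str]:
        return [f"{v}_pc{i}" for v, i in self.retained]


def _keep_drop(a: dict, b: dict) -> bool:
    """True if ``a`` outranks ``b``: a correlated tibia-only component loses
    to a tibia-fibula one (the fibula may brace the tibia under load), then
    higher explained variance wins, then the lower PC index."""
    va, vb = a["variant"], b["variant"]
    if {va, vb} == {"tibia", "tibia_fibula"}:
        return va == "tibia_fibula"
    if a["pct_variance"] != b["pct_variance"]:
        return a["pct_variance"] > b["pct_variance"]
    return a["pc"] <= b["pc"]


def collinearity_screen(scores: dict[str, np.ndarray],
                        pct_variance: dict[str, np.ndarray],
                        cutoff: float = 0.6) -> ScreeningResult:
    """Screen PC-score columns across shape-model variants for collinearity.

    ``scores`` maps variant -> (n_subjects, k) score table; ``pct_variance``
    maps variant -> per-component percentage variance.  Pairs with |Pearson
    r| > cutoff are processed in descending |r|; within each pair the lower
    priority component is removed (variant rule first, then variance, then PC
    index).  The retained set is pairwise |r| <= cutoff and the screen is
    idempotent.
    """
    cols = []
    n_subj = None
    for variant, table in scores.items():
        table = np.asarray(table, dtype=float)
        if n_subj is None:
            n_subj = len(table)
        elif len(table) != n_subj:
            raise ValueError("score tables must share the subject count")
        for j in range(table.shape[1]):
            col = table[:, j]
            if np.std(col) == 0:
                raise ValueError(
                    f"constant score column {variant} PC{j + 1}: correlation undefined")
            cols.append({"variant": variant, "pc": j + 1,
                         "pct_variance": float(np.asarray(pct_variance[variant])[j]),
                         "values": col})
    m = len(cols)
    mat = np.corrcoef(np.stack([c["values"] for c in cols])) if m > 1 else np.ones((1, 1))
    pairs = [(abs(mat[i, j]), i, j)
             for i in range(m) for j in range(i + 1, m)
             if abs(mat[i, j]) > cutoff]
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    alive = [True] * m
    removed = []
    for r, i, j in pairs:
        if not (alive[i] and alive[j]):
            continue
        ki, kd = (i, j) if _keep_drop(cols[i], cols[j]) else (j, i)
        alive[kd] = False
        removed.append({"variant": cols[kd]["variant"], "pc": cols[kd]["pc"],
                        "partner": (cols[ki]["variant"], cols[ki]["pc"]),
                        "abs_r": float(r)})
    retained = [(c["variant"], c["pc"]) for c, a in zip(cols, alive) if a]
    return ScreeningResult(retained=retained, removed=removed, cutoff=cutoff)


class CollinearityScreen(BaseEstimator):
    """Estimator wrapper for the screen; ``fit`` stores the screening result
    and ``transform`` selects the retained score columns from a DataFrame
    whose columns are named ``{variant}_pc{i}``."""

    def __init__(self, cutoff: float = 0.6):
        self.cutoff = cutoff

    def fit(self, scores: dict[str, np.ndarray],
            pct_variance: dict[str, np.ndarray]) -> "CollinearityScreen":
        self.result_ = collinearity_screen(scores, pct_variance, self.cutoff)
        return self

    def transform(self, frame: pd.DataFrame) -> pd.DataFrame:
        return frame[self.result_.retained_columns()]
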
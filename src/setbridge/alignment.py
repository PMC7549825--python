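"""Procrustes alignment of one enrichment-score space onto another.

Enrichment scores computed from two platforms for the same samples live in the
same nominal space (one axis per gene set) but can differ by a systematic
offset, scale and rotation — e.g. the positive non-uniform shift that heavy
zero-inflation of counts imposes on the scores.  The classical three-step
Procrustes transform (translation, one global scale, orthogonal rotation) is
fitted on paired rows — overlapping samples, or per-class mean vectors when no
samples overlap — and can then be applied to any matrix over the same
variables, enabling models trained on one platform to be reused on the other.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "ProcrustesTransform",
    "fit_procrustes",
    "apply_procrustes",
    "fit_procrustes_groupmeans",
]


@dataclass
class ProcrustesTransform:
    """Affine-orthogonal map from a source coordinate frame onto a target's.

    Maps raw source rows x to ``(x - source_center) @ rotation * scale +
    target_center``.  ``rotation`` is orthogonal (reflections permitted unless
    fitted with ``allow_reflection=False``); ``scale`` is a single positive
    global factor, per the classical three-step formulation.
    """

    source_center: np.ndarray
    target_center: np.ndarray
    scale: float
    rotation: np.ndarray

    def __post_init__(self) -> None:
        self.source_center = np.asarray(self.source_center, dtype=float).ravel()
        self.target_center = np.asarray(self.target_center, dtype=float).ravel()
        self.rotation = np.asarray(self.rotation, dtype=float)
        p = self.source_center.size
        if self.rotation.shape != (p, p) or self.target_center.size != p:
            raise ValueError("inconsistent transform dimensions")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(p), atol=1e-8):
            raise ValueError("rotation is not orthogonal within 1e-8")

    @property
    def n_variables(self) -> int:
        return self.source_center.size

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "source_center": self.source_center.tolist(),
                    "target_center": self.target_center.tolist(),
                    "scale": self.scale,
                    "rotation": self.rotation.tolist(),
                },
                indent=2,
            )
            + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ProcrustesTransform":
        d = json.loads(Path(path).read_text())
        return cls(
            np.array(d["source_center"]),
            np.array(d["target_center"]),
            float(d["scale"]),
            np.array(d["rotation"]),
        )


def fit_procrustes(
    source: np.ndarray,
    target: np.ndarray,
    allow_reflection: bool = True,
) -> ProcrustesTransform:
    """Fit translation + global scale + orthogonal rotation on paired rows.

    Both matrices are centered; the rotation is the orthogonal matrix
    minimizing the squared error between the rotated centered source and the
    centered target (from the SVD of their cross-product), and the scale is
    the least-squares scalar.  With fewer paired rows than variables the
    cross-product is rank-deficient and the rotation's action on the unspanned
    null space is completed arbitrarily (but deterministically) by the SVD
    bases; only behavior on the spanned subspace is identified by the data.

    ``allow_reflection=False`` restricts to proper rotations (det = +1).
    """
    X = np.asarray(source, dtype=float)
    Y = np.asarray(target, dtype=float)
    if X.ndim != 2 or X.shape != Y.shape:
        raise ValueError(f"paired matrices of identical shape required, got {X.shape} vs {Y.shape}")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 paired rows")
    mu_x = X.mean(axis=0)
    mu_y = Y.mean(axis=0)
    Xc = X - mu_x
    Yc = Y - mu_y
    norm_x = np.linalg.norm(Xc)
    if norm_x == 0 or np.linalg.norm(Yc) == 0:
        raise ValueError("zero matrix after centering: transform undefined")
    U, s, Vt = np.linalg.svd(Xc.T @ Yc)
    if not allow_reflection:
        d = np.sign(np.linalg.det(U @ Vt))
        D = np.ones(s.size)
        D[-1] = d
        rotation = (U * D) @ Vt
        trace = float(np.sum(s * D))
    else:
        rotation = U @ Vt
        trace = float(s.sum())
    scale = trace / norm_x**2
    if scale <= 0:
        # anti-correlated degenerate fit; keep scale positive, rotation absorbs signs
        scale = np.finfo(float).tiny
    return ProcrustesTransform(mu_x, mu_y, scale, rotation)


def apply_procrustes(t: ProcrustesTransform, data: np.ndarray) -> np.ndarray:
    """Map rows of ``data`` from the source frame into the target frame."""
    X = np.asarray(data, dtype=float)
    one_row = X.ndim == 1
    X = np.atleast_2d(X)
    if X.shape[1] != t.n_variables:
        raise ValueError(f"data has {X.shape[1]} variables, transform expects {t.n_variables}")
    out = (X - t.source_center) @ t.rotation * t.scale + t.target_center
    return out[0] if one_row else out


def fit_procrustes_groupmeans(
    source: np.ndarray,
    source_labels: Sequence[str],
    target: np.ndarray,
    target_labels: Sequence[str],
    allow_reflection: bool = True,
) -> ProcrustesTransform:
    """Fit a Procrustes transform on per-class mean vectors.

    For the no-overlap scenario: the two datasets share no samples but share
    class labels, so the k class-mean vectors on each side act as the paired
    rows.  Both label sets must contain the same >= 2 classes, each non-empty
    on both sides; means are paired in sorted class order.  The returned
    transform applies to full sample matrices.  Reduces exactly to
    :func:`fit_procrustes` when every class is a singleton sample.
    """
    X = np.asarray(source, dtype=float)
    Y = np.asarray(target, dtype=float)
    ls = np.asarray(list(map(str, source_labels)))
    lt = np.asarray(list(map(str, target_labels)))
    if X.shape[0] != ls.size or Y.shape[0] != lt.size:
        raise ValueError("label length must match matrix rows")
    classes_s, classes_t = set(ls), set(lt)
    if classes_s != classes_t:
        raise ValueError(
            f"class mismatch: only in source {sorted(classes_s - classes_t)}, "
            f"only in target {sorted(classes_t - classes_s)}"
        )
    classes = sorted(classes_s)
    if len(classes) < 2:
        raise ValueError("need at least 2 shared classes")
    means_s = np.vstack([X[ls == c].mean(axis=0) for c in classes])
    means_t = np.vstack([Y[lt == c].mean(axis=0) for c in classes])
    return fit_procrustes(means_s, means_t, allow_reflection=allow_reflection)
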
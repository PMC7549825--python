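"""Agreement between paired platform measurements of the same samples.

Two complementary per-sample-pair statistics: the Spearman rank correlation
(how consistently the two platforms order the features) and the residual
variance var(E) — the fraction of total variance carried by the second
principal component of the paired two-column data, i.e. the spread around the
best-fit line.  var(E) = 0 means the platforms are perfectly collinear; its
maximum is 0.5 (uncorrelated).  Whole-dataset similarity of the sample
configurations is measured by the modified RV matrix correlation, which zeroes
the diagonals of the sample cross-product matrices so that a matrix is not
trivially similar to itself through its own norms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import json

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairConcordance",
    "ConcordanceReport",
    "spearman",
    "var_e",
    "pairwise_report",
    "modified_rv",
]


@dataclass(frozen=True)
class PairConcordance:
    """Spearman rho and residual variance of one paired sample."""

    sample_id: str
    rho: float
    var_e: float


@dataclass
class ConcordanceReport:
    """Per-sample concordance plus summary means; ``rhos`` is histogram-ready."""

    pairs: list[PairConcordance]

    @property
    def rhos(self) -> np.ndarray:
        return np.array([p.rho for p in self.pairs])

    @property
    def var_es(self) -> np.ndarray:
        return np.array([p.var_e for p in self.pairs])

    @property
    def mean_rho(self) -> float:
        return float(self.rhos.mean())

    @property
    def mean_var_e(self) -> float:
        return float(self.var_es.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": [p.sample_id for p in self.pairs],
                "rho": self.rhos,
                "var_e": self.var_es,
            }
        )

    def to_tsv(self, path: str | Path, summary: bool = True) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        if summary:
            path.with_suffix(path.suffix + ".json").write_text(
                json.dumps(
                    {"mean_rho": self.mean_rho, "mean_var_e": self.mean_var_e, "n": len(self.pairs)},
                    indent=2,
                )
                + "\n"
            )


def _check_pair(x, y, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} paired values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("values must be finite")
    return x, y


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    x, y = _check_pair(x, y)
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("zero variance in a rank vector: Spearman undefined")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def var_e(x: Sequence[float], y: Sequence[float], scale: bool = True) -> float:
    """Fraction of paired-sample variance on the second principal component.

    Both columns are mean-centered and, by default, scaled to unit standard
    deviation before the 2x2 eigen-decomposition; autoscaling keeps var(E)
    meaningful when the two platforms live on very different scales (with
    scaling, var_e == (1 - |Pearson rho|)/2).  Returns lambda_2 / (lambda_1 +
    lambda_2), in [0, 0.5].
    """
    x, y = _check_pair(x, y)
    xc = x - x.mean()
    yc = y - y.mean()
    sx, sy = xc.std(ddof=1), yc.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero-variance column: var(E) undefined")
    if scale:
        xc, yc = xc / sx, yc / sy
    cov = np.cov(np.vstack([xc, yc]))
    lam = np.linalg.eigvalsh(cov)  # ascending
    return float(lam[0] / lam.sum())


def pairwise_report(
    a: np.ndarray | pd.DataFrame,
    b: np.ndarray | pd.DataFrame,
    sample_ids: Sequence[str] | None = None,
    scale: bool = True,
) -> ConcordanceReport:
    """Column-paired Spearman and var(E) for two variables x samples matrices.

    Columns are paired positionally; the caller aligns samples first (see
    :func:`setbridge.harmonize.align_samples`).
    """
    if isinstance(a, pd.DataFrame):
        if sample_ids is None:
            sample_ids = a.columns.astype(str).tolist()
        a = a.to_numpy(float)
    if isinstance(b, pd.DataFrame):
        b = b.to_numpy(float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if sample_ids is None:
        sample_ids = [str(i) for i in range(a.shape[1])]
    pairs = [
        PairConcordance(str(sid), spearman(a[:, j], b[:, j]), var_e(a[:, j], b[:, j], scale=scale))
        for j, sid in enumerate(sample_ids)
    ]
    return ConcordanceReport(pairs)


def modified_rv(x: np.ndarray, y: np.ndarray) -> float:
    """Modified RV coefficient between two samples x variables matrices.

    Columns of each matrix are mean-centered and scaled to unit variance; the
    sample configuration matrices XX' and YY' have their diagonals set to zero
    before taking their matrix inner product normalized by the product of
    their Frobenius norms.  Symmetric, in [-1, 1], and high when the relative
    layout of samples agrees between the two datasets regardless of which
    variables produced it.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 2 or y.ndim != 2 or x.shape[0] != y.shape[0]:
        raise ValueError("x and y must be 2-D with the same number of samples (rows)")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 samples")

    def standardized_gram(m: np.ndarray) -> np.ndarray:
        mc = m - m.mean(axis=0)
        sd = mc.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("zero-variance column")
        mc = mc / sd
        g = mc @ mc.T
        np.fill_diagonal(g, 0.0)
        return g

    gx = standardized_gram(x)
    gy = standardized_gram(y)
    denom = np.linalg.norm(gx) * np.linalg.norm(gy)
    if denom == 0:
        raise ValueError("degenerate configuration: zero Frobenius norm")
    return float(np.sum(gx * gy) / denom)
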
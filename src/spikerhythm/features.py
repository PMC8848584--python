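"""Hand-crafted time-series features fused with the learned code.

Two statistics accompany the auto-encoder code: a dispersion measure of the
ISI sequence (coefficient of variation by default, lag-1 autocovariance as
an alternative) and Pincus approximate entropy ApEn(m, r), the standard
regularity statistic for short spike-train data.  ``fuse`` concatenates the
824-dimensional learned code with the two scalars (scaled on the training
set) into the 826-dimensional vector the classifier sees.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "approximate_entropy",
    "dispersion_feature",
    "FeatureScaler",
    "fuse",
    "feature_table",
]


def _phi(x: np.ndarray, m: int, r: float) -> float:
    """Φ^m(r): mean log fraction of m-templates within Chebyshev distance r
    (self-matches included)."""
    n = len(x)
    n_templates = n - m + 1
    # embedding matrix: rows are the m-length templates
    emb = np.lib.stride_tricks.sliding_window_view(x, m)
    # Chebyshev distances between all template pairs
    dist = np.abs(emb[:, None, :] - emb[None, :, :]).max(axis=2)
    counts = (dist <= r).sum(axis=1)
    return float(np.mean(np.log(counts / n_templates)))


def approximate_entropy(x, m: int = 2, r: Optional[float] = None,
                        r_frac: float = 0.2) -> float:
    """Pincus approximate entropy ApEn(m, r) = Φ^m(r) − Φ^{m+1}(r).

    Chebyshev distance, self-matches included, natural logarithm.  When ``r``
    is not given it defaults to ``r_frac`` times the sample SD of ``x`` (with
    a small floor for constant input), which makes ApEn invariant to affine
    rescaling of the data.  Larger values indicate a more complex, more
    random sequence; a perfectly regular (constant) sequence scores 0.
    """
    x = np.asarray(x, dtype=float).ravel()
    if len(x) <= m + 1:
        raise ValueError(f"sequence too short for ApEn: n={len(x)}, need > {m + 1}")
    if r is None:
        sd = x.std()
        r = r_frac * sd if sd > 0 else 1e-12
    if r <= 0:
        raise ValueError("tolerance r must be > 0")
    return _phi(x, m, r) - _phi(x, m + 1, r)


def dispersion_feature(x, mode: str = "cv", ddof: int = 1) -> float:
    """Dispersion of an ISI sequence.

    ``cv`` (default): coefficient of variation SD(x)/mean(x), the standard
    ISI dispersion statistic (scale-invariant).  ``lag1_autocov``: mean of
    (x_i − x̄)(x_{i+1} − x̄) (translation-invariant).
    """
    x = np.asarray(x, dtype=float).ravel()
    if len(x) < 2:
        raise ValueError("need at least 2 values")
    if mode == "cv":
        mu = x.mean()
        if mu == 0:
            raise ValueError("zero mean: coefficient of variation undefined")
        return float(x.std(ddof=ddof) / mu)
    if mode == "lag1_autocov":
        xc = x - x.mean()
        return float(np.mean(xc[:-1] * xc[1:]))
    raise ValueError(f"unknown dispersion mode {mode!r}")


@dataclass
class FeatureScaler:
    """Scales the two scalar features using statistics of the training set
    only.  ``kind``: 'minmax' (default), 'zscore' or 'none'."""

    kind: str = "minmax"
    lo_: Optional[np.ndarray] = None
    hi_: Optional[np.ndarray] = None
    mean_: Optional[np.ndarray] = None
    sd_: Optional[np.ndarray] = None

    def fit(self, scalars: np.ndarray) -> "FeatureScaler":
        scalars = np.atleast_2d(np.asarray(scalars, dtype=float))
        self.lo_ = scalars.min(axis=0)
        self.hi_ = scalars.max(axis=0)
        self.mean_ = scalars.mean(axis=0)
        self.sd_ = scalars.std(axis=0)
        return self

    @property
    def fitted(self) -> bool:
        return self.lo_ is not None

    def transform(self, scalars: np.ndarray) -> np.ndarray:
        if self.kind == "none":
            return np.atleast_2d(np.asarray(scalars, dtype=float))
        if not self.fitted:
            raise RuntimeError("scaler not fitted; call fit on training features first")
        scalars = np.atleast_2d(np.asarray(scalars, dtype=float))
        if self.kind == "minmax":
            span = np.where(self.hi_ > self.lo_, self.hi_ - self.lo_, 1.0)
            return (scalars - self.lo_) / span
        if self.kind == "zscore":
            sd = np.where(self.sd_ > 0, self.sd_, 1.0)
            return (scalars - self.mean_) / sd
        raise ValueError(f"unknown scaler kind {self.kind!r}")


def fuse(code: np.ndarray, cov, apen, scaler: FeatureScaler,
         use_cov: bool = True, use_apen: bool = True) -> np.ndarray:
    """Concatenate [code ‖ scaled(cov) ‖ scaled(apen)] row-wise.

    ``code`` is (n, d); ``cov`` and ``apen`` are length-n vectors.  The
    ablation flags drop either scalar, giving fused widths d / d+1 / d+2.
    """
    code = np.atleast_2d(np.asarray(code, dtype=float))
    scalars = np.column_stack([np.asarray(cov, float).ravel(),
                               np.asarray(apen, float).ravel()])
    if scaler.kind != "none" and not scaler.fitted:
        raise RuntimeError("scaler not fitted; call fit on training features first")
    scaled = scaler.transform(scalars)
    parts = [code]
    if use_cov:
        parts.append(scaled[:, [0]])
    if use_apen:
        parts.append(scaled[:, [1]])
    return np.hstack(parts)


def feature_table(X: np.ndarray, m: int = 2, r_frac: float = 0.2,
                  cov_mode: str = "cv") -> np.ndarray:
    """(n, 2) array of [dispersion, ApEn] per row of ``X``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    out = np.empty((X.shape[0], 2))
    for i, row in enumerate(X):
        out[i, 0] = dispersion_feature(row, mode=cov_mode)
        out[i, 1] = approximate_entropy(row, m=m, r_frac=r_frac)
    return out
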
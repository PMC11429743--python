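"""Genomic relationship kernels.

Two kernels over hybrid dosage vectors are provided: the classical
additive GRM, ZZ'/(2*sum p(1-p)), and the first-order arc-cosine kernel

    k(x, x') = (1/pi) * ||x|| * ||x'|| * (sin(theta) + (pi - theta) cos(theta)),
    theta = arccos( x.x' / (||x|| ||x'||) ),

computed on markers centered by twice the allele frequency so that theta
is a genuine genetic-correlation angle. The arc-cosine kernel mimics the
covariance of an infinitely wide one-layer neural network and is the
nonlinear relationship matrix used by both halves of the winning
competition model; deeper recursive compositions are available through
``n_layers`` but default to a single layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomicKernel",
    "center_markers",
    "arc_cosine_kernel",
    "additive_grm",
]

_SYM_TOL = 1e-10
_PSD_TOL = 1e-8


@dataclass
class GenomicKernel:
    """A symmetric PSD hybrid relationship matrix with labels.

    Invariants (checked at construction): symmetry to 1e-10, minimum
    eigenvalue above ``-1e-8 * trace/n``, and — for normalized kernels —
    a unit diagonal.
    """

    hybrids: list
    values: np.ndarray
    kind: str = "additive"
    normalized: bool = False
    _index: pd.Index = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.hybrids)
        if self.values.shape != (n, n):
            raise ValueError("kernel matrix shape does not match hybrid labels")
        asym = np.abs(self.values - self.values.T).max() if n else 0.0
        if asym > _SYM_TOL:
            raise ValueError(f"kernel not symmetric (max asymmetry {asym:.2e})")
        self.values = 0.5 * (self.values + self.values.T)
        w_min = float(np.linalg.eigvalsh(self.values).min()) if n else 0.0
        bound = -_PSD_TOL * max(np.trace(self.values) / max(n, 1), 1.0)
        if w_min < bound:
            raise ValueError(f"kernel not PSD (min eigenvalue {w_min:.2e})")
        self._index = pd.Index(self.hybrids)
        if self._index.has_duplicates:
            raise ValueError("duplicate hybrid labels in kernel")

    @property
    def n_hybrids(self) -> int:
        return len(self.hybrids)

    def loc(self, rows, cols=None) -> np.ndarray:
        """Sub-matrix for the given hybrid labels (rows x cols)."""
        ri = self._indices(rows)
        ci = ri if cols is None else self._indices(cols)
        return self.values[np.ix_(ri, ci)]

    def _indices(self, labels) -> np.ndarray:
        idx = self._index.get_indexer(pd.Index(labels))
        if (idx < 0).any():
            missing = list(pd.Index(labels)[idx < 0])
            raise KeyError(f"hybrids not in kernel: {missing[:5]}")
        return idx

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self._index, columns=self._index)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="hybrid")

    @classmethod
    def from_csv(cls, path, kind: str = "additive", normalized: bool = False):
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index), df.to_numpy(), kind=kind, normalized=normalized)


def _allele_freqs(M: pd.DataFrame) -> np.ndarray:
    return M.to_numpy(dtype=float).mean(axis=0) / 2.0


def center_markers(M: pd.DataFrame, freqs: np.ndarray | None = None) -> np.ndarray:
    """Center dosage column j by twice its allele frequency."""
    X = M.to_numpy(dtype=float)
    p = _allele_freqs(M) if freqs is None else np.asarray(freqs, dtype=float)
    return X - 2.0 * p


def arc_cosine_kernel(
    M: pd.DataFrame,
    normalize: bool = True,
    n_layers: int = 1,
    freqs: np.ndarray | None = None,
) -> GenomicKernel:
    """First-order arc-cosine kernel on centered markers.

    With ``normalize=True`` (default) the kernel is rescaled to
    k(x,x') / sqrt(k(x,x) k(x',x')), giving an exact unit diagonal. The
    cosine is clipped to [-1, 1] before the arccos. ``n_layers > 1``
    composes the kernel recursively.
    """
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    Z = center_markers(M, freqs)
    norms = np.linalg.norm(Z, axis=1)
    if np.any(norms == 0.0):
        bad = list(M.index[norms == 0.0])
        raise ValueError(f"zero-norm (all-reference) hybrid rows: {bad[:5]}")

    K = Z @ Z.T
    for _ in range(n_layers):
        d = np.sqrt(np.clip(np.diag(K), 0.0, None))
        cos = K / np.outer(d, d)
        np.clip(cos, -1.0, 1.0, out=cos)
        theta = np.arccos(cos)
        K = (1.0 / np.pi) * np.outer(d, d) * (np.sin(theta) + (np.pi - theta) * cos)

    if normalize:
        d = np.sqrt(np.diag(K))
        K = K / np.outer(d, d)
        np.fill_diagonal(K, 1.0)
    K = 0.5 * (K + K.T)
    return GenomicKernel(list(M.index), K, kind="arc_cosine", normalized=normalize)


def additive_grm(M: pd.DataFrame, freqs: np.ndarray | None = None) -> GenomicKernel:
    """VanRaden additive GRM: ZZ' / (2 * sum_j p_j (1 - p_j))."""
    p = _allele_freqs(M) if freqs is None else np.asarray(freqs, dtype=float)
    Z = center_markers(M, p)
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise ValueError("all markers monomorphic; GRM undefined")
    K = Z @ Z.T / denom
    return GenomicKernel(list(M.index), K, kind="additive")
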
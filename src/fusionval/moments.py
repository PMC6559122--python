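"""Sample moment container: a labeled covariance matrix plus its sample size."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SampleMoments"]


@dataclass
class SampleMoments:
    """A labeled sample covariance matrix with the number of observations.

    Parameters
    ----------
    labels : list of str
        Variable names, in the order of the rows/columns of ``s_matrix``.
    s_matrix : ndarray
        Symmetric sample covariance matrix (unbiased, divisor N-1 by the
        usual convention; the estimator only assumes it is a covariance).
    n_obs : int
        Number of observations the matrix was computed from.
    """

    labels: list[str]
    s_matrix: np.ndarray
    n_obs: int
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.s_matrix = np.asarray(self.s_matrix, dtype=float)
        p = len(self.labels)
        if self.s_matrix.shape != (p, p):
            raise ValueError(
                f"covariance matrix is {self.s_matrix.shape}, but {p} labels given"
            )
        if len(set(self.labels)) != p:
            raise ValueError("duplicate variable labels")
        if not np.allclose(self.s_matrix, self.s_matrix.T, atol=1e-8):
            raise ValueError("covariance matrix is not symmetric")
        self.s_matrix = 0.5 * (self.s_matrix + self.s_matrix.T)
        if self.n_obs <= p:
            raise ValueError(f"n_obs={self.n_obs} must exceed the number of variables p={p}")
        # Non-PD input is flagged, not fatal: downstream fitting will fail
        # loudly if the matrix is genuinely unusable.
        eigmin = float(np.linalg.eigvalsh(self.s_matrix).min())
        if eigmin <= 0:
            self.warnings.append(
                f"sample covariance matrix is not positive definite (min eigenvalue {eigmin:.3g})"
            )

    @property
    def p(self) -> int:
        return len(self.labels)

    @property
    def is_positive_definite(self) -> bool:
        return not any("positive definite" in w for w in self.warnings)

    def variance(self, name: str) -> float:
        i = self.labels.index(name)
        return float(self.s_matrix[i, i])

    def reorder(self, labels: list[str]) -> "SampleMoments":
        """Return a copy restricted to, and ordered by, ``labels``."""
        missing = [x for x in labels if x not in self.labels]
        if missing:
            raise KeyError(f"variables not present in the covariance matrix: {missing}")
        idx = [self.labels.index(x) for x in labels]
        return SampleMoments(list(labels), self.s_matrix[np.ix_(idx, idx)], self.n_obs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.s_matrix, index=self.labels, columns=self.labels)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, n_obs: int) -> "SampleMoments":
        return cls(list(frame.columns), frame.to_numpy(dtype=float), n_obs)
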
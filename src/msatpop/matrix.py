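"""Labeled symmetric pairwise matrices.

Every between-population statistic in this package (F_ST, Nm, molecular
coancestry, Nei's Ds, (δµ)², divergence times) is carried as a
:class:`PairwiseMatrix`: a square symmetric matrix with an ordered list of
population labels and a statistic tag describing the diagonal convention.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PairwiseMatrix"]

#: statistics whose diagonal is 0 by definition (distances)
_DISTANCE_TAGS = {"FST", "Ds", "dmu2", "generations", "years"}


@dataclass
class PairwiseMatrix:
    """Symmetric population-by-population matrix of one statistic.

    Parameters
    ----------
    labels : ordered population names.
    values : square array; must be symmetric within 1e-12 on finite entries.
    statistic : tag, one of ``FST, Nm, fij, Ds, dmu2, generations, years``
        (free-form tags are allowed for derived quantities).
    """

    labels: list[str]
    values: np.ndarray
    statistic: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} does not match {n} labels")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate population labels")
        finite = np.isfinite(self.values) & np.isfinite(self.values.T)
        if not np.allclose(self.values[finite], self.values.T[finite], atol=1e-12, rtol=0):
            raise ValueError("matrix is not symmetric")
        inf = np.isinf(self.values)
        if not (inf == inf.T).all():
            raise ValueError("matrix is not symmetric (infinite entries)")

    # -- access -----------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.labels)

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def submatrix(self, labels: list[str]) -> "PairwiseMatrix":
        idx = [self.labels.index(x) for x in labels]
        return PairwiseMatrix(list(labels), self.values[np.ix_(idx, idx)], self.statistic)

    def apply(self, func, statistic: str | None = None) -> "PairwiseMatrix":
        """Elementwise transform preserving labels (e.g. F_ST → Nm)."""
        return PairwiseMatrix(
            list(self.labels), func(self.values.copy()), statistic or self.statistic
        )

    def offdiag(self) -> np.ndarray:
        """Upper-triangle (off-diagonal) values, row-major order."""
        iu = np.triu_indices(self.n, 1)
        return self.values[iu]

    def allclose(self, other: "PairwiseMatrix", atol: float = 1e-12) -> bool:
        return self.labels == other.labels and np.allclose(
            self.values, other.values, atol=atol, rtol=0, equal_nan=True
        )

    # -- serialization -----------------------------------------------------
    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)

    @classmethod
    def from_csv(cls, path, statistic: str = "") -> "PairwiseMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index.astype(str)), df.values.astype(float), statistic)

    def to_phylip(self) -> str:
        """PHYLIP square distance-matrix text (names padded to 10 chars)."""
        lines = [f"{self.n:5d}"]
        for lab, row in zip(self.labels, self.values):
            name = f"{lab[:10]:<10}"
            lines.append(name + " ".join(f"{v:.6f}" for v in row))
        return "\n".join(lines) + "\n"

    def to_lower_triangle(self, decimals: int = 3) -> str:
        """Lower-triangle text layout used by the published pairwise tables."""
        width = max(len(x) for x in self.labels) + 1
        out = [" " * width + "\t".join(self.labels[:-1])]
        for i, lab in enumerate(self.labels):
            cells = [f"{self.values[i, j]:.{decimals}f}" for j in range(i)]
            out.append(f"{lab:<{width}}" + "\t".join(cells))
        return "\n".join(out) + "\n"
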
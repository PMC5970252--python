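"""Two-sample data container.

The package operates on a pair of independent samples ``X1`` (``n1 x m``)
and ``X2`` (``n2 x m``) drawn from m-variate distributions that are assumed
to differ, if at all, only in location.  Rows are subjects, columns are
variables (e.g. genes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TwoSampleMatrix"]


@dataclass(frozen=True)
class TwoSampleMatrix:
    """The paired samples of a two-group comparison.

    Parameters
    ----------
    x1, x2 : ndarray of shape (n1, m) and (n2, m)
        Real data matrices with identical column count.  Every entry must
        be finite; each group needs at least two subjects.
    """

    x1: np.ndarray
    x2: np.ndarray

    def __post_init__(self) -> None:
        x1 = np.asarray(self.x1, dtype=float)
        x2 = np.asarray(self.x2, dtype=float)
        if x1.ndim != 2 or x2.ndim != 2:
            raise ValueError("x1 and x2 must be 2-D (samples x variables)")
        if x1.shape[1] != x2.shape[1]:
            raise ValueError(
                f"column mismatch: x1 has {x1.shape[1]} variables, "
                f"x2 has {x2.shape[1]}"
            )
        if x1.shape[1] < 1:
            raise ValueError("at least one variable is required")
        if x1.shape[0] < 2 or x2.shape[0] < 2:
            raise ValueError("each group needs at least 2 samples")
        if not (np.isfinite(x1).all() and np.isfinite(x2).all()):
            raise ValueError("non-finite entries in the data matrix")
        object.__setattr__(self, "x1", x1)
        object.__setattr__(self, "x2", x2)

    @property
    def n1(self) -> int:
        return self.x1.shape[0]

    @property
    def n2(self) -> int:
        return self.x2.shape[0]

    @property
    def n(self) -> int:
        return self.n1 + self.n2

    @property
    def m(self) -> int:
        return self.x1.shape[1]

    def pooled(self) -> np.ndarray:
        """Stack both groups: rows 0..n1-1 are group 1, the rest group 2."""
        return np.vstack([self.x1, self.x2])

    def swapped(self) -> "TwoSampleMatrix":
        """Return the dataset with the two group labels exchanged."""
        return TwoSampleMatrix(self.x2, self.x1)
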
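"""Between-sample normalization by quantile-curve offset regression.

Sequencing depth differs between samples by a roughly multiplicative
factor, which in log space is a single additive offset.  The model
estimates that offset per sample from the mid-to-upper part of the
expression distribution, where signal dominates zeros and noise:

1. per sample, evaluate the quantiles of log2(expression + pseudocount)
   on a fixed grid between the median (0.5-quantile) and the
   0.98-quantile (default step 0.01, i.e. 49 grid points);
2. average the per-sample quantile curves point-wise into an *average
   quantile curve*;
3. regress each sample's curve onto the average curve with an
   intercept-only fit: the least-squares solution is the mean
   difference of the two curves over the grid (an L1 / median-difference
   fit is available as ``method="median"``).

Applying the model adds each sample's offset to its log2(expression +
pseudocount) column, i.e. rescales the sample multiplicatively.
The extreme upper tail (above the 0.98-quantile) is excluded so a few
highly expressed genes cannot dominate the fit; the lower half is
excluded because it is pseudocount- and dropout-dominated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .quantify import ExpressionMatrix

DEFAULT_Q_LO = 0.5
DEFAULT_Q_HI = 0.98
DEFAULT_Q_STEP = 0.01
DEFAULT_PSEUDOCOUNT = 0.5


def make_quantile_grid(q_lo: float = DEFAULT_Q_LO, q_hi: float = DEFAULT_Q_HI,
                       step: float = DEFAULT_Q_STEP) -> np.ndarray:
    """Discretize [q_lo, q_hi] with the given step (endpoints included)."""
    if not 0 <= q_lo < q_hi <= 1:
        raise ValidationError(f"invalid quantile range [{q_lo}, {q_hi}]")
    n = int(round((q_hi - q_lo) / step)) + 1
    grid = q_lo + step * np.arange(n)
    return grid[grid <= q_hi + 1e-12]


class QuantileOffsetNormalization:
    """Normalization model for a raw :class:`ExpressionMatrix`.

    Parameters
    ----------
    matrix:
        Raw (trimmed-mean count scale) expression; absent genes (NaN in
        any sample) are excluded from quantile estimation.
    grid:
        Quantile grid; defaults to 0.50..0.98 step 0.01.
    pseudocount:
        Added before log2 so zeros are finite; default 0.5.
    """

    def __init__(self, matrix: ExpressionMatrix, grid: np.ndarray | None = None,
                 pseudocount: float = DEFAULT_PSEUDOCOUNT):
        if matrix.scale != "raw":
            raise ValidationError("normalization is fitted on the raw matrix")
        if pseudocount <= 0:
            raise ValidationError("pseudocount must be > 0")
        self.matrix = matrix
        self.grid = make_quantile_grid() if grid is None else np.asarray(grid, float)
        if self.grid.size < 2 or np.any(np.diff(self.grid) <= 0):
            raise ValidationError("quantile grid must be strictly increasing")
        self.pseudocount = float(pseudocount)

        data = matrix.data
        if data.shape[1] < 2:
            raise ValidationError("normalization needs at least 2 samples")
        quantifiable = data.notna().all(axis=1)
        if quantifiable.sum() < 2:
            raise ValidationError("fewer than 2 quantifiable genes")
        self._values = data.loc[quantifiable]
        for s in data.columns:
            if (self._values[s] == 0).all():
                raise ValidationError(f"sample {s!r} is all zero; cannot normalize")

    def sample_curves(self) -> pd.DataFrame:
        """Per-sample quantile curves of log2(value + pseudocount)."""
        logv = np.log2(self._values.to_numpy(float) + self.pseudocount)
        curves = np.quantile(logv, self.grid, axis=0)  # grid x samples
        return pd.DataFrame(curves, index=self.grid, columns=self._values.columns)

    def fit(self, method: str = "least-squares") -> "NormalizationResults":
        """Estimate per-sample offsets against the average quantile curve.

        ``method="least-squares"`` (default) gives the closed-form mean
        difference; ``method="median"`` gives the L1-optimal median
        difference, robust to a few discordant grid points.
        """
        curves = self.sample_curves()
        average = curves.mean(axis=1)
        residual = average.to_numpy()[:, None] - curves.to_numpy()
        if method == "least-squares":
            offsets = residual.mean(axis=0)
        elif method == "median":
            offsets = np.median(residual, axis=0)
        else:
            raise ValidationError(f"unknown offset fit method {method!r}")
        return NormalizationResults(
            grid=self.grid,
            average_curve=average.to_numpy(),
            offsets=pd.Series(offsets, index=curves.columns, name="offset_log2"),
            pseudocount=self.pseudocount,
            method=method,
            sample_curves=curves,
        )


@dataclass
class NormalizationResults:
    """Fitted per-sample offsets (log2 units) and the curves behind them."""

    grid: np.ndarray
    average_curve: np.ndarray
    offsets: pd.Series
    pseudocount: float
    method: str
    sample_curves: pd.DataFrame | None = field(default=None, repr=False)

    def apply(self, matrix: ExpressionMatrix) -> ExpressionMatrix:
        """Normalize a raw matrix: log2(value + pseudocount) + offset.

        Absent genes stay absent.  The matrix must contain exactly the
        samples the model was fitted on.
        """
        if matrix.scale != "raw":
            raise ValidationError("apply expects a raw matrix")
        missing = set(matrix.samples) - set(self.offsets.index)
        if missing:
            raise ValidationError(f"samples not in the fitted model: {sorted(missing)}")
        logv = np.log2(matrix.data + self.pseudocount)
        normalized = logv + self.offsets.reindex(matrix.samples)
        return ExpressionMatrix(data=normalized, scale="normalized-log2")

    def summary(self) -> str:
        lines = [
            "Quantile-curve offset normalization",
            f"  grid: {self.grid[0]:.2f}..{self.grid[-1]:.2f} "
            f"({self.grid.size} points), pseudocount {self.pseudocount}, "
            f"fit: {self.method}",
            "  sample offsets (log2):",
        ]
        for s, o in self.offsets.items():
            lines.append(f"    {s:20s} {o:+.4f}  (x{2.0 ** o:.3f} linear)")
        return "\n".join(lines)

    def to_json(self, path) -> None:
        payload = {
            "grid": self.grid.tolist(),
            "average_curve": self.average_curve.tolist(),
            "offsets": {s: float(o) for s, o in self.offsets.items()},
            "pseudocount": self.pseudocount,
            "method": self.method,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "NormalizationResults":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            grid=np.asarray(payload["grid"], float),
            average_curve=np.asarray(payload["average_curve"], float),
            offsets=pd.Series(payload["offsets"], name="offset_log2"),
            pseudocount=payload["pseudocount"],
            method=payload["method"],
        )

    def plot(self, ax=None):
        """Quantile curves per sample against the average curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.sample_curves is not None:
            for s in self.sample_curves.columns:
                ax.plot(self.grid, self.sample_curves[s], alpha=0.6, label=str(s))
        ax.plot(self.grid, self.average_curve, "k--", lw=2, label="average")
        ax.set_xlabel("quantile")
        ax.set_ylabel("log2(expression + pseudocount)")
        ax.legend(fontsize="small")
        return ax


def fit_normalization(matrix: ExpressionMatrix, grid: np.ndarray | None = None,
                      pseudocount: float = DEFAULT_PSEUDOCOUNT,
                      method: str = "least-squares") -> NormalizationResults:
    """Functional wrapper: fit the quantile-offset model on a raw matrix."""
    return QuantileOffsetNormalization(matrix, grid=grid,
                                       pseudocount=pseudocount).fit(method=method)


def apply_normalization(matrix: ExpressionMatrix,
                        model: NormalizationResults) -> ExpressionMatrix:
    """Functional wrapper: apply fitted offsets to the raw matrix."""
    return model.apply(matrix)
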
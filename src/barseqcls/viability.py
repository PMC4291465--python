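"""CFU viability curves and median chronological lifespan.

Viability at each timepoint is the colony-forming fraction relative to the
reference timepoint (set to 100%); the median chronological lifespan is
where a least-squares order-2 polynomial fitted to viability-vs-time first
crosses 50%. Pool curves can transiently exceed 100% (residual divisions
early in quiescence), so values above 100 are legal.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class NoMedianError(ValueError):
    """Fitted viability does not cross 50% within the observed time range."""


@dataclass
class SurvivalCurve:
    """Viability (percent of reference) per timepoint for one or more replicates."""

    timepoints: np.ndarray
    viability: np.ndarray  # percent; reference = 100
    replicate: np.ndarray
    unit: str = "weeks"

    def __post_init__(self):
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        self.replicate = np.asarray(self.replicate)
        if np.any(self.viability < 0):
            raise ValueError("viability must be non-negative")

    @classmethod
    def from_tsv(cls, path: str | Path, unit: str | None = None) -> "SurvivalCurve":
        """Read a viability TSV: timepoint, replicate, plated, cfu[, unit]."""
        df = pd.read_csv(path, sep="\t")
        u = unit or (str(df["unit"].iloc[0]) if "unit" in df else "weeks")
        curves = [
            cfu_to_viability(
                sub["cfu"].to_numpy(),
                sub["plated"].to_numpy(),
                sub["timepoint"].to_numpy(),
                replicate=rep,
                unit=u,
            )
            for rep, sub in df.groupby("replicate")
        ]
        return concat_curves(curves)


def concat_curves(curves: Sequence[SurvivalCurve]) -> SurvivalCurve:
    return SurvivalCurve(
        timepoints=np.concatenate([c.timepoints for c in curves]),
        viability=np.concatenate([c.viability for c in curves]),
        replicate=np.concatenate([c.replicate for c in curves]),
        unit=curves[0].unit,
    )


def cfu_to_viability(
    cfu: Sequence[float],
    plated_cells: Sequence[float],
    timepoints: Sequence[float],
    replicate: int | str = 1,
    unit: str = "weeks",
) -> SurvivalCurve:
    """Convert CFU counts to percent viability relative to the first timepoint.

    viability_t = 100 * (cfu_t / plated_t) / (cfu_0 / plated_0), where the
    reference is the earliest timepoint. Plating-efficiency differences
    cancel; values may exceed 100.
    """
    cfu = np.asarray(cfu, dtype=float)
    plated = np.asarray(plated_cells, dtype=float)
    t = np.asarray(timepoints, dtype=float)
    if np.any(plated <= 0):
        raise ValueError("plated cell counts must be positive")
    order = np.argsort(t)
    cfu, plated, t = cfu[order], plated[order], t[order]
    eff = cfu / plated
    if eff[0] <= 0:
        raise ValueError("reference timepoint must have cfu > 0")
    return SurvivalCurve(
        timepoints=t,
        viability=100.0 * eff / eff[0],
        replicate=np.full(len(t), replicate),
        unit=unit,
    )


class QuadraticSurvival:
    """Order-2 polynomial model of viability versus time.

    Replicates are pooled into one point cloud for the least-squares fit
    (fit on points, not on averaged curves). `fit()` returns a
    :class:`SurvivalFit` exposing the coefficients and the median lifespan.
    """

    def __init__(self, curve: SurvivalCurve):
        if len(np.unique(curve.timepoints)) < 3:
            raise ValueError("need at least 3 distinct timepoints for an order-2 fit")
        self.curve = curve

    def fit(self) -> "SurvivalFit":
        t, v = self.curve.timepoints, self.curve.viability
        coeffs = np.polyfit(t, v, deg=2)
        if not np.all(np.isfinite(coeffs)):
            raise ValueError("degenerate polynomial fit")
        return SurvivalFit(coeffs=coeffs, curve=self.curve)


@dataclass
class SurvivalFit:
    """Fitted quadratic survival model."""

    coeffs: np.ndarray  # highest degree first, np.polyval convention
    curve: SurvivalCurve

    def predict(self, t) -> np.ndarray:
        return np.polyval(self.coeffs, t)

    @property
    def median_lifespan(self) -> float:
        """Smallest time in the observed range where the fit crosses 50%."""
        t = self.curve.timepoints
        lo, hi = float(t.min()), float(t.max())
        roots = np.roots(np.polyadd(self.coeffs, [-50.0]))
        real = sorted(r.real for r in roots if abs(r.imag) < 1e-9 and lo - 1e-9 <= r.real <= hi + 1e-9)
        if not real:
            raise NoMedianError(
                f"fitted viability does not reach 50% within [{lo:g}, {hi:g}] {self.curve.unit}"
            )
        return float(real[0])

    def summary(self) -> str:
        a, b, c = self.coeffs
        try:
            med = f"{self.median_lifespan:.2f} {self.curve.unit}"
        except NoMedianError:
            med = "not reached in observed range"
        return "\n".join(
            [
                "Quadratic survival fit",
                "=" * 40,
                f"points fitted:     {len(self.curve.timepoints)}"
                f" ({len(np.unique(self.curve.replicate))} replicate(s))",
                f"v(t) = {a:.4g} t^2 + {b:.4g} t + {c:.4g}",
                f"median lifespan:   {med}",
            ]
        )

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.curve
        for rep in np.unique(c.replicate):
            m = c.replicate == rep
            ax.plot(c.timepoints[m], c.viability[m], "o", label=f"replicate {rep}")
        grid = np.linspace(c.timepoints.min(), c.timepoints.max(), 200)
        ax.plot(grid, self.predict(grid), "-", color="0.3", label="order-2 fit")
        ax.axhline(50, ls="--", lw=0.8, color="0.5")
        ax.set_xlabel(f"time ({c.unit})")
        ax.set_ylabel("viability (%)")
        ax.legend()
        return ax


def median_cls(curve: SurvivalCurve) -> float:
    """Median chronological lifespan: fit an order-2 polynomial and return
    the first 50% crossing within the observed time range."""
    if not np.any(curve.viability < 50.0) and not np.any(
        np.polyval(np.polyfit(curve.timepoints, curve.viability, 2), curve.timepoints) < 50.0
    ):
        raise NoMedianError("all observed viability is above 50%")
    return QuadraticSurvival(curve).fit().median_lifespan
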
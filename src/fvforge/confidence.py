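"""Data-driven model confidence.

Confidence is the conditional probability P(x | s) that a region is modeled
within an RMSD threshold x, given a conditioning value s: framework sequence
identity (%) for framework regions, loop length for CDRs.  Probabilities are
counting ratios over a calibration table of (conditioning value, RMSD)
observations — pairwise framework superimpositions for the framework, loop
prediction benchmarks for the CDRs.

Identity conditioning uses a sliding s +/- 2.5 window evaluated on a 1-unit
grid (each reported bin is 1% wide; neighbouring windows overlap); loop
lengths are discrete, so length conditioning is an exact match.  Inverting
the curve at a chosen confidence level (default 75%) yields the expected
RMSD of a region.  Bins without data raise :class:`ConfidenceUnavailable`
rather than reporting 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

IDENTITY_WINDOW = 2.5
DEFAULT_CONFIDENCE = 0.75
DEFAULT_GRID_STEP = 0.1


class ConfidenceUnavailable(ValueError):
    """No calibration data for the requested conditioning value."""


@dataclass
class CalibrationTable:
    """Observations (conditioning value, outcome RMSD) for one region kind.

    Conditioning values are framework sequence identities (%) or CDR loop
    lengths.  Stored observations may be unordered pairs: the ordered-pair
    double counting of a symmetric all-vs-all comparison cancels in every
    probability ratio.
    """

    conditioning: np.ndarray
    rmsd: np.ndarray
    kind: str = ""

    def __post_init__(self):
        self.conditioning = np.asarray(self.conditioning, dtype=float)
        self.rmsd = np.asarray(self.rmsd, dtype=float)
        if self.conditioning.shape != self.rmsd.shape or self.conditioning.ndim != 1:
            raise ValueError("conditioning and rmsd must be equal-length 1-D arrays")
        if len(self.rmsd) and self.rmsd.min() < 0:
            raise ValueError("RMSD observations must be non-negative")

    def __len__(self) -> int:
        return len(self.rmsd)

    @classmethod
    def from_superimpositions(cls, table: pd.DataFrame, kind: str = "") -> "CalibrationTable":
        """Build from a pairwise superimposition table (identity/rmsd columns)."""
        return cls(table["identity"].to_numpy(), table["rmsd"].to_numpy(), kind)

    @classmethod
    def from_rows(cls, rows, kind: str = "") -> "CalibrationTable":
        arr = np.asarray(list(rows), dtype=float)
        if arr.size == 0:
            return cls(np.empty(0), np.empty(0), kind)
        return cls(arr[:, 0], arr[:, 1], kind)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"conditioning": self.conditioning, "rmsd": self.rmsd,
                             "kind": self.kind})

    def save(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path) -> "CalibrationTable":
        df = pd.read_csv(path, sep="\t")
        kind = str(df["kind"].iloc[0]) if "kind" in df and len(df) else ""
        return cls(df["conditioning"].to_numpy(), df["rmsd"].to_numpy(), kind)


def _window_mask(table: CalibrationTable, s: float, window: float) -> np.ndarray:
    return np.abs(table.conditioning - s) <= window


def marginal_probability(table: CalibrationTable, s: float,
                         window: float = IDENTITY_WINDOW) -> float:
    """Fraction of observations with conditioning value in [s - w, s + w]."""
    if len(table) == 0:
        raise ConfidenceUnavailable(f"{table.kind or 'calibration'}: empty table")
    return float(_window_mask(table, s, window).mean())


def joint_probability(table: CalibrationTable, s: float, x: float,
                      window: float = IDENTITY_WINDOW) -> float:
    """Fraction of observations in-window AND with RMSD <= x."""
    if len(table) == 0:
        raise ConfidenceUnavailable(f"{table.kind or 'calibration'}: empty table")
    return float((_window_mask(table, s, window) & (table.rmsd <= x)).mean())


def conditional_probability(table: CalibrationTable, s: float, x: float,
                            window: float = IDENTITY_WINDOW) -> float:
    """P(RMSD <= x | conditioning in s +/- window) = joint / marginal."""
    marginal = marginal_probability(table, s, window)
    if marginal == 0.0:
        raise ConfidenceUnavailable(
            f"{table.kind or 'calibration'}: no observations near s={s}")
    return joint_probability(table, s, x, window) / marginal


def loop_confidence(table: CalibrationTable, length: int, x: float) -> float:
    """CDR-loop confidence conditioned on exact loop length (no window)."""
    return conditional_probability(table, float(length), x, window=0.0)


def expected_rmsd_at_confidence(table: CalibrationTable, s: float,
                                p: float = DEFAULT_CONFIDENCE,
                                window: float = IDENTITY_WINDOW,
                                grid_step: float = DEFAULT_GRID_STEP,
                                x_max: float | None = None) -> float:
    """Smallest grid RMSD threshold x with P(x | s) >= p.

    Raises :class:`ConfidenceUnavailable` when there is no data at s or the
    curve never reaches p within the grid (insufficient data).
    """
    marginal = marginal_probability(table, s, window)
    if marginal == 0.0:
        raise ConfidenceUnavailable(
            f"{table.kind or 'calibration'}: no observations near s={s}")
    if x_max is None:
        in_window = table.rmsd[_window_mask(table, s, window)]
        x_max = float(np.ceil(in_window.max() / grid_step) * grid_step)
    n_steps = int(round(x_max / grid_step)) + 1
    for i in range(n_steps):
        x = i * grid_step
        if joint_probability(table, s, x, window) / marginal >= p:
            return round(x, 10)
    raise ConfidenceUnavailable(
        f"{table.kind or 'calibration'}: confidence {p} not reached within "
        f"RMSD grid [0, {x_max}]")


def confidence_curve(table: CalibrationTable, s: float,
                     window: float = IDENTITY_WINDOW,
                     grid_step: float = DEFAULT_GRID_STEP,
                     x_max: float | None = None) -> pd.DataFrame:
    """P(x | s) over an RMSD grid, for export/plotting."""
    if x_max is None:
        x_max = float(np.ceil(table.rmsd.max() / grid_step) * grid_step) if len(table) else 1.0
    xs = np.round(np.arange(0.0, x_max + grid_step / 2, grid_step), 10)
    ps = [conditional_probability(table, s, x, window) for x in xs]
    return pd.DataFrame({"rmsd_threshold": xs, "probability": ps})
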
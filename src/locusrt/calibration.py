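"""Transfer a pre-trained model to a new chromatographic condition.

A model trained under one gradient predicts RTs on that gradient's scale.
When the same peptide chemistry runs under a different gradient or column,
predicted and observed RTs remain strongly linearly related, so a small set
of peptides observed under the new condition ("calibration peptides") is
enough to fit

    observed RT = A × predicted RT + B

by ordinary least squares; predictions for all other peptides are then
mapped through the same line.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import CalibrationError
from .peptides import Peptide, RTDataset


@dataclass(frozen=True)
class CalibrationFit:
    """Fitted slope A (dimensionless), intercept B (minutes)."""

    A: float
    B: float
    n_calibrants: int
    residual_sd: float  # sqrt(SSR / (n - 2)), minutes; 0 when n == 2

    def __post_init__(self) -> None:
        if self.n_calibrants < 2:
            raise ValueError("a calibration fit needs at least 2 peptides")
        if not np.isfinite(self.A) or self.A == 0:
            raise ValueError(f"slope A must be finite and nonzero, got {self.A}")


def select_calibration_peptides(dataset: RTDataset, n: int) -> list[Peptide]:
    """Top-*n* peptides by descending rank score.

    The rank score stands in for "how reliably and abundantly is this
    peptide observed" — e.g. spectral-library identification counts. Ties
    break lexicographically by sequence so selection is deterministic.
    """
    if n < 1 or n > len(dataset):
        raise CalibrationError(
            f"requested {n} calibrants from a dataset of {len(dataset)}"
        )
    missing = [p.sequence for p in dataset if p.rank_score is None]
    if missing:
        raise CalibrationError(
            f"{len(missing)} peptide(s) lack rank_score (e.g. {missing[0]})"
        )
    ranked = sorted(dataset, key=lambda p: (-p.rank_score, p.sequence))
    return ranked[:n]


def fit_calibration(
    observed: Sequence[float],
    predicted: Sequence[float],
    *,
    trim_outliers: bool = False,
    trim_sd: float = 3.0,
) -> CalibrationFit:
    """OLS fit of observed = A·predicted + B.

    ``trim_outliers`` adds one refit pass after discarding points whose
    residual exceeds ``trim_sd`` residual standard deviations (off by
    default: the plain fit is the reference behaviour).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be equal-length 1-D")
    if len(obs) < 2:
        raise CalibrationError("need at least 2 calibration points")
    if np.ptp(pred) == 0:
        raise CalibrationError("all predicted RTs identical: slope undefined")

    def _ols(o: np.ndarray, p: np.ndarray) -> tuple[float, float, float]:
        res = stats.linregress(p, o)
        resid = o - (res.slope * p + res.intercept)
        n = len(o)
        sd = float(np.sqrt(np.sum(resid**2) / (n - 2))) if n > 2 else 0.0
        return float(res.slope), float(res.intercept), sd

    A, B, sd = _ols(obs, pred)
    n_used = len(obs)
    if trim_outliers and sd > 0:
        resid = obs - (A * pred + B)
        keep = np.abs(resid) <= trim_sd * sd
        if keep.sum() >= 2 and np.ptp(pred[keep]) > 0 and keep.sum() < len(obs):
            A, B, sd = _ols(obs[keep], pred[keep])
            n_used = int(keep.sum())
    return CalibrationFit(A=A, B=B, n_calibrants=n_used, residual_sd=sd)


def apply_calibration(fit: CalibrationFit, predicted: Sequence[float]) -> np.ndarray:
    """Elementwise A·x + B."""
    return fit.A * np.asarray(predicted, dtype=float) + fit.B


def write_calibration(fit: CalibrationFit, path: str | Path) -> None:
    """Write the fit as a small key-value text file."""
    lines = [
        f"A\t{fit.A!r}",
        f"B\t{fit.B!r}",
        f"n_calibrants\t{fit.n_calibrants}",
        f"residual_sd\t{fit.residual_sd!r}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_calibration(path: str | Path) -> CalibrationFit:
    kv = {}
    for line in Path(path).read_text().splitlines():
        if line.strip():
            key, val = line.split("\t", 1)
            kv[key] = val
    try:
        return CalibrationFit(
            A=float(kv["A"]),
            B=float(kv["B"]),
            n_calibrants=int(kv["n_calibrants"]),
            residual_sd=float(kv["residual_sd"]),
        )
    except (KeyError, ValueError) as exc:
        raise CalibrationError(f"malformed calibration file {path}: {exc}") from exc
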
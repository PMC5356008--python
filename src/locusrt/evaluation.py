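"""Prediction-quality statistics for scheduled targeted acquisition.

Besides Pearson correlation and the signed-error distribution, the key
operational statistic is Δt95%: the width (minutes) of the narrowest
extraction window, centered on the predicted RT, that contains the observed
RT for 95% of peptides. A scheduled SRM/SWATH method monitors each target
only inside such a window, so a smaller Δt95% means more targets fit into
one run. The capacity curve makes that explicit: for each candidate window
width it reports the fraction of peptides whose prediction error fits
inside the window.

Signed errors are predicted − observed throughout.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import EmptyInputError, EvaluationError

#: Default capacity-curve extraction-window widths, minutes.
DEFAULT_WINDOWS = (0.5, 1.0, 2.0, 4.0, 8.0, 16.0)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation of two RT lists."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D")
    if len(x) < 3:
        raise EvaluationError("need at least 3 points for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise EvaluationError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y)[0])


def delta_t95(
    errors: Sequence[float],
    *,
    coverage: float = 0.95,
    method: str = "symmetric",
    percentile_method: str = "inverted_cdf",
) -> float:
    """Width of the extraction window covering *coverage* of the errors.

    ``method="symmetric"`` (default): the window is centered on the
    prediction, so its width is twice the smallest half-width h with
    |error| ≤ h for at least 95% of peptides — i.e. twice the ⌈0.95·n⌉-th
    smallest |error|. This is what a scheduler centered on predicted RTs
    uses. ``percentile_method="linear"`` switches to the interpolated
    percentile instead of the exact covering order statistic.

    ``method="minimal"``: the narrowest (possibly asymmetric) interval of
    signed errors containing ⌈0.95·n⌉ of them.
    """
    e = np.asarray(errors, dtype=float)
    if e.size == 0:
        raise EmptyInputError("no errors supplied")
    if not (0 < coverage < 1):
        raise ValueError("coverage must be in (0, 1)")
    if e.size < 20:
        warnings.warn(
            f"Δt95% on only {e.size} values: the {coverage:.0%} quantile is "
            "poorly determined",
            stacklevel=2,
        )
    if method == "symmetric":
        return 2.0 * float(
            np.quantile(np.abs(e), coverage, method=percentile_method)
        )
    if method == "minimal":
        s = np.sort(e)
        m = int(np.ceil(coverage * s.size))
        return float(np.min(s[m - 1 :] - s[: s.size - m + 1]))
    raise ValueError(f"unknown method {method!r}")


def capacity_curve(
    errors: Sequence[float], windows: Sequence[float] = DEFAULT_WINDOWS
) -> list[tuple[float, float]]:
    """Fraction of peptides tracked inside each centered extraction window.

    For a window of width w the peptide is tracked when |error| ≤ w/2.
    Returns (width, fraction) pairs; fractions are non-decreasing in width.
    """
    e = np.abs(np.asarray(errors, dtype=float))
    w = np.asarray(windows, dtype=float)
    if np.any(w <= 0):
        raise ValueError("window widths must be positive")
    if np.any(np.diff(w) < 0):
        raise ValueError("window widths must be sorted ascending")
    if e.size == 0:
        raise EmptyInputError("no errors supplied")
    return [(float(wi), float(np.mean(e <= wi / 2.0))) for wi in w]


def error_distribution(
    predicted: Sequence[float],
    observed: Sequence[float],
    *,
    bin_width: float = 1.0,
) -> tuple[float, float, tuple[np.ndarray, np.ndarray]]:
    """Mean, sample SD (n−1) and histogram of signed errors.

    Returns ``(error_mean, error_sd, (counts, bin_edges))`` with histogram
    bins of ``bin_width`` minutes aligned to the bin-width lattice.
    """
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise ValueError("predicted and observed must be equal-length 1-D")
    if len(pred) < 2:
        raise ValueError("need at least 2 points for an error SD")
    e = pred - obs
    lo = np.floor(e.min() / bin_width) * bin_width
    hi = np.ceil(e.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(e, bins=edges)
    return float(e.mean()), float(e.std(ddof=1)), (counts, edges)


@dataclass
class EvaluationReport:
    """All headline statistics for one predicted-vs-observed comparison."""

    n: int
    pearson_r: float
    error_mean: float  # minutes, predicted − observed
    error_sd: float  # minutes, n−1 denominator
    delta_t95: float  # minutes
    delta_t95_pct_of_gradient: float | None  # percent, None without gradient
    capacity_curve: list[tuple[float, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "pearson_r": self.pearson_r,
            "error_mean": self.error_mean,
            "error_sd": self.error_sd,
            "delta_t95": self.delta_t95,
            "delta_t95_pct_of_gradient": self.delta_t95_pct_of_gradient,
            "capacity_curve": [[w, f] for w, f in self.capacity_curve],
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "EvaluationReport":
        return cls(
            n=int(doc["n"]),
            pearson_r=float(doc["pearson_r"]),
            error_mean=float(doc["error_mean"]),
            error_sd=float(doc["error_sd"]),
            delta_t95=float(doc["delta_t95"]),
            delta_t95_pct_of_gradient=(
                None
                if doc["delta_t95_pct_of_gradient"] is None
                else float(doc["delta_t95_pct_of_gradient"])
            ),
            capacity_curve=[(float(w), float(f)) for w, f in doc["capacity_curve"]],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "EvaluationReport":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def write_text(self, path: str | Path, curve_path: str | Path | None = None) -> None:
        """Key-value summary plus an optional TSV of the capacity curve."""
        lines = [
            f"n\t{self.n}",
            f"pearson_r\t{self.pearson_r:.6f}",
            f"error_mean_min\t{self.error_mean:.6f}",
            f"error_sd_min\t{self.error_sd:.6f}",
            f"delta_t95_min\t{self.delta_t95:.6f}",
        ]
        if self.delta_t95_pct_of_gradient is not None:
            lines.append(
                f"delta_t95_pct_of_gradient\t{self.delta_t95_pct_of_gradient:.4f}"
            )
        Path(path).write_text("\n".join(lines) + "\n")
        if curve_path is not None:
            rows = ["window_minutes\tfraction_tracked"] + [
                f"{w}\t{f}" for w, f in self.capacity_curve
            ]
            Path(curve_path).write_text("\n".join(rows) + "\n")


def evaluate(
    predicted: Sequence[float],
    observed: Sequence[float],
    gradient_minutes: float | None = None,
    *,
    windows: Sequence[float] = DEFAULT_WINDOWS,
) -> EvaluationReport:
    """Compose the full report for one prediction run."""
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    errors = pred - obs
    mean, sd, _ = error_distribution(pred, obs)
    dt = delta_t95(errors)
    return EvaluationReport(
        n=len(pred),
        pearson_r=pearson_r(pred, obs),
        error_mean=mean,
        error_sd=sd,
        delta_t95=dt,
        delta_t95_pct_of_gradient=(
            100.0 * dt / gradient_minutes if gradient_minutes else None
        ),
        capacity_curve=capacity_curve(errors, windows),
    )
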
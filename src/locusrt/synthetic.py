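"""Synthetic peptide/RT datasets with a known ground-truth retention model.

The generator emulates the statistical shape of an LC-MS/MS identification
list: tryptic-like peptide sequences (C-terminal K/R, fully cleaved, with a
short-skewed length distribution) and retention times driven by an
additive hydrophobicity model with terminal-position effects,

    RT = intercept + Σ_i coef(aa_i) · w(i) + length_coef · L + N(0, noise_sd),

clipped to [0, gradient]. The position weight w(i) multiplies the residue
coefficient near the termini (first three and last three positions), which
is what makes *where* a residue sits informative — the property a
locus-aware predictor exploits and a composition-only model cannot see.

The ground truth is deliberately additive-linear, not an SVR, so that
recovery experiments are non-circular. Every dataset is regenerable from
(model, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import GenerationError
from .peptides import AMINO_ACIDS, Peptide, RTDataset

logger = logging.getLogger(__name__)

#: Kyte–Doolittle hydropathy index, the classic residue hydrophobicity
#: scale; more hydrophobic residues retain longer on a reversed-phase
#: column.
KYTE_DOOLITTLE = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8,
    "G": -0.4, "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8,
    "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5, "R": -4.5,
    "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}

#: Minutes of retention per hydropathy unit in the default model. At this
#: scale a typical tryptic mixture spreads over most of a 120-min gradient
#: (RT sd ≈ 20 min), as real identification lists do.
_DEFAULT_COEF_SCALE = 2.0

# Truncated-geometric length distribution: tryptic peptides are heavily
# skewed short (median ≈ 10 within the 7–25 window at this rate).
_LENGTH_GEOM_P = 0.18

_INTERNAL_RESIDUES = tuple(a for a in AMINO_ACIDS if a not in "KR")


@dataclass
class GroundTruthRTModel:
    """Additive-plus-positional ground truth for synthetic RTs.

    Parameters
    ----------
    residue_coefficients:
        Minutes of retention contributed by one copy of each residue at an
        interior position.
    nterm_position_multipliers / cterm_position_multipliers:
        Factors applied to the residue coefficient at the first/last three
        sequence positions (index 0 = terminal residue side). For peptides
        shorter than 6 residues both factors apply multiplicatively.
    length_coefficient:
        Minutes per residue of chain length.
    intercept:
        Baseline elution time, minutes.
    gradient_minutes:
        Total gradient; RTs are clipped into [0, gradient_minutes].
    noise_sd:
        Homoscedastic Gaussian measurement noise, minutes.
    """

    residue_coefficients: dict[str, float] = field(
        default_factory=lambda: {
            aa: _DEFAULT_COEF_SCALE * v for aa, v in KYTE_DOOLITTLE.items()
        }
    )
    nterm_position_multipliers: tuple[float, float, float] = (1.5, 1.3, 1.1)
    cterm_position_multipliers: tuple[float, float, float] = (1.4, 1.2, 1.1)
    length_coefficient: float = 0.7
    intercept: float = 50.0
    gradient_minutes: float = 120.0
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.residue_coefficients)
        if missing:
            raise ValueError(f"missing residue coefficient(s) {sorted(missing)}")
        if self.gradient_minutes <= 0:
            raise ValueError("gradient_minutes must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @classmethod
    def default(cls) -> "GroundTruthRTModel":
        return cls()

    def to_dict(self) -> dict:
        return {
            "residue_coefficients": dict(self.residue_coefficients),
            "nterm_position_multipliers": list(self.nterm_position_multipliers),
            "cterm_position_multipliers": list(self.cterm_position_multipliers),
            "length_coefficient": self.length_coefficient,
            "intercept": self.intercept,
            "gradient_minutes": self.gradient_minutes,
            "noise_sd": self.noise_sd,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "GroundTruthRTModel":
        return cls(
            residue_coefficients={k: float(v) for k, v in doc["residue_coefficients"].items()},
            nterm_position_multipliers=tuple(doc["nterm_position_multipliers"]),
            cterm_position_multipliers=tuple(doc["cterm_position_multipliers"]),
            length_coefficient=float(doc["length_coefficient"]),
            intercept=float(doc["intercept"]),
            gradient_minutes=float(doc["gradient_minutes"]),
            noise_sd=float(doc["noise_sd"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruthRTModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def noiseless_rt(sequence: str, model: GroundTruthRTModel) -> float:
    """Ground-truth RT before noise, clipped to the gradient."""
    L = len(sequence)
    total = model.intercept + model.length_coefficient * L
    for i, aa in enumerate(sequence):
        w = 1.0
        if i < 3:
            w *= model.nterm_position_multipliers[i]
        if i >= L - 3:
            w *= model.cterm_position_multipliers[L - 1 - i]
        total += model.residue_coefficients[aa] * w
    return float(np.clip(total, 0.0, model.gradient_minutes))


def ground_truth_rt(
    peptide: Peptide | str,
    model: GroundTruthRTModel,
    rng: np.random.Generator,
) -> float:
    """One noisy RT draw for a peptide, clipped to [0, gradient]."""
    seq = peptide.sequence if isinstance(peptide, Peptide) else peptide
    rt = noiseless_rt(seq, model)
    if model.noise_sd > 0:
        rt += rng.normal(0.0, model.noise_sd)
    return float(np.clip(rt, 0.0, model.gradient_minutes))


def _sample_length(rng: np.random.Generator, lo: int, hi: int) -> int:
    if lo == hi:
        return lo
    while True:
        L = lo + rng.geometric(_LENGTH_GEOM_P) - 1
        if L <= hi:
            return int(L)


def generate_peptides(
    n: int,
    length_range: tuple[int, int] = (7, 25),
    seed: int | np.random.Generator = 0,
) -> list[Peptide]:
    """Random unique tryptic-like peptides.

    Sequences end in K or R and contain no internal K/R (fully cleaved),
    with lengths drawn from a short-skewed truncated-geometric distribution
    over ``length_range``. Reproducible from *seed*. Raises
    :class:`GenerationError` when the requested count cannot be realized as
    unique sequences (tiny length ranges).
    """
    lo, hi = length_range
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (1 <= lo <= hi):
        raise ValueError(f"invalid length_range {length_range}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    peptides: list[Peptide] = []
    seen: set[str] = set()
    attempts = 0
    max_attempts = 50 * n + 1000
    while len(peptides) < n:
        attempts += 1
        if attempts > max_attempts:
            raise GenerationError(
                f"could not generate {n} unique peptides in lengths "
                f"[{lo}, {hi}] after {attempts} attempts"
            )
        L = _sample_length(rng, lo, hi)
        if L == 1:
            seq = str(rng.choice(("K", "R")))
        else:
            body = "".join(rng.choice(_INTERNAL_RESIDUES, size=L - 1))
            seq = body + str(rng.choice(("K", "R")))
        if seq not in seen:
            seen.add(seq)
            peptides.append(Peptide(seq))
    return peptides


def generate_dataset(
    n: int,
    model: GroundTruthRTModel | None = None,
    seed: int = 0,
    *,
    length_range: tuple[int, int] = (7, 25),
    exclude: Sequence[str] = (),
) -> RTDataset:
    """Peptides + noisy ground-truth RTs + random rank scores.

    ``exclude`` lists sequences that must not appear (e.g. the training set
    when generating held-out data under the same seed stream). The fraction
    of RTs clipped at the gradient bounds is logged.
    """
    if model is None:
        model = GroundTruthRTModel.default()
    rng = np.random.default_rng(seed)
    excluded = set(exclude)
    peptides: list[Peptide] = []
    raw = generate_peptides(n + len(excluded), length_range, rng)
    kept = [p for p in raw if p.sequence not in excluded][:n]
    while len(kept) < n:
        extra = generate_peptides(n, length_range, rng)
        for p in extra:
            if p.sequence not in excluded and all(q.sequence != p.sequence for q in kept):
                kept.append(p)
                if len(kept) == n:
                    break
    n_clipped = 0
    for p in kept:
        rt_clean = noiseless_rt(p.sequence, model)
        rt = rt_clean + (rng.normal(0.0, model.noise_sd) if model.noise_sd > 0 else 0.0)
        clipped = float(np.clip(rt, 0.0, model.gradient_minutes))
        if clipped != rt:
            n_clipped += 1
        peptides.append(
            Peptide(p.sequence, observed_rt=clipped, rank_score=float(rng.random()))
        )
    if n_clipped:
        logger.info("clipped %d/%d RTs at gradient bounds", n_clipped, n)
    return RTDataset(tuple(peptides), gradient_minutes=model.gradient_minutes)


def transfer_dataset(
    dataset: RTDataset,
    slope: float,
    offset: float,
    *,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> RTDataset:
    """The same peptides observed under a rescaled gradient.

    New RTs are ``slope·RT + offset`` (plus optional Gaussian noise),
    clipped into the rescaled gradient ``slope·gradient + offset``. With
    zero noise the relation to the source RTs is exactly affine, which is
    the controlled setting for calibration-recovery experiments.
    """
    if slope <= 0:
        raise ValueError("slope must be positive")
    if dataset.gradient_minutes is None:
        raise ValueError("source dataset must carry gradient_minutes")
    new_gradient = slope * dataset.gradient_minutes + offset
    if new_gradient <= 0:
        raise ValueError("rescaled gradient must be positive")
    rng = np.random.default_rng(seed)
    peptides = []
    for p in dataset:
        rt = slope * p.observed_rt + offset
        if noise_sd > 0:
            rt += rng.normal(0.0, noise_sd)
        peptides.append(
            Peptide(
                p.sequence,
                observed_rt=float(np.clip(rt, 0.0, new_gradient)),
                rank_score=p.rank_score,
            )
        )
    return RTDataset(tuple(peptides), gradient_minutes=new_gradient)
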
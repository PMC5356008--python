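"""Peptide/RT tables, in-silico tryptic digestion, filtering and splitting.

The unit of data throughout the package is a :class:`Peptide` — a validated
sequence over the 20 standard amino acids, optionally carrying an observed
retention time (minutes) and a rank score used only when picking calibration
peptides. An :class:`RTDataset` is an ordered, duplicate-free collection of
peptides that all have observed RTs, tied to the gradient length of the run
they came from.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from pyteomics import parser as _pyt_parser

from .errors import (
    AlphabetError,
    EmptyInputError,
    FormatError,
    SplitError,
)

#: The 20 standard residues, alphabetical by one-letter code. This ordering
#: is the canonical residue-channel order used by the encoder and is
#: serialized with every trained model.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: Trypsin cleaves C-terminal to K or R unless the next residue is P.
TRYPSIN_RULE = r"[KR](?!P)"


def validate_sequence(sequence: str) -> str:
    """Return *sequence* if it is a nonempty string over the standard alphabet.

    Raises :class:`AlphabetError` otherwise.
    """
    if not isinstance(sequence, str) or len(sequence) == 0:
        raise AlphabetError("peptide sequence must be a nonempty string")
    bad = set(sequence) - _AA_SET
    if bad:
        raise AlphabetError(
            f"sequence {sequence!r} contains invalid residue(s) {sorted(bad)}"
        )
    return sequence


@dataclass(frozen=True)
class Peptide:
    """A validated amino-acid sequence with optional observed RT (minutes).

    Parameters
    ----------
    sequence:
        Uppercase string over ``ACDEFGHIKLMNPQRSTVWY``.
    observed_rt:
        Observed retention time in minutes, nonnegative, or ``None``.
    rank_score:
        Nonnegative score used to rank calibration-peptide candidates
        (higher = preferred), or ``None``.
    """

    sequence: str
    observed_rt: float | None = None
    rank_score: float | None = None

    def __post_init__(self) -> None:
        validate_sequence(self.sequence)
        if self.observed_rt is not None:
            rt = float(self.observed_rt)
            if not math.isfinite(rt) or rt < 0:
                raise ValueError(f"observed_rt must be finite and >= 0, got {rt}")
            object.__setattr__(self, "observed_rt", rt)
        if self.rank_score is not None:
            rs = float(self.rank_score)
            if not math.isfinite(rs) or rs < 0:
                raise ValueError(f"rank_score must be finite and >= 0, got {rs}")
            object.__setattr__(self, "rank_score", rs)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class RTDataset:
    """An ordered collection of peptides with observed RTs.

    Invariants: sequences are unique; when ``gradient_minutes`` is set, every
    observed RT lies within ``[0, gradient_minutes]``.
    """

    peptides: tuple[Peptide, ...] = field(default_factory=tuple)
    gradient_minutes: float | None = None

    def __post_init__(self) -> None:
        self.peptides = tuple(self.peptides)
        seen: set[str] = set()
        for p in self.peptides:
            if p.observed_rt is None:
                raise ValueError(f"peptide {p.sequence} has no observed RT")
            if p.sequence in seen:
                raise ValueError(f"duplicate sequence {p.sequence}")
            seen.add(p.sequence)
        if self.gradient_minutes is not None:
            g = float(self.gradient_minutes)
            if not (g > 0):
                raise ValueError("gradient_minutes must be positive")
            self.gradient_minutes = g
            for p in self.peptides:
                if p.observed_rt > g:
                    raise ValueError(
                        f"RT {p.observed_rt} of {p.sequence} exceeds gradient {g}"
                    )

    def __len__(self) -> int:
        return len(self.peptides)

    def __iter__(self):
        return iter(self.peptides)

    @property
    def sequences(self) -> list[str]:
        return [p.sequence for p in self.peptides]

    @property
    def rts(self) -> np.ndarray:
        return np.array([p.observed_rt for p in self.peptides], dtype=float)


class TableReadResult(NamedTuple):
    """Outcome of :func:`read_peptide_table`."""

    dataset: RTDataset
    n_rejected: int
    n_modified_dropped: int


# anything beyond plain uppercase letters marks a modification annotation,
# e.g. "M(ox)", "C[+57.02]", "m" (lowercase = modified in some exports)
_MOD_RE = re.compile(r"[^A-Z]|[a-z]")


def _looks_modified(seq: str) -> bool:
    return bool(_MOD_RE.search(seq))


def read_peptide_table(
    path: str | Path,
    *,
    sep: str | None = None,
    sequence_col: str = "sequence",
    rt_col: str = "rt",
    rank_col: str = "rank_score",
    gradient_minutes: float | None = None,
    drop_modified: bool = False,
    on_duplicate: str = "error",
) -> TableReadResult:
    """Read a delimited peptide/RT table.

    Parameters
    ----------
    path:
        TSV/CSV file with a header row.
    sep:
        Field delimiter; ``None`` sniffs it from the file.
    sequence_col, rt_col, rank_col:
        Column names. ``rank_col`` is optional in the file.
    gradient_minutes:
        Total gradient time of the run; RTs exceeding it are invalid.
    drop_modified:
        If true, rows whose sequence carries modification annotations
        (any non-uppercase-letter character) are silently dropped and
        counted separately; otherwise they count as rejected rows.
    on_duplicate:
        ``"error"`` rejects the whole file on a duplicate sequence;
        ``"first"`` keeps the first occurrence.

    Returns
    -------
    TableReadResult
        The validated dataset plus counts of rejected rows (invalid
        residues/RT) and of modification-annotated rows dropped.
    """
    path = Path(path)
    if not path.read_text().strip():
        raise EmptyInputError(f"{path} is empty")
    try:
        frame = pd.read_csv(path, sep=sep, engine="python")
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path} is empty") from None
    except Exception as exc:  # malformed delimited text
        raise FormatError(f"could not parse {path}: {exc}") from exc

    missing = {sequence_col, rt_col} - set(frame.columns)
    if missing:
        raise FormatError(f"{path} lacks required column(s) {sorted(missing)}")

    has_rank = rank_col in frame.columns
    peptides: list[Peptide] = []
    seen: set[str] = set()
    n_rejected = 0
    n_modified = 0
    for _, row in frame.iterrows():
        seq = str(row[sequence_col]).strip()
        if _looks_modified(seq):
            if drop_modified:
                n_modified += 1
            else:
                n_rejected += 1
            continue
        try:
            rt = float(row[rt_col])
            rank = float(row[rank_col]) if has_rank and pd.notna(row[rank_col]) else None
            pep = Peptide(seq, observed_rt=rt, rank_score=rank)
        except (ValueError, TypeError):
            n_rejected += 1
            continue
        if gradient_minutes is not None and rt > gradient_minutes:
            n_rejected += 1
            continue
        if seq in seen:
            if on_duplicate == "first":
                continue
            raise FormatError(f"duplicate sequence {seq} in {path}")
        seen.add(seq)
        peptides.append(pep)

    if not peptides:
        raise EmptyInputError(f"{path} contains no valid peptide rows")
    dataset = RTDataset(tuple(peptides), gradient_minutes=gradient_minutes)
    return TableReadResult(dataset, n_rejected, n_modified)


def write_peptide_table(
    path: str | Path,
    peptides: Iterable[Peptide],
    *,
    sep: str = "\t",
) -> None:
    """Write peptides as a delimited table (sequence, rt, rank_score)."""
    rows = [
        {"sequence": p.sequence, "rt": p.observed_rt, "rank_score": p.rank_score}
        for p in peptides
    ]
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def write_predictions(
    path: str | Path,
    sequences: Sequence[str],
    predicted_rt: Sequence[float],
    calibrated_rt: Sequence[float] | None = None,
    *,
    sep: str = "\t",
) -> None:
    """Write a prediction table (sequence, predicted_rt[, calibrated_rt])."""
    data = {"sequence": list(sequences), "predicted_rt": list(predicted_rt)}
    if calibrated_rt is not None:
        data["calibrated_rt"] = list(calibrated_rt)
    pd.DataFrame(data).to_csv(path, sep=sep, index=False)


def digest_sequence(sequence: str, missed_cleavages: int = 0) -> list[str]:
    """Tryptic fragments of one protein sequence, in N→C order of their start.

    Cleaves C-terminal to K/R except before P, producing every product with
    up to ``missed_cleavages`` internal missed sites. Duplicated fragments
    within the protein are kept once (first occurrence).
    """
    validate_sequence(sequence)
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    out: list[str] = []
    seen: set[str] = set()
    for _, frag in sorted(
        _pyt_parser.icleave(sequence, TRYPSIN_RULE, missed_cleavages=missed_cleavages)
    ):
        if frag and frag not in seen:
            seen.add(frag)
            out.append(frag)
    return out


def digest_fasta(
    path: str | Path,
    missed_cleavages: int = 0,
    *,
    min_length: int = 1,
    with_provenance: bool = False,
):
    """In-silico tryptic digestion of a multi-record FASTA file.

    Returns the unique peptides (no RTs) in first-seen order; with
    ``with_provenance=True`` also returns a mapping from peptide sequence to
    the description lines of the source records.

    Raises :class:`FormatError` when the file has no FASTA records and
    :class:`AlphabetError` when a protein contains a nonstandard residue.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path} contains no FASTA records")
    peptides: list[Peptide] = []
    provenance: dict[str, list[str]] = {}
    seen: set[str] = set()
    for rec in records:
        seq = str(rec.seq).upper()
        for frag in digest_sequence(seq, missed_cleavages):
            if len(frag) < min_length:
                continue
            provenance.setdefault(frag, []).append(rec.description)
            if frag not in seen:
                seen.add(frag)
                peptides.append(Peptide(frag))
    if with_provenance:
        return peptides, provenance
    return peptides


def length_filter(
    peptides: Sequence[Peptide], max_len: int = 25
) -> tuple[list[Peptide], list[Peptide]]:
    """Partition peptides into (kept, removed) by ``len <= max_len``.

    Order is preserved in both halves. The default of 25 residues matches
    the encoder's positional capacity: longer peptides are rarely observed
    in ESI-MS and are handled by terminal truncation at prediction time.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    kept = [p for p in peptides if len(p) <= max_len]
    removed = [p for p in peptides if len(p) > max_len]
    return kept, removed


def split_train_test(dataset: RTDataset, seed: int) -> tuple[RTDataset, RTDataset]:
    """Random equal split of a dataset into (train, test) halves.

    For n peptides, training receives ⌈n/2⌉ and test ⌊n/2⌋ — the odd
    peptide goes to training. The partition is a uniformly random disjoint
    split, reproducible from *seed*; each half preserves the input order.
    """
    n = len(dataset)
    if n < 2:
        raise SplitError(f"cannot split {n} peptide(s) into two groups")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = (n + 1) // 2
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])
    g = dataset.gradient_minutes
    train = RTDataset(tuple(dataset.peptides[i] for i in train_idx), gradient_minutes=g)
    test = RTDataset(tuple(dataset.peptides[i] for i in test_idx), gradient_minutes=g)
    return train, test
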
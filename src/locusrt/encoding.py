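"""Terminal-anchored binary locus vectors.

A peptide is represented on a fixed grid of 25 sequence positions, each
holding a 20-channel one-hot residue code, giving a 500-entry binary vector
(flattened position-major). Residues are anchored from both termini toward
the center: for a peptide of length L ≤ 25, the first ⌈L/2⌉ residues fill
grid positions 1..⌈L/2⌉ and the last ⌊L/2⌋ residues fill the last ⌊L/2⌋
grid positions, leaving the middle of the grid zero. A 7-mer therefore puts
its first 4 residues on positions 1–4 and its last 3 on positions 23–25.

Peptides longer than 25 residues are encoded from their first 13 and last
12 residues only; the overhanging middle residues do not enter the vector.

For peptides of length ≤ 25 the map is injective: the original sequence can
be read back from the vector, because the occupied positions always form a
prefix and a suffix of the grid with the prefix at least as long as the
suffix.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .errors import AlphabetError
from .peptides import AMINO_ACIDS, Peptide, validate_sequence

N_POSITIONS = 25
N_RESIDUES = 20
N_FEATURES = N_POSITIONS * N_RESIDUES  # 500

#: Residue → channel index (alphabetical one-letter order). Serialized with
#: every trained model as encoding provenance.
AA_TO_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: How the (position, residue) grid is flattened into the 500-vector.
FLATTENING = "position-major"

_N_FRONT_LONG = 13  # leading residues kept for peptides longer than 25
_N_BACK_LONG = 12  # trailing residues kept for peptides longer than 25


def occupied_positions(length: int) -> tuple[list[int], list[int]]:
    """Grid positions (0-based) and residue indices encoded for *length*.

    Returns ``(grid_positions, residue_indices)`` of equal length
    ``min(length, 25)``: residue ``residue_indices[k]`` of the peptide sits
    at grid position ``grid_positions[k]``.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if length <= N_POSITIONS:
        n_front = (length + 1) // 2
        n_back = length - n_front
        grid = list(range(n_front)) + list(range(N_POSITIONS - n_back, N_POSITIONS))
        residues = list(range(length))
    else:
        grid = list(range(N_POSITIONS))
        residues = list(range(_N_FRONT_LONG)) + list(
            range(length - _N_BACK_LONG, length)
        )
    return grid, residues


def encode_peptide(peptide: Peptide | str) -> np.ndarray:
    """Encode one peptide as a 500-entry binary locus vector (float64)."""
    seq = peptide.sequence if isinstance(peptide, Peptide) else validate_sequence(peptide)
    vec = np.zeros(N_FEATURES, dtype=np.float64)
    grid, residues = occupied_positions(len(seq))
    for pos, ridx in zip(grid, residues):
        vec[pos * N_RESIDUES + AA_TO_INDEX[seq[ridx]]] = 1.0
    return vec


def encode_batch(peptides: Iterable[Peptide | str]) -> np.ndarray:
    """Encode peptides into an (n, 500) matrix; row order follows input.

    An invalid residue raises :class:`AlphabetError` naming the row.
    """
    rows = []
    for i, p in enumerate(peptides):
        try:
            rows.append(encode_peptide(p))
        except AlphabetError as exc:
            raise AlphabetError(f"row {i}: {exc}") from exc
    if not rows:
        return np.zeros((0, N_FEATURES), dtype=np.float64)
    return np.vstack(rows)


def decode_vector(vector: Sequence[float]) -> str:
    """Invert :func:`encode_peptide` for peptides of length ≤ 25.

    Raises ``ValueError`` when the vector is not the image of any such
    peptide. (Peptides longer than 25 residues are not invertible: their
    middle residues never enter the vector.)
    """
    vec = np.asarray(vector, dtype=float)
    if vec.shape != (N_FEATURES,):
        raise ValueError(f"expected shape ({N_FEATURES},), got {vec.shape}")
    grid = vec.reshape(N_POSITIONS, N_RESIDUES)
    if not np.isin(grid, (0.0, 1.0)).all():
        raise ValueError("vector entries must be 0 or 1")
    per_pos = grid.sum(axis=1)
    if per_pos.max(initial=0) > 1:
        raise ValueError("a grid position holds more than one residue")
    occupied = np.flatnonzero(per_pos)
    length = len(occupied)
    if length == 0:
        raise ValueError("empty vector decodes to no peptide")
    expected_grid, _ = occupied_positions(length)
    if list(occupied) != expected_grid:
        raise ValueError("occupied positions do not match any terminal anchoring")
    residues = np.argmax(grid[occupied], axis=1)
    return "".join(AMINO_ACIDS[r] for r in residues)


def feature_names() -> list[str]:
    """Human-readable names for the 500 columns, e.g. ``pos03_F``."""
    return [
        f"pos{pos + 1:02d}_{aa}"
        for pos in range(N_POSITIONS)
        for aa in AMINO_ACIDS
    ]


def write_feature_matrix(
    path,
    peptides: Sequence[Peptide | str],
    *,
    sparse: bool = False,
) -> None:
    """Export encoded peptides for inspection.

    Dense form: TSV with a ``sequence`` column plus the 500 named columns.
    Sparse form: coordinate triplets ``row<TAB>column<TAB>1`` preceded by a
    header line, one line per set entry.
    """
    mat = encode_batch(peptides)
    seqs = [p.sequence if isinstance(p, Peptide) else p for p in peptides]
    with open(path, "w") as fh:
        if sparse:
            fh.write("row\tcolumn\tvalue\n")
            for r, c in zip(*np.nonzero(mat)):
                fh.write(f"{r}\t{c}\t1\n")
        else:
            fh.write("sequence\t" + "\t".join(feature_names()) + "\n")
            for seq, row in zip(seqs, mat):
                fh.write(seq + "\t" + "\t".join(str(int(v)) for v in row) + "\n")
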
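"""Reading and writing PSI-BLAST PSSM profiles, FASTA input, and
synthetic profile generation.

A PSSM (position-specific scoring matrix) is the L x 20 matrix of
per-position substitution log-odds scores that PSI-BLAST emits with
``-out_ascii_pssm``.  Scores are typically small integers (roughly
-10..13).  All profiles are normalised internally to the canonical
column order ``ARNDCQEGHILKMFPSTWYV`` regardless of the order the file
declares, so downstream encoders never see a permuted axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

#: Canonical amino-acid column ordering used throughout the package.
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

_AA_SET = set(AA_ORDER)


@dataclass
class PssmProfile:
    """An evolutionary profile: one protein's L x 20 substitution scores.

    Parameters
    ----------
    protein_id : str
        Identifier carried through feature tables and reports.
    sequence : str
        One-letter residue string of length L.
    scores : numpy.ndarray
        Float array of shape (L, 20); row i holds the log-odds score of
        each of the 20 amino-acid types at sequence position i.
    column_order : str
        The amino-acid ordering of the score columns.  Always
        :data:`AA_ORDER` after construction; a different permutation is
        re-mapped on the fly.
    """

    protein_id: str
    sequence: str
    scores: np.ndarray
    column_order: str = AA_ORDER

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError(
                f"{self.protein_id}: scores must be L x 20, got {self.scores.shape}"
            )
        if len(self.sequence) != self.scores.shape[0]:
            raise ValueError(
                f"{self.protein_id}: sequence length {len(self.sequence)} "
                f"!= score rows {self.scores.shape[0]}"
            )
        if self.scores.shape[0] < 1:
            raise ValueError(f"{self.protein_id}: empty profile")
        if sorted(self.column_order) != sorted(AA_ORDER):
            raise ValueError(
                f"column_order must be a permutation of {AA_ORDER!r}, "
                f"got {self.column_order!r}"
            )
        if self.column_order != AA_ORDER:
            perm = [self.column_order.index(a) for a in AA_ORDER]
            self.scores = self.scores[:, perm]
            self.column_order = AA_ORDER

    @property
    def length(self) -> int:
        return self.scores.shape[0]


@dataclass
class SyntheticConfig:
    """Parameters for the synthetic profile generator.

    The generator emulates the statistical shape of PSI-BLAST profiles
    for a binary classification benchmark: integer scores drawn
    uniformly from ``[score_low, score_high]`` over variable lengths,
    with ``class_shift`` added to a fixed subset of score columns for
    positive-class (DNA-binding) proteins so that classifiers can
    exceed chance by a controllable margin.
    """

    n_samples_per_class: int = 200
    length_range: tuple[int, int] = (50, 150)
    score_low: int = -10
    score_high: int = 13
    class_shift: float = 5.0
    seed: int = 0
    shift_columns: tuple[int, ...] = (0, 1, 2, 3, 4)

    def __post_init__(self) -> None:
        if self.n_samples_per_class < 1:
            raise ValueError("n_samples_per_class must be positive")
        lo, hi = self.length_range
        if lo < 2 or hi < lo:
            raise ValueError("length_range must satisfy 2 <= L_min <= L_max")
        if self.score_low >= self.score_high:
            raise ValueError("score_low must be < score_high")
        if not all(0 <= c < 20 for c in self.shift_columns):
            raise ValueError("shift_columns must be indices in 0..19")


def read_pssm(path: str | Path) -> PssmProfile:
    """Read a PSI-BLAST ASCII PSSM file (``-out_ascii_pssm`` dialect).

    The format is: free header lines, a column-letter header, then one
    line per residue carrying a position index, the residue letter, 20
    log-odds scores, 20 weighted percentages and two trailing
    statistics.  Only the first 20 numeric columns are consumed;
    footer lines after the matrix are ignored.

    Raises
    ------
    ValueError
        If a residue row does not contain 20 parseable scores (the
        message cites the offending line number), or if no residue
        rows are found.
    """
    path = Path(path)
    column_order = AA_ORDER
    sequence: list[str] = []
    rows: list[list[float]] = []
    in_matrix = False
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            tokens = raw.split()
            if not in_matrix:
                # The column header line lists >= 20 single amino-acid letters.
                if len(tokens) >= 20 and all(
                    len(t) == 1 and t in _AA_SET for t in tokens[:20]
                ):
                    column_order = "".join(tokens[:20])
                    in_matrix = True
                continue
            if not tokens:
                break  # blank line ends the matrix
            if not tokens[0].lstrip("-").isdigit():
                break  # footer (Lambda/K statistics)
            if len(tokens) < 2 or len(tokens[1]) != 1 or not tokens[1].isalpha():
                raise ValueError(f"{path}: line {lineno}: expected residue letter")
            try:
                scores = [float(t) for t in tokens[2:22]]
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: unparseable score ({exc})"
                ) from None
            if len(scores) != 20:
                raise ValueError(
                    f"{path}: line {lineno}: expected 20 scores, got {len(scores)}"
                )
            sequence.append(tokens[1].upper())
            rows.append(scores)
    if not rows:
        raise ValueError(f"{path}: no PSSM rows found (empty or not a PSSM file)")
    return PssmProfile(
        protein_id=path.stem,
        sequence="".join(sequence),
        scores=np.array(rows, dtype=float),
        column_order=column_order,
    )


def write_pssm(profile: PssmProfile, path: str | Path) -> None:
    """Write a profile in the PSI-BLAST ASCII dialect that
    :func:`read_pssm` accepts (round-trip safe for integral scores)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\n")
        fh.write("Last position-specific scoring matrix computed\n")
        header = " ".join(f"{a:>3}" for a in profile.column_order)
        fh.write(f"          {header}\n")
        for i, (residue, row) in enumerate(zip(profile.sequence, profile.scores), 1):
            cells = " ".join(
                f"{int(v):>3d}" if float(v).is_integer() else f"{v:>7.3f}" for v in row
            )
            fh.write(f"{i:>5} {residue} {cells}\n")
        fh.write("\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as ``(id, uppercase sequence)`` in file order."""
    records = [
        (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        warnings.warn(f"{path}: no FASTA records found", stacklevel=2)
    return records


def generate_synthetic_dataset(
    cfg: SyntheticConfig,
) -> tuple[list[PssmProfile], np.ndarray]:
    """Generate ``2 * n_samples_per_class`` labelled synthetic profiles.

    Negative-class profiles (label 0) have integer scores uniform in
    ``[score_low, score_high]``; positive-class profiles (label 1)
    additionally receive ``cfg.class_shift`` on ``cfg.shift_columns``.
    Fully reproducible under a fixed ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.length_range
    profiles: list[PssmProfile] = []
    labels: list[int] = []
    for label in (0, 1):
        for i in range(cfg.n_samples_per_class):
            length = int(rng.integers(lo, hi + 1))
            scores = rng.integers(
                cfg.score_low, cfg.score_high + 1, size=(length, 20)
            ).astype(float)
            if label == 1 and cfg.class_shift != 0:
                scores[:, list(cfg.shift_columns)] += cfg.class_shift
            seq = "".join(rng.choice(list(AA_ORDER), size=length))
            profiles.append(
                PssmProfile(
                    protein_id=f"{'pos' if label else 'neg'}_{i:04d}",
                    sequence=seq,
                    scores=scores,
                )
            )
            labels.append(label)
    return profiles, np.array(labels, dtype=int)
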
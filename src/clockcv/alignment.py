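"""Nucleotide alignments with site-pattern compression and tip dates.

Sequences are stored as small-integer codes (A,C,G,T -> 0..3; gaps and
any IUPAC ambiguity -> 4, treated as fully missing).  Site patterns are
compressed once on construction; the likelihood engine works on the
compressed patterns, which is exact for i.i.d.-site models.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from Bio import AlignIO

__all__ = [
    "Alignment",
    "SiteSplit",
    "DateSpec",
    "AlignmentError",
    "DateParseError",
    "read_alignment",
    "write_fasta",
]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
MISSING = 4
_LETTER = np.array(list("ACGT-"))


class AlignmentError(ValueError):
    pass


class DateParseError(ValueError):
    pass


@dataclass(frozen=True)
class DateSpec:
    """Rule for extracting a decimal-year date from a taxon label.

    The label is split on ``delimiter`` and ``field`` selects the piece
    (negative indices count from the end; default: last ``|``-delimited
    field).
    """

    delimiter: str = "|"
    field: int = -1

    def parse(self, label: str) -> float:
        parts = label.split(self.delimiter)
        try:
            return float(parts[self.field])
        except (IndexError, ValueError):
            raise DateParseError(
                f"cannot parse a decimal-year date from taxon {label!r} "
                f"(delimiter {self.delimiter!r}, field {self.field})"
            ) from None


def encode(seq: str) -> np.ndarray:
    out = np.empty(len(seq), dtype=np.int8)
    for i, ch in enumerate(seq.upper()):
        out[i] = _CODE.get(ch, MISSING)
    return out


class Alignment:
    """Taxa x sites nucleotide matrix with compressed site patterns."""

    def __init__(
        self,
        taxa: Sequence[str],
        codes: np.ndarray,
        tip_dates: Optional[Sequence[float]] = None,
    ):
        self.taxa = [str(t) for t in taxa]
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentError("taxon names must be unique")
        self.codes = np.asarray(codes, dtype=np.int8)
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.taxa):
            raise AlignmentError("codes must be a (taxa, sites) matrix")
        self.tip_dates = None
        if tip_dates is not None:
            self.tip_dates = np.asarray(tip_dates, dtype=float)
            if self.tip_dates.shape != (len(self.taxa),):
                raise AlignmentError("tip_dates length must match taxa")
        self.patterns, self.pattern_weights = self._compress(self.codes)

    @staticmethod
    def _compress(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        patterns, counts = np.unique(codes, axis=1, return_counts=True)
        return patterns, counts.astype(np.int64)

    @classmethod
    def from_sequences(
        cls,
        taxa: Sequence[str],
        sequences: Sequence[str],
        tip_dates: Optional[Sequence[float]] = None,
    ) -> "Alignment":
        lengths = {len(s) for s in sequences}
        if len(lengths) > 1:
            raise AlignmentError(
                f"sequences have unequal lengths: {sorted(lengths)}"
            )
        codes = np.vstack([encode(s) for s in sequences])
        return cls(taxa, codes, tip_dates)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[1]

    def sequence(self, i: int) -> str:
        return "".join(_LETTER[np.minimum(self.codes[i], 4)])

    def take_sites(self, indices: np.ndarray) -> "Alignment":
        """Sub-alignment of the given 0-based site positions."""
        idx = np.asarray(indices, dtype=np.int64)
        if idx.size == 0:
            raise AlignmentError("cannot build an empty alignment")
        return Alignment(self.taxa, self.codes[:, idx], self.tip_dates)


@dataclass(frozen=True)
class SiteSplit:
    """Disjoint, exhaustive train/test partition of site positions."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    train_fraction: float

    def __post_init__(self):
        tr = set(self.train_indices.tolist())
        te = set(self.test_indices.tolist())
        if tr & te:
            raise AlignmentError("train and test sites overlap")
        n = len(tr) + len(te)
        if tr | te != set(range(n)):
            raise AlignmentError("train and test sites must cover all positions")
        expected = round(self.train_fraction * n)
        if len(tr) != expected:
            raise AlignmentError(
                f"training set has {len(tr)} sites, expected {expected}"
            )


def _guess_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext in (".nex", ".nexus", ".nxs"):
        return "nexus"
    return "fasta"


def read_alignment(
    path: str,
    date_spec: Optional[DateSpec] = DateSpec(),
    fmt: Optional[str] = None,
    require_dates: bool = False,
) -> Alignment:
    """Read a FASTA or NEXUS alignment; attach decimal-year tip dates.

    Dates are extracted from taxon labels by ``date_spec``; pass
    ``date_spec=None`` to skip.  With ``require_dates=True`` an
    unparseable label raises :class:`DateParseError` naming the taxon;
    otherwise dates are attached only if every label parses.
    """
    fmt = fmt or _guess_format(path)
    try:
        msa = AlignIO.read(path, fmt)
    except ValueError as exc:
        raise AlignmentError(f"cannot read {path} as {fmt}: {exc}") from exc
    taxa = [rec.id for rec in msa]
    seqs = [str(rec.seq) for rec in msa]
    dates = None
    if date_spec is not None:
        try:
            dates = [date_spec.parse(t) for t in taxa]
        except DateParseError:
            if require_dates:
                raise
            dates = None
    return Alignment.from_sequences(taxa, seqs, tip_dates=dates)


def write_fasta(alignment: Alignment, path: str) -> None:
    with open(path, "w") as fh:
        for i, name in enumerate(alignment.taxa):
            fh.write(f">{name}\n{alignment.sequence(i)}\n")
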
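"""Domain types and I/O for isomiR expression panels.

An isomiR is a length/sequence variant of a mature miRNA produced by
imprecise Drosha/Dicer cleavage or post-transcriptional nucleotide
addition.  Names follow the ``<mirna> |<end><change>-<k>`` convention:
``hsa-miR-21-5p |3′t-2`` is the variant of hsa-miR-21-5p with two
nucleotides trimmed from the 3′ end.  This module parses and formats
those names, holds the feature-by-sample expression matrix and the
per-sample subtype labels, and reads/writes the TSV interchange formats
used by every pipeline stage.
"""

from __future__ import annotations

import enum
import os
import re
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "End",
    "Change",
    "Unit",
    "IsomiRID",
    "ExpressionMatrix",
    "LabelVector",
    "IsomiRParseError",
    "parse_isomir_name",
    "compute_rpm",
    "read_matrix",
    "write_matrix",
    "read_labels",
    "write_labels",
]

# full round-trip precision for float64
_FLOAT_FMT = "%.17g"


class End(enum.Enum):
    """Which end of the mature miRNA the variant modifies."""

    THREE_PRIME = "3′"
    FIVE_PRIME = "5′"


class Change(enum.Enum):
    """Whether nucleotides are trimmed from or added to that end."""

    TRIM = "t"
    ADDITION = "a"


class Unit(enum.Enum):
    COUNTS = "counts"
    RPM = "rpm"


class IsomiRParseError(ValueError):
    """Raised when an isomiR name does not follow the nomenclature."""


# "<mirna> | <3|5><′ or '><t|a>-<int>"; whitespace around "|" optional,
# unicode prime and ASCII apostrophe both accepted.
_NAME_RE = re.compile(
    r"^\s*(?P<mirna>[^|]*?)\s*\|\s*(?P<end>[35])[′'](?P<change>[ta])-(?P<n>-?\d+)\s*$"
)


@dataclass(frozen=True)
class IsomiRID:
    """A parsed isomiR name.

    ``n_nt`` counts the nucleotides trimmed (``change=TRIM``) or added
    (``change=ADDITION``) at the 3′ or 5′ end of the parent miRNA.
    """

    mirna: str
    end: End
    change: Change
    n_nt: int
    raw: str = ""

    def __post_init__(self) -> None:
        if self.n_nt < 1:
            raise IsomiRParseError(
                f"nucleotide count must be >= 1, got {self.n_nt!r}"
            )
        if not self.mirna:
            raise IsomiRParseError("empty miRNA name")

    def canonical(self) -> str:
        """Canonical form: unicode prime, single space before the separator."""
        return f"{self.mirna} |{self.end.value}{self.change.value}-{self.n_nt}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical()


def parse_isomir_name(name: str) -> IsomiRID:
    """Parse an isomiR name like ``hsa-miR-21-5p | 3′t-2``.

    The ``|`` separates the parent miRNA name from the variant symbol.
    The variant symbol is ``<end><change>-<count>`` where end is 3′ or 5′
    (ASCII apostrophe accepted), change is ``t`` (trim) or ``a``
    (addition), and count is a positive integer.  Case of the miRNA name
    is preserved.

    Raises
    ------
    IsomiRParseError
        If the separator is missing, the variant symbol is malformed, or
        the nucleotide count is not a positive integer.  The message
        names the offending token.
    """
    if "|" not in name:
        raise IsomiRParseError(f"missing '|' separator in {name!r}")
    m = _NAME_RE.match(name)
    if m is None:
        variant = name.split("|", 1)[1].strip()
        raise IsomiRParseError(f"malformed variant symbol {variant!r} in {name!r}")
    n_nt = int(m.group("n"))
    if n_nt < 1:
        raise IsomiRParseError(f"non-positive nucleotide count {n_nt} in {name!r}")
    return IsomiRID(
        mirna=m.group("mirna"),
        end=End.THREE_PRIME if m.group("end") == "3" else End.FIVE_PRIME,
        change=Change.TRIM if m.group("change") == "t" else Change.ADDITION,
        n_nt=n_nt,
        raw=name,
    )


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen[i] = 1
    if dups:
        raise ValueError(f"duplicate {what}: {sorted(set(dups))}")


@dataclass
class ExpressionMatrix:
    """Features x samples matrix of non-negative expression values.

    ``values[i, j]`` is the expression of feature ``feature_ids[i]`` in
    sample ``sample_ids[j]``, either raw read counts or RPM.
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    unit: Unit = Unit.COUNTS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = list(self.feature_ids)
        self.sample_ids = list(self.sample_ids)
        if self.values.ndim != 2:
            raise ValueError("expression values must be 2-D (features x samples)")
        m, n = self.values.shape
        if m != len(self.feature_ids) or n != len(self.sample_ids):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.feature_ids)} feature ids / {len(self.sample_ids)} sample ids"
            )
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")
        if (self.values < 0).any():
            raise ValueError("expression values must be non-negative")
        _check_unique(self.feature_ids, "feature ids")
        _check_unique(self.sample_ids, "sample ids")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_features(self, ids: Iterable[str]) -> "ExpressionMatrix":
        """Row subset preserving this matrix's row order."""
        wanted = set(ids)
        idx = [i for i, f in enumerate(self.feature_ids) if f in wanted]
        missing = wanted - {self.feature_ids[i] for i in idx}
        if missing:
            raise KeyError(f"features not in matrix: {sorted(missing)}")
        return ExpressionMatrix(
            self.values[idx], [self.feature_ids[i] for i in idx],
            list(self.sample_ids), self.unit,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.sample_ids
        )


@dataclass
class LabelVector:
    """Per-sample discrete subtype labels with the 0/1 label metric."""

    labels: np.ndarray
    sample_ids: list[str] | None = None
    classes: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.ndim != 1:
            raise ValueError("labels must be 1-D")
        if self.sample_ids is not None:
            self.sample_ids = list(self.sample_ids)
            if len(self.sample_ids) != len(self.labels):
                raise ValueError("sample_ids length does not match labels")
        self.classes = sorted({str(y) for y in self.labels})

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def distance_matrix(self) -> np.ndarray:
        """d(y_i, y_j): 0 if labels equal, 1 otherwise (symmetric, 0 diagonal)."""
        y = self.labels
        return (y[:, None] != y[None, :]).astype(float)

    def codes(self) -> np.ndarray:
        """Integer codes in the (sorted) class order."""
        lookup = {c: k for k, c in enumerate(self.classes)}
        return np.array([lookup[str(y)] for y in self.labels], dtype=int)

    def class_counts(self) -> dict[str, int]:
        vals, counts = np.unique(self.labels.astype(str), return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def reorder(self, sample_ids: Sequence[str]) -> "LabelVector":
        """Labels in the order of ``sample_ids``; errors on missing samples."""
        if self.sample_ids is None:
            raise ValueError("label vector carries no sample ids to reorder by")
        lookup = dict(zip(self.sample_ids, self.labels))
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise ValueError(f"samples missing labels: {missing}")
        return LabelVector(
            np.array([lookup[s] for s in sample_ids], dtype=object),
            list(sample_ids),
        )


def compute_rpm(
    counts: ExpressionMatrix, library_sizes: Sequence[float] | None = None
) -> ExpressionMatrix:
    """Reads-per-million normalisation: count / library size x 1e6.

    ``library_sizes`` defaults to the per-sample column sums of the count
    matrix, in which case every RPM column sums to 1e6.
    """
    if library_sizes is None:
        library_sizes = counts.values.sum(axis=0)
    lib = np.asarray(library_sizes, dtype=float)
    if lib.shape != (counts.n_samples,):
        raise ValueError(
            f"need one library size per sample ({counts.n_samples}), got {lib.shape}"
        )
    if (lib <= 0).any():
        bad = [counts.sample_ids[i] for i in np.flatnonzero(lib <= 0)]
        raise ValueError(f"non-positive library size for samples: {bad}")
    return ExpressionMatrix(
        counts.values / lib[None, :] * 1e6,
        list(counts.feature_ids),
        list(counts.sample_ids),
        Unit.RPM,
    )


def atomic_write_text(path: str | os.PathLike, text: str) -> None:
    """Write via a temp file in the same directory, then rename."""
    path = os.fspath(path)
    d = os.path.dirname(path) or "."
    fd, tmp = tempfile.mkstemp(dir=d, prefix=".tmp-", suffix=".part")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_matrix(matrix: ExpressionMatrix, path: str | os.PathLike) -> None:
    """Write the expression TSV: header ``isomir_id\\t<sample>...``.

    Floats are written with 17 significant digits so that a read/write
    round trip reproduces the values exactly.
    """
    lines = ["\t".join(["isomir_id", *matrix.sample_ids])]
    for fid, row in zip(matrix.feature_ids, matrix.values):
        lines.append("\t".join([fid, *(_FLOAT_FMT % v for v in row)]))
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_matrix(path: str | os.PathLike, unit: Unit = Unit.COUNTS) -> ExpressionMatrix:
    """Read an expression TSV (first column = feature id, rest numeric)."""
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str,
                     comment="#", encoding="utf-8")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature rows in {path}: {dups}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    if np.isnan(values).any():
        bad_rows = [df.index[i] for i in np.unique(np.where(np.isnan(values))[0])]
        raise ValueError(f"ragged/missing cells in {path} for features: {bad_rows}")
    return ExpressionMatrix(values, df.index.tolist(), df.columns.tolist(), unit)


def write_labels(labels: LabelVector, path: str | os.PathLike) -> None:
    if labels.sample_ids is None:
        raise ValueError("label vector has no sample ids to write")
    lines = ["sample_id\tsubtype"]
    lines += [f"{s}\t{y}" for s, y in zip(labels.sample_ids, labels.labels)]
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_labels(
    path: str | os.PathLike, sample_ids: Sequence[str] | None = None
) -> LabelVector:
    """Read a labels TSV (``sample_id\\tsubtype``).

    If ``sample_ids`` is given (e.g. the matrix column order), the result
    is reordered to match and every listed sample must be present.
    """
    df = pd.read_csv(path, sep="\t", header=0, dtype=str, comment="#",
                     encoding="utf-8")
    if df.shape[1] < 2:
        raise ValueError(f"labels file {path} needs columns sample_id and subtype")
    sids = df.iloc[:, 0].tolist()
    _check_unique(sids, "sample ids in labels file")
    lv = LabelVector(df.iloc[:, 1].to_numpy(dtype=object), sids)
    if sample_ids is not None:
        lv = lv.reorder(sample_ids)
    return lv
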
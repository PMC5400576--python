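"""Association lists, adjacency matrices, and ranked-candidate files.

The external data format is a plain two-column text file, one known
miRNA-disease association per line (miRNA name, disease name), the layout
in which curated association databases such as HMDD are commonly exported.
Internally the known associations become a dense binary adjacency matrix
``M`` (miRNAs on rows, diseases on columns) together with the observed
index set omega, which is what the completion solver consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AssociationTable",
    "AssociationMatrix",
    "RankedCandidate",
    "ParseError",
    "read_association_list",
    "build_adjacency",
    "write_rankings",
    "read_rankings",
]


class ParseError(ValueError):
    """Raised for a malformed line in an association list; carries the line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        super().__init__(message)


@dataclass(frozen=True)
class AssociationTable:
    """De-duplicated ordered list of (miRNA name, disease name) pairs."""

    records: tuple[tuple[str, str], ...]

    def __post_init__(self):
        seen = set()
        for m, d in self.records:
            if not m or not d:
                raise ValueError("association names must be non-empty after trimming")
            if m != m.strip() or d != d.strip():
                raise ValueError("association names must be whitespace-trimmed")
            if (m, d) in seen:
                raise ValueError(f"duplicate association record {(m, d)!r}")
            seen.add((m, d))

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "AssociationTable":
        """Trim and de-duplicate, preserving first-occurrence order."""
        seen: set[tuple[str, str]] = set()
        records = []
        for m, d in pairs:
            key = (m.strip(), d.strip())
            if key in seen:
                continue
            seen.add(key)
            records.append(key)
        return cls(tuple(records))

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class AssociationMatrix:
    """Binary adjacency matrix M with its observed index set and name maps.

    ``M[i, j] == 1`` iff miRNA ``mirna_names[i]`` has a known association
    with disease ``disease_names[j]``; omega is exactly the set of those
    (i, j) index pairs.
    """

    M: np.ndarray
    omega: frozenset[tuple[int, int]]
    mirna_names: tuple[str, ...]
    disease_names: tuple[str, ...]
    _mirna_index: dict = field(init=False, repr=False, compare=False)
    _disease_index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        M = np.asarray(self.M, dtype=float)
        if M.ndim != 2:
            raise ValueError("M must be a 2-d matrix")
        if M.shape != (len(self.mirna_names), len(self.disease_names)):
            raise ValueError("M shape must match the name lists")
        expected = np.zeros_like(M)
        for i, j in self.omega:
            expected[i, j] = 1.0
        if not np.array_equal(M, expected):
            raise ValueError("M must be 1 exactly on omega and 0 elsewhere")
        if len(set(self.mirna_names)) != len(self.mirna_names):
            raise ValueError("duplicate miRNA names")
        if len(set(self.disease_names)) != len(self.disease_names):
            raise ValueError("duplicate disease names")
        object.__setattr__(self, "M", M)
        object.__setattr__(
            self, "_mirna_index", {n: i for i, n in enumerate(self.mirna_names)}
        )
        object.__setattr__(
            self, "_disease_index", {n: j for j, n in enumerate(self.disease_names)}
        )

    @property
    def nm(self) -> int:
        return self.M.shape[0]

    @property
    def nd(self) -> int:
        return self.M.shape[1]

    @property
    def omega_mask(self) -> np.ndarray:
        """Boolean mask of observed entries, same shape as M."""
        return self.M == 1.0

    def mirna_index(self, name: str) -> int:
        return self._mirna_index[name]

    def disease_index(self, name: str) -> int:
        return self._disease_index[name]

    def without(self, pairs: Iterable[tuple[int, int]]) -> "AssociationMatrix":
        """A copy with the given observed entries removed (set to 0, dropped from omega)."""
        pairs = frozenset(pairs)
        extra = pairs - self.omega
        if extra:
            raise ValueError(f"pairs not in omega: {sorted(extra)[:5]}")
        M = self.M.copy()
        for i, j in pairs:
            M[i, j] = 0.0
        return AssociationMatrix(
            M, self.omega - pairs, self.mirna_names, self.disease_names
        )


@dataclass(frozen=True)
class RankedCandidate:
    rank: int
    mirna: str
    disease: str
    score: float


def read_association_list(path, delimiter: str = "\t") -> AssociationTable:
    """Read a two-column association list.

    Blank lines and lines starting with ``#`` are ignored. Each remaining
    line must have at least two delimited fields (extra fields are ignored);
    fields are whitespace-trimmed and duplicate pairs collapse to their
    first occurrence.
    """
    path = Path(path)
    pairs = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = [f.strip() for f in stripped.split(delimiter)]
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise ParseError(
                    f"{path}:{lineno}: expected two non-empty "
                    f"{delimiter!r}-delimited fields, got {stripped!r}",
                    line_number=lineno,
                )
            pairs.append((fields[0], fields[1]))
    return AssociationTable.from_pairs(pairs)


def build_adjacency(table: AssociationTable) -> AssociationMatrix:
    """Build the binary adjacency matrix from an association table.

    Row order is the first-occurrence order of miRNA names in the table,
    column order likewise for diseases. An empty table yields a 0x0 matrix
    with a warning, since it cannot be completed downstream.
    """
    if len(table) == 0:
        warnings.warn("empty association table: 0x0 adjacency matrix", stacklevel=2)
    mirnas: list[str] = []
    diseases: list[str] = []
    mi: dict[str, int] = {}
    di: dict[str, int] = {}
    omega = set()
    for m, d in table.records:
        if m not in mi:
            mi[m] = len(mirnas)
            mirnas.append(m)
        if d not in di:
            di[d] = len(diseases)
            diseases.append(d)
        omega.add((mi[m], di[d]))
    M = np.zeros((len(mirnas), len(diseases)))
    for i, j in omega:
        M[i, j] = 1.0
    return AssociationMatrix(M, frozenset(omega), tuple(mirnas), tuple(diseases))


_RANKING_HEADER = ("rank", "miRNA", "disease", "score")


def write_rankings(rankings: Sequence[RankedCandidate], path) -> None:
    """Write ranked candidates as TSV with a header and fixed-precision scores."""
    if not rankings:
        raise ValueError("rankings must be non-empty")
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(_RANKING_HEADER) + "\n")
        for r in rankings:
            fh.write(f"{r.rank}\t{r.mirna}\t{r.disease}\t{r.score:.6f}\n")


def read_rankings(path) -> list[RankedCandidate]:
    """Read a ranked-candidate TSV written by :func:`write_rankings`."""
    path = Path(path)
    out = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _RANKING_HEADER:
            raise ParseError(f"{path}:1: unexpected header {header!r}", line_number=1)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 4:
                raise ParseError(
                    f"{path}:{lineno}: expected 4 fields", line_number=lineno
                )
            out.append(
                RankedCandidate(int(fields[0]), fields[1], fields[2], float(fields[3]))
            )
    return out
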
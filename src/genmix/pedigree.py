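"""Pedigrees and the additive (numerator) relationship matrix.

The polygenic covariance structure of the mixed model is ``A * sigma_a^2``
where ``A`` is the numerator relationship matrix over all pedigree members.
``A`` is computed by the tabular (recursive) method, which yields exact
inbreeding coefficients on the diagonal (``A_ii = 1 + F_i``).

Ids are opaque strings; a parent coded with the unknown sentinel is treated
as a unique, unrelated founder and contributes nothing to the recursion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import PedigreeError

__all__ = [
    "PedigreeRecord",
    "Pedigree",
    "RelationshipMatrix",
    "read_pedigree",
    "compute_A",
    "inbreeding",
]


@dataclass(frozen=True)
class PedigreeRecord:
    """One individual with its (possibly unknown) sire and dam.

    Unknown parents are represented as ``None``.
    """

    individual_id: str
    sire_id: Optional[str]
    dam_id: Optional[str]


@dataclass
class Pedigree:
    """Topologically ordered pedigree: every parent precedes its offspring."""

    records: list[PedigreeRecord]
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.index = {}
        for i, rec in enumerate(self.records):
            if rec.individual_id in self.index:
                raise PedigreeError(f"duplicate individual id: {rec.individual_id!r}")
            self.index[rec.individual_id] = i
        for i, rec in enumerate(self.records):
            for par in (rec.sire_id, rec.dam_id):
                if par is not None:
                    j = self.index.get(par)
                    if j is None:
                        raise PedigreeError(
                            f"parent {par!r} of {rec.individual_id!r} not in pedigree"
                        )
                    if j >= i:
                        raise PedigreeError(
                            f"pedigree not topologically sorted: parent {par!r} "
                            f"does not precede offspring {rec.individual_id!r}"
                        )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.individual_id for r in self.records]

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Positions of each individual's sire and dam (-1 for unknown)."""
        sire = np.full(len(self), -1, dtype=np.int64)
        dam = np.full(len(self), -1, dtype=np.int64)
        for i, rec in enumerate(self.records):
            if rec.sire_id is not None:
                sire[i] = self.index[rec.sire_id]
            if rec.dam_id is not None:
                dam[i] = self.index[rec.dam_id]
        return sire, dam

    def is_founder(self) -> np.ndarray:
        """Boolean mask: both parents unknown."""
        sire, dam = self.parent_indices()
        return (sire < 0) & (dam < 0)

    @classmethod
    def from_records(cls, records: Iterable[PedigreeRecord]) -> "Pedigree":
        """Build a pedigree from records in any order (topological sort).

        Parents that are referenced but never defined are inserted as
        founders.  Raises :class:`PedigreeError` on parentage cycles or
        duplicate ids.
        """
        records = list(records)
        defined: dict[str, PedigreeRecord] = {}
        order_seen: list[str] = []
        for rec in records:
            if rec.individual_id in defined:
                raise PedigreeError(f"duplicate individual id: {rec.individual_id!r}")
            defined[rec.individual_id] = rec
            order_seen.append(rec.individual_id)

        # insert referenced-but-undefined parents as founders, in order of
        # first reference so output is deterministic
        for rec in records:
            for par in (rec.sire_id, rec.dam_id):
                if par is not None and par not in defined:
                    defined[par] = PedigreeRecord(par, None, None)
                    order_seen.insert(order_seen.index(rec.individual_id), par)

        # Kahn's algorithm, stable with respect to input order
        remaining = dict(defined)
        placed: dict[str, int] = {}
        out: list[PedigreeRecord] = []
        progress = True
        pending = list(order_seen)
        while pending and progress:
            progress = False
            still: list[str] = []
            for iid in pending:
                rec = remaining[iid]
                ok = all(
                    par is None or par in placed
                    for par in (rec.sire_id, rec.dam_id)
                )
                if ok:
                    placed[iid] = len(out)
                    out.append(rec)
                    progress = True
                else:
                    still.append(iid)
            pending = still
        if pending:
            raise PedigreeError(
                f"cycle in parentage involving individual {pending[0]!r}"
            )
        return cls(out)


@dataclass
class RelationshipMatrix:
    """Symmetric additive relationship matrix over an ordered id list."""

    values: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("relationship matrix shape does not match id count")
        self._index = {iid: i for i, iid in enumerate(self.ids)}

    def subset(self, ids: Sequence[str]) -> "RelationshipMatrix":
        """Restrict to the given ids (in the given order).

        Relationship values through individuals outside the subset are
        preserved because they were accumulated when the full matrix was
        built.
        """
        try:
            idx = np.array([self._index[i] for i in ids], dtype=np.int64)
        except KeyError as exc:
            raise KeyError(f"id {exc.args[0]!r} not in relationship matrix") from exc
        return RelationshipMatrix(self.values[np.ix_(idx, idx)], list(ids))

    def to_tsv(self, path: str) -> None:
        """Write as a TSV with id header row and column (debugging aid)."""
        df = pd.DataFrame(self.values, index=self.ids, columns=self.ids)
        df.to_csv(path, sep="\t", index_label="id")


def read_pedigree(
    path: str,
    unknown_code: str = "0",
    delimiter: Optional[str] = None,
    header: Optional[bool] = None,
) -> Pedigree:
    """Read a 3+ column (id, sire, dam) text pedigree.

    Parameters
    ----------
    path:
        Whitespace- or `delimiter`-separated text file.
    unknown_code:
        Sentinel for an unknown parent (default ``"0"``).
    delimiter:
        Field separator; ``None`` splits on arbitrary whitespace.
    header:
        ``True``/``False`` to force; ``None`` auto-detects a header line by
        the first line's second or third field not being the unknown code
        while the first field re-appears nowhere as a parent -- in practice
        we use the common convention that a header contains the token "id"
        or "sire" or "dam" (case-insensitive).
    """
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(delimiter) if delimiter else line.split()
            if len(parts) < 3:
                raise PedigreeError(f"pedigree line has fewer than 3 fields: {line!r}")
            rows.append(parts[:3])
    if not rows:
        raise PedigreeError(f"empty pedigree file: {path}")
    if header is None:
        first = [f.lower() for f in rows[0]]
        header = any(tok in first for tok in ("id", "individual", "sire", "dam", "animal"))
    if header:
        rows = rows[1:]

    def _clean(tok: str) -> Optional[str]:
        return None if tok == unknown_code else tok

    records = [PedigreeRecord(r[0], _clean(r[1]), _clean(r[2])) for r in rows]
    return Pedigree.from_records(records)


def write_pedigree(ped: Pedigree, path: str, unknown_code: str = "0") -> None:
    """Write a pedigree as 3-column TSV (id, sire, dam)."""
    with open(path, "w") as fh:
        fh.write("id\tsire\tdam\n")
        for rec in ped.records:
            fh.write(
                f"{rec.individual_id}\t{rec.sire_id or unknown_code}\t"
                f"{rec.dam_id or unknown_code}\n"
            )


def compute_A(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular (recursive) method.

    For individual ``i`` with parents ``s, d`` (processed in pedigree order):

    - ``A_ij = 0.5 * (A_js + A_jd)`` for every earlier ``j``,
    - ``A_ii = 1 + 0.5 * A_sd``,

    an unknown parent contributing 0 to both.  Founders have diagonal 1 and
    are unrelated to everything that precedes them.
    """
    n = len(ped)
    sire, dam = ped.parent_indices()
    A = np.zeros((n, n))
    zero = np.zeros(n)
    for i in range(n):
        s, d = sire[i], dam[i]
        row_s = A[s, :i] if s >= 0 else zero[:i]
        row_d = A[d, :i] if d >= 0 else zero[:i]
        A[i, :i] = 0.5 * (row_s + row_d)
        A[:i, i] = A[i, :i]
        a_sd = A[s, d] if (s >= 0 and d >= 0) else 0.0
        A[i, i] = 1.0 + 0.5 * a_sd
    return RelationshipMatrix(A, ped.ids)


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients ``F_i = A_ii - 1`` (founders: 0)."""
    return np.diag(compute_A(ped).values) - 1.0
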
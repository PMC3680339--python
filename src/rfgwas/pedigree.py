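"""Pedigree containers and the numerator relationship matrix.

The numerator relationship matrix A holds expected additive genetic
covariances between animals (twice the kinship coefficient); its diagonal is
1 + F, the animal's inbreeding coefficient.  A is built by the tabular
method, processing animals parents-before-offspring; its inverse is
assembled directly from pedigree structure by Henderson's rules, accounting
for inbreeding, which is both sparse and numerically stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "PedigreeError",
    "Pedigree",
    "RelationshipMatrix",
    "build_a_matrix",
    "build_a_inverse",
]

#: tokens treated as "parent unknown" in input tables
UNKNOWN_TOKENS = {"0", "", "NA", "na", "nan", "None", ".", "*"}


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, duplicate id, missing parent)."""


def _normalise_parent(value) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    return None if s in UNKNOWN_TOKENS else s


@dataclass
class Pedigree:
    """Ordered pedigree: animal ids with sire/dam links.

    Animals are stored in topological order (every parent precedes all of
    its offspring).  ``sire_idx``/``dam_idx`` hold positional indices into
    ``ids`` with -1 meaning unknown.
    """

    ids: list[str]
    sire_idx: np.ndarray
    dam_idx: np.ndarray
    _pos: dict[str, int] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self._pos:
            self._pos = {a: i for i, a in enumerate(self.ids)}

    # -- construction ------------------------------------------------------

    @classmethod
    def from_records(cls, records) -> "Pedigree":
        """Build from an iterable of (animal, sire, dam) or a DataFrame.

        Parent ids equal to 0/NA/empty mean "unknown".  A parent that never
        appears as an animal is added as a founder.  Raises
        :class:`PedigreeError` on duplicate ids or cycles.
        """
        if isinstance(records, pd.DataFrame):
            rows = records.iloc[:, :3].itertuples(index=False, name=None)
        else:
            rows = records
        parents: dict[str, tuple[str | None, str | None]] = {}
        order: list[str] = []
        for animal, sire, dam in rows:
            a = str(animal).strip()
            if a in parents:
                raise PedigreeError(f"duplicate animal id {a!r}")
            parents[a] = (_normalise_parent(sire), _normalise_parent(dam))
            order.append(a)
        # implicit founders: parents never listed as animals
        for a in order:
            for p in parents[a]:
                if p is not None and p not in parents:
                    parents[p] = (None, None)
        all_ids = list(parents)

        # Kahn topological sort (parents before offspring)
        children: dict[str, list[str]] = {a: [] for a in all_ids}
        indeg = {a: 0 for a in all_ids}
        for a in all_ids:
            for p in parents[a]:
                if p is not None:
                    children[p].append(a)
                    indeg[a] += 1
        queue = [a for a in all_ids if indeg[a] == 0]
        topo: list[str] = []
        while queue:
            nxt: list[str] = []
            for a in queue:
                topo.append(a)
                for c in children[a]:
                    indeg[c] -= 1
                    if indeg[c] == 0:
                        nxt.append(c)
            queue = nxt
        if len(topo) != len(all_ids):
            bad = sorted(a for a in all_ids if indeg[a] > 0)
            raise PedigreeError(f"pedigree contains a cycle involving {bad[:5]}")

        pos = {a: i for i, a in enumerate(topo)}
        sire = np.array(
            [pos[parents[a][0]] if parents[a][0] is not None else -1 for a in topo],
            dtype=np.int64,
        )
        dam = np.array(
            [pos[parents[a][1]] if parents[a][1] is not None else -1 for a in topo],
            dtype=np.int64,
        )
        return cls(ids=topo, sire_idx=sire, dam_idx=dam, _pos=pos)

    @classmethod
    def from_tsv(cls, path) -> "Pedigree":
        """Read a TSV with columns animal, sire, dam (header row required)."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls.from_records(df)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_frame(self) -> pd.DataFrame:
        sire = [self.ids[i] if i >= 0 else "0" for i in self.sire_idx]
        dam = [self.ids[i] if i >= 0 else "0" for i in self.dam_idx]
        return pd.DataFrame({"animal": self.ids, "sire": sire, "dam": dam})

    # -- queries -----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, animal: str) -> int:
        try:
            return self._pos[str(animal)]
        except KeyError:
            raise KeyError(f"animal {animal!r} not in pedigree") from None

    def __contains__(self, animal) -> bool:
        return str(animal) in self._pos

    @property
    def founder_mask(self) -> np.ndarray:
        return (self.sire_idx < 0) & (self.dam_idx < 0)

    def inbreeding(self) -> np.ndarray:
        """Per-animal inbreeding coefficients F (diagonal of A minus 1)."""
        return np.diag(build_a_matrix(self).values) - 1.0


@dataclass
class RelationshipMatrix:
    """Numerator relationship matrix over a fixed id order."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self._pos = {a: i for i, a in enumerate(self.ids)}

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self._pos[str(a)], self._pos[str(b)]])

    def submatrix(self, animals) -> "RelationshipMatrix":
        idx = [self._pos[str(a)] for a in animals]
        return RelationshipMatrix(
            ids=[str(a) for a in animals], values=self.values[np.ix_(idx, idx)]
        )


def build_a_matrix(pedigree: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    Processing animals in topological order j:
    a_ij = (a_i,sire(j) + a_i,dam(j)) / 2 for previously processed i, and
    a_jj = 1 + a_sire(j),dam(j) / 2; unknown parents contribute 0.
    """
    n = len(pedigree)
    A = np.zeros((n, n))
    s, d = pedigree.sire_idx, pedigree.dam_idx
    for j in range(n):
        sj, dj = s[j], d[j]
        row = np.zeros(j)
        if sj >= 0:
            row += 0.5 * A[:j, sj]
        if dj >= 0:
            row += 0.5 * A[:j, dj]
        A[:j, j] = row
        A[j, :j] = row
        A[j, j] = 1.0 + (0.5 * A[sj, dj] if (sj >= 0 and dj >= 0) else 0.0)
    return RelationshipMatrix(ids=list(pedigree.ids), values=A)


def build_a_inverse(pedigree: Pedigree) -> sparse.csr_matrix:
    """Sparse inverse of A assembled by Henderson's rules with inbreeding.

    The Mendelian sampling variance d_j is 0.5 - 0.25 (F_s + F_d) with both
    parents known, 0.75 - 0.25 F_p with one, and 1 for founders; each animal
    contributes the usual (1, -1/2) pattern scaled by 1/d_j.
    """
    n = len(pedigree)
    F = pedigree.inbreeding()
    s, d = pedigree.sire_idx, pedigree.dam_idx
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(i: int, j: int, v: float) -> None:
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for j in range(n):
        sj, dj = s[j], d[j]
        if sj >= 0 and dj >= 0:
            dd = 0.5 - 0.25 * (F[sj] + F[dj])
        elif sj >= 0 or dj >= 0:
            p = sj if sj >= 0 else dj
            dd = 0.75 - 0.25 * F[p]
        else:
            dd = 1.0
        w = 1.0 / dd
        add(j, j, w)
        for p in (sj, dj):
            if p >= 0:
                add(p, j, -0.5 * w)
                add(j, p, -0.5 * w)
        for p in (sj, dj):
            for q in (sj, dj):
                if p >= 0 and q >= 0:
                    add(p, q, 0.25 * w)
    return sparse.csr_matrix(
        sparse.coo_matrix((vals, (rows, cols)), shape=(n, n))
    )
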
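"""LD reference: signed SNP-by-SNP correlation matrix with positions.

Plain-text formats only. The dense format has a header line of
whitespace-separated rsids followed by the matrix rows; positions live
in a companion two-column file (rsid, base position). A long-form
triple format (rsid_a, rsid_b, r) is also accepted; unlisted pairs are
zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SYMMETRY_TOL = 1e-8


class LDError(ValueError):
    """Malformed LD input."""


@dataclass
class LDMatrix:
    rsids: list[str]
    r: np.ndarray
    positions: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        m = len(self.rsids)
        if self.r.shape != (m, m):
            raise LDError(f"matrix shape {self.r.shape} does not match {m} rsids")
        if self.positions.shape != (m,):
            raise LDError("positions length does not match rsids")
        if m and np.max(np.abs(self.r - self.r.T)) > SYMMETRY_TOL:
            raise LDError("LD matrix is asymmetric beyond tolerance 1e-8")
        if m and np.max(np.abs(np.diag(self.r) - 1.0)) > SYMMETRY_TOL:
            raise LDError("LD matrix diagonal must be 1")
        if m and np.max(np.abs(self.r)) > 1.0 + SYMMETRY_TOL:
            raise LDError("LD correlations must lie in [-1, 1]")
        # enforce exact symmetry/diagonal after tolerance check
        self.r = (self.r + self.r.T) / 2.0
        np.fill_diagonal(self.r, 1.0)
        self._index = {rsid: i for i, rsid in enumerate(self.rsids)}
        if len(self._index) != m:
            raise LDError("duplicate rsids in LD matrix")

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index

    def index(self, rsid: str) -> int:
        try:
            return self._index[rsid]
        except KeyError:
            raise LDError(f"rsid {rsid} not in LD matrix") from None

    def position(self, rsid: str) -> int:
        return int(self.positions[self.index(rsid)])

    def corr(self, a: str, b: str) -> float:
        return float(self.r[self.index(a), self.index(b)])

    def submatrix(self, rsids: list[str]) -> "LDMatrix":
        idx = [self.index(x) for x in rsids]
        return LDMatrix(
            rsids=list(rsids),
            r=self.r[np.ix_(idx, idx)],
            positions=self.positions[idx],
        )

    @classmethod
    def identity(cls, rsids: list[str], positions) -> "LDMatrix":
        """Independence reference (all off-diagonal correlations zero)."""
        return cls(rsids=list(rsids), r=np.eye(len(rsids)), positions=positions)


def read_ld_matrix(matrix_path, positions_path) -> LDMatrix:
    with open(matrix_path) as fh:
        header = fh.readline().split()
        rows = [[float(x) for x in line.split()] for line in fh if line.strip()]
    if len(rows) != len(header):
        raise LDError(
            f"{matrix_path}: {len(rows)} matrix rows for {len(header)} rsids"
        )
    positions = _read_positions(positions_path, header)
    return LDMatrix(rsids=header, r=np.array(rows), positions=positions)


def read_ld_triples(triples_path, positions_path) -> LDMatrix:
    """Long-form (rsid_a, rsid_b, r) input; missing pairs are independent."""
    entries: list[tuple[str, str, float]] = []
    order: dict[str, int] = {}
    with open(triples_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 3:
                raise LDError(f"{triples_path}: bad triple line {line!r}")
            a, b, r = parts[0], parts[1], float(parts[2])
            for x in (a, b):
                if x not in order:
                    order[x] = len(order)
            entries.append((a, b, r))
    rsids = list(order)
    m = len(rsids)
    mat = np.eye(m)
    for a, b, r in entries:
        i, j = order[a], order[b]
        mat[i, j] = r
        mat[j, i] = r
    positions = _read_positions(positions_path, rsids)
    return LDMatrix(rsids=rsids, r=mat, positions=positions)


def _read_positions(path, rsids: list[str]) -> np.ndarray:
    pos_map: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 2:
                raise LDError(f"{path}: bad position line {line!r}")
            pos_map[parts[0]] = int(parts[1])
    missing = [x for x in rsids if x not in pos_map]
    if missing:
        raise LDError(f"{path}: no position for {missing[:5]}")
    return np.array([pos_map[x] for x in rsids], dtype=np.int64)


def write_ld_matrix(ld: LDMatrix, matrix_path, positions_path) -> None:
    with open(matrix_path, "w") as fh:
        fh.write(" ".join(ld.rsids) + "\n")
        for row in ld.r:
            fh.write(" ".join(repr(float(x)) for x in row) + "\n")
    with open(positions_path, "w") as fh:
        for rsid, pos in zip(ld.rsids, ld.positions):
            fh.write(f"{rsid} {int(pos)}\n")
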
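"""Pairwise distances under the Jukes-Cantor (JC69) model and site-level
diagnostics (fixed differences, within-group divergence) on aligned barcodes.

Conventions, chosen once and applied everywhere:

* distances are *proportions* (substitutions/site); percent rendering is a
  presentation-layer concern;
* pairwise deletion for distances: a site enters a pair's comparison only if
  both characters are unambiguous bases (A/C/G/T) - gaps and ambiguity codes
  are treated identically as missing data;
* complete deletion at the site level for fixed differences: a column is
  evaluated only if every member of both partitions is unambiguous there;
* observed proportions p >= 0.75 are outside the JC domain and raise
  :class:`SaturationError` rather than returning a sentinel - barcode-scale
  data should never get there, so silence would hide upstream faults.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .specimen_io import AlignmentSet

P_DISTANCE = "p_distance"
JC69 = "jc69"
MODELS = (P_DISTANCE, JC69)

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


class UndefinedDistanceError(ValueError):
    """A pair of sequences shares no comparable sites."""


class SaturationError(ValueError):
    """Observed proportion of differences at or beyond the JC69 limit (3/4)."""


def encode_sequence(seq: str) -> np.ndarray:
    """Map a sequence string to uint8 codes: A,C,G,T -> 0..3, all gap and
    ambiguity characters -> 255 (missing)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def p_distance(seq_a: str, seq_b: str) -> tuple[float, int]:
    """Observed proportion of differing sites under pairwise deletion.

    Returns ``(p, n_sites)`` where ``n_sites`` counts the sites at which both
    sequences carry an unambiguous base.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    a, b = encode_sequence(seq_a), encode_sequence(seq_b)
    usable = (a != 255) & (b != 255)
    n = int(usable.sum())
    if n == 0:
        raise UndefinedDistanceError("no comparable sites between sequences")
    diffs = int(((a != b) & usable).sum())
    return diffs / n, n


def jc_distance(p: float) -> float:
    """Jukes-Cantor correction d = -(3/4) ln(1 - 4p/3).

    Defined for 0 <= p < 0.75; the correction never shrinks divergence
    (d >= p, d(0) = 0).
    """
    if p < 0:
        raise ValueError(f"p must be >= 0, got {p}")
    if p >= 0.75:
        raise SaturationError(f"p = {p} is at or beyond the JC69 limit of 0.75")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def jc_site_probability(d: float) -> float:
    """Invert the JC correction: expected proportion of differing sites p for
    a true divergence of d substitutions/site. Used by the simulator so that
    realized JC estimates are unbiased for the requested divergence."""
    if d < 0:
        raise ValueError("d must be >= 0")
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with per-pair comparable-site
    counts."""

    ids: tuple[str, ...]
    values: np.ndarray
    model: str
    comparable_sites: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("matrix not symmetric")
        if (np.diag(self.values) != 0).any():
            raise ValueError("nonzero diagonal")
        if (self.values < 0).any():
            raise ValueError("negative distances")

    def get(self, id_a: str, id_b: str) -> float:
        i, j = self.ids.index(id_a), self.ids.index(id_b)
        return float(self.values[i, j])

    def submatrix(self, ids) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(
            ids=tuple(ids),
            values=self.values[np.ix_(idx, idx)],
            model=self.model,
            comparable_sites=self.comparable_sites[np.ix_(idx, idx)],
        )

    def to_tsv(self, path) -> None:
        """Square PHYLIP-like tab-separated export with an id header
        row/column."""
        with open(path, "w") as fh:
            fh.write("id\t" + "\t".join(self.ids) + "\n")
            for i, sid in enumerate(self.ids):
                row = "\t".join(f"{v:.8f}" for v in self.values[i])
                fh.write(f"{sid}\t{row}\n")


def distance_matrix(aln: AlignmentSet, model: str = JC69) -> DistanceMatrix:
    """All-pairs distance matrix under ``p_distance`` or ``jc69``.

    Raises :class:`UndefinedDistanceError` naming the pair if any pair has
    zero comparable sites.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    ids = tuple(aln.records)
    if len(ids) < 2:
        raise ValueError("need at least 2 records")
    mat = np.stack([encode_sequence(aln.records[i]) for i in ids])
    usable = mat != 255
    n = len(ids)
    values = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=int)
    np.fill_diagonal(sites, aln.length)
    for i in range(n):
        for j in range(i + 1, n):
            both = usable[i] & usable[j]
            ns = int(both.sum())
            if ns == 0:
                raise UndefinedDistanceError(
                    f"no comparable sites between {ids[i]!r} and {ids[j]!r}"
                )
            p = float(((mat[i] != mat[j]) & both).sum()) / ns
            d = jc_distance(p) if model == JC69 else p
            values[i, j] = values[j, i] = d
            sites[i, j] = sites[j, i] = ns
    return DistanceMatrix(ids=ids, values=values, model=model, comparable_sites=sites)


@dataclass(frozen=True)
class FixedDifferenceReport:
    """Diagnostic (fixed) sites between two specimen partitions."""

    partition_a_ids: tuple[str, ...]
    partition_b_ids: tuple[str, ...]
    n_fixed: int
    fixed_site_columns: tuple[int, ...]
    n_shared_polymorphic: int

    def __post_init__(self) -> None:
        assert self.n_fixed == len(self.fixed_site_columns)
        assert all(
            a < b
            for a, b in zip(self.fixed_site_columns, self.fixed_site_columns[1:])
        )


def fixed_differences(
    aln: AlignmentSet, part_a, part_b
) -> FixedDifferenceReport:
    """Count columns at which the two partitions are each monomorphic for
    different bases.

    A site is evaluated only when every member of both partitions carries an
    unambiguous base there (site-level complete deletion). Also reports the
    number of sites polymorphic within *both* partitions (shared
    polymorphisms).
    """
    part_a, part_b = tuple(part_a), tuple(part_b)
    if not part_a or not part_b:
        raise ValueError("partitions must be non-empty")
    if set(part_a) & set(part_b):
        raise ValueError("partitions overlap")
    for sid in (*part_a, *part_b):
        if sid not in aln.records:
            raise KeyError(f"id {sid!r} not in alignment")
    a = np.stack([encode_sequence(aln.records[i]) for i in part_a])
    b = np.stack([encode_sequence(aln.records[i]) for i in part_b])
    usable = (a != 255).all(axis=0) & (b != 255).all(axis=0)
    mono_a = (a == a[0]).all(axis=0)
    mono_b = (b == b[0]).all(axis=0)
    fixed = usable & mono_a & mono_b & (a[0] != b[0])
    poly_a = usable & ~mono_a
    poly_b = usable & ~mono_b
    cols = tuple(int(c) for c in np.nonzero(fixed)[0])
    return FixedDifferenceReport(
        partition_a_ids=part_a,
        partition_b_ids=part_b,
        n_fixed=len(cols),
        fixed_site_columns=cols,
        n_shared_polymorphic=int((poly_a & poly_b).sum()),
    )


def max_intragroup_divergence(aln: AlignmentSet, ids, model: str = JC69) -> float:
    """Maximum pairwise distance within a set of records; 0 for singletons."""
    ids = list(ids)
    if not ids:
        raise ValueError("need at least one id")
    for sid in ids:
        if sid not in aln.records:
            raise KeyError(f"id {sid!r} not in alignment")
    if len(ids) == 1:
        return 0.0
    dm = distance_matrix(aln.subset(ids), model=model)
    return float(dm.values.max())
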
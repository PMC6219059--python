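"""Pedigree and genomic relationship matrices.

The additive (numerator) relationship matrix **A** is built with the dense
tabular method; the genomic relationship matrix **G** follows VanRaden's
Method 1, ``G = ZZ' / (2 Σ p_j (1 - p_j))`` with ``Z = M - 2p``.  Both are
held in :class:`RelationshipMatrix`, which also provides the variance factor
``mean(diag K) - mean(K)`` (verbally ``1 + F̄ - 2f̄``) that scales the
expected genetic variance of a focal cohort in every LR expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Pedigree",
    "RelationshipMatrix",
    "GenotypeMatrix",
    "PedigreeError",
    "build_nrm",
    "inbreeding",
    "build_grm",
    "maf_filter",
    "variance_factor",
]

#: reserved unknown-parent code in files
UNKNOWN = "0"


class PedigreeError(ValueError):
    """Structural problem in a pedigree (ordering, unknown ids, cycles)."""


@dataclass
class Pedigree:
    """Ordered trio records (individual, sire, dam).

    ``sire_idx``/``dam_idx`` are positions into ``ids`` or -1 for an unknown
    parent.  The constructor enforces a topological ordering: each parent
    must appear as an individual *before* any of its offspring, which also
    rules out cycles and self-ancestry.
    """

    ids: list[str]
    sire_idx: np.ndarray
    dam_idx: np.ndarray

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, str]]) -> "Pedigree":
        ids: list[str] = []
        pos: dict[str, int] = {}
        sires: list[int] = []
        dams: list[int] = []
        trios = [(str(a), str(s), str(d)) for a, s, d in records]
        known = {a for a, _, _ in trios}
        for a, s, d in trios:
            if a == UNKNOWN:
                raise PedigreeError("individual id '0' is reserved for unknown parents")
            if a in pos:
                raise PedigreeError(f"duplicate individual id {a!r}")
            for p, lst in ((s, sires), (d, dams)):
                if p == UNKNOWN:
                    lst.append(-1)
                elif p in pos:
                    lst.append(pos[p])
                elif p in known:
                    raise PedigreeError(
                        f"parent {p!r} of {a!r} appears after its offspring; "
                        "pedigree must be sorted parents-first (cycles are impossible "
                        "in a valid ordering)"
                    )
                else:
                    raise PedigreeError(f"unknown id referenced as parent: {p!r}")
            pos[a] = len(ids)
            ids.append(a)
        return cls(ids, np.asarray(sires, dtype=np.int64), np.asarray(dams, dtype=np.int64))

    def __len__(self) -> int:
        return len(self.ids)

    def parents(self, individual: str) -> tuple[str | None, str | None]:
        i = self.ids.index(individual)
        s, d = self.sire_idx[i], self.dam_idx[i]
        return (self.ids[s] if s >= 0 else None, self.ids[d] if d >= 0 else None)


@dataclass
class RelationshipMatrix:
    """Symmetric PSD relationship matrix with individual ids.

    `source` is ``"pedigree"`` for a numerator relationship matrix or
    ``"genomic"`` for a VanRaden GRM.
    """

    ids: list[str]
    matrix: np.ndarray
    source: str = "pedigree"
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError(f"matrix shape {self.matrix.shape} does not match {n} ids")
        self._index = {i: k for k, i in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def indices(self, ids: Sequence[str]) -> np.ndarray:
        try:
            return np.asarray([self._index[i] for i in ids], dtype=np.int64)
        except KeyError as e:
            raise KeyError(f"id {e.args[0]!r} not in relationship matrix") from None

    def submatrix(self, ids: Sequence[str]) -> np.ndarray:
        ix = self.indices(ids)
        return self.matrix[np.ix_(ix, ix)]

    @cached_property
    def mean_diagonal(self) -> float:
        return float(np.mean(np.diag(self.matrix)))

    @cached_property
    def mean_all(self) -> float:
        return float(np.mean(self.matrix))

    @cached_property
    def inverse(self) -> np.ndarray:
        """Dense inverse.

        A GRM built from observed allele frequencies is singular by
        construction (the centered dosage rows sum to ~0), so genomic
        matrices always receive a 1e-8 diagonal ridge before inversion.
        """
        from scipy.linalg import cho_factor, cho_solve

        n = len(self.ids)
        M = self.matrix + 1e-8 * np.eye(n) if self.source == "genomic" else self.matrix
        try:
            return cho_solve(cho_factor(M, lower=True), np.eye(n))
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                "singular relationship matrix; consider adding a small ridge to the diagonal"
            ) from None


@dataclass
class GenotypeMatrix:
    """Biallelic dosage matrix (individuals x loci), values 0/1/2 or NaN."""

    ids: list[str]
    locus_ids: list[str]
    dosages: np.ndarray  # float, NaN = missing

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.ids), len(self.locus_ids)):
            raise ValueError("dosage matrix shape does not match ids/locus ids")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be 0, 1, 2 or missing")

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def allele_frequencies(self) -> np.ndarray:
        """Observed frequency of the counted allele per locus."""
        return np.nanmean(self.dosages, axis=0) / 2.0


def build_nrm(pedigree: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    ``A[i,i] = 1 + 0.5 A[s,d]`` and ``A[i,j] = 0.5 (A[j,s] + A[j,d])`` with
    unknown-parent contributions of zero, so ``diag(A) = 1 + F`` exactly.
    """
    n = len(pedigree)
    A = np.zeros((n, n))
    s, d = pedigree.sire_idx, pedigree.dam_idx
    for i in range(n):
        si, di = s[i], d[i]
        A[i, i] = 1.0 + (0.5 * A[si, di] if si >= 0 and di >= 0 else 0.0)
        if i > 0:
            row = np.zeros(i)
            if si >= 0:
                row += A[:i, si]
            if di >= 0:
                row += A[:i, di]
            A[:i, i] = A[i, :i] = 0.5 * row
    return RelationshipMatrix(list(pedigree.ids), A, source="pedigree")


def inbreeding(pedigree: Pedigree) -> np.ndarray:
    """Inbreeding coefficients ``F = diag(A) - 1`` (founders have F = 0)."""
    return np.diag(build_nrm(pedigree).matrix) - 1.0


def maf_filter(genotypes: GenotypeMatrix, threshold: float) -> GenotypeMatrix:
    """Keep loci with minor allele frequency strictly above ``threshold``."""
    if not 0 <= threshold < 0.5:
        raise ValueError("MAF threshold must be in [0, 0.5)")
    p = genotypes.allele_frequencies()
    maf = np.minimum(p, 1.0 - p)
    keep = maf > threshold
    return GenotypeMatrix(
        list(genotypes.ids),
        [l for l, k in zip(genotypes.locus_ids, keep) if k],
        genotypes.dosages[:, keep],
    )


def build_grm(
    genotypes: GenotypeMatrix, freqs: np.ndarray | None = None
) -> RelationshipMatrix:
    """VanRaden Method 1 GRM.

    Parameters
    ----------
    genotypes:
        Dosage matrix; missing dosages are mean-imputed to ``2 p_j``.
    freqs:
        Allele frequencies to centre and scale with.  Defaults to the
        frequencies observed in `genotypes`; supply base-population
        frequencies to reference relationships to an earlier base.
    """
    p = genotypes.allele_frequencies() if freqs is None else np.asarray(freqs, dtype=float)
    if p.shape != (genotypes.n_loci,):
        raise ValueError("frequency vector length does not match number of loci")
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0:
        raise ValueError(
            "all loci monomorphic (zero VanRaden denominator); filter or supply frequencies"
        )
    M = genotypes.dosages.copy()
    nan = np.isnan(M)
    if nan.any():
        M[nan] = np.broadcast_to(2.0 * p, M.shape)[nan]
    Z = M - 2.0 * p
    G = (Z @ Z.T) / denom
    return RelationshipMatrix(list(genotypes.ids), G, source="genomic")


def variance_factor(K: RelationshipMatrix, focal: Sequence[str]) -> float:
    """``mean(diag K_f) - mean(K_f)`` over the focal cohort.

    This is ``tr(S K_f)/n`` with S the centering matrix -- the exact
    quadratic-form quantity behind every LR expectation (the grand mean
    includes the diagonal).  For one non-inbred individual it is 0; for n
    unrelated non-inbred individuals it is ``1 - 1/n``.
    """
    if len(focal) == 0:
        raise ValueError("focal set is empty")
    sub = K.submatrix(list(focal))
    return float(np.mean(np.diag(sub)) - np.mean(sub))
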
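"""Marker-matrix estimation of the ridge-regression expectation term.

The ridge-regression form of the Rabier accuracy replaces ``Me/N`` with
``E(||x' X' V^-1||^2)``, where ``X`` is the centered training allele-content
matrix, ``x'`` a centered test-individual marker row, and
``V = X X' + lambda I`` the ridge coefficient system.  This module simulates
genotype matrices (independent markers, Hardy-Weinberg sampling), estimates
the expectation term by a symmetric positive-definite solve, and converts
the estimate back to an effective-segment count ``Me_hat = N * eterm``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .errors import LinearAlgebraError, ParameterError

__all__ = [
    "GenotypeSet",
    "RidgeSpec",
    "simulate_genotypes",
    "estimate_eterm",
    "me_from_eterm",
    "default_ridge_lambda",
    "write_genotype_matrix",
    "read_genotype_matrix",
    "genotype_set_from_raw",
]


@dataclass(frozen=True)
class RidgeSpec:
    """Ridge regularization parameter ``lam > 0`` in ``V = X X' + lam I``."""

    lam: float

    def __post_init__(self):
        if not (isinstance(self.lam, (int, float)) and np.isfinite(self.lam)
                and self.lam > 0):
            raise ParameterError(f"ridge lam must be positive and finite, "
                                 f"got {self.lam!r}")


def default_ridge_lambda(m_markers: int, h2: float) -> float:
    """Standard ridge-regression-BLUP shrinkage ``M (1 - h2) / h2``.

    Corresponds to a per-marker genetic variance of ``sigma_g^2 / M`` with
    total variance 1; the caller may always override.
    """
    if not 0 < h2 < 1:
        raise ParameterError(f"h2 must be in (0, 1) for the default ridge "
                             f"parameter, got {h2!r}")
    if m_markers < 1:
        raise ParameterError(f"m_markers must be positive, got {m_markers!r}")
    return m_markers * (1.0 - h2) / h2


@dataclass(frozen=True)
class GenotypeSet:
    """Simulated allele-content matrices for training and test individuals.

    ``raw_train``/``raw_test`` hold allele counts in {0, 1, 2}; the centered
    matrices subtract ``2 p_j`` per marker column (the Hardy-Weinberg column
    mean).  Regeneration from the same seed and shape parameters is
    bit-identical.
    """

    raw_train: np.ndarray
    raw_test: np.ndarray
    allele_freqs: np.ndarray
    seed: int | None = None

    def __post_init__(self):
        raw_train = np.asarray(self.raw_train)
        raw_test = np.asarray(self.raw_test)
        freqs = np.asarray(self.allele_freqs, dtype=float)
        if raw_train.ndim != 2 or raw_test.ndim != 2:
            raise ParameterError("genotype matrices must be 2-dimensional")
        if raw_train.shape[1] != raw_test.shape[1]:
            raise ParameterError(
                f"train and test matrices must share marker columns "
                f"({raw_train.shape[1]} != {raw_test.shape[1]})")
        if freqs.shape != (raw_train.shape[1],):
            raise ParameterError("allele_freqs length must equal the number "
                                 "of marker columns")
        if np.any((freqs <= 0) | (freqs >= 1)):
            raise ParameterError("allele frequencies must lie strictly in (0, 1)")
        for name, m in (("raw_train", raw_train), ("raw_test", raw_test)):
            if not np.isin(m, (0, 1, 2)).all():
                raise ParameterError(f"{name} entries must be allele counts "
                                     f"in {{0, 1, 2}}")
        object.__setattr__(self, "raw_train", raw_train.astype(np.int64))
        object.__setattr__(self, "raw_test", raw_test.astype(np.int64))
        object.__setattr__(self, "allele_freqs", freqs)

    @property
    def n_train(self) -> int:
        return self.raw_train.shape[0]

    @property
    def n_test(self) -> int:
        return self.raw_test.shape[0]

    @property
    def m_markers(self) -> int:
        return self.raw_train.shape[1]

    @property
    def train_matrix(self) -> np.ndarray:
        """Centered training matrix ``X`` (entries ``raw - 2 p_j``)."""
        return self.raw_train - 2.0 * self.allele_freqs

    @property
    def test_matrix(self) -> np.ndarray:
        """Centered test rows, same columns and centering as the training set."""
        return self.raw_test - 2.0 * self.allele_freqs


def simulate_genotypes(n_train: int, n_test: int, m_markers: int,
                       freq_low: float = 0.05, freq_high: float = 0.95,
                       seed: int | None = None) -> GenotypeSet:
    """Simulate independent-marker genotypes for one population.

    Per-marker allele frequencies are drawn uniformly on
    ``[freq_low, freq_high]`` (then one stream draws training genotypes,
    then test genotypes, each entry binomial with 2 trials — two
    independent allele draws under Hardy-Weinberg).  Training and test
    individuals come from the same population.  The stream order
    (frequencies, training matrix, test matrix) is part of the seeding
    contract.
    """
    for name, v in (("n_train", n_train), ("n_test", n_test),
                    ("m_markers", m_markers)):
        if not (isinstance(v, (int, np.integer)) and v >= 1):
            raise ParameterError(f"{name} must be a positive integer, got {v!r}")
    if not (0.0 < freq_low <= freq_high < 1.0):
        raise ParameterError(
            f"require 0 < freq_low <= freq_high < 1, got "
            f"freq_low={freq_low!r}, freq_high={freq_high!r}")
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(freq_low, freq_high, size=m_markers)
    raw_train = rng.binomial(2, freqs, size=(n_train, m_markers))
    raw_test = rng.binomial(2, freqs, size=(n_test, m_markers))
    return GenotypeSet(raw_train=raw_train, raw_test=raw_test,
                       allele_freqs=freqs, seed=seed)


def estimate_eterm(geno: GenotypeSet, ridge: RidgeSpec | float) -> float:
    """Estimate ``E(||x' X' V^-1||^2)`` over the test rows of ``geno``.

    For the fixed training matrix ``X``, forms ``V = X X' + lam I`` and
    computes ``||x' X' V^-1||^2`` for each centered test row ``x'`` via a
    Cholesky solve (never an explicit inverse), returning the mean over
    test rows.  For training and test individuals sampled from the same
    population the estimate is bounded by 1.
    """
    if not isinstance(ridge, RidgeSpec):
        ridge = RidgeSpec(float(ridge))
    X = geno.train_matrix
    n = X.shape[0]
    V = X @ X.T
    V[np.diag_indices(n)] += ridge.lam
    try:
        cf = cho_factor(V, lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - lam > 0 keeps V pd
        raise LinearAlgebraError(f"Cholesky factorization of V failed: {exc}")
    # row x' of the test set: x' X' V^-1 = (V^-1 X x)'  (V symmetric)
    # stack all test rows: rows of (test @ X.T) @ V^-1
    B = geno.test_matrix @ X.T          # n_test x n_train
    rows = cho_solve(cf, B.T).T          # each row is x' X' V^-1
    return float(np.mean(np.sum(rows * rows, axis=1)))


def me_from_eterm(eterm_estimate: float, n_train: int) -> float:
    """Effective-segment estimate ``Me_hat = N * eterm``.

    For same-population sampling the estimate is bounded by ``N``.
    Plugging ``Me_hat`` into the standard Rabier formula reproduces the
    ridge-regression form exactly.
    """
    if eterm_estimate < 0:
        raise ParameterError(f"eterm estimate must be >= 0, got {eterm_estimate!r}")
    n = int(n_train)
    if n < 1:
        raise ParameterError(f"n_train must be a positive integer, got {n_train!r}")
    return n * float(eterm_estimate)


# ---------------------------------------------------------------------------
# plain-text import/export (raw {0,1,2} coding on disk)
# ---------------------------------------------------------------------------

def write_genotype_matrix(raw: np.ndarray, path: str | Path,
                          individual_ids=None, marker_names=None) -> None:
    """Write a raw {0,1,2} matrix as tab-delimited text.

    Layout: header row ``id<TAB>marker names...``, then one row per
    individual with its identifier in the first column.
    """
    raw = np.asarray(raw)
    n, m = raw.shape
    if individual_ids is None:
        individual_ids = [f"ind{i + 1}" for i in range(n)]
    if marker_names is None:
        marker_names = [f"m{j + 1}" for j in range(m)]
    if len(individual_ids) != n or len(marker_names) != m:
        raise ParameterError("identifier lists must match the matrix shape")
    with open(path, "w", newline="\n") as fh:
        fh.write("id\t" + "\t".join(marker_names) + "\n")
        for ind, row in zip(individual_ids, raw):
            fh.write(str(ind) + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_genotype_matrix(path: str | Path):
    """Read a matrix written by :func:`write_genotype_matrix`.

    Returns ``(raw, individual_ids, marker_names)``.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2 or header[0] != "id":
            raise ParameterError(
                f"{path}: expected header starting with 'id' and marker names")
        marker_names = header[1:]
        ids, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ParameterError(f"{path}:{lineno}: expected "
                                     f"{len(header)} fields, got {len(fields)}")
            ids.append(fields[0])
            try:
                rows.append([int(v) for v in fields[1:]])
            except ValueError:
                raise ParameterError(f"{path}:{lineno}: non-integer genotype")
    if not rows:
        raise ParameterError(f"{path}: no genotype rows")
    return np.array(rows, dtype=np.int64), ids, marker_names


def genotype_set_from_raw(raw_train: np.ndarray, raw_test: np.ndarray,
                          allele_freqs=None) -> GenotypeSet:
    """Assemble a :class:`GenotypeSet` from raw matrices.

    If ``allele_freqs`` is omitted, frequencies are recomputed from the
    training matrix as half its column means, clipped away from 0 and 1.
    """
    raw_train = np.asarray(raw_train)
    if allele_freqs is None:
        p = raw_train.mean(axis=0) / 2.0
        eps = 1.0 / (4.0 * max(raw_train.shape[0], 1))
        allele_freqs = np.clip(p, eps, 1.0 - eps)
    return GenotypeSet(raw_train=raw_train, raw_test=np.asarray(raw_test),
                       allele_freqs=np.asarray(allele_freqs, dtype=float))
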
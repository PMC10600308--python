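"""Inference phase: geneset-constrained greedy dictionary learning.

The data matrix is standardized column-wise, then atoms are constructed one
at a time. Each atom is the leading principal component of the residual
restricted to one geneset's features, zero-padded to full width, and its
contribution is removed by deflation. Genesets are visited in the order of
their Box-Cox-normalized explained variance; how often that order is
recomputed is governed by the static/dynamic threshold ``t``.

Variance units: all "variance" quantities are squared Frobenius norms of the
standardized data (i.e. restricted-covariance eigenvalues times ``n - 1``),
so that the deflation ledger closes exactly:
``||residual||_F^2 + sum(variance_removed) == ||Xz||_F^2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import ExpressionMatrix, MembershipMatrix

#: components with squared-norm variance below this fraction of the geneset
#: total are numerically null and never enter the ordering
_RANK_EPS = 1e-10

#: guard for the Box-Cox divisor (size-1 genesets at small lambda)
_DIVISOR_EPS = 1e-12


@dataclass
class StandardizationParams:
    """Per-feature means and standard deviations learned on training data."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.mu.shape != self.sigma.shape or self.mu.ndim != 1:
            raise ValueError("mu and sigma must be 1-D vectors of equal length")
        if not (self.sigma > 0).all():
            raise ValueError("sigma must be strictly positive")

    def apply(self, values: np.ndarray) -> np.ndarray:
        """Standardize a matrix with the stored training statistics."""
        values = np.asarray(values, dtype=float)
        if values.shape[1] != self.mu.size:
            raise ValueError(
                f"matrix has {values.shape[1]} features, expected {self.mu.size}"
            )
        return (values - self.mu) / self.sigma


@dataclass
class Atom:
    """One dictionary row: a unit-norm direction in feature space.

    Inference atoms have support restricted to their geneset; discovery atoms
    carry ``geneset_index=None``. ``variance_removed`` is the squared norm
    ``||R d||^2`` this atom explained on the residual it was built from.
    """

    coeffs: np.ndarray
    geneset_index: int | None
    phase: str  # "inference" | "discovery"
    variance_removed: float
    component_rank: int = 0


@dataclass
class VarianceLedger:
    """Ordered geneset indices and their Box-Cox-normalized variances.

    Produced by :func:`order_of_genesets` (``actual`` empty) and by
    :func:`inference_phase`, where ``order``/``expected``/``actual`` are
    aligned with the accepted atoms and ``reevaluations`` counts how many
    times the ordering was recomputed.
    """

    order: list[int] = field(default_factory=list)
    expected: list[float] = field(default_factory=list)
    component: list[int] = field(default_factory=list)
    actual: list[float] = field(default_factory=list)
    reevaluations: int = 0
    lam: float | None = 1.0 / 3.0
    t: float = 0.9

    def __len__(self) -> int:
        return len(self.order)


def standardize(X: ExpressionMatrix) -> tuple[np.ndarray, StandardizationParams]:
    """Column-wise standardization of an expression matrix.

    Uses the sample standard deviation (``n - 1`` denominator). Constant
    columns are mapped to all-zeros and their sigma recorded as 1 so the
    parameters stay reusable on future data.
    """
    if X.n < 2:
        raise ValueError("standardization requires at least 2 samples")
    mu = X.values.mean(axis=0)
    sigma = X.values.std(axis=0, ddof=1)
    sigma = np.where(sigma > 0, sigma, 1.0)
    params = StandardizationParams(mu=mu, sigma=sigma)
    return params.apply(X.values), params


def box_cox(y: float, lam: float) -> float:
    """Box-Cox power transform ``(y**lam - 1)/lam`` (``log y`` at lam=0)."""
    if y <= 0:
        raise ValueError(f"box_cox requires y > 0, got {y}")
    if lam == 0:
        return float(np.log(y))
    return float((y**lam - 1.0) / lam)


def _size_divisor(geneset_size: int, lam: float | None) -> float:
    if lam is None:  # normalization disabled
        return 1.0
    return max(box_cox(float(geneset_size), lam), _DIVISOR_EPS)


def normalize_variance(v: float, geneset_size: int, lam: float | None) -> float:
    """Penalize raw explained variance by the Box-Cox transform of the size.

    Larger genesets have more coefficients to adjust and trivially explain
    more variance; dividing by ``box_cox(|g|, lam)`` removes that advantage
    when ranking genesets. ``lam=None`` disables the normalization entirely
    (the raw variance is used, reproducing the large-geneset selection bias).
    """
    if geneset_size < 1:
        raise ValueError("geneset_size must be >= 1")
    if v < 0:
        raise ValueError("variance must be nonnegative")
    return v / _size_divisor(geneset_size, lam)


def _fix_sign(v: np.ndarray) -> np.ndarray:
    """Deterministic eigenvector sign: largest-|coeff| entry made positive.

    ``argmax`` returns the first maximum, so exact ties resolve to the lowest
    feature index.
    """
    k = int(np.argmax(np.abs(v)))
    return -v if v[k] < 0 else v


def geneset_pca_spectrum(
    Xz: np.ndarray, g: np.ndarray, mode: str = "full"
) -> list[tuple[np.ndarray, float]]:
    """PCA of the data restricted to the feature subset ``g``.

    Returns ``(eigvec, variance)`` pairs sorted by decreasing variance, where
    ``variance`` is in squared-norm units (eigenvalue of the restricted
    covariance times ``n - 1``). ``mode="first"`` returns only the leading
    pair. Eigenvectors are unit-norm over ``g`` with deterministic sign.
    """
    g = np.asarray(g, dtype=int)
    if g.size == 0:
        raise ValueError("geneset support is empty")
    if mode not in ("full", "first"):
        raise ValueError(f"unknown mode {mode!r}")
    sub = Xz[:, g]
    # standardization already centered the columns; no per-geneset re-centering
    _, s, vt = np.linalg.svd(sub, full_matrices=False)
    variances = s**2
    pairs = [(_fix_sign(vt[j]), float(variances[j])) for j in range(len(s))]
    return pairs[:1] if mode == "first" else pairs


def order_of_genesets(
    Xz: np.ndarray, G: MembershipMatrix, a1: int, lam: float | None
) -> VarianceLedger:
    """Rank (geneset, component) pairs by Box-Cox-normalized variance.

    For every geneset a full restricted PCA is run; all normalized component
    variances are pooled and sorted descending, ties broken by lower geneset
    then component index. The top ``a1`` pairs are returned — a geneset may
    appear several times, once per retained component.
    """
    if a1 < 1:
        raise ValueError("a1 must be >= 1")
    sizes = G.sizes()
    if not (sizes > 0).any():
        raise ValueError("no geneset with non-empty support")
    pool: list[tuple[float, int, int]] = []  # (normalized variance, i, j)
    for i in range(G.m):
        if sizes[i] == 0:
            continue
        g = G.support(i)
        spectrum = geneset_pca_spectrum(Xz, g, mode="full")
        total = sum(v for _, v in spectrum)
        if total <= 0:
            continue
        divisor = _size_divisor(int(sizes[i]), lam)
        for j, (_, v) in enumerate(spectrum):
            if v < _RANK_EPS * total:
                continue
            pool.append((v / divisor, i, j))
    pool.sort(key=lambda rec: (-rec[0], rec[1], rec[2]))
    if len(pool) < a1:
        warnings.warn(
            f"only {len(pool)} components available for a1={a1}; returning all",
            stacklevel=2,
        )
    top = pool[:a1]
    return VarianceLedger(
        order=[i for _, i, _ in top],
        expected=[v for v, _, _ in top],
        component=[j for _, _, j in top],
        lam=lam,
    )


def construct_atom(Xz: np.ndarray, g: np.ndarray) -> Atom | None:
    """Build an atom from the leading restricted principal component.

    The coefficients for features outside ``g`` are zero. Returns ``None``
    when the restricted data are numerically all-zero (fully deflated
    geneset), which callers must treat as a rejection, not an atom.
    """
    g = np.asarray(g, dtype=int)
    if g.size == 0:
        raise ValueError("geneset support is empty")
    sub = Xz[:, g]
    total = float(np.sum(sub**2))
    if total <= _RANK_EPS * max(1.0, float(np.sum(Xz**2))):
        return None
    (vec, var), = geneset_pca_spectrum(Xz, g, mode="first")
    d = np.zeros(Xz.shape[1])
    d[g] = vec
    return Atom(coeffs=d, geneset_index=None, phase="inference", variance_removed=var)


def deflate(Xz: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Remove an atom's contribution: ``X <- X (I - d^T d)``.

    Implemented as a rank-1 update ``X - (X d) d^T`` so the p x p projector
    is never materialized.
    """
    d = np.asarray(d, dtype=float).ravel()
    nrm = np.linalg.norm(d)
    if abs(nrm - 1.0) > 1e-8:
        raise ValueError(f"atom must be unit norm, got ||d||={nrm}")
    return Xz - np.outer(Xz @ d, d)


def inference_phase(
    Xz: np.ndarray,
    G: MembershipMatrix,
    a1: int,
    t: float = 0.9,
    lam: float | None = 1.0 / 3.0,
) -> tuple[list[Atom], VarianceLedger, np.ndarray]:
    """Greedy construction of up to ``a1`` geneset-constrained atoms.

    The next candidate geneset comes from the current ordering. The atom is
    built on the residual and its actual normalized variance compared with
    the ordering's expectation; if the ratio drops to ``t`` or below the atom
    is dropped, the ordering recomputed on the residual, and the fresh
    ordering's first atom accepted unconditionally (its expectation equals
    its actual by construction). ``t=0`` therefore yields a single ordering
    call (static strategy); ``t=1`` recomputes at essentially every step
    (dynamic strategy).
    """
    if not 0.0 <= t <= 1.0:
        raise ValueError("t must lie in [0, 1]")
    R = np.array(Xz, dtype=float, copy=True)
    ledger = VarianceLedger(lam=lam, t=t)

    current = order_of_genesets(R, G, a1, lam)
    queue = list(zip(current.order, current.expected, current.component))
    pos = 0
    fresh = True  # head of a freshly computed ordering: accept unconditionally

    atoms: list[Atom] = []
    accepted_since_reorder = True
    while len(atoms) < a1:
        if pos >= len(queue):
            # ordering exhausted before a1 atoms (rejections along the way)
            if not accepted_since_reorder:
                warnings.warn("no constructible atom remains", stacklevel=2)
                break
            try:
                current = order_of_genesets(R, G, a1 - len(atoms), lam)
            except ValueError:
                break
            ledger.reevaluations += 1
            if not current.order:
                warnings.warn("residual variance exhausted before a1 atoms", stacklevel=2)
                break
            queue = list(zip(current.order, current.expected, current.component))
            pos = 0
            fresh = True
            accepted_since_reorder = False
        i, expected, comp = queue[pos]
        pos += 1
        atom = construct_atom(R, G.support(i))
        if atom is None:
            fresh = False
            continue
        size = int(G.sizes()[i])
        vhat = normalize_variance(atom.variance_removed, size, lam)
        if not fresh and expected > 0 and vhat / expected <= t:
            # actual fell short of expectation: drop, recompute the ordering
            new = order_of_genesets(R, G, max(a1 - len(atoms), 1), lam)
            ledger.reevaluations += 1
            if not new.order:
                warnings.warn("residual variance exhausted before a1 atoms", stacklevel=2)
                break
            queue = list(zip(new.order, new.expected, new.component))
            pos = 0
            fresh = True
            continue
        atom.geneset_index = i
        atom.component_rank = comp
        atoms.append(atom)
        ledger.order.append(i)
        ledger.expected.append(expected)
        ledger.component.append(comp)
        ledger.actual.append(vhat)
        R = deflate(R, atom.coeffs)
        fresh = False
        accepted_since_reorder = True

    if len(atoms) < a1:
        warnings.warn(
            f"inference stopped at {len(atoms)} of {a1} requested atoms",
            stacklevel=2,
        )
    return atoms, ledger, R
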
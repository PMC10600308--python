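"""Discovery phase: unconstrained sparse atoms on the inference residual.

Atoms are extracted by truncated power iteration: alternate the covariance
action of the residual with hard-thresholding to the ``nz`` largest-magnitude
coefficients, renormalize, and deflate between atoms with the same projector
used in inference. This guarantees the cardinality contract — every atom has
exactly ``nz`` non-zeros whenever the residual supports it — which
penalty-tuned l1 formulations do not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .inference import Atom, _fix_sign, deflate


@dataclass
class DiscoveryConfig:
    """Settings for sparse-atom extraction.

    ``a2`` atoms with ``nz`` non-zeros each (default 2000, capped at p);
    iteration stops at relative change below ``tol`` or ``max_iter`` sweeps.
    ``subsample`` optionally restricts extraction to a seeded row subsample.
    """

    a2: int = 0
    nz: int = 2000
    max_iter: int = 500
    tol: float = 1e-6
    seed: int | None = None
    subsample: int | None = None

    def validate(self, p: int) -> None:
        if self.a2 < 0:
            raise ValueError("a2 must be nonnegative")
        if self.nz < 1:
            raise ValueError("nz must be positive")
        if self.nz > p:
            raise ValueError(f"nz={self.nz} exceeds feature count p={p}")


def _truncate(w: np.ndarray, nz: int) -> np.ndarray:
    """Keep the nz largest-|w| entries, zero the rest; renormalize.

    Ties resolve to the lower feature index (stable sort on -|w|).
    """
    if nz >= w.size:
        out = w.copy()
    else:
        keep = np.argsort(-np.abs(w), kind="stable")[:nz]
        out = np.zeros_like(w)
        out[keep] = w[keep]
    nrm = np.linalg.norm(out)
    if nrm == 0:
        return out
    return out / nrm


def _leading_sparse_component(
    R: np.ndarray, nz: int, max_iter: int, tol: float
) -> np.ndarray | None:
    """One sparse leading direction of R by truncated power iteration."""
    _, s, vt = np.linalg.svd(R, full_matrices=False)
    if s[0] <= 0:
        return None
    d = _truncate(vt[0], nz)
    if not d.any():
        return None
    for _ in range(max_iter):
        w = R.T @ (R @ d)
        if not np.any(w):
            break
        d_new = _truncate(w, nz)
        if not d_new.any():
            break
        d_new = _fix_sign(d_new)
        if np.linalg.norm(d_new - _fix_sign(d)) < tol:
            d = d_new
            break
        d = d_new
    return _fix_sign(d)


def discovery_phase(residual: np.ndarray, cfg: DiscoveryConfig) -> list[Atom]:
    """Extract ``cfg.a2`` sparse atoms from the inference residual.

    Successive leading sparse components with deflation in between; each
    atom records the squared norm it removed. Returns an empty list (with a
    warning) when the residual is already numerically zero.
    """
    if cfg.a2 == 0:
        return []
    cfg.validate(residual.shape[1])
    R = np.array(residual, dtype=float, copy=True)
    if cfg.subsample is not None and cfg.subsample < R.shape[0]:
        rng = np.random.default_rng(cfg.seed)
        rows = rng.choice(R.shape[0], size=cfg.subsample, replace=False)
        R = R[np.sort(rows)]
    total = float(np.sum(residual**2))
    if total <= 0 or float(np.sum(R**2)) <= 1e-12 * max(1.0, total):
        warnings.warn("residual is numerically zero; no discovery atoms", stacklevel=2)
        return []

    # deflation is applied to the full residual so variance accounting stays
    # consistent even under row subsampling
    R_full = np.array(residual, dtype=float, copy=True)
    atoms: list[Atom] = []
    for _ in range(cfg.a2):
        if float(np.sum(R**2)) <= 1e-12 * max(1.0, total):
            warnings.warn(
                f"residual exhausted after {len(atoms)} discovery atoms", stacklevel=2
            )
            break
        d = _leading_sparse_component(R, cfg.nz, cfg.max_iter, cfg.tol)
        if d is None or not d.any():
            break
        var = float(np.sum((R_full @ d) ** 2))
        atoms.append(
            Atom(
                coeffs=d,
                geneset_index=None,
                phase="discovery",
                variance_removed=var,
            )
        )
        R_full = deflate(R_full, d)
        R = R_full if cfg.subsample is None or cfg.subsample >= residual.shape[0] else deflate(R, d)
    return atoms
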
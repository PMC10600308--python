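"""Fit orchestration, out-of-sample projection, and variance accounting.

The fitted artifact couples the dictionary ``D = [D1; D2]`` with the
training standardization so that any new matrix — even a single sample — is
projected consistently: ``L = Xz D+`` with ``D+`` the Moore-Penrose
pseudo-inverse, computed once per model and cached.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import ExpressionMatrix, MembershipMatrix
from .discovery import DiscoveryConfig, discovery_phase
from .inference import (
    Atom,
    StandardizationParams,
    VarianceLedger,
    inference_phase,
    standardize,
)

#: singular values below this fraction of the largest are treated as zero
#: when pseudo-inverting D (overlapping genesets yield near-dependent rows)
_PINV_RCOND = 1e-10

DEFAULT_T = 0.9
DEFAULT_LAM = 1.0 / 3.0
DEFAULT_NZ = 2000


@dataclass
class AtomMeta:
    """Provenance of one dictionary row."""

    name: str
    phase: str  # "inference" | "discovery"
    geneset_name: str | None
    geneset_index: int | None
    component_rank: int
    variance_removed: float


@dataclass
class PaslModel:
    """Fitted dictionary-learning artifact.

    ``D1`` holds the geneset-constrained atoms (inference phase), ``D2`` the
    unconstrained sparse atoms (discovery phase); scores are computed against
    the stacked dictionary ``D``.
    """

    D1: sp.csr_matrix
    D2: sp.csr_matrix
    std: StandardizationParams
    atom_meta: list[AtomMeta]
    hyper: dict
    ledger: VarianceLedger
    feature_ids: list[str]
    covered: np.ndarray  # boolean mask: feature belongs to >=1 geneset
    _pinv: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.D1 = sp.csr_matrix(self.D1)
        self.D2 = sp.csr_matrix(self.D2)
        self.covered = np.asarray(self.covered, dtype=bool)
        if len(self.atom_meta) != self.a1 + self.a2:
            raise ValueError("atom_meta length must equal a1 + a2")

    @property
    def a1(self) -> int:
        return self.D1.shape[0]

    @property
    def a2(self) -> int:
        return self.D2.shape[0]

    @property
    def D(self) -> sp.csr_matrix:
        if self.a2 == 0:
            return self.D1
        return sp.vstack([self.D1, self.D2], format="csr")

    @property
    def atom_names(self) -> list[str]:
        return [m.name for m in self.atom_meta]

    def pinv(self) -> np.ndarray:
        """Cached Moore-Penrose pseudo-inverse of D (p x a)."""
        if self._pinv is None:
            self._pinv = np.linalg.pinv(self.D.toarray(), rcond=_PINV_RCOND)
        return self._pinv


@dataclass
class ScoreMatrix:
    """Samples-by-atoms latent representation (pathway activity scores).

    The first ``a1`` columns are inference scores tied to named genesets,
    the remainder discovery scores.
    """

    values: np.ndarray
    sample_ids: list[str]
    atom_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.atom_names)):
            raise ValueError("score matrix shape does not match ids")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.atom_names)


def _atoms_to_sparse(atoms: list[Atom], p: int) -> sp.csr_matrix:
    if not atoms:
        return sp.csr_matrix((0, p))
    return sp.csr_matrix(np.vstack([a.coeffs for a in atoms]))


def fit(
    X: ExpressionMatrix,
    G: MembershipMatrix,
    a1: int,
    a2: int = 0,
    t: float = DEFAULT_T,
    lam: float | None = DEFAULT_LAM,
    nz: int = DEFAULT_NZ,
    seed: int | None = None,
    discovery_subsample: int | None = None,
) -> PaslModel:
    """Learn a PASL dictionary: standardize, inference phase, discovery phase.

    ``nz`` is capped at the feature count. Deterministic for a given seed
    (the seed only matters when ``discovery_subsample`` is set; both phases
    are otherwise deterministic).
    """
    if a1 + a2 == 0:
        raise ValueError("a1 + a2 must be positive")
    if X.feature_ids != G.feature_ids:
        raise ValueError("expression matrix and membership matrix features differ")
    Xz, params = standardize(X)

    atoms: list[Atom] = []
    ledger = VarianceLedger(lam=lam, t=t)
    residual = Xz
    if a1 > 0:
        atoms, ledger, residual = inference_phase(Xz, G, a1, t=t, lam=lam)

    cfg = DiscoveryConfig(
        a2=a2,
        nz=min(nz, X.p),
        seed=seed,
        subsample=discovery_subsample,
    )
    disc_atoms = discovery_phase(residual, cfg) if a2 > 0 else []

    meta: list[AtomMeta] = []
    per_geneset_count: dict[int, int] = {}
    for atom in atoms:
        gi = atom.geneset_index
        k = per_geneset_count.get(gi, 0) + 1
        per_geneset_count[gi] = k
        gname = G.geneset_names[gi]
        meta.append(
            AtomMeta(
                name=f"GS:{gname}#{k}",
                phase="inference",
                geneset_name=gname,
                geneset_index=gi,
                component_rank=atom.component_rank,
                variance_removed=atom.variance_removed,
            )
        )
    for k, atom in enumerate(disc_atoms, start=1):
        meta.append(
            AtomMeta(
                name=f"DISC#{k}",
                phase="discovery",
                geneset_name=None,
                geneset_index=None,
                component_rank=0,
                variance_removed=atom.variance_removed,
            )
        )

    return PaslModel(
        D1=_atoms_to_sparse(atoms, X.p),
        D2=_atoms_to_sparse(disc_atoms, X.p),
        std=params,
        atom_meta=meta,
        hyper={
            "a1": a1,
            "a2": a2,
            "t": t,
            "lam": lam,
            "nz": min(nz, X.p),
            "seed": seed,
        },
        ledger=ledger,
        feature_ids=list(X.feature_ids),
        covered=G.covered_features(),
    )


def _standardized_new(
    Xnew: ExpressionMatrix, model: PaslModel, allow_subset: bool = False
) -> np.ndarray:
    """Standardize new data with the training statistics, aligning features.

    With ``allow_subset`` features absent from the new matrix are zero-filled
    (i.e., imputed at the training mean); extra features are an error either
    way.
    """
    if Xnew.feature_ids == model.feature_ids:
        return model.std.apply(Xnew.values)
    new_set = set(Xnew.feature_ids)
    model_set = set(model.feature_ids)
    extra = new_set - model_set
    if extra:
        raise ValueError(
            f"{len(extra)} features absent from the model (e.g. {sorted(extra)[:3]})"
        )
    missing = model_set - new_set
    if missing and not allow_subset:
        raise ValueError(
            f"{len(missing)} model features missing from input; "
            "pass allow_subset=True to zero-fill"
        )
    col = {f: j for j, f in enumerate(Xnew.feature_ids)}
    Xz = np.zeros((Xnew.n, len(model.feature_ids)))
    for j, f in enumerate(model.feature_ids):
        if f in col:
            Xz[:, j] = (Xnew.values[:, col[f]] - model.std.mu[j]) / model.std.sigma[j]
    return Xz


def transform(
    Xnew: ExpressionMatrix, model: PaslModel, allow_subset: bool = False
) -> ScoreMatrix:
    """Project new samples into pathway activity scores: ``L = Xz D+``.

    Standardization always uses the training mu/sigma, so a single test
    sample can be transformed without estimating anything from it.
    """
    Xz = _standardized_new(Xnew, model, allow_subset=allow_subset)
    L = Xz @ model.pinv()
    return ScoreMatrix(
        values=L, sample_ids=list(Xnew.sample_ids), atom_names=model.atom_names
    )


def _dictionary_for_scope(model: PaslModel, scope: str) -> sp.csr_matrix:
    if scope == "inference_only":
        return model.D1
    if scope == "all":
        return model.D
    raise ValueError(f"unknown scope {scope!r}")


def _explained_variance_xz(
    Xz: np.ndarray,
    model: PaslModel,
    scope: str = "all",
    restrict_to_covered_features: bool = False,
) -> float:
    D = _dictionary_for_scope(model, scope).toarray()
    if restrict_to_covered_features:
        Xz = Xz[:, model.covered]
        D = D[:, model.covered]
    total = float(np.sum(Xz**2))
    if total <= 0:
        raise ValueError("explained variance undefined for an all-zero matrix")
    L = Xz @ np.linalg.pinv(D, rcond=_PINV_RCOND)
    resid = Xz - L @ D
    return 1.0 - float(np.sum(resid**2)) / total


def explained_variance(
    Xlike: ExpressionMatrix,
    model: PaslModel,
    scope: str = "all",
    restrict_to_covered_features: bool = False,
    allow_subset: bool = False,
) -> float:
    """Fraction of standardized variance retained by the projection.

    ``1 - ||Xz - L D||_F^2 / ||Xz||_F^2`` with L the least-squares scores.
    With ``restrict_to_covered_features`` the features outside every geneset
    are dropped from numerator and denominator, focusing on the variance a
    geneset-constrained dictionary could possibly explain.
    """
    Xz = _standardized_new(Xlike, model, allow_subset=allow_subset)
    return _explained_variance_xz(
        Xz, model, scope=scope, restrict_to_covered_features=restrict_to_covered_features
    )


def permuted_baseline(
    Xvalid: ExpressionMatrix,
    model: PaslModel,
    seed: int | None = None,
    scope: str = "all",
    restrict_to_covered_features: bool = False,
) -> float:
    """Explained variance after a random column (feature) permutation.

    Destroying the feature identity turns the dictionary into a random
    sub-space projection of the same sparsity, the natural control for the
    generalization of a learned dictionary.
    """
    Xz = _standardized_new(Xvalid, model)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(Xz.shape[1])
    return _explained_variance_xz(
        Xz[:, perm],
        model,
        scope=scope,
        restrict_to_covered_features=restrict_to_covered_features,
    )
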
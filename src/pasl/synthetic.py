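"""Planted-model synthetic data for exercising the whole pipeline.

Emulates the size-bias calibration experiment: randomly drawn genesets with
sizes uniform over {30, 50, 100, 200}, a true dictionary supported on a
random subset of them with coefficients uniform on [-1.5,-0.5] u [0.5,1.5]
(scores likewise, keeping them away from zero), and isotropic Gaussian
noise. Everything is reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, MembershipMatrix
from .io import build_membership
from .containers import GenesetCollection
from .model import PaslModel

SIZE_CLASSES = (30, 50, 100, 200)


@dataclass
class SyntheticSpec:
    """Generative settings for the planted model.

    Defaults mirror the size-bias experiment: n=400 samples, p=500 features,
    geneset sizes uniform over {30, 50, 100, 200}, 40 genesets of which 20
    carry a planted factor, noise_sd=0.1 relative to the O(1) signal scale.
    """

    n: int = 400
    p: int = 500
    n_genesets: int = 40
    n_active: int = 20
    geneset_sizes: tuple[int, ...] = SIZE_CLASSES
    noise_sd: float = 0.1
    seed: int | None = None
    disjoint: bool = False  # carve non-overlapping genesets (needs sum sizes <= p)

    def validate(self) -> None:
        if max(self.geneset_sizes) > self.p:
            raise ValueError("largest geneset size exceeds feature count")
        if self.n_active > self.n_genesets:
            raise ValueError("n_active cannot exceed n_genesets")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated dataset."""

    G_true: MembershipMatrix
    D_true: np.ndarray
    L_true: np.ndarray
    active_indices: np.ndarray
    size_class: np.ndarray  # per active geneset
    spec: SyntheticSpec = field(repr=False, default=None)


def _two_sided_uniform(rng: np.random.Generator, shape) -> np.ndarray:
    """i.i.d. uniform on [-1.5, -0.5] u [0.5, 1.5]."""
    mag = rng.uniform(0.5, 1.5, size=shape)
    sign = rng.choice((-1.0, 1.0), size=shape)
    return mag * sign


def simulate(spec: SyntheticSpec) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Draw genesets, a planted dictionary and scores; emit X = L D + noise."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    feature_ids = [f"f{j:04d}" for j in range(spec.p)]
    sizes = rng.choice(spec.geneset_sizes, size=spec.n_genesets)

    if spec.disjoint:
        if int(sizes.sum()) > spec.p:
            raise ValueError(
                "disjoint genesets require total size <= p; "
                f"got {int(sizes.sum())} > {spec.p}"
            )
        pool = rng.permutation(spec.p)
        supports = []
        offset = 0
        for s in sizes:
            supports.append(np.sort(pool[offset : offset + s]))
            offset += s
    else:
        supports = [
            np.sort(rng.choice(spec.p, size=s, replace=False)) for s in sizes
        ]

    entries = [
        (f"GS{i:03d}", f"size={sizes[i]}", frozenset(feature_ids[j] for j in supports[i]))
        for i in range(spec.n_genesets)
    ]
    G_true = build_membership(GenesetCollection(entries=entries), feature_ids)

    active = np.sort(rng.choice(spec.n_genesets, size=spec.n_active, replace=False))
    D_true = np.zeros((spec.n_active, spec.p))
    for k, i in enumerate(active):
        D_true[k, supports[i]] = _two_sided_uniform(rng, len(supports[i]))
    L_true = _two_sided_uniform(rng, (spec.n, spec.n_active))
    noise = rng.normal(0.0, spec.noise_sd, size=(spec.n, spec.p)) if spec.noise_sd else 0.0
    X = L_true @ D_true + noise

    truth = SyntheticTruth(
        G_true=G_true,
        D_true=D_true,
        L_true=L_true,
        active_indices=active,
        size_class=sizes[active],
        spec=spec,
    )
    expr = ExpressionMatrix(
        values=X,
        sample_ids=[f"s{i:04d}" for i in range(spec.n)],
        feature_ids=feature_ids,
    )
    return expr, truth


def simulate_two_class(
    spec: SyntheticSpec,
    effect: np.ndarray,
    class_sizes: tuple[int, int],
) -> tuple[ExpressionMatrix, SyntheticTruth, pd.Series]:
    """Two-class planted data: class 2 scores shifted by ``effect`` per atom.

    ``effect = 0`` gives an exchangeable null for calibration checks.
    """
    if sum(class_sizes) != spec.n:
        raise ValueError("class sizes must sum to n")
    effect = np.asarray(effect, dtype=float)
    if effect.shape != (spec.n_active,):
        raise ValueError(f"effect must have length n_active={spec.n_active}")
    X, truth = simulate(spec)
    n1 = class_sizes[0]
    labels = np.array(["A"] * n1 + ["B"] * class_sizes[1])
    # shifting the class-2 scores adds shift @ D to those rows of X; the
    # noise realization is untouched
    shift = np.zeros((spec.n, spec.n_active))
    shift[n1:] = effect
    truth.L_true = truth.L_true + shift
    X = ExpressionMatrix(
        X.values + shift @ truth.D_true, X.sample_ids, X.feature_ids
    )
    return X, truth, pd.Series(labels, index=X.sample_ids, name="class")


def size_class_histogram(model: PaslModel, truth: SyntheticTruth) -> dict[int, int]:
    """Count accepted inference atoms per ground-truth geneset size class."""
    sizes = truth.G_true.sizes()
    counts = {c: 0 for c in SIZE_CLASSES}
    for meta in model.atom_meta:
        if meta.phase != "inference":
            continue
        s = int(sizes[meta.geneset_index])
        counts[s] = counts.get(s, 0) + 1
    return counts
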
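"""Readers and writers for the external formats.

GMT geneset files, expression matrices as TSV (header row = feature ids,
first column = sample ids), two-column label and probe-annotation TSVs, and
a JSON model archive with the dictionary stored as sparse triplets.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import ExpressionMatrix, GenesetCollection, MembershipMatrix
from .inference import StandardizationParams, VarianceLedger
from .model import AtomMeta, PaslModel

logger = logging.getLogger(__name__)

MODEL_SCHEMA_VERSION = 1


def read_gmt(path: str | Path) -> GenesetCollection:
    """Parse a GMT file: one geneset per line, tab-separated.

    Fields are name, description, then members; duplicate members within a
    line are deduplicated. Lines with fewer than 3 fields and duplicate
    geneset names are errors.
    """
    entries: list[tuple[str, str, frozenset[str]]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3"
                )
            name, desc = fields[0], fields[1]
            members = frozenset(f for f in fields[2:] if f)
            if not members:
                raise ValueError(f"{path}:{lineno}: geneset {name!r} has no members")
            if name in seen:
                raise ValueError(f"{path}:{lineno}: duplicate geneset name {name!r}")
            seen.add(name)
            entries.append((name, desc, members))
    return GenesetCollection(entries=entries)


def write_gmt(collection: GenesetCollection, path: str | Path) -> None:
    """Write a geneset collection in GMT format (members sorted for stability)."""
    with open(path, "w") as fh:
        for name, desc, members in collection.entries:
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def read_annotation(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column TSV probe -> gene multimap (one row per pair)."""
    table = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if table.shape[1] < 2:
        raise ValueError(f"{path}: annotation table needs 2 columns (probe, gene)")
    mapping: dict[str, set[str]] = {}
    for probe, gene in zip(table.iloc[:, 0], table.iloc[:, 1]):
        mapping.setdefault(str(probe), set()).add(str(gene))
    return mapping


def build_membership(
    genesets: GenesetCollection,
    feature_ids: list[str],
    annotation: dict[str, set[str]] | None = None,
) -> MembershipMatrix:
    """Build the binary membership matrix G over the measured features.

    ``G[i, j] = 1`` when at least one gene measured by feature ``j`` belongs
    to geneset ``i``. Without an annotation multimap, the feature ids are
    taken to be geneset-member identifiers themselves. Genesets with empty
    support are dropped (logged); zero surviving genesets is fatal.
    """
    if not feature_ids:
        raise ValueError("feature_ids must be non-empty")
    rows: list[int] = []
    cols: list[int] = []
    kept_names: list[str] = []
    dropped: list[str] = []
    for name, _, members in genesets.entries:
        support: list[int] = []
        for j, feat in enumerate(feature_ids):
            genes = annotation.get(feat, set()) if annotation is not None else {feat}
            if genes & members:
                support.append(j)
        if not support:
            dropped.append(name)
            continue
        i = len(kept_names)
        kept_names.append(name)
        rows.extend([i] * len(support))
        cols.extend(support)
    if not kept_names:
        raise ValueError("no geneset has non-empty support on these features")
    if dropped:
        logger.warning(
            "dropped %d geneset(s) with empty support: %s", len(dropped), dropped
        )
    matrix = sp.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)),
        shape=(len(kept_names), len(feature_ids)),
    )
    return MembershipMatrix(
        matrix=matrix,
        geneset_names=kept_names,
        feature_ids=list(feature_ids),
        dropped_names=dropped,
    )


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read an expression TSV: header = feature ids, first column = sample ids."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.isna().any().any():
        raise ValueError(f"{path}: expression matrix contains missing values")
    return ExpressionMatrix(
        values=frame.to_numpy(dtype=float),
        sample_ids=[str(s) for s in frame.index],
        feature_ids=[str(f) for f in frame.columns],
    )


def write_expression(X: ExpressionMatrix, path: str | Path) -> None:
    X.to_frame().to_csv(path, sep="\t", index_label="sample_id")


def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column TSV (sample_id, class) into a Series."""
    table = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if table.shape[1] < 2:
        raise ValueError(f"{path}: label table needs 2 columns (sample_id, class)")
    return pd.Series(table.iloc[:, 1].values, index=table.iloc[:, 0].values, name="class")


def write_labels(labels: pd.Series, path: str | Path) -> None:
    labels.to_frame().to_csv(path, sep="\t", header=False)


def _triplets(matrix: sp.csr_matrix) -> dict:
    coo = sp.coo_matrix(matrix)
    return {
        "shape": list(coo.shape),
        "row": coo.row.tolist(),
        "col": coo.col.tolist(),
        "data": coo.data.tolist(),
    }


def _from_triplets(block: dict) -> sp.csr_matrix:
    return sp.csr_matrix(
        (block["data"], (block["row"], block["col"])), shape=tuple(block["shape"])
    )


def save_model(model: PaslModel, path: str | Path) -> None:
    """Serialize a fitted model to a single JSON archive.

    The dictionary is stored as sparse triplets; floats survive the
    round-trip at full double precision (JSON shortest-repr encoding).
    """
    payload = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "hyper": model.hyper,
        "feature_ids": model.feature_ids,
        "mu": model.std.mu.tolist(),
        "sigma": model.std.sigma.tolist(),
        "covered": model.covered.astype(int).tolist(),
        "D1": _triplets(model.D1),
        "D2": _triplets(model.D2),
        "atom_meta": [
            {
                "name": m.name,
                "phase": m.phase,
                "geneset_name": m.geneset_name,
                "geneset_index": m.geneset_index,
                "component_rank": m.component_rank,
                "variance_removed": m.variance_removed,
            }
            for m in model.atom_meta
        ],
        "ledger": {
            "order": model.ledger.order,
            "expected": model.ledger.expected,
            "component": model.ledger.component,
            "actual": model.ledger.actual,
            "reevaluations": model.ledger.reevaluations,
            "lam": model.ledger.lam,
            "t": model.ledger.t,
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path: str | Path) -> PaslModel:
    """Load a model archive written by :func:`save_model`."""
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: truncated or corrupt model archive") from exc
    version = payload.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise ValueError(
            f"{path}: model schema version {version!r} "
            f"not supported (expected {MODEL_SCHEMA_VERSION})"
        )
    led = payload["ledger"]
    return PaslModel(
        D1=_from_triplets(payload["D1"]),
        D2=_from_triplets(payload["D2"]),
        std=StandardizationParams(
            mu=np.asarray(payload["mu"]), sigma=np.asarray(payload["sigma"])
        ),
        atom_meta=[AtomMeta(**m) for m in payload["atom_meta"]],
        hyper=payload["hyper"],
        ledger=VarianceLedger(
            order=led["order"],
            expected=led["expected"],
            component=led["component"],
            actual=led["actual"],
            reevaluations=led["reevaluations"],
            lam=led["lam"],
            t=led["t"],
        ),
        feature_ids=payload["feature_ids"],
        covered=np.asarray(payload["covered"], dtype=bool),
    )


def export_ledger(model: PaslModel, path: str | Path) -> None:
    """Write the per-atom variance ledger as TSV."""
    led = model.ledger
    rows = []
    for k in range(len(led.actual)):
        meta = model.atom_meta[k]
        rows.append(
            {
                "atom": k,
                "geneset": meta.geneset_name,
                "component_rank": led.component[k],
                "expected": led.expected[k],
                "actual": led.actual[k],
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
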
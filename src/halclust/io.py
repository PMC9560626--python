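"""Readers, writers and model persistence.

Input matrices come from CSV/TSV (RFC-4180, ``.`` decimal, header row) or
from FCS 3.0/3.1 flow-cytometry files (event data of named channels, read
without any transformation — scale transforms are explicit configuration,
not hidden I/O behavior).

A fitted model is persisted as a single versioned tar archive containing a
JSON manifest (schema version, config, seed, tree topology and scores) and
one joblib blob per internal node holding its classifier ensemble.  Loaders
refuse archives with a newer schema than they understand.
"""

from __future__ import annotations

import io as _io
import json
import logging
import tarfile
import time
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
import pandas as pd

from halclust.datasets import LabeledDataset
from halclust.embedding import Normalizer
from halclust.linkage import MergeTree, TreeNode

logger = logging.getLogger(__name__)

__all__ = ["read_matrix", "write_matrix", "read_fcs", "save_model", "load_model"]

SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# tabular input


def read_matrix(
    path,
    format: Optional[str] = None,
    feature_subset: Optional[Sequence[str]] = None,
    label_column: str = "label",
) -> LabeledDataset:
    """Read a numeric matrix (plus optional labels) from CSV, TSV or FCS.

    The format is inferred from the file suffix unless given.  For CSV/TSV
    a column named ``label`` (configurable) is split off as ground-truth
    labels; for FCS the named channels are read in the requested order.
    """
    path = Path(path)
    if format is None:
        format = {".csv": "csv", ".tsv": "tsv", ".txt": "tsv", ".fcs": "fcs"}.get(
            path.suffix.lower()
        )
        if format is None:
            raise ValueError(f"cannot infer format from suffix of {path.name!r}")
    if format == "fcs":
        names, data = read_fcs(path, channels=feature_subset)
        return LabeledDataset(X=data, y=None, meta={"features": names, "path": str(path)})
    sep = {"csv": ",", "tsv": "\t"}[format]
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    y = None
    if label_column in df.columns:
        y = df.pop(label_column).to_numpy(dtype=np.int64)
    if feature_subset is not None:
        missing = [c for c in feature_subset if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns {missing}; available: {list(df.columns)}")
        df = df[list(feature_subset)]
    bad = df.columns[~df.dtypes.map(lambda d: np.issubdtype(d, np.number))]
    if len(bad):
        raise ValueError(f"non-numeric column(s): {list(bad)}")
    return LabeledDataset(
        X=df.to_numpy(dtype=np.float64), y=y,
        meta={"features": list(df.columns), "path": str(path)},
    )


def write_matrix(path, X: np.ndarray, y: Optional[np.ndarray] = None,
                 feature_names: Optional[Sequence[str]] = None) -> None:
    """Write a matrix (and optional labels) as CSV with header ``f1..fD[,label]``."""
    X = np.asarray(X)
    names = list(feature_names) if feature_names is not None else [
        f"f{i + 1}" for i in range(X.shape[1])
    ]
    df = pd.DataFrame(X, columns=names)
    if y is not None:
        df["label"] = np.asarray(y)
    # 17 significant digits: doubles survive the text round trip bit-exactly
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# FCS 3.0 / 3.1


def read_fcs(path, channels: Optional[Sequence[str]] = None):
    """Read event data from an FCS 3.0/3.1 file.

    Returns ``(channel_names, data)`` with ``data`` of shape
    ``($TOT, n_channels)``.  Only floating-point data types (``$DATATYPE``
    F or D) in list mode are supported, which covers modern cytometer
    output.  No compensation or scale transform is applied.
    """
    raw = Path(path).read_bytes()
    version = raw[:6].decode("ascii", errors="replace")
    if not version.startswith("FCS3"):
        raise ValueError(f"unsupported FCS version {version!r} (need FCS3.0/3.1)")

    def _offset(lo: int, hi: int) -> int:
        return int(raw[lo:hi].decode("ascii").strip() or 0)

    text_start, text_end = _offset(10, 18), _offset(18, 26)
    data_start, data_end = _offset(26, 34), _offset(34, 42)
    text = raw[text_start : text_end + 1]
    delim = text[:1].decode("latin-1")
    parts = text.decode("latin-1").split(delim)[1:]
    kw = {parts[i].strip(): parts[i + 1] for i in range(0, len(parts) - 1, 2)}

    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    dtype_code = kw["$DATATYPE"].strip().upper()
    if dtype_code not in ("F", "D"):
        raise ValueError(f"unsupported $DATATYPE {dtype_code!r} (only F/D)")
    byteord = kw.get("$BYTEORD", "1,2,3,4").strip()
    little = byteord.startswith("1")
    base = np.dtype("f4" if dtype_code == "F" else "f8")
    dt = base.newbyteorder("<" if little else ">")
    names = [kw.get(f"$P{i}N", f"P{i}").strip() for i in range(1, n_par + 1)]

    if data_start == 0:
        data_start = int(kw["$BEGINDATA"])
        data_end = int(kw["$ENDDATA"])
    buf = raw[data_start : data_end + 1]
    n_values = n_par * n_tot
    data = np.frombuffer(buf[: n_values * dt.itemsize], dtype=dt).astype(np.float64)
    data = data.reshape(n_tot, n_par)
    if channels is not None:
        missing = [c for c in channels if c not in names]
        if missing:
            raise ValueError(f"channel(s) {missing} not found; available: {names}")
        cols = [names.index(c) for c in channels]
        return list(channels), data[:, cols]
    return names, data


# ---------------------------------------------------------------------------
# model persistence


def save_model(model, path) -> None:
    """Persist a fitted model as a versioned tar archive.

    The archive holds ``manifest.json`` (schema version, config, seed, tree
    topology with edge and cv scores, the normalizer) plus one joblib blob
    per internal tree node with the node's classifier ensemble.
    """
    tree: MergeTree = model.tree
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seed": getattr(model, "seed", None),
        "config": getattr(model, "config", None),
        "config_hash": getattr(model, "config_hash", None),
        "normalizer": {
            "means": model.normalizer.means.tolist(),
            "sds": model.normalizer.sds.tolist(),
            "floor": model.normalizer.floor,
        },
        "tree": {
            "root": tree.root,
            "leaves": list(tree.leaves),
            "nodes": [
                {
                    "id": n.id,
                    "children": list(n.children) if n.children else None,
                    "edge_score": n.edge_score,
                    "cv_score": n.cv_score,
                }
                for n in tree.nodes.values()
            ],
        },
    }
    with tarfile.open(path, "w") as tar:

        def _add(name: str, payload: bytes) -> None:
            info = tarfile.TarInfo(name)
            info.size = len(payload)
            tar.addfile(info, _io.BytesIO(payload))

        _add("manifest.json", json.dumps(manifest, indent=1).encode())
        for nid, node in tree.nodes.items():
            if node.ensemble is not None:
                buf = _io.BytesIO()
                joblib.dump(node.ensemble, buf)
                _add(f"nodes/{nid}.joblib", buf.getvalue())


class FittedModel:
    """Container binding a merge tree to its normalizer and provenance."""

    def __init__(self, tree: MergeTree, normalizer: Normalizer, config=None,
                 seed=None, config_hash=None, train_indices=None, train_labels=None):
        self.tree = tree
        self.normalizer = normalizer
        self.config = config
        self.seed = seed
        self.config_hash = config_hash
        # diagnostics: downsample rows used for training and their
        # pure-cluster labels (not persisted in the archive)
        self.train_indices = train_indices
        self.train_labels = train_labels


def load_model(path) -> FittedModel:
    """Load a model archive written by :func:`save_model`."""
    with tarfile.open(path, "r") as tar:
        manifest = json.loads(tar.extractfile("manifest.json").read())
        if manifest["schema_version"] > SCHEMA_VERSION:
            raise ValueError(
                f"model schema {manifest['schema_version']} is newer than "
                f"supported version {SCHEMA_VERSION}"
            )
        nodes = {}
        for rec in manifest["tree"]["nodes"]:
            nodes[rec["id"]] = TreeNode(
                id=rec["id"],
                children=tuple(rec["children"]) if rec["children"] else None,
                edge_score=rec["edge_score"],
                cv_score=rec["cv_score"],
            )
        for member in tar.getmembers():
            if member.name.startswith("nodes/"):
                nid = int(Path(member.name).stem)
                nodes[nid].ensemble = joblib.load(tar.extractfile(member))
    tree = MergeTree(nodes=nodes, root=manifest["tree"]["root"],
                     leaves=list(manifest["tree"]["leaves"]))
    norm = Normalizer(
        means=np.array(manifest["normalizer"]["means"]),
        sds=np.array(manifest["normalizer"]["sds"]),
        floor=manifest["normalizer"]["floor"],
    )
    return FittedModel(tree=tree, normalizer=norm, config=manifest.get("config"),
                       seed=manifest.get("seed"),
                       config_hash=manifest.get("config_hash"))
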
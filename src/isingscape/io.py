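"""Reading and writing networks, datasets and landscapes.

The canonical network format is a JSON document with keys ``labels``,
``thresholds``, ``weights`` (row-major), optional ``beta`` (default 1)
and a free-form ``metadata`` object.  Floats are serialized with
``repr`` (17 significant digits), so a write/read round trip
reproduces the network exactly.  A CSV pair (weights matrix +
thresholds table) is accepted as a secondary dialect for spreadsheet
interoperability.  Person-level data travel as RFC-4180 CSV with a
header row of node labels and one integer row per person; rows with
missing cells are dropped with a logged count.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import IsingNetwork
from .estimation import BinaryDataset, binarize

__all__ = [
    "read_data_csv",
    "read_network",
    "read_network_csv",
    "write_data_csv",
    "write_network",
]


class NetworkParseError(ValueError):
    """A network file failed validation; the message names the field."""


def write_network(network: IsingNetwork, path, metadata: dict | None = None) -> None:
    """Write a network as canonical JSON (exact round-trip precision)."""
    doc = {
        "labels": list(network.labels),
        "thresholds": [float(x) for x in network.thresholds],
        "weights": [[float(x) for x in row] for row in network.weights],
        "beta": float(network.beta),
        "metadata": metadata or {},
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


def read_network(path) -> IsingNetwork:
    """Read a network from canonical JSON; ``beta`` defaults to 1."""
    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise NetworkParseError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(doc, dict):
        raise NetworkParseError(f"{path}: expected a JSON object at top level")
    for key in ("labels", "thresholds", "weights"):
        if key not in doc:
            raise NetworkParseError(f"{path}: missing required field '{key}'")
    try:
        return IsingNetwork(
            labels=tuple(str(x) for x in doc["labels"]),
            thresholds=np.asarray(doc["thresholds"], dtype=float),
            weights=np.asarray(doc["weights"], dtype=float),
            beta=float(doc.get("beta", 1.0)),
        )
    except (TypeError, ValueError) as exc:
        raise NetworkParseError(f"{path}: {exc}") from exc


def read_network_metadata(path) -> dict:
    """Metadata object stored alongside a network JSON file."""
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    return doc.get("metadata", {}) if isinstance(doc, dict) else {}


def read_network_csv(weights_path, thresholds_path, beta: float = 1.0) -> IsingNetwork:
    """Read a network from a CSV pair.

    ``weights_path``: square matrix with node labels as header row
    (and optionally as an index column).  ``thresholds_path``: two
    columns ``label,threshold``, one row per node, same label order.
    """
    wdf = pd.read_csv(weights_path)
    if wdf.shape[1] == wdf.shape[0] + 1:  # first column is an index of labels
        wdf = wdf.set_index(wdf.columns[0])
    labels = tuple(str(c) for c in wdf.columns)
    if wdf.shape[0] != wdf.shape[1]:
        raise NetworkParseError(
            f"{weights_path}: weights matrix is {wdf.shape[0]}x{wdf.shape[1]}, "
            "expected square"
        )
    tdf = pd.read_csv(thresholds_path)
    if "label" not in tdf.columns or "threshold" not in tdf.columns:
        raise NetworkParseError(
            f"{thresholds_path}: expected columns 'label' and 'threshold'"
        )
    tlabels = tuple(str(x) for x in tdf["label"])
    if tlabels != labels:
        raise NetworkParseError(
            f"{thresholds_path}: threshold labels {tlabels} do not match "
            f"weight-matrix labels {labels}"
        )
    try:
        return IsingNetwork(
            labels=labels,
            thresholds=tdf["threshold"].to_numpy(dtype=float),
            weights=wdf.to_numpy(dtype=float),
            beta=beta,
        )
    except (TypeError, ValueError) as exc:
        raise NetworkParseError(f"{weights_path}: {exc}") from exc


def read_data_csv(path, binarize_threshold: float | None = None) -> BinaryDataset:
    """Read a persons x nodes dataset from CSV (header row required).

    Rows containing missing cells are dropped (the count is reported
    via a warning).  With ``binarize_threshold`` set, ordinal values
    are recoded to presence/absence; otherwise entries must already be
    0/1.
    """
    df = pd.read_csv(path)
    n_before = df.shape[0]
    df = df.dropna()
    dropped = n_before - df.shape[0]
    if dropped:
        warnings.warn(
            f"{path}: dropped {dropped} rows with missing cells",
            UserWarning,
            stacklevel=2,
        )
    labels = tuple(str(c) for c in df.columns)
    values = df.to_numpy(dtype=float)
    if binarize_threshold is not None:
        return binarize(values, threshold=binarize_threshold, labels=labels)
    try:
        return BinaryDataset(values=values.astype(np.int8), labels=labels)
    except ValueError as exc:
        raise ValueError(
            f"{path}: {exc} (pass a binarize threshold for ordinal data)"
        ) from exc


def write_data_csv(dataset: BinaryDataset, path) -> None:
    """Write a dataset as CSV in the dialect read_data_csv expects."""
    pd.DataFrame(dataset.values, columns=list(dataset.labels)).to_csv(
        path, index=False
    )
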
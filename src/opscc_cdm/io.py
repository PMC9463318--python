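"""Serialization: patient CSV, model JSON, recipe YAML, XDSL export.

The CSV convention mirrors clinical data extraction: column names and cell
values must match the model's node and state names exactly
(case-sensitive); comma-separated, UTF-8, mandatory header, no quoting
(state labels may not contain commas).  Model documents are JSON with full-
precision probabilities and are lossless round-trippers.  XDSL (the XML
dialect of the GeNIe/SMILE modelling ecosystem) is supported export-only,
for loading a model into the reference modeller.
"""

from __future__ import annotations

import json
import logging
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .model import (
    CPT,
    LOAD_RENORM_TOL,
    PROB_TOL,
    BayesianNetwork,
    DiscreteVariable,
    ModelError,
)
from .learning import DataError, PatientDataset

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# patient datasets (CSV)
# ---------------------------------------------------------------------------


def read_dataset_csv(path: str | Path, network: BayesianNetwork) -> PatientDataset:
    """Read and validate a patient-record CSV against the model.

    Every column must name a model variable and every cell a legal state of
    that variable; violations are reported with (row, column) coordinates.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in df.columns:
        empty = df[col] == ""
        if empty.any():
            row = int(np.flatnonzero(empty.to_numpy())[0])
            raise DataError(f"empty cell at (row {row}, column {col!r})")
    dataset = PatientDataset(df, provenance="file")
    dataset.validate_against(network)
    logger.info(
        "read %d records x %d columns from %s", dataset.n_records,
        len(dataset.columns), path,
    )
    return dataset


def write_dataset_csv(dataset: PatientDataset, path: str | Path) -> None:
    for col in dataset.columns:
        if "," in col or dataset.df[col].astype(str).str.contains(",").any():
            raise DataError(f"column {col!r} contains a comma; not representable")
    dataset.df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# model documents (JSON)
# ---------------------------------------------------------------------------


def model_to_document(network: BayesianNetwork) -> dict:
    """Plain-JSON document for a network (schema version, variables, edges,
    CPT rows in declared state order, metadata)."""
    return {
        "schema_version": SCHEMA_VERSION,
        "metadata": dict(network.metadata),
        "variables": [
            {"name": v.name, "states": list(v.states), "role": v.role}
            for v in network.variables
        ],
        "edges": [list(e) for e in network.edges],
        "cpts": [
            {
                "child": name,
                "parents": list(cpt.parents),
                "rows": cpt.table.tolist(),
            }
            for name, cpt in network.cpts.items()
        ],
    }


def _require_field(doc: Mapping, name: str):
    if name not in doc:
        raise ModelError(f"model document missing field {name!r}")
    return doc[name]


def document_to_model(doc: Mapping) -> BayesianNetwork:
    """Validate a model document and build the network.

    CPT rows off normalisation by at most ``LOAD_RENORM_TOL`` are silently
    renormalised; anything worse is a load error naming the row.
    """
    version = _require_field(doc, "schema_version")
    if version != SCHEMA_VERSION:
        raise ModelError(f"unsupported schema_version {version!r}")
    variables = [
        DiscreteVariable(
            _require_field(v, "name"),
            tuple(_require_field(v, "states")),
            v.get("role", "diagnostic"),
        )
        for v in _require_field(doc, "variables")
    ]
    cpts: dict[str, CPT] = {}
    for entry in _require_field(doc, "cpts"):
        child = _require_field(entry, "child")
        table = np.asarray(_require_field(entry, "rows"), dtype=float)
        sums = table.sum(axis=1)
        off = np.abs(sums - 1.0)
        if (off > LOAD_RENORM_TOL).any():
            row = int(np.argmax(off))
            raise ModelError(
                f"cpts[{child!r}] row {row} sums to {sums[row]!r}; "
                f"off by more than {LOAD_RENORM_TOL}"
            )
        if (off > PROB_TOL).any():
            table = table / sums[:, None]
        cpts[child] = CPT(child, tuple(_require_field(entry, "parents")), table)
    net = BayesianNetwork(
        variables, cpts=cpts, metadata=doc.get("metadata", {})
    )
    declared = sorted(tuple(e) for e in _require_field(doc, "edges"))
    if declared != sorted(net.edges):
        raise ModelError("field 'edges' inconsistent with CPT parent lists")
    return net


def write_model_json(network: BayesianNetwork, path: str | Path) -> None:
    doc = model_to_document(network)
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


def read_model_json(path: str | Path) -> BayesianNetwork:
    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ModelError(f"not valid JSON: {path} ({exc})") from exc
    return document_to_model(doc)


# ---------------------------------------------------------------------------
# recipes (YAML)
# ---------------------------------------------------------------------------


def write_recipe_yaml(steps: Sequence[Mapping], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({"steps": [dict(s) for s in steps]}, fh, sort_keys=False)


def read_recipe_yaml(path: str | Path) -> list[dict]:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping) or "steps" not in doc:
        raise ModelError(f"recipe file {path} lacks a 'steps' list")
    return [dict(s) for s in doc["steps"]]


# ---------------------------------------------------------------------------
# XDSL export
# ---------------------------------------------------------------------------


def _xdsl_id(label: str) -> str:
    out = "".join(c if c.isalnum() or c == "_" else "_" for c in label)
    if not out or not (out[0].isalpha() or out[0] == "_"):
        out = "s" + out
    return out


def export_xdsl(network: BayesianNetwork, path: str | Path) -> None:
    """Write a minimal XDSL-dialect XML file (export-only).

    One ``cpt`` element per node with ``state`` children and a whitespace-
    separated probability list in row-major parent order, the flattening the
    reference modeller expects.  Submodels and layout are not emitted.
    """
    smile = ET.Element("smile", version="1.0", id=_xdsl_id(
        network.metadata.get("title", "network")
    ))
    nodes = ET.SubElement(smile, "nodes")
    for name in network.topological_order():
        var = network.variable(name)
        cpt = network.cpt(name)
        el = ET.SubElement(nodes, "cpt", id=_xdsl_id(name))
        for s in var.states:
            ET.SubElement(el, "state", id=_xdsl_id(s))
        if cpt.parents:
            parents_el = ET.SubElement(el, "parents")
            parents_el.text = " ".join(_xdsl_id(p) for p in cpt.parents)
        probs = ET.SubElement(el, "probabilities")
        probs.text = " ".join(repr(float(x)) for x in cpt.table.ravel())
    ET.SubElement(smile, "extensions")
    tree = ET.ElementTree(smile)
    ET.indent(tree)
    tree.write(path, encoding="utf-8", xml_declaration=True)
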
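"""Readers and writers for the plain-text formats the pipeline exchanges.

Expression matrices travel as TSV (first column = feature id, header =
sample ids) or GCT 1.2; annotations and probe maps as TSV; ORR tables and
reports as JSON; configurations as YAML.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import pandas as pd
import yaml

FLOAT_FORMAT = "%.6g"


def read_matrix(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() == ".gct":
        return read_gct(path)
    m = pd.read_csv(path, sep="\t", index_col=0)
    return m


def write_matrix(matrix: pd.DataFrame, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".gct":
        write_gct(matrix, path)
        return
    matrix.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_gct(path) -> pd.DataFrame:
    """Read a GCT 1.2 file (feature id in column 1, description dropped)."""
    with open(path) as fh:
        version = fh.readline().strip()
        if not version.startswith("#1.2"):
            raise ValueError(f"unsupported GCT version line: {version!r}")
        fh.readline()  # dimensions; trusted from the table itself
        df = pd.read_csv(fh, sep="\t", index_col=0)
    return df.drop(columns=["Description"], errors="ignore")


def write_gct(matrix: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{matrix.shape[0]}\t{matrix.shape[1]}\n")
        out = matrix.copy()
        out.insert(0, "Description", "na")
        out.index.name = "Name"
        out.to_csv(fh, sep="\t", float_format=FLOAT_FORMAT)


def read_annotation(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, dtype=str)


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t")


def read_probe_map(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0], name="gene")


def write_probe_map(probe_map: pd.Series, path) -> None:
    df = pd.DataFrame({"probe_id": probe_map.index, "gene_symbol": probe_map.to_numpy()})
    df.to_csv(path, sep="\t", index=False)


def read_orr_table(path) -> dict[str, float]:
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            return {k: float(v) for k, v in json.load(fh).items()}
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1].astype(float)))


def write_json(obj, path) -> None:
    if is_dataclass(obj) and not isinstance(obj, type):
        obj = asdict(obj)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(x):
    if hasattr(x, "item"):
        return x.item()
    if hasattr(x, "to_dict"):
        return x.to_dict()
    if isinstance(x, (set, frozenset, tuple)):
        return list(x)
    return str(x)


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_yaml(obj, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
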
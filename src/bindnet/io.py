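"""Plain-text table IO: labeled square matrices, tidy tables, edge lists.

All formats are tab-separated text. Floats are written with 17 significant
digits so every round-trip is bit-exact.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "write_matrix",
    "read_matrix",
    "write_table",
    "read_table",
    "write_edge_list",
    "read_edge_list",
    "mask_to_edge_list",
    "edge_list_to_mask",
]

_FLOAT_FMT = "%.17g"


class ParseError(ValueError):
    """Malformed delimited text; message names the offending line."""


def write_matrix(path, matrix: np.ndarray, labels: list[str]) -> None:
    """Write a labeled square matrix as TSV with a header row and label column."""
    matrix = np.asarray(matrix)
    n = matrix.shape[0]
    if matrix.shape != (n, n) or len(labels) != n:
        raise ValueError("matrix must be square with one label per row")
    with open(path, "w") as fh:
        fh.write("\t".join(["region", *labels]) + "\n")
        for lab, row in zip(labels, matrix):
            cells = "\t".join(_FLOAT_FMT % v for v in row.astype(float))
            fh.write(f"{lab}\t{cells}\n")


def read_matrix(path) -> tuple[np.ndarray, list[str]]:
    """Read a labeled square TSV matrix; errors name the offending line."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    labels = header[1:]
    n = len(labels)
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != n + 1:
            raise ParseError(f"{path}: line {lineno}: expected {n + 1} fields, got {len(parts)}")
        if parts[0] != labels[len(rows)]:
            raise ParseError(
                f"{path}: line {lineno}: row label {parts[0]!r} does not match "
                f"column label {labels[len(rows)]!r}"
            )
        try:
            rows.append([float(v) for v in parts[1:]])
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: non-numeric cell ({exc})") from None
    if len(rows) != n:
        raise ParseError(f"{path}: expected {n} data rows, found {len(rows)}")
    return np.array(rows), labels


def write_table(path, table: pd.DataFrame) -> None:
    """Write a tidy table as TSV at full float precision."""
    table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_table(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from None


def mask_to_edge_list(mask: np.ndarray, weights: np.ndarray | None = None) -> pd.DataFrame:
    """Upper-triangle edges (i < j, 0-based) of a boolean adjacency mask."""
    mask = np.asarray(mask, dtype=bool)
    iu, ju = np.triu_indices(mask.shape[0], 1)
    keep = mask[iu, ju]
    out = pd.DataFrame({"node_i": iu[keep], "node_j": ju[keep]})
    out["weight"] = weights[iu, ju][keep] if weights is not None else 1.0
    return out


def edge_list_to_mask(edges: pd.DataFrame, n_nodes: int) -> np.ndarray:
    mask = np.zeros((n_nodes, n_nodes), dtype=bool)
    i = edges["node_i"].to_numpy(dtype=int)
    j = edges["node_j"].to_numpy(dtype=int)
    if (i >= n_nodes).any() or (j >= n_nodes).any() or (i < 0).any() or (j < 0).any():
        raise ParseError("edge list references nodes outside the parcellation")
    mask[i, j] = mask[j, i] = True
    return mask


def write_edge_list(path, mask: np.ndarray, weights: np.ndarray | None = None) -> None:
    write_table(path, mask_to_edge_list(mask, weights))


def read_edge_list(path, n_nodes: int) -> np.ndarray:
    return edge_list_to_mask(read_table(path), n_nodes)
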
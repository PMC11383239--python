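"""Reading and writing the delimited-text formats of the pipeline.

View tables are TSV/CSV files with a header of variable names and a
first column of sample IDs. Output tables (stability paths, scores,
contribution matrices) are TSV with floats at 10 significant digits;
structured results (selections, run manifests) are JSON. Lines starting
with ``#`` in input tables are treated as comments, which is how output
files embed their run seed and configuration hash without breaking
round-trips.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .solvers import CanonicalModel
from .stability import SelectionResult, StabilityPath
from .views import ViewMatrix

__all__ = [
    "read_view_table",
    "read_labels",
    "align_views",
    "write_view_table",
    "write_scores",
    "write_stability_path",
    "selection_to_dict",
    "write_selection",
    "write_contributions",
]

FLOAT_FMT = "%.10g"


def _sep_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_view_table(path, sep: str | None = None) -> ViewMatrix:
    """Read a samples x variables table (first column = sample IDs).

    The delimiter is inferred from the extension (``.csv`` -> comma,
    anything else -> tab) unless given. Non-numeric cells raise with
    their row/column location.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep), index_col=0, comment="#")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            row = bad[0] if len(bad) else df.index[df[col].isna()][0]
            raise ValueError(
                f"non-numeric cell in {path.name} at row {row!r}, column {col!r}"
            )
    if df.isna().any().any():
        raise ValueError(f"missing values in {path.name}")
    return ViewMatrix(
        df.to_numpy(dtype=float),
        [str(c) for c in df.columns],
        [str(i) for i in df.index],
    )


def read_labels(path, sep: str | None = None) -> dict[str, str]:
    """Read a two-column (sample_id, label) table into a dict."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep), comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"label file {path.name} needs two columns")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def align_views(vx: ViewMatrix, vy: ViewMatrix) -> tuple[ViewMatrix, ViewMatrix]:
    """Align two views on their shared sample IDs, first-view order.

    Samples present in only one view are dropped (and reported); fewer
    than 2 shared samples is an error.
    """
    ids_y = {s: i for i, s in enumerate(vy.sample_ids)}
    shared = [s for s in vx.sample_ids if s in ids_y]
    if len(shared) < 2:
        raise ValueError(
            f"only {len(shared)} shared sample ID(s) between the views"
        )
    dropped_x = len(vx.sample_ids) - len(shared)
    dropped_y = len(vy.sample_ids) - len(shared)
    if dropped_x or dropped_y:
        import warnings

        warnings.warn(
            f"dropped unmatched samples: {dropped_x} from view 1, "
            f"{dropped_y} from view 2",
            UserWarning,
            stacklevel=2,
        )
    ix = [vx.sample_ids.index(s) for s in shared]
    iy = [ids_y[s] for s in shared]
    return (
        ViewMatrix(vx.values[ix], list(vx.variable_names), shared),
        ViewMatrix(vy.values[iy], list(vy.variable_names), shared),
    )


def _write_df(df: pd.DataFrame, path, sep: str, header_comment: str | None):
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep=sep, float_format=FLOAT_FMT)


def write_view_table(view: ViewMatrix, path, sep: str | None = None,
                     header_comment: str | None = None) -> None:
    path = Path(path)
    df = pd.DataFrame(view.values, index=view.sample_ids, columns=view.variable_names)
    df.index.name = "sample_id"
    _write_df(df, path, _sep_for(path, sep), header_comment)


def write_scores(names_x, scores_x, names_y, scores_y, path,
                 header_comment: str | None = None) -> None:
    """Two-column (variable, score) TSV over both views, X first."""
    df = pd.DataFrame(
        {
            "variable": list(names_x) + list(names_y),
            "view": ["X"] * len(names_x) + ["Y"] * len(names_y),
            "score": np.concatenate([np.asarray(scores_x), np.asarray(scores_y)]),
        }
    ).set_index("variable")
    _write_df(df, path, "\t", header_comment)


def write_stability_path(spath: StabilityPath, names_x, names_y, path,
                         header_comment: str | None = None) -> None:
    """Wide TSV: rows = grid index with (c_x, c_y), columns = variables."""
    df = pd.DataFrame(
        np.hstack([spath.p_x_probs, spath.p_y_probs]),
        columns=list(names_x) + list(names_y),
    )
    df.insert(0, "c_y", spath.grid.c_y)
    df.insert(0, "c_x", spath.grid.c_x)
    df.index.name = "grid_index"
    _write_df(df, path, "\t", header_comment)


def selection_to_dict(result: SelectionResult) -> dict:
    m = result.refit
    return {
        "strategy": result.strategy,
        "hyperparameter": result.hyperparameter,
        "selected_x_indices": [int(i) for i in result.selected_x],
        "selected_y_indices": [int(i) for i in result.selected_y],
        "selected_x_names": list(result.names_x),
        "selected_y_names": list(result.names_y),
        "refit": {
            "a": [float(v) for v in m.a],
            "b": [float(v) for v in m.b],
            "correlation": float(m.correlation),
            "method": m.method,
            "converged": bool(m.converged),
        },
    }


def write_selection(result: SelectionResult, path, extra: dict | None = None) -> None:
    payload = selection_to_dict(result)
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_contributions(contrib, path, header_comment: str | None = None) -> None:
    df = pd.DataFrame(contrib.values, index=contrib.row_names,
                      columns=contrib.col_names)
    df.index.name = "variable"
    _write_df(df, path, "\t", header_comment)


def model_from_dict(d: dict) -> CanonicalModel:
    """Rebuild a refitted model from a selection JSON payload."""
    m = d["refit"]
    return CanonicalModel(
        np.asarray(m["a"], dtype=float),
        np.asarray(m["b"], dtype=float),
        float(m["correlation"]),
        m.get("method", "pmd"),
        0,
        bool(m.get("converged", True)),
    )
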
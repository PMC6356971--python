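"""Reading and writing the package's delimited-text formats.

Views are CSV/TSV numeric matrices with the instance id in the first column
and feature names in the header row.  Labels and clusterings are TSV with
the instance id first.  The delimiter is taken from the file extension
(``.tsv``/``.txt`` = tab, otherwise comma).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .ensemble import DataView, Ensemble, ensemble_from_label_table
from .errors import ParameterError, ViewAlignmentError

__all__ = [
    "load_view",
    "load_views",
    "write_labels",
    "load_labels",
    "load_clusterings_table",
    "write_clusterings_table",
]


def _sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","


def load_view(path, view_name: str | None = None) -> DataView:
    """Load one instance-by-feature matrix; rejects missing values."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    if df.isna().any().any():
        raise ParameterError(f"{path} contains missing values; impute or drop them first")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as err:
        raise ParameterError(f"{path} contains non-numeric entries") from err
    return DataView(
        values=values,
        instance_ids=[str(i) for i in df.index],
        view_name=view_name or path.stem,
    )


def load_views(paths) -> list[DataView]:
    """Load several views and verify identical instance id order."""
    views = [load_view(p) for p in paths]
    ref = views[0].instance_ids
    for v in views[1:]:
        if v.instance_ids != ref:
            raise ViewAlignmentError(
                f"view {v.view_name!r} instance ids differ from {views[0].view_name!r}; "
                "views must list the same instances in the same order"
            )
    return views


def write_labels(path, instance_ids: list[str], labels: np.ndarray) -> None:
    pd.DataFrame({"instance_id": instance_ids, "label": np.asarray(labels, dtype=int)}).to_csv(
        path, sep="\t", index=False
    )


def load_labels(path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    if not {"instance_id", "label"} <= set(df.columns):
        raise ParameterError(f"{path} must have columns instance_id and label")
    return [str(i) for i in df["instance_id"]], df["label"].to_numpy(dtype=int)


def load_clusterings_table(path) -> tuple[list[str], Ensemble]:
    """Load precomputed base clusterings: one column per clustering."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    if df.shape[1] < 2:
        raise ParameterError("a clusterings table needs at least 2 clustering columns")
    return [str(i) for i in df.index], ensemble_from_label_table(df.to_numpy(dtype=int))


def write_clusterings_table(path, instance_ids: list[str], ensemble: Ensemble) -> None:
    data = {f"clustering{m}": c.labels for m, c in enumerate(ensemble.clusterings)}
    pd.DataFrame(data, index=pd.Index(instance_ids, name="instance_id")).to_csv(path, sep="\t")
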
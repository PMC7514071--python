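"""Tabular input/output for two-group data and results."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ImpactResult, LabeledSample

logger = logging.getLogger("impactsize")

__all__ = ["read_two_group_table", "write_labeled_sample_csv", "write_result_json"]


def read_two_group_table(
    path,
    value_col: str = "value",
    class_col: str = "group",
    delimiter: str | None = None,
    order: str = "sorted",
    levels=None,
) -> LabeledSample:
    """Read a delimited table into a validated :class:`LabeledSample`.

    The delimiter is sniffed unless given explicitly.  Rows with missing
    values in either column are dropped (and counted in the log).  The
    class column must have exactly two levels after dropping; by default
    they are mapped to (X1, X2) in sorted order — the sign of Impact
    depends on this, so ``levels`` can override the assignment.
    """
    path = Path(path)
    if delimiter is None:
        df = pd.read_csv(path, sep=None, engine="python")
    else:
        df = pd.read_csv(path, sep=delimiter)
    for col in (value_col, class_col):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path} (have {list(df.columns)})")
    sub = df[[value_col, class_col]]
    kept = sub.dropna()
    dropped = len(sub) - len(kept)
    if dropped:
        logger.warning("dropped %d row(s) with missing values from %s", dropped, path)

    raw = kept[value_col]
    numeric = pd.to_numeric(raw, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.any():
        idx = list(kept.index[bad][:5])
        raise ValueError(f"non-numeric value(s) in column {value_col!r} at row index {idx}")

    found = pd.unique(kept[class_col])
    if len(found) != 2:
        raise ValueError(
            f"class column {class_col!r} must have exactly 2 levels, "
            f"found {len(found)}: {sorted(map(str, found))}")
    sample = LabeledSample.from_arrays(numeric.to_numpy(), kept[class_col].to_numpy(),
                                       levels=levels, order=order)
    logger.info("read %d rows from %s: groups %r (n=%d) and %r (n=%d)",
                len(kept), path, sample.levels[0], sample.x1.size,
                sample.levels[1], sample.x2.size)
    return sample


def write_labeled_sample_csv(sample: LabeledSample, path) -> None:
    """Write a sample as a two-column CSV (value, group)."""
    pd.DataFrame({"value": sample.values, "group": sample.labels}).to_csv(path, index=False)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_result_json(result: ImpactResult, path, extra: dict | None = None) -> dict:
    """Serialize an ImpactResult (plus optional extras) as JSON.

    Floats are written with full repr precision, so reading the file back
    reproduces every numeric field exactly.
    """
    payload = {k: _jsonable(v) for k, v in result.to_dict().items()}
    if extra:
        payload.update({k: _jsonable(v) for k, v in extra.items()})
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
    return payload
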
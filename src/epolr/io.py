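"""Tabular input/output for cohort data and analysis results."""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd

from .model import CohortTable

log = logging.getLogger("epolr")

__all__ = ["read_cohort_csv", "write_results"]


def read_cohort_csv(path, *, outcome: str, baseline: str, arm: str,
                    stratum: Optional[str] = None,
                    k_max: Optional[int] = None) -> CohortTable:
    """Read and validate a per-subject cohort from a delimited text file.

    Rows with missing values in the analysis columns are dropped (with a
    logged count); scores are coerced to integers and, when ``k_max`` is
    given, range-checked against the declared scale.
    """
    df = pd.read_csv(path)
    cols = [outcome, baseline, arm] + ([stratum] if stratum else [])
    for c in cols:
        if c not in df.columns:
            raise KeyError(f"column {c!r} not found in {path}; "
                           f"available: {list(df.columns)}")
    n0 = len(df)
    df = df.dropna(subset=cols)
    if len(df) < n0:
        log.warning("dropped %d row(s) with missing analysis fields",
                    n0 - len(df))
    if k_max is not None:
        bad = df.index[(df[outcome] < 0) | (df[outcome] > k_max)]
        if len(bad):
            raise ValueError(
                f"outcome out of range 0..{k_max} in rows {list(bad[:10])}")
    return CohortTable.from_frame(df, outcome=outcome, baseline=baseline,
                                  arm=arm, stratum=stratum)


def _round_floats(obj, ndigits: int):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def write_results(results, path, fmt: str = "json", *,
                  metadata: Optional[dict] = None, ndigits: int = 4) -> None:
    """Write analysis results deterministically as JSON or CSV.

    ``results`` is a mapping (JSON) or a DataFrame (CSV).  A metadata block
    (seed, config echo) is embedded in JSON output or written as a ``#``
    header line in CSV output.
    """
    path = Path(path)
    if fmt == "json":
        payload = {"results": _round_floats(results, ndigits)}
        if metadata:
            payload["metadata"] = metadata
        path.write_text(json.dumps(payload, indent=2, sort_keys=True,
                                   default=str) + "\n")
    elif fmt == "csv":
        df = results if isinstance(results, pd.DataFrame) \
            else pd.DataFrame(results)
        with path.open("w") as fh:
            if metadata:
                fh.write("# " + json.dumps(metadata, sort_keys=True,
                                           default=str) + "\n")
            df.round(ndigits).to_csv(fh, index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}")
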
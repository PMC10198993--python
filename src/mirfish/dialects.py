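"""Readers for the four predictor export dialects.

Each tool names its columns differently; the mapping lives in a packaged
YAML file (``data/tool_columns.yaml``) so a header change upstream is a
config edit, not a code change.
"""

from __future__ import annotations

import math
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .consensus import PredictionRecord

_SCORE_FIELDS = ("p_value", "prediction_score", "mitg_score", "context_plus", "pct")


def load_column_mapping(path: str | Path | None = None) -> dict:
    """The tool -> {field: column} mapping (packaged default, or a YAML file)."""
    if path is None:
        text = (
            resources.files("mirfish.data").joinpath("tool_columns.yaml").read_text()
        )
    else:
        text = Path(path).read_text()
    return yaml.safe_load(text)


def read_prediction_table(
    path: str | Path,
    tool: str,
    mapping: dict | None = None,
) -> list[PredictionRecord]:
    """Parse one tool's export (CSV or TSV, sniffed) into PredictionRecords."""
    if mapping is None:
        mapping = load_column_mapping()
    if tool not in mapping:
        raise ValueError(f"no column mapping for tool {tool!r}")
    columns = mapping[tool]
    frame = pd.read_csv(path, sep=None, engine="python")
    records = []
    for _, row in frame.iterrows():
        scores = {}
        for f in _SCORE_FIELDS:
            col = columns.get(f)
            if col is not None and col in frame.columns:
                value = row[col]
                if value is not None and not (isinstance(value, float) and math.isnan(value)):
                    scores[f] = float(value)

        def _pos(field):
            col = columns.get(field)
            if col is None or col not in frame.columns:
                return None
            value = row[col]
            if value is None or (isinstance(value, float) and math.isnan(value)):
                return None
            return int(value)

        records.append(
            PredictionRecord(
                tool=tool,
                mirna=str(row[columns["mirna"]]),
                gene=str(row[columns["gene"]]),
                scores=scores,
                site_start=_pos("site_start"),
                site_end=_pos("site_end"),
            )
        )
    return records
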
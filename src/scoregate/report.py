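"""Report rendering: per-class rate tables with Mean / SD footer rows.

Reports mirror the usual layout of per-species benchmark tables: one body
row per class, then an unweighted ``Mean`` row and a sample-standard-
deviation row across classes.  Undefined cells (a class whose accuracy
has no kept predictions) render as ``NA`` and are excluded from the
footer statistics, with the exclusion count noted.

Rates are stored on [0, 1]; the ``percent`` display scale multiplies them
by 100 for easier reading, matching common reporting practice.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .errors import ScoregateError
from .rates import summarize

_FORMATS = ("csv", "json", "markdown")
_MEAN_ROW = "Mean"
_SD_ROW = "Standard Deviation"
_CELL_FMT = "{:.6g}"


def _footer(per_class: pd.DataFrame) -> pd.DataFrame:
    means, sds = {}, {}
    for col in per_class.columns:
        vals = per_class[col].dropna().to_numpy(dtype=float)
        if vals.size:
            means[col], sds[col] = summarize(vals)
        else:
            means[col] = sds[col] = np.nan
    return pd.DataFrame([means, sds], index=[_MEAN_ROW, _SD_ROW])


def build_report_frame(per_class: pd.DataFrame, scale: str = "unit") -> pd.DataFrame:
    """Body rows plus Mean / Standard Deviation footer, optionally in percent.

    Accuracy columns stay on [0, 1] even under the percent scale — they
    are conventionally reported as proportions, rates as percentages.
    """
    if scale not in ("unit", "percent"):
        raise ScoregateError(f"unknown scale {scale!r}")
    frame = per_class.copy().astype(float)
    if scale == "percent":
        rate_cols = [c for c in frame.columns if "accuracy" not in c]
        frame[rate_cols] = frame[rate_cols] * 100.0
    out = pd.concat([frame, _footer(frame)])
    out.index.name = "class"
    return out


def render_report(per_class: pd.DataFrame, fmt: str = "csv", scale: str = "unit") -> str:
    """Render a report as csv, json or markdown with identical numeric content."""
    if fmt not in _FORMATS:
        raise ScoregateError(f"unknown report format {fmt!r}")
    frame = build_report_frame(per_class, scale=scale)
    n_undef = int(per_class.isna().to_numpy().sum())
    if fmt == "csv":
        text = frame.to_csv(na_rep="NA", float_format="%.6g")
        if n_undef:
            text += f"# NA cells excluded from Mean/SD: {n_undef}\n"
        return text
    if fmt == "json":
        payload = {
            "rows": {
                str(idx): {c: (None if pd.isna(v) else float(f"{v:.6g}")) for c, v in row.items()}
                for idx, row in frame.iterrows()
            },
            "na_cells_excluded": n_undef,
            "scale": scale,
        }
        return json.dumps(payload, indent=2) + "\n"
    # markdown
    cols = list(frame.columns)
    lines = ["| class | " + " | ".join(cols) + " |",
             "| --- | " + " | ".join("---" for _ in cols) + " |"]
    for idx, row in frame.iterrows():
        cells = ["NA" if pd.isna(v) else _CELL_FMT.format(v) for v in row]
        lines.append(f"| {idx} | " + " | ".join(cells) + " |")
    if n_undef:
        lines.append(f"\nNA cells excluded from Mean/SD: {n_undef}")
    return "\n".join(lines) + "\n"
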
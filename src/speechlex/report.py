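"""Report tables: per-task feature means and the two-panel reliability/ITV
layout, with csv, json and markdown renderings."""

from __future__ import annotations

import json

import pandas as pd

from .corpus import TASKS, FeatureMatrix
from .errors import ValidationError
from .model import SpeechReliabilityResults

FORMATS = ("csv", "json", "markdown")


def feature_means_table(matrix: FeatureMatrix) -> pd.DataFrame:
    """Between-participant mean (SD) of each feature per task.

    Rows are features in matrix order, columns the five tasks, cells
    formatted ``mean (SD)``.
    """
    df = matrix.df
    stats = df.groupby(["feature_name", "task_id"], sort=False)["value"].agg(
        ["mean", "std"]
    )
    out = pd.DataFrame(index=list(matrix.feature_names), columns=list(TASKS),
                       dtype=object)
    for (feat, task), row in stats.iterrows():
        out.loc[feat, task] = f"{row['mean']:.2f} ({row['std']:.2f})"
    out.index.name = "feature"
    return out


def reliability_table(results: SpeechReliabilityResults) -> pd.DataFrame:
    """Two-panel layout: within-task-type reliabilities on top (one row per
    task type x group, one column per feature), the cross-task ITV panel
    below (one row per group)."""
    rel = results.reliability.pivot_table(
        index=["task_type", "group"], columns="feature_name", values="r_mean",
        sort=False,
    )
    rel.index = [f"{t}/{g}" for t, g in rel.index]
    itv = results.itv.pivot_table(
        index="group", columns="feature_name", values="itv", sort=False
    )
    itv.index = [f"itv/{g}" for g in itv.index]
    table = pd.concat([rel, itv])
    table.index.name = "panel"
    table.columns.name = None
    return table


def render(df: pd.DataFrame, fmt: str) -> str:
    if fmt == "csv":
        return df.to_csv()
    if fmt == "json":
        return json.dumps(
            {str(idx): {str(c): row[c] for c in df.columns}
             for idx, row in df.iterrows()},
            indent=2, default=float,
        )
    if fmt == "markdown":
        return render_markdown(df)
    raise ValidationError(f"unknown report format {fmt!r}; choose from {FORMATS}")


def render_markdown(df: pd.DataFrame) -> str:
    """Pipe-table rendering; numeric cells keep full repr precision so the
    table parses back losslessly."""
    index_name = df.index.name or "index"
    header = [index_name, *map(str, df.columns)]
    rows = [[repr(i) if not isinstance(i, str) else i, *(
        repr(v) if not isinstance(v, str) else v for v in row)]
        for i, row in zip(df.index, df.itertuples(index=False))]
    widths = [max(len(h), *(len(r[k]) for r in rows)) if rows else len(h)
              for k, h in enumerate(header)]
    def line(cells):
        return "| " + " | ".join(c.ljust(w) for c, w in zip(cells, widths)) + " |"
    out = [line(header), line(["-" * w for w in widths])]
    out += [line(r) for r in rows]
    return "\n".join(out) + "\n"


def parse_markdown(text: str) -> pd.DataFrame:
    """Parse a pipe table produced by :func:`render_markdown` back into a
    DataFrame (numbers via ``eval``-free literal parsing)."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if len(lines) < 2:
        raise ValidationError("not a markdown table")

    def split(ln: str) -> list[str]:
        return [c.strip() for c in ln.strip().strip("|").split("|")]

    header = split(lines[0])
    rows = [split(ln) for ln in lines[2:]]

    def coerce(cell: str):
        for cast in (int, float):
            try:
                return cast(cell)
            except ValueError:
                continue
        if cell == "nan":
            return float("nan")
        return cell

    data = [[coerce(c) for c in r] for r in rows]
    df = pd.DataFrame(data, columns=header).set_index(header[0])
    return df


def write_report(df: pd.DataFrame, path, fmt: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(render(df, fmt))
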
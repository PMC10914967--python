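"""Reading survey CSVs and writing pipeline reports.

Two entry points exist for input data: respondent-level answer pairs
(long or wide CSV) and pre-tabulated per-item category frequencies.
Answer cells that are missing or unparseable are excluded cell-wise (that
respondent's other items survive) and recorded in an exclusion log, never
imputed.  All CSVs are comma-separated UTF-8 with a header row.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .classification import ItemFrequencyTable
from .core import (
    AnswerPair,
    CATEGORIES,
    KanoCategory,
    RunConfig,
    SurveyDataset,
    parse_answer,
    round_half_away,
)
from .pipeline import PipelineResult


class EmptyDatasetError(ValueError):
    """No valid respondent remained after exclusions."""


@dataclass
class Exclusion:
    respondent_id: str
    item_id: str
    reason: str


@dataclass
class ReadResult:
    """Validated dataset plus the cell-wise exclusion log."""

    dataset: SurveyDataset
    exclusions: list[Exclusion] = field(default_factory=list)

    @property
    def n_excluded(self) -> int:
        return len(self.exclusions)


def _finish(items, responses, exclusions) -> ReadResult:
    dataset = SurveyDataset(items=items, responses=responses)
    if not responses:
        raise EmptyDatasetError("no valid answer pairs in input")
    return ReadResult(dataset=dataset, exclusions=exclusions)


def _is_missing(value) -> bool:
    return pd.isna(value) or (isinstance(value, str) and not value.strip())


def read_survey(path: str | Path, layout: str = "long") -> ReadResult:
    """Read a respondent-level survey CSV.

    Long layout: columns respondent_id, item_id, functional, dysfunctional
    (one answer pair per row).  Wide layout: one row per respondent, two
    columns per item named ``<item>_f`` and ``<item>_d``, plus an optional
    respondent_id column.  Answers may be integer codes 1-5 or labels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if layout == "long":
        return _read_long(path)
    if layout == "wide":
        return _read_wide(path)
    raise ValueError(f"unknown layout {layout!r} (expected 'long' or 'wide')")


def _read_long(path: Path) -> ReadResult:
    df = pd.read_csv(path, dtype=str)
    required = {"respondent_id", "item_id", "functional", "dysfunctional"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"long CSV missing columns: {sorted(missing)}")
    items: list[tuple[str, str]] = []
    seen_items: set[str] = set()
    responses: list[AnswerPair] = []
    exclusions: list[Exclusion] = []
    for row in df.itertuples(index=False):
        rid = str(row.respondent_id)
        iid = str(row.item_id)
        if iid not in seen_items:
            seen_items.add(iid)
            items.append((iid, iid))
        pair = _parse_cell(rid, iid, row.functional, row.dysfunctional, exclusions)
        if pair is not None:
            responses.append(pair)
    return _finish(items, responses, exclusions)


_WIDE_F = re.compile(r"^(?P<item>.+)_f$")


def _wide_item_columns(columns: Sequence[str]) -> list[tuple[str, str, str]]:
    out = []
    colset = set(columns)
    for col in columns:
        m = _WIDE_F.match(col)
        if m:
            d_col = f"{m.group('item')}_d"
            if d_col in colset:
                out.append((m.group("item"), col, d_col))
    if not out:
        raise ValueError("wide CSV has no <item>_f / <item>_d column pairs")
    return out


def _read_wide(path: Path) -> ReadResult:
    df = pd.read_csv(path, dtype=str)
    pairs = _wide_item_columns(list(df.columns))
    items = [(item, item) for item, _, _ in pairs]
    has_rid = "respondent_id" in df.columns
    responses: list[AnswerPair] = []
    exclusions: list[Exclusion] = []
    for idx, row in enumerate(df.to_dict(orient="records")):
        rid = str(row["respondent_id"]) if has_rid else f"r{idx + 1}"
        for item, f_col, d_col in pairs:
            pair = _parse_cell(rid, item, row[f_col], row[d_col], exclusions)
            if pair is not None:
                responses.append(pair)
    return _finish(items, responses, exclusions)


def _parse_cell(rid, iid, f_token, d_token, exclusions) -> AnswerPair | None:
    if _is_missing(f_token) or _is_missing(d_token):
        exclusions.append(Exclusion(rid, iid, "missing answer"))
        return None
    try:
        f = parse_answer(f_token)
        d = parse_answer(d_token)
    except ValueError as exc:
        exclusions.append(Exclusion(rid, iid, str(exc)))
        return None
    return AnswerPair(respondent_id=rid, item_id=iid, functional=f, dysfunctional=d)


def read_frequency_table(path: str | Path) -> list[ItemFrequencyTable]:
    """Read pre-tabulated per-item category counts.

    Expected columns: item_id, A, I, M, O, R, Q (non-negative integers);
    an optional label column is carried through.  The row total becomes
    the item's effective N.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    required = {"item_id"} | {c.value for c in CATEGORIES}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"frequency CSV missing columns: {sorted(missing)}")
    tables: list[ItemFrequencyTable] = []
    for row in df.to_dict(orient="records"):
        counts = {}
        for cat in CATEGORIES:
            raw = row[cat.value]
            value = float(raw)
            if value != int(value):
                raise ValueError(
                    f"item {row['item_id']}: non-integer count {raw!r} for {cat.value}"
                )
            if value < 0:
                raise ValueError(
                    f"item {row['item_id']}: negative count for {cat.value}"
                )
            counts[cat] = int(value)
        tables.append(
            ItemFrequencyTable(
                item_id=str(row["item_id"]),
                counts=counts,
                label=str(row.get("label", "") or ""),
            )
        )
    return tables


def read_wide_matrices(path: str | Path) -> tuple[np.ndarray, np.ndarray, int]:
    """Extract functional and dysfunctional item-response matrices.

    Reads a wide-layout CSV, keeps complete cases only (respondents with
    every answer present and parseable) and returns
    (functional matrix, dysfunctional matrix, n_complete), with items in
    column order.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    pairs = _wide_item_columns(list(df.columns))
    func_rows, dysf_rows = [], []
    for row in df.to_dict(orient="records"):
        try:
            f = [int(parse_answer(row[f_col])) for _, f_col, _ in pairs]
            d = [int(parse_answer(row[d_col])) for _, _, d_col in pairs]
        except ValueError:
            continue
        func_rows.append(f)
        dysf_rows.append(d)
    if not func_rows:
        raise EmptyDatasetError("no complete respondents in input")
    return np.array(func_rows, float), np.array(dysf_rows, float), len(func_rows)


def _fmt(value: float, decimals: int) -> str:
    return f"{round_half_away(value, decimals):.{decimals}f}"


def write_report(
    result: PipelineResult,
    outdir: str | Path,
    exclusions: Sequence[Exclusion] = (),
) -> dict[str, Path]:
    """Write the attribute table, influence table, matrix JSON and run log.

    Returns a name -> path map of the files written.  Numeric columns are
    rounded (half away from zero) at the configured display precision.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    d = cfg.decimals

    attr_path = outdir / "attributes.tsv"
    attr_rows = [
        {
            "item": a.item_id,
            "traditional": a.traditional.value,
            "CS": _fmt(a.cs, d),
            "TS": _fmt(a.ts, d),
            "optimized": a.optimized.label,
        }
        for a in result.attributes
    ]
    pd.DataFrame(
        attr_rows, columns=["item", "traditional", "CS", "TS", "optimized"]
    ).to_csv(attr_path, sep="\t", index=False)

    infl_path = outdir / "influence.tsv"
    infl_rows = [
        {"item": i.item_id, "SI": _fmt(i.si, d), "DSI": _fmt(i.dsi, d)}
        for i in result.influences
        if i.quadrant is not None
    ]
    pd.DataFrame(infl_rows, columns=["item", "SI", "DSI"]).to_csv(
        infl_path, sep="\t", index=False
    )

    matrix_path = outdir / "matrix.json"
    cd = cfg.centroid_decimals
    matrix = {
        "centroid": [
            round_half_away(result.centroid.si_mean, cd),
            round_half_away(result.centroid.dsi_abs_mean, cd),
        ],
        "items": [
            {
                "id": i.item_id,
                "si": round_half_away(i.si, d) if i.quadrant is not None else None,
                "dsi": round_half_away(i.dsi, d) if i.quadrant is not None else None,
                "quadrant": i.quadrant.value if i.quadrant is not None else None,
                "rank": i.priority_rank,
            }
            for i in result.influences
        ],
    }
    matrix_path.write_text(json.dumps(matrix, indent=2) + "\n")

    log_path = outdir / "run_log.txt"
    lines = [
        "kanokit run log",
        f"ts_threshold={cfg.ts_threshold}",
        f"cs_threshold={cfg.cs_threshold}",
        f"decimals={cfg.decimals}",
        f"centroid_decimals={cfg.centroid_decimals}",
        f"tie_break_order={''.join(c.value for c in cfg.tie_break_order)}",
        f"quadrant_convention={cfg.quadrant_convention}",
        f"seed={cfg.seed}",
        f"n_items={len(result.frequencies)}",
        f"n_exclusions={len(exclusions)}",
    ]
    lines += [
        f"excluded: respondent={e.respondent_id} item={e.item_id} reason={e.reason}"
        for e in exclusions
    ]
    log_path.write_text("\n".join(lines) + "\n")

    return {
        "attributes": attr_path,
        "influence": infl_path,
        "matrix": matrix_path,
        "run_log": log_path,
    }


def write_survey_long(dataset: SurveyDataset, path: str | Path) -> Path:
    """Write a SurveyDataset as a long-layout CSV (integer answer codes)."""
    path = Path(path)
    rows = [
        {
            "respondent_id": p.respondent_id,
            "item_id": p.item_id,
            "functional": int(p.functional),
            "dysfunctional": int(p.dysfunctional),
        }
        for p in dataset.responses
    ]
    pd.DataFrame(
        rows, columns=["respondent_id", "item_id", "functional", "dysfunctional"]
    ).to_csv(path, index=False)
    return path


def load_run_config(path: str | Path | None) -> RunConfig:
    """Build a RunConfig from a JSON file (missing keys keep defaults)."""
    if path is None:
        return RunConfig()
    data = json.loads(Path(path).read_text())
    if "tie_break_order" in data:
        data["tie_break_order"] = tuple(
            KanoCategory(c) for c in data["tie_break_order"]
        )
    return RunConfig(**data)
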
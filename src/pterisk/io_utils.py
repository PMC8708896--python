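"""CSV readers/writers and report rendering.

All tabular interchange is UTF-8, comma-delimited CSV with "." decimals.
Readers validate row by row and raise :class:`InputFormatError` carrying the
1-based data row number of the first offending cell, so a bad file fails
loudly and addressably rather than propagating NaNs.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .concentration_stats import POLLUTANTS, RECORD_COLUMNS, SEASONS
from .errors import InputFormatError
from .synthetic_data import SURVEY_COLUMNS

log = logging.getLogger(__name__)

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputFormatError(f"{path}: missing column(s) {missing}")


def _parse_bool(raw, row: int, path) -> bool:
    s = str(raw).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise InputFormatError(f"{path} row {row}: cannot parse censored flag {raw!r}")


def read_concentrations(path: str | Path) -> pd.DataFrame:
    """Load a long-format concentration file into the canonical frame.

    Expected header: ``site,season,day,element,value,censored``.  Unknown
    elements, unknown seasons, negative or non-numeric values are rejected
    with the offending row number.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, RECORD_COLUMNS, path)
    if df.empty:
        warnings.warn(f"{path}: no data rows", stacklevel=2)
        return pd.DataFrame(columns=RECORD_COLUMNS)

    out = []
    for i, rec in enumerate(df.to_dict("records"), start=1):
        element = rec["element"].strip()
        if element not in POLLUTANTS:
            raise InputFormatError(f"{path} row {i}: unknown element {element!r}")
        season = rec["season"].strip()
        if season not in SEASONS:
            raise InputFormatError(f"{path} row {i}: unknown season {season!r}")
        try:
            value = float(rec["value"])
            site = int(rec["site"])
            day = int(rec["day"])
        except ValueError as exc:
            raise InputFormatError(f"{path} row {i}: non-numeric field ({exc})") from None
        if value < 0:
            raise InputFormatError(f"{path} row {i}: negative value {value}")
        out.append({"site": site, "season": season, "day": day, "element": element,
                    "value": value, "censored": _parse_bool(rec["censored"], i, path)})
    return pd.DataFrame(out, columns=RECORD_COLUMNS)


def read_survey(path: str | Path) -> pd.DataFrame:
    """Load the exposure survey: ``id,group,bw_kg,ed_years,sa_cm2``.

    Enforces the study inclusion rule ED ≥ 1 year and positive body weight
    and skin area; duplicate ids are kept but suffixed, with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, SURVEY_COLUMNS, path)

    out = []
    for i, rec in enumerate(df.to_dict("records"), start=1):
        group = rec["group"].strip()
        if group not in ("adult", "child"):
            raise InputFormatError(f"{path} row {i}: unknown group {group!r}")
        try:
            bw = float(rec["bw_kg"])
            ed = float(rec["ed_years"])
            sa = float(rec["sa_cm2"])
        except ValueError as exc:
            raise InputFormatError(f"{path} row {i}: non-numeric field ({exc})") from None
        if bw <= 0:
            raise InputFormatError(f"{path} row {i}: body weight must be positive, got {bw}")
        if ed < 1:
            raise InputFormatError(
                f"{path} row {i}: exposure duration {ed} below the 1-year inclusion rule"
            )
        if sa <= 0:
            raise InputFormatError(f"{path} row {i}: skin area must be positive, got {sa}")
        out.append({"id": rec["id"].strip(), "group": group, "bw_kg": bw,
                    "ed_years": ed, "sa_cm2": sa})
    result = pd.DataFrame(out, columns=SURVEY_COLUMNS)

    dup = result["id"].duplicated(keep=False)
    if dup.any():
        warnings.warn(f"{path}: duplicate respondent ids; suffixing duplicates", stacklevel=2)
        counts: dict[str, int] = {}
        ids = []
        for rid in result["id"]:
            counts[rid] = counts.get(rid, 0) + 1
            ids.append(rid if counts[rid] == 1 else f"{rid}_{counts[rid]}")
        result["id"] = ids
    return result


def _format_sci(x) -> str:
    if isinstance(x, (int, np.integer)):
        return str(x)
    if isinstance(x, (float, np.floating)):
        if np.isnan(x):
            return "BDL"
        return f"{x:.3g}"
    return str(x)


def write_table(df: pd.DataFrame, csv_path: str | Path, text_path: str | Path | None = None,
                title: str | None = None) -> None:
    """Write a frame as CSV and, optionally, an aligned text table (3 sig. digits)."""
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    try:
        df.to_csv(csv_path, index=False)
    except OSError as exc:
        raise InputFormatError(f"cannot write {csv_path}: {exc}") from exc
    if text_path is not None:
        rendered = df.to_string(index=False, formatters={
            col: _format_sci for col in df.columns
        })
        body = (f"{title}\n\n{rendered}\n" if title else rendered + "\n")
        Path(text_path).write_text(body, encoding="utf-8")


def render_reports(outdir: str | Path, *, seasonal_summary=None, risk_tables=None,
                   mc_summaries=None, sensitivity=None) -> list[Path]:
    """Render whichever analysis products are supplied.

    ``risk_tables``/``mc_summaries`` are ``{label: DataFrame}`` mappings;
    each product is written as ``<name>.csv`` plus an aligned ``<name>.txt``.
    Returns the list of files written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(df, name, title):
        csv_path = outdir / f"{name}.csv"
        txt_path = outdir / f"{name}.txt"
        write_table(df.reset_index() if df.index.nlevels > 1 or df.index.name else df,
                    csv_path, txt_path, title)
        written.extend([csv_path, txt_path])

    if seasonal_summary is not None:
        emit(seasonal_summary, "seasonal_summary",
             "Element concentrations by season (ug/m3)")
    for label, table in (risk_tables or {}).items():
        emit(table, f"risk_{label}", f"Dose, hazard and cancer risk — {label}")
    for label, table in (mc_summaries or {}).items():
        emit(table, f"mc_{label}", f"Monte Carlo summary — {label}")
    if sensitivity is not None:
        emit(sensitivity, "sensitivity", "Contribution to variance (signed %, Σ|share| = 100)")
    for p in written:
        log.info("wrote %s", p)
    return written
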
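"""Readers for the plain-text table dialects used by the pipeline.

All inputs are UTF-8 TSV/CSV with a header row.  Assay tables are wide
(one row per extract, one column per cell line or pathogen) and use the
screening literature's cell conventions: ``-`` for no activity,
``mean ± sd`` for measured values, and ``<x`` / ``>x`` for censored
bounds.  ``(MBC)`` annotations on dilution endpoints are kept as a
boolean flag.
"""

from __future__ import annotations

import csv
import math
import re
from importlib.resources import files
from pathlib import Path
from typing import Mapping

import pandas as pd

from .community import IsolateRecord, normalize_label, tissue_from_code

__all__ = [
    "read_isolate_table",
    "read_taxonomy_map",
    "read_gi_table",
    "read_ic50_table",
    "read_zi_table",
    "read_mic_table",
    "parse_pm_cell",
    "fixture_path",
    "load_isolates",
    "load_taxonomy",
    "load_gi",
    "load_ic50",
    "load_zi",
    "load_mic",
]

_INACTIVE = {"-", "", "na", "nd"}
_PM_RE = re.compile(r"^(?P<cens>[<>])?\s*(?P<mean>[0-9.]+)\s*(?:±\s*(?P<sd>[0-9.]+))?$")


def _delimiter(path: Path, dialect: str | None) -> str:
    if dialect in ("tsv", "\t"):
        return "\t"
    if dialect in ("csv", ","):
        return ","
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_isolate_table(path, dialect: str | None = None) -> list[IsolateRecord]:
    """Read an isolate table into records.

    Required columns: ``isolate_code`` and ``taxon_label``.  A
    ``tissue`` column is optional; when absent the tissue is inferred
    from the isolate-code suffix (L = leaf, R = root, F = flower).
    Optional columns ``accession``, ``closest_match``, ``identity_pct``
    are carried along as metadata.  Duplicate isolate codes and unknown
    tissue values are errors.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=_delimiter(path, dialect))
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, expected a header row")
        cols = {c.strip().lower() for c in reader.fieldnames}
        missing = {"isolate_code", "taxon_label"} - cols
        if missing:
            raise ValueError(f"{path}: missing required columns {sorted(missing)}")

        records: list[IsolateRecord] = []
        seen: set[str] = set()
        for row in reader:
            row = {k.strip().lower(): (v or "").strip() for k, v in row.items() if k}
            code = row["isolate_code"]
            if not code:
                continue
            if code in seen:
                raise ValueError(f"{path}: duplicate isolate code {code!r}")
            seen.add(code)
            tissue = row.get("tissue", "").lower() or tissue_from_code(code)
            ident = row.get("identity_pct", "")
            records.append(
                IsolateRecord(
                    isolate_code=code,
                    tissue=tissue,
                    taxon_label=normalize_label(row["taxon_label"]),
                    accession=row.get("accession") or None,
                    closest_match=row.get("closest_match") or None,
                    identity_pct=float(ident) if ident else None,
                )
            )
    return records


def read_taxonomy_map(path) -> dict[str, dict[str, str]]:
    """Read a genus -> (order, class, phylum) map from TSV."""
    df = pd.read_csv(path, sep="\t")
    need = {"genus", "order", "class", "phylum"}
    if not need <= set(df.columns):
        raise ValueError(f"taxonomy map must have columns {sorted(need)}")
    return {
        str(r["genus"]).strip(): {
            "order": str(r["order"]).strip(),
            "class": str(r["class"]).strip(),
            "phylum": str(r["phylum"]).strip(),
        }
        for _, r in df.iterrows()
    }


def parse_pm_cell(cell: str) -> tuple[float, float, str] | None:
    """Parse a ``mean ± sd`` cell, possibly censored.

    Returns ``(value, sd, censor)`` with censor one of ``exact``,
    ``lt`` (value is an upper bound, "<x") or ``gt`` (lower bound,
    ">x"); ``None`` for an inactive ``-`` cell.
    """
    text = str(cell).strip()
    if text.lower() in _INACTIVE:
        return None
    mbc = "(mbc)" in text.lower()
    text = re.sub(r"\(\s*MBC\s*\)", "", text, flags=re.I).strip()
    m = _PM_RE.match(text)
    if not m:
        raise ValueError(f"cannot parse cell {cell!r}")
    censor = {"<": "lt", ">": "gt", None: "exact"}[m.group("cens")]
    sd = float(m.group("sd")) if m.group("sd") else math.nan
    value = float(m.group("mean"))
    return (value, sd, censor) if not mbc else (value, sd, censor + "+mbc")


def _read_wide(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    first = df.columns[0]
    return df.set_index(first)


def read_gi_table(path) -> pd.DataFrame:
    """Percent growth inhibition matrix (extract x cell line), means only."""
    raw = _read_wide(path)

    def mean_of(cell):
        parsed = parse_pm_cell(cell)
        if parsed is None:
            return math.nan
        return parsed[0]

    return raw.map(mean_of).astype(float)


def read_ic50_table(path) -> pd.DataFrame:
    """IC50 table in long form: extract_id, cell_line, ic50, sd, censor.

    ``censor`` is ``exact`` or ``below_min`` (a "<x" entry, meaning the
    half-inhibition point lies below the lowest tested concentration x).
    """
    raw = _read_wide(path)
    rows = []
    for extract, row in raw.iterrows():
        for line, cell in row.items():
            parsed = parse_pm_cell(cell)
            if parsed is None:
                continue
            value, sd, censor = parsed
            rows.append(
                {
                    "extract_id": extract,
                    "cell_line": line,
                    "ic50": value,
                    "sd": sd,
                    "censor": {"lt": "below_min", "gt": "above_max"}.get(censor, "exact"),
                }
            )
    return pd.DataFrame(rows)


def read_zi_table(path) -> pd.DataFrame:
    """Disc-diffusion panel, long form: extract_id, pathogen, zi_mm, sd.

    Inactive ("-") cells are kept with NaN zi_mm so that fractions are
    defined over the full extract panel.
    """
    raw = _read_wide(path)
    rows = []
    for extract, row in raw.iterrows():
        for pathogen, cell in row.items():
            parsed = parse_pm_cell(cell)
            rows.append(
                {
                    "extract_id": extract,
                    "pathogen": pathogen,
                    "zi_mm": parsed[0] if parsed else math.nan,
                    "sd": parsed[1] if parsed else math.nan,
                }
            )
    return pd.DataFrame(rows)


def read_mic_table(path) -> pd.DataFrame:
    """Broth-dilution panel, long form: extract_id, pathogen, mic, censor, mbc.

    ``censor``: ``exact`` for an in-series endpoint, ``gt`` for ">x"
    (growth at every tested concentration).  ``mbc`` marks endpoints
    annotated as bactericidal.
    """
    raw = _read_wide(path)
    rows = []
    for extract, row in raw.iterrows():
        for pathogen, cell in row.items():
            parsed = parse_pm_cell(cell)
            if parsed is None:
                rec = {"mic": math.nan, "censor": "none", "mbc": False}
            else:
                value, _, censor = parsed
                mbc = censor.endswith("+mbc")
                rec = {"mic": value, "censor": censor.replace("+mbc", ""), "mbc": mbc}
            rows.append({"extract_id": extract, "pathogen": pathogen, **rec})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Packaged survey fixtures


def fixture_path(name: str) -> Path:
    """Path to a packaged data table (e.g. ``"isolates.tsv"``)."""
    return Path(str(files("endodiv") / "data" / name))


def load_isolates() -> list[IsolateRecord]:
    return read_isolate_table(fixture_path("isolates.tsv"))


def load_taxonomy() -> Mapping[str, Mapping[str, str]]:
    return read_taxonomy_map(fixture_path("taxonomy.tsv"))


def load_gi() -> pd.DataFrame:
    return read_gi_table(fixture_path("cytotoxicity_gi.tsv"))


def load_ic50() -> pd.DataFrame:
    return read_ic50_table(fixture_path("ic50.tsv"))


def load_zi() -> pd.DataFrame:
    return read_zi_table(fixture_path("zone_inhibition.tsv"))


def load_mic() -> pd.DataFrame:
    return read_mic_table(fixture_path("mic.tsv"))
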
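"""End-to-end orchestration: isolate table -> diversity/similarity/beta
tables; assay tables -> screening summaries; deterministic report files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import alpha, beta, bioactivity, io
from .community import build_abundance_matrix

log = logging.getLogger("endodiv")

__all__ = ["PipelineConfig", "run_pipeline", "write_report"]


@dataclass
class PipelineConfig:
    """Inputs and thresholds for one pipeline run.

    Any path left as ``None`` falls back to the packaged survey
    fixtures.  ``gi_threshold`` is the strict percent-inhibition cut
    for the cytotoxicity screen; ``ic50_cutoff`` is the NCI crude-
    extract potency criterion (IC50 < 20 ug/mL); ``mic_cutoff`` bounds
    the dilution screen.
    """

    isolates: str | Path | None = None
    taxonomy: str | Path | None = None
    gi_table: str | Path | None = None
    ic50_table: str | Path | None = None
    zi_table: str | Path | None = None
    mic_table: str | Path | None = None
    resolution_mode: str = "label"
    gi_threshold: float = 50.0
    ic50_cutoff: float = 20.0
    mic_cutoff: float = 100.0
    gradient_order: list[str] | None = None
    table_compat: bool = False
    out_dir: str | Path = "results"
    formats: tuple[str, ...] = ("tsv",)
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("gi_threshold", "ic50_cutoff", "mic_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _load(path, default_loader, reader):
    return default_loader() if path is None else reader(path)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every analysis stage; returns a bundle of result tables.

    Keys: ``diversity`` (index x tissue table), ``similarity``
    (combined grid, Sorensen above / Jaccard below the diagonal),
    ``similarity_sorensen``/``similarity_jaccard`` (full symmetric
    tables), ``beta`` (turnover suite), ``cytotoxicity``, ``ic50``,
    ``zone_inhibition`` and ``mic`` summaries.
    """
    records = _load(config.isolates, io.load_isolates, io.read_isolate_table)
    if not records:
        raise ValueError("no records in isolate table")
    log.info("isolates: %d records", len(records))
    matrix = build_abundance_matrix(records, mode=config.resolution_mode)

    diversity = pd.DataFrame(
        {
            t: alpha.alpha_profile(matrix.tissue_counts(t)).to_series(
                compat=config.table_compat
            )
            for t in matrix.tissues
        }
    )
    log.info("diversity: %d indices x %d tissues", *diversity.shape)

    sim = beta.similarity_matrix(matrix)
    grid = sim["jaccard"].copy()
    for i in range(len(grid)):
        for j in range(i + 1, len(grid)):
            grid.iloc[i, j] = sim["sorensen"].iloc[i, j]

    suite = beta.gradient_beta_suite(matrix, order=config.gradient_order)
    beta_series = suite.to_series()
    log.info("beta suite over %d samples (S=%d)", suite.n_samples, suite.S_total)

    gi = _load(config.gi_table, io.load_gi, io.read_gi_table)
    cyto = bioactivity.cytotoxic_screen_summary(gi, threshold=config.gi_threshold)
    ic50 = bioactivity.ic50_activity_counts(
        _load(config.ic50_table, io.load_ic50, io.read_ic50_table),
        threshold=config.ic50_cutoff,
    )
    zi = bioactivity.zi_screen_summary(
        _load(config.zi_table, io.load_zi, io.read_zi_table)
    )
    mic = bioactivity.mic_screen_summary(
        _load(config.mic_table, io.load_mic, io.read_mic_table),
        cutoff=config.mic_cutoff,
    )
    log.info(
        "screens: %d/%d cytotoxic (all lines), %d ZI-active, %d MIC-active",
        cyto["all_line_active"],
        cyto["n_extracts"],
        zi["overall_active"],
        mic["overall_active"],
    )

    return {
        "diversity": diversity,
        "similarity": grid,
        "similarity_sorensen": sim["sorensen"],
        "similarity_jaccard": sim["jaccard"],
        "beta": beta_series,
        "beta_summary": suite,
        "cytotoxicity": cyto,
        "ic50": ic50,
        "zone_inhibition": zi,
        "mic": mic,
    }


def _flatten(summary: dict, prefix: str = "") -> pd.Series:
    rows: dict[str, float] = {}
    for key, value in summary.items():
        if isinstance(value, dict):
            rows.update(_flatten(value, prefix=f"{key}."))
        else:
            rows[prefix + key] = value
    return pd.Series(rows)


def write_report(results: dict, out_dir, formats=("tsv",)) -> list[Path]:
    """Write the result bundle to disk; returns the files written.

    TSV output is long/tidy where sensible; markdown mirrors the
    rendered table layouts (similarity grid with Sorensen above and
    Jaccard below the diagonal).  Output is deterministic: fixed column
    order, fixed rounding handled upstream.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    tables = {
        "diversity": results["diversity"],
        "similarity": results["similarity"],
        "beta": results["beta"].rename("value").to_frame(),
        "cytotoxicity_summary": _flatten(results["cytotoxicity"]).rename("value").to_frame(),
        "ic50_summary": _flatten(results["ic50"]).rename("value").to_frame(),
        "zone_inhibition_summary": _flatten(results["zone_inhibition"]).rename("value").to_frame(),
        "mic_summary": _flatten(results["mic"]).rename("value").to_frame(),
    }
    for name, table in tables.items():
        if "tsv" in formats:
            path = out / f"{name}.tsv"
            table.to_csv(path, sep="\t")
            written.append(path)
        if "markdown" in formats:
            path = out / f"{name}.md"
            path.write_text(table.to_markdown() + "\n", encoding="utf-8")
            written.append(path)
    return written
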
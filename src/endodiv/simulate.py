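"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators mirror the three observation processes:

* community sampling — isolates are a multinomial draw per tissue from
  a tissue-specific taxon composition (culturing n isolates from a
  tissue whose endophyte community has fixed relative abundances);
* MTT plates — optical densities constructed so that blank-subtracted
  percent growth inhibition equals a true 4PL dose-response curve plus
  additive Gaussian noise on the %GI scale;
* dilution series — growth occurs exactly below a latent true MIC,
  optionally with a per-well misclassification rate.

Every generator is a pure function of its spec (including the seed),
so a fixed spec reproduces byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import TISSUES, IsolateRecord

__all__ = [
    "CommunitySpec",
    "AssaySpec",
    "simulate_community",
    "simulate_mtt_plate",
    "simulate_dilution_series",
    "community_spec_from_records",
]

_TISSUE_SUFFIX = {"leaf": "L", "root": "R", "flower": "F"}

#: Concentration series used by the two assay emulations (ug/mL).
MTT_CONCENTRATIONS = (10.0, 25.0, 50.0, 100.0)
DILUTION_SERIES = (12.5, 25.0, 50.0, 100.0)


@dataclass(frozen=True)
class CommunitySpec:
    """Tissue-specific taxon compositions and per-tissue sample sizes."""

    composition: dict  # tissue -> {taxon: probability}
    n_isolates: dict  # tissue -> int
    seed: int = 0

    def __post_init__(self) -> None:
        for tissue, probs in self.composition.items():
            if tissue not in TISSUES:
                raise ValueError(f"unknown tissue {tissue!r}")
            total = sum(probs.values())
            if not probs or not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(f"probabilities for {tissue} sum to {total}, not 1")
            if any(p < 0 for p in probs.values()):
                raise ValueError("negative probability")
        if any(n < 0 for n in self.n_isolates.values()):
            raise ValueError("negative isolate count")


@dataclass(frozen=True)
class AssaySpec:
    """True dose-response curves and latent MICs for assay emulation."""

    curves: dict = field(default_factory=dict)  # (extract, line) -> (lower, upper, hill, ic50)
    concentrations: tuple = MTT_CONCENTRATIONS
    noise_sd: float = 0.0  # additive sd on the %GI scale
    mics: dict = field(default_factory=dict)  # (extract, pathogen) -> ug/mL or inf
    dilution_series: tuple = DILUTION_SERIES
    misclassification: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for key, (lower, upper, hill, ic50) in self.curves.items():
            if ic50 <= 0:
                raise ValueError(f"non-positive IC50 for {key}")
        if self.noise_sd < 0:
            raise ValueError("negative noise sd")
        series = set(self.dilution_series)
        for key, mic in self.mics.items():
            if not (math.isinf(mic) or mic in series):
                raise ValueError(f"true MIC for {key} must lie in the series or be inf")
        if not 0 <= self.misclassification <= 1:
            raise ValueError("misclassification rate outside [0, 1]")


def simulate_community(spec: CommunitySpec) -> list[IsolateRecord]:
    """Draw isolate records: one multinomial per tissue.

    Isolate codes follow the tissue-suffix convention ("SIM-1 L", ...),
    numbered consecutively across tissues in canonical tissue order.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[IsolateRecord] = []
    serial = 0
    for tissue in TISSUES:
        if tissue not in spec.composition:
            continue
        probs = spec.composition[tissue]
        taxa = sorted(probs)
        n = int(spec.n_isolates.get(tissue, 0))
        draws = rng.multinomial(n, [probs[t] for t in taxa])
        for taxon, k in zip(taxa, draws):
            for _ in range(int(k)):
                serial += 1
                records.append(
                    IsolateRecord(
                        isolate_code=f"SIM-{serial} {_TISSUE_SUFFIX[tissue]}",
                        tissue=tissue,
                        taxon_label=taxon,
                    )
                )
    return records


def community_spec_from_records(records, n_isolates, seed: int = 0) -> CommunitySpec:
    """Build a spec from observed records' empirical tissue compositions."""
    comp: dict[str, dict[str, float]] = {}
    for rec in records:
        comp.setdefault(rec.tissue, {})
        comp[rec.tissue][rec.taxon_label] = comp[rec.tissue].get(rec.taxon_label, 0) + 1
    for tissue, tally in comp.items():
        total = sum(tally.values())
        comp[tissue] = {t: k / total for t, k in tally.items()}
    if isinstance(n_isolates, int):
        n_isolates = {t: n_isolates for t in comp}
    return CommunitySpec(composition=comp, n_isolates=dict(n_isolates), seed=seed)


def _four_pl_gi(c: float, lower: float, upper: float, hill: float, ic50: float) -> float:
    return lower + (upper - lower) / (1.0 + (ic50 / c) ** hill)


# OD anchors for plate construction; %GI is scale-free so any viable
# control window works (see percent_growth_inhibition's affine invariance)
_OD_BLANK = 0.05
_OD_CONTROL = 1.05


def simulate_mtt_plate(spec: AssaySpec) -> pd.DataFrame:
    """Long-format OD table for every curve x concentration.

    Columns: extract_id, cell_line, concentration, od_treated,
    od_control, od_blank.  Blank-subtracting these ODs recovers
    4PL(c) + Gaussian(0, noise_sd) percent growth inhibition exactly.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for (extract, line), params in sorted(spec.curves.items()):
        for c in spec.concentrations:
            gi = _four_pl_gi(c, *params)
            if spec.noise_sd > 0:
                gi += rng.normal(0.0, spec.noise_sd)
            od_treated = _OD_BLANK + (1.0 - gi / 100.0) * (_OD_CONTROL - _OD_BLANK)
            rows.append(
                {
                    "extract_id": extract,
                    "cell_line": line,
                    "concentration": c,
                    "od_treated": od_treated,
                    "od_control": _OD_CONTROL,
                    "od_blank": _OD_BLANK,
                }
            )
    return pd.DataFrame(rows)


def simulate_dilution_series(spec: AssaySpec) -> pd.DataFrame:
    """Growth-flag table: growth iff concentration < true MIC.

    With a non-zero misclassification rate each well's flag flips
    independently with that probability.  Columns: extract_id,
    pathogen, concentration, growth.
    """
    rng = np.random.default_rng(spec.seed + 1)
    rows = []
    for (extract, pathogen), mic in sorted(spec.mics.items()):
        for c in spec.dilution_series:
            growth = c < mic
            if spec.misclassification > 0 and rng.random() < spec.misclassification:
                growth = not growth
            rows.append(
                {
                    "extract_id": extract,
                    "pathogen": pathogen,
                    "concentration": c,
                    "growth": bool(growth),
                }
            )
    return pd.DataFrame(rows)
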
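"""Community observations from culture-based endophyte surveys.

An isolate table (one row per cultured isolate, with its tissue of
origin and a species-level taxon label) is turned into a taxon x tissue
abundance matrix, from which dominance and frequency statistics are
computed.  Two taxon-resolution modes are supported:

``label``
    isolates sharing a normalized species label are one taxon even when
    they come from different tissues (e.g. "Cladosporium sp." cultured
    from both leaf and root is a single taxon);
``label_per_tissue``
    a taxon is a (label, tissue) pair, so assemblages never share taxa.

The distinction matters because indeterminate labels like "Genus sp."
cannot be proven conspecific across tissues; pooled richness, and hence
every multi-sample beta statistic, depends on which convention is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TISSUES",
    "IsolateRecord",
    "AbundanceMatrix",
    "normalize_label",
    "genus_of",
    "tissue_from_code",
    "build_abundance_matrix",
    "relative_proportion",
    "genus_frequency",
    "class_composition",
    "presence_set",
    "UnmappedGenusError",
]

#: Canonical tissue order used throughout (survey sampling order).
TISSUES = ("leaf", "root", "flower")

_SUFFIX_TO_TISSUE = {"L": "leaf", "R": "root", "F": "flower"}


class UnmappedGenusError(KeyError):
    """A genus in the isolate table has no taxonomy-map entry."""

    def __init__(self, genera: Sequence[str]):
        self.genera = sorted(set(genera))
        super().__init__(f"genera missing from taxonomy map: {', '.join(self.genera)}")


def normalize_label(label: str) -> str:
    """Normalize a species label for identity comparisons.

    Internal whitespace is collapsed, the label is stripped, and a
    trailing period is removed unless it belongs to an "sp."/"spp."
    epithet (which is kept, as it is part of the conventional label).
    Case is preserved for display; callers compare via ``casefold``.
    """
    lab = " ".join(label.split())
    if lab.endswith(".") and not lab.lower().endswith(("sp.", "spp.")):
        lab = lab.rstrip(".")
    return lab


def genus_of(taxon_label: str) -> str:
    """First whitespace-delimited token of a species label.

    "sp."/"spp." are epithets, never genera; anamorph/teleomorph pairs
    such as Gibberella vs Fusarium or Neosartorya vs Aspergillus are
    distinct genera here — no synonym folding is attempted.
    """
    tokens = normalize_label(taxon_label).split()
    if not tokens:
        raise ValueError("empty taxon label")
    return tokens[0]


def tissue_from_code(isolate_code: str) -> str:
    """Infer tissue of origin from the isolate-code suffix (L/R/F)."""
    stripped = isolate_code.strip()
    if not stripped:
        raise ValueError("empty isolate code")
    suffix = stripped[-1].upper()
    try:
        return _SUFFIX_TO_TISSUE[suffix]
    except KeyError:
        raise ValueError(
            f"cannot infer tissue from isolate code {isolate_code!r}: "
            f"suffix {suffix!r} is not one of L/R/F"
        ) from None


@dataclass(frozen=True)
class IsolateRecord:
    """One cultured endophyte isolate."""

    isolate_code: str
    tissue: str
    taxon_label: str
    accession: str | None = None
    closest_match: str | None = None
    identity_pct: float | None = None

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r}; expected one of {TISSUES}")
        if not normalize_label(self.taxon_label):
            raise ValueError(f"empty taxon label for isolate {self.isolate_code!r}")
        if self.identity_pct is not None and not (0.0 <= self.identity_pct <= 100.0):
            raise ValueError(f"identity_pct {self.identity_pct} outside [0, 100]")

    @property
    def genus(self) -> str:
        return genus_of(self.taxon_label)


@dataclass
class AbundanceMatrix:
    """Integer taxon x tissue count matrix.

    ``taxa`` are display identifiers (in ``label_per_tissue`` mode the
    tissue is appended in brackets); ``labels`` holds the bare species
    label for each row so genus logic is mode-independent.
    """

    taxa: list[str]
    tissues: list[str]
    counts: np.ndarray
    resolution_mode: str = "label"
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.taxa), len(self.tissues)):
            raise ValueError("counts shape does not match taxa x tissues")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if (self.counts.sum(axis=1) == 0).any():
            raise ValueError("all-zero taxon row")
        if not self.labels:
            self.labels = list(self.taxa)

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    def tissue_index(self, tissue: str) -> int:
        try:
            return self.tissues.index(tissue)
        except ValueError:
            raise KeyError(f"unknown tissue {tissue!r}; have {self.tissues}") from None

    def tissue_counts(self, tissue: str) -> np.ndarray:
        """Non-zero count vector for one tissue assemblage."""
        col = self.counts[:, self.tissue_index(tissue)]
        return col[col > 0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxa, columns=self.tissues)


def build_abundance_matrix(
    records: Iterable[IsolateRecord], mode: str = "label"
) -> AbundanceMatrix:
    """Tabulate isolate records into a taxon x tissue count matrix.

    Taxon identity is the normalized species label (case-insensitive);
    in ``label_per_tissue`` mode the tissue is part of the identity.
    Taxa are ordered by first appearance, tissues in canonical order.
    """
    records = list(records)
    if not records:
        raise ValueError("no records")
    if mode not in ("label", "label_per_tissue"):
        raise ValueError(f"unknown resolution mode {mode!r}")

    tissues = [t for t in TISSUES if any(r.tissue == t for r in records)]
    keys: list[tuple] = []
    display: dict[tuple, str] = {}
    bare: dict[tuple, str] = {}
    cells: dict[tuple, dict[str, int]] = {}
    for rec in records:
        lab = normalize_label(rec.taxon_label)
        key = (lab.casefold(),) if mode == "label" else (lab.casefold(), rec.tissue)
        if key not in cells:
            keys.append(key)
            display[key] = lab if mode == "label" else f"{lab} [{rec.tissue}]"
            bare[key] = lab
            cells[key] = {}
        cells[key][rec.tissue] = cells[key].get(rec.tissue, 0) + 1

    counts = np.zeros((len(keys), len(tissues)), dtype=int)
    for i, key in enumerate(keys):
        for j, t in enumerate(tissues):
            counts[i, j] = cells[key].get(t, 0)
    return AbundanceMatrix(
        taxa=[display[k] for k in keys],
        tissues=tissues,
        counts=counts,
        resolution_mode=mode,
        labels=[bare[k] for k in keys],
    )


def _taxon_row(matrix: AbundanceMatrix, taxon: str) -> int:
    want = normalize_label(taxon).casefold()
    for i, t in enumerate(matrix.taxa):
        if t.casefold() == want or matrix.labels[i].casefold() == want:
            return i
    raise KeyError(f"taxon {taxon!r} not in matrix")


def relative_proportion(matrix: AbundanceMatrix, taxon: str) -> float:
    """P_i: fraction of all isolates belonging to one taxon (row sum / N)."""
    return float(matrix.counts[_taxon_row(matrix, taxon)].sum()) / matrix.n_total


def genus_frequency(matrix: AbundanceMatrix, tissue: str, genus: str) -> float:
    """Within-tissue colonization frequency of a genus.

    Exact match on the label's first token: isolates of that genus in
    the tissue divided by all isolates in the tissue.
    """
    j = matrix.tissue_index(tissue)
    col = matrix.counts[:, j]
    total = int(col.sum())
    if total == 0:
        return 0.0
    want = genus.strip().casefold()
    hit = sum(
        int(col[i])
        for i, lab in enumerate(matrix.labels)
        if genus_of(lab).casefold() == want
    )
    return hit / total


def class_composition(
    records: Iterable[IsolateRecord], taxmap: Mapping[str, Mapping[str, str]]
) -> pd.Series:
    """Fraction of isolates per fungal class, via a genus->class map.

    ``taxmap`` maps genus to a mapping with at least a ``class`` entry
    (see :func:`endodiv.io.read_taxonomy_map`).  Raises
    :class:`UnmappedGenusError` listing every offender if any genus in
    the records lacks an entry.  Fractions sum to 1.
    """
    records = list(records)
    if not records:
        raise ValueError("no records")
    folded = {g.casefold(): v for g, v in taxmap.items()}
    missing = [r.genus for r in records if r.genus.casefold() not in folded]
    if missing:
        raise UnmappedGenusError(missing)
    tallies: dict[str, int] = {}
    for rec in records:
        cls = folded[rec.genus.casefold()]["class"]
        tallies[cls] = tallies.get(cls, 0) + 1
    out = pd.Series(tallies, dtype=float).sort_values(ascending=False)
    return out / len(records)


def presence_set(matrix: AbundanceMatrix, tissue: str) -> set[str]:
    """Taxa with count > 0 in one tissue."""
    j = matrix.tissue_index(tissue)
    return {matrix.taxa[i] for i in np.nonzero(matrix.counts[:, j])[0]}
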
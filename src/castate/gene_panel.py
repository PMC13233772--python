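"""Curated Ca2+ gene panel: loading, validation, and queries.

A panel is a table of gene symbols, each annotated with exactly one fine
functional group (e.g. "voltage-gated Ca2+ channels, VGCC-family") and one
broad functional class (e.g. "Channels"). Groups with at least
``MIN_GROUP_SIZE`` member genes are eligible for enrichment analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import CountMatrix

__all__ = [
    "GenePanel",
    "PanelFormatError",
    "PanelValidationError",
    "load_panel",
    "intersect_with_matrix",
    "functional_class_composition",
    "MIN_GROUP_SIZE",
]

#: Minimum member genes for a functional group to enter enrichment.
MIN_GROUP_SIZE = 5

REQUIRED_COLUMNS = ("gene", "group", "class")


class PanelFormatError(ValueError):
    """Panel file is malformed (missing columns, unreadable)."""


class PanelValidationError(ValueError):
    """Panel content violates an invariant (conflicting annotation)."""


@dataclass
class GenePanel:
    """Validated gene panel with a two-level functional annotation."""

    entries: pd.DataFrame  # columns: gene, group, class; one row per gene
    species_aliases: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        self.entries = (
            pd.DataFrame(self.entries)[list(REQUIRED_COLUMNS)]
            .drop_duplicates()
            .reset_index(drop=True)
        )
        dup = self.entries["gene"].duplicated(keep=False)
        if dup.any():
            bad = sorted(self.entries.loc[dup, "gene"].unique())
            raise PanelValidationError(
                f"conflicting annotations for gene(s): {bad}"
            )
        # every group maps to exactly one class
        g2c = self.entries.groupby("group")["class"].nunique()
        if (g2c > 1).any():
            bad = sorted(g2c[g2c > 1].index)
            raise PanelValidationError(f"group(s) mapped to >1 class: {bad}")

    # -- queries -----------------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return pd.Index(self.entries["gene"])

    @property
    def groups(self) -> list[str]:
        return sorted(self.entries["group"].unique())

    @property
    def classes(self) -> list[str]:
        return sorted(self.entries["class"].unique())

    def group_sizes(self) -> pd.Series:
        return self.entries.groupby("group").size()

    def eligible_groups(self, min_size: int = MIN_GROUP_SIZE) -> list[str]:
        """Functional groups large enough for enrichment analysis."""
        sizes = self.group_sizes()
        return sorted(sizes[sizes >= min_size].index)

    def group_members(self, group: str) -> list[str]:
        return self.entries.loc[self.entries["group"] == group, "gene"].tolist()

    def class_of(self) -> pd.Series:
        """gene -> functional class."""
        return self.entries.set_index("gene")["class"]

    def group_of(self) -> pd.Series:
        """gene -> functional group."""
        return self.entries.set_index("gene")["group"]

    def apply_aliases(self, symbols: Sequence[str]) -> list[str]:
        """Map matrix gene symbols through the species alias map."""
        if not self.species_aliases:
            return list(symbols)
        return [self.species_aliases.get(s, s) for s in symbols]


def load_panel(path, species_aliases: Mapping[str, str] | None = None) -> GenePanel:
    """Load a tab-separated panel file (columns: gene, group, class).

    Duplicate rows with identical content collapse silently; a symbol listed
    with conflicting annotations raises :class:`PanelValidationError`.
    """
    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise PanelFormatError(
            f"panel file {path} missing column(s) {missing}; "
            f"expected header with {REQUIRED_COLUMNS}"
        )
    return GenePanel(entries=df, species_aliases=species_aliases)


def mouse_case_aliases(symbols: Sequence[str]) -> dict[str, str]:
    """Simple case-convention alias map: mouse title-case -> human upper-case.

    The published human/mouse ortholog mapping is not available, so this maps
    by symbol case only (e.g. ``Calb1`` -> ``CALB1``) and nothing else.
    """
    return {s: s.upper() for s in symbols if s != s.upper()}


def intersect_with_matrix(
    panel: GenePanel, matrix: CountMatrix
) -> tuple[CountMatrix, list[str]]:
    """Restrict a count matrix to panel genes (panel column order).

    Returns the restricted matrix and the list of panel genes absent from the
    matrix. Matching is case-sensitive after applying the explicit alias map.
    Raises if no gene overlaps.
    """
    mapped = panel.apply_aliases(matrix.gene_ids)
    pos_of = {}
    for pos, sym in enumerate(mapped):
        pos_of.setdefault(sym, pos)  # first occurrence wins
    keep_positions: list[int] = []
    missing: list[str] = []
    for gene in panel.genes:
        pos = pos_of.get(gene)
        if pos is None:
            missing.append(gene)
        else:
            keep_positions.append(pos)
    if not keep_positions:
        raise ValueError("no panel genes found in the count matrix")
    restricted = matrix.subset_genes(np.array(keep_positions))
    # report under panel symbols so downstream lookups are uniform
    restricted.gene_ids = pd.Index(
        [mapped[p] for p in keep_positions]
    )
    return restricted, missing


def functional_class_composition(
    top_genes: Mapping[str, Sequence[str]],
    panel: GenePanel,
    n: int = 50,
) -> pd.DataFrame:
    """Per-state proportions of the broad functional classes among top genes.

    Parameters
    ----------
    top_genes
        Mapping state label -> ranked gene list (best first); genes must
        belong to the panel.
    n
        Number of leading genes to use; if a ranking is shorter, all of its
        genes are used with a warning.

    Returns
    -------
    DataFrame indexed by state, one column per panel class; rows sum to 1.
    """
    class_of = panel.class_of()
    rows = {}
    for state, ranked in top_genes.items():
        ranked = list(ranked)
        if n > len(ranked):
            warnings.warn(
                f"state {state!r}: requested top {n} of {len(ranked)} ranked "
                "genes; using all"
            )
        used = ranked[: min(n, len(ranked))]
        unknown = [g for g in used if g not in class_of.index]
        if unknown:
            raise KeyError(f"genes not in panel: {unknown}")
        counts = class_of.loc[used].value_counts()
        rows[state] = counts / counts.sum()
    out = pd.DataFrame(rows).T.reindex(columns=panel.classes).fillna(0.0)
    out.index.name = "state"
    return out
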
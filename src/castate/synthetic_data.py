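"""Synthetic panel-restricted UMI counts with known ground truth.

Counts are drawn from the same hierarchical gamma-Poisson structure the
factorization assumes: per-factor gamma gene loadings (with planted marker
genes up-weighted), per-cell gamma loadings whose expected mix follows a
group-specific factor-usage vector (lineage cells interpolate usage between
two groups), and Poisson emission of the loading inner product. An optional
cell-cycle-like confounder factor is tied to dedicated marker genes. An
optional block of unstructured background genes (mean-matched to the panel
genes but without group structure) emulates the rest of the transcriptome
for null-sampling and random-gene comparisons.

Every fixture is generated programmatically; nothing here is real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CountMatrix
from .gene_panel import GenePanel

__all__ = [
    "GroupSpec",
    "LineageSpec",
    "ConfoundSpec",
    "SyntheticDesign",
    "SyntheticTruth",
    "Fixture",
    "generate",
    "make_panel",
    "standard_fixtures",
]

#: Multiplier applied to planted marker-gene loadings so markers dominate
#: top-gene rankings detectably.
MARKER_BOOST = 8.0


@dataclass
class GroupSpec:
    """One cell group: name, size, and its factor-usage probability vector.

    ``marker_factor`` pins the factor the group's planted markers load on
    (default: the group's highest-usage factor).
    """

    name: str
    n_cells: int
    usage: np.ndarray  # length K_true, sums to 1
    n_markers: int = 0
    marker_factor: int | None = None

    def __post_init__(self) -> None:
        self.usage = np.asarray(self.usage, dtype=np.float64)
        if abs(self.usage.sum() - 1.0) > 1e-8:
            raise ValueError(f"group {self.name}: usage must sum to 1")
        if (self.usage < 0).any():
            raise ValueError(f"group {self.name}: negative usage")


@dataclass
class LineageSpec:
    """Cells interpolating factor usage between two groups."""

    start_group: str
    end_group: str
    n_cells: int
    name: str | None = None


@dataclass
class ConfoundSpec:
    """Cell-cycle-like confounder: extra factor + dedicated marker genes."""

    marker_names: tuple[str, ...] = ("TOP2A", "MKI67", "BIRC5")
    cycling_fraction: float = 0.3
    n_panel_genes: int = 30  # panel genes also loading on the confounder


@dataclass
class SyntheticDesign:
    """Full description of a synthetic dataset."""

    n_genes: int
    k_true: int
    groups: list[GroupSpec]
    lineages: list[LineageSpec] = field(default_factory=list)
    confound: ConfoundSpec | None = None
    gene_shape: float = 0.3
    cell_concentration: float = 15.0
    mean_total: float = 250.0
    depth_sd: float = 0.25
    n_background: int = 0
    #: dedicated signature genes per factor (all structure factors); makes
    #: every factor well separated in gene space. 0 disables.
    factor_markers: int = 0
    #: optional extra-Poisson noise: counts ~ Poisson(rate * Gamma(1/d, d))
    #: i.e. negative-binomial emission with dispersion d. None = pure
    #: Poisson (the model-matched default used by all standard fixtures);
    #: the over-dispersed variant exists for robustness checks only.
    dispersion: float | None = None

    @property
    def n_cells(self) -> int:
        return sum(g.n_cells for g in self.groups) + sum(
            l.n_cells for l in self.lineages
        )

    @property
    def k_total(self) -> int:
        return self.k_true + (1 if self.confound else 0)


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside the counts."""

    theta: np.ndarray  # cells x k_total expected cell loadings
    beta: np.ndarray  # panel genes x k_total gene loadings
    group_labels: np.ndarray
    lineage_position: np.ndarray  # nan for non-lineage cells
    marker_map: dict[str, list[str]]
    confound_factor: int | None
    confound_markers: list[str]
    cycling: np.ndarray | None
    panel_genes: list[str]


@dataclass
class Fixture:
    """A named bundle: counts + truth + a matching synthetic panel."""

    name: str
    matrix: CountMatrix
    truth: SyntheticTruth
    panel: GenePanel
    design: SyntheticDesign


def make_panel(
    gene_names,
    n_groups: int = 46,
    n_classes: int = 10,
    marker_map: dict[str, list[str]] | None = None,
) -> GenePanel:
    """Synthetic functional annotation over the given genes.

    Genes are dealt round-robin into ``n_groups`` functional groups (so every
    group has >= floor(n/n_groups) members) and groups round-robin into
    ``n_classes`` classes. When a marker map is given, each group's planted
    markers are kept inside a single functional group so class-composition
    differences between states are detectable.
    """
    gene_names = list(gene_names)
    n_groups = min(n_groups, max(1, len(gene_names) // 5))
    n_classes = min(n_classes, n_groups)
    group_names = [f"group_{i:02d}" for i in range(n_groups)]
    class_names = [f"class_{i:02d}" for i in range(n_classes)]
    group_of_gene: dict[str, str] = {}
    gi = 0
    if marker_map:
        for block, (state, markers) in enumerate(sorted(marker_map.items())):
            for m in markers:
                group_of_gene[m] = group_names[block % n_groups]
    rest = [g for g in gene_names if g not in group_of_gene]
    for j, g in enumerate(rest):
        group_of_gene[g] = group_names[j % n_groups]
    entries = pd.DataFrame(
        {
            "gene": gene_names,
            "group": [group_of_gene[g] for g in gene_names],
            "class": [
                class_names[group_names.index(group_of_gene[g]) % n_classes]
                for g in gene_names
            ],
        }
    )
    return GenePanel(entries=entries)


def generate(
    design: SyntheticDesign, seed: int = 0
) -> tuple[CountMatrix, SyntheticTruth]:
    """Draw a (CountMatrix, SyntheticTruth) pair from the design.

    Same seed implies identical output.
    """
    n = design.n_cells
    if n <= 0:
        raise ValueError("design has no cells")
    g = design.n_genes
    K = design.k_total
    rng = np.random.default_rng(seed)
    panel_genes = [f"CAG{i:04d}" for i in range(g)]

    # --- gene loadings -----------------------------------------------------
    beta = rng.gamma(design.gene_shape, 1.0, size=(g, K))
    marker_map: dict[str, list[str]] = {}
    used: set[int] = set()

    def _plant_markers(factor: int, count: int) -> list[int]:
        free = np.setdiff1d(np.arange(g), sorted(used))
        pick = rng.choice(free, size=count, replace=False)
        used.update(pick.tolist())
        # marker loadings: up-weighted and bounded away from zero (a plain
        # boost of a near-zero gamma(0.3) draw could leave a marker silent)
        beta[pick, factor] = MARKER_BOOST * rng.gamma(2.0, 0.5, size=count)
        others = np.setdiff1d(np.arange(K), [factor])
        beta[np.ix_(pick, others)] *= 0.1  # markers are factor-specific
        return sorted(pick.tolist())

    factor_marker_idx: dict[int, list[int]] = {}
    if design.factor_markers > 0:
        for k in range(design.k_true):
            factor_marker_idx[k] = _plant_markers(k, design.factor_markers)
    for group in design.groups:
        if group.n_markers <= 0:
            continue
        dominant = (
            int(group.marker_factor)
            if group.marker_factor is not None
            else int(np.argmax(group.usage))
        )
        if dominant in factor_marker_idx:
            idx = factor_marker_idx[dominant][: group.n_markers]
        else:
            idx = _plant_markers(dominant, group.n_markers)
        marker_map[group.name] = [panel_genes[i] for i in idx]

    confound_factor = None
    confound_markers: list[str] = []
    if design.confound is not None:
        confound_factor = K - 1
        free = np.setdiff1d(np.arange(g), sorted(used))
        pick = rng.choice(
            free, size=design.confound.n_panel_genes, replace=False
        )
        beta[pick, confound_factor] = rng.gamma(
            2.0, 2.0, size=design.confound.n_panel_genes
        )
        confound_markers = list(design.confound.marker_names)

    # --- cell loadings ------------------------------------------------------
    usages = np.zeros((n, design.k_true))
    group_labels = np.empty(n, dtype=object)
    lineage_position = np.full(n, np.nan)
    row = 0
    usage_of = {gr.name: gr.usage for gr in design.groups}
    for gr in design.groups:
        usages[row : row + gr.n_cells] = gr.usage
        group_labels[row : row + gr.n_cells] = gr.name
        row += gr.n_cells
    for lin in design.lineages:
        u0, u1 = usage_of[lin.start_group], usage_of[lin.end_group]
        t = np.linspace(0.0, 1.0, lin.n_cells)
        usages[row : row + lin.n_cells] = (
            (1 - t)[:, None] * u0[None, :] + t[:, None] * u1[None, :]
        )
        group_labels[row : row + lin.n_cells] = (
            lin.name or f"{lin.start_group}->{lin.end_group}"
        )
        lineage_position[row : row + lin.n_cells] = t
        row += lin.n_cells

    conc = design.cell_concentration
    theta_struct = rng.gamma(
        np.maximum(conc * usages, 1e-3), 1.0, size=(n, design.k_true)
    )
    theta_struct /= theta_struct.sum(axis=1, keepdims=True)

    theta = np.zeros((n, K))
    theta[:, : design.k_true] = theta_struct
    cycling = None
    if design.confound is not None:
        cycling = rng.random(n) < design.confound.cycling_fraction
        load = np.where(
            cycling,
            rng.gamma(4.0, 0.15, size=n),  # strong, tight -> high correlation
            rng.gamma(0.3, 0.01, size=n),
        )
        theta[:, confound_factor] = load

    # calibrate per-cell depth to the target panel total
    depth = np.exp(rng.normal(0.0, design.depth_sd, size=n))
    col_mass = beta.sum(axis=0)  # expected gene mass per factor
    raw_total = theta @ col_mass
    theta *= (design.mean_total * depth / raw_total)[:, None]

    rates = theta @ beta.T
    if design.dispersion is not None and design.dispersion > 0:
        d = design.dispersion
        rates = rates * rng.gamma(1.0 / d, d, size=rates.shape)
    counts = rng.poisson(rates)

    gene_names = list(panel_genes)
    blocks = [sp.csr_matrix(counts)]

    if confound_markers:
        # markers express (almost) exclusively with the confounder loading
        mk_load = rng.gamma(3.0, 3.0, size=len(confound_markers))
        mk_rates = np.outer(theta[:, confound_factor], mk_load) + 0.01
        blocks.append(sp.csr_matrix(rng.poisson(mk_rates)))
        gene_names += confound_markers

    if design.n_background > 0:
        # background means cover the panel's mean range log-uniformly, so
        # any +/-10% matching window around a panel gene's mean contains
        # many background candidates
        panel_means = rates.mean(axis=0)
        lo = max(panel_means.min(), 1e-3) * 0.9
        hi = panel_means.max() * 1.1
        mu = np.exp(
            rng.uniform(np.log(lo), np.log(hi), size=design.n_background)
        )
        bg_rates = np.outer(depth, mu)
        blocks.append(sp.csr_matrix(rng.poisson(bg_rates)))
        gene_names += [f"BG{i:04d}" for i in range(design.n_background)]

    X = sp.hstack(blocks, format="csr")
    cell_meta = pd.DataFrame(
        {
            "cell_type": group_labels,
            "group": group_labels,
            "lineage_position": lineage_position,
        },
        index=pd.Index([f"cell{i:05d}" for i in range(n)], name="cell"),
    )
    if cycling is not None:
        cell_meta["cycling"] = cycling
    matrix = CountMatrix(counts=X, cell_meta=cell_meta, gene_ids=gene_names)
    truth = SyntheticTruth(
        theta=theta,
        beta=beta,
        group_labels=group_labels,
        lineage_position=lineage_position,
        marker_map=marker_map,
        confound_factor=confound_factor,
        confound_markers=confound_markers,
        cycling=cycling,
        panel_genes=panel_genes,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# standard fixtures
# ---------------------------------------------------------------------------

#: Factor pair each six_state group does NOT use (its "off" factors) and the
#: factor its planted markers load on. Groups share most factors but differ
#: in which two they lack, so true per-cell profiles are spread over ~6
#: factors (top-4 usage ~= 0.65) while group separation stays large — the
#: regime in which the top-m coverage rule for K selection is informative.
#: Each group leaves two factors (its "off pair") nearly unused; any two
#: groups share at most one off factor, so group profiles stay well
#: separated while every cell spreads its mass over ~6 factors — the regime
#: in which the top-m coverage rule for K selection is informative.
_SIX_STATE_OFF_PAIRS = [(0, 1), (2, 3), (4, 5), (6, 7), (0, 2), (1, 3)]
_SIX_STATE_MARKER_FACTORS = [2, 0, 1, 5, 3, 4]
#: Anti-symmetric +/-25% usage tilts across ON factors. Twin factors that
#: share an off-group pattern (e.g. the two factors both unused only by one
#: group) receive opposite tilt patterns, which breaks their usage
#: degeneracy and keeps all 8 factors identifiable. 0 marks an OFF factor.
_SIX_STATE_TILT = np.array(
    [
        [0, 0, +1, -1, +1, -1, +1, -1],
        [+1, -1, 0, 0, -1, +1, +1, -1],
        [-1, +1, +1, -1, 0, 0, -1, +1],
        [+1, -1, -1, +1, +1, +1, 0, 0],
        [0, +1, 0, +1, -1, +1, -1, -1],
        [+1, 0, -1, 0, +1, -1, +1, -1],
    ],
    dtype=float,
)


def _six_state_design() -> SyntheticDesign:
    """2,000 cells x 800 panel genes, K_true=8, 6 groups + background."""
    K = 8
    low = 0.04
    groups = []
    sizes = [334, 334, 333, 333, 333, 333]
    for i, (p, q) in enumerate(_SIX_STATE_OFF_PAIRS):
        u = np.full(K, (1.0 - 2 * low) / 6)
        u *= 1.0 + 0.20 * _SIX_STATE_TILT[i]
        u[p] = low
        u[q] = low
        u /= u.sum()
        groups.append(
            GroupSpec(
                f"state_{i}", sizes[i], u, n_markers=10,
                marker_factor=_SIX_STATE_MARKER_FACTORS[i],
            )
        )
    return SyntheticDesign(
        n_genes=800,
        k_true=K,
        groups=groups,
        cell_concentration=150.0,
        mean_total=2000.0,
        n_background=1200,
    )


def _lineage_design() -> SyntheticDesign:
    """Three branches out of a common progenitor group."""
    K = 5
    base = 0.04
    prog = np.full(K, base)
    prog[0] = 1.0 - base * (K - 1)
    groups = [GroupSpec("progenitor", 250, prog / prog.sum())]
    for b in range(3):
        u = np.full(K, base)
        u[1 + b] = 1.0 - base * (K - 1)
        groups.append(GroupSpec(f"terminal_{b}", 250, u / u.sum(), n_markers=8))
    lineages = [
        LineageSpec("progenitor", f"terminal_{b}", 150, name=f"branch_{b}")
        for b in range(3)
    ]
    return SyntheticDesign(
        n_genes=400, k_true=K, groups=groups, lineages=lineages,
        n_background=400,
    )


def _cycling_design() -> SyntheticDesign:
    """Two groups plus a cell-cycle-like confounder with tied markers."""
    K = 4
    u0 = np.array([0.7, 0.1, 0.15, 0.05])
    u1 = np.array([0.1, 0.7, 0.15, 0.05])
    return SyntheticDesign(
        n_genes=300,
        k_true=K,
        groups=[
            GroupSpec("g0", 1000, u0, n_markers=8),
            GroupSpec("g1", 1000, u1, n_markers=8),
        ],
        confound=ConfoundSpec(),
        n_background=200,
    )


#: planted (type, state, count) impurity blocks of the "impure" fixture;
#: `removed` marks the blocks the two purity rules must catch.
_IMPURE_BLOCKS = [
    # type, placements {state: count}, removed (type, state) pairs
    ("F1", {"A": 819, "B": 81}, [("F1", "B")]),       # 9.0% < 10%
    ("F2", {"B": 728, "C": 72}, [("F2", "C")]),       # 9.0% < 10%
    ("F3", {"C": 455, "D": 45}, [("F3", "D")]),       # 9.0% < 10%
    ("F4", {"D": 273, "E": 27}, [("F4", "E")]),       # 9.0% < 10%
    ("F5", {"B": 136, "D": 14}, [("F5", "D")]),       # 14 < 15 cells
    ("F6", {"C": 126, "E": 14}, [("F6", "E")]),       # 14 < 15 cells
    ("G1", {"A": 160, "B": 40}, []),                  # 20%, >= 15 -> kept
    ("G2", {"C": 80, "D": 20}, []),                   # 20%, >= 15 -> kept
    ("H15", {"A": 120, "B": 15}, []),                 # boundary: exactly 15
]

_IMPURE_STATE_SIZES = {"A": 1200, "B": 1000, "C": 800, "D": 400, "E": 240}


def impure_truth_tables() -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """(cell table with planted type/state labels, expected removed pairs).

    State E (240 cells) is below the 250-cell merge threshold; all planted
    impurity blocks below the "<10% or <15 cells" purity rule are listed in
    the second return value.
    """
    removed: list[tuple[str, str]] = []
    per_state: dict[str, list[str]] = {s: [] for s in _IMPURE_STATE_SIZES}
    for t, placements, rem in _IMPURE_BLOCKS:
        removed.extend(rem)
        for s, cnt in placements.items():
            per_state[s].extend([t] * cnt)
    rows: list[tuple[str, str]] = []
    # cells ordered by state to align with the generator's group blocks
    for s, total in _IMPURE_STATE_SIZES.items():
        fill = total - len(per_state[s])
        if fill < 0:
            raise AssertionError(f"state {s} over-filled")
        per_state[s].extend([f"base_{s}"] * fill)
        rows.extend((t, s) for t in per_state[s])
    df = pd.DataFrame(rows, columns=["cell_type", "state"])
    df.index = pd.Index([f"cell{i:05d}" for i in range(len(df))], name="cell")
    return df, removed


def _impure_design() -> SyntheticDesign:
    K = 6
    sizes = _IMPURE_STATE_SIZES
    groups = []
    for i, (name, size) in enumerate(sizes.items()):
        u = np.full(K, 0.02)
        u[i] = 0.85
        u /= u.sum()
        groups.append(GroupSpec(name, size, u, n_markers=5))
    return SyntheticDesign(n_genes=300, k_true=K, groups=groups)


def standard_fixtures(seed: int = 0, names=None) -> dict[str, Fixture]:
    """Build the named test fixtures (all generated, deterministic in seed).

    * ``six_state`` — clustering/recovery harness (2,000 x 800 panel genes,
      K_true=8, 6 groups, 1,200 matched background genes).
    * ``lineage`` — three branches from one progenitor, usage gradients.
    * ``cycling`` — confounder factor tied to TOP2A/MKI67/BIRC5-style markers.
    * ``impure`` — planted low-purity (cell type, state) crossings and one
      sub-250-cell state for the refinement rules.
    """
    builders = {
        "six_state": _six_state_design,
        "lineage": _lineage_design,
        "cycling": _cycling_design,
        "impure": _impure_design,
    }
    wanted = list(builders) if names is None else list(names)
    out: dict[str, Fixture] = {}
    for offset, name in enumerate(wanted):
        design = builders[name]()
        matrix, truth = generate(design, seed=seed + offset)
        panel = make_panel(
            truth.panel_genes, marker_map=truth.marker_map or None
        )
        if name == "impure":
            table, _ = impure_truth_tables()
            matrix.cell_meta["cell_type"] = table["cell_type"].to_numpy()
            matrix.cell_meta["planted_state"] = table["state"].to_numpy()
        out[name] = Fixture(
            name=name, matrix=matrix, truth=truth, panel=panel, design=design
        )
    return out
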
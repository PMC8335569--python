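"""Figure generation: oncoprint-style waterfall, co-occurrence grid,
mutation-vs-abundance heat map, and Kaplan-Meier curves.

Every plot function writes the figure to ``spec.path`` and a companion
``<path>.layout.tsv`` holding the exact data/layout table the figure was
drawn from; the function returns that table so tests can assert on content
rather than pixels. Output is deterministic for fixed input and spec.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .association import zscore_rows  # noqa: E402
from .errors import ValidationError  # noqa: E402
from .mutation import MutationMatrix  # noqa: E402
from .survival import km_curve, log_rank  # noqa: E402

_FORMATS = ("png", "pdf", "svg")


@dataclasses.dataclass
class PlotSpec:
    """Where and how to render a figure."""

    path: str | Path
    format: str | None = None
    width: float = 8.0
    height: float = 6.0
    dpi: int = 150

    def __post_init__(self) -> None:
        self.path = Path(self.path)
        if self.format is None:
            suffix = self.path.suffix.lstrip(".").lower()
            self.format = suffix if suffix in _FORMATS else "png"
        if self.format not in _FORMATS:
            raise ValidationError(f"format must be one of {_FORMATS}, got {self.format!r}")
        if self.width <= 0 or self.height <= 0 or self.dpi <= 0:
            raise ValidationError("plot dimensions and dpi must be positive")

    @property
    def layout_path(self) -> Path:
        return Path(str(self.path) + ".layout.tsv")


def _finish(fig, spec: PlotSpec, layout: pd.DataFrame) -> pd.DataFrame:
    spec.path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(spec.path, format=spec.format, dpi=spec.dpi)
    plt.close(fig)
    layout.to_csv(spec.layout_path, sep="\t")
    return layout


def memo_sort_columns(matrix: pd.DataFrame) -> list[str]:
    """Oncoprint column order: samples mutated in higher-frequency genes first."""
    bits = matrix.to_numpy()
    # lexsort uses the last key as primary; rows are already frequency-sorted,
    # so feed them bottom-up with the top gene as the primary key.
    order = np.lexsort(tuple(-bits[i] for i in range(bits.shape[0] - 1, -1, -1)))
    return [matrix.columns[j] for j in order]


def plot_waterfall(mutations: MutationMatrix, genes, spec: PlotSpec) -> pd.DataFrame:
    """Waterfall (oncoprint) of the chosen mutation genes.

    Genes as rows in descending mutation frequency; columns memo-sorted.
    The layout table is the reordered binary matrix with a final
    ``frequency`` column.
    """
    genes = list(genes)
    if not genes:
        raise ValidationError("gene list is empty")
    for g in genes:
        if g not in mutations.genes:
            raise ValidationError(f"gene {g!r} not in mutation matrix")
    freq = mutations.frequency
    genes = sorted(genes, key=lambda g: (-freq[g], g))
    sub = mutations.data.loc[genes]
    cols = memo_sort_columns(sub)
    sub = sub.loc[:, cols]

    fig, (ax, axf) = plt.subplots(
        1, 2, figsize=(spec.width, spec.height), width_ratios=[5, 1], sharey=True
    )
    ax.imshow(sub.to_numpy(), aspect="auto", cmap="Greys", interpolation="nearest",
              vmin=0, vmax=1)
    ax.set_yticks(range(len(genes)), genes)
    ax.set_xticks([])
    ax.set_xlabel(f"{sub.shape[1]} samples")
    axf.barh(range(len(genes)), [freq[g] for g in genes], color="steelblue")
    axf.invert_yaxis()
    axf.set_xlabel("frequency")
    fig.tight_layout()

    layout = sub.copy()
    layout["frequency"] = [freq[g] for g in genes]
    return _finish(fig, spec, layout)


def plot_cooc_mutex(cooc: pd.DataFrame, spec: PlotSpec) -> pd.DataFrame:
    """Triangular grid of pairwise co-occurrence / mutual exclusivity.

    Colour encodes -log10(p) signed by odds-ratio direction (positive =
    co-occurring tendency). Layout table = the pair table with the signed
    score column.
    """
    if cooc.empty:
        raise ValidationError("empty co-occurrence table")
    table = cooc.copy().reset_index(drop=True)
    sign = np.where(table["odds_ratio"] > 1, 1.0, -1.0)
    with np.errstate(divide="ignore"):
        mag = -np.log10(np.clip(table["p"].to_numpy(float), 1e-300, 1.0))
    table["signed_log10_p"] = sign * mag

    genes = sorted(set(table["gene_a"]) | set(table["gene_b"]))
    idx = {g: i for i, g in enumerate(genes)}
    grid = np.full((len(genes), len(genes)), np.nan)
    for _, row in table.iterrows():
        i, j = idx[row["gene_a"]], idx[row["gene_b"]]
        i, j = min(i, j), max(i, j)
        grid[i, j] = row["signed_log10_p"]
    fig, ax = plt.subplots(figsize=(spec.width, spec.height))
    vmax = np.nanmax(np.abs(grid)) or 1.0
    im = ax.imshow(grid, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(len(genes)), genes, rotation=90)
    ax.set_yticks(range(len(genes)), genes)
    fig.colorbar(im, ax=ax, label="signed -log10 p (red = co-occurring)")
    fig.tight_layout()
    return _finish(fig, spec, table)


def plot_heatmap_cell(
    abundance: pd.DataFrame,
    mutation_vector: pd.Series,
    driven_cells,
    spec: PlotSpec,
) -> pd.DataFrame:
    """Heat map of z-scored abundance of the driven cells, columns grouped
    mutated | non-mutated (sample-id order within groups), with a status
    annotation row. Layout table = annotation row stacked on the z matrix.
    """
    driven_cells = list(driven_cells)
    if not driven_cells:
        raise ValidationError("empty driven-cell set")
    missing = [c for c in driven_cells if c not in abundance.index]
    if missing:
        raise ValidationError(f"cells {missing} not in abundance matrix")
    shared = [s for s in abundance.columns if s in mutation_vector.index]
    if not shared:
        raise ValidationError("no shared samples between abundance and mutation vector")
    mv = mutation_vector.loc[shared]
    mutated = sorted(s for s in shared if mv[s] == 1)
    wild = sorted(s for s in shared if mv[s] == 0)
    cols = mutated + wild
    z = zscore_rows(abundance.loc[driven_cells, cols])

    fig, (ax_ann, ax) = plt.subplots(
        2, 1, figsize=(spec.width, spec.height), height_ratios=[1, 14], sharex=True
    )
    ax_ann.imshow(mv.loc[cols].to_numpy()[None, :], aspect="auto", cmap="binary",
                  interpolation="nearest")
    ax_ann.set_yticks([0], ["mutated"])
    lim = float(np.abs(z.to_numpy()).max()) or 1.0
    im = ax.imshow(z.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-lim, vmax=lim,
                   interpolation="nearest")
    ax.set_yticks(range(len(driven_cells)), driven_cells)
    ax.set_xticks([])
    ax.axvline(len(mutated) - 0.5, color="black", lw=1)
    fig.colorbar(im, ax=ax, label="abundance z-score")
    fig.tight_layout()

    ann = pd.DataFrame([mv.loc[cols].to_numpy()], index=["__mutation_status__"], columns=cols)
    layout = pd.concat([ann, z])
    return _finish(fig, spec, layout)


def plot_km(groups: pd.Series, survival: pd.DataFrame, spec: PlotSpec) -> pd.DataFrame:
    """Kaplan-Meier step curves for the risk groups with the log-rank p.

    Layout table columns: group, time, survival, at_risk; the log-rank p is
    repeated in a ``logrank_p`` column.
    """
    shared = [s for s in groups.index if s in survival.index]
    if not shared:
        raise ValidationError("no shared samples between groups and survival table")
    g = groups.loc[shared]
    surv = survival.loc[shared]
    chi2, p = log_rank(g, surv)

    fig, ax = plt.subplots(figsize=(spec.width, spec.height))
    frames = []
    for label, color in zip(sorted(g.unique()), ("crimson", "steelblue")):
        mask = g == label
        curve = km_curve(surv.loc[mask, "time"], surv.loc[mask, "event"])
        curve.insert(0, "group", label)
        frames.append(curve)
        ax.step(curve["time"], curve["survival"], where="post", color=color,
                label=f"{label} (n={int(mask.sum())})")
        cens = surv.loc[mask & (surv["event"] == 0)]
        if not cens.empty:
            surv_at = np.array([
                curve.loc[curve["time"] <= t, "survival"].iloc[-1] for t in cens["time"]
            ])
            ax.plot(cens["time"], surv_at, "|", color=color, markersize=8)
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.05)
    ax.legend()
    ax.set_title(f"log-rank p = {p:.3g}")
    fig.tight_layout()

    layout = pd.concat(frames, ignore_index=True)
    layout["logrank_p"] = p
    return _finish(fig, spec, layout)
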
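"""Mutation-driven immune-cell identification.

For each mutation gene: (1) SAM finds the cells whose abundance differs
between mutated and wild-type samples; (2) those cells' abundance rows are
z-scored across all samples and binarized at |z| > 2 into an "up-response"
and a "down-response" matrix (an entry is an extreme per-sample excursion of
that cell); (3) each significant cell's binary response vector — taken from
the matrix matching its SAM direction — is crossed with the binary mutation
vector in a 2x2 table and tested with Fisher's exact test; (4) p-values are
Benjamini-Hochberg adjusted across the cells tested for that gene (a global
across-gene mode is available) and cells below the FDR cut are reported as
driven by the mutation.

Also provides pairwise mutation co-occurrence / mutual-exclusivity calls
from the same exact test applied to pairs of mutation vectors.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .mutation import MutationMatrix
from .sam import DEFAULT_FDR_CUT, DEFAULT_N_PERM, SamResult, sam_test

DEFAULT_Z_THRESHOLD = 2.0


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-scores with sample SD (ddof=1); constant rows become zeros.

    Constant rows are recorded in ``result.attrs['constant_rows']``.
    """
    if matrix.shape[1] < 2:
        raise ValidationError("z-scoring needs >=2 columns")
    values = matrix.to_numpy(dtype=np.float64)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    constant = sd[:, 0] == 0
    sd[constant] = 1.0
    z = (values - mean) / sd
    z[constant] = 0.0
    out = pd.DataFrame(z, index=matrix.index, columns=matrix.columns)
    out.attrs["constant_rows"] = list(matrix.index[constant])
    return out


@dataclasses.dataclass
class BinaryCellMatrices:
    """Binary up-/down-response matrices from thresholded z-scores."""

    up: pd.DataFrame
    down: pd.DataFrame
    z_threshold: float = DEFAULT_Z_THRESHOLD

    def __post_init__(self) -> None:
        if ((self.up.to_numpy() == 1) & (self.down.to_numpy() == 1)).any():
            raise ValidationError("up and down response matrices must be disjoint")


def binarize(z_matrix: pd.DataFrame, z_threshold: float = DEFAULT_Z_THRESHOLD) -> BinaryCellMatrices:
    """up = 1 iff z > threshold (strict); down = 1 iff z <= -threshold."""
    if z_threshold <= 0:
        raise ValidationError("z_threshold must be > 0")
    z = z_matrix.to_numpy(dtype=np.float64)
    up = (z > z_threshold).astype(np.int8)
    down = (z <= -z_threshold).astype(np.int8)
    mk = lambda a: pd.DataFrame(a, index=z_matrix.index, columns=z_matrix.columns)
    return BinaryCellMatrices(up=mk(up), down=mk(down), z_threshold=float(z_threshold))


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 count table.

    Returns ``(odds_ratio, p)`` with the sample odds ratio a*d/(b*c)
    (``inf`` when b*c == 0 and a*d > 0). A zero row or column margin is
    degenerate: p = 1 and the odds ratio is NaN.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValidationError("table must be 2x2")
    if np.any(t < 0) or t.sum() == 0 or not np.issubdtype(t.dtype, np.integer):
        if not np.issubdtype(t.dtype, np.integer):
            if not np.allclose(t, np.round(t)):
                raise ValidationError("table entries must be nonnegative integers")
            t = np.round(t).astype(np.int64)
        if np.any(t < 0) or t.sum() == 0:
            raise ValidationError("table entries must be nonnegative with positive total")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return float("nan"), 1.0
    if b * c == 0:
        odds = float("inf")
    else:
        odds = (a * d) / (b * c)
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    return odds, min(p, 1.0)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), input order."""
    p = np.asarray(p, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclasses.dataclass
class AssociationResult:
    """Driven-cell calls for one mutation gene.

    ``table`` has one row per SAM-significant cell tested by the exact test
    (cell, direction, odds_ratio, p, fdr); ``driven`` restricts it to
    fdr < fdr_cut.
    """

    gene: str
    frequency: float
    table: pd.DataFrame
    fdr_cut: float = DEFAULT_FDR_CUT
    sam: SamResult | None = None
    note: str = ""

    @property
    def driven(self) -> pd.DataFrame:
        if self.table.empty:
            return self.table
        return self.table[self.table["fdr"] < self.fdr_cut]

    @property
    def driven_cells(self) -> list[str]:
        return list(self.driven["cell"])


_EMPTY_COLUMNS = ["cell", "direction", "odds_ratio", "p", "fdr"]


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(columns=_EMPTY_COLUMNS)


def associate(
    abundance: pd.DataFrame,
    mutations: MutationMatrix,
    sam_fdr: float = DEFAULT_FDR_CUT,
    fisher_fdr: float = DEFAULT_FDR_CUT,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    global_fdr: bool = False,
) -> dict[str, AssociationResult]:
    """Run the per-gene identification over every gene of the mutation matrix.

    Both matrices are reduced to their shared samples (in abundance column
    order); at least 20 shared samples are required and fewer than 50 draws a
    warning. Genes whose mutation vector has <2 mutated or <2 wild-type
    samples are skipped with a warning and yield an empty result, as do genes
    with no SAM-significant cell.
    """
    shared = [s for s in abundance.columns if s in set(mutations.samples)]
    if not shared:
        raise ValidationError("no shared samples between abundance and mutation matrices")
    if len(shared) < 20:
        raise ValidationError(f"only {len(shared)} shared samples; >=20 required")
    if len(shared) < 50:
        warnings.warn(f"only {len(shared)} shared samples; results may be underpowered",
                      stacklevel=2)
    ab = abundance.loc[:, shared]
    mut = mutations.data.loc[:, shared]
    freq = mutations.frequency

    seeds = np.random.SeedSequence(seed).spawn(len(mut.index))
    results: dict[str, AssociationResult] = {}
    pooled_p: list[tuple[str, int, float]] = []

    for gi, gene in enumerate(mut.index):
        labels = mut.loc[gene].to_numpy()
        n_mut = int(labels.sum())
        if n_mut < 2 or labels.size - n_mut < 2:
            warnings.warn(f"gene {gene!r}: <2 samples in a mutation class; skipped", stacklevel=2)
            results[gene] = AssociationResult(
                gene=gene, frequency=float(freq[gene]), table=_empty_table(),
                fdr_cut=fisher_fdr, note="skipped: <2 samples in a class",
            )
            continue

        sam = sam_test(ab, labels, n_perm=n_perm,
                       seed=np.random.default_rng(seeds[gi]), fdr_cut=sam_fdr)
        sig = sam.significant
        if len(sig) == 0:
            results[gene] = AssociationResult(
                gene=gene, frequency=float(freq[gene]), table=_empty_table(),
                fdr_cut=fisher_fdr, sam=sam,
            )
            continue

        z = zscore_rows(ab.loc[sig])
        binary = binarize(z, z_threshold=z_threshold)
        d_by_cell = pd.Series(sam.d, index=sam.cell_ids)

        rows = []
        for cell in sig:
            direction = 1 if d_by_cell[cell] > 0 else -1
            resp = (binary.up if direction > 0 else binary.down).loc[cell].to_numpy()
            a = int(((labels == 1) & (resp == 1)).sum())
            b = int(((labels == 1) & (resp == 0)).sum())
            c = int(((labels == 0) & (resp == 1)).sum())
            d = int(((labels == 0) & (resp == 0)).sum())
            odds, p = fisher_exact_2x2([[a, b], [c, d]])
            rows.append({"cell": cell, "direction": "up" if direction > 0 else "down",
                         "odds_ratio": odds, "p": p})
        table = pd.DataFrame(rows)
        if global_fdr:
            pooled_p.extend((gene, i, float(r["p"])) for i, r in table.iterrows())
            table["fdr"] = np.nan
        else:
            table["fdr"] = bh_adjust(table["p"].to_numpy())
            table = table.sort_values(["p", "cell"], kind="stable").reset_index(drop=True)
        results[gene] = AssociationResult(
            gene=gene, frequency=float(freq[gene]), table=table,
            fdr_cut=fisher_fdr, sam=sam,
        )

    if global_fdr and pooled_p:
        qs = bh_adjust([p for _, _, p in pooled_p])
        for (gene, i, _), q in zip(pooled_p, qs):
            results[gene].table.loc[i, "fdr"] = q
        for res in results.values():
            if not res.table.empty:
                res.table = res.table.sort_values(["p", "cell"], kind="stable").reset_index(drop=True)
    return results


def summarize(results: Mapping[str, AssociationResult]) -> pd.DataFrame:
    """Summary table (gene, cells, cell_count, mutation_rate), genes with at
    least one driven cell, sorted by descending cell count then gene id."""
    rows = []
    for gene, res in results.items():
        cells = sorted(res.driven_cells)
        if not cells:
            continue
        rows.append({"gene": gene, "cells": ", ".join(cells),
                     "cell_count": len(cells), "mutation_rate": res.frequency})
    out = pd.DataFrame(rows, columns=["gene", "cells", "cell_count", "mutation_rate"])
    if not out.empty:
        out = out.sort_values(["cell_count", "gene"], ascending=[False, True],
                              kind="stable").reset_index(drop=True)
    return out


def cooc_mutex(
    mutations: MutationMatrix,
    genes: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise co-occurrence / mutual exclusivity of mutation vectors.

    For every unordered gene pair the 2x2 table of joint mutation status is
    tested with Fisher's exact test; a pair is labelled ``co-occurring`` when
    odds_ratio > 1 and p < alpha, ``mutually exclusive`` when odds_ratio < 1
    and p < alpha, otherwise ``none``.
    """
    genes = list(genes) if genes is not None else list(mutations.genes)
    if len(genes) < 2:
        raise ValidationError("co-occurrence analysis needs >=2 genes")
    for g in genes:
        if g not in mutations.genes:
            raise ValidationError(f"gene {g!r} not in mutation matrix")
    data = mutations.data.loc[genes].to_numpy()
    rows = []
    for (i, ga), (j, gb) in itertools.combinations(enumerate(genes), 2):
        va, vb = data[i], data[j]
        a = int(((va == 1) & (vb == 1)).sum())
        b = int(((va == 1) & (vb == 0)).sum())
        c = int(((va == 0) & (vb == 1)).sum())
        d = int(((va == 0) & (vb == 0)).sum())
        odds, p = fisher_exact_2x2([[a, b], [c, d]])
        if p < alpha and odds > 1:
            label = "co-occurring"
        elif p < alpha and odds < 1:
            label = "mutually exclusive"
        else:
            label = "none"
        rows.append({"gene_a": ga, "gene_b": gb, "odds_ratio": odds, "p": p, "label": label})
    return pd.DataFrame(rows)
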
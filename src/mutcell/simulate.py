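"""Synthetic cohorts with known ground truth.

The generator emulates the statistical structure the pipeline assumes: per
gene an independent Bernoulli mutation status at a stated frequency; per
cell a standard-normal baseline abundance with planted additive mean shifts
(in SD units) in the mutated samples of selected (gene, cell) pairs; and
exponential survival times whose hazard is proportional to
``exp(sum_c beta_c * a_c)`` with independent exponential censoring.

Optionally a genes x samples expression matrix is emitted in which each
cell's signature genes (from a generated GMT) track that cell's abundance,
so that the full expression -> ssGSEA -> association path can be exercised.
The gene-dropout experiment removes a random fraction of expression genes to
probe the robustness of the identified gene-cell associations.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .mutation import MutationMatrix


@dataclasses.dataclass
class CohortTruth:
    """Planted ground truth of a synthetic cohort.

    ``associations`` holds (gene, cell, direction +1/-1, effect size in SD
    units); ``frequencies`` maps each gene to its Bernoulli mutation
    frequency; ``survival_betas`` maps cells to planted log-hazard slopes.
    """

    associations: list[tuple[str, str, int, float]]
    frequencies: dict[str, float]
    survival_betas: dict[str, float]
    seed: int

    def __post_init__(self) -> None:
        for gene, cell, direction, effect in self.associations:
            if direction not in (-1, 1):
                raise ValidationError(f"direction must be +1/-1 for ({gene}, {cell})")
            if effect <= 0:
                raise ValidationError(f"effect size must be > 0 for ({gene}, {cell})")
        for gene, f in self.frequencies.items():
            if not 0.0 < f < 1.0:
                raise ValidationError(f"mutation frequency must be in (0,1) for {gene}")

    @property
    def planted_pairs(self) -> set[tuple[str, str, str]]:
        return {(g, c, "up" if d > 0 else "down") for g, c, d, _ in self.associations}


@dataclasses.dataclass
class SimulatedCohort:
    """One synthetic cohort: abundance, mutations, survival, optional expression."""

    abundance: pd.DataFrame
    mutations: MutationMatrix
    survival: pd.DataFrame
    truth: CohortTruth
    expression: pd.DataFrame | None = None
    gene_sets: dict[str, list[str]] | None = None


def make_truth(
    n_genes: int,
    n_cells: int,
    planted: Sequence[tuple[int, int, int, float]] = (),
    frequency: float | Mapping[str, float] = 0.2,
    survival_betas: Mapping[str, float] | None = None,
    seed: int = 0,
) -> CohortTruth:
    """Build a CohortTruth from index-based plants.

    ``planted`` entries are (gene index, cell index, direction, effect).
    """
    genes = [f"G{i + 1:03d}" for i in range(n_genes)]
    cells = [f"C{i + 1:03d}" for i in range(n_cells)]
    assoc = []
    for gi, ci, direction, effect in planted:
        if not (0 <= gi < n_genes and 0 <= ci < n_cells):
            raise ValidationError(f"planted index ({gi}, {ci}) out of range")
        assoc.append((genes[gi], cells[ci], direction, effect))
    if isinstance(frequency, Mapping):
        freqs = {g: float(frequency[g]) for g in genes}
    else:
        freqs = {g: float(frequency) for g in genes}
    return CohortTruth(
        associations=assoc,
        frequencies=freqs,
        survival_betas=dict(survival_betas or {}),
        seed=int(seed),
    )


def generate_cohort(
    n_samples: int,
    n_cells: int,
    n_genes: int,
    truth: CohortTruth,
    censor_rate: float = 0.3,
    base_hazard: float = 0.01,
    expression: bool = False,
    genes_per_set: int = 10,
    n_background_genes: int = 300,
    signature_noise_sd: float = 0.5,
) -> SimulatedCohort:
    """Draw one cohort under the planted truth (deterministic in truth.seed)."""
    if n_samples < 20:
        raise ValidationError("n_samples must be >= 20")
    rng = np.random.default_rng(truth.seed)
    samples = [f"S{i + 1:04d}" for i in range(n_samples)]
    genes = [f"G{i + 1:03d}" for i in range(n_genes)]
    cells = [f"C{i + 1:03d}" for i in range(n_cells)]
    for g, c, _, _ in truth.associations:
        if g not in genes or c not in cells:
            raise ValidationError(f"planted pair ({g}, {c}) outside the cohort dimensions")

    mut = np.zeros((n_genes, n_samples), dtype=np.int8)
    for i, g in enumerate(genes):
        mut[i] = rng.random(n_samples) < truth.frequencies.get(g, 0.2)
    mutations = MutationMatrix(
        data=pd.DataFrame(mut, index=pd.Index(genes, name="gene"), columns=samples)
    )

    ab = rng.standard_normal((n_cells, n_samples))
    cell_row = {c: i for i, c in enumerate(cells)}
    gene_row = {g: i for i, g in enumerate(genes)}
    for g, c, direction, effect in truth.associations:
        carriers = mut[gene_row[g]] == 1
        ab[cell_row[c], carriers] += direction * effect
    abundance = pd.DataFrame(ab, index=pd.Index(cells, name="cell"), columns=samples)

    beta = np.array([truth.survival_betas.get(c, 0.0) for c in cells])
    hazard = base_hazard * np.exp(beta @ ab)
    t_event = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        c_rate = base_hazard * censor_rate / (1.0 - censor_rate)
        t_cens = rng.exponential(1.0 / c_rate, size=n_samples)
    else:
        t_cens = np.full(n_samples, np.inf)
    event = (t_event <= t_cens).astype(int)
    time = np.minimum(t_event, t_cens)
    survival = pd.DataFrame({"time": time, "event": event},
                            index=pd.Index(samples, name="sample"))

    expr = None
    gene_sets = None
    if expression:
        gene_sets = {
            c: [f"{c}_SG{k + 1:02d}" for k in range(genes_per_set)] for c in cells
        }
        sig_rows = []
        sig_names = []
        for c in cells:
            noise = rng.standard_normal((genes_per_set, n_samples)) * signature_noise_sd
            sig_rows.append(ab[cell_row[c]][None, :] + noise)
            sig_names.extend(gene_sets[c])
        bg = rng.standard_normal((n_background_genes, n_samples))
        bg_names = [f"BG{k + 1:04d}" for k in range(n_background_genes)]
        expr = pd.DataFrame(
            np.vstack(sig_rows + [bg]),
            index=pd.Index(sig_names + bg_names, name="gene"),
            columns=samples,
        )

    return SimulatedCohort(
        abundance=abundance, mutations=mutations, survival=survival,
        truth=truth, expression=expr, gene_sets=gene_sets,
    )


def dropout_genes(expression: pd.DataFrame, fraction: float, seed: int | None = None) -> pd.DataFrame:
    """Remove a uniformly random gene subset of size round(fraction * n)."""
    if not 0.0 <= fraction < 1.0:
        raise ValidationError("dropout fraction must be in [0, 1)")
    n = expression.shape[0]
    k = int(round(fraction * n))
    if k == 0:
        return expression.copy()
    rng = np.random.default_rng(seed)
    drop = rng.choice(n, size=k, replace=False)
    keep = np.setdiff1d(np.arange(n), drop)
    return expression.iloc[keep]


def dropout_series(
    expression: pd.DataFrame,
    fractions: Sequence[float],
    seed: int | None = None,
) -> dict[float, pd.DataFrame]:
    """Nested gene-dropout series: one random gene order per seed, with the
    removed set at each fraction containing the removed sets of all smaller
    fractions. The coupling makes the information removed monotone in the
    fraction, which sharpens seed-averaged robustness curves."""
    for f in fractions:
        if not 0.0 <= f < 1.0:
            raise ValidationError("dropout fraction must be in [0, 1)")
    n = expression.shape[0]
    perm = np.random.default_rng(seed).permutation(n)
    out = {}
    for f in fractions:
        k = int(round(f * n))
        out[f] = expression.iloc[np.sort(perm[k:])]
    return out


def overlap_score(
    baseline: Mapping[str, Sequence[str]],
    other: Mapping[str, Sequence[str]],
) -> pd.Series:
    """Per-gene fraction of the baseline driven cells recovered in ``other``.

    Genes with an empty baseline cell set are skipped.
    """
    rows = {}
    for gene, cells_a in baseline.items():
        cells_a = set(cells_a)
        if not cells_a:
            continue
        cells_b = set(other.get(gene, ()))
        rows[gene] = len(cells_a & cells_b) / len(cells_a)
    return pd.Series(rows, name="overlap", dtype=float)
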
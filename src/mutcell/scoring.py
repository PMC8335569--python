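"""Cell-abundance inference from bulk expression via single-sample GSEA.

For every sample the genes are ranked by descending expression and each
cell-type signature receives a weighted Kolmogorov-Smirnov-like running-sum
enrichment score: the cumulative, rank-weighted fraction of signature genes
encountered minus the cumulative fraction of non-signature genes. Because the
score depends on within-sample ranks only, it is invariant to any strictly
monotone per-sample transform of expression (scaling, log, quantile shifts).

The rank weight is ``rankvalue**alpha`` with rankvalue N..1 from the top of
the ranking; ``alpha=0.25`` is the customary default. With ``normalize=True``
all scores are divided by the global (max - min) range of the score matrix so
that abundances are comparable across cell types.

Matrices produced by external deconvolution tools (xCell, CIBERSORT, ...)
are supported as precomputed imports; their algorithms are not re-implemented
here and the downstream pipeline treats any cells x samples abundance matrix
as interchangeable.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import read_matrix, truncate_barcodes

DEFAULT_ALPHA = 0.25


@dataclasses.dataclass(frozen=True)
class SsgseaParams:
    """Scoring parameters: rank-weight exponent and global range normalization."""

    alpha: float = DEFAULT_ALPHA
    normalize: bool = True

    def __post_init__(self) -> None:
        if not np.isfinite(self.alpha) or self.alpha < 0:
            raise ValidationError(f"alpha must be finite and >= 0, got {self.alpha}")


def ssgsea_score(
    expression: pd.DataFrame,
    gene_sets: Mapping[str, Sequence[str]],
    params: SsgseaParams | None = None,
) -> pd.DataFrame:
    """Score every gene set in every sample; returns cells x samples.

    Genes absent from the expression matrix are dropped per set (a warning
    reports the counts). A set with no gene present yields a NaN row; a set
    covering *all* genes has an empty complement and is an error. Ties in
    expression are broken deterministically by ascending gene id.
    """
    params = params or SsgseaParams()
    if expression.index.has_duplicates:
        raise ValidationError("expression matrix has duplicate gene ids")
    n_genes, n_samples = expression.shape
    if n_samples < 1 or n_genes < 2:
        raise ValidationError("expression matrix too small to score")

    gene_pos = {g: i for i, g in enumerate(expression.index)}
    missing_report: dict[str, int] = {}
    set_members: dict[str, np.ndarray] = {}
    for name, genes in gene_sets.items():
        genes = list(dict.fromkeys(genes))
        present = [gene_pos[g] for g in genes if g in gene_pos]
        dropped = len(genes) - len(present)
        if dropped:
            missing_report[name] = dropped
        if len(present) == n_genes:
            raise ValidationError(
                f"gene set {name!r} covers every expression gene; the complement is empty"
            )
        set_members[name] = np.asarray(present, dtype=np.intp)
    if not any(m.size for m in set_members.values()):
        raise ValidationError("no gene set has any gene present in the expression matrix")
    if missing_report:
        warnings.warn(
            "genes absent from the expression matrix were dropped per set: "
            + ", ".join(f"{k}: {v}" for k, v in sorted(missing_report.items())),
            stacklevel=2,
        )

    values = expression.to_numpy(dtype=np.float64)
    # Secondary sort key: lexicographic rank of the gene id (ascending on ties).
    gene_rank = np.empty(n_genes, dtype=np.intp)
    gene_rank[np.argsort(expression.index.to_numpy().astype(str), kind="stable")] = np.arange(n_genes)

    # rankvalue at ranking position i (0-based) is N - i; weight = rankvalue**alpha
    weights = (np.arange(n_genes, 0, -1, dtype=np.float64)) ** params.alpha

    scores = np.full((len(set_members), n_samples), np.nan)
    in_set = np.zeros(n_genes, dtype=bool)
    for j in range(n_samples):
        order = np.lexsort((gene_rank, -values[:, j]))
        for si, (name, members) in enumerate(set_members.items()):
            if members.size == 0:
                continue
            in_set[:] = False
            in_set[members] = True
            hit = in_set[order]
            hit_w = np.where(hit, weights, 0.0)
            denom = hit_w.sum()
            p_hit = np.cumsum(hit_w) / denom
            p_miss = np.cumsum(~hit) / (n_genes - members.size)
            scores[si, j] = float(np.sum(p_hit - p_miss))

    if params.normalize:
        finite = scores[np.isfinite(scores)]
        rng = finite.max() - finite.min() if finite.size else 0.0
        if rng > 0:
            scores = scores / rng

    return pd.DataFrame(
        scores, index=pd.Index(list(set_members), name="cell"), columns=expression.columns
    )


def import_abundance(
    path: str | Path,
    expected_samples: Sequence[str],
    barcode_length: int | None = None,
) -> pd.DataFrame:
    """Load a precomputed cells x samples abundance TSV and align its columns.

    Column ids are matched to ``expected_samples`` after optional barcode
    truncation; extra columns are dropped with a warning and any missing
    expected sample is an error.
    """
    df = read_matrix(path)
    truncated = truncate_barcodes(df.columns, barcode_length)
    if len(set(truncated)) != len(truncated):
        raise ValidationError(f"{path}: barcode truncation makes sample ids collide")
    df.columns = truncated
    expected = [str(s) for s in expected_samples]
    missing = [s for s in expected if s not in df.columns]
    if missing:
        raise ValidationError(f"{path}: abundance matrix is missing expected samples {missing}")
    extra = [s for s in df.columns if s not in set(expected)]
    if extra:
        warnings.warn(f"{len(extra)} abundance column(s) not in the expected sample set were dropped",
                      stacklevel=2)
    return df.loc[:, expected]
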
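"""Model/Results interface over the mutation -> immune-cell pipeline.

``MutationImmuneModel`` holds the aligned cell-abundance matrix, binary
mutation matrix and (optionally) survival data for one cohort; ``fit()``
runs the SAM -> binarization -> Fisher/FDR identification for every mutation
gene and returns a ``MutationImmuneResults`` carrying the per-gene
association tables, a Table-1-style ``summary()`` and plotting helpers.

``CellRiskModel`` fits the multivariate Cox model on the driven cells of one
gene; its ``CellRiskResults`` carries coefficients with standard errors and
confidence intervals, per-sample risk scores, the median-split risk groups,
the log-rank comparison, and the Kaplan-Meier plot.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as mio
from .association import (
    DEFAULT_Z_THRESHOLD,
    AssociationResult,
    associate,
    cooc_mutex,
    summarize,
)
from .errors import ValidationError
from .mutation import DEFAULT_MIN_FREQUENCY, MutationMatrix, build_mutation_matrix
from .plots import PlotSpec, plot_cooc_mutex, plot_heatmap_cell, plot_km, plot_waterfall
from .sam import DEFAULT_FDR_CUT, DEFAULT_N_PERM
from .scoring import SsgseaParams, import_abundance, ssgsea_score
from .survival import fit_cox, log_rank, median_split, risk_scores


class MutationImmuneModel:
    """Association model of immune-cell abundance with somatic mutation status."""

    def __init__(
        self,
        abundance: pd.DataFrame,
        mutations: MutationMatrix | pd.DataFrame,
        survival: pd.DataFrame | None = None,
    ):
        if isinstance(mutations, pd.DataFrame):
            mutations = MutationMatrix(data=mutations)
        self.abundance = abundance
        self.mutations = mutations
        self.survival = survival

    @classmethod
    def from_files(
        cls,
        expression: str | Path | None = None,
        gene_sets: str | Path | None = None,
        abundance: str | Path | None = None,
        maf: str | Path | None = None,
        mutation_matrix: str | Path | None = None,
        survival: str | Path | None = None,
        min_freq: float = DEFAULT_MIN_FREQUENCY,
        barcode_length: int | None = mio.DEFAULT_BARCODE_LENGTH,
        ssgsea: SsgseaParams | None = None,
    ) -> "MutationImmuneModel":
        """Assemble a model from files on disk.

        Provide either ``expression`` + ``gene_sets`` (scored natively) or a
        precomputed ``abundance`` matrix, and either a ``maf`` or a binary
        ``mutation_matrix`` TSV. Sample ids are matched after barcode
        truncation.
        """
        if (expression is None) == (abundance is None):
            raise ValidationError("provide exactly one of expression or abundance")
        if (maf is None) == (mutation_matrix is None):
            raise ValidationError("provide exactly one of maf or mutation_matrix")

        if expression is not None:
            if gene_sets is None:
                raise ValidationError("gene_sets (GMT) required with expression input")
            expr = mio.read_expression(expression)
            expr.columns = _truncate_unique(expr.columns, barcode_length, "expression")
            ab = ssgsea_score(expr, mio.read_gmt(gene_sets), ssgsea)
        else:
            ab = mio.read_matrix(abundance)
            ab.columns = _truncate_unique(ab.columns, barcode_length, "abundance")

        if maf is not None:
            records = mio.read_maf(maf)
            mut = build_mutation_matrix(
                records, list(ab.columns), min_freq=min_freq, barcode_length=barcode_length
            )
        else:
            mdf = mio.read_matrix(mutation_matrix)
            mdf.columns = _truncate_unique(mdf.columns, barcode_length, "mutation")
            mut = MutationMatrix(data=mdf.astype(np.int8), min_frequency=min_freq)

        surv = mio.read_survival(survival) if survival is not None else None
        if surv is not None:
            surv.index = _truncate_unique(surv.index, barcode_length, "survival")
        return cls(abundance=ab, mutations=mut, survival=surv)

    def fit(
        self,
        sam_fdr: float = DEFAULT_FDR_CUT,
        fisher_fdr: float = DEFAULT_FDR_CUT,
        z_threshold: float = DEFAULT_Z_THRESHOLD,
        n_perm: int = DEFAULT_N_PERM,
        seed: int | None = None,
        global_fdr: bool = False,
    ) -> "MutationImmuneResults":
        results = associate(
            self.abundance,
            self.mutations,
            sam_fdr=sam_fdr,
            fisher_fdr=fisher_fdr,
            z_threshold=z_threshold,
            n_perm=n_perm,
            seed=seed,
            global_fdr=global_fdr,
        )
        return MutationImmuneResults(self, results)


class MutationImmuneResults:
    """Fitted driven-cell calls for every mutation gene of a cohort."""

    def __init__(self, model: MutationImmuneModel, associations: dict[str, AssociationResult]):
        self.model = model
        self.associations = associations

    def summary(self) -> pd.DataFrame:
        """Genes with >=1 driven cell: gene, cells, cell_count, mutation_rate."""
        return summarize(self.associations)

    def detail(self, gene: str) -> pd.DataFrame:
        """Per-cell exact-test table for one gene (cell, direction, OR, p, fdr)."""
        if gene not in self.associations:
            raise ValidationError(f"gene {gene!r} was not analyzed")
        return self.associations[gene].table

    def driven_cells(self, gene: str) -> list[str]:
        if gene not in self.associations:
            raise ValidationError(f"gene {gene!r} was not analyzed")
        return self.associations[gene].driven_cells

    def driven_map(self) -> dict[str, list[str]]:
        return {g: r.driven_cells for g, r in self.associations.items()}

    def pairs(self) -> set[tuple[str, str, str]]:
        """All reported (gene, cell, direction) triples."""
        out = set()
        for gene, res in self.associations.items():
            for _, row in res.driven.iterrows():
                out.add((gene, row["cell"], row["direction"]))
        return out

    def cooccurrence(self, genes: Sequence[str] | None = None, alpha: float = 0.05) -> pd.DataFrame:
        if genes is None:
            genes = list(self.summary()["gene"])
        return cooc_mutex(self.model.mutations, genes, alpha=alpha)

    def risk_model(self, gene: str, cells: Sequence[str] | None = None) -> "CellRiskModel":
        """Cox risk-signature model on this gene's driven cells."""
        if self.model.survival is None:
            raise ValidationError("model has no survival data")
        cells = list(cells) if cells is not None else self.driven_cells(gene)
        if not cells:
            raise ValidationError(f"gene {gene!r} has no driven cells")
        return CellRiskModel(
            gene=gene,
            abundance_subset=self.model.abundance.loc[cells],
            survival=self.model.survival,
        )

    # -- plotting -----------------------------------------------------------
    def plot_waterfall(self, spec: PlotSpec, genes: Sequence[str] | None = None) -> pd.DataFrame:
        genes = list(genes) if genes is not None else list(self.summary()["gene"])
        return plot_waterfall(self.model.mutations, genes, spec)

    def plot_cooccurrence(self, spec: PlotSpec, genes: Sequence[str] | None = None) -> pd.DataFrame:
        return plot_cooc_mutex(self.cooccurrence(genes), spec)

    def plot_heatmap(self, gene: str, spec: PlotSpec) -> pd.DataFrame:
        return plot_heatmap_cell(
            self.model.abundance,
            self.model.mutations.vector(gene),
            self.driven_cells(gene),
            spec,
        )


class CellRiskModel:
    """Multivariate Cox model of survival on the driven cells of one gene."""

    def __init__(self, gene: str, abundance_subset: pd.DataFrame, survival: pd.DataFrame):
        self.gene = gene
        self.abundance_subset = abundance_subset
        self.survival = mio.validate_survival(survival)

    def fit(self, ties: str = "breslow", zscore: bool = False) -> "CellRiskResults":
        """Fit and build the risk signature.

        ``zscore=True`` standardises each cell's abundance row before both
        the fit and the risk score (the default uses raw abundances).
        """
        ab = self.abundance_subset
        if zscore:
            from .association import zscore_rows

            ab = zscore_rows(ab)
        cox = fit_cox(ab, self.survival, ties=ties)
        scores = risk_scores(cox.params, ab.loc[:, cox.samples])
        groups = median_split(scores)
        chi2, p = log_rank(groups, self.survival)
        return CellRiskResults(self, cox, scores, groups, chi2, p)


class CellRiskResults:
    """Fitted risk signature: coefficients, scores, groups, log-rank test."""

    def __init__(self, model: CellRiskModel, cox, scores: pd.Series, groups: pd.Series,
                 logrank_chi2: float, logrank_p: float):
        self.model = model
        self.cox = cox
        self.risk_scores = scores
        self.groups = groups
        self.logrank_chi2 = logrank_chi2
        self.logrank_p = logrank_p

    @property
    def params(self) -> pd.Series:
        return self.cox.params

    @property
    def bse(self) -> pd.Series:
        return self.cox.bse

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.cox.conf_int(alpha)

    def summary(self) -> pd.DataFrame:
        """Coefficient table: beta, se, hazard ratio, 95% CI, z, p."""
        from scipy import stats as _st

        beta = self.params
        se = self.bse
        z = beta / se
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "beta": beta,
                "se": se,
                "hazard_ratio": np.exp(beta),
                "ci_lower": ci["lower"],
                "ci_upper": ci["upper"],
                "z": z,
                "p": 2 * _st.norm.sf(np.abs(z)),
            }
        )

    def plot_km(self, spec: PlotSpec) -> pd.DataFrame:
        return plot_km(self.groups, self.model.survival, spec)


def _truncate_unique(ids, length, what: str):
    truncated = mio.truncate_barcodes(ids, length)
    if len(set(truncated)) != len(truncated):
        raise ValidationError(f"{what}: barcode truncation to {length} makes sample ids collide")
    return pd.Index(truncated)
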
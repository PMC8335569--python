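"""Binary gene x sample mutation matrix from MAF records.

Only non-silent (protein-altering) variant classes count as mutation events:
nonsense, missense, frame-shift indels, splice site, nonstop, translation
start site, and in-frame indels. A gene's mutation frequency is its mutated
fraction over the declared sample universe (typically the expression-matched
samples), and genes below the frequency threshold are dropped; the threshold
is inclusive, so at the 1% default a gene mutated in exactly 1% of samples
is retained.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import MafRecord, truncate_barcodes

#: Canonical MAF Variant_Classification tokens treated as non-silent.
NONSILENT_CLASSES = frozenset(
    s.lower()
    for s in (
        "Nonsense_Mutation",
        "Missense_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "Splice_Site",
        "Nonstop_Mutation",
        "Translation_Start_Site",
        "In_Frame_Del",
        "In_Frame_Ins",
    )
)

DEFAULT_MIN_FREQUENCY = 0.01


def classify_nonsilent(variant_classification: str) -> bool:
    """True iff the token is one of the non-silent MAF classes (case-insensitive)."""
    return str(variant_classification).strip().lower() in NONSILENT_CLASSES


@dataclasses.dataclass
class MutationMatrix:
    """Binary genes x samples mutation-status matrix.

    ``data`` holds 0/1 int8 values; ``frequency`` is the per-gene mutated
    fraction over all columns; ``min_frequency`` is the retention threshold
    the matrix was built with.
    """

    data: pd.DataFrame
    min_frequency: float = 0.0
    n_skipped_records: int = 0

    def __post_init__(self) -> None:
        vals = self.data.to_numpy()
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise ValidationError("mutation matrix entries must be 0 or 1")
        self.data = self.data.astype(np.int8)
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise ValidationError("mutation matrix has duplicate gene or sample ids")

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    @property
    def frequency(self) -> pd.Series:
        return self.data.sum(axis=1) / self.data.shape[1]

    def vector(self, gene: str) -> pd.Series:
        if gene not in self.data.index:
            raise ValidationError(f"gene {gene!r} not in mutation matrix")
        return self.data.loc[gene]


def build_mutation_matrix(
    records: Iterable[MafRecord],
    samples: Sequence[str],
    min_freq: float = DEFAULT_MIN_FREQUENCY,
    barcode_length: int | None = None,
) -> MutationMatrix:
    """Aggregate MAF records into a binary mutation matrix over ``samples``.

    A cell (gene, sample) is 1 iff at least one non-silent record exists for
    that pair; samples with no records get all-zero columns. Records whose
    (optionally barcode-truncated) sample is not in the universe are skipped
    with a warning. Genes with frequency < ``min_freq`` are dropped and the
    rest sorted by descending frequency, ties broken by gene id.
    """
    samples = list(dict.fromkeys(str(s) for s in samples))
    if not samples:
        raise ValidationError("sample universe is empty")
    if not 0.0 <= min_freq <= 1.0:
        raise ValidationError(f"min_freq must be in [0, 1], got {min_freq}")
    col = {s: j for j, s in enumerate(samples)}

    pairs: set[tuple[str, str]] = set()
    n_skipped = 0
    for rec in records:
        if not classify_nonsilent(rec.variant_classification):
            continue
        barcode = truncate_barcodes([rec.sample_barcode], barcode_length)[0]
        if barcode not in col:
            n_skipped += 1
            continue
        pairs.add((rec.gene_symbol, barcode))
    if n_skipped:
        warnings.warn(
            f"{n_skipped} non-silent MAF record(s) had sample barcodes outside "
            "the declared sample universe and were skipped",
            stacklevel=2,
        )

    genes = sorted({g for g, _ in pairs})
    values = np.zeros((len(genes), len(samples)), dtype=np.int8)
    gene_row = {g: i for i, g in enumerate(genes)}
    for g, s in pairs:
        values[gene_row[g], col[s]] = 1

    data = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples)
    freq = data.sum(axis=1) / len(samples)
    data = data.loc[freq >= min_freq]
    freq = freq.loc[data.index]
    order = sorted(data.index, key=lambda g: (-freq[g], g))
    data = data.loc[order]
    return MutationMatrix(data=data, min_frequency=min_freq, n_skipped_records=n_skipped)
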
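"""Somatic mutation calls and the binary sample x gene mutation matrix.

The mutual-exclusivity screen operates on a 0/1 indicator matrix (rows =
patients, columns = genes, 1 = mutated) built from MAF-like call tables.
Genes are kept only if their cohort-wide mutation rate exceeds a threshold
(default 4%), except for an always-retained anchor panel of DNA
de/methylation genes (IDH1/2, TET1/2/3, DNMT1/3A/3B/3L).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("mutexm")

#: Canonical vocabulary of variant class labels; anything else maps to "other".
VARIANT_CLASSES = frozenset(
    {
        "missense",
        "nonsense",
        "frameshift",
        "splice_site",
        "in_frame_indel",
        "silent",
        "fusion",
        "other",
    }
)

#: Default anchor panel: the DNA de/methylation gene families.
DEFAULT_ANCHORS = (
    "IDH1",
    "IDH2",
    "TET1",
    "TET2",
    "TET3",
    "DNMT1",
    "DNMT3A",
    "DNMT3B",
    "DNMT3L",
)

# Mapping from MAF Variant_Classification labels to the internal vocabulary.
_MAF_CLASS_MAP = {
    "MISSENSE_MUTATION": "missense",
    "NONSENSE_MUTATION": "nonsense",
    "FRAME_SHIFT_DEL": "frameshift",
    "FRAME_SHIFT_INS": "frameshift",
    "SPLICE_SITE": "splice_site",
    "IN_FRAME_DEL": "in_frame_indel",
    "IN_FRAME_INS": "in_frame_indel",
    "SILENT": "silent",
    "FUSION": "fusion",
}


class FormatError(ValueError):
    """A call table violates the expected column/field layout."""


class EmptyInputError(ValueError):
    """An input contains no usable records."""


@dataclass(frozen=True)
class MutationCall:
    """One somatic mutation or fusion call.

    Fusion calls (e.g. CBFB-MYH11) are recorded under the 5' partner gene
    symbol with ``variant_class="fusion"``, so that fusions and point
    mutations of the same gene pool into a single matrix column.
    """

    sample_id: str
    gene_symbol: str
    variant_class: str = "other"

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise FormatError("sample_id must be non-empty")
        if not self.gene_symbol:
            raise FormatError("gene_symbol must be non-empty")
        if self.variant_class not in VARIANT_CLASSES:
            object.__setattr__(self, "variant_class", "other")


@dataclass
class BinaryMutationMatrix:
    """Sample x gene mutation indicator matrix (1 = mutated, 0 = wild type)."""

    samples: list[str]
    genes: list[str]
    values: np.ndarray  # shape (n_samples, n_genes), dtype int8

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample_ids")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene symbols")
        if self.values.shape != (len(self.samples), len(self.genes)):
            raise ValueError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.samples)} samples x {len(self.genes)} genes"
            )
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("matrix entries must be 0 or 1")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def column(self, gene: str) -> np.ndarray:
        try:
            j = self.genes.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in matrix") from None
        return self.values[:, j]

    def mutation_rates(self) -> pd.Series:
        """Per-gene fraction of mutated samples."""
        return pd.Series(
            self.values.mean(axis=0), index=self.genes, name="mutation_rate"
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.samples, name="sample"),
                            columns=self.genes)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BinaryMutationMatrix":
        return cls(
            samples=[str(s) for s in df.index],
            genes=[str(g) for g in df.columns],
            values=df.to_numpy(),
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BinaryMutationMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls.from_frame(df)


@dataclass
class AnchorPanel:
    """Genes always retained by the rate filter and used as screen anchors."""

    genes: tuple[str, ...] = field(default=DEFAULT_ANCHORS)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("anchor panel must be non-empty")
        self.genes = tuple(dict.fromkeys(g.upper() for g in self.genes))

    def present_in(self, m: BinaryMutationMatrix) -> list[str]:
        """Anchors present in the matrix; absent anchors are warned about."""
        present = [g for g in self.genes if g in m.genes]
        missing = [g for g in self.genes if g not in m.genes]
        if missing:
            logger.warning("anchors absent from matrix, skipped: %s",
                           ", ".join(missing))
        return present

    @classmethod
    def from_file(cls, path: str | Path) -> "AnchorPanel":
        genes = [ln.strip() for ln in Path(path).read_text().splitlines()
                 if ln.strip() and not ln.startswith("#")]
        return cls(tuple(genes))


# ---------------------------------------------------------------------------
# Reading call tables
# ---------------------------------------------------------------------------

_MAF_COLS = {"Tumor_Sample_Barcode": "sample", "Hugo_Symbol": "gene",
             "Variant_Classification": "variant_class"}


def read_calls(path: str | Path, format: str = "auto") -> list[MutationCall]:
    """Read a mutation call table (simple TSV or minimal MAF dialect).

    Parameters
    ----------
    path
        Tab-separated UTF-8 file with a header row. The simple dialect needs
        columns ``sample`` and ``gene`` (optional ``variant_class``); the MAF
        dialect is auto-detected from ``Tumor_Sample_Barcode`` /
        ``Hugo_Symbol`` headers. Extra columns are ignored.
    format
        ``"tsv"``, ``"maf-minimal"`` or ``"auto"``.

    Returns
    -------
    list of :class:`MutationCall`, one per non-header row, gene symbols
    upper-cased, sample IDs verbatim.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: empty call table") from None

    is_maf = "Tumor_Sample_Barcode" in df.columns and "Hugo_Symbol" in df.columns
    if format == "auto":
        format = "maf-minimal" if is_maf else "tsv"
    if format == "maf-minimal":
        if not is_maf:
            missing = [c for c in ("Tumor_Sample_Barcode", "Hugo_Symbol")
                       if c not in df.columns]
            raise FormatError(f"{path}: missing MAF column(s) {missing}")
        df = df.rename(columns=_MAF_COLS)
        if "variant_class" in df.columns:
            df["variant_class"] = (
                df["variant_class"].str.upper().map(_MAF_CLASS_MAP).fillna("other")
            )
    elif format == "tsv":
        for col in ("sample", "gene"):
            if col not in df.columns:
                raise FormatError(f"{path}: missing mandatory column {col!r}")
    else:
        raise ValueError(f"unknown format {format!r}")

    if df.empty:
        raise EmptyInputError(f"{path}: no call records")

    if "variant_class" not in df.columns:
        df["variant_class"] = "other"

    calls = []
    for row in df.itertuples(index=False):
        sample = getattr(row, "sample")
        gene = getattr(row, "gene")
        vc = getattr(row, "variant_class")
        if pd.isna(sample) or not str(sample).strip():
            raise FormatError(f"{path}: blank sample field")
        if pd.isna(gene) or not str(gene).strip():
            raise FormatError(f"{path}: blank gene field")
        vc = str(vc).strip().lower() if not pd.isna(vc) else "other"
        calls.append(MutationCall(str(sample).strip(),
                                  str(gene).strip().upper(), vc))
    return calls


# ---------------------------------------------------------------------------
# Binarization and rate filtering
# ---------------------------------------------------------------------------


def binarize(
    calls: Iterable[MutationCall],
    samples: Sequence[str] | None = None,
    exclude_classes: Iterable[str] = (),
) -> BinaryMutationMatrix:
    """Collapse calls into a 0/1 sample x gene matrix.

    Entry (s, g) is 1 iff at least one call exists for that pair; call
    multiplicity is collapsed. When a full cohort ``samples`` list is given,
    samples without any call appear as all-zero rows (they carry the
    wild-type evidence the exclusivity test needs), and calls from sample IDs
    outside the cohort are an error. ``exclude_classes`` drops calls of the
    named variant classes (e.g. ``{"silent"}``) before binarization; no class
    is excluded by default.
    """
    exclude = frozenset(exclude_classes)
    calls = [c for c in calls if c.variant_class not in exclude]

    if samples is None:
        if not calls:
            raise EmptyInputError("no calls and no cohort sample list")
        sample_list = list(dict.fromkeys(c.sample_id for c in calls))
    else:
        sample_list = list(dict.fromkeys(str(s) for s in samples))
        known = set(sample_list)
        unknown = sorted({c.sample_id for c in calls} - known)
        if unknown:
            raise ValueError(f"calls from samples not in cohort: {unknown}")

    gene_list = sorted({c.gene_symbol for c in calls})
    s_idx = {s: i for i, s in enumerate(sample_list)}
    g_idx = {g: j for j, g in enumerate(gene_list)}
    values = np.zeros((len(sample_list), len(gene_list)), dtype=np.int8)
    for c in calls:
        values[s_idx[c.sample_id], g_idx[c.gene_symbol]] = 1
    return BinaryMutationMatrix(sample_list, gene_list, values)


def filter_by_rate(
    m: BinaryMutationMatrix,
    min_rate: float = 0.04,
    keep: AnchorPanel | None = None,
) -> BinaryMutationMatrix:
    """Keep genes whose mutation rate is strictly above ``min_rate``.

    Anchor-panel genes present in the matrix are retained regardless of
    rate. Sample set and gene order are preserved.
    """
    if not 0 <= min_rate < 1:
        raise ValueError(f"min_rate must be in [0, 1), got {min_rate}")
    rates = m.values.mean(axis=0)
    keep_set = set(keep.present_in(m)) if keep is not None else set()
    cols = [j for j, g in enumerate(m.genes)
            if rates[j] > min_rate or g in keep_set]
    return BinaryMutationMatrix(
        samples=list(m.samples),
        genes=[m.genes[j] for j in cols],
        values=m.values[:, cols],
    )
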
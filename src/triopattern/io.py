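"""Reading, validation and replicate aggregation of FPKM expression datasets.

The pipeline's universe is an :class:`ExpressionDataset`: a gene x sample
FPKM matrix, per-sample metadata (genotype, tissue, replicate) and a cross
design listing each hybrid with its two inbred parents.  Genes with an
aggregated FPKM below ``expression_threshold`` (default 1.0) are treated as
non-expressed; the threshold is applied to the replicate-aggregated value,
not per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

#: FPKM below which a gene counts as non-expressed in a genotype x tissue.
EXPRESSION_THRESHOLD = 1.0

AggregationMethod = Literal["mean", "median"]


class DatasetError(ValueError):
    """Raised when an input file violates the dataset contract."""


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one RNA-seq sample (e.g. ``ZC_L1``)."""

    sample_id: str
    genotype: str
    tissue: str
    replicate: int

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise DatasetError(
                f"sample {self.sample_id!r}: replicate must be >= 1, got {self.replicate}"
            )


@dataclass(frozen=True)
class CrossSpec:
    """One cross of the diallel design: a hybrid and its two inbred parents."""

    hybrid: str
    parent1: str
    parent2: str

    def __post_init__(self) -> None:
        if self.parent1 == self.parent2:
            raise DatasetError(f"cross {self.hybrid!r}: parents must differ")
        if self.hybrid in (self.parent1, self.parent2):
            raise DatasetError(f"cross {self.hybrid!r}: hybrid cannot be its own parent")


@dataclass
class GenotypeTissueProfile:
    """Per-gene aggregated expression of one genotype in one tissue."""

    genotype: str
    tissue: str
    values: pd.Series  # gene_id -> aggregated FPKM
    expressed: pd.Series  # gene_id -> bool, values >= threshold
    threshold: float = EXPRESSION_THRESHOLD
    n_replicates: int = 0


@dataclass
class ExpressionDataset:
    """FPKM matrix plus sample metadata and cross design.

    ``matrix`` is genes x samples with the gene identifier as index; every
    column must be described by exactly one :class:`SampleMeta`.
    """

    matrix: pd.DataFrame
    samples: list[SampleMeta]
    design: list[CrossSpec]

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if self.matrix.index.has_duplicates:
            dupes = self.matrix.index[self.matrix.index.duplicated()].unique().tolist()
            raise DatasetError(f"duplicate gene IDs in matrix: {dupes[:5]}")
        meta_ids = [s.sample_id for s in self.samples]
        if len(set(meta_ids)) != len(meta_ids):
            raise DatasetError("duplicate sample_id in sample sheet")
        triples = {(s.genotype, s.tissue, s.replicate) for s in self.samples}
        if len(triples) != len(self.samples):
            raise DatasetError("duplicate (genotype, tissue, replicate) triple in sample sheet")
        meta_set = set(meta_ids)
        for col in self.matrix.columns:
            if col not in meta_set:
                raise DatasetError(f"matrix column {col!r} missing from sample sheet")
        matrix_cols = set(self.matrix.columns)
        for sid in meta_ids:
            if sid not in matrix_cols:
                raise DatasetError(f"sample sheet entry {sid!r} has no matrix column")

        values = self.matrix.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            bad = self._first_bad_cell(lambda v: not _is_number(v))
            raise DatasetError(f"non-numeric FPKM at gene {bad[0]!r}, sample {bad[1]!r}")
        finite = np.isfinite(values)
        if not finite.all():
            i, j = np.argwhere(~finite)[0]
            raise DatasetError(
                f"non-finite FPKM at gene {self.matrix.index[i]!r}, "
                f"sample {self.matrix.columns[j]!r}"
            )
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise DatasetError(
                f"negative FPKM at gene {self.matrix.index[i]!r}, "
                f"sample {self.matrix.columns[j]!r}"
            )

        genotypes_with_samples = {s.genotype for s in self.samples}
        for cross in self.design:
            for g in (cross.hybrid, cross.parent1, cross.parent2):
                if g not in genotypes_with_samples:
                    raise DatasetError(
                        f"genotype {g!r} named in cross {cross.hybrid!r} has no samples"
                    )

    def _first_bad_cell(self, pred) -> tuple[str, str]:
        for gene, row in self.matrix.iterrows():
            for col, v in row.items():
                if pred(v):
                    return str(gene), str(col)
        raise AssertionError("no offending cell found")  # pragma: no cover

    # -- accessors -----------------------------------------------------------

    @property
    def gene_ids(self) -> pd.Index:
        return self.matrix.index

    @property
    def samples_df(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.sample_id, s.genotype, s.tissue, s.replicate) for s in self.samples],
            columns=["sample_id", "genotype", "tissue", "replicate"],
        )

    @property
    def tissues(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.tissue, None)
        return list(seen)

    def sample_columns(self, genotype: str, tissue: str) -> list[str]:
        return [
            s.sample_id for s in self.samples if s.genotype == genotype and s.tissue == tissue
        ]


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


# -- file I/O ----------------------------------------------------------------


def read_dataset(matrix_path, samples_path, design_path) -> ExpressionDataset:
    """Read and validate the three TSV inputs into an :class:`ExpressionDataset`.

    The matrix TSV has a ``gene_id`` first column and one column per sample;
    the sample sheet has columns ``sample_id, genotype, tissue, replicate``;
    the design sheet has columns ``hybrid, parent1, parent2``.
    """
    matrix = pd.read_csv(matrix_path, sep="\t", dtype={0: str})
    if matrix.columns[0] != "gene_id":
        raise DatasetError(
            f"matrix first column must be 'gene_id', got {matrix.columns[0]!r}"
        )
    matrix = matrix.set_index("gene_id")
    # locate non-numeric cells before the float cast so the error can name them
    for col in matrix.columns:
        if not np.issubdtype(matrix[col].dtype, np.number):
            coerced = pd.to_numeric(matrix[col], errors="coerce")
            bad = coerced.isna() & matrix[col].notna()
            if bad.any():
                gene = matrix.index[bad.to_numpy().nonzero()[0][0]]
                raise DatasetError(f"non-numeric FPKM at gene {gene!r}, sample {col!r}")
            matrix[col] = coerced
    if matrix.isna().to_numpy().any():
        i, j = np.argwhere(matrix.isna().to_numpy())[0]
        raise DatasetError(
            f"missing FPKM at gene {matrix.index[i]!r}, sample {matrix.columns[j]!r}"
        )
    matrix = matrix.astype(float)

    sheet = pd.read_csv(samples_path, sep="\t", dtype=str)
    _require_columns(sheet, ["sample_id", "genotype", "tissue", "replicate"], samples_path)
    samples = [
        SampleMeta(r.sample_id, r.genotype, r.tissue, int(r.replicate))
        for r in sheet.itertuples()
    ]

    design_df = pd.read_csv(design_path, sep="\t", dtype=str)
    _require_columns(design_df, ["hybrid", "parent1", "parent2"], design_path)
    design = [CrossSpec(r.hybrid, r.parent1, r.parent2) for r in design_df.itertuples()]

    return ExpressionDataset(matrix=matrix, samples=samples, design=design)


def write_dataset(ds: ExpressionDataset, outdir) -> dict[str, Path]:
    """Write the three TSVs readable by :func:`read_dataset`; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "matrix.tsv",
        "samples": outdir / "samples.tsv",
        "design": outdir / "design.tsv",
    }
    ds.matrix.to_csv(paths["matrix"], sep="\t", float_format="%.6g", index_label="gene_id")
    ds.samples_df.to_csv(paths["samples"], sep="\t", index=False)
    pd.DataFrame(
        [(c.hybrid, c.parent1, c.parent2) for c in ds.design],
        columns=["hybrid", "parent1", "parent2"],
    ).to_csv(paths["design"], sep="\t", index=False)
    return paths


def _require_columns(df: pd.DataFrame, cols: Iterable[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DatasetError(f"{path}: missing required columns {missing}")


# -- aggregation and trio assembly ------------------------------------------


def aggregate_replicates(
    ds: ExpressionDataset,
    genotype: str,
    tissue: str,
    threshold: float = EXPRESSION_THRESHOLD,
    method: AggregationMethod = "mean",
) -> GenotypeTissueProfile:
    """Collapse replicate columns of one genotype x tissue to a single profile.

    The expressed flag is ``aggregated value >= threshold``; the threshold is
    applied after aggregation, not per replicate.
    """
    cols = ds.sample_columns(genotype, tissue)
    if not cols:
        raise DatasetError(f"no replicates for genotype {genotype!r} in tissue {tissue!r}")
    block = ds.matrix[cols]
    values = block.mean(axis=1) if method == "mean" else block.median(axis=1)
    return GenotypeTissueProfile(
        genotype=genotype,
        tissue=tissue,
        values=values,
        expressed=values >= threshold,
        threshold=threshold,
        n_replicates=len(cols),
    )


def build_trios(
    ds: ExpressionDataset,
    tissue: str,
    threshold: float = EXPRESSION_THRESHOLD,
    method: AggregationMethod = "mean",
    drop_unexpressed: bool = True,
) -> pd.DataFrame:
    """Assemble per-gene (parent1, parent2, F1) trios for every cross in a tissue.

    Returns a frame with one row per gene x cross and columns ``gene_id,
    hybrid, tissue, parent1, parent2, p1_value, p2_value, f1_value,
    p1_expressed, p2_expressed, f1_expressed``.  Genes non-expressed in all
    three genotypes are dropped when ``drop_unexpressed`` (they carry no
    pattern information downstream).
    """
    profiles: dict[str, GenotypeTissueProfile] = {}

    def profile(genotype: str) -> GenotypeTissueProfile:
        if genotype not in profiles:
            profiles[genotype] = aggregate_replicates(ds, genotype, tissue, threshold, method)
        return profiles[genotype]

    frames = []
    for cross in ds.design:
        p1, p2, f1 = profile(cross.parent1), profile(cross.parent2), profile(cross.hybrid)
        frame = pd.DataFrame(
            {
                "gene_id": ds.gene_ids,
                "hybrid": cross.hybrid,
                "tissue": tissue,
                "parent1": cross.parent1,
                "parent2": cross.parent2,
                "p1_value": p1.values.to_numpy(),
                "p2_value": p2.values.to_numpy(),
                "f1_value": f1.values.to_numpy(),
                "p1_expressed": p1.expressed.to_numpy(),
                "p2_expressed": p2.expressed.to_numpy(),
                "f1_expressed": f1.expressed.to_numpy(),
            }
        )
        frames.append(frame)
    trios = pd.concat(frames, ignore_index=True)
    if drop_unexpressed:
        any_on = trios.p1_expressed | trios.p2_expressed | trios.f1_expressed
        trios = trios.loc[any_on].reset_index(drop=True)
    return trios
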
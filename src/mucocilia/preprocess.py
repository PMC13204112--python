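"""Count-matrix IO, CPM / log2(CPM+1) transforms, Z-scores and the JESREC score.

Expression containers are thin wrappers around pandas DataFrames (genes as
rows, samples as columns). Every transform records the expression "space"
(cpm, log2cpm1, zscore) so downstream consumers can refuse the wrong input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "CountMatrix",
    "SampleMetadata",
    "ExpressionMatrix",
    "JesrecInput",
    "read_counts",
    "write_counts",
    "read_metadata",
    "cpm",
    "log2p1",
    "gene_zscores",
    "jesrec_score",
]

GROUPS = ("Ctrl", "nonECRS", "PreECRS", "PostECRS")

COVARIATE_COLUMNS = (
    "blood_eos", "total_ige", "lund_mackay", "feno", "tissue_eos", "jesrec",
)


class FormatError(ValueError):
    """Malformed input file (non-integer counts, duplicates, bad cells)."""


class SpaceError(ValueError):
    """An operation received an ExpressionMatrix in the wrong space."""


class DegenerateSampleError(ValueError):
    """A sample has zero library size."""


@dataclass
class CountMatrix:
    """Integer UMI counts, genes x samples."""

    data: pd.DataFrame  # index = genes, columns = samples

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene symbols: {dups}")
        if df.columns.duplicated().any():
            raise FormatError("duplicate sample ids")
        arr = df.to_numpy()
        if np.any(arr < 0):
            g, s = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative count at gene {df.index[g]!r}, sample {df.columns[s]!r}"
            )
        if not np.allclose(arr, np.round(arr)):
            g, s = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
            raise FormatError(
                f"non-integer count {arr[g, s]!r} at gene {df.index[g]!r}, "
                f"sample {df.columns[s]!r}"
            )
        self.data = df.astype(np.int64)

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def library_sizes(self) -> pd.Series:
        return self.data.sum(axis=0)


@dataclass
class ExpressionMatrix:
    """Real-valued expression, genes x samples, with its space recorded."""

    data: pd.DataFrame
    space: str  # one of {"cpm", "log2cpm1", "zscore"}
    flagged_genes: tuple[str, ...] = ()  # zero-variance rows (zscore space)

    def __post_init__(self) -> None:
        if self.space not in {"cpm", "log2cpm1", "zscore"}:
            raise SpaceError(f"unknown expression space {self.space!r}")
        if not np.isfinite(self.data.to_numpy()).all():
            raise ValueError("expression values must be finite")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class SampleMetadata:
    """Per-sample annotations encoding the paired Pre/Post design.

    Required columns: sample_id, patient_id, group. PostECRS samples must be
    paired: each PostECRS patient also contributes a PreECRS sample; Ctrl and
    nonECRS patients are singletons.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        for col in ("sample_id", "patient_id", "group"):
            if col not in t.columns:
                raise FormatError(f"metadata is missing required column {col!r}")
        if t["sample_id"].duplicated().any():
            raise FormatError("duplicate sample_id in metadata")
        bad = set(t["group"]) - set(GROUPS)
        if bad:
            raise FormatError(f"unknown group labels: {sorted(bad)}")
        pre_patients = set(t.loc[t["group"] == "PreECRS", "patient_id"])
        post_patients = set(t.loc[t["group"] == "PostECRS", "patient_id"])
        unpaired = post_patients - pre_patients
        if unpaired:
            raise FormatError(
                f"PostECRS samples without a PreECRS sample for patients: {sorted(unpaired)}"
            )
        for grp in ("Ctrl", "nonECRS"):
            counts = t.loc[t["group"] == grp, "patient_id"].value_counts()
            multi = counts[counts > 1]
            if len(multi):
                raise FormatError(
                    f"{grp} patients must have exactly one sample; violated by "
                    f"{sorted(multi.index)}"
                )
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def group_of(self) -> pd.Series:
        return self.table.set_index("sample_id")["group"]

    def patient_of(self) -> pd.Series:
        return self.table.set_index("sample_id")["patient_id"]

    def covariates(self, names: list[str] | None = None) -> pd.DataFrame:
        names = list(names) if names is not None else [
            c for c in COVARIATE_COLUMNS if c in self.table.columns
        ]
        missing = [c for c in names if c not in self.table.columns]
        if missing:
            raise KeyError(f"covariate columns not in metadata: {missing}")
        return self.table.set_index("sample_id")[names].astype(float)


def read_counts(
    path: str | Path,
    fmt: str = "tsv",
    genes_path: str | Path | None = None,
    samples_path: str | Path | None = None,
    strict: bool = True,
) -> CountMatrix:
    """Read a gene x sample count matrix.

    fmt="tsv": first column gene symbols, header row of sample ids.
    fmt="mtx": MatrixMarket coordinate file plus one-symbol-per-line gene
    and sample list files (omitted entries are zero).

    With strict=False, fractional counts (e.g. from multimapper-splitting
    quantifiers) are truncated toward zero with a warning instead of
    raising.
    """
    path = Path(path)
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
    elif fmt == "mtx":
        if genes_path is None or samples_path is None:
            raise ValueError("mtx format requires genes_path and samples_path")
        mat = scipy.io.mmread(str(path))
        genes = Path(genes_path).read_text().split()
        samples = Path(samples_path).read_text().split()
        dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
        if dense.shape != (len(genes), len(samples)):
            raise FormatError(
                f"matrix shape {dense.shape} does not match gene/sample lists "
                f"({len(genes)}, {len(samples)})"
            )
        df = pd.DataFrame(dense, index=genes, columns=samples)
    else:
        raise ValueError(f"unknown counts format {fmt!r}")
    arr = df.to_numpy()
    if not strict and not np.allclose(arr, np.round(arr)):
        warnings.warn("truncating fractional counts toward zero (strict=False)")
        df = df.apply(np.floor)
    return CountMatrix(df)


def write_counts(counts: CountMatrix, path: str | Path, fmt: str = "tsv") -> None:
    """Write counts as TSV, or as .mtx plus sibling genes.txt/samples.txt."""
    path = Path(path)
    if fmt == "tsv":
        counts.data.to_csv(path, sep="\t")
    elif fmt == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(counts.data.to_numpy()))
        path.with_name("genes.txt").write_text("\n".join(counts.genes) + "\n")
        path.with_name("samples.txt").write_text("\n".join(counts.samples) + "\n")
    else:
        raise ValueError(f"unknown counts format {fmt!r}")


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read a sample-metadata CSV (sample_id, patient_id, group, covariates)."""
    return SampleMetadata(pd.read_csv(path))


def cpm(counts: CountMatrix) -> ExpressionMatrix:
    """Counts per million: each sample column rescaled to sum to 1e6."""
    lib = counts.library_sizes()
    zero = lib[lib == 0]
    if len(zero):
        raise DegenerateSampleError(
            f"zero library size for samples: {list(zero.index)}"
        )
    values = counts.data.to_numpy(dtype=float) / lib.to_numpy() * 1e6
    return ExpressionMatrix(
        pd.DataFrame(values, index=counts.data.index, columns=counts.data.columns),
        space="cpm",
    )


def log2p1(expr: ExpressionMatrix) -> ExpressionMatrix:
    """log2(CPM + 1); requires cpm-space input."""
    if expr.space != "cpm":
        raise SpaceError(f"log2p1 expects cpm space, got {expr.space!r}")
    return ExpressionMatrix(np.log2(expr.data + 1.0), space="log2cpm1")


def gene_zscores(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene Z-scores across all samples (sd divisor n-1).

    Genes with zero variance are set to all-zero and reported in
    ``flagged_genes``.
    """
    if expr.space != "log2cpm1":
        raise SpaceError(f"gene_zscores expects log2cpm1 space, got {expr.space!r}")
    if expr.data.shape[1] < 2:
        raise ValueError("Z-scores require at least 2 samples")
    vals = expr.data.to_numpy()
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    flat = (sd == 0).ravel()
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (vals - mean) / sd_safe
    z[flat, :] = 0.0
    return ExpressionMatrix(
        pd.DataFrame(z, index=expr.data.index, columns=expr.data.columns),
        space="zscore",
        flagged_genes=tuple(np.asarray(expr.data.index)[flat]),
    )


@dataclass(frozen=True)
class JesrecInput:
    """Inputs to the JESREC clinical scoring rule.

    bilateral: bilateral disease involvement (3 points)
    polyps: presence of nasal polyps (2 points)
    ethmoid_dominant_ct: CT ethmoid/maxillary opacification ratio >= 1 (2 points)
    blood_eos_pct: peripheral blood eosinophils, percent
    """

    bilateral: bool
    polyps: bool
    ethmoid_dominant_ct: bool
    blood_eos_pct: float

    def __post_init__(self) -> None:
        if self.blood_eos_pct < 0:
            raise ValueError("blood eosinophil percentage cannot be negative")


def jesrec_score(inp: JesrecInput) -> tuple[int, bool]:
    """JESREC clinical score and the >= 11 clinical-eligibility flag.

    Eosinophil tiers: <=2% -> 0, (2,5]% -> 4, (5,10]% -> 8, >10% -> 10
    points. Note full ECRS diagnosis additionally requires tissue
    eosinophils >= 70 cells/HPF, which is outside this pure scoring rule.
    """
    eos = inp.blood_eos_pct
    if eos <= 2:
        tier = 0
    elif eos <= 5:
        tier = 4
    elif eos <= 10:
        tier = 8
    else:
        tier = 10
    score = 3 * bool(inp.bilateral) + 2 * bool(inp.polyps) + 2 * bool(inp.ethmoid_dominant_ct) + tier
    return score, score >= 11
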
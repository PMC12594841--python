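"""Readers and writers for the on-disk formats the pipeline touches.

Canonical orientation is genes-as-rows (the Matrix Market sidecar
convention: ``genes.tsv`` rows match matrix rows, ``barcodes.tsv`` rows
match matrix columns). Gene identifiers are matched case-sensitively by
default; :func:`GeneSignatureSet.casefold` supports mixed human/mouse
symbol usage (ZEB2 vs Zeb2).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

log = logging.getLogger(__name__)


class FormatError(ValueError):
    """A file failed structural validation."""


@dataclass
class ExpressionMatrix:
    """Genes x cells count matrix with optional derived layers."""

    counts: sp.spmatrix | np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    layers: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes or len(self.cell_ids) != n_cells:
            raise FormatError(
                f"id/matrix mismatch: {len(self.gene_ids)} gene ids vs {n_genes} rows, "
                f"{len(self.cell_ids)} cell ids vs {n_cells} columns"
            )
        for ids, kind in ((self.gene_ids, "gene"), (self.cell_ids, "cell")):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise FormatError(f"duplicate {kind} id: {i!r}")
                seen.add(i)
        for name, layer in self.layers.items():
            if layer.shape != self.counts.shape:
                raise FormatError(f"layer {name!r} shape {layer.shape} != {self.counts.shape}")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def dense_counts(self) -> np.ndarray:
        if sp.issparse(self.counts):
            return np.asarray(self.counts.todense())
        return np.asarray(self.counts)


@dataclass
class CellAnnotation:
    """Per-cell metadata: tissue compartment, patient, optional cluster."""

    table: pd.DataFrame  # index: cell_id; columns: tissue, patient[, cluster, segment]

    REQUIRED = ("tissue", "patient")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise FormatError(f"annotation missing required column {col!r}")
        if self.table.index.duplicated().any():
            dup = self.table.index[self.table.index.duplicated()][0]
            raise FormatError(f"duplicate cell id in annotation: {dup!r}")

    def check_matches(self, em: ExpressionMatrix) -> None:
        a, b = set(self.table.index), set(em.cell_ids)
        if a != b:
            raise FormatError(
                f"annotation/matrix cell id mismatch: {len(a - b)} only in annotation, "
                f"{len(b - a)} only in matrix"
            )


@dataclass
class GeneSignatureSet:
    """Named gene sets (GMT-style)."""

    sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise FormatError(f"signature {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise FormatError(f"signature {name!r} contains duplicate genes")

    def casefold(self) -> "GeneSignatureSet":
        """Case-folded copy for cross-species symbol matching."""
        return GeneSignatureSet(
            {n: list(dict.fromkeys(g.upper() for g in genes)) for n, genes in self.sets.items()}
        )

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]


# ---------------------------------------------------------------------------
# counts


def read_counts(path: str | Path, format: str = "mtx") -> ExpressionMatrix:
    """Read a genes x cells count matrix.

    ``mtx``: Matrix Market file with ``genes.tsv`` and ``barcodes.tsv``
    sidecars in the same directory. If the matrix arrives transposed and the
    sidecar lengths disambiguate the orientation, it is auto-transposed.
    ``tsv``: dense table, first column gene ids, header row cell ids.
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        counts = df.to_numpy()
        return ExpressionMatrix(counts, [str(g) for g in df.index], [str(c) for c in df.columns])
    if format != "mtx":
        raise ValueError(f"unknown counts format {format!r}")

    mtx_path = path if path.is_file() else path / "matrix.mtx"
    base = mtx_path.parent
    genes = _read_single_column(base / "genes.tsv")
    barcodes = _read_single_column(base / "barcodes.tsv")
    mat = sp.csr_matrix(scipy.io.mmread(mtx_path))
    if mat.shape == (len(genes), len(barcodes)):
        pass
    elif mat.shape == (len(barcodes), len(genes)) and len(genes) != len(barcodes):
        mat = sp.csr_matrix(mat.T)
    else:
        raise FormatError(
            f"matrix shape {mat.shape} incompatible with {len(genes)} genes / "
            f"{len(barcodes)} barcodes"
        )
    return ExpressionMatrix(mat, genes, barcodes)


def write_counts(em: ExpressionMatrix, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat = sp.coo_matrix(em.counts)
    scipy.io.mmwrite(outdir / "matrix.mtx", mat, field="integer" if _is_integer(mat) else "real")
    (outdir / "genes.tsv").write_text("".join(g + "\n" for g in em.gene_ids))
    (outdir / "barcodes.tsv").write_text("".join(c + "\n" for c in em.cell_ids))


def _is_integer(mat: sp.coo_matrix) -> bool:
    return bool(np.issubdtype(mat.dtype, np.integer))


def _read_single_column(path: Path) -> list[str]:
    if not path.exists():
        raise FormatError(f"missing sidecar file {path}")
    out = []
    for line in path.read_text().splitlines():
        if line.strip():
            out.append(line.split("\t")[0].strip())
    return out


# ---------------------------------------------------------------------------
# annotation


def read_annotation(path: str | Path) -> CellAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "cell_id" not in df.columns:
        raise FormatError("annotation TSV must have a 'cell_id' column")
    return CellAnnotation(df.set_index("cell_id"))


def write_annotation(ann: CellAnnotation, path: str | Path) -> None:
    ann.table.rename_axis("cell_id").reset_index().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str | Path) -> GeneSignatureSet:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>genes...``."""
    sets: dict[str, list[str]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{ln}: GMT line has {len(fields)} fields, need >= 3")
        name, genes = fields[0], [g for g in fields[2:] if g]
        deduped = list(dict.fromkeys(genes))
        if len(deduped) != len(genes):
            warnings.warn(f"{path}:{ln}: duplicate genes in set {name!r} deduplicated")
        sets[name] = deduped
    return GeneSignatureSet(sets)


def write_gmt(gss: GeneSignatureSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in gss.sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def default_signatures() -> GeneSignatureSet:
    """Signature sets shipped with the package (human CD8 T-cell markers plus
    the murine terminal-effector signature)."""
    text = resources.files("scregulon").joinpath("_data/signatures.gmt").read_text()
    sets: dict[str, list[str]] = {}
    for line in text.splitlines():
        if line.strip():
            f = line.split("\t")
            sets[f[0]] = list(dict.fromkeys(g for g in f[2:] if g))
    return GeneSignatureSet(sets)


def default_tf_symbols() -> list[str]:
    """Candidate-regulator symbol list shipped with the package."""
    text = resources.files("scregulon").joinpath("_data/tf_symbols.txt").read_text()
    return [line.strip() for line in text.splitlines() if line.strip() and not line.startswith("#")]


# ---------------------------------------------------------------------------
# regulon tables


def read_regulon_table(path: str | Path) -> pd.DataFrame:
    """Read a regulon TSV with columns tf, target, mode, likelihood.

    A missing likelihood column defaults to 1.0 (with a warning). Out-of-range
    mode/likelihood is an error, never a clip.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("tf", "target", "mode"):
        if col not in df.columns:
            raise FormatError(f"regulon table missing column {col!r}")
    if "likelihood" not in df.columns:
        warnings.warn(f"{path}: likelihood column absent; defaulting to 1.0")
        df["likelihood"] = 1.0
    _validate_regulon_frame(df)
    return df[["tf", "target", "mode", "likelihood"]]


def write_regulon_table(df: pd.DataFrame, path: str | Path) -> None:
    _validate_regulon_frame(df)
    df[["tf", "target", "mode", "likelihood"]].to_csv(path, sep="\t", index=False)


def _validate_regulon_frame(df: pd.DataFrame) -> None:
    mode = df["mode"].to_numpy(dtype=float)
    if np.any(mode < -1) or np.any(mode > 1):
        bad = mode[(mode < -1) | (mode > 1)][0]
        raise FormatError(f"mode {bad} outside [-1, 1]")
    lik = df["likelihood"].to_numpy(dtype=float)
    if np.any(lik <= 0) or np.any(lik > 1):
        bad = lik[(lik <= 0) | (lik > 1)][0]
        raise FormatError(f"likelihood {bad} outside (0, 1]")
    if df.duplicated(subset=["tf", "target"]).any():
        row = df[df.duplicated(subset=["tf", "target"])].iloc[0]
        raise FormatError(f"duplicate (tf, target) pair: ({row['tf']}, {row['target']})")
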
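"""Delimited-text input/output.

All files are tab-separated UTF-8 with ``.`` as the decimal separator
(comma-separated accepted via ``sep=","``), mirroring the conventions of GEO
series matrices. Three table kinds are handled:

* Ct tables — long format, one row per (sample, gene) measurement with
  columns ``sample``, ``gene``, ``ct`` and an optional ``replicate`` column
  for technical replicates.
* Expression matrices — wide format, genes as rows and samples as columns,
  first column holding gene symbols.
* Reference sets — wide format, one row per reference cell line with columns
  ``cell_line``, ``label`` (sensitive/resistant) followed by one column per
  panel gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputFormatError, PanelError
from .panels import GenePanel, normalize_gene_symbol

SENSITIVE = "sensitive"
RESISTANT = "resistant"
VALID_LABELS = (SENSITIVE, RESISTANT)


@dataclass
class CtTable:
    """Raw qPCR cycle-threshold measurements in long form.

    ``entries`` maps (sample, gene) to the list of replicate Ct values; a
    single measurement is a one-element list. Every sample must carry a Ct
    for the reference gene (18S rRNA by default).
    """

    samples: list[str]
    entries: dict[tuple[str, str], list[float]]
    reference_gene: str = "18S"

    def __post_init__(self) -> None:
        for (sample, gene), cts in self.entries.items():
            for ct in cts:
                if not math.isfinite(ct):
                    raise InputFormatError(
                        f"non-finite Ct for sample {sample!r}, gene {gene!r}"
                    )
        for sample in self.samples:
            if (sample, self.reference_gene) not in self.entries:
                raise InputFormatError(
                    f"sample {sample!r} lacks a Ct for reference gene "
                    f"{self.reference_gene!r}"
                )

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, gene in self.entries:
            seen.setdefault(gene)
        return list(seen)

    def ct(self, sample: str, gene: str) -> float:
        """Mean Ct over technical replicates for one (sample, gene)."""
        try:
            cts = self.entries[(sample, gene)]
        except KeyError:
            raise InputFormatError(
                f"no Ct measured for gene {gene!r} in sample {sample!r}"
            ) from None
        return float(np.mean(cts))

    def has(self, sample: str, gene: str) -> bool:
        return (sample, gene) in self.entries


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with a declared or unknown scale."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray  # shape (n_genes, n_samples)
    scale_hint: str = "unknown"  # linear | log2 | unknown

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise InputFormatError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if self.scale_hint not in ("linear", "log2", "unknown"):
            raise InputFormatError(f"invalid scale_hint {self.scale_hint!r}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise InputFormatError(
                f"non-finite value at gene {self.genes[bad[0]]!r}, "
                f"sample {self.samples[bad[1]]!r}"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        """Restrict to the given genes (matrix row order preserved)."""
        keep = set(genes)
        missing = keep - set(self.genes)
        if missing:
            raise PanelError(f"genes absent from matrix: {sorted(missing)}")
        idx = [i for i, g in enumerate(self.genes) if g in keep]
        return ExpressionMatrix(
            genes=[self.genes[i] for i in idx],
            samples=list(self.samples),
            values=self.values[idx, :],
            scale_hint=self.scale_hint,
        )


def read_ct_table(
    path: str | Path, reference_gene: str = "18S", sep: str = "\t"
) -> CtTable:
    """Read a long-format Ct table.

    Expected columns: ``sample``, ``gene``, ``ct`` and optionally
    ``replicate``. Duplicate (sample, gene) rows without distinct replicate
    indices are rejected; rows with a replicate column are averaged later,
    at profile construction.
    """
    path = Path(path)
    if not path.exists():
        raise InputFormatError(f"Ct table not found: {path}")
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except pd.errors.EmptyDataError:
        raise InputFormatError(f"empty Ct table: {path}") from None
    required = {"sample", "gene", "ct"}
    if not required.issubset(df.columns):
        raise InputFormatError(
            f"{path}: expected columns {sorted(required)}, got {list(df.columns)}"
        )
    has_replicate = "replicate" in df.columns

    entries: dict[tuple[str, str], list[float]] = {}
    seen_rep: set[tuple[str, str, str]] = set()
    samples: dict[str, None] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        sample = str(row.sample).strip()
        gene = normalize_gene_symbol(str(row.gene))
        try:
            ct = float(row.ct)
        except (TypeError, ValueError):
            raise InputFormatError(
                f"{path} line {i}: unparseable Ct value {row.ct!r}"
            ) from None
        if not math.isfinite(ct):
            raise InputFormatError(f"{path} line {i}: non-finite Ct value")
        key = (sample, gene)
        if has_replicate:
            rep = str(row.replicate).strip()
            if (sample, gene, rep) in seen_rep:
                raise InputFormatError(
                    f"{path} line {i}: duplicate replicate {rep!r} for "
                    f"({sample!r}, {gene!r})"
                )
            seen_rep.add((sample, gene, rep))
            entries.setdefault(key, []).append(ct)
        else:
            if key in entries:
                raise InputFormatError(
                    f"{path} line {i}: duplicate row for ({sample!r}, {gene!r})"
                )
            entries[key] = [ct]
        samples.setdefault(sample)

    for sample in samples:
        if (sample, reference_gene) not in entries:
            raise InputFormatError(
                f"{path}: sample {sample!r} lacks reference gene "
                f"{reference_gene!r}"
            )
    return CtTable(samples=list(samples), entries=entries, reference_gene=reference_gene)


def write_ct_table(table: CtTable, path: str | Path, sep: str = "\t") -> None:
    rows = []
    for (sample, gene), cts in table.entries.items():
        if len(cts) == 1:
            rows.append({"sample": sample, "gene": gene, "ct": repr(float(cts[0]))})
        else:
            for k, ct in enumerate(cts, start=1):
                rows.append(
                    {"sample": sample, "gene": gene, "ct": repr(float(ct)), "replicate": k}
                )
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def read_expression_matrix(path: str | Path, sep: str = "\t") -> ExpressionMatrix:
    """Read a genes-x-samples matrix; first column gene symbols, header samples."""
    path = Path(path)
    if not path.exists():
        raise InputFormatError(f"expression matrix not found: {path}")
    lines = path.read_text(encoding="utf-8").splitlines()
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise InputFormatError(f"empty expression matrix: {path}")
    header = lines[0].split(sep)
    samples = [c.strip() for c in header[1:]]
    if not samples:
        raise InputFormatError(f"{path}: no sample columns in header")
    genes: list[str] = []
    values: list[list[float]] = []
    for ridx, ln in enumerate(lines[1:], start=2):
        cells = ln.split(sep)
        if len(cells) != len(samples) + 1:
            raise InputFormatError(
                f"{path} row {ridx}: ragged row with {len(cells)} cells, "
                f"expected {len(samples) + 1}"
            )
        gene = normalize_gene_symbol(cells[0])
        if gene in genes:
            raise InputFormatError(f"{path} row {ridx}: duplicated gene symbol {gene!r}")
        row_vals = []
        for sample, cell in zip(samples, cells[1:]):
            cell = cell.strip()
            if cell == "" or cell.upper() in ("NA", "NAN"):
                raise InputFormatError(
                    f"{path}: missing value for gene {gene!r}, sample {sample!r}"
                )
            try:
                row_vals.append(float(cell))
            except ValueError:
                raise InputFormatError(
                    f"{path}: unparseable value {cell!r} for gene {gene!r}, "
                    f"sample {sample!r}"
                ) from None
        genes.append(gene)
        values.append(row_vals)
    if not genes:
        raise InputFormatError(f"{path}: no gene rows")
    return ExpressionMatrix(
        genes=genes, samples=samples, values=np.array(values), scale_hint="unknown"
    )


def write_expression_matrix(
    m: ExpressionMatrix, path: str | Path, sep: str = "\t"
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(sep.join(["gene", *m.samples]) + "\n")
        for gene, row in zip(m.genes, m.values):
            fh.write(sep.join([gene, *(repr(float(v)) for v in row)]) + "\n")


def read_labels(path: str | Path, sep: str = "\t") -> dict[str, str]:
    """Read a response-label table with columns ``sample`` and ``label``."""
    path = Path(path)
    if not path.exists():
        raise InputFormatError(f"label file not found: {path}")
    df = pd.read_csv(path, sep=sep, dtype=str)
    if "sample" not in df.columns or "label" not in df.columns:
        raise InputFormatError(f"{path}: expected columns sample, label")
    labels: dict[str, str] = {}
    for _, row in df.iterrows():
        sample = str(row["sample"]).strip()
        if sample in labels:
            raise InputFormatError(f"{path}: duplicate sample {sample!r}")
        labels[sample] = str(row["label"]).strip()
    return labels


def write_labels(labels: dict[str, str], path: str | Path, sep: str = "\t") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"sample{sep}label\n")
        for sample, label in labels.items():
            fh.write(f"{sample}{sep}{label}\n")


def read_panel(path: str | Path, name: str | None = None, sep: str = "\t") -> GenePanel:
    """Read a panel file: ``gene<TAB>assay_id`` (assay id optional per row)."""
    path = Path(path)
    if not path.exists():
        raise InputFormatError(f"panel file not found: {path}")
    genes: list[str] = []
    assay_ids: dict[str, str] = {}
    for ln in path.read_text(encoding="utf-8").splitlines():
        if not ln.strip() or ln.startswith("#"):
            continue
        cells = ln.split(sep)
        gene = normalize_gene_symbol(cells[0])
        if gene == "gene":  # optional header
            continue
        genes.append(gene)
        if len(cells) > 1 and cells[1].strip():
            assay_ids[gene] = cells[1].strip()
    return GenePanel(name=name or path.stem, genes=tuple(genes), assay_ids=assay_ids)


def write_panel(panel: GenePanel, path: str | Path, sep: str = "\t") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"gene{sep}assay_id\n")
        for g in panel.genes:
            fh.write(f"{g}{sep}{panel.assay_ids.get(g, '')}\n")
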
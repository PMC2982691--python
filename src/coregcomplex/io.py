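"""Readers and writers for the three TSV data sources.

TSV is the canonical interchange format:

* expression: one file per condition -- header row of time-point labels,
  first column the gene ID, empty cells / ``NA`` / ``NaN`` meaning missing;
* regulation: two columns ``tf<TAB>target`` (an optional third column is
  ignored);
* PPI: two columns of interacting protein IDs.

All loaders transparently accept gzip-compressed files (``.gz`` suffix).
A read-only converter for MATLAB ``.mat`` containers is provided so that
externally distributed datasets can be turned into the three TSVs once and
then diffed and versioned as plain text.
"""

from __future__ import annotations

import gzip
import io as _io
import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .data import ExpressionPanel, PPINetwork, RegulatoryNetwork

logger = logging.getLogger(__name__)

MISSING_MARKERS = {"", "NA", "NaN", "nan", "na"}

__all__ = [
    "load_expression_panel",
    "write_expression_panel",
    "load_regulatory_network",
    "write_regulatory_network",
    "load_ppi_network",
    "write_ppi_network",
    "filter_unmapped_proteins",
    "convert_mat",
]


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


# ---------------------------------------------------------------------------
# expression


def _parse_expression_tsv(path: str | Path) -> pd.DataFrame:
    with _open_text(path) as fh:
        lines = fh.read().splitlines()
    lines = [ln for ln in lines if ln.strip() != ""]
    if len(lines) < 2:
        raise ValueError(f"{path}: no data rows")
    header = lines[0].split("\t")
    timepoints = header[1:]
    if len(timepoints) < 2:
        raise ValueError(f"{path}: need >= 2 time-point columns")
    genes: list[str] = []
    values: list[list[float]] = []
    seen: set[str] = set()
    for row_no, ln in enumerate(lines[1:], start=2):
        cells = ln.split("\t")
        gene = cells[0].strip()
        if gene in seen:
            raise ValueError(f"{path}: duplicate gene ID {gene!r}")
        seen.add(gene)
        if len(cells) - 1 != len(timepoints):
            raise ValueError(
                f"{path}: row {row_no} has {len(cells) - 1} values, "
                f"expected {len(timepoints)}"
            )
        row: list[float] = []
        for col_no, cell in enumerate(cells[1:], start=2):
            cell = cell.strip()
            if cell in MISSING_MARKERS:
                row.append(np.nan)
                continue
            try:
                row.append(float(cell))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value {cell!r} at row {row_no}, "
                    f"column {col_no}"
                ) from None
        genes.append(gene)
        values.append(row)
    return pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=timepoints)


def load_expression_panel(
    paths: Mapping[str, str | Path] | str | Path,
) -> ExpressionPanel:
    """Load per-condition expression matrices from TSV file(s).

    Parameters
    ----------
    paths
        Either a mapping ``{condition label: path}``, or a single path (the
        condition is then labelled by the file stem).

    Missing cells are flagged in the mask (as NaN), never imputed.
    """
    if isinstance(paths, (str, Path)):
        stem = Path(paths).name
        for suffix in (".gz", ".tsv", ".txt"):
            if stem.endswith(suffix):
                stem = stem[: -len(suffix)]
        paths = {stem: paths}
    frames = {cond: _parse_expression_tsv(p) for cond, p in paths.items()}
    return ExpressionPanel(frames)


def write_expression_panel(
    panel: ExpressionPanel, paths: Mapping[str, str | Path]
) -> None:
    """Write each condition to TSV with full-precision floats, NA = missing."""
    for cond, path in paths.items():
        df = panel.frame(cond)
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "wt") as fh:
            fh.write("gene\t" + "\t".join(map(str, df.columns)) + "\n")
            for gene, row in zip(df.index, df.to_numpy()):
                cells = ["NA" if not np.isfinite(v) else repr(float(v)) for v in row]
                fh.write(str(gene) + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# regulation


def load_regulatory_network(path: str | Path) -> RegulatoryNetwork:
    """Load TF->target pairs from a 2(+)-column TSV; duplicates collapsed."""
    pairs: set[tuple[str, str]] = set()
    with _open_text(path) as fh:
        for line_no, ln in enumerate(fh, start=1):
            if ln.strip() == "":
                continue
            cells = ln.rstrip("\n").split("\t")
            tf = cells[0].strip()
            target = cells[1].strip() if len(cells) > 1 else ""
            if tf == "":
                raise ValueError(f"{path}: blank TF field at line {line_no}")
            if target == "":
                raise ValueError(f"{path}: blank target field at line {line_no}")
            pairs.add((tf, target))
    return RegulatoryNetwork.from_edges(pairs)


def write_regulatory_network(tr: RegulatoryNetwork, path: str | Path) -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for tf, tg in sorted(tr.edges):
            fh.write(f"{tf}\t{tg}\n")


# ---------------------------------------------------------------------------
# PPI


def load_ppi_network(
    path: str | Path, gene_map: Mapping[str, str] | None = None
) -> PPINetwork:
    """Load an undirected PPI edge list from a 2-column TSV.

    Self-loops are dropped (count logged) and duplicate pairs collapsed.
    Proteins absent from ``gene_map`` are kept but flagged; use
    :func:`filter_unmapped_proteins` to remove proteins without usable
    expression coverage.
    """
    raw_edges: list[tuple[str, str]] = []
    with _open_text(path) as fh:
        for line_no, ln in enumerate(fh, start=1):
            if ln.strip() == "":
                continue
            cells = ln.rstrip("\n").split("\t")
            if len(cells) < 2 or cells[0].strip() == "" or cells[1].strip() == "":
                raise ValueError(f"{path}: malformed PPI row at line {line_no}")
            raw_edges.append((cells[0].strip(), cells[1].strip()))
    net = PPINetwork(raw_edges, coding_gene_of=gene_map)
    net.n_raw_edges = len(raw_edges)
    if gene_map is not None:
        unmapped = [p for p in net.proteins if p not in gene_map]
        if unmapped:
            logger.warning(
                "%d PPI protein(s) missing from the gene map (kept, flagged)",
                len(unmapped),
            )
    if not raw_edges:
        logger.warning("%s: empty PPI edge list", path)
    return net


def write_ppi_network(ppi: PPINetwork, path: str | Path) -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for u, v in sorted(ppi.edges()):
            fh.write(f"{u}\t{v}\n")


def filter_unmapped_proteins(ppi: PPINetwork, panel: ExpressionPanel) -> PPINetwork:
    """Drop proteins whose coding gene has no profile in any condition.

    Incident edges go with them.  Idempotent.
    """
    keep = {p for p in ppi.proteins if panel.covers(ppi.gene_of(p))}
    removed = len(ppi.proteins) - len(keep)
    if removed:
        logger.info("filtered %d protein(s) without expression coverage", removed)
    return ppi.subset(keep)


# ---------------------------------------------------------------------------
# MAT container import


def convert_mat(
    expression_mat: str | Path | None = None,
    regulation_mat: str | Path | None = None,
    ppi_mat: str | Path | None = None,
    out_dir: str | Path = ".",
) -> list[Path]:
    """Convert MATLAB ``.mat`` containers to the canonical TSVs (read-only).

    Expected layouts (best effort -- unknown variables are reported):

    * expression container: one 2-D numeric array per condition, with an
      optional companion cell array of gene IDs named ``<var>_genes`` or a
      shared ``genes`` variable;
    * regulation container: an N x 2 cell/char array of (tf, target) pairs;
    * PPI container: an N x 2 cell/char array of protein pairs.

    Returns the list of TSV paths written.
    """
    from scipy.io import loadmat

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _load(path):
        try:
            return loadmat(path, squeeze_me=False)
        except NotImplementedError:  # v7.3 container
            import h5py

            data = {}
            with h5py.File(path, "r") as fh:
                for key in fh:
                    data[key] = np.array(fh[key])
            return data

    def _cellstr(arr) -> list[str]:
        out = []
        for item in np.asarray(arr).ravel():
            while isinstance(item, np.ndarray) and item.size == 1:
                item = item.ravel()[0]
            out.append(str(item).strip())
        return out

    def _pairs(mat: dict) -> list[tuple[str, str]]:
        for key, val in mat.items():
            if key.startswith("__"):
                continue
            arr = np.asarray(val)
            if arr.ndim == 2 and arr.shape[1] == 2 and arr.shape[0] > 0:
                col0 = _cellstr(arr[:, 0])
                col1 = _cellstr(arr[:, 1])
                return list(zip(col0, col1))
        raise ValueError("no N x 2 pair array found in MAT container")

    if regulation_mat is not None:
        pairs = _pairs(_load(regulation_mat))
        path = out_dir / "regulation.tsv"
        write_regulatory_network(RegulatoryNetwork.from_edges(pairs), path)
        written.append(path)
    if ppi_mat is not None:
        pairs = _pairs(_load(ppi_mat))
        path = out_dir / "ppi.tsv"
        write_ppi_network(PPINetwork(pairs), path)
        written.append(path)
    if expression_mat is not None:
        mat = _load(expression_mat)
        gene_lists = {
            k: _cellstr(v) for k, v in mat.items() if k.endswith("_genes")
        }
        shared_genes = _cellstr(mat["genes"]) if "genes" in mat else None
        frames: dict[str, pd.DataFrame] = {}
        for key, val in mat.items():
            if key.startswith("__") or key == "genes" or key.endswith("_genes"):
                continue
            arr = np.asarray(val)
            if arr.ndim != 2 or not np.issubdtype(arr.dtype, np.number):
                continue
            genes = gene_lists.get(f"{key}_genes", shared_genes)
            if genes is None or len(genes) != arr.shape[0]:
                logger.warning("skipping MAT variable %r: no matching gene IDs", key)
                continue
            frames[key] = pd.DataFrame(
                arr.astype(float),
                index=pd.Index(genes, name="gene"),
                columns=[f"t{i}" for i in range(arr.shape[1])],
            )
        if not frames:
            raise ValueError("no usable condition matrices found in MAT container")
        paths = {cond: out_dir / f"expression_{cond}.tsv" for cond in frames}
        write_expression_panel(ExpressionPanel(frames), paths)
        written.extend(paths.values())
    return written
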
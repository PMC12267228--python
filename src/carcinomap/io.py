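"""File-format plumbing: MTX bundles, GMT gene sets, tile tables, images.

Matrix Market files follow the 10x-style triplet convention: the matrix is
genes x spots, indices in the file are 1-based (converted to 0-based
internally), with ``features.tsv`` and ``barcodes.tsv`` naming rows and
columns and a ``positions.csv`` giving Visium-style spot coordinates
(barcode, array_row, array_col, pixel_x, pixel_y).

All tables written here start with '#' comment lines naming units and
conventions; readers skip them.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Dict, List, Union

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .datatypes import SpotDataset, TileSet, ValidationError

PathLike = Union[str, os.PathLike]


class ParseError(ValidationError):
    """A file could not be parsed; the message locates the problem."""


# ---------------------------------------------------------------------------
# Tables with convention headers
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: PathLike, comment: str) -> None:
    """CSV with leading '#' comment lines stating units/conventions."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in comment.strip().splitlines():
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def read_table(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# MTX bundle
# ---------------------------------------------------------------------------

def write_mtx_bundle(ds: SpotDataset, directory: PathLike) -> None:
    """Write a SpotDataset as matrix.mtx + features.tsv + barcodes.tsv +
    positions.csv (plus truth tables when planted ground truth exists)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(
        str(d / "matrix.mtx"),
        sparse.coo_matrix(ds.counts.astype(np.int64)),
        field="integer",
    )
    pd.Series(ds.gene_ids).to_csv(d / "features.tsv", sep="\t",
                                  index=False, header=False)
    pd.Series(ds.spot_ids).to_csv(d / "barcodes.tsv", sep="\t",
                                  index=False, header=False)
    positions = ds.coords.reset_index()
    positions.insert(1, "sample", ds.sample_label)
    positions.to_csv(d / "positions.csv", index=False)
    if ds.truth is not None:
        ds.truth.reset_index().to_csv(d / "truth_spots.csv", index=False)
    if ds.gene_truth is not None:
        ds.gene_truth.reset_index().to_csv(d / "truth_genes.csv", index=False)


def _precheck_mtx(path: Path) -> None:
    """Cheap structural scan so parse failures report a line number."""
    with open(path) as fh:
        lines = fh.readlines()
    body = [
        (i + 1, ln) for i, ln in enumerate(lines)
        if ln.strip() and not ln.startswith("%")
    ]
    if not body:
        raise ParseError(f"{path}: no size line found")
    lineno, size_line = body[0]
    parts = size_line.split()
    if len(parts) != 3:
        raise ParseError(f"{path}:{lineno}: malformed size line {size_line!r}")
    try:
        nnz = int(parts[2])
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: non-integer size entry") from exc
    entries = body[1:]
    if len(entries) < nnz:
        last = entries[-1][0] if entries else lineno
        raise ParseError(
            f"{path}: truncated after line {last}: "
            f"{len(entries)} entries found, {nnz} declared"
        )
    for ln_no, entry in entries[:nnz]:
        if len(entry.split()) != 3:
            raise ParseError(f"{path}:{ln_no}: malformed entry {entry.strip()!r}")


def read_mtx_bundle(directory: PathLike) -> SpotDataset:
    """Read a 10x-style triplet directory back into a SpotDataset."""
    d = Path(directory)
    for name in ("matrix.mtx", "features.tsv", "barcodes.tsv", "positions.csv"):
        if not (d / name).exists():
            raise ValidationError(f"missing {name} in {d}")
    _precheck_mtx(d / "matrix.mtx")
    try:
        mat = spio.mmread(str(d / "matrix.mtx"))
    except Exception as exc:  # pragma: no cover - precheck catches most
        raise ParseError(f"{d / 'matrix.mtx'}: {exc}") from exc
    counts = np.asarray(sparse.coo_matrix(mat).todense()).astype(np.int64)
    gene_ids = pd.read_csv(d / "features.tsv", sep="\t", header=None)[0].to_numpy(str)
    spot_ids = pd.read_csv(d / "barcodes.tsv", sep="\t", header=None)[0].to_numpy(str)
    if counts.shape != (len(gene_ids), len(spot_ids)):
        raise ValidationError(
            f"matrix is {counts.shape} but features.tsv/barcodes.tsv give "
            f"({len(gene_ids)}, {len(spot_ids)})"
        )
    positions = pd.read_csv(d / "positions.csv")
    if "barcode" not in positions.columns:
        raise ValidationError("positions.csv must have a 'barcode' column")
    positions = positions.set_index("barcode").loc[spot_ids]
    sample = (
        positions.pop("sample").to_numpy(str)
        if "sample" in positions.columns
        else np.array(["sample0"] * len(spot_ids))
    )
    truth = gene_truth = None
    if (d / "truth_spots.csv").exists():
        truth = pd.read_csv(d / "truth_spots.csv").set_index("barcode").loc[spot_ids]
    if (d / "truth_genes.csv").exists():
        gene_truth = pd.read_csv(d / "truth_genes.csv").set_index("gene").loc[gene_ids]
        gene_truth["switch_direction"] = (
            gene_truth["switch_direction"].fillna("").astype(str)
        )
    coords = positions[["array_row", "array_col", "pixel_x", "pixel_y"]]
    return SpotDataset(
        counts=counts,
        gene_ids=gene_ids,
        spot_ids=spot_ids,
        coords=coords,
        sample_label=sample,
        truth=truth,
        gene_truth=gene_truth,
    )


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: PathLike) -> Dict[str, List[str]]:
    """Tab-separated GMT: name, description, genes...  Returns name -> genes."""
    sets: Dict[str, List[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT lines need name, description and "
                    f"at least one gene"
                )
            name = parts[0]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: Dict[str, List[str]], path: PathLike,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


# ---------------------------------------------------------------------------
# Tile tables and images
# ---------------------------------------------------------------------------

def write_tileset(ts: TileSet, directory: PathLike) -> None:
    """TileSet as tiles.csv (slide_id, roi_id, x, y, w, h, label) +
    features.csv."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    table = pd.DataFrame(
        {
            "slide_id": ts.slide_id,
            "roi_id": ts.roi_id if ts.roi_id is not None else "",
            "x": ts.tiles[:, 0],
            "y": ts.tiles[:, 1],
            "w": ts.tiles[:, 2],
            "h": ts.tiles[:, 3],
            "label": ts.labels if ts.labels is not None else -1,
        }
    )
    write_table(
        table, d / "tiles.csv",
        "tile boxes in level-0 pixels, 0-based top-left origin, half-open",
    )
    if ts.features is not None:
        feat = pd.DataFrame(
            ts.features,
            columns=[f"f{i}" for i in range(ts.features.shape[1])],
        )
        feat.insert(0, "slide_id", ts.slide_id)
        feat.insert(1, "x", ts.tiles[:, 0])
        feat.insert(2, "y", ts.tiles[:, 1])
        feat.to_csv(d / "features.csv", index=False)


def read_tileset(directory: PathLike) -> TileSet:
    d = Path(directory)
    table = read_table(d / "tiles.csv")
    features = None
    if (d / "features.csv").exists():
        feat = pd.read_csv(d / "features.csv")
        features = feat[[c for c in feat.columns if c.startswith("f")]].to_numpy()
    labels = table["label"].to_numpy()
    return TileSet(
        slide_id=table["slide_id"].to_numpy(str),
        tiles=table[["x", "y", "w", "h"]].to_numpy(int),
        roi_id=table["roi_id"].to_numpy(str) if "roi_id" in table else None,
        features=features,
        labels=None if (labels == -1).all() else labels,
    )


def write_image(array: np.ndarray, path: PathLike) -> None:
    """Save a grayscale or label image as PNG (labels shifted so -1 -> 0)."""
    from PIL import Image

    arr = np.asarray(array)
    if arr.dtype != np.uint8:
        arr = np.clip(arr.astype(np.int64) + 1, 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(Path(path))


def read_image(path: PathLike) -> np.ndarray:
    from PIL import Image

    return np.asarray(Image.open(Path(path)))
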
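"""Readers and writers for the pipeline's on-disk formats.

Counts travel as TSV (genes x samples) or MatrixMarket plus a CSV sample
sheet; disease lists as two-column TSV (symbol, direction); gene sets as
GMT; images as multi-channel TIFF with the pixel size in the metadata;
VFA stacks as 3-D TIFF with a YAML sidecar carrying flip angles and TR.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import io as spio
from scipy import sparse

from .design import StudyDesign
from .diffexpr import CountMatrix
from .mrit1 import VfaStack

FLOAT_FMT = "%.6g"


def write_counts_tsv(counts: CountMatrix, path) -> None:
    counts.to_frame().to_csv(path, sep="\t", index_label="gene")


def read_counts_tsv(path) -> CountMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix.from_frame(frame)


def write_counts_mtx(counts: CountMatrix, prefix) -> None:
    """MatrixMarket triple: <prefix>.mtx, <prefix>.genes.txt, <prefix>.samples.txt"""
    prefix = Path(prefix)
    spio.mmwrite(str(prefix.with_suffix(".mtx")), sparse.csr_matrix(counts.values))
    prefix.with_suffix(".genes.txt").write_text("\n".join(counts.gene_ids) + "\n")
    prefix.with_suffix(".samples.txt").write_text("\n".join(counts.sample_ids) + "\n")


def read_counts_mtx(prefix) -> CountMatrix:
    prefix = Path(prefix)
    values = np.asarray(spio.mmread(str(prefix.with_suffix(".mtx"))).todense())
    genes = prefix.with_suffix(".genes.txt").read_text().splitlines()
    samples = prefix.with_suffix(".samples.txt").read_text().splitlines()
    return CountMatrix(values.astype(np.int64), genes, samples)


def write_sample_sheet(design: StudyDesign, path) -> None:
    design.to_frame().to_csv(path, index=False)


def read_sample_sheet(path) -> StudyDesign:
    return StudyDesign.from_frame(pd.read_csv(path))


def write_gene_list_tsv(per_direction: dict, path) -> None:
    rows = [(sym, d) for d in ("up", "down") for sym in per_direction.get(d, [])]
    pd.DataFrame(rows, columns=["symbol", "direction"]).to_csv(path, sep="\t", index=False)


def read_gene_list_tsv(path) -> dict:
    frame = pd.read_csv(path, sep="\t")
    return {
        d: list(frame.loc[frame["direction"] == d, "symbol"])
        for d in ("up", "down")
    }


def read_gmt(path) -> dict:
    sets = {}
    for line in Path(path).read_text().splitlines():
        parts = line.rstrip("\n").split("\t")
        if len(parts) >= 3:
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_multichannel_tiff(channels: dict, um_per_px: float, path) -> None:
    stack = np.stack([np.asarray(v, dtype=np.float32) for v in channels.values()])
    tifffile.imwrite(
        path,
        stack,
        photometric="minisblack",
        metadata={"um_per_px": um_per_px, "channels": list(channels.keys())},
    )


def read_multichannel_tiff(path):
    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    names = meta.get("channels", [f"ch{i}" for i in range(stack.shape[0])])
    return dict(zip(names, stack)), float(meta.get("um_per_px", 1.0))


def write_label_tiff(labels: np.ndarray, um_per_px: float, path) -> None:
    tifffile.imwrite(path, labels.astype(np.uint16), photometric="minisblack",
                     metadata={"um_per_px": um_per_px})


def write_vfa_stack(stack: VfaStack, tiff_path, sidecar_path) -> None:
    tifffile.imwrite(tiff_path, stack.signals.astype(np.float32), photometric="minisblack")
    Path(sidecar_path).write_text(
        yaml.safe_dump(
            {"flip_angles_deg": [float(a) for a in stack.flip_angles_deg],
             "tr_ms": float(stack.tr_ms)}
        )
    )


def read_vfa_stack(tiff_path, sidecar_path) -> VfaStack:
    signals = tifffile.imread(tiff_path)
    meta = yaml.safe_load(Path(sidecar_path).read_text())
    return VfaStack(
        signals=signals,
        flip_angles_deg=tuple(meta["flip_angles_deg"]),
        tr_ms=float(meta["tr_ms"]),
    )
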
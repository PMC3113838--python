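"""Readers and writers for the pipeline's plain-text and image formats.

Spot tables are tab-separated with the canonical columns of
:data:`mitomir.synthetic.SPOT_COLUMNS`; ``read_spot_table`` accepts a
column-name mapping for tables produced by other quantification software.
Sequences use FASTA (Biopython), annotations GFF3 or GenBank, channel
images 16-bit grayscale TIFF or PNG.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from mitomir.synthetic import SPOT_COLUMNS

__all__ = [
    "read_spot_table",
    "write_spot_table",
    "read_fasta",
    "write_fasta",
    "read_channel_image",
    "write_channel_image",
]


def write_spot_table(scan: pd.DataFrame, path) -> None:
    scan.to_csv(path, sep="\t", index=False)


def read_spot_table(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a spot-level table; ``column_map`` maps user column names to the
    canonical ones (e.g. ``{"gene": "probe_id"}``)."""
    df = pd.read_csv(path, sep="\t")
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"spot table {path} lacks columns {missing}")
    df["is_calibrator"] = df["is_calibrator"].astype(bool)
    return df


def read_fasta(path) -> dict[str, str]:
    """FASTA file -> ordered mapping of id -> sequence (uppercase)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_channel_image(image: np.ndarray, path) -> None:
    """Write a nonnegative intensity array as 16-bit grayscale TIFF/PNG."""
    arr = np.clip(np.asarray(image), 0, 65535).astype(np.uint16)
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(str(path), arr)
    else:
        import imageio.v3 as iio

        iio.imwrite(str(path), arr)


def read_channel_image(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        arr = tifffile.imread(str(path))
    else:
        import imageio.v3 as iio

        arr = iio.imread(str(path))
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 3:  # collapse any trailing channel axis of a gray image
        arr = arr[..., 0]
    return arr
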
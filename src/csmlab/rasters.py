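"""Plain-text label-raster snapshots (portable greymap style).

Snapshots are written as an ASCII grid of integer labels with a small
header carrying the dimensions and the MCS index, so that 2D and 3D
rasters round-trip losslessly through text files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["write_raster", "read_raster"]

_MAGIC = "CSMLAB-RASTER"


def write_raster(path, labels: np.ndarray, mcs: int) -> None:
    labels = np.asarray(labels)
    with open(path, "w") as fh:
        fh.write(f"{_MAGIC}\n")
        fh.write(" ".join(str(d) for d in labels.shape) + "\n")
        fh.write(f"{mcs}\n")
        flat = labels.reshape(-1, labels.shape[-1])
        for row in flat:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


def read_raster(path) -> tuple[np.ndarray, int]:
    text = Path(path).read_text().splitlines()
    if not text or text[0].strip() != _MAGIC:
        raise ValueError(f"{path} is not a csmlab raster file")
    shape = tuple(int(v) for v in text[1].split())
    mcs = int(text[2])
    data = np.array([int(v) for line in text[3:] for v in line.split()],
                    dtype=np.int32)
    return data.reshape(shape), mcs
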
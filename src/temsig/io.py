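"""TIFF / CSV / YAML plumbing shared by the CLI and the analysis drivers."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = ["read_stack", "write_stack", "read_config", "write_config",
           "write_ktr_dataset"]


def read_stack(path) -> np.ndarray:
    """Read a single- or multi-page TIFF as a (T, H, W) or (H, W) array."""
    return tifffile.imread(str(path))


def write_stack(path, stack: np.ndarray, as_uint16: bool = False) -> None:
    """Write a frame-major stack as a multi-page TIFF (one file per channel).

    ``as_uint16`` converts float [0, 1] data to 16-bit counts.
    """
    arr = np.asarray(stack)
    if as_uint16 and not np.issubdtype(arr.dtype, np.integer):
        arr = np.clip(arr, 0, 1)
        arr = np.round(arr * np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(str(path), arr)


def read_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_config(path, config: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def write_ktr_dataset(outdir, nuclear: np.ndarray, ktr: np.ndarray,
                      truth, config: dict, as_uint16: bool = False) -> Path:
    """Write a synthetic KTR movie: one TIFF per channel, truth CSV, config YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_stack(outdir / "nuclear.tif", nuclear, as_uint16=as_uint16)
    write_stack(outdir / "ktr.tif", ktr, as_uint16=as_uint16)
    truth.to_frame().to_csv(outdir / "ground_truth_cells.csv", index=False)
    cn = pd.DataFrame(truth.cn)
    cn.insert(0, "cell", np.arange(truth.n_cells))
    cn.to_csv(outdir / "ground_truth_cn.csv", index=False)
    write_config(outdir / "config.yaml", config)
    return outdir
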
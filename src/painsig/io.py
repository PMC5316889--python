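"""NIfTI, metadata-table and configuration I/O.

Volumes travel as NIfTI (3-D weight/stat maps, 4-D trial stacks) with a
fixed 2 mm isotropic affine by default; per-trial metadata travels as a
UTF-8 TSV with a header row and a mandated column set. Reading against an
expected grid is strict: a shape or affine mismatch is an error, never a
silent resample.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grid import GridSpec

__all__ = [
    "DEFAULT_AFFINE",
    "write_volume",
    "read_volume",
    "write_mask",
    "read_grid",
    "write_meta",
    "read_meta",
    "load_config",
    "save_config",
    "MANDATED_COLUMNS",
]

DEFAULT_AFFINE = np.diag([2.0, 2.0, 2.0, 1.0])

MANDATED_COLUMNS = [
    "subject", "run", "trial", "intensity_level", "rating",
    "painful_flag", "excluded_flag",
]


def write_volume(path, values: np.ndarray, grid: GridSpec,
                 affine: np.ndarray | None = None) -> None:
    """Write an in-mask vector (3-D map) or (n, n_vox) stack (4-D) as NIfTI."""
    import nibabel as nib

    affine = DEFAULT_AFFINE if affine is None else np.asarray(affine, float)
    vol = grid.unmask(np.asarray(values, dtype=float))
    nib.save(nib.Nifti1Image(vol, affine), str(path))


def read_volume(path, grid: GridSpec, affine: np.ndarray | None = None):
    """Read a NIfTI map or stack back to in-mask vectors.

    Returns (n_vox,) for a 3-D file, (n, n_vox) for a 4-D file. Raises if
    the file's shape or affine disagrees with the expected grid.
    """
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.shape[:3] != grid.shape:
        raise ValueError(
            f"volume shape {data.shape[:3]} does not match grid {grid.shape}"
        )
    expected = DEFAULT_AFFINE if affine is None else np.asarray(affine, float)
    if not np.allclose(img.affine, expected, atol=1e-6):
        raise ValueError("affine mismatch against the expected grid; refusing "
                         "to resample implicitly")
    return grid.mask_volume(data)


def write_mask(path, grid: GridSpec, affine: np.ndarray | None = None) -> None:
    """Write the grid mask itself as a binary NIfTI volume."""
    import nibabel as nib

    affine = DEFAULT_AFFINE if affine is None else np.asarray(affine, float)
    nib.save(nib.Nifti1Image(grid.mask.astype(np.uint8), affine), str(path))


def read_grid(path) -> GridSpec:
    """Rebuild a :class:`GridSpec` from a mask NIfTI."""
    import nibabel as nib

    img = nib.load(str(path))
    mask = np.asanyarray(img.dataobj) > 0
    return GridSpec(shape=mask.shape, mask=mask)


def write_meta(path, meta: pd.DataFrame) -> None:
    """Write a per-trial metadata table as TSV (mandated columns enforced)."""
    _check_meta(meta)
    meta.to_csv(path, sep="\t", index=False)


def read_meta(path) -> pd.DataFrame:
    """Read a per-trial metadata TSV; unknown columns are preserved."""
    df = pd.read_csv(path, sep="\t")
    _check_meta(df)
    return df


def _check_meta(df: pd.DataFrame) -> None:
    for col in MANDATED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"metadata table is missing mandated column {col!r}")
    for col in ("painful_flag", "excluded_flag"):
        vals = set(pd.unique(df[col].astype(int)))
        if not vals <= {0, 1}:
            raise ValueError(f"{col} must contain only 0/1, found {sorted(vals)}")


def load_config(path) -> dict:
    """Load a YAML run configuration."""
    import yaml

    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(path, config: dict) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
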
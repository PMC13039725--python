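"""Gridded containers shared across the pipeline.

An :class:`EnvGrid` is a stack of named environmental variables on a regular
row x column grid with a shared validity mask; a :class:`TransformedGrid`
holds the same geometry after a fitted dissimilarity model has mapped each
predictor onto its compositional-turnover scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class EnvGrid:
    """Cell-indexed stack of environmental variables.

    Parameters
    ----------
    data
        Mapping variable name -> 2-D float array (rows x cols). All arrays
        share one shape. Missing values are NaN.
    mask
        Boolean validity mask (True = valid cell). A cell is valid only when
        every variable is finite there.
    climate_vars
        Names of the variables that change between epochs; the rest are
        static (topography, soil).
    epoch
        "current" or a scenario/slice tag such as "RCP8.5-SSP5:2060-2080".
    """

    data: dict[str, np.ndarray]
    mask: np.ndarray
    climate_vars: tuple[str, ...] = ()
    epoch: str = "current"
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {v.shape for v in self.data.values()}
        if len(shapes) > 1:
            raise ValueError(f"variable arrays disagree in shape: {shapes}")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape not in shapes and shapes:
            raise ValueError("mask shape does not match variable arrays")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def variables(self) -> list[str]:
        return list(self.data)

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def valid_indices(self) -> np.ndarray:
        """Flat indices of valid cells, in row-major order."""
        return np.flatnonzero(self.mask.ravel())

    def stack(self, variables: list[str] | None = None) -> np.ndarray:
        """Valid cells as an (n_valid, n_vars) matrix in row-major cell order."""
        names = variables if variables is not None else self.variables
        cols = [self.data[name].ravel()[self.valid_indices()] for name in names]
        return np.column_stack(cols) if cols else np.empty((self.n_valid, 0))

    def copy(self) -> "EnvGrid":
        return EnvGrid(
            data={k: v.copy() for k, v in self.data.items()},
            mask=self.mask.copy(),
            climate_vars=self.climate_vars,
            epoch=self.epoch,
            attrs=dict(self.attrs),
        )

    def refresh_mask(self) -> None:
        """Recompute the mask as the intersection of per-variable finiteness."""
        valid = np.ones(self.shape, dtype=bool)
        for arr in self.data.values():
            valid &= np.isfinite(arr)
        self.mask = valid

    # ---------------------------------------------------------------- I/O

    def to_frame(self) -> pd.DataFrame:
        """Long format: cell_id,row,col,variable,value (valid cells only)."""
        rows, cols = self.shape
        rr, cc = np.divmod(np.arange(rows * cols), cols)
        records = []
        flat_mask = self.mask.ravel()
        for name, arr in self.data.items():
            flat = arr.ravel()
            records.append(
                pd.DataFrame(
                    {
                        "cell_id": np.arange(rows * cols)[flat_mask],
                        "row": rr[flat_mask],
                        "col": cc[flat_mask],
                        "variable": name,
                        "value": flat[flat_mask],
                    }
                )
            )
        return pd.concat(records, ignore_index=True)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def write_tiff(self, path: str | Path) -> None:
        """One band per variable; NaN outside the mask. Metadata sidecar JSON."""
        import tifffile

        stack = np.stack(
            [np.where(self.mask, self.data[v], np.nan) for v in self.variables]
        ).astype(np.float32)
        tifffile.imwrite(str(path), stack)
        sidecar = Path(str(path) + ".json")
        sidecar.write_text(
            json.dumps(
                {"bands": self.variables, "epoch": self.epoch, "shape": list(self.shape)},
                indent=2,
            )
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, climate_vars: tuple[str, ...] = (),
                   epoch: str = "current") -> "EnvGrid":
        rows = int(frame["row"].max()) + 1
        cols = int(frame["col"].max()) + 1
        data: dict[str, np.ndarray] = {}
        for name, sub in frame.groupby("variable"):
            arr = np.full((rows, cols), np.nan)
            arr[sub["row"].to_numpy(), sub["col"].to_numpy()] = sub["value"].to_numpy()
            data[name] = arr
        grid = cls(data=data, mask=np.ones((rows, cols), bool),
                   climate_vars=climate_vars, epoch=epoch)
        grid.refresh_mask()
        return grid


@dataclass
class TransformedGrid:
    """Per-cell, per-predictor values on the fitted turnover scale.

    ``data[p]`` holds f_p(x) = sum_k beta_{p,k} I_{p,k}(x); each lies in
    [0, sum_k beta_{p,k}]. Geometry and mask mirror the source EnvGrid.
    """

    data: dict[str, np.ndarray]
    mask: np.ndarray
    epoch: str = "current"

    @property
    def predictors(self) -> list[str]:
        return list(self.data)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def valid_indices(self) -> np.ndarray:
        return np.flatnonzero(self.mask.ravel())

    def stack(self) -> np.ndarray:
        """(n_valid, n_predictors) matrix in row-major cell order."""
        idx = self.valid_indices()
        return np.column_stack([self.data[p].ravel()[idx] for p in self.predictors])

    def to_frame(self) -> pd.DataFrame:
        rows, cols = self.shape
        rr, cc = np.divmod(np.arange(rows * cols), cols)
        flat_mask = self.mask.ravel()
        frames = [
            pd.DataFrame(
                {
                    "cell_id": np.arange(rows * cols)[flat_mask],
                    "row": rr[flat_mask],
                    "col": cc[flat_mask],
                    "predictor": p,
                    "value": arr.ravel()[flat_mask],
                }
            )
            for p, arr in self.data.items()
        ]
        return pd.concat(frames, ignore_index=True)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def write_class_map_tiff(class_map: np.ndarray, legend: dict[int, str],
                         path: str | Path) -> None:
    """Integer class-code raster with a class-legend CSV alongside."""
    import tifffile

    tifffile.imwrite(str(path), class_map.astype(np.int32))
    legend_path = Path(str(path)).with_suffix(".legend.csv")
    pd.DataFrame(
        sorted(legend.items()), columns=["code", "land_use_class"]
    ).to_csv(legend_path, index=False)
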
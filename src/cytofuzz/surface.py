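"""Dose-lattice evaluation of a fitted fuzzy model and optimum finding.

The fitted model is evaluated over the full experimental dose box
(IL-2 in [0, 40], IL-7 in [0, 100], IL-15 in [0, 100] ng/mL by default) to
produce the predicted growth-rate surface behind the heat map, the ranked
optima, and a long-format TSV export.  The TSV is the canonical artifact;
the rendered image is best-effort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fuzzy import MamdaniFIS

DEFAULT_BOUNDS = ((0.0, 40.0), (0.0, 100.0), (0.0, 100.0))


@dataclass
class SurfaceGrid:
    il2: np.ndarray
    il7: np.ndarray
    il15: np.ndarray
    values: np.ndarray  # shape (len(il2), len(il7), len(il15))

    def __post_init__(self) -> None:
        expected = (len(self.il2), len(self.il7), len(self.il15))
        if self.values.shape != expected:
            raise ValueError(
                f"values shape {self.values.shape} != axes {expected}"
            )

    def to_long(self) -> pd.DataFrame:
        mesh = np.meshgrid(self.il2, self.il7, self.il15, indexing="ij")
        return pd.DataFrame(
            {
                "il2": mesh[0].ravel(),
                "il7": mesh[1].ravel(),
                "il15": mesh[2].ravel(),
                "rate": self.values.ravel(),
            }
        )


def evaluate_grid(
    fis: MamdaniFIS,
    bounds=DEFAULT_BOUNDS,
    resolution: tuple[int, int, int] = (41, 51, 51),
    chunk: int = 8192,
) -> SurfaceGrid:
    """Predict at every lattice point of the dose box (pure, deterministic)."""
    if any(r < 2 for r in resolution):
        raise ValueError("resolution must be >= 2 per axis")
    axes = [
        np.linspace(lo, hi, r) for (lo, hi), r in zip(bounds, resolution)
    ]
    mesh = np.meshgrid(*axes, indexing="ij")
    doses = np.column_stack([m.ravel() for m in mesh])
    values = np.empty(len(doses))
    for start in range(0, len(doses), chunk):
        sl = slice(start, start + chunk)
        values[sl] = fis.predict(doses[sl])
    return SurfaceGrid(axes[0], axes[1], axes[2], values.reshape(resolution))


def find_optima(grid: SurfaceGrid, top_k: int = 1) -> pd.DataFrame:
    """Top-k lattice points by predicted rate, ties in lexicographic dose order."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    long = grid.to_long()
    # lexsort uses the last key as primary
    order = np.lexsort(
        (long["il15"], long["il7"], long["il2"], -long["rate"])
    )
    return long.iloc[order[:top_k]].reset_index(drop=True)


def export_heatmap(grid: SurfaceGrid, tsv_path, png_path=None) -> None:
    """Write the long-format surface TSV; optionally render slice heat maps."""
    grid.to_long().to_csv(tsv_path, sep="\t", index=False)
    if png_path is None:
        return
    try:  # the image is illustrative only
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        n_slices = min(4, len(grid.il15))
        picks = np.linspace(0, len(grid.il15) - 1, n_slices).astype(int)
        fig, axes = plt.subplots(
            1, n_slices, figsize=(4 * n_slices, 3.5), squeeze=False
        )
        vmin, vmax = grid.values.min(), grid.values.max()
        for ax, k in zip(axes[0], picks):
            im = ax.imshow(
                grid.values[:, :, k].T,
                origin="lower",
                aspect="auto",
                extent=(
                    grid.il2[0], grid.il2[-1], grid.il7[0], grid.il7[-1]
                ),
                vmin=vmin, vmax=vmax, cmap="viridis",
            )
            ax.set_xlabel("IL-2 (ng/mL)")
            ax.set_ylabel("IL-7 (ng/mL)")
            ax.set_title(f"IL-15 = {grid.il15[k]:.0f} ng/mL")
        fig.colorbar(im, ax=axes[0], label="predicted rate (1/hr)")
        fig.savefig(png_path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    except Exception:  # pragma: no cover - rendering is not load-bearing
        pass


def read_surface(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
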
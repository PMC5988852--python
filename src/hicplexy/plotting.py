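"""Heatmap export of observed/expected log-ratio maps.

The analysis runs at 100 kb bins; for display the log-ratio matrix is
aggregated to a coarser grid (2.5 Mb by default) by block-averaging the
per-cell log ratios, and rendered with a diverging palette (red =
enriched, blue = depleted). A bit-exact text dump accompanies the image
so renders are comparable across platforms.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .normalization import RatioMatrix


class PlotError(ValueError):
    pass


def aggregate_block_mean(values: np.ndarray, factor_r: int, factor_c: int) -> np.ndarray:
    """Block-average a matrix by integer factors (partial edge blocks use
    the actual cell count)."""
    r, c = values.shape
    out_r = -(-r // factor_r)
    out_c = -(-c // factor_c)
    out = np.empty((out_r, out_c))
    for i in range(out_r):
        for j in range(out_c):
            block = values[
                i * factor_r : (i + 1) * factor_r,
                j * factor_c : (j + 1) * factor_c,
            ]
            out[i, j] = block.mean()
    return out


def export_heatmap(
    ratio: RatioMatrix,
    display_bin_size: int = 2_500_000,
    chromosomes: tuple[str, str] | None = None,
    txt_path: str | Path | None = None,
    png_path: str | Path | None = None,
    vmax: float = 3.0,
) -> np.ndarray:
    """Aggregate and export a log-ratio heatmap.

    ``chromosomes`` selects a chromosome-pair sub-matrix (both equal for
    an intra view); None renders the whole genome. Returns the
    aggregated matrix.
    """
    scheme = ratio.scheme
    if display_bin_size < scheme.bin_size:
        raise PlotError("display bin size must be >= analysis bin size")
    factor = display_bin_size // scheme.bin_size

    ranges = scheme.bin_ranges()
    if chromosomes is not None:
        ca, cb = chromosomes
        if ca not in ranges or cb not in ranges:
            raise PlotError(f"unknown chromosome in {chromosomes}")
        blocks = ratio.block(ca, cb)
    else:
        names = list(scheme.genome)
        rows = []
        for a in names:
            row = [ratio.block(a, b) for b in names]
            rows.append(np.concatenate(row, axis=1))
        blocks = np.concatenate(rows, axis=0)
    if blocks.size == 0:
        raise PlotError("empty region selection")

    agg = aggregate_block_mean(blocks, factor, factor)

    if txt_path is not None:
        with open(txt_path, "w") as fh:
            for row in agg:
                fh.write("\t".join(f"{v:.6f}" for v in row) + "\n")
    if png_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 8))
        im = ax.imshow(
            agg, cmap="RdBu_r", vmin=-vmax, vmax=vmax, interpolation="nearest"
        )
        fig.colorbar(im, ax=ax, label="log2(observed/expected)")
        ax.set_xlabel("display bin")
        ax.set_ylabel("display bin")
        fig.savefig(png_path, dpi=120)
        plt.close(fig)
    return agg
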
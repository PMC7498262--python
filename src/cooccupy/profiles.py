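"""Summit-centered coverage matrices and average density profiles.

These are the computational core of ChIP density heatmaps: every peak
contributes a row of mean per-base coverage in fixed-width bins across a
window of +/- ``flank`` bp around its summit.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .intervals import Peak

__all__ = ["CoverageTrack", "DensityMatrix", "read_bedgraph", "density_matrix",
           "average_profile", "write_matrix_tsv"]


class CoverageTrack:
    """Dense per-base coverage, one float array per chromosome."""

    def __init__(self, arrays: Mapping[str, np.ndarray]):
        self.arrays = {c: np.asarray(a, dtype=float) for c, a in arrays.items()}
        for chrom, arr in self.arrays.items():
            if np.any(arr < 0):
                raise ValueError(f"negative coverage on {chrom}")

    def total(self) -> float:
        return float(sum(a.sum() for a in self.arrays.values()))


def read_bedgraph(
    path: str | os.PathLike, chrom_lengths: Mapping[str, int] | None = None
) -> CoverageTrack:
    """Read a 4-column bedGraph (0-based half-open) into dense arrays.

    Chromosome lengths default to the maximum end seen per chromosome.
    """
    spans: dict[str, list[tuple[int, int, float]]] = {}
    path = os.fspath(path)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            cols = line.split()
            if len(cols) < 4:
                raise ValueError(f"{path}:{lineno}: bedGraph needs 4 columns")
            chrom, start, end, value = cols[0], int(cols[1]), int(cols[2]), float(cols[3])
            if end <= start or start < 0:
                raise ValueError(f"{path}:{lineno}: bad interval [{start}, {end})")
            spans.setdefault(chrom, []).append((start, end, value))
    arrays: dict[str, np.ndarray] = {}
    for chrom, lst in spans.items():
        length = (
            chrom_lengths[chrom]
            if chrom_lengths is not None and chrom in chrom_lengths
            else max(e for _, e, _ in lst)
        )
        arr = np.zeros(length)
        for s, e, v in lst:
            arr[s:e] = v
        arrays[chrom] = arr
    if chrom_lengths:
        for chrom, length in chrom_lengths.items():
            arrays.setdefault(chrom, np.zeros(length))
    return CoverageTrack(arrays)


@dataclass
class DensityMatrix:
    peak_ids: list[str]
    bin_edges: np.ndarray  # len bins+1, positions relative to summit
    values: np.ndarray     # peaks x bins, mean per-base coverage
    flank: int
    bin_size: int
    n_missing_chrom: int = 0

    @property
    def bin_midpoints(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2


def density_matrix(
    coverage: CoverageTrack,
    peaks: Sequence[Peak],
    flank: int = 2000,
    bin_size: int = 50,
    sort_rows: str = "signal",
) -> DensityMatrix:
    """Per-peak binned coverage in ``[summit - flank, summit + flank)``.

    Each cell is the mean per-base coverage within its bin. Windows truncated
    at chromosome ends average over the covered bases only (bins entirely
    outside the chromosome are 0). Peaks on chromosomes absent from the track
    become zero rows and are tallied in ``n_missing_chrom``. ``sort_rows``:
    ``signal`` orders rows by descending window total, ``input`` keeps peak
    order.
    """
    if flank <= 0 or bin_size <= 0 or (2 * flank) % bin_size:
        raise ValueError("bin_size must divide 2*flank and both must be positive")
    if sort_rows not in ("signal", "input"):
        raise ValueError(f"sort_rows must be 'signal' or 'input', got {sort_rows!r}")
    n_bins = 2 * flank // bin_size
    edges = np.arange(n_bins + 1) * bin_size - flank
    values = np.zeros((len(peaks), n_bins))
    missing = 0
    for i, p in enumerate(peaks):
        arr = coverage.arrays.get(p.chrom)
        if arr is None:
            missing += 1
            continue
        for j in range(n_bins):
            lo = p.summit + int(edges[j])
            hi = p.summit + int(edges[j + 1])
            clo, chi = max(lo, 0), min(hi, arr.size)
            if chi > clo:
                values[i, j] = arr[clo:chi].mean()
    ids = [p.peak_id for p in peaks]
    if sort_rows == "signal":
        order = np.argsort(-values.sum(axis=1), kind="mergesort")
        values = values[order]
        ids = [ids[k] for k in order]
    return DensityMatrix(ids, edges, values, flank, bin_size, missing)


def average_profile(matrix: DensityMatrix) -> np.ndarray:
    """Column means of the density matrix (the 'average density' panel)."""
    if matrix.values.shape[0] == 0:
        raise ValueError("density matrix has no rows")
    return matrix.values.mean(axis=0)


def write_matrix_tsv(matrix: DensityMatrix, path: str | os.PathLike) -> None:
    mids = matrix.bin_midpoints
    with open(path, "w") as fh:
        fh.write("peak_id\t" + "\t".join(f"{m:g}" for m in mids) + "\n")
        for pid, row in zip(matrix.peak_ids, matrix.values):
            fh.write(pid + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")
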
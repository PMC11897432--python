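"""Readers and writers for count matrices, bin annotation and results.

Count matrices are cells x bins, as delimited text (TSV/CSV, optionally
gzipped, optional header row and cell-id column) or HDF5 (dataset
``counts``, optional ``bins``).  Bin annotation follows BED conventions:
0-based, half-open, sorted, non-overlapping.  Corrected counts are kept
real-valued; nothing here rounds them.
"""

from __future__ import annotations

import gzip
import hashlib
import json
from pathlib import Path

import numpy as np

from .breakpoints import BinCountMatrix, SegmentMap
from .data_model import tree_to_dot, tree_to_json
from .search import InferenceResult

__all__ = [
    "read_counts",
    "write_counts",
    "read_bins",
    "write_segments",
    "write_outputs",
    "config_hash",
]


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_counts(path: str | Path) -> BinCountMatrix:
    """Load a cells x bins matrix from TSV/CSV(.gz) or HDF5."""
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        import h5py

        with h5py.File(path, "r") as fh:
            counts = np.asarray(fh["counts"], dtype=float)
            bins = None
            if "bins" in fh:
                raw = fh["bins"]
                bins = [
                    (c.decode() if isinstance(c, bytes) else str(c), int(s), int(e))
                    for c, s, e in zip(raw["chrom"], raw["start"], raw["end"])
                ]
        return BinCountMatrix(counts, bins)

    delim = "," if ".csv" in path.suffixes or path.suffix == ".csv" else None
    rows: list[list[float]] = []
    with _open_text(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            fields = line.strip().split(delim) if delim else line.split()
            if not fields:
                continue
            if line_no == 1 and any(_not_numeric(f) for f in fields):
                continue  # header row
            if _not_numeric(fields[0]):
                fields = fields[1:]  # leading cell-id column
            try:
                rows.append([float(f) for f in fields])
            except ValueError as exc:
                raise ValueError(f"{path}:{line_no}: non-numeric count field") from exc
    if not rows:
        raise ValueError(f"{path}: no data rows")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError(f"{path}: ragged rows (widths {sorted(widths)})")
    return BinCountMatrix(np.asarray(rows, dtype=float))


def _not_numeric(token: str) -> bool:
    try:
        float(token)
        return False
    except ValueError:
        return True


def write_counts(matrix: BinCountMatrix, path: str | Path) -> None:
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("counts", data=matrix.counts)
        return
    np.savetxt(path, matrix.counts, fmt="%.10g", delimiter="\t")


def read_bins(path: str | Path, one_based: bool = False) -> list[tuple[str, int, int]]:
    """Parse a BED-like bin annotation; order preserved, overlap rejected."""
    bins: list[tuple[str, int, int]] = []
    with _open_text(Path(path)) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split()[:3]
            s, e = int(start), int(end)
            if one_based:
                s -= 1
            if e <= s:
                raise ValueError(f"empty or inverted bin: {line.strip()}")
            bins.append((chrom, s, e))
    for (c1, _, e1), (c2, s2, _) in zip(bins, bins[1:]):
        if c1 == c2 and s2 < e1:
            raise ValueError("bins overlap or are out of order")
    return bins


def write_segments(
    segmap: SegmentMap,
    path: str | Path,
    bins: list[tuple[str, int, int]] | None = None,
) -> None:
    """Segment map as TSV; genomic coordinates included when bins are known."""
    with open(path, "w") as fh:
        if bins is None:
            fh.write("start_bin\tend_bin\tn_bins\n")
            for s, e in zip(segmap.starts, segmap.ends):
                fh.write(f"{s}\t{e}\t{e - s}\n")
        else:
            fh.write("chrom\tstart\tend\tstart_bin\tend_bin\tn_bins\n")
            for s, e in zip(segmap.starts, segmap.ends):
                chrom, gstart, _ = bins[s]
                _, _, gend = bins[e - 1]
                fh.write(f"{chrom}\t{gstart}\t{gend}\t{s}\t{e}\t{e - s}\n")


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def write_outputs(
    result: InferenceResult,
    out_dir: str | Path,
    config: dict | None = None,
) -> None:
    """Write tree.json, tree.dot, cnvs.tsv, attachments.tsv, diagnostics.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = dict(config or {})
    stamp = {"config_hash": config_hash(cfg), "config": cfg}

    (out / "tree.json").write_text(tree_to_json(result.tree))
    counts_per_node = np.bincount(result.sigma, minlength=result.tree.n + 1)
    (out / "tree.dot").write_text(tree_to_dot(result.tree, counts_per_node))
    np.savetxt(out / "cnvs.tsv", result.copy_numbers, fmt="%d", delimiter="\t")
    np.savetxt(out / "attachments.tsv", result.sigma[:, None], fmt="%d")
    diag = {
        "score": result.score,
        "nu": result.nu,
        "robust": result.robust,
        **stamp,
        **result.diagnostics,
    }
    (out / "diagnostics.json").write_text(json.dumps(diag, indent=1, default=str))
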
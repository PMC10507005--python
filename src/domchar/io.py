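"""Delimited-text readers and writers for every pipeline artifact.

All on-disk formats are TSV: one (mz, intensity) file per sample-replicate
plus a metadata table, the formula-by-sample intensity matrix, summary and
ordination tables, and the bioassay plate.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .assign import AssignedTable, PeakList

PEAKS_SUBDIR = "peaks"


def write_peak_lists(
    peaks: list[PeakList],
    out_dir: str | Path,
    sample_groups: dict[str, str] | None = None,
) -> Path:
    """Write one TSV per replicate plus a metadata TSV; returns meta path."""
    out_dir = Path(out_dir)
    peak_dir = out_dir / PEAKS_SUBDIR
    peak_dir.mkdir(parents=True, exist_ok=True)
    meta_rows = []
    for pl in peaks:
        fname = f"{pl.sample_id}_rep{pl.replicate_id}.tsv"
        pl.to_frame().to_csv(peak_dir / fname, sep="\t", index=False)
        meta_rows.append(
            {
                "sample_id": pl.sample_id,
                "group": (sample_groups or {}).get(pl.sample_id, ""),
                "replicate": pl.replicate_id,
                "file": f"{PEAKS_SUBDIR}/{fname}",
            }
        )
    meta_path = out_dir / "meta.tsv"
    pd.DataFrame(meta_rows).to_csv(meta_path, sep="\t", index=False)
    return meta_path


def read_peak_lists(meta_path: str | Path) -> tuple[list[PeakList], pd.DataFrame]:
    """Load replicate peak lists listed in a metadata TSV."""
    meta_path = Path(meta_path)
    if not meta_path.exists():
        raise FileNotFoundError(f"metadata file not found: {meta_path}")
    meta = pd.read_csv(meta_path, sep="\t")
    required = {"sample_id", "replicate", "file"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata is missing columns {sorted(missing)}")
    peaks = []
    for _, row in meta.iterrows():
        path = meta_path.parent / row["file"]
        if not path.exists():
            raise FileNotFoundError(f"peak list not found: {path}")
        df = pd.read_csv(path, sep="\t")
        peaks.append(
            PeakList(
                sample_id=str(row["sample_id"]),
                replicate_id=row["replicate"],
                mz=df["mz"].to_numpy(),
                intensity=df["intensity"].to_numpy(),
            )
        )
    return peaks, meta


def write_assigned_table(result: AssignedTable, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result.table.rename_axis("formula").to_csv(out_dir / "table.tsv", sep="\t")
    result.annotations.rename_axis("formula").to_csv(
        out_dir / "annotations.tsv", sep="\t"
    )


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"table not found: {path}")
    return pd.read_csv(path, sep="\t", index_col=0)
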
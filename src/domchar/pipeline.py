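"""End-to-end orchestration: synthesis (optional), assignment, composition,
ordination and bioactivity from one serializable configuration.

Every stage reads its inputs from, and writes its outputs to, the run
directory, so any stage can be re-run from persisted intermediates and the
whole run is reproducible byte-for-byte from the config and seeds. A
manifest records parameter values, seeds and row counts per stage.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .assign import DEFAULT_ELEMENT_BOUNDS, assign_samples
from .bioactivity import ic50_table, regress
from .compose import CATEGORIES, heteroatom_table, summarize_all
from .ordinate import bray_curtis_matrix, envfit_table, pcoa
from .synth import SynthConfig, generate_bioassay_plate, generate_formula_library, render_peak_lists

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

#: Descriptors fitted post hoc to the ordination by default: the nine
#: category percentages plus the intensity-weighted indices.
DEFAULT_ENVFIT_DESCRIPTORS = list(CATEGORIES) + ["DBE_w", "AImod_w", "MW_w"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All stage parameters plus paths; round-trips through JSON unchanged."""

    mode: str = "synthetic"              # "synthetic" | "user-data"
    output_dir: str = "domchar_run"
    meta_path: str | None = None         # user-data mode inputs
    bioassay_path: str | None = None
    synth: SynthConfig = field(default_factory=SynthConfig)
    tol_ppm: float = 0.5
    mdl_level: float | None = None
    element_bounds: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_ELEMENT_BOUNDS)
    )
    n_perm: int = 10_000
    alpha: float = 0.1
    envfit_seed: int = 0
    ic50_method: str = "interpolation"
    envfit_descriptors: list[str] = field(
        default_factory=lambda: list(DEFAULT_ENVFIT_DESCRIPTORS)
    )
    regression_descriptor: str = "Aromatic_pct"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        synth = data.pop("synth", {})
        if isinstance(synth, dict):
            synth = dict(synth)
            for key in ("mass_range_da", "intensity_lognormal_mu_sigma"):
                if key in synth and synth[key] is not None:
                    synth[key] = tuple(synth[key])
            if "element_bounds" in synth:
                synth["element_bounds"] = {
                    el: tuple(v) for el, v in synth["element_bounds"].items()
                }
            synth = SynthConfig(**synth)
        if "element_bounds" in data:
            data["element_bounds"] = {
                el: tuple(v) for el, v in data["element_bounds"].items()
            }
        return cls(synth=synth, **data)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _stage_synth(config: PipelineConfig, out: Path) -> dict:
    truth = generate_formula_library(config.synth)
    peaks = render_peak_lists(truth, config.synth)
    plate = generate_bioassay_plate(truth, config.synth)
    io.write_peak_lists(peaks, out, truth.sample_groups)
    gt_rows = []
    for sid, df in truth.samples.items():
        sub = df.copy()
        sub.insert(0, "sample_id", sid)
        gt_rows.append(sub)
    pd.concat(gt_rows, ignore_index=True).to_csv(
        out / "ground_truth.tsv", sep="\t", index=False
    )
    truth.descriptors.rename_axis("sample_id").to_csv(
        out / "true_descriptors.tsv", sep="\t"
    )
    plate.to_csv(out / "bioassay.tsv", sep="\t", index=False)
    return {
        "n_samples": len(truth.samples),
        "n_peak_lists": len(peaks),
        "n_truth_formulas": int(sum(len(df) for df in truth.samples.values())),
        "n_bioassay_wells": int(len(plate)),
    }


def _stage_assign(config: PipelineConfig, out: Path) -> dict:
    meta_path = Path(config.meta_path) if config.mode == "user-data" else out / "meta.tsv"
    peaks, _ = io.read_peak_lists(meta_path)
    result = assign_samples(
        peaks,
        tol_ppm=config.tol_ppm,
        bounds=config.element_bounds,
        mdl_level=config.mdl_level,
        scan_range=config.synth.mass_range_da,
    )
    io.write_assigned_table(result, out)
    return {
        "n_formulas": int(result.table.shape[0]),
        "n_samples": int(result.table.shape[1]),
    }


def _stage_compose(config: PipelineConfig, out: Path) -> dict:
    table = io.read_table(out / "table.tsv")
    summary = summarize_all(table)
    summary.to_csv(out / "summary.tsv", sep="\t")
    het = heteroatom_table(table)
    het.to_csv(out / "heteroatoms.tsv", sep="\t")
    return {"n_summary_rows": int(len(summary))}


def _stage_ordinate(config: PipelineConfig, out: Path) -> dict:
    table = io.read_table(out / "table.tsv")
    summary = io.read_table(out / "summary.tsv")
    dm = bray_curtis_matrix(table)
    result = pcoa(dm)
    result.scores.rename_axis("sample_id").to_csv(out / "scores.tsv", sep="\t")
    eig = pd.DataFrame(
        {
            "eigenvalue": result.eigenvalues,
            "proportion_explained": np.concatenate(
                [result.proportion_explained,
                 np.full(len(result.eigenvalues) - len(result.proportion_explained), np.nan)]
            ),
        }
    )
    eig.rename_axis("axis").to_csv(out / "eigenvalues.tsv", sep="\t")
    desc_cols = [c for c in config.envfit_descriptors if c in summary.columns]
    fits = envfit_table(
        result, summary[desc_cols], n_perm=config.n_perm,
        alpha=config.alpha, seed=config.envfit_seed,
    )
    fits.to_csv(out / "envfit.tsv", sep="\t")
    explained_2d = float(result.proportion_explained[: 2].sum())
    return {
        "n_axes": int(result.n_axes),
        "explained_first2_pct": 100.0 * explained_2d,
        "n_descriptors_fitted": int(len(fits)),
    }


def _stage_bioactivity(config: PipelineConfig, out: Path) -> dict:
    plate_path = (
        Path(config.bioassay_path) if config.mode == "user-data" else out / "bioassay.tsv"
    )
    if not plate_path.exists():
        raise FileNotFoundError(f"bioassay table not found: {plate_path}")
    plate = pd.read_csv(plate_path, sep="\t")
    table1 = ic50_table(plate, method=config.ic50_method)
    table1.to_csv(out / "ic50.tsv", sep="\t")

    summary = io.read_table(out / "summary.tsv")
    # derived descriptor: total aromatic share (O-rich + O-poor)
    summary = summary.assign(Aromatic_pct=summary["A_Or"] + summary["A_Op"])
    flat = table1.reset_index()
    reg_rows = []
    for assay, sub in flat.groupby("assay"):
        sub = sub.set_index("sample_id")
        response = -np.log10(sub["ic50_mean"])
        n_censored = int(sub["censored"].sum())
        for col in [config.regression_descriptor]:
            if col not in summary.columns:
                continue
            try:
                fit = regress(summary[col], response, n_censored=n_censored)
            except ValueError:
                continue
            reg_rows.append(
                {
                    "assay": assay,
                    "descriptor": col,
                    "response": "neg_log10_ic50",
                    "slope": fit.slope,
                    "intercept": fit.intercept,
                    "r2": fit.r2,
                    "p": fit.p_value,
                    "stars": fit.stars,
                    "n": fit.n,
                    "n_censored": fit.n_censored,
                }
            )
    reg = pd.DataFrame(reg_rows)
    reg.to_csv(out / "regressions.tsv", sep="\t", index=False)
    return {"n_assays": int(flat["assay"].nunique()), "n_regressions": int(len(reg))}


STAGES = {
    "synth": _stage_synth,
    "assign": _stage_assign,
    "compose": _stage_compose,
    "ordinate": _stage_ordinate,
    "bioactivity": _stage_bioactivity,
}


def run_pipeline(config: PipelineConfig, stages: list[str] | None = None) -> dict:
    """Execute the pipeline stages in order; returns the run manifest.

    In synthetic mode the chain is synth -> assign -> compose -> ordinate ->
    bioactivity; in user-data mode the synth stage is skipped and peak lists
    and bioassay tables are read from the configured paths. A stage failure
    aborts the run with the stage name attached.
    """
    if config.mode not in ("synthetic", "user-data"):
        raise ValueError(f"unknown mode {config.mode!r}")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    order = stages or (
        ["synth", "assign", "compose", "ordinate", "bioactivity"]
        if config.mode == "synthetic"
        else ["assign", "compose", "ordinate", "bioactivity"]
    )
    manifest: dict = {
        "package_version": __version__,
        "config": config.to_dict(),
        "stages": {},
    }
    for stage in order:
        try:
            manifest["stages"][stage] = STAGES[stage](config, out)
        except (FileNotFoundError, ValueError, KeyError) as exc:
            raise PipelineError(stage, str(exc)) from exc
    config.to_json(out / "config.json")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
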
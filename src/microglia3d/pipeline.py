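"""End-to-end driver: classify -> segment -> measure -> colocalize -> compare.

``run_pipeline`` consumes a :class:`~microglia3d.io.PipelineConfig` plus a
list of ``(stack path, group tag)`` pairs and a trained classifier (or
sparse labels to train one), executes every stage in the documented order
and writes tidy CSVs, label TIFFs, a statistics report and a JSON manifest.
All outputs are deterministic given the configuration and seeds.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import SparseLabelMap, VoxelClassifier, train_classifier
from .coloc import coloc_per_cell, segment_cd68
from .core import AcquisitionGeometry, Stack
from .features import FeatureBank
from .io import PipelineConfig, RunManifest, file_sha256, read_stack, write_labels
from .morphometry import count_density, measure_labels
from .segment import segment_stack
from .stats import GroupTable, summarize, two_sample_test, two_way_anova_bonferroni

log = logging.getLogger("microglia3d")

#: per-cell metrics compared between groups in the report
COMPARED_METRICS = (
    "volume_um3",
    "convex_hull_volume_um3",
    "solidity_3d",
    "area_um2",
    "perimeter_um",
    "convex_hull_area_um2",
    "convex_hull_perimeter_um",
    "solidity_2d",
    "convexity",
    "circularity",
    "minor_axis_um",
    "major_axis_um",
    "axis_ratio",
)


@dataclass
class StackResult:
    stack_id: str
    group: str
    labels: object  # LabelVolume of the accepted cells
    morphometry: pd.DataFrame
    coloc: pd.DataFrame
    density: dict
    otsu_threshold: float
    n_vessel_excluded_voxels: int


@dataclass
class PipelineResult:
    per_cell: pd.DataFrame
    per_stack: pd.DataFrame
    tests: pd.DataFrame
    anova: object | None
    manifest: RunManifest
    report_text: str
    stack_results: list[StackResult] = field(default_factory=list)


def bank_from_config(config: PipelineConfig) -> FeatureBank:
    return FeatureBank(
        sigmas=tuple(config.sigmas),
        anisotropy_correction=config.anisotropy_correction,
    )


def process_stack(
    stack: Stack,
    stack_id: str,
    group: str,
    classifier: VoxelClassifier,
    config: PipelineConfig,
) -> StackResult:
    """Run one stack through classification, segmentation and measurement."""
    iba1 = stack.channel(0)
    pmap = classifier.predict_probabilities(iba1)
    seg = segment_stack(
        pmap,
        smooth_sigma=config.smooth_sigma,
        v_threshold=config.v_threshold,
        min_volume_um3=config.min_volume_um3,
        min_separation_um=config.min_separation_um,
        marker_min_distance_um=config.marker_min_distance_um,
    )
    provenance = {"stack_id": stack_id, "params_hash": config.config_hash()}
    records = measure_labels(seg.labels, provenance)
    morpho = pd.DataFrame([r.to_dict() for r in records])
    morpho.insert(0, "stack_id", stack_id)
    morpho.insert(1, "group", group)

    if stack.n_channels >= 2:
        cd68_mask, _ = segment_cd68(stack.channel(1), seg.labels, scope=config.cd68_scope)
        vox_vol = float(np.prod(stack.spacing))
        crecords, _ = coloc_per_cell(
            cd68_mask, seg.labels, positivity_min_um3=config.positivity_min_voxels * vox_vol
        )
        coloc_df = pd.DataFrame([r.to_dict() for r in crecords])
    else:
        coloc_df = pd.DataFrame(
            columns=["label_id", "cell_volume_um3", "cd68_volume_um3", "cd68_ratio", "cd68_positive"]
        )
    if len(coloc_df):
        coloc_df.insert(0, "stack_id", stack_id)
        coloc_df.insert(1, "group", group)

    nz, ny, nx = stack.shape_zyx
    dz, dy, dx = stack.spacing
    geom = AcquisitionGeometry(nx=nx, ny=ny, nz=nz, dx=dx, dy=dy, dz=dz)
    dens = count_density(seg.labels, geom).to_dict()
    dens.update({"stack_id": stack_id, "group": group})
    return StackResult(
        stack_id=stack_id,
        group=group,
        labels=seg.labels,
        morphometry=morpho,
        coloc=coloc_df,
        density=dens,
        otsu_threshold=seg.otsu_threshold,
        n_vessel_excluded_voxels=seg.n_vessel_excluded_voxels,
    )


def _group_stats(per_cell: pd.DataFrame, per_stack: pd.DataFrame, alpha: float):
    """Two-sample tests per metric (per-cell) and per-subject densities."""
    rows = []
    groups = sorted(per_cell["group"].unique()) if len(per_cell) else []
    if len(groups) == 2:
        g0, g1 = groups
        for metric in COMPARED_METRICS:
            if metric not in per_cell.columns:
                continue
            a = per_cell.loc[per_cell["group"] == g0, metric].to_numpy(float)
            b = per_cell.loc[per_cell["group"] == g1, metric].to_numpy(float)
            if len(a) < 3 or len(b) < 3:
                continue
            res = two_sample_test(a, b, normality_alpha=alpha)
            row = res.to_dict()
            row.update({"metric": metric, "unit_of_analysis": "cell",
                        f"mean_{g0}": a.mean(), f"mean_{g1}": b.mean()})
            rows.append(row)
        if "cd68_ratio" in per_cell.columns and per_cell["cd68_ratio"].notna().any():
            for metric in ("cd68_volume_um3", "cd68_ratio"):
                a = per_cell.loc[per_cell["group"] == g0, metric].dropna().to_numpy(float)
                b = per_cell.loc[per_cell["group"] == g1, metric].dropna().to_numpy(float)
                if len(a) >= 3 and len(b) >= 3:
                    res = two_sample_test(a, b, normality_alpha=alpha)
                    row = res.to_dict()
                    row.update({"metric": metric, "unit_of_analysis": "cell",
                                f"mean_{g0}": a.mean(), f"mean_{g1}": b.mean()})
                    rows.append(row)
        # densities compare per-stack (subject-average analogue) values
        for metric in ("density_per_mm2", "density_per_mm3"):
            a = per_stack.loc[per_stack["group"] == g0, metric].to_numpy(float)
            b = per_stack.loc[per_stack["group"] == g1, metric].to_numpy(float)
            if len(a) >= 3 and len(b) >= 3:
                res = two_sample_test(a, b, normality_alpha=alpha)
                row = res.to_dict()
                row.update({"metric": metric, "unit_of_analysis": "stack",
                            f"mean_{g0}": a.mean(), f"mean_{g1}": b.mean()})
                rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(
    config: PipelineConfig,
    inputs: list[tuple[str, str]],
    classifier: VoxelClassifier | None = None,
    training_stack: Stack | None = None,
    training_labels: SparseLabelMap | None = None,
    output_dir: str | None = None,
    write_outputs: bool = True,
) -> PipelineResult:
    """Execute the full pipeline over ``(stack path, group)`` inputs.

    Either a trained ``classifier`` or a ``(training_stack,
    training_labels)`` pair must be supplied.
    """
    t_start = time.time()
    timings: dict[str, float] = {}
    out_dir = Path(output_dir or config.output_dir)
    if write_outputs:
        out_dir.mkdir(parents=True, exist_ok=True)

    if classifier is None:
        if training_stack is None or training_labels is None:
            raise ValueError("either a trained classifier or training data is required")
        t0 = time.time()
        classifier = train_classifier(
            training_stack.channel(0),
            training_labels,
            bank=bank_from_config(config),
            n_trees=config.n_trees,
            max_depth=config.max_depth,
            seed=config.classifier_seed,
        )
        timings["train"] = time.time() - t0

    manifest = RunManifest(config_hash=config.config_hash(), package_version=__version__)
    stack_results = []
    for path, group in inputs:
        t0 = time.time()
        stack = read_stack(path, default_spacing=(config.dz, config.dy, config.dx))
        sid = Path(path).stem
        try:
            result = process_stack(stack, sid, group, classifier, config)
        except Exception as exc:  # abort with stage context
            raise RuntimeError(f"pipeline failed on stack {sid!r}: {exc}") from exc
        stack_results.append(result)
        manifest.inputs.append({"path": str(path), "sha256": file_sha256(path), "group": group})
        timings[f"stack:{sid}"] = time.time() - t0

    per_cell_parts = []
    for r in stack_results:
        df = r.morphometry
        if len(r.coloc):
            df = df.merge(
                r.coloc[["label_id", "cd68_volume_um3", "cd68_ratio", "cd68_positive"]],
                on="label_id", how="left",
            )
        per_cell_parts.append(df)
    per_cell = (
        pd.concat(per_cell_parts, ignore_index=True) if per_cell_parts else pd.DataFrame()
    )
    per_stack = pd.DataFrame([r.density for r in stack_results])

    t0 = time.time()
    tests = _group_stats(per_cell, per_stack, config.normality_alpha)
    anova = None
    if (
        len(per_cell)
        and "cd68_positive" in per_cell.columns
        and per_cell["cd68_positive"].notna().any()
        and per_cell["group"].nunique() == 2
    ):
        strat = per_cell.dropna(subset=["cd68_positive"]).copy()
        strat["cd68_status"] = np.where(strat["cd68_positive"].astype(bool), "CD68+", "CD68-")
        counts = strat.groupby(["group", "cd68_status"]).size()
        if len(counts) == 4 and (counts >= 2).all():
            anova = two_way_anova_bonferroni(
                GroupTable(strat.rename(columns={"volume_um3": "value"})[
                    ["value", "group", "cd68_status"]
                ]),
                factor2="cd68_status",
            )
    timings["stats"] = time.time() - t0

    report = _format_report(per_cell, per_stack, tests, anova)
    manifest.stage_timings_s = {k: round(v, 3) for k, v in timings.items()}

    if write_outputs:
        per_cell.to_csv(out_dir / "per_cell.csv", index=False, float_format="%.8g")
        per_stack.to_csv(out_dir / "per_stack.csv", index=False, float_format="%.8g")
        tests.to_csv(out_dir / "group_tests.csv", index=False, float_format="%.8g")
        (out_dir / "stats_report.txt").write_text(report)
        for r in stack_results:
            write_labels(out_dir / f"{r.stack_id}_labels.tif", r.labels)
        manifest.outputs = sorted(p.name for p in out_dir.iterdir())
        manifest.write(out_dir / "manifest.json")

    log.info("pipeline finished in %.1f s", time.time() - t_start)
    return PipelineResult(
        per_cell=per_cell,
        per_stack=per_stack,
        tests=tests,
        anova=anova,
        manifest=manifest,
        report_text=report,
        stack_results=stack_results,
    )


def _format_report(per_cell, per_stack, tests, anova) -> str:
    lines = ["Group comparison report", "=" * 60]
    if len(per_cell):
        for g, sub in per_cell.groupby("group"):
            s = summarize(sub["volume_um3"], label=g)
            lines.append(f"{g}: n={s['n']} cells, volume {s['text']} um^3")
    if len(per_stack):
        for g, sub in per_stack.groupby("group"):
            s2 = summarize(sub["density_per_mm2"], label=g)
            s3 = summarize(sub["density_per_mm3"], label=g)
            lines.append(f"{g}: density {s2['text']} /mm^2, {s3['text']} /mm^3")
    if len(tests):
        lines.append("-" * 60)
        for _, row in tests.iterrows():
            lines.append(
                f"{row['metric']:28s} {row['test']:15s} p={row['p_value']:.4g} {row['stars']}"
            )
    if anova is not None:
        lines.append("-" * 60)
        lines.append("two-way ANOVA (volume ~ group x CD68 status, Type II SS):")
        for eff in ("group", "factor2", "interaction"):
            lines.append(f"  {eff:12s} p={anova.effect_p(eff):.4g}")
        for c in anova.contrasts:
            lines.append(
                f"  {c.extra['comparison']:32s} p_bonf={c.p_value:.4g} {c.stars}"
            )
    return "\n".join(lines) + "\n"
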
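"""Desk-scale in-silico replica of the multicenter relaxometry study.

One YAML config drives the whole design: a shared digital phantom with
per-subject ground-truth jitter, two (or more) simulated acquisition
centers, scan–rescan replicates, several fitting pipelines (optimizer
backends) and several atlas sets for multi-atlas fusion. ``run_study``
emits per-subject regional tables, inter-center / inter-pipeline agreement
reports, inter-atlas-set Dice and parcel-volume tables, and scan–rescan
reports, all as CSV plus the NIfTI volumes behind them.

Every random draw takes its seed from ``master_seed`` combined with a
stable string key (subject/center/scan/stage) via CRC-32, so reruns are
bit-identical and adding a subject never changes another subject's data.
"""

from __future__ import annotations

import logging
import time
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analysis, fusion, phantom
from .fitting import FitOptions, Optimizer, fit_t1_map, fit_t2_map
from .phantom import (
    CenterEffect,
    PhantomSpec,
    RegionTruth,
    default_ir_protocol,
    default_multiecho_protocol,
)
from .volume_io import (
    AcquisitionProtocol,
    LabelVolume,
    Modality,
    write_labels,
    write_series,
)

__all__ = ["AtlasSetSpec", "StudyConfig", "validate_config", "run_study", "derive_seed"]

log = logging.getLogger("relaxo.study")

# per-subject multiplicative jitter of the ground truth (fractional SD)
T1_JITTER_SD = 0.03
T2_JITTER_SD = 0.05


def derive_seed(master_seed: int, *parts) -> int:
    """Deterministic sub-seed: CRC-32 of the key path folded with the master."""
    key = "/".join(str(p) for p in parts)
    return (int(master_seed) ^ zlib.crc32(key.encode())) % (2**31)


@dataclass(frozen=True)
class AtlasSetSpec:
    """How to build one synthetic atlas set from the ground-truth labels."""

    n_atlases: int
    perturbation_voxels: float
    seed: int

    def __post_init__(self) -> None:
        if self.n_atlases < 1:
            raise ValueError("n_atlases must be >= 1")
        if self.perturbation_voxels < 0:
            raise ValueError("perturbation_voxels must be >= 0")


@dataclass
class StudyConfig:
    """Validated description of one in-silico study run."""

    master_seed: int
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    ir_protocol: AcquisitionProtocol = field(default_factory=default_ir_protocol)
    multiecho_protocol: AcquisitionProtocol = field(
        default_factory=default_multiecho_protocol
    )
    centers: dict[str, CenterEffect] = field(
        default_factory=lambda: {
            "C1": CenterEffect(gain=1.0, bias_field_amplitude=0.05, noise_sigma=20.0),
            "C2": CenterEffect(gain=1.1, bias_field_amplitude=0.05, noise_sigma=20.0),
        }
    )
    n_subjects: int = 2
    rescan_subjects: tuple[int, ...] = (0,)
    fit_pipelines: dict[str, FitOptions] = field(
        default_factory=lambda: {
            "fLM": FitOptions(optimizer=Optimizer.LEAST_SQUARES_LM),
            "fSimplex": FitOptions(optimizer=Optimizer.SIMPLEX),
        }
    )
    atlas_sets: dict[str, AtlasSetSpec] = field(
        default_factory=lambda: {
            "s11": AtlasSetSpec(n_atlases=11, perturbation_voxels=1.0, seed=11),
            "s12": AtlasSetSpec(n_atlases=12, perturbation_voxels=1.0, seed=12),
        }
    )

    def __post_init__(self) -> None:
        if self.master_seed is None:
            raise ValueError("master_seed is required (no silent nondeterminism)")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.ir_protocol.modality is not Modality.IR_T1:
            raise ValueError("ir_protocol must have modality IR_T1")
        if self.multiecho_protocol.modality is not Modality.MULTIECHO_T2:
            raise ValueError("multiecho_protocol must have modality MULTIECHO_T2")
        for idx in self.rescan_subjects:
            if not 0 <= idx < self.n_subjects:
                raise ValueError(f"rescan subject index {idx} out of range")
        for group, names in (
            ("centers", self.centers),
            ("fit_pipelines", self.fit_pipelines),
            ("atlas_sets", self.atlas_sets),
        ):
            if len(names) < 1:
                raise ValueError(f"{group} must not be empty")


def _protocol_from_cfg(doc: dict, modality: Modality, path: str) -> AcquisitionProtocol:
    try:
        return AcquisitionProtocol(
            modality=modality,
            times_ms=tuple(float(t) for t in doc["times_ms"]),
            tr_ms=float(doc["tr_ms"]),
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise ValueError(f"{path}: {exc}") from exc


def validate_config(path: str | Path) -> StudyConfig:
    """Load and fully validate a YAML study config; defaults filled in.

    Every invariant violation is reported with the offending key path.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if "master_seed" not in doc:
        raise ValueError("config: missing required key 'master_seed'")
    kwargs: dict = {"master_seed": int(doc["master_seed"])}

    if "phantom" in doc:
        pdoc = dict(doc["phantom"])
        spec_kwargs: dict = {}
        if "grid_shape" in pdoc:
            spec_kwargs["grid_shape"] = tuple(int(s) for s in pdoc["grid_shape"])
        if "seed" in pdoc:
            spec_kwargs["seed"] = int(pdoc["seed"])
        if "region_truth" in pdoc:
            truth = phantom.default_region_truth()
            for key, entry in pdoc["region_truth"].items():
                lid = int(key)
                if lid not in truth:
                    raise ValueError(f"phantom.region_truth.{key}: unknown label id")
                try:
                    truth[lid] = RegionTruth(
                        t1_ms=float(entry["t1_ms"]),
                        t2_ms=float(entry["t2_ms"]),
                        proton_density=float(entry.get("proton_density", 1000.0)),
                    )
                except ValueError as exc:
                    name = phantom.canonical_lut().set_index("label_id").loc[
                        lid, "region_name"
                    ]
                    raise ValueError(
                        f"phantom.region_truth.{key} ({name}): {exc}"
                    ) from exc
            spec_kwargs["region_truth"] = truth
        try:
            kwargs["phantom"] = PhantomSpec(**spec_kwargs)
        except ValueError as exc:
            raise ValueError(f"phantom: {exc}") from exc

    if "ir_protocol" in doc:
        kwargs["ir_protocol"] = _protocol_from_cfg(
            doc["ir_protocol"], Modality.IR_T1, "ir_protocol"
        )
    if "multiecho_protocol" in doc:
        kwargs["multiecho_protocol"] = _protocol_from_cfg(
            doc["multiecho_protocol"], Modality.MULTIECHO_T2, "multiecho_protocol"
        )
    if "centers" in doc:
        centers = {}
        for name, c in doc["centers"].items():
            try:
                centers[str(name)] = CenterEffect(
                    gain=float(c.get("gain", 1.0)),
                    bias_field_amplitude=float(c.get("bias_field_amplitude", 0.0)),
                    noise_sigma=float(c.get("noise_sigma", 0.0)),
                    seed=int(c.get("seed", 0)),
                )
            except ValueError as exc:
                raise ValueError(f"centers.{name}: {exc}") from exc
        kwargs["centers"] = centers
    if "n_subjects" in doc:
        kwargs["n_subjects"] = int(doc["n_subjects"])
    if "rescan_subjects" in doc:
        kwargs["rescan_subjects"] = tuple(int(i) for i in doc["rescan_subjects"])
    if "fit_pipelines" in doc:
        pipes = {}
        for name, p in doc["fit_pipelines"].items():
            try:
                pipes[str(name)] = FitOptions(
                    optimizer=Optimizer(p.get("optimizer", "lm")),
                    max_iterations=int(p.get("max_iterations", 500)),
                    convergence_tol=float(p.get("convergence_tol", 1e-6)),
                )
            except ValueError as exc:
                raise ValueError(f"fit_pipelines.{name}: {exc}") from exc
        kwargs["fit_pipelines"] = pipes
    if "atlas_sets" in doc:
        sets = {}
        for name, s in doc["atlas_sets"].items():
            try:
                sets[str(name)] = AtlasSetSpec(
                    n_atlases=int(s["n_atlases"]),
                    perturbation_voxels=float(s.get("perturbation_voxels", 1.0)),
                    seed=int(s.get("seed", 0)),
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"atlas_sets.{name}: {exc}") from exc
        kwargs["atlas_sets"] = sets
    try:
        return StudyConfig(**kwargs)
    except ValueError as exc:
        raise ValueError(f"config: {exc}") from exc


# ---------------------------------------------------------------------------
# Study execution


def _jittered_truth(
    config: StudyConfig, subject: int
) -> dict[int, RegionTruth]:
    """Per-subject multiplicative jitter of the ground-truth relaxation times."""
    rng = np.random.default_rng(derive_seed(config.master_seed, "subject", subject))
    out = {}
    for lid, truth in config.phantom.region_truth.items():
        f1 = max(0.5, 1.0 + rng.normal(0.0, T1_JITTER_SD))
        f2 = max(0.5, 1.0 + rng.normal(0.0, T2_JITTER_SD))
        out[lid] = RegionTruth(
            t1_ms=min(truth.t1_ms * f1, phantom.T1_MAX_MS),
            t2_ms=min(truth.t2_ms * f2, phantom.T2_MAX_MS),
            proton_density=truth.proton_density,
        )
    return out


def build_atlas_set(
    labels: LabelVolume, spec: AtlasSetSpec, master_seed: int
) -> fusion.AtlasSet:
    """Perturbed copies of the ground-truth parcellation, one per atlas.

    Seeds derive from the spec's own seed (not its name), so two sets with
    identical specs contain identical atlases — the null-control case.
    """
    atlases = [
        phantom.perturb_labels(
            labels,
            spec.perturbation_voxels,
            seed=derive_seed(master_seed, "atlas", spec.seed, k),
        )
        for k in range(spec.n_atlases)
    ]
    return fusion.AtlasSet(atlases=atlases)


def _fit_series(series, pipeline: FitOptions, modality: Modality):
    if modality is Modality.IR_T1:
        return fit_t1_map(series, pipeline)
    return fit_t2_map(series, pipeline)


def run_study(config: StudyConfig, out_dir: str | Path) -> dict:
    """Execute the full in-silico study and write its report bundle.

    Returns a dict of the in-memory results (regional tables, agreement
    reports, Dice tables) keyed as the files are named. Bit-identical
    across reruns of the same config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []
    t_start = time.time()

    def _log(stage: str, **info) -> None:
        log.info("%s %s", stage, info)
        manifest.append({"stage": stage, **info, "t_s": round(time.time() - t_start, 2)})

    results: dict = {}

    # --- shared parcellation and fused atlas sets -------------------------
    labels = phantom.make_label_phantom(config.phantom)
    write_labels(labels, out / "labels_truth.nii.gz", out / "lut.tsv")
    _log("phantom", grid=config.phantom.grid_shape, seed=config.phantom.seed)

    fused: dict[str, LabelVolume] = {}
    for name, aspec in config.atlas_sets.items():
        aset = build_atlas_set(labels, aspec, config.master_seed)
        fused[name] = fusion.fuse_max_probability(aset)
        write_labels(fused[name], out / f"parcellation_{name}.nii.gz", out / "lut.tsv")
        _log("fusion", atlas_set=name, n_atlases=aspec.n_atlases)
    results["parcellations"] = fused

    set_names = list(config.atlas_sets)
    ref_set = set_names[0]
    seg_rows = []
    for name in set_names:
        vols = fusion.parcel_volumes(fused[name])
        vols.insert(0, "atlas_set", name)
        seg_rows.append(vols)
        if name != ref_set:
            for r in labels.lut.itertuples():
                seg_rows.append(
                    pd.DataFrame(
                        [
                            {
                                "atlas_set": f"dice:{ref_set}-vs-{name}",
                                "label_id": int(r.label_id),
                                "region_name": r.region_name,
                                "voxel_count": np.nan,
                                "volume_mm3": np.nan,
                                "dice": fusion.dice_score(
                                    fused[ref_set], fused[name], int(r.label_id)
                                ),
                            }
                        ]
                    )
                )
    seg_table = pd.concat(seg_rows, ignore_index=True)
    seg_table.to_csv(out / "segmentation_comparison.csv", index=False)
    results["segmentation_comparison"] = seg_table

    # --- per subject x center x scan: simulate, fit, regional stats -------
    center_names = list(config.centers)
    pipe_names = list(config.fit_pipelines)
    stats_rows = []
    region_tables: dict[tuple, pd.DataFrame] = {}
    for subject in range(config.n_subjects):
        truth = _jittered_truth(config, subject)
        spec = replace(config.phantom, region_truth=truth)
        t1_map, t2_map, pd_map = phantom.truth_maps(labels, spec)
        n_scans = 2 if subject in config.rescan_subjects else 1
        for center in center_names:
            effect = config.centers[center]
            for scan in range(n_scans):
                for modality, tmap, protocol in (
                    (Modality.IR_T1, t1_map, config.ir_protocol),
                    (Modality.MULTIECHO_T2, t2_map, config.multiecho_protocol),
                ):
                    seed = derive_seed(
                        config.master_seed, subject, center, scan, modality.value
                    )
                    if modality is Modality.IR_T1:
                        series = phantom.simulate_ir_series(
                            tmap, pd_map, protocol, seed=seed,
                            voxel_size_um=config.phantom.voxel_size_um,
                        )
                    else:
                        series = phantom.simulate_multiecho_series(
                            tmap, pd_map, protocol, seed=seed,
                            voxel_size_um=config.phantom.voxel_size_um,
                        )
                    series = phantom.apply_center_effect(
                        series,
                        replace(
                            effect,
                            seed=derive_seed(
                                config.master_seed, subject, center, scan,
                                modality.value, "center",
                            ),
                        ),
                    )
                    tag = f"sub{subject:02d}_{center}_scan{scan}_{modality.value}"
                    write_series(
                        series, out / f"{tag}.nii.gz", out / f"{tag}.json"
                    )
                    _log("simulate", tag=tag, seed=seed)
                    for pipe in pipe_names:
                        pm = _fit_series(
                            series, config.fit_pipelines[pipe], modality
                        )
                        stats = analysis.region_means(pm, fused[ref_set])
                        key = (subject, center, scan, modality.value, pipe)
                        region_tables[key] = stats
                        annotated = stats.copy()
                        annotated.insert(0, "pipeline", pipe)
                        annotated.insert(0, "modality", modality.value)
                        annotated.insert(0, "scan", scan)
                        annotated.insert(0, "center", center)
                        annotated.insert(0, "subject", subject)
                        stats_rows.append(annotated)
                        _log("fit", tag=tag, pipeline=pipe)

    regional = pd.concat(stats_rows, ignore_index=True)
    regional.to_csv(out / "regional_values.csv", index=False)
    results["regional_values"] = regional
    results["region_tables"] = region_tables

    def _mean_over_subjects(center: str, modality: str, pipe: str) -> np.ndarray:
        tables = [
            region_tables[(s, center, 0, modality, pipe)]["mean_ms"].to_numpy()
            for s in range(config.n_subjects)
        ]
        return np.nanmean(np.stack(tables), axis=0)

    # --- inter-center agreement (first pipeline, first scan) --------------
    inter_center: dict[str, analysis.AgreementReport] = {}
    if len(center_names) >= 2:
        c1, c2 = center_names[0], center_names[1]
        for modality in (Modality.IR_T1, Modality.MULTIECHO_T2):
            x = _mean_over_subjects(c1, modality.value, pipe_names[0])
            y = _mean_over_subjects(c2, modality.value, pipe_names[0])
            inter_center[modality.value] = analysis.compare_regions(x, y)
        results["inter_center"] = inter_center

    # --- inter-pipeline agreement (first center, first scan) --------------
    inter_pipeline: dict[tuple, analysis.AgreementReport] = {}
    for i, pa in enumerate(pipe_names):
        for pb in pipe_names[i + 1 :]:
            for modality in (Modality.IR_T1, Modality.MULTIECHO_T2):
                x = _mean_over_subjects(center_names[0], modality.value, pa)
                y = _mean_over_subjects(center_names[0], modality.value, pb)
                inter_pipeline[(pa, pb, modality.value)] = analysis.compare_regions(
                    x, y
                )
    results["inter_pipeline"] = inter_pipeline

    # --- scan-rescan reports ----------------------------------------------
    rescan: dict[tuple, analysis.ScanRescanReport] = {}
    for subject in config.rescan_subjects:
        for center in center_names:
            for modality in (Modality.IR_T1, Modality.MULTIECHO_T2):
                s1 = region_tables[(subject, center, 0, modality.value, pipe_names[0])]
                s2 = region_tables[(subject, center, 1, modality.value, pipe_names[0])]
                rescan[(subject, center, modality.value)] = analysis.scan_rescan_report(
                    s1, s2
                )
    results["scan_rescan"] = rescan

    # --- summary tables ----------------------------------------------------
    def _report_row(kind: str, key: str, rep: analysis.AgreementReport) -> dict:
        mean_d, sd_d, (lo, hi) = rep.bland_altman
        return {
            "comparison": kind,
            "key": key,
            "n_pairs": rep.n_pairs,
            "mean_diff": mean_d,
            "sd_diff": sd_d,
            "loa_low": lo,
            "loa_high": hi,
            "slope": rep.slope,
            "intercept": rep.intercept,
            "r_squared": rep.r_squared,
            "mean_percent_error": rep.mean_percent_error,
            "mann_whitney_p": rep.mann_whitney_p,
            "wilcoxon_p": rep.wilcoxon_p,
            "alpha": rep.alpha,
        }

    summary = [
        _report_row("inter_center", mod, rep) for mod, rep in inter_center.items()
    ] + [
        _report_row("inter_pipeline", f"{pa}-vs-{pb}:{mod}", rep)
        for (pa, pb, mod), rep in inter_pipeline.items()
    ]
    if summary:
        pd.DataFrame(summary).to_csv(out / "agreement_summary.csv", index=False)

    rescan_rows = []
    for (subject, center, mod), rep in rescan.items():
        t = rep.table.copy()
        t.insert(0, "modality", mod)
        t.insert(0, "center", center)
        t.insert(0, "subject", subject)
        t["wilcoxon_p"] = rep.wilcoxon_p
        t["r_squared"] = rep.r_squared
        rescan_rows.append(t)
    if rescan_rows:
        pd.concat(rescan_rows, ignore_index=True).to_csv(
            out / "scan_rescan.csv", index=False
        )

    pd.DataFrame(manifest).to_csv(out / "manifest.csv", index=False)
    results["manifest"] = pd.DataFrame(manifest)
    return results
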
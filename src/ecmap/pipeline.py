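"""Pipeline orchestration, configuration, file formats and provenance.

Sequences the full analysis: simulate (optional) -> motion QC -> masks ->
centrality pair per subject -> permutation cluster test with and without
motion regression -> intersection cluster mask -> marker association ->
genotype-risk prediction.  Every intermediate is persisted (NIfTI volumes,
TSV tables, JSON reports) and a manifest records a checksum for each
artifact, so identical configs reproduce identical bundles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association as assoc
from . import cluster as clu
from . import cohort as coh
from . import ecm
from . import prediction as pred

__all__ = ["PipelineConfig", "PipelineError", "qc_exclude", "run_full_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Everything a full run needs; all randomness flows from named seeds."""

    out_dir: str = "ecmap_out"
    cohort: coh.CohortSpec = field(default_factory=coh.CohortSpec)
    highpass_cutoff_s: float = 182.0
    ecm_tol: float = 1e-9
    ecm_max_iter: int = 1000
    n_permutations: int = 1000
    permutation_seed: int = 0
    threshold_grid: tuple[float, float, float] = (1.5, 5.0, 0.1)
    connectivity: int = 26
    n_boot: int = 2000
    bootstrap_seed: int = 0
    motion_threshold_mm: float = 0.5

    def grid(self) -> np.ndarray:
        lo, hi, step = self.threshold_grid
        return np.round(np.arange(lo, hi + 1e-9, step), 10)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["community_layout"] = {
            str(k): np.asarray(v).tolist()
            for k, v in d["cohort"]["community_layout"].items()
        }
        return d

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort_raw = raw.pop("cohort", {})
        if "community_layout" in cohort_raw and cohort_raw["community_layout"]:
            cohort_raw["community_layout"] = {
                int(k): np.asarray(v)
                for k, v in cohort_raw["community_layout"].items()
            }
        for tup_key in ("grid_shape", "band_hz"):
            if tup_key in cohort_raw:
                cohort_raw[tup_key] = tuple(cohort_raw[tup_key])
        if "threshold_grid" in raw:
            raw["threshold_grid"] = tuple(raw["threshold_grid"])
        return cls(cohort=coh.CohortSpec(**cohort_raw), **raw)


def qc_exclude(traces: list[coh.MotionTrace], threshold_mm: float) -> list[int]:
    """Indices of subjects whose mean displacement is within the threshold."""
    if threshold_mm < 0:
        raise ValueError("motion threshold must be >= 0")
    return [i for i, t in enumerate(traces) if t.mean_displacement_mm <= threshold_mm]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=1, default=_json_default))


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_full_pipeline(config: PipelineConfig, write_bold: bool = False) -> dict:
    """Execute the whole analysis and persist a reproducible report bundle.

    Returns the report dictionary (also written as ``report.json``).  Set
    ``write_bold`` to persist the simulated 4D runs themselves; masks,
    centrality maps, tables and reports are always written.
    """
    out = Path(config.out_dir)
    for sub in ("cohort", "ecm", "cluster", "association", "prediction"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    spec = config.cohort

    # --- simulate -----------------------------------------------------
    runs, traces, table, truth = coh.generate_cohort(spec)
    table.to_csv(out / "cohort" / "participants.tsv", sep="\t", index=False)
    (out / "cohort" / "ground_truth.json").write_text(truth.to_json())
    for i, trace in enumerate(traces):
        trace.save(out / "cohort" / f"sub-{i:03d}_motion.txt")
    if write_bold:
        for i, run in enumerate(runs):
            ecm.save_volume(run.data, spec.voxel_size_mm,
                            out / "cohort" / f"sub-{i:03d}_bold.nii.gz")

    # --- motion QC ----------------------------------------------------
    kept = qc_exclude(traces, config.motion_threshold_mm)
    qc_report = {
        "n_total": spec.n_subjects,
        "n_kept": len(kept),
        "n_excluded": spec.n_subjects - len(kept),
        "threshold_mm": config.motion_threshold_mm,
        "mean_displacement_mm": [t.mean_displacement_mm for t in traces],
        "kept_indices": kept,
    }
    _write_json(out / "cohort" / "qc.json", qc_report)
    if not kept:
        raise PipelineError("qc: every subject exceeded the motion threshold; "
                            f"see {out / 'cohort' / 'qc.json'}")
    runs = [runs[i] for i in kept]
    traces = [traces[i] for i in kept]
    table = table.iloc[kept].reset_index(drop=True)

    # --- masks and centrality ------------------------------------------
    try:
        masks = [ecm.single_subject_mask(r) for r in runs]
        analysis_mask = ecm.intersection_mask(masks)
    except ValueError as exc:
        raise PipelineError(f"masking: {exc}") from exc
    pairs = [
        ecm.ecm_pair(run, trace.params, analysis_mask,
                     cutoff_s=config.highpass_cutoff_s,
                     tol=config.ecm_tol, max_iter=config.ecm_max_iter)
        for run, trace in zip(runs, traces)
    ]
    # voxels can drop out of individual maps via the variance screen; use the
    # common mask across subjects for the group analysis
    common_mask = np.logical_and.reduce([p[0].mask for p in pairs])
    ecm.save_volume(common_mask.astype(np.float32), spec.voxel_size_mm,
                    out / "ecm" / "analysis_mask.nii.gz")
    plain_vols = np.stack([p[0].to_volume() for p in pairs])
    mreg_vols = np.stack([p[1].to_volume() for p in pairs])
    for i in range(len(runs)):
        ecm.save_volume(plain_vols[i], spec.voxel_size_mm,
                        out / "ecm" / f"sub-{i:03d}_ecm.nii.gz")
        ecm.save_volume(mreg_vols[i], spec.voxel_size_mm,
                        out / "ecm" / f"sub-{i:03d}_ecm_mreg.nii.gz")

    # --- cluster inference, with and without motion regression ---------
    design = clu.build_design(table)
    reports = {}
    for name, vols in (("plain", plain_vols), ("mreg", mreg_vols)):
        stack = vols[:, common_mask]
        reports[name] = clu.run_cluster_test(
            stack, common_mask, design,
            n_permutations=config.n_permutations,
            seed=config.permutation_seed,
            candidate_grid=config.grid(),
            connectivity=config.connectivity,
        )
        clu.cluster_table(reports[name], spec.voxel_size_mm).to_csv(
            out / "cluster" / f"clusters_{name}.tsv", sep="\t", index=False)
        ecm.save_volume(
            clu.significant_voxel_mask(reports[name].clusters, spec.grid_shape
                                       ).astype(np.float32),
            spec.voxel_size_mm, out / "cluster" / f"sig_mask_{name}.nii.gz")
        _write_json(out / "cluster" / f"null_{name}.json", {
            "forming_threshold": reports[name].forming_threshold,
            "mass_threshold": reports[name].mass_threshold,
            "n_permutations": reports[name].n_permutations,
            "null_masses": reports[name].null_masses,
        })
    cluster_mask = clu.intersect_analyses(
        reports["plain"].clusters, reports["mreg"].clusters, spec.grid_shape)
    ecm.save_volume(cluster_mask.astype(np.float32), spec.voxel_size_mm,
                    out / "cluster" / "intersection_mask.nii.gz")

    report: dict = {
        "config_hash": config.config_hash(),
        "seeds": {"cohort": spec.seed, "permutation": config.permutation_seed,
                  "bootstrap": config.bootstrap_seed},
        "qc": {k: qc_report[k] for k in ("n_total", "n_kept", "n_excluded")},
        "analysis_mask_voxels": int(common_mask.sum()),
        "cluster": {
            name: {
                "forming_threshold": rep.forming_threshold,
                "mass_threshold": rep.mass_threshold,
                "n_significant": len(rep.significant_clusters),
            }
            for name, rep in reports.items()
        },
        "intersection_voxels": int(cluster_mask.sum()),
        "intersection_volume_mm3": float(cluster_mask.sum())
        * spec.voxel_size_mm ** 3,
    }

    # --- association + prediction (motion-regressed values) ------------
    if not cluster_mask.any():
        report["association"] = None
        report["prediction"] = None
        report["note"] = ("empty intersection cluster mask: no significant "
                          "group difference survived both analyses; "
                          "association and prediction were skipped")
    else:
        means = assoc.extract_cluster_means(mreg_vols, cluster_mask)
        pd.DataFrame({"subject_id": table["subject_id"],
                      "cluster_mean_ec": means}).to_csv(
            out / "association" / "cluster_means.tsv", sep="\t", index=False)
        fits = assoc.marker_table(means, table)
        fits.to_csv(out / "association" / "marker_fits.tsv", sep="\t", index=False)
        try:
            assoc.plot_marker_fits(means, table, out / "association")
        except ImportError:
            warnings.warn("matplotlib unavailable; marker plots skipped")
        f_stat, p_val = assoc.group_anova(means, table["group"].to_numpy())
        report["association"] = {"anova_f": f_stat, "anova_p": p_val,
                                 "markers": fits.to_dict(orient="records")}

        labels = table["group"].to_numpy()
        base = pred.evaluate_model(means[:, None], labels, ["cluster_mean_ec"],
                                   n_boot=config.n_boot, seed=config.bootstrap_seed)
        aug = pred.evaluate_model(
            np.column_stack([means, table["age"].to_numpy(dtype=float)]),
            labels, ["cluster_mean_ec", "age"],
            n_boot=config.n_boot, seed=config.bootstrap_seed)
        comparison = pred.compare_models(base, aug)
        pd.DataFrame({"fpr": base.fpr, "tpr": base.tpr}).to_csv(
            out / "prediction" / "roc.tsv", sep="\t", index=False)
        _write_json(out / "prediction" / "report.json", {
            "comparison": comparison,
            "probabilities": base.probabilities,
            "flagged_folds": base.flagged_folds,
        })
        report["prediction"] = comparison

    _write_json(out / "report.json", report)
    provenance_config = config.to_dict()
    provenance_config.pop("out_dir", None)
    _write_json(out / "provenance.json", {
        "config": provenance_config,
        "config_hash": config.config_hash(),
        "versions": _versions(),
    })
    manifest = {
        str(p.relative_to(out)): _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    _write_json(out / "manifest.json", manifest)
    return report


def _versions() -> dict:
    import nibabel
    import scipy
    import sklearn
    import statsmodels

    import ecmap

    return {
        "ecmap": ecmap.__version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "nibabel": nibabel.__version__,
        "statsmodels": statsmodels.__version__,
        "sklearn": sklearn.__version__,
    }
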
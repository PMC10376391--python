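"""End-to-end runs: simulate -> fit -> features -> analyze.

A run is described by a single YAML/JSON config with either a ``simulate``
block (synthetic cohort, optionally with image-level phantoms) or a ``paths``
block (real NIfTI volumes + masks + labels).  Each stage consumes only files
written by earlier stages plus the config, every output directory carries a
manifest with the config hash and seed, and the whole chain is deterministic
given the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import phantom as ph
from . import stats as st
from . import texture as tx
from .signal_models import BValueScheme, FitConfig, ParameterMaps, fit_maps

logger = logging.getLogger("dkitex")

__all__ = [
    "RunConfig",
    "load_config",
    "run_simulate",
    "run_fit",
    "run_features",
    "run_analyze",
    "run_all",
    "render_report",
    "setup_logging",
]

_DEFAULT_COMBINATION = ["md_p75", "md_p90", "mk_p90"]


@dataclass
class RunConfig:
    """Parsed run configuration; exactly one of ``simulate``/``paths`` is set."""

    seed: int = 0
    simulate: dict | None = None
    paths: dict | None = None
    fit: dict = field(default_factory=dict)
    texture: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.paths is None):
            raise ValueError("config must contain exactly one of 'simulate' or 'paths'")

    @property
    def hash(self) -> str:
        payload = json.dumps(
            {"seed": self.seed, "simulate": self.simulate, "paths": self.paths,
             "fit": self.fit, "texture": self.texture, "stats": self.stats},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def fit_config(self) -> FitConfig:
        return FitConfig(**self.fit)


def load_config(path: str | Path, seed: int | None = None) -> RunConfig:
    """Load a YAML or JSON run config; ``seed`` overrides the file's seed."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig(
        seed=int(raw.get("seed", 0)),
        simulate=raw.get("simulate"),
        paths=raw.get("paths"),
        fit=raw.get("fit", {}) or {},
        texture=raw.get("texture", {}) or {},
        stats=raw.get("stats", {}) or {},
    )
    if seed is not None:
        cfg.seed = int(seed)
    return cfg


def setup_logging(outdir: Path | None = None, verbose: bool = False) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        handlers.append(logging.FileHandler(outdir / "run.log"))
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        handlers=handlers, force=True,
    )


def _provenance(config: RunConfig) -> dict:
    from . import __version__

    return {
        "config_hash": config.hash,
        "seed": config.seed,
        "dkitex_version": __version__,
        "numpy_version": np.__version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }


def _check_writable(outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    probe = outdir / ".write_probe"
    try:
        probe.write_text("ok")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {outdir} is not writable: {exc}") from exc


def _group_dists(sim: dict) -> tuple[ph.GroupDistribution, ph.GroupDistribution, str]:
    endpoint = sim.get("endpoint", "stage")
    if endpoint == "stage":
        pos, neg = ph.STAGE_MIBC, ph.STAGE_NMIBC
    elif endpoint == "grade":
        pos, neg = ph.GRADE_HIGH, ph.GRADE_LOW
    else:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    if "n_pos" in sim:
        pos = ph.GroupDistribution(pos.label, int(sim["n_pos"]), pos.markers)
    if "n_neg" in sim:
        neg = ph.GroupDistribution(neg.label, int(sim["n_neg"]), neg.markers)
    return pos, neg, endpoint


def run_simulate(config: RunConfig, outdir: str | Path) -> dict:
    """Generate the synthetic cohort (and optional phantoms) on disk."""
    import nibabel as nib

    if config.simulate is None:
        raise ValueError("run_simulate requires a 'simulate' config block")
    outdir = Path(outdir)
    _check_writable(outdir)
    sim = config.simulate
    pos, neg, endpoint = _group_dists(sim)
    ss = np.random.SeedSequence(config.seed)
    cohort_seed, phantom_seed = ss.spawn(2)

    reader_model = ph.ReaderScoreModel(**sim.get("reader_model", {}))
    cohort = ph.sample_cohort(
        pos, neg, seed=np.random.default_rng(cohort_seed), endpoint=endpoint,
        latent_rho=float(sim.get("latent_rho", 0.0)), reader_model=reader_model,
    )
    cohort_csv = outdir / "cohort.csv"
    cohort.to_csv(cohort_csv, index=False, float_format="%.6g")

    phantom_kwargs = dict(sim.get("phantom", {}))
    for key in ("shape", "spacing", "semi_axes_mm", "center_mm"):
        if key in phantom_kwargs and phantom_kwargs[key] is not None:
            phantom_kwargs[key] = tuple(phantom_kwargs[key])
    scheme = BValueScheme.default()
    spec = ph.PhantomSpec(scheme=scheme, **phantom_kwargs)
    scheme_tsv = outdir / "scheme.tsv"
    spec.scheme.to_tsv(scheme_tsv)

    files: dict[str, dict] = {}
    if sim.get("phantoms", False):
        affine = np.diag([*spec.spacing, 1.0])
        children = phantom_seed.spawn(len(cohort))
        for row, child in zip(cohort.itertuples(index=False), children):
            rng = np.random.default_rng(child)
            truth = ph.make_truth_fields(
                spec,
                md_mean=row.truth_md_mean * 1e-3,  # table scale -> mm^2/s
                mk_mean=row.truth_mk_mean,
                seed=rng,
            )
            dwi = ph.simulate_dwi(truth, spec.scheme, spec.sigma, seed=rng)
            pid = row.patient_id
            paths = {
                "dwi": str(outdir / f"dwi_{pid}.nii.gz"),
                "mask": str(outdir / f"mask_{pid}.nii.gz"),
                "truth_md": str(outdir / f"truth_md_{pid}.nii.gz"),
                "truth_mk": str(outdir / f"truth_mk_{pid}.nii.gz"),
            }
            nib.save(nib.Nifti1Image(dwi.astype(np.float64), affine), paths["dwi"])
            nib.save(nib.Nifti1Image(truth["mask"].astype(np.uint8), affine), paths["mask"])
            nib.save(nib.Nifti1Image(truth["md"], affine), paths["truth_md"])
            nib.save(nib.Nifti1Image(truth["mk"], affine), paths["truth_mk"])
            files[pid] = paths
        logger.info("simulated %d phantoms on %s grid", len(files), spec.shape)

    manifest = {
        "provenance": _provenance(config),
        "endpoint": endpoint,
        "n_patients": int(len(cohort)),
        "phantoms": bool(sim.get("phantoms", False)),
        "cohort_csv": str(cohort_csv),
        "scheme_tsv": str(scheme_tsv),
        "spacing": list(spec.spacing),
        "files": files,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    logger.info("cohort of %d patients written to %s", len(cohort), outdir)
    return manifest


def _load_manifest(outdir: Path) -> dict:
    path = outdir / "manifest.json"
    if not path.exists():
        raise FileNotFoundError(f"{path} not found: run the simulate stage first")
    return json.loads(path.read_text())


def _maps_from_files(outdir: Path, pid: str, model: str, mask: np.ndarray,
                     spacing, config: FitConfig) -> ParameterMaps:
    import nibabel as nib

    names = ("s0", "md", "mk") if model == "dki" else ("s0", "adc")
    params = {}
    for n in names:
        p = outdir / f"{pid}_{model}_{n}.nii.gz"
        params[n] = np.asarray(nib.load(p).dataobj, dtype=float)
    fitted = np.all([np.isfinite(params[n]) for n in names], axis=0) & mask
    return ParameterMaps(
        model=model, shape=mask.shape, spacing=tuple(spacing), params=params,
        mask=mask, fitted=fitted, converged=fitted,
        residual_norm=np.where(fitted, 0.0, np.nan),
        n_points_used=np.zeros(mask.shape, dtype=np.int32), config=config,
    )


def run_fit(config: RunConfig, simdir: str | Path, outdir: str | Path) -> dict:
    """Fit DKI and ADC maps for every patient volume; collect failures."""
    import nibabel as nib

    simdir, outdir = Path(simdir), Path(outdir)
    _check_writable(outdir)
    manifest = _load_manifest(simdir)
    if not manifest.get("files"):
        raise ValueError("manifest lists no image files; nothing to fit "
                         "(summary-level cohorts skip the fit stage)")
    scheme = BValueScheme.from_tsv(manifest["scheme_tsv"])
    fit_cfg = config.fit_config()
    spacing = tuple(manifest["spacing"])
    fit_hash = hashlib.sha256(json.dumps(
        {"fit": config.fit, "hash": manifest["provenance"]["config_hash"]},
        sort_keys=True).encode()).hexdigest()[:16]

    done_marker = outdir / "fit_summary.json"
    if done_marker.exists():
        prior = json.loads(done_marker.read_text())
        if prior.get("fit_hash") == fit_hash:
            logger.info("fit outputs up to date (hash %s); skipping", fit_hash)
            return prior

    failures: list[dict] = []
    fitted_ids: list[str] = []
    for pid, paths in manifest["files"].items():
        try:
            dwi = np.asarray(nib.load(paths["dwi"]).dataobj, dtype=float)
            mask = np.asarray(nib.load(paths["mask"]).dataobj) > 0
            dki = fit_maps(dwi, scheme, mask, model="dki", config=fit_cfg, spacing=spacing)
            adc = fit_maps(dwi, scheme, mask, model="adc", config=fit_cfg, spacing=spacing)
            dki.save(outdir, pid)
            adc.save(outdir, pid)
            fitted_ids.append(pid)
        except Exception as exc:  # per-patient failure: log, continue
            logger.error("fit failed for %s: %s", pid, exc)
            failures.append({"patient_id": pid, "error": str(exc)})
    summary = {
        "provenance": _provenance(config),
        "fit_hash": fit_hash,
        "n_fitted": len(fitted_ids),
        "fitted_ids": fitted_ids,
        "failures": failures,
        "simdir": str(simdir),
        "spacing": list(spacing),
    }
    done_marker.write_text(json.dumps(summary, indent=1))
    logger.info("fitted maps for %d patients (%d failures)", len(fitted_ids), len(failures))
    return summary


def run_features(config: RunConfig, simdir: str | Path, fitdir: str | Path | None,
                 outdir: str | Path) -> pd.DataFrame:
    """Build the per-patient feature table (features.csv).

    With image-level phantoms the features come from the fitted maps; for a
    summary-level cohort (no phantoms) the generator's patient summaries are
    used directly as features.
    """
    simdir, outdir = Path(simdir), Path(outdir)
    _check_writable(outdir)
    manifest = _load_manifest(simdir)
    cohort = pd.read_csv(manifest["cohort_csv"])

    if manifest.get("files"):
        if fitdir is None:
            raise ValueError("fitdir is required when the cohort has image files")
        fitdir = Path(fitdir)
        import nibabel as nib

        fit_cfg = config.fit_config()
        spacing = tuple(manifest["spacing"])

        def patients():
            for pid, paths in manifest["files"].items():
                mask = np.asarray(nib.load(paths["mask"]).dataobj) > 0
                yield pid, {
                    "dki": _maps_from_files(fitdir, pid, "dki", mask, spacing, fit_cfg),
                    "adc": _maps_from_files(fitdir, pid, "adc", mask, spacing, fit_cfg),
                }

        feats, errors = tx.feature_table(
            patients(),
            nbins=int(config.texture.get("nbins", 64)),
            inhomogeneity=config.texture.get("inhomogeneity", "cv"),
        )
        if errors:
            logger.warning("feature extraction failed for %d patients", len(errors))
            (outdir / "feature_errors.json").write_text(json.dumps(errors, indent=1))
    else:
        truth_cols = [c for c in cohort.columns if c.startswith("truth_")]
        feats = cohort[["patient_id", *truth_cols]].rename(
            columns={c: c.removeprefix("truth_") for c in truth_cols})
        logger.info("summary-level cohort: generator summaries used as features")

    table = cohort[["patient_id", "stage", "grade",
                    "reader1_virads", "reader2_virads"]].merge(
        feats, on="patient_id", how="inner")
    table.to_csv(outdir / "features.csv", index=False, float_format="%.8g")
    logger.info("feature table with %d rows written", len(table))
    return table


# ---------------------------------------------------------------------------
# Analysis / reporting
# ---------------------------------------------------------------------------

_ENDPOINT_POS = {"stage": ("stage", "MIBC"), "grade": ("grade", "high")}


def _marker_columns(table: pd.DataFrame) -> list[str]:
    skip = {"patient_id", "stage", "grade", "reader1_virads", "reader2_virads"}
    return [c for c in table.columns if c not in skip]


def run_analyze(config: RunConfig, featdir: str | Path, outdir: str | Path) -> dict:
    """Group comparisons, per-marker ROC, ICC, VI-RADS rule and combinations."""
    featdir, outdir = Path(featdir), Path(outdir)
    _check_writable(outdir)
    table = pd.read_csv(featdir / "features.csv")
    stats_cfg = config.stats
    endpoints = stats_cfg.get("endpoints", ["stage", "grade"])
    alpha = float(stats_cfg.get("alpha", 0.05))
    virads_threshold = int(stats_cfg.get("virads_threshold", 3))
    combo_members = stats_cfg.get("combination", _DEFAULT_COMBINATION)

    report: dict[str, Any] = {"provenance": _provenance(config), "endpoints": {}}

    icc = st.icc_agreement(table[["reader1_virads", "reader2_virads"]].to_numpy())
    report["reader_icc"] = {"icc": icc.icc, "band": icc.band}

    for endpoint in endpoints:
        col, pos_label = _ENDPOINT_POS[endpoint]
        labels = (table[col] == pos_label).to_numpy()
        if labels.all() or not labels.any():
            logger.warning("endpoint %s has a single class; skipped", endpoint)
            report["endpoints"][endpoint] = {"skipped": "single class"}
            continue

        comparison_rows = []
        roc_rows = []
        for marker in _marker_columns(table):
            vals = table[marker].to_numpy(dtype=float)
            ok = np.isfinite(vals)
            cmp = st.mann_whitney(vals[ok & ~labels], vals[ok & labels])
            comparison_rows.append({
                "marker": marker,
                "neg_mean": cmp.mean_a, "neg_sd": cmp.sd_a,
                "pos_mean": cmp.mean_b, "pos_sd": cmp.sd_b,
                "u": cmp.u_statistic, "p": cmp.p_value,
            })
            if cmp.p_value < alpha:
                roc = st.roc_auc(vals[ok], labels[ok])
                roc_rows.append({
                    "marker": marker, "auc": roc.auc,
                    "ci_lo": roc.ci95[0], "ci_hi": roc.ci95[1],
                    "cutoff": roc.cutoff, "sensitivity": roc.sensitivity,
                    "specificity": roc.specificity, "direction": roc.direction,
                })

        vr = st.virads_classifier(
            table["reader1_virads"].to_numpy(), labels, threshold=virads_threshold)
        combo_block = {}
        members = [m for m in combo_members if m in table.columns]
        if len(members) >= 1:
            sub = table[members].copy()
            ok = np.isfinite(sub.to_numpy(dtype=float)).all(axis=1)
            combo = st.fit_combination(sub[ok], labels[ok])
            combo_roc = st.roc_auc(combo.scores, labels[ok], direction="higher")
            combo_block["markers_only"] = {
                "members": members, "auc": combo_roc.auc,
                "ci": list(combo_roc.ci95), "separated": combo.separated,
            }
            with_vr = sub[ok].assign(virads=table.loc[ok, "reader1_virads"])
            combo_vr = st.fit_combination(with_vr, labels[ok])
            combo_vr_roc = st.roc_auc(combo_vr.scores, labels[ok], direction="higher")
            combo_block["with_virads"] = {
                "members": members + ["virads"], "auc": combo_vr_roc.auc,
                "ci": list(combo_vr_roc.ci95), "separated": combo_vr.separated,
            }

        report["endpoints"][endpoint] = {
            "n_pos": int(labels.sum()), "n_neg": int((~labels).sum()),
            "positive_label": pos_label,
            "comparison": comparison_rows,
            "roc": roc_rows,
            "virads": {"threshold": virads_threshold, "auc": vr.auc,
                       "ci": list(vr.ci95), "sensitivity": vr.sensitivity,
                       "specificity": vr.specificity},
            "combination": combo_block,
        }
        pd.DataFrame(comparison_rows).to_csv(
            outdir / f"comparison_{endpoint}.csv", index=False, float_format="%.6g")
        pd.DataFrame(roc_rows).to_csv(
            outdir / f"roc_{endpoint}.csv", index=False, float_format="%.6g")

    (outdir / "report.json").write_text(json.dumps(report, indent=1))
    (outdir / "report.txt").write_text(render_report(report))
    logger.info("analysis report written to %s", outdir)
    return report


def render_report(report: dict) -> str:
    """Human-readable rendering of a run report."""
    lines = []
    prov = report.get("provenance", {})
    lines.append("dkitex run report")
    lines.append(f"config hash {prov.get('config_hash')}  seed {prov.get('seed')}  "
                 f"version {prov.get('dkitex_version')}")
    icc = report.get("reader_icc", {})
    lines.append(f"reader VI-RADS agreement: ICC(2,1) = {icc.get('icc', float('nan')):.3f} "
                 f"({icc.get('band')})")
    for endpoint, block in report.get("endpoints", {}).items():
        lines.append("")
        lines.append(f"== endpoint: {endpoint} ==")
        if "skipped" in block:
            lines.append(f"  skipped: {block['skipped']}")
            continue
        lines.append(f"  {block['n_pos']} {block['positive_label']} vs "
                     f"{block['n_neg']} other")
        lines.append(f"  {'marker':<18}{'neg mean±SD':>16}{'pos mean±SD':>16}{'p':>10}")
        for row in block["comparison"]:
            lines.append(
                f"  {row['marker']:<18}"
                f"{row['neg_mean']:8.2f}±{row['neg_sd']:<6.2f}"
                f"{row['pos_mean']:8.2f}±{row['pos_sd']:<6.2f}"
                f"{row['p']:>10.3g}")
        lines.append(f"  {'marker':<18}{'AUC':>6}{'cutoff':>9}{'sens%':>7}{'spec%':>7}  95% CI")
        for row in block["roc"]:
            lines.append(
                f"  {row['marker']:<18}{row['auc']:6.2f}{row['cutoff']:9.2f}"
                f"{row['sensitivity']:7.1f}{row['specificity']:7.1f}  "
                f"[{row['ci_lo']:.2f}, {row['ci_hi']:.2f}]")
        vr = block["virads"]
        lines.append(f"  VI-RADS >= {vr['threshold']}: AUC {vr['auc']:.2f}, "
                     f"sens {vr['sensitivity']:.0f}%, spec {vr['specificity']:.0f}%")
        for key, cb in block.get("combination", {}).items():
            lines.append(f"  combination ({key}: {'+'.join(cb['members'])}): "
                         f"AUC {cb['auc']:.2f}")
    return "\n".join(lines) + "\n"


def run_all(config: RunConfig, outdir: str | Path) -> dict:
    """Run simulate -> fit -> features -> analyze under one output directory."""
    outdir = Path(outdir)
    manifest = run_simulate(config, outdir / "sim")
    fitdir = None
    if manifest.get("files"):
        run_fit(config, outdir / "sim", outdir / "maps")
        fitdir = outdir / "maps"
    run_features(config, outdir / "sim", fitdir, outdir / "features")
    return run_analyze(config, outdir / "features", outdir / "report")
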
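"""End-to-end orchestration: simulate -> preprocess -> annotate -> select
-> model -> glm -> mdea, with a manifest for reproducibility.

Every stage writes a diffable text artefact (TSV, JSON) into the run
directory; the manifest records the configuration, the seed, and a
checksum per output so that identical configurations yield byte-identical
runs.  The stage log records the feature funnel (peaks pooled, features
aligned, frequency-filtered, isotopologue-flagged, formula-assigned,
markers selected) for every run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .formulas import (default_building_blocks, format_formula,
                       neutral_from_ion, packaged_name_table)
from .glm import fit_ancova_many, interaction_screen
from .mdea import mdea
from .models import cross_validate
from .network import (build_network, check_assignments, propagate_formulas,
                      remove_isotopologues, annotate_names)
from .preprocess import (align_peaks, apply_calibration, estimate_calibration,
                         frequency_filter, CalibrationCurve)
from .select import build_marker_set, log2_halfmin
from .simulate import SimulationConfig, simulate_dataset

log = logging.getLogger("mdinet")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    out_dir: str = "mdinet_run"
    seed: int = 0
    # input: either simulate, or read peak lists + metadata from disk
    simulate: bool = True
    sim: SimulationConfig | None = None
    peaks_dir: str | None = None
    metadata_path: str | None = None
    # stage parameters
    tol_ppm: float = 1.0
    min_freq: float = 0.10
    calib_min_freq: float = 0.70
    calib_window_ppm: float = 3.0
    seed_fraction: float = 0.05
    k_neighbors: int = 10
    n_select: int = 40
    n_components: int = 2
    keepX: int | None = None
    n_orthogonal: int = 1
    n_folds: int = 7
    n_permutations: int = 100
    alpha: float = 0.05
    # stage toggles
    stages: tuple[str, ...] = ("preprocess", "annotate", "select", "model",
                               "glm", "mdea")

    def validate(self) -> None:
        if not 0 < self.min_freq <= 1:
            raise ValueError("min_freq must be in (0, 1]")
        if self.simulate:
            (self.sim or SimulationConfig(seed=self.seed)).validate()
        else:
            if not self.peaks_dir or not Path(self.peaks_dir).is_dir():
                raise FileNotFoundError(
                    f"peaks_dir not found: {self.peaks_dir!r} (simulation is off)")
            if not self.metadata_path or not Path(self.metadata_path).is_file():
                raise FileNotFoundError(
                    f"metadata file not found: {self.metadata_path!r} "
                    "(simulation is off)")


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    return obj


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index=True):
    df.to_csv(path, sep="\t", index=index, float_format="%.8g")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all enabled stages; return the manifest dictionary."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    counts: dict[str, int] = {}
    manifest: dict = {"version": __version__, "seed": cfg.seed}

    (out / "config.json").write_text(
        json.dumps(_to_jsonable(cfg), indent=2, sort_keys=True) + "\n")
    outputs["config"] = out / "config.json"

    stage = "input"
    try:
        gt = None
        if cfg.simulate:
            sim = cfg.sim or SimulationConfig(seed=cfg.seed)
            gt, cohort, peaks = simulate_dataset(sim)
            meta = cohort.metadata
            truth_path = out / "ground_truth.tsv"
            _write_tsv(gt.to_frame(), truth_path, index=False)
            outputs["ground_truth"] = truth_path
        else:
            peaks = {}
            for f in sorted(Path(cfg.peaks_dir).glob("*.tsv")):
                if f.name in ("metadata.tsv", "ground_truth.tsv"):
                    continue
                peaks[f.stem] = pd.read_csv(f, sep="\t")
            meta = pd.read_csv(cfg.metadata_path, sep="\t")
        counts["samples"] = len(meta)
        counts["peaks_pooled"] = int(sum(len(p) for p in peaks.values()))

        stage = "preprocess"
        # pass 1: uncalibrated alignment to obtain self-calibration references
        matrix0 = align_peaks(peaks, tol_ppm=cfg.tol_ppm, metadata=meta)
        refs = matrix0.mz[matrix0.frequency >= cfg.calib_min_freq].to_numpy()
        calibrated = {}
        calib_rows = []
        for sid, df in peaks.items():
            curve = estimate_calibration(df, refs,
                                         match_window_ppm=cfg.calib_window_ppm,
                                         on_failure="identity")
            calibrated[sid] = apply_calibration(df, curve)
            calib_rows.append({"sample_id": sid, "n_matches": curve.n_matches,
                               "residual_ppm_sd": curve.residual_ppm_sd,
                               "identity": curve.flagged_identity})
        matrix = align_peaks(calibrated, tol_ppm=cfg.tol_ppm, metadata=meta)
        counts["features_aligned"] = len(matrix.feature_ids)
        matrix = frequency_filter(matrix, cfg.min_freq)
        counts["features_after_frequency_filter"] = len(matrix.feature_ids)
        _write_tsv(pd.DataFrame(calib_rows), out / "calibration.tsv", index=False)
        _write_tsv(matrix.to_frame(), out / "feature_matrix.tsv")
        outputs["calibration"] = out / "calibration.tsv"
        outputs["feature_matrix"] = out / "feature_matrix.tsv"

        stage = "annotate"
        matrix = remove_isotopologues(matrix, tol_ppm=cfg.tol_ppm)
        iso = matrix.flags["isotopologue"]
        counts["isotopologues_flagged"] = int(iso.sum())
        keep = ~iso
        ann_matrix = matrix.subset(keep)
        neutral = neutral_from_ion(ann_matrix.mz.to_numpy())
        catalogue = default_building_blocks()
        net = build_network(list(ann_matrix.feature_ids), neutral, catalogue,
                            tol_ppm=cfg.tol_ppm)
        counts["network_edges"] = net.n_edges
        seeds = _make_seeds(cfg, gt, ann_matrix, neutral)
        assignments = propagate_formulas(net, seeds, tol_ppm=cfg.tol_ppm)
        counts["formulas_assigned"] = sum(a.assigned for a in assignments)
        counts["noise_flagged"] = sum(a.is_noise for a in assignments)
        check = check_assignments(assignments, dict(zip(ann_matrix.feature_ids,
                                                        neutral)), net,
                                  tol_ppm=cfg.tol_ppm)
        names = annotate_names(assignments, packaged_name_table())
        ass_df = pd.DataFrame(
            [{"feature_id": a.feature_id,
              "formula": format_formula(a.formula) if a.assigned else "",
              "error_ppm": a.error_ppm, "provenance": a.provenance,
              "noise": a.is_noise} for a in assignments]).set_index("feature_id")
        ass_df["names"] = names.set_index("feature_id")["names"]
        _write_tsv(ass_df, out / "assignments.tsv")
        _write_tsv(net.edge_table(), out / "network_edges.tsv", index=False)
        _write_tsv(check, out / "assignment_check.tsv", index=False)
        outputs["assignments"] = out / "assignments.tsv"
        outputs["network_edges"] = out / "network_edges.tsv"
        outputs["assignment_check"] = out / "assignment_check.tsv"

        stage = "select"
        X = log2_halfmin(ann_matrix.intensities.to_numpy().T)
        y = meta.set_index("sample_id").loc[ann_matrix.sample_ids, "group"].to_numpy()
        fmap = {a.feature_id: format_formula(a.formula)
                for a in assignments if a.assigned}
        markers = build_marker_set(X, y, list(ann_matrix.feature_ids),
                                   ann_matrix.mz.to_numpy(),
                                   n_select=min(cfg.n_select, X.shape[1]),
                                   k_neighbors=cfg.k_neighbors, seed=cfg.seed,
                                   formulas=fmap)
        counts["markers_selected"] = len(markers)
        counts["markers_up"] = int((markers.table["direction"] == "up").sum())
        counts["markers_down"] = int((markers.table["direction"] == "down").sum())
        _write_tsv(markers.table, out / "markers.tsv")
        outputs["markers"] = out / "markers.tsv"

        marker_cols = [list(ann_matrix.feature_ids).index(f)
                       for f in markers.feature_ids]
        Xm = X[:, marker_cols]

        stage = "model"
        reports = {}
        for kind, spec in (("splsda", {"kind": "splsda",
                                       "n_components": cfg.n_components,
                                       "keepX": cfg.keepX}),
                           ("oplsda", {"kind": "oplsda",
                                       "n_orthogonal": cfg.n_orthogonal})):
            rep = cross_validate(spec, Xm, y, n_folds=cfg.n_folds, seed=cfg.seed,
                                 n_permutations=cfg.n_permutations)
            reports[kind] = {"r2y": rep.r2y, "q2": rep.q2, "auc": rep.auc,
                             "ber": {str(k): v for k, v in rep.ber.items()},
                             "permutation_p": rep.permutation_p}
        (out / "model_report.json").write_text(
            json.dumps(_to_jsonable(reports), indent=2, sort_keys=True) + "\n")
        outputs["model_report"] = out / "model_report.json"

        stage = "glm"
        ages = meta.set_index("sample_id").loc[ann_matrix.sample_ids, "age"].to_numpy()
        sexes = meta.set_index("sample_id").loc[ann_matrix.sample_ids, "sex"].to_numpy()
        glm_res = fit_ancova_many(Xm, markers.feature_ids, y, ages, sexes)
        glm_res = interaction_screen(glm_res, alpha=cfg.alpha)
        glm_res.insert(0, "formula", [fmap.get(f, "") for f in glm_res.index])
        _write_tsv(glm_res, out / "glm_results.tsv")
        outputs["glm_results"] = out / "glm_results.tsv"

        stage = "mdea"
        enr = mdea(net, set(markers.feature_ids), catalogue)
        _write_tsv(enr, out / "mdea.tsv", index=False)
        outputs["mdea"] = out / "mdea.tsv"
        try:
            _plot_mdea(enr, out / "mdea_z.svg")
            outputs["mdea_plot"] = out / "mdea_z.svg"
        except Exception as exc:  # plotting must never fail a run
            log.warning("MDEA plot skipped: %s", exc)

    except Exception as exc:
        manifest.update({"status": "failed", "failed_stage": stage,
                         "error": str(exc), "counts": counts,
                         "outputs": {k: str(v) for k, v in outputs.items()}})
        (out / "manifest.json").write_text(
            json.dumps(_to_jsonable(manifest), indent=2, sort_keys=True) + "\n")
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    for name, c in counts.items():
        log.info("%s = %d", name, c)
    manifest.update({
        "status": "ok",
        "counts": counts,
        "parameter_hash": hashlib.sha256(
            (out / "config.json").read_bytes()).hexdigest()[:16],
        "outputs": {k: {"path": str(v), "sha256": _checksum(v)}
                    for k, v in outputs.items()},
    })
    (out / "manifest.json").write_text(
        json.dumps(_to_jsonable(manifest), indent=2, sort_keys=True) + "\n")
    return manifest


def _make_seeds(cfg: PipelineConfig, gt, matrix, neutral_masses):
    """Seed annotations for formula propagation.

    Simulated runs emulate "known peaks" by revealing the true formula of
    a deterministic fraction of ground-truth metabolites; runs on real
    peak lists match features against the packaged reference-compound
    table within 0.2 ppm.
    """
    from .formulas import monoisotopic_mass, parse_formula
    ids = list(matrix.feature_ids)
    seeds = {}
    if gt is not None:
        rng = np.random.default_rng(cfg.seed + 7)
        n_seed = max(1, int(round(cfg.seed_fraction * gt.n)))
        pick = rng.choice(gt.n, size=n_seed, replace=False)
        for k in pick:
            m = gt.neutral_masses[k]
            j = int(np.argmin(np.abs(neutral_masses - m)))
            if abs(neutral_masses[j] - m) / m * 1e6 <= 0.5:
                seeds[ids[j]] = gt.formulas[k]
    else:
        table = packaged_name_table()
        ref = {f: monoisotopic_mass(parse_formula(f)) for f in table}
        for f, m in ref.items():
            j = int(np.argmin(np.abs(neutral_masses - m)))
            if abs(neutral_masses[j] - m) / m * 1e6 <= 0.2:
                seeds[ids[j]] = parse_formula(f)
    return seeds


def _plot_mdea(enr: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    plt.rcParams["svg.hashsalt"] = "mdinet"   # deterministic SVG output
    fig, ax = plt.subplots(figsize=(6, 3.5))
    sub = enr[enr.a + enr.b > 0]
    ax.bar(sub["block"], sub["z"], color="#446688")
    ax.axhline(2.0, ls="--", lw=0.8, color="0.4")
    ax.set_ylabel("enrichment Z-score")
    ax.set_xlabel("building block")
    ax.tick_params(axis="x", rotation=60)
    fig.tight_layout()
    fig.savefig(path, metadata={"Date": None})
    plt.close(fig)
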
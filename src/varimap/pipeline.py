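"""End-to-end pipeline orchestration with config validation and manifests.

Stages run in method order: simulate (optional) -> qc -> factorize
(normalize, HVG, scale, PCA, varimax) -> interpret (cluster matching, RF
covariate importance, technical screen) -> score (signatures + group
tests) -> zonate (optional spatial arm). Every stage writes its
artifacts under the run directory and a manifest records the config,
seeds and sha256 of each written file, so two runs with the same config
and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import factor as fc
from . import interpret as it
from . import qc as qcmod
from . import signatures as sg
from . import simulate as sim
from . import zonation as zn
from .containers import CountMatrix, NormalizedMatrix, ValidationError

__all__ = ["RunConfig", "validate_config", "run_pipeline", "StageError", "STAGES"]

logger = logging.getLogger("varimap")

STAGES = ["simulate", "qc", "factorize", "interpret", "score", "zonate"]

_DEFAULTS = {
    "seed": 0,
    "covariate": "strain",
    "normalization": {"scale": 10000.0},
    "hvg_n": 2000,
    "K_pca": 15,
    "K_varimax": 30,
    "kaiser": True,
    "rf": {"trees": 500, "split_ratio": "3:1"},
    "signature": {"n": 10, "r_max": 1500},
    "qc": {"mito_pattern": qcmod.MITO_PATTERN},
}

_KNOWN_KEYS = {
    "seed",
    "outdir",
    "covariate",
    "simulate",
    "samples",
    "qc",
    "normalization",
    "hvg_n",
    "K_pca",
    "K_varimax",
    "kaiser",
    "rf",
    "signature",
    "zonation",
}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and last good artifact."""

    def __init__(self, stage: str, last_good: str | None, cause: Exception):
        self.stage = stage
        self.last_good = last_good
        super().__init__(
            f"stage {stage!r} failed ({cause}); last good artifact: {last_good}"
        )


@dataclass
class RunConfig:
    """Validated, default-filled run configuration."""

    raw: dict
    seed: int
    covariate: str
    scale: float
    hvg_n: int
    K_pca: int
    K_varimax: int
    kaiser: bool
    rf_trees: int
    rf_train_fraction: float
    signature_n: int
    r_max: int
    mito_pattern: str
    thresholds: qcmod.QCThresholds
    simulate: dict | None
    samples: dict | None
    zonation: dict | None
    outdir: str | None = None


def _parse_split_ratio(value) -> float:
    if isinstance(value, (int, float)):
        frac = float(value)
    else:
        try:
            a, b = str(value).split(":")
            a, b = float(a), float(b)
        except Exception as exc:
            raise ValidationError(f"split_ratio {value!r} does not parse as a:b") from exc
        if a <= 0 or b <= 0:
            raise ValidationError("split_ratio parts must be positive")
        frac = a / (a + b)
    if not (0 < frac < 1):
        raise ValidationError(f"split_ratio {value!r} gives train fraction {frac}")
    return frac


def validate_config(path_or_dict) -> RunConfig:
    """Parse and validate a JSON/YAML run config, filling defaults.

    Unknown top-level keys are an error (no silent ignore); errors are
    aggregated so one pass reports every problem.
    """
    if isinstance(path_or_dict, dict):
        raw = dict(path_or_dict)
    else:
        text = Path(path_or_dict).read_text()
        raw = yaml.safe_load(text)  # YAML is a superset of JSON
        if not isinstance(raw, dict):
            raise ValidationError("config must be a mapping")

    errors: list[str] = []
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        errors.append(f"unknown config keys: {sorted(unknown)}")

    def get(key, default):
        v = raw.get(key, default)
        return v if v is not None else default

    seed = get("seed", _DEFAULTS["seed"])
    if not isinstance(seed, int):
        errors.append("seed must be an integer")

    norm = {**_DEFAULTS["normalization"], **get("normalization", {})}
    scale = float(norm.get("scale", 10000.0))
    if scale <= 0:
        errors.append("normalization scale must be positive")

    qc_cfg = {**_DEFAULTS["qc"], **get("qc", {})}
    min_lib = {str(k): float(v) for k, v in qc_cfg.get("min_library_size", {}).items()}
    max_mito = {str(k): float(v) for k, v in qc_cfg.get("max_mito_percent", {}).items()}
    for s, v in max_mito.items():
        if not (0 < v <= 100):
            errors.append(f"max_mito_percent for {s!r} out of range (0, 100]: {v}")
    for s, v in min_lib.items():
        if v < 0:
            errors.append(f"min_library_size for {s!r} negative: {v}")

    rf_cfg = {**_DEFAULTS["rf"], **get("rf", {})}
    try:
        train_frac = _parse_split_ratio(rf_cfg.get("split_ratio", "3:1"))
    except ValidationError as exc:
        errors.append(str(exc))
        train_frac = 0.75

    sig_cfg = {**_DEFAULTS["signature"], **get("signature", {})}
    samples = raw.get("samples")
    simulate_cfg = raw.get("simulate")
    if samples is None and simulate_cfg is None:
        errors.append("config needs either 'samples' (input paths) or 'simulate'")
    if samples is not None:
        for sid, paths in samples.items():
            for key in ("matrix_dir",):
                if key not in paths:
                    errors.append(f"samples[{sid!r}] lacks {key!r}")
                elif not Path(paths[key]).exists():
                    errors.append(f"samples[{sid!r}].{key} does not exist: {paths[key]}")
        for sid in samples:
            if str(sid) not in min_lib or str(sid) not in max_mito:
                errors.append(f"QC thresholds missing for sample {sid!r}")

    if errors:
        raise ValidationError("; ".join(errors))

    return RunConfig(
        raw=raw,
        seed=int(seed),
        covariate=str(get("covariate", "strain")),
        scale=scale,
        hvg_n=int(get("hvg_n", _DEFAULTS["hvg_n"])),
        K_pca=int(get("K_pca", _DEFAULTS["K_pca"])),
        K_varimax=int(get("K_varimax", _DEFAULTS["K_varimax"])),
        kaiser=bool(get("kaiser", _DEFAULTS["kaiser"])),
        rf_trees=int(rf_cfg.get("trees", 500)),
        rf_train_fraction=train_frac,
        signature_n=int(sig_cfg.get("n", 10)),
        r_max=int(sig_cfg.get("r_max", 1500)),
        mito_pattern=str(qc_cfg.get("mito_pattern", qcmod.MITO_PATTERN)),
        thresholds=qcmod.QCThresholds(min_lib, max_mito),
        simulate=simulate_cfg,
        samples=samples,
        zonation=raw.get("zonation"),
        outdir=raw.get("outdir"),
    )


# ---------------------------------------------------------------------------
# artifact I/O helpers


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _save_scaled(scaled: NormalizedMatrix, path: Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=scaled.values, compression="gzip")
        f.create_dataset(
            "gene_ids", data=np.array(scaled.gene_ids, dtype=h5py.string_dtype())
        )
        f.create_dataset(
            "cell_ids", data=np.array(scaled.cell_ids, dtype=h5py.string_dtype())
        )
        f.attrs["provenance"] = json.dumps(scaled.provenance)


def _load_scaled(path: Path) -> NormalizedMatrix:
    with h5py.File(path, "r") as f:
        return NormalizedMatrix(
            f["values"][:],
            [g.decode() for g in f["gene_ids"][:]],
            [c.decode() for c in f["cell_ids"][:]],
            json.loads(f.attrs["provenance"]),
        )


def _smd(scores: np.ndarray, labels: np.ndarray) -> float:
    """Standardized mean difference of scores between the two label groups."""
    names = sorted(set(labels))
    a, b = scores[labels == names[0]], scores[labels == names[1]]
    pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
    return float((a.mean() - b.mean()) / pooled) if pooled > 0 else 0.0


# ---------------------------------------------------------------------------
# the run


@dataclass
class PipelineRun:
    config: RunConfig
    outdir: Path
    manifest: dict = field(default_factory=dict)

    counts: CountMatrix | None = None
    meta: pd.DataFrame | None = None
    truth: sim.SyntheticTruth | None = None
    norm_all: NormalizedMatrix | None = None
    scaled: NormalizedMatrix | None = None
    model: fc.FactorModel | None = None
    importance: it.ImportanceReport | None = None
    match: it.FactorMatch | None = None
    summary: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self._files: list[Path] = []
        self.manifest = {
            "seed": self.config.seed,
            "config": self.config.raw,
            "stages": [],
            "files": {},
        }

    def _record(self, path: Path) -> None:
        self._files.append(path)

    # -- stages -------------------------------------------------------------

    def stage_simulate(self) -> None:
        cfg = self.config.simulate or {}
        sim_config = sim.default_config(
            seed=self.config.seed,
            n_cells_per_sample=int(cfg.get("n_cells_per_sample", 1000)),
            n_genes=int(cfg.get("n_genes", 1200)),
            with_zonation=True,
        )
        self.counts, self.meta, self.truth = sim.simulate_cells(sim_config)
        self._sim_config = sim_config
        d = self.outdir / "simulated"
        sim.write_10x_mtx(self.counts, d)
        self.meta.to_csv(d / "cell_meta.tsv", sep="\t")
        truth_path = d / "truth.json"
        truth_path.write_text(
            json.dumps(
                {
                    "program_gene_sets": self.truth.program_gene_sets,
                    "planted_factor_specs": self.truth.planted_factor_specs,
                    "mito_genes": self.truth.mito_genes,
                },
                indent=2,
            )
        )
        for p in (d / "matrix.mtx", d / "cell_meta.tsv", truth_path):
            self._record(p)
        # synthetic runs get permissive thresholds unless configured
        if not self.config.thresholds.min_library_size:
            sids = [s.sample_id for s in sim_config.samples]
            self.config.thresholds = qcmod.QCThresholds(
                {s: 500.0 for s in sids}, {s: 40.0 for s in sids}
            )
        logger.info(
            "simulate: %d genes x %d cells", self.counts.n_genes, self.counts.n_cells
        )

    def _load_inputs(self) -> None:
        parts, metas = [], []
        for sid, paths in self.config.samples.items():
            cm = qcmod.read_10x_mtx(paths["matrix_dir"])
            m = (
                pd.read_csv(paths["meta_tsv"], sep="\t", index_col=0)
                if "meta_tsv" in paths
                else pd.DataFrame(index=cm.cell_ids)
            )
            m["sample_id"] = str(sid)
            parts.append(cm)
            metas.append(m)
        genes = parts[0].gene_ids
        for cm in parts[1:]:
            if cm.gene_ids != genes:
                raise ValidationError("samples have mismatched gene universes")
        import scipy.sparse as sp

        self.counts = CountMatrix(
            sp.hstack([cm.X for cm in parts]),
            genes,
            [c for cm in parts for c in cm.cell_ids],
        )
        self.meta = pd.concat(metas)

    def stage_qc(self) -> None:
        if self.counts is None:
            self._load_inputs()
        qc_stats = qcmod.compute_cell_qc(self.counts, self.config.mito_pattern)
        meta = self.meta.join(qc_stats)
        self.counts, self.meta = qcmod.filter_cells(
            self.counts, meta, self.config.thresholds
        )
        report = (
            self.meta.groupby("sample_id")
            .agg(
                n_cells=("library_size", "size"),
                median_library=("library_size", "median"),
                median_genes=("n_genes_expressed", "median"),
                mean_mito=("mito_fraction", "mean"),
            )
        )
        path = self.outdir / "qc_report.tsv"
        report.to_csv(path, sep="\t")
        self.meta.to_csv(self.outdir / "cell_meta_qc.tsv", sep="\t")
        self._record(path)
        self._record(self.outdir / "cell_meta_qc.tsv")
        self.summary["n_cells_after_qc"] = int(self.counts.n_cells)
        logger.info("qc: retained %d cells", self.counts.n_cells)

    def stage_factorize(self) -> None:
        self.norm_all = qcmod.normalize_log(self.counts, self.config.scale)
        hvgs = qcmod.select_hvgs(self.norm_all, min(self.config.hvg_n, self.norm_all.n_genes))
        scaled = qcmod.scale_genes(self.norm_all.subset_genes(hvgs))
        self.scaled = scaled
        _save_scaled(scaled, self.outdir / "scaled_hvg.h5")
        self._record(self.outdir / "scaled_hvg.h5")

        K = min(self.config.K_varimax, min(scaled.n_genes, scaled.n_cells))
        pca = fc.fit_pca(scaled, K)
        self.model = fc.varimax_rotate(pca, kaiser=self.config.kaiser)
        fc.save_factor_model(pca, self.outdir / "pca")
        fc.save_factor_model(self.model, self.outdir / "varimax")
        for p in ("loadings.tsv", "scores.tsv", "rotation.tsv", "meta.json"):
            self._record(self.outdir / "varimax" / p)
        logger.info(
            "factorize: %d HVGs, K=%d, varimax converged=%s",
            len(hvgs),
            K,
            self.model.converged,
        )

    def stage_interpret(self) -> None:
        labels = self.meta["cluster"]
        norm_hvg = self.norm_all.subset_genes(self.scaled.gene_ids)
        profiles = it.cluster_mean_profiles(norm_hvg, labels)
        for cluster in profiles.means.columns:
            de = it.de_wilcoxon(norm_hvg, labels, cluster)
            ranked = it.rank_de_genes(de)
            profiles.top_de[cluster] = list(ranked["gene"])
            ranked.head(200).to_csv(
                self.outdir / f"de_{cluster}.tsv", sep="\t", index=False
            )
        self.profiles = profiles
        self.match = it.factor_cluster_correlation(profiles, self.model)
        self.match.correlation.to_csv(self.outdir / "factor_cluster_correlation.tsv", sep="\t")
        self._record(self.outdir / "factor_cluster_correlation.tsv")

        cov = self.meta[self.config.covariate]
        self.importance = it.covariate_factor_importance(
            self.model,
            cov,
            split_ratio=self.config.rf_train_fraction,
            seed=self.config.seed,
            n_trees=self.config.rf_trees,
        )
        imp = self.importance.importance.sort_values(ascending=False)
        imp.rename("mean_decrease_gini").to_csv(self.outdir / "factor_importance.tsv", sep="\t")
        self._record(self.outdir / "factor_importance.tsv")

        tech = it.technical_covariate_check(self.model, self.meta)
        tech.to_csv(self.outdir / "technical_screen.tsv", sep="\t")
        self._record(self.outdir / "technical_screen.tsv")

        cov_vals = cov.to_numpy()
        fac_names = self.model.factor_names()
        smd_global = {
            name: _smd(self.model.scores[:, k], cov_vals)
            for k, name in enumerate(fac_names)
        }
        # the paper's two-factor structure: among all factors, the global
        # covariate factor maximizes |SMD| over all cells; the restricted
        # one maximizes the per-cluster |SMD| excess over its global |SMD|
        global_factor = max(smd_global, key=lambda n: abs(smd_global[n]))
        clusters = list(profiles.means.columns)
        restricted_factor, restricted_cluster, best_excess = None, None, 0.0
        for k, name in enumerate(fac_names):
            if name == global_factor:
                continue
            for cl in clusters:
                mask = (labels == cl).to_numpy()
                if mask.sum() < 4 or len(set(cov_vals[mask])) < 2:
                    continue
                excess = abs(_smd(self.model.scores[mask, k], cov_vals[mask])) - abs(
                    smd_global[name]
                )
                if excess > best_excess:
                    restricted_factor, restricted_cluster, best_excess = name, cl, excess
        localization = None
        if restricted_factor is not None:
            corr50 = it.factor_cluster_correlation(profiles, self.model, top_n=50)
            localization = str(corr50.correlation[restricted_factor].abs().idxmax())
        self.summary.update(
            {
                "top_importance_factors": list(imp.index[:2]),
                "rf_accuracy": self.importance.accuracy,
                "rf_sensitivity": self.importance.sensitivity,
                "rf_specificity": self.importance.specificity,
                "global_smd": smd_global,
                "global_strain_factor": global_factor,
                "restricted_strain_factor": restricted_factor,
                "restricted_strain_cluster": restricted_cluster,
                "restricted_factor_localized_to": localization,
                "best_factor_per_cluster": self.match.best_factor.to_dict(),
            }
        )
        logger.info(
            "interpret: top covariate factors %s (accuracy %.4f)",
            self.summary["top_importance_factors"],
            self.importance.accuracy,
        )

    def stage_score(self) -> None:
        fac_names = self.model.factor_names()
        targets = [self.summary["global_strain_factor"]]
        restricted = self.summary.get("restricted_strain_factor")
        if restricted and restricted not in targets:
            targets.append(restricted)
        reports = {}
        for name in targets:
            k = fac_names.index(name)
            sig = sg.extract_signature(self.model, k, self.config.signature_n)
            sg.write_gmt(sig, self.outdir / f"signature_{name}.gmt")
            scores = sg.bipolar_score(
                self.norm_all, sig, min(self.config.r_max, self.norm_all.n_genes - 1)
            )
            scores.rename("bipolar_score").to_csv(
                self.outdir / f"signature_scores_{name}.tsv", sep="\t"
            )
            fc.export_rnk(self.model, k, self.outdir / f"{name}.rnk")
            reports[name] = sg.compare_groups(
                scores, self.meta[self.config.covariate]
            )
            if name == restricted and self.summary.get("restricted_strain_cluster"):
                reports[f"{name}_within_cluster"] = sg.compare_groups(
                    scores,
                    self.meta[self.config.covariate],
                    within=self.meta["cluster"],
                    restrict_to=self.summary["restricted_strain_cluster"],
                )
        path = self.outdir / "signature_reports.json"
        path.write_text(json.dumps(reports, indent=2))
        self._record(path)
        self.summary["signature_reports"] = reports
        logger.info("score: signature group tests written for %s", targets)

    def stage_zonate(self) -> None:
        if self.config.simulate is not None:
            cfg = self.config.simulate or {}
            sim_config = sim.default_config(
                seed=self.config.seed,
                n_cells_per_sample=int(cfg.get("n_cells_per_sample", 1000)),
                n_genes=int(cfg.get("n_genes", 1200)),
                with_zonation=True,
            )
            spots, truth = sim.simulate_spots(sim_config)
            pp = [g for g, d in truth.zonated_gene_directions.items() if d == "periportal"]
            pc = [g for g, d in truth.zonated_gene_directions.items() if d == "pericentral"]
            markers = zn.MarkerSets(pp[:10], pc[:10])
            layer = pd.Series(truth.spot_layer_of_spot, index=spots.counts.cell_ids)
        else:
            zcfg = self.config.zonation or {}
            if "matrix_dir" not in zcfg:
                logger.info("zonate: no spatial input configured; skipping")
                return
            cm = qcmod.read_10x_mtx(zcfg["matrix_dir"])
            pos = pd.read_csv(zcfg["positions_tsv"], sep="\t", index_col=0)
            spots = sim.SpatialDataset(cm, pos)
            mk = pd.read_csv(zcfg["markers_tsv"], sep="\t")
            markers = zn.MarkerSets(
                list(mk.iloc[:, 0].dropna()), list(mk.iloc[:, 1].dropna())
            )
            layer = pos["layer"] if "layer" in pos.columns else None

        spots, _removed = qcmod.spatial_gene_filter(spots)
        model = zn.fit_spatial_pca(spots, K=min(5, spots.n_spots - 1))
        axis = zn.identify_zonation_axis(model, markers)
        scores = zn.zonation_score(spots, axis, model)
        scores.rename("zonation_score").to_csv(self.outdir / "zonation_scores.tsv", sep="\t")
        self._record(self.outdir / "zonation_scores.tsv")
        out = {
            "factor": axis.factor + 1,
            "sign": axis.sign,
            "periportal_p": axis.periportal_p,
            "pericentral_p": axis.pericentral_p,
        }
        if layer is not None:
            import scipy.stats

            rho = scipy.stats.spearmanr(layer.to_numpy(), scores.to_numpy()).statistic
            out["spearman_vs_layer"] = float(rho)
        (self.outdir / "zonation_axis.json").write_text(json.dumps(out, indent=2))
        self._record(self.outdir / "zonation_axis.json")
        self.summary["zonation"] = out
        logger.info("zonate: axis factor %d sign %+d", axis.factor + 1, axis.sign)

    # -- driver -------------------------------------------------------------

    def run(self, stages: list[str] | None = None) -> Path:
        todo = stages or STAGES
        last_good: str | None = None
        for stage in STAGES:
            if stage not in todo:
                continue
            if stage == "simulate" and self.config.simulate is None:
                continue
            if stage == "zonate" and self.config.simulate is None and self.config.zonation is None:
                continue
            try:
                getattr(self, f"stage_{stage}")()
            except Exception as exc:  # noqa: BLE001 - abort with context
                raise StageError(stage, last_good, exc) from exc
            self.manifest["stages"].append(stage)
            if self._files:
                last_good = str(self._files[-1])
        self.finalize()
        return self.outdir

    def finalize(self) -> None:
        summary_path = self.outdir / "summary.json"
        summary_path.write_text(json.dumps(self.summary, indent=2, default=str))
        self._record(summary_path)
        for p in self._files:
            if p.exists():
                self.manifest["files"][str(p.relative_to(self.outdir))] = _sha256(p)
        (self.outdir / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, default=str)
        )


def run_pipeline(
    config: RunConfig | dict | str | Path,
    outdir: str | Path | None = None,
    stages: list[str] | None = None,
) -> PipelineRun:
    """Validate the config, execute the requested stages, return the run."""
    if not isinstance(config, RunConfig):
        config = validate_config(config)
    outdir = Path(outdir or config.outdir or "varimap_run")
    if not logging.getLogger("varimap").handlers:
        logging.basicConfig(stream=sys.stderr, level=logging.INFO)
    fh = logging.FileHandler(outdir / "run.log") if outdir.exists() else None
    if fh is None:
        outdir.mkdir(parents=True, exist_ok=True)
        fh = logging.FileHandler(outdir / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)
    try:
        run = PipelineRun(config, outdir)
        run.run(stages)
    finally:
        logger.removeHandler(fh)
        fh.close()
    return run
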
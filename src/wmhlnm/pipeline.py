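"""End-to-end orchestration: simulate -> lnm -> predict -> infer.

Each stage consumes only the on-disk artifacts of prior stages, so a run
directory is a self-contained, re-runnable record. All tabular outputs are
TSV with a header row plus a sidecar JSON schema; volumes are NIfTI; the
functional connectome is a compressed ``.npz``. Stage seeds are derived
from the master seed by stable hashing of the stage name, so the whole run
is byte-reproducible and stages are independently seeded.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .imaging import (
    BinaryMask,
    Parcellation,
    Volume3D,
    read_mask,
    read_roi_table,
    read_volume,
    write_roi_table,
    write_volume,
)
from .inference import (
    network_average_betas,
    permutation_glm_fwe,
    spin_permutation_test,
    tract_level_report,
)
from .lnm import (
    LNMScoreMatrix,
    THRESHOLD_FRACTIONS,
    build_lnm_matrix,
    functional_seed_maps,
    structural_seed_maps,
    volumetric_features,
)
from .prediction import (
    ALPHA_GRID,
    FEATURE_SETS,
    added_performance_ratio,
    assemble_features,
    learning_curve,
    nested_ridge_cv,
    pairwise_comparisons,
)
from .synthetic import (
    COGNITIVE_DOMAINS,
    DomainEffect,
    EffectSpec,
    FunctionalConnectome,
    PatientTable,
    ToyBrainConfig,
    _stage_seed,
    brain_mask,
    simulate_demographics,
    simulate_cognition,
    simulate_functional_connectome,
    simulate_structural_streamline_map,
    simulate_wmh_masks,
)


class PipelineError(RuntimeError):
    """A stage failed; the message is tagged with the stage name."""


# ---------------------------------------------------------------------------
# configuration


@dataclass
class CohortOptions:
    n_patients: int = 200
    n_subjects: int = 20
    n_timepoints: int = 100
    within_network_corr: float = 0.6
    volume_lognorm_mu: float = float(np.log(60.0))
    volume_lognorm_sigma: float = 0.7
    periventricular_bias: float = 0.7
    streamline_density: float = 40.0
    streamline_decay: float = 1.5
    missing_rate: float = 0.0


@dataclass
class LNMOptions:
    polarity: str = "positive"
    threshold_fraction: float = 1.0
    penumbra_mm: float | None = None
    penumbra_only: bool = False
    hemisphere: str | None = None

    def __post_init__(self):
        if self.threshold_fraction not in THRESHOLD_FRACTIONS:
            raise ValueError(
                f"threshold_fraction must be one of {THRESHOLD_FRACTIONS}"
            )
        if self.polarity not in ("positive", "negative"):
            raise ValueError("polarity must be 'positive' or 'negative'")


@dataclass
class PredictionOptions:
    domains: tuple[str, ...] = COGNITIVE_DOMAINS
    feature_sets: tuple[str, ...] = FEATURE_SETS
    k_outer: int = 10
    k_inner: int = 5
    repeats: int = 10
    alphas: tuple[float, ...] = ALPHA_GRID
    n_bins: int = 10
    learning_fractions: tuple[float, ...] | None = None

    def __post_init__(self):
        unknown = set(self.feature_sets) - set(FEATURE_SETS)
        if unknown:
            raise ValueError(f"unknown feature sets: {unknown}")


@dataclass
class InferenceOptions:
    domains: tuple[str, ...] = COGNITIVE_DOMAINS
    modalities: tuple[str, ...] = ("fLNM", "sLNM")
    n_perm: int = 1000
    n_spins: int = 1000


@dataclass
class RunConfig:
    """One plain-text config drives the whole pipeline."""

    seed: int = 0
    toy_brain: ToyBrainConfig = field(default_factory=ToyBrainConfig)
    cohort: CohortOptions = field(default_factory=CohortOptions)
    effects: EffectSpec = field(default_factory=EffectSpec.default)
    lnm: LNMOptions = field(default_factory=LNMOptions)
    prediction: PredictionOptions = field(default_factory=PredictionOptions)
    inference: InferenceOptions = field(default_factory=InferenceOptions)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["effects"] = {k: asdict(v) for k, v in self.effects.domains.items()}
        return d

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")

        def _sub(klass, value):
            if value is None:
                return klass()
            fields = {f.name for f in dataclasses.fields(klass)}
            bad = set(value) - fields
            if bad:
                raise ValueError(f"unknown {klass.__name__} keys: {sorted(bad)}")
            value = {
                k: tuple(v) if isinstance(v, list) else v for k, v in value.items()
            }
            return klass(**value)

        effects_raw = raw.pop("effects", None)
        if effects_raw is None:
            effects = EffectSpec.default()
        else:
            effects = EffectSpec(
                {
                    dom: _sub(DomainEffect, spec)
                    for dom, spec in effects_raw.items()
                }
            )
        return cls(
            seed=int(raw.get("seed", 0)),
            toy_brain=_sub(ToyBrainConfig, raw.get("toy_brain")),
            cohort=_sub(CohortOptions, raw.get("cohort")),
            effects=effects,
            lnm=_sub(LNMOptions, raw.get("lnm")),
            prediction=_sub(PredictionOptions, raw.get("prediction")),
            inference=_sub(InferenceOptions, raw.get("inference")),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(self.to_dict()), fh, sort_keys=True)

    def config_hash(self) -> str:
        canon = json.dumps(_plain(self.to_dict()), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


@dataclass
class RunReport:
    config_hash: str
    seed: int
    version: str
    stages: dict = field(default_factory=dict)  # stage -> {files, seconds}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "RunReport":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


# ---------------------------------------------------------------------------
# artifact layout


def _paths(outdir: Path) -> dict[str, Path]:
    return {
        "simulate": outdir / "simulate",
        "lnm": outdir / "lnm",
        "predict": outdir / "predict",
        "infer": outdir / "infer",
    }


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)
    schema = {
        "columns": [
            {"name": str(c), "dtype": str(df[c].dtype)} for c in df.columns
        ]
    }
    path.with_suffix(path.suffix + ".schema.json").write_text(json.dumps(schema, indent=2))


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: RunConfig, outdir: Path) -> list[str]:
    d = _paths(outdir)["simulate"]
    (d / "tracts").mkdir(parents=True, exist_ok=True)
    (d / "masks").mkdir(exist_ok=True)
    (d / "structural").mkdir(exist_ok=True)
    co = cfg.cohort
    from .synthetic import make_toy_brain

    parc = make_toy_brain(cfg.toy_brain, _stage_seed(cfg.seed, "brain"))
    fc = simulate_functional_connectome(
        parc, S=co.n_subjects, T=co.n_timepoints,
        within_network_corr=co.within_network_corr,
        seed=_stage_seed(cfg.seed, "functional"),
    )
    struct = simulate_structural_streamline_map(
        parc, density=co.streamline_density, decay=co.streamline_decay,
        seed=_stage_seed(cfg.seed, "structural"),
    )
    masks = simulate_wmh_masks(
        parc, co.n_patients,
        volume_lognorm_params=(co.volume_lognorm_mu, co.volume_lognorm_sigma),
        periventricular_bias=co.periventricular_bias,
        seed=_stage_seed(cfg.seed, "lesions"),
    )
    demo = simulate_demographics(co.n_patients, seed=_stage_seed(cfg.seed, "demographics"))

    # cognition needs LNM scores of the generative (untresholded) kind
    fmaps = functional_seed_maps(parc, fc)
    smaps = structural_seed_maps(parc, struct)
    flnm = build_lnm_matrix(masks, fmaps)
    slnm = build_lnm_matrix(masks, smaps)
    patients = simulate_cognition(
        PatientTable(demo, masks), {"fLNM": flnm, "sLNM": slnm}, parc, cfg.effects,
        seed=_stage_seed(cfg.seed, "cognition"), missing_rate=co.missing_rate,
    )

    write_volume(parc.label_volume, d / "parcellation.nii.gz")
    write_roi_table(parc, d / "roi_table.tsv")
    for tid, tm in parc.tract_masks.items():
        write_volume(tm, d / "tracts" / f"tract_{tid}.nii.gz")
    if parc.tract_endpoints:
        (d / "tract_endpoints.json").write_text(
            json.dumps({str(k): list(v) for k, v in parc.tract_endpoints.items()})
        )
    np.savez_compressed(
        d / "functional_connectome.npz",
        series=fc.series,
        brain_indices=fc.brain_indices,
        voxel_network=fc.voxel_network,
    )
    for rid, vol in struct.items():
        write_volume(vol, d / "structural" / f"roi_{rid}.nii.gz")
    for i, m in enumerate(masks):
        write_volume(m, d / "masks" / f"patient_{i:04d}.nii.gz")
    patients.to_tsv(d / "patients.tsv")
    truth = {
        "seed": cfg.seed,
        "effects": {k: asdict(v) for k, v in cfg.effects.domains.items()},
    }
    (d / "truth.json").write_text(json.dumps(_plain(truth), indent=2))
    return sorted(str(p.relative_to(outdir)) for p in d.rglob("*") if p.is_file())


def _load_parcellation(d: Path) -> Parcellation:
    label = read_volume(d / "parcellation.nii.gz")
    table = read_roi_table(d / "roi_table.tsv")
    tracts = {}
    for p in sorted((d / "tracts").glob("tract_*.nii.gz")):
        rid = int(p.name.split("_")[1].split(".")[0])
        tracts[rid] = read_mask(p)
    endpoints = None
    ep_path = d / "tract_endpoints.json"
    if ep_path.exists():
        endpoints = {
            int(k): tuple(v) for k, v in json.loads(ep_path.read_text()).items()
        }
    return Parcellation(label, table, tracts, endpoints)


def _load_simulation(outdir: Path):
    d = _paths(outdir)["simulate"]
    if not d.exists():
        raise PipelineError("[lnm] simulate stage outputs not found")
    parc = _load_parcellation(d)
    npz = np.load(d / "functional_connectome.npz")
    fc = FunctionalConnectome(
        npz["series"], npz["brain_indices"],
        parc.label_volume.with_data(np.zeros(parc.label_volume.shape, dtype=np.int16)),
        npz["voxel_network"],
    )
    struct = {}
    for p in sorted((d / "structural").glob("roi_*.nii.gz")):
        rid = int(p.name.split("_")[1].split(".")[0])
        struct[rid] = read_volume(p)
    masks = [read_mask(p) for p in sorted((d / "masks").glob("patient_*.nii.gz"))]
    patients = PatientTable.from_tsv(d / "patients.tsv", masks)
    return parc, fc, struct, patients


def stage_lnm(cfg: RunConfig, outdir: Path) -> list[str]:
    d = _paths(outdir)["lnm"]
    (d / "seed_maps").mkdir(parents=True, exist_ok=True)
    parc, fc, struct, patients = _load_simulation(outdir)
    fmaps = functional_seed_maps(parc, fc)
    smaps = structural_seed_maps(parc, struct)
    manifest = []
    for rid, sm in fmaps.items():
        f = d / "seed_maps" / f"functional_roi_{rid}.nii.gz"
        write_volume(sm.map, f)
        manifest.append({"roi_id": rid, "modality": "functional", "file": f.name})
    for rid, sm in smaps.items():
        f = d / "seed_maps" / f"structural_roi_{rid}.nii.gz"
        write_volume(sm.map, f)
        manifest.append({"roi_id": rid, "modality": "structural",
                         "file": f.name, "provenance": "synthetic"})
    (d / "seed_maps" / "manifest.json").write_text(json.dumps(manifest, indent=2))

    opts = cfg.lnm
    kwargs = dict(
        threshold_fraction=opts.threshold_fraction,
        hemisphere=opts.hemisphere,
        parc=parc,
        penumbra_mm=opts.penumbra_mm,
        penumbra_only=opts.penumbra_only,
    )
    flnm = build_lnm_matrix(patients.masks, fmaps, polarity=opts.polarity, **kwargs)
    slnm = build_lnm_matrix(patients.masks, smaps, polarity="positive", **kwargs)
    vol = volumetric_features(patients.masks, parc.tract_masks)
    for mat, name in ((flnm, "flnm"), (slnm, "slnm")):
        _write_tsv(mat.scores.rename(columns=lambda c: f"roi_{c}"),
                   d / f"{name}_scores.tsv", index=True)
        _write_tsv(mat.empty_selection.rename(columns=lambda c: f"roi_{c}"),
                   d / f"{name}_empty_flags.tsv", index=True)
    _write_tsv(vol.to_frame().rename(columns=lambda c: f"tract_{c}_wmh_ml"
                                     if isinstance(c, (int, np.integer)) else c),
               d / "volumetric_features.tsv", index=True)
    return sorted(str(p.relative_to(outdir)) for p in d.rglob("*") if p.is_file())


def _load_matrix(path: Path, modality: str) -> LNMScoreMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = [int(c.replace("roi_", "")) for c in df.columns]
    return LNMScoreMatrix(modality, "positive", 1.0, df, df * 0, df.isna())


def _load_lnm(outdir: Path):
    from .lnm import VolumetricFeatures

    d = _paths(outdir)["lnm"]
    if not d.exists():
        raise PipelineError("[predict] lnm stage outputs not found")
    flnm = _load_matrix(d / "flnm_scores.tsv", "fLNM")
    slnm = _load_matrix(d / "slnm_scores.tsv", "sLNM")
    vol = pd.read_csv(d / "volumetric_features.tsv", sep="\t", index_col=0)
    total = vol["total_wmh_ml"]
    tract = vol.drop(columns="total_wmh_ml")
    tract.columns = [int(c.replace("tract_", "").replace("_wmh_ml", "")) for c in tract.columns]
    return flnm, slnm, VolumetricFeatures(total, tract)


def stage_predict(cfg: RunConfig, outdir: Path) -> list[str]:
    d = _paths(outdir)["predict"]
    d.mkdir(parents=True, exist_ok=True)
    sim = _paths(outdir)["simulate"]
    patients = pd.read_csv(sim / "patients.tsv", sep="\t")
    flnm, slnm, vol = _load_lnm(outdir)
    po = cfg.prediction
    all_records = []
    comparisons = []
    curves = []
    for domain in po.domains:
        results = {}
        for set_id in po.feature_sets:
            fs = assemble_features(set_id, patients, domain, flnm, slnm, vol)
            res = nested_ridge_cv(
                fs.X.to_numpy(), fs.y.to_numpy(),
                k_outer=po.k_outer, k_inner=po.k_inner, alphas=po.alphas,
                repeats=po.repeats, n_bins=po.n_bins,
                seed=_stage_seed(cfg.seed, f"predict:{domain}:{set_id}"),
                continuous=fs.continuous, feature_set=set_id, domain=domain,
            )
            rec = res.records.copy()
            rec.insert(0, "feature_set", set_id)
            rec.insert(0, "domain", domain)
            all_records.append(rec)
            results[set_id] = res
            if po.learning_fractions:
                lc = learning_curve(
                    fs.X.to_numpy(), fs.y.to_numpy(),
                    fractions=po.learning_fractions,
                    seed=_stage_seed(cfg.seed, f"curve:{domain}:{set_id}"),
                    k_outer=po.k_outer, k_inner=po.k_inner, alphas=po.alphas,
                    repeats=po.repeats, n_bins=po.n_bins, continuous=fs.continuous,
                )
                lc.insert(0, "feature_set", set_id)
                lc.insert(0, "domain", domain)
                curves.append(lc)
        cmp = pairwise_comparisons(results)
        cmp.insert(0, "domain", domain)
        comparisons.append(cmp)
    _write_tsv(pd.concat(all_records, ignore_index=True), d / "cv_scores.tsv")
    _write_tsv(pd.concat(comparisons, ignore_index=True), d / "comparisons.tsv")
    if curves:
        _write_tsv(pd.concat(curves, ignore_index=True), d / "learning_curves.tsv")
    return sorted(str(p.relative_to(outdir)) for p in d.rglob("*") if p.is_file())


def stage_infer(cfg: RunConfig, outdir: Path) -> list[str]:
    d = _paths(outdir)["infer"]
    d.mkdir(parents=True, exist_ok=True)
    sim = _paths(outdir)["simulate"]
    parc = _load_parcellation(sim)
    patients = pd.read_csv(sim / "patients.tsv", sep="\t")
    flnm, slnm, _ = _load_lnm(outdir)
    io = cfg.inference
    mats = {"fLNM": flnm, "sLNM": slnm}
    for domain in io.domains:
        ok = patients[domain].notna()
        covs = patients.loc[ok, ["age", "sex", "education"]]
        y = patients.loc[ok, domain].to_numpy()
        for modality in io.modalities:
            X = mats[modality].scores.loc[ok.to_numpy()]
            glm = permutation_glm_fwe(
                y, X, covs, n_perm=io.n_perm,
                seed=_stage_seed(cfg.seed, f"infer:{domain}:{modality}"),
                metadata={"domain": domain, "modality": modality},
            )
            tag = f"{modality.lower()}_{domain}"
            _write_tsv(glm.table.reset_index(), d / f"roi_stats_{tag}.tsv")
            cortical = glm.table.loc[[i for i in parc.cortical_ids if i in glm.table.index]]
            spins = spin_permutation_test(
                cortical["beta"], parc, n_spins=io.n_spins,
                seed=_stage_seed(cfg.seed, f"spin:{domain}:{modality}"),
            )
            _write_tsv(spins.table.reset_index(), d / f"networks_{tag}.tsv")
            _write_tsv(tract_level_report(glm, parc).reset_index(),
                       d / f"tracts_{tag}.tsv")
    return sorted(str(p.relative_to(outdir)) for p in d.rglob("*") if p.is_file())


STAGES = (
    ("simulate", stage_simulate),
    ("lnm", stage_lnm),
    ("predict", stage_predict),
    ("infer", stage_infer),
)


def run_pipeline(cfg: RunConfig, outdir, force: bool = False) -> RunReport:
    """Execute all stages in order and write ``run_report.json``.

    A rerun into a directory holding a report for a *different* config
    refuses to overwrite unless ``force`` is set.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report_path = outdir / "run_report.json"
    chash = cfg.config_hash()
    if report_path.exists() and not force:
        old = RunReport.from_json(report_path)
        if old.config_hash != chash:
            raise PipelineError(
                "output directory holds a run with a different config; "
                "pass force=True to overwrite"
            )
    cfg.to_yaml(outdir / "config.yaml")
    report = RunReport(config_hash=chash, seed=cfg.seed, version=__version__)
    for name, fn in STAGES:
        t0 = time.perf_counter()
        try:
            files = fn(cfg, outdir)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"[{name}] stage failed: {exc}") from exc
        report.stages[name] = {
            "files": files,
            "seconds": round(time.perf_counter() - t0, 3),
        }
        report.to_json(report_path)  # partial outputs retained on later failure
    return report


def summarize_run(outdir) -> str:
    """Human-readable summary: mean test r per feature set and domain,
    FWE-significant ROI counts, network spin p-values, and the added-
    performance ratio where all three required means exist."""
    outdir = Path(outdir)
    report = RunReport.from_json(outdir / "run_report.json")
    lines = [
        f"wmhlnm run {report.config_hash} (seed {report.seed}, v{report.version})"
    ]
    for stage, info in report.stages.items():
        lines.append(f"  stage {stage}: {len(info['files'])} files, {info['seconds']}s")
        for f in info["files"]:
            if not (outdir / f).exists():
                raise PipelineError(f"report references a missing file: {f}")
    pred = outdir / "predict" / "cv_scores.tsv"
    if pred.exists():
        scores = pd.read_csv(pred, sep="\t")
        mean_r = (
            scores.groupby(["domain", "feature_set"])["pearson_r"].mean().unstack()
        )
        lines.append("\nmean test Pearson r per feature set:")
        lines.append(mean_r.round(3).to_string())
        for domain, row in mean_r.iterrows():
            needed = ("demo", "demo+totalWMH", "demo+fLNM+sLNM")
            if all(k in row and np.isfinite(row[k]) for k in needed):
                try:
                    ratio = added_performance_ratio(
                        row["demo"], row["demo+totalWMH"], row["demo+fLNM+sLNM"]
                    )
                    lines.append(
                        f"  {domain}: added-performance ratio (LNM vs total volume)"
                        f" = {ratio:.2f}"
                    )
                except ZeroDivisionError:
                    pass
    else:
        lines.append("  prediction stage skipped")
    infer_dir = outdir / "infer"
    if infer_dir.exists() and any(infer_dir.glob("roi_stats_*.tsv")):
        lines.append("\nROI-level inference:")
        for f in sorted(infer_dir.glob("roi_stats_*.tsv")):
            tab = pd.read_csv(f, sep="\t")
            n_sig = int((tab["p_fwe"] < 0.05).sum())
            lines.append(f"  {f.stem}: {n_sig} ROIs significant at FWE 0.05")
        for f in sorted(infer_dir.glob("networks_*.tsv")):
            tab = pd.read_csv(f, sep="\t")
            sig = tab[tab["p_spin"] < 0.05]
            nets = ", ".join(
                f"{r.network} (p={r.p_spin:.3f})" for r in sig.itertuples()
            ) or "none"
            lines.append(f"  {f.stem}: spin-significant networks: {nets}")
    else:
        lines.append("  inference stage skipped")
    return "\n".join(lines)
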
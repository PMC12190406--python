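"""End-to-end orchestration from a single structured config.

A pipeline run executes: simulate (design, ratings, single-trial brain
images with a planted mediator region) -> calibrate -> behavioral mixed
models -> voxelwise mediation (intensity and valence variants with their
cue codings) -> signature expression -> map thresholding, writing tabular
outputs as TSV, image outputs as NIfTI, and a JSON manifest recording
seeds, package versions and SHA-256 hashes of every artifact.  Rerunning
with the same config reproduces identical hashes.

Every stochastic stage must carry an explicit seed in the config; a run
with a missing seed fails validation rather than falling back to global
state.
"""

from __future__ import annotations

import copy
import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import behavioral, calibration, mediation, signatures, synthetic, thresholding
from .errors import ConfigurationError

logger = logging.getLogger("cuemed.pipeline")

_DEFAULTS = {
    "out_dir": "cuemed_out",
    "stages": {
        "simulate": True,
        "calibrate": True,
        "behavioral": True,
        "mediation": True,
        "signatures": True,
        "thresholding": True,
    },
    "design": {
        "n_subjects_per_group": 10,
        "n_runs": 5,
        "trials_per_run": 12,
        "n_conditioning": 10,
        "n_test": 50,
        "seed": None,
    },
    "ratings": {"preset": "paper_defaults", "seed": None},
    "brain": {
        "shape": [12, 12, 12],
        "region_center": [6, 6, 6],
        "region_half_width": 1,
        "a_mean": 0.6, "a_sd": 0.2, "b_mean": 0.6, "b_sd": 0.2,
        "ab_corr": 0.0,
        "region_noise_sd": 1.0, "voxel_noise_sd": 1.0,
        "write_images": False,
        "seed": None,
    },
    "calibration": {"n_magnitudes": 8, "noise_sd": 0.5,
                    "max_magnitude": None, "seed": None},
    "mediation": {"outcome_kinds": ["intensity", "valence"],
                  "n_boot": 2000, "moderators": ["group"], "seed": None},
    "signatures": [{"name": "synthetic_uniform", "kind": "uniform"},
                   {"name": "synthetic_region", "kind": "region",
                    "region": "planted"}],
    "thresholding": {"preset": "mediation", "q": 0.05, "connectivity": 6},
}

_STOCHASTIC_STAGES = {"simulate": ("design", "ratings", "brain"),
                      "calibrate": ("calibration",),
                      "mediation": ("mediation",)}


@dataclass(frozen=True)
class PipelineConfig:
    data: dict

    def __getitem__(self, key):
        return self.data[key]

    def to_dict(self) -> dict:
        return copy.deepcopy(self.data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.data, fh, sort_keys=True)


def _merge(defaults, overrides):
    if not isinstance(overrides, dict):
        return copy.deepcopy(overrides)
    out = {}
    for key, val in defaults.items():
        if key in overrides:
            out[key] = (_merge(val, overrides[key])
                        if isinstance(val, dict) else copy.deepcopy(overrides[key]))
        else:
            out[key] = copy.deepcopy(val)
    for key in overrides:
        if key not in defaults:
            raise ConfigurationError(f"unknown config field: {key!r}")
    return out


def validate_config(source) -> PipelineConfig:
    """Schema-check a config mapping or YAML file path; fill defaults.

    Raises :class:`ConfigurationError` naming the offending field, in
    particular for any enabled stochastic stage without an explicit seed.
    """
    if isinstance(source, (str, os.PathLike)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    elif isinstance(source, PipelineConfig):
        raw = source.to_dict()
    else:
        raw = copy.deepcopy(dict(source))
    data = _merge(_DEFAULTS, raw)

    for stage, sections in _STOCHASTIC_STAGES.items():
        if not data["stages"].get(stage):
            continue
        for section in sections:
            if data[section].get("seed") is None:
                raise ConfigurationError(
                    f"stage {stage!r} is enabled but {section}.seed is unset")
    med = data["mediation"]
    if med["n_boot"] < 1:
        raise ConfigurationError("mediation.n_boot must be >= 1")
    for kind in med["outcome_kinds"]:
        if kind not in {"intensity", "valence"}:
            raise ConfigurationError(f"unknown outcome kind {kind!r}")
    th = data["thresholding"]
    if th["preset"] not in thresholding.THRESHOLD_PRESETS:
        raise ConfigurationError(f"unknown threshold preset {th['preset']!r}")
    return PipelineConfig(data=data)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _region_from_config(brain_cfg) -> synthetic.MediatorRegion:
    c = np.asarray(brain_cfg["region_center"], dtype=int)
    hw = int(brain_cfg["region_half_width"])
    rng = range(-hw, hw + 1)
    coords = np.array([[c[0] + i, c[1] + j, c[2] + k]
                       for i in rng for j in rng for k in rng])
    return synthetic.MediatorRegion(
        name="planted", coords=coords,
        a_mean=brain_cfg["a_mean"], a_sd=brain_cfg["a_sd"],
        b_mean=brain_cfg["b_mean"], b_sd=brain_cfg["b_sd"],
        ab_corr=brain_cfg["ab_corr"])


def build_brain_spec(cfg: PipelineConfig) -> synthetic.BrainSimSpec:
    brain = cfg["brain"]
    return synthetic.BrainSimSpec(
        shape=tuple(brain["shape"]),
        regions=(_region_from_config(brain),),
        region_noise_sd=brain["region_noise_sd"],
        voxel_noise_sd=brain["voxel_noise_sd"],
        seed=brain["seed"])


def _save_map(data, affine, path):
    import nibabel as nib

    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), path)
    return path


def run_pipeline(config, out_dir: str | None = None) -> dict:
    """Execute the configured stages; returns the artifact manifest.

    On a stage failure the manifest records the completed stages and the
    failing one, then the exception propagates.
    """
    cfg = validate_config(config)
    out_dir = out_dir or cfg["out_dir"]
    os.makedirs(out_dir, exist_ok=True)
    manifest = {"config": cfg.to_dict(), "stages_completed": [],
                "failed_stage": None, "outputs": {},
                "versions": _versions()}
    state: dict = {}

    def artifact(name, path):
        manifest["outputs"][name] = {"path": os.path.relpath(path, out_dir),
                                     "sha256": _sha256(path)}

    stage_order = ["simulate", "calibrate", "behavioral", "mediation",
                   "signatures", "thresholding"]
    runners = {
        "simulate": _stage_simulate, "calibrate": _stage_calibrate,
        "behavioral": _stage_behavioral, "mediation": _stage_mediation,
        "signatures": _stage_signatures, "thresholding": _stage_thresholding,
    }
    for stage in stage_order:
        if not cfg["stages"].get(stage):
            logger.info("stage %s disabled; skipping", stage)
            continue
        t0 = time.perf_counter()
        try:
            runners[stage](cfg, state, out_dir, artifact)
        except Exception:
            manifest["failed_stage"] = stage
            _write_manifest(manifest, out_dir)
            raise
        manifest["stages_completed"].append(stage)
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)
    _write_manifest(manifest, out_dir)
    return manifest


def _versions() -> dict:
    import nibabel
    import scipy
    import statsmodels

    from . import __version__

    return {"cuemed": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
            "nibabel": nibabel.__version__}


def _write_manifest(manifest, out_dir):
    path = os.path.join(out_dir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return path


# --- stages ----------------------------------------------------------------

def _stage_simulate(cfg, state, out_dir, artifact):
    design_cfg = cfg["design"]
    spec = synthetic.DesignSpec(
        n_subjects_per_group=design_cfg["n_subjects_per_group"],
        n_runs=design_cfg["n_runs"],
        trials_per_run=design_cfg["trials_per_run"],
        n_conditioning=design_cfg["n_conditioning"],
        n_test=design_cfg["n_test"],
        seed=design_cfg["seed"])
    table = synthetic.generate_design(spec)
    preset = cfg["ratings"]["preset"]
    if preset == "paper_defaults":
        params = synthetic.RatingParams.paper_defaults()
    elif preset == "noiseless":
        params = synthetic.RatingParams.noiseless()
    else:
        raise ConfigurationError(f"unknown ratings preset {preset!r}")
    table = synthetic.generate_ratings(table, params, seed=cfg["ratings"]["seed"])

    brain_spec = build_brain_spec(cfg)
    dataset = synthetic.generate_brain(table, brain_spec, seed=cfg["brain"]["seed"])
    state.update(table=dataset.table, dataset=dataset, brain_spec=brain_spec,
                 design_spec=spec, rating_params=params)

    table_path = os.path.join(out_dir, "trials.tsv")
    synthetic.write_trial_table(dataset.table, table_path)
    artifact("trials", table_path)
    truth_path = os.path.join(out_dir, "planted_truth.tsv")
    dataset.truth.to_csv(truth_path, sep="\t", index=False)
    artifact("planted_truth", truth_path)
    if cfg["brain"]["write_images"]:
        paths = synthetic.write_brain_nifti(dataset, os.path.join(out_dir, "betas"))
        for name, p in paths.items():
            artifact(f"betas_{name}", p)
    else:
        mask_path = _save_map(dataset.mask.astype(float), dataset.affine,
                              os.path.join(out_dir, "mask.nii"))
        artifact("mask", mask_path)


def _stage_calibrate(cfg, state, out_dir, artifact):
    """Simulated Day-1 calibration: per-subject linear psychometric fits."""
    cal = cfg["calibration"]
    rng = np.random.default_rng(cal["seed"])
    subjects = (state["table"]["subject"].unique()
                if "table" in state else [f"sub{i:02d}" for i in range(10)])
    reports = {}
    for subject in subjects:
        mags = np.linspace(0.2, 2.0, cal["n_magnitudes"])
        slope = rng.uniform(3.0, 6.0)
        intercept = rng.uniform(-1.0, 1.0)
        ratings = intercept + slope * mags + rng.normal(0, cal["noise_sd"],
                                                        mags.size)
        reports[str(subject)] = calibration.calibration_report(
            mags, ratings, modality="synthetic",
            max_magnitude=cal["max_magnitude"])
    path = os.path.join(out_dir, "calibration.json")
    with open(path, "w") as fh:
        json.dump(reports, fh, indent=2, sort_keys=True)
    artifact("calibration", path)
    state["calibration"] = reports


def _stage_behavioral(cfg, state, out_dir, artifact):
    rows = []
    fits = {}
    for outcome in ("intensity", "valence"):
        spec = behavioral.ModelSpec(outcome=outcome)
        frame = behavioral.encode_predictors(state["table"], spec)
        fit = behavioral.fit_lmm(frame, spec)
        fits[outcome] = fit
        for term, rec in fit.params.iterrows():
            rows.append({"outcome": outcome, "term": term,
                         "estimate": rec["estimate"], "se": rec["se"],
                         "stat": rec["stat"], "p": rec["p"],
                         "converged": fit.converged})
    path = os.path.join(out_dir, "behavioral_lmm.tsv")
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    artifact("behavioral_lmm", path)
    state["behavioral"] = fits


def _stage_mediation(cfg, state, out_dir, artifact):
    med = cfg["mediation"]
    dataset = state["dataset"]
    mask = dataset.mask
    results = {}
    for i, kind in enumerate(med["outcome_kinds"]):
        betas, xs, ys = mediation.dataset_mediation_inputs(
            dataset, outcome_kind=kind)
        res = mediation.voxelwise_mediation(
            betas, xs, ys, n_boot=med["n_boot"], seed=med["seed"] + i)
        results[kind] = res
        for stat in ("a", "b", "ab", "c", "c_prime"):
            vol = np.zeros(mask.shape)
            vol[mask] = getattr(res, stat)
            artifact(f"mediation_{kind}_{stat}", _save_map(
                vol, dataset.affine,
                os.path.join(out_dir, f"mediation_{kind}_{stat}.nii")))
            pvol = np.ones(mask.shape)
            pvol[mask] = res.p[stat]
            artifact(f"mediation_{kind}_{stat}_p", _save_map(
                pvol, dataset.affine,
                os.path.join(out_dir, f"mediation_{kind}_{stat}_p.nii")))
        # scalar mediation of the planted-region average, with moderators
        region = state["brain_spec"].regions[0]
        flat_region = np.zeros(mask.shape, dtype=bool)
        flat_region[tuple(region.coords.T)] = True
        ridx = flat_region[mask]
        paths = [mediation.fit_subject_paths(
            xs[s], betas[s][:, ridx].mean(axis=1), ys[s], subject=s)
            for s in betas]
        scalar = mediation.bootstrap_test(paths, n_boot=med["n_boot"],
                                          seed=med["seed"] + 100 + i)
        groups = [s_group for s_group in (
            state["table"].drop_duplicates("subject")
            .set_index("subject").loc[list(betas), "group"])]
        design = mediation.level2_design(groups, factors=med["moderators"])
        moderated = mediation.moderated_mediation(
            paths, design, n_boot=med["n_boot"], seed=med["seed"] + 200 + i)
        summary = {
            "outcome": kind,
            "region_a": scalar.a, "region_b": scalar.b,
            "region_ab": scalar.ab, "region_cov_ab": scalar.cov_ab,
            "region_p_ab": scalar.p["ab"],
            "n_subjects": scalar.n_subjects,
        }
        for path_name, rec in moderated.items():
            for col in design.columns:
                summary[f"mod_{path_name}_{col}"] = rec["estimate"][col]
                summary[f"mod_{path_name}_{col}_p"] = rec["p"][col]
        results[f"{kind}_summary"] = summary
        results[f"{kind}_subject_paths"] = paths
    path = os.path.join(out_dir, "mediation_summary.tsv")
    pd.DataFrame([results[f"{k}_summary"]
                  for k in med["outcome_kinds"]]).to_csv(path, sep="\t",
                                                         index=False)
    artifact("mediation_summary", path)
    state["mediation"] = results


def _stage_signatures(cfg, state, out_dir, artifact):
    dataset = state["dataset"]
    brain_spec = state["brain_spec"]
    groups = (state["table"].drop_duplicates("subject")
              .set_index("subject")["group"].to_dict())
    kind = cfg["mediation"]["outcome_kinds"][0]
    betas, xs, ys = mediation.dataset_mediation_inputs(dataset,
                                                       outcome_kind=kind)
    # per-subject path-a maps: OLS slope of each voxel on the cue code
    path_maps = {}
    for s in betas:
        p = mediation.fit_subject_paths(xs[s], betas[s], ys[s], subject=s)
        vol = np.zeros(dataset.mask.shape)
        vol[dataset.mask] = p.a
        path_maps[s] = vol
    rows = []
    for sig_cfg in cfg["signatures"]:
        pattern = synthetic.generate_pattern(
            brain_spec, sig_cfg["name"], kind=sig_cfg["kind"],
            region=sig_cfg.get("region"), seed=sig_cfg.get("seed", 0))
        tests = signatures.path_signature_tests(
            pattern, path_maps, groups, image_mask=dataset.mask)
        for g, t in tests["ttests"].items():
            rows.append({"pattern": pattern.name, "path": "a", "group": g,
                         "mean": t["mean"], "t": t["t"], "p": t["p"]})
        if tests["anova"] is not None:
            rows.append({"pattern": pattern.name, "path": "a",
                         "group": "ANOVA", "mean": np.nan,
                         "t": tests["anova"]["F"], "p": tests["anova"]["p"]})
    path = os.path.join(out_dir, "signature_tests.tsv")
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    artifact("signature_tests", path)


def _stage_thresholding(cfg, state, out_dir, artifact):
    if "mediation" not in state:
        logger.warning("mediation outputs missing; thresholding skipped")
        return
    th = cfg["thresholding"]
    preset = thresholding.THRESHOLD_PRESETS[th["preset"]]
    dataset = state["dataset"]
    mask = dataset.mask
    fdr_masks = []
    rows = []
    for kind in cfg["mediation"]["outcome_kinds"]:
        res = state["mediation"][kind]
        pvol = np.ones(mask.shape)
        pvol[mask] = res.p["ab"]
        sig, realized = thresholding.fdr_bh(pvol, mask, q=th["q"])
        fdr_masks.append(sig)
        artifact(f"fdr_{kind}", _save_map(
            sig.astype(float), dataset.affine,
            os.path.join(out_dir, f"fdr_{kind}_ab.nii")))
        clusters = thresholding.cluster_filter(
            pvol, mask, primary_p=preset["primary_p"], k_min=preset["k_min"],
            grow_ps=preset["grow_ps"], connectivity=th["connectivity"])
        frame = clusters.to_frame(affine=dataset.affine)
        frame.insert(0, "outcome", kind)
        rows.append(frame)
        state[f"fdr_{kind}"] = {"mask": sig, "threshold": realized,
                                "clusters": clusters}
    if len(fdr_masks) > 1:
        conj = thresholding.conjunction(fdr_masks)
        artifact("fdr_conjunction", _save_map(
            conj.astype(float), dataset.affine,
            os.path.join(out_dir, "fdr_conjunction.nii")))
    path = os.path.join(out_dir, "clusters.tsv")
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)
    artifact("clusters", path)
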
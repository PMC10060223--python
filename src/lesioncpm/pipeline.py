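"""End-to-end orchestration: cohort I/O, run configuration, analysis report.

A cohort directory holds everything the analysis needs::

    cohort/
      config.yaml               generator settings (provenance)
      brain_mask.nii.gz  parcellation.nii.gz  edge_density.nii.gz
      atlas_ac/  atlas_fc/      one NIfTI per ROI + manifest.json
      lesions/group{1,2,3}/     one binary NIfTI per subject
      behavior_group{1,2,3}.tsv
      network_subset.txt        a priori network ROI ids, one per line
      ground_truth.json         generator ground truth (synthetic cohorts)

``run_analysis`` executes the configured stages — behavioral scoring,
disconnection matrices, CPM at three generalization levels (within-sample
cross-validation, cross-sample, cross-task), AIC model comparisons with FDR
across the three analyses, optional random-ROI permutation null and
voxel-wise back-projection — and writes a JSON + Markdown report.  All
randomness is seeded from the run config, so reruns are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as bhv
from .backprojection import BackprojectionConfig, permutation_correct
from .connectivity_maps import ConnectivityAtlas
from .cpm import crossval_cpm, roi_tscores, train_test_cpm
from .disconnection import disconnection_matrix, DisconnectionMatrix
from .model_comparison import compare_models, fdr_bh
from .permutation_tests import random_roi_null
from .synthetic_cohort import Cohort, SyntheticConfig, simulate_cohort
from .volumes import LesionMask, read_volume, write_volume, Volume3D, Parcellation

logger = logging.getLogger("lesioncpm")

__all__ = [
    "RunConfig",
    "ConfigError",
    "validate_config",
    "run_analysis",
    "write_cohort",
    "load_cohort",
    "LoadedCohort",
]


class ConfigError(ValueError):
    """Schema violation in a run configuration."""


# ---------------------------------------------------------------------------
# cohort directory I/O

GROUPS = ("group1", "group2", "group3")
GROUP_TASKS = {"group1": "TMT", "group2": "TMT", "group3": "Stroop"}


def write_cohort(cohort: Cohort, directory) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    ph = cohort.phantom
    write_volume(ph.brain_mask, d / "brain_mask.nii.gz")
    write_volume(ph.parcellation.labels, d / "parcellation.nii.gz")
    write_volume(ph.edge_density, d / "edge_density.nii.gz")
    ph.atlas_ac.save(d / "atlas_ac")
    ph.atlas_fc.save(d / "atlas_fc")
    (d / "network_subset.txt").write_text(
        "\n".join(str(r) for r in ph.network_subset) + "\n"
    )
    (d / "hemispheres.json").write_text(
        json.dumps(
            dict(zip(map(str, ph.parcellation.roi_ids), ph.parcellation.hemisphere))
        )
    )
    for group in GROUPS:
        gdir = d / "lesions" / group
        gdir.mkdir(parents=True, exist_ok=True)
        for les in cohort.lesions[group]:
            write_volume(les.mask, gdir / f"{les.subject_id}.nii.gz")
        recs = cohort.behavior[group]
        rows = []
        for r in recs:
            rows.append(
                {
                    "subject_id": r.subject_id,
                    "tmt_a_s": r.tmt_a_s,
                    "tmt_b_s": r.tmt_b_s,
                    "stroop_c": r.stroop_c_correct,
                    "stroop_w": r.stroop_w_correct,
                    "stroop_cw": r.stroop_cw_correct,
                }
            )
        pd.DataFrame(rows).to_csv(d / f"behavior_{group}.tsv", sep="\t", index=False)
    (d / "ground_truth.json").write_text(
        json.dumps(
            {
                "planted_shared": cohort.planted_shared,
                "planted_task1": cohort.planted_task1,
                "planted_task2": cohort.planted_task2,
                "groups": {g: cohort.ground_truth[g].to_dict() for g in GROUPS},
            },
            indent=1,
        )
    )
    with open(d / "config.yaml", "w") as fh:
        yaml.safe_dump(
            {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in vars(cohort.cfg).items()},
            fh,
        )
    return d


@dataclass
class LoadedCohort:
    brain_mask: Volume3D
    parcellation: Parcellation
    atlas_ac: ConnectivityAtlas
    atlas_fc: ConnectivityAtlas
    edge_density: Volume3D
    network_subset: list[int]
    lesions: dict[str, list[LesionMask]]
    behavior: dict[str, list[bhv.BehavioralRecord]]
    ground_truth: dict | None = None


def load_cohort(directory) -> LoadedCohort:
    d = Path(directory)
    if not d.is_dir():
        raise FileNotFoundError(f"cohort directory not found: {d}")
    for sub in ("atlas_ac/manifest.json", "atlas_fc/manifest.json"):
        if not (d / sub).exists():
            raise FileNotFoundError(f"missing atlas manifest: {d / sub}")
    brain_mask = read_volume(d / "brain_mask.nii.gz")
    labels = read_volume(d / "parcellation.nii.gz")
    atlas_ac = ConnectivityAtlas.load(d / "atlas_ac")
    atlas_fc = ConnectivityAtlas.load(d / "atlas_fc")
    hemis = None
    if (d / "hemispheres.json").exists():
        hmap = json.loads((d / "hemispheres.json").read_text())
        hemis = [hmap[str(r)] for r in atlas_ac.roi_ids]
    parcellation = Parcellation(
        labels=labels, roi_ids=list(atlas_ac.roi_ids), hemisphere=hemis
    )
    network = [
        int(line)
        for line in (d / "network_subset.txt").read_text().split()
        if line.strip()
    ]
    lesions: dict[str, list[LesionMask]] = {}
    behavior: dict[str, list[bhv.BehavioralRecord]] = {}
    for group in GROUPS:
        gdir = d / "lesions" / group
        lesions[group] = [
            LesionMask(mask=read_volume(p), subject_id=p.name.removesuffix(".nii.gz"))
            for p in sorted(gdir.glob("*.nii.gz"))
        ]
        behavior[group] = bhv.read_behavior_table(d / f"behavior_{group}.tsv")
    gt = None
    if (d / "ground_truth.json").exists():
        gt = json.loads((d / "ground_truth.json").read_text())
    return LoadedCohort(
        brain_mask=brain_mask,
        parcellation=parcellation,
        atlas_ac=atlas_ac,
        atlas_fc=atlas_fc,
        edge_density=read_volume(d / "edge_density.nii.gz"),
        network_subset=network,
        lesions=lesions,
        behavior=behavior,
        ground_truth=gt,
    )


# ---------------------------------------------------------------------------
# run configuration

_SCHEMA: dict = {
    "cohort_dir": (str, None),
    "out_dir": (str, "results"),
    "analyses": (list, ["within_cv", "cross_sample", "cross_task"]),
    "seed": (int, 0),
    "cpm": {
        "alpha": (float, 0.01),
        "sign_policy_ac": (str, "positive_only"),
        "sign_policy_fc": (str, "two_sided"),
        "cv_scheme": (str, "loo"),
        "k_folds": (int, 5),
    },
    "comparison": {
        "k": (int, 1),
        "B_bootstrap": (int, 100),
    },
    "permutation": {
        "enabled": (bool, False),
        "B": (int, 200),
    },
    "backprojection": {
        "enabled": (bool, False),
        "n_perm": (int, 200),
        "correction": (str, "max_stat"),
        "alpha": (float, 0.05),
    },
}

_ANALYSES = ("within_cv", "cross_sample", "cross_task")


@dataclass
class RunConfig:
    cohort_dir: str
    out_dir: str = "results"
    analyses: list[str] = field(default_factory=lambda: list(_ANALYSES))
    seed: int = 0
    cpm: dict = field(default_factory=dict)
    comparison: dict = field(default_factory=dict)
    permutation: dict = field(default_factory=dict)
    backprojection: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "cohort_dir": self.cohort_dir,
            "out_dir": self.out_dir,
            "analyses": list(self.analyses),
            "seed": self.seed,
            "cpm": dict(self.cpm),
            "comparison": dict(self.comparison),
            "permutation": dict(self.permutation),
            "backprojection": dict(self.backprojection),
        }


def _apply_schema(raw: dict, schema: dict, prefix: str = "") -> dict:
    out = {}
    unknown = set(raw) - set(schema)
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(prefix + k for k in unknown)}")
    for key, spec in schema.items():
        if isinstance(spec, dict):
            sub = raw.get(key, {})
            if not isinstance(sub, dict):
                raise ConfigError(f"{prefix}{key}: expected a mapping")
            out[key] = _apply_schema(sub, spec, prefix=f"{prefix}{key}.")
        else:
            typ, default = spec
            if key in raw and raw[key] is not None:
                val = raw[key]
                if typ is float and isinstance(val, int) and not isinstance(val, bool):
                    val = float(val)
                if not isinstance(val, typ) or (typ is int and isinstance(val, bool)):
                    raise ConfigError(
                        f"{prefix}{key}: expected {typ.__name__}, got "
                        f"{type(val).__name__} ({val!r})"
                    )
                out[key] = val
            else:
                out[key] = default
    return out


def validate_config(path_or_dict) -> RunConfig:
    """Load + validate a YAML run config: defaults filled, types checked,
    unknown keys rejected."""
    if isinstance(path_or_dict, dict):
        raw = path_or_dict
    else:
        text = Path(path_or_dict).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a YAML mapping")
    norm = _apply_schema(raw, _SCHEMA)
    alpha = norm["cpm"]["alpha"]
    if not (0 < alpha < 1):
        raise ConfigError(f"cpm.alpha must be in (0, 1), got {alpha}")
    bad = set(norm["analyses"]) - set(_ANALYSES)
    if bad:
        raise ConfigError(f"unknown analyses: {sorted(bad)}")
    if norm["backprojection"]["correction"] not in ("max_stat", "tfce"):
        raise ConfigError("backprojection.correction must be 'max_stat' or 'tfce'")
    return RunConfig(**norm)


# ---------------------------------------------------------------------------
# analysis orchestration


def _scores(cohort: LoadedCohort, group: str) -> bhv.ScoreVector:
    task = GROUP_TASKS[group]
    vec = bhv.score_records(cohort.behavior[group], task)
    vec = vec.dropna()
    return bhv.standardize_scores(vec)


def _matrices(cohort: LoadedCohort) -> dict[str, dict[str, DisconnectionMatrix]]:
    out: dict[str, dict[str, DisconnectionMatrix]] = {}
    for group in GROUPS:
        out[group] = {
            "AC": disconnection_matrix(cohort.lesions[group], cohort.atlas_ac),
            "FC": disconnection_matrix(cohort.lesions[group], cohort.atlas_fc),
            "edge_density": disconnection_matrix(
                cohort.lesions[group],
                ConnectivityAtlas(
                    kind="edge_density", maps=[cohort.edge_density], roi_ids=[]
                ),
            ),
        }
    return out


def _align(mat: DisconnectionMatrix, vec: bhv.ScoreVector):
    df = mat.scores.loc[vec.subject_ids]
    return df, vec.values


def _volume_matrix(mat: DisconnectionMatrix) -> pd.DataFrame:
    return pd.DataFrame({0: mat.lesion_volumes_mm3})


def run_analysis(cfg: RunConfig) -> dict:
    """Execute the configured stages and write report.json / report.md."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "load_cohort"
    try:
        cohort = load_cohort(cfg.cohort_dir)
        stage = "behavioral_scores"
        scores = {g: _scores(cohort, g) for g in GROUPS}
        stage = "disconnection"
        mats = _matrices(cohort)

        alpha = cfg.cpm.get("alpha", 0.01)
        pol_ac = cfg.cpm.get("sign_policy_ac", "positive_only")
        pol_fc = cfg.cpm.get("sign_policy_fc", "two_sided")
        k = cfg.comparison.get("k", 1)
        B_boot = cfg.comparison.get("B_bootstrap", 100)
        network = cohort.network_subset

        def model_spec(kind: str, roi_scope: str):
            policy = pol_fc if kind == "FC" else pol_ac
            def matrix_for(group: str):
                m = mats[group][kind]
                if kind == "lesion_volume":
                    return _volume_matrix(mats[group]["AC"])
                if roi_scope == "network" and kind in ("AC", "FC"):
                    return m.subset_rois(network).scores
                return m.scores
            return matrix_for, policy

        MODELS = {
            "AC_all": model_spec("AC", "all"),
            "FC_all": model_spec("FC", "all"),
            "AC_network": model_spec("AC", "network"),
            "FC_network": model_spec("FC", "network"),
            "edge_density": (
                lambda group: mats[group]["edge_density"].scores,
                pol_ac,
            ),
            "lesion_volume": (
                lambda group: _volume_matrix(mats[group]["AC"]),
                pol_ac,
            ),
        }

        def predict(model: str, analysis: str):
            matrix_for, policy = MODELS[model]
            if analysis == "within_cv":
                df, yv = (
                    matrix_for("group1").loc[scores["group1"].subject_ids],
                    scores["group1"].values,
                )
                return crossval_cpm(
                    df, yv,
                    scheme=cfg.cpm.get("cv_scheme", "loo"),
                    k=cfg.cpm.get("k_folds", 5),
                    seed=cfg.seed,
                    alpha=alpha, sign_policy=policy,
                )
            test_group = "group2" if analysis == "cross_sample" else "group3"
            df_tr = matrix_for("group1").loc[scores["group1"].subject_ids]
            df_te = matrix_for(test_group).loc[scores[test_group].subject_ids]
            return train_test_cpm(
                df_tr, scores["group1"].values,
                df_te, scores[test_group].values,
                alpha=alpha, sign_policy=policy,
            )

        stage = "cpm"
        preds: dict[tuple[str, str], object] = {}
        model_names = ["AC_all", "FC_all", "AC_network", "FC_network",
                       "edge_density", "lesion_volume"]
        for analysis in cfg.analyses:
            for model in model_names:
                logger.info("CPM: %s / %s", analysis, model)
                preds[(analysis, model)] = predict(model, analysis)

        stage = "model_comparison"
        pairs = [
            ("AC_all", "FC_all"),
            ("AC_network", "AC_all"),
            ("AC_network", "edge_density"),
            ("AC_network", "lesion_volume"),
        ]
        comparisons: dict[str, dict[str, dict]] = {}
        for m1, m2 in pairs:
            key = f"{m1}_vs_{m2}"
            per_analysis = {}
            raw_p = []
            for analysis in cfg.analyses:
                comp = compare_models(
                    preds[(analysis, m1)], preds[(analysis, m2)],
                    k=k, B_bootstrap=B_boot, seed=cfg.seed,
                    labels=(m1, m2),
                )
                per_analysis[analysis] = comp.to_dict()
                raw_p.append(comp.p)
            if len(raw_p) > 1:
                reject, p_adj = fdr_bh(raw_p, q=0.05)
                for analysis, pa, rj in zip(cfg.analyses, p_adj, reject):
                    per_analysis[analysis]["p_fdr"] = float(pa)
                    per_analysis[analysis]["significant_fdr"] = bool(rj)
            comparisons[key] = per_analysis

        report: dict = {
            "config": cfg.to_dict(),
            "n_subjects": {g: len(scores[g].subject_ids) for g in GROUPS},
            "network_subset": network,
            "comparisons": comparisons,
        }

        if cfg.permutation.get("enabled", False):
            stage = "permutation"
            analysis = "cross_task" if "cross_task" in cfg.analyses else cfg.analyses[-1]
            test_group = {"within_cv": "group1", "cross_sample": "group2",
                          "cross_task": "group3"}[analysis]
            perm = random_roi_null(
                mats["group1"]["AC"].scores.loc[scores["group1"].subject_ids],
                mats[test_group]["AC"].scores.loc[scores[test_group].subject_ids],
                scores["group1"].values,
                scores[test_group].values,
                k=len(network),
                B=cfg.permutation.get("B", 200),
                seed=cfg.seed,
                observed_roi_ids=network,
                alpha=alpha,
                sign_policy=pol_ac,
            )
            report["random_roi_null"] = {
                "analysis": analysis,
                "observed_aic": perm.observed,
                "p": perm.p,
                "B": perm.B,
                "seed": perm.seed,
            }

        if cfg.backprojection.get("enabled", False):
            stage = "backprojection"
            df, yv = _align(mats["group1"]["AC"], scores["group1"])
            tvec = roi_tscores(df, yv)
            bp_cfg = BackprojectionConfig(
                n_perm=cfg.backprojection.get("n_perm", 200),
                correction=cfg.backprojection.get("correction", "max_stat"),
                alpha=cfg.backprojection.get("alpha", 0.05),
            )
            stat = permutation_correct(
                cohort.atlas_ac,
                tvec.to_numpy(),
                config=bp_cfg,
                seed=cfg.seed,
                brain_mask=cohort.brain_mask,
            )
            write_volume(stat.t_map, out_dir / "backprojection_t.nii.gz")
            write_volume(stat.p_corr_map, out_dir / "backprojection_p_corr.nii.gz")
            write_volume(stat.mask, out_dir / "backprojection_sig_mask.nii.gz")
            report["backprojection"] = {
                "n_perm": bp_cfg.n_perm,
                "correction": bp_cfg.correction,
                "n_significant_voxels": int(stat.mask.data.sum()),
                "t_map": str(out_dir / "backprojection_t.nii.gz"),
                "p_corr_map": str(out_dir / "backprojection_p_corr.nii.gz"),
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    (out_dir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    (out_dir / "report.md").write_text(_markdown_report(report))
    return report


def _markdown_report(report: dict) -> str:
    lines = ["# Lesion-CPM analysis report", ""]
    lines.append("## Samples")
    for g, n in report["n_subjects"].items():
        lines.append(f"- {g}: n = {n}")
    lines.append("")
    lines.append("## Model comparisons (dAIC, p, R)")
    lines.append("")
    lines.append("| comparison | analysis | dAIC | p | p_FDR | R |")
    lines.append("|---|---|---|---|---|---|")
    for key, per in report["comparisons"].items():
        for analysis, c in per.items():
            pf = c.get("p_fdr")
            lines.append(
                f"| {key} | {analysis} | {c['delta_aic']:.2f} | {c['p']:.3g} | "
                f"{'' if pf is None else format(pf, '.3g')} | {c['R']:.3f} |"
            )
    if "random_roi_null" in report:
        r = report["random_roi_null"]
        lines += ["", "## Random-ROI specificity null",
                  f"- analysis: {r['analysis']}; observed test AIC = "
                  f"{r['observed_aic']:.2f}; empirical p = {r['p']:.4g} (B = {r['B']})"]
    if "backprojection" in report:
        b = report["backprojection"]
        lines += ["", "## Back-projection",
                  f"- {b['n_significant_voxels']} significant voxels "
                  f"({b['correction']}, {b['n_perm']} permutations)"]
    lines.append("")
    return "\n".join(lines)


def simulate_to_dir(cfg: SyntheticConfig, directory) -> Path:
    """Generate a cohort and write it as a cohort directory."""
    cohort = simulate_cohort(cfg)
    return write_cohort(cohort, directory)
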
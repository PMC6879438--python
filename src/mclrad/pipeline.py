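"""End-to-end orchestration: simulate -> segment -> extract -> harmonize ->
score risk -> survival -> predict.

Every stage is a pure function of (inputs, config, seed); artifacts are
plain CSV/JSON files and the manifest records a SHA-256 per artifact plus a
config snapshot, so re-running with an identical config reproduces
byte-identical tables.

Two feature paths exist.  The image path segments each generated PET volume
from its seed points and extracts first-order + co-occurrence features;
the feature-level path uses the generator's measured-feature table
directly, which is how large simulated cohorts (hundreds of patients) are
analysed without paying the imaging cost.  Both paths then share batch
distortion, ComBat harmonization, risk scoring and survival analysis.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .harmonize import combat_fit_apply
from .predict import forward_select, logistic_univariate, run_prediction_experiment
from .radiomics import TEXTURE_FEATURE_NAMES, extract_all
from .riskmodels import SignatureConfig, build_risk_profiles
from .survival import cox_hr, km_estimate, logrank_test, roc_cutoff
from .synthdata import (
    CohortConfig,
    generate_cohort,
    inject_batch_effects,
)
from .volumes import build_tmtv

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

#: Risk groupings analysed by the survival stage, in reporting order.
SURVIVAL_GROUPINGS = (
    "metabolic_risk_2cat",
    "metabolic_risk",
    "mipi_cat",
    "mipi_b_cat",
    "mipi_m_cat",
    "mipi_bm_cat",
)


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    use_images: bool = False
    apply_batch_effects: bool = True
    harmonization: bool = True
    signature: SignatureConfig = field(default_factory=SignatureConfig)
    reselect: bool = False          # rerun univariate + forward selection
    recut: bool = False             # recompute ROC cut-offs on this cohort
    run_prediction: bool = False
    n_repeats: int = 5
    threshold_fraction: float = 0.41
    n_bins: int = 64
    min_pairs: int = 20
    min_batch_size: int = 3
    outdir: str | None = None


@dataclass
class PipelineResult:
    features: pd.DataFrame
    harmonized: pd.DataFrame
    profiles: pd.DataFrame
    survival: dict
    cutoffs: dict
    selection: dict | None
    prediction: dict | None
    manifest: dict
    cohort: object


def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(name):
    """Decorator-free stage wrapper: re-raise with the failing stage name."""
    class _Ctx:
        def __init__(self, n):
            self.n = n

        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage {self.n!r} failed: {exc}") from exc
            return False

    return _Ctx(name)


def _extract_image_features(cohort, cfg: PipelineConfig) -> pd.DataFrame:
    rows = []
    for vol, seeds, _truth_mask in cohort.volumes:
        seed_list = [tuple(r) for r in seeds[["x", "y", "z"]].to_numpy()]
        mask = build_tmtv(vol, seed_list, cfg.threshold_fraction)
        row = {"patient_id": vol.patient_id}
        row.update(
            extract_all(vol, mask, n_bins=cfg.n_bins, min_pairs=cfg.min_pairs)
        )
        rows.append(row)
    feats = pd.DataFrame(rows)
    scan = cohort.patients[["patient_id", "scanner"]]
    return feats.merge(scan, on="patient_id")


def _survival_for_grouping(profiles, patients, grouping) -> dict:
    df = profiles.merge(
        patients[["patient_id", "pfs_months", "progressed"]], on="patient_id"
    )
    groups = df[grouping].astype(str)
    out: dict = {"grouping": grouping, "n_per_group": groups.value_counts().to_dict()}
    medians = {}
    for g in groups.unique():
        sel = groups == g
        km = km_estimate(df.loc[sel, "pfs_months"], df.loc[sel, "progressed"])
        medians[g] = km.median
    out["median_pfs_months"] = medians
    if groups.nunique() < 2:
        out["logrank"] = None
        out["cox"] = None
        return out
    lr = logrank_test(df["pfs_months"], df["progressed"], groups)
    out["logrank"] = {"statistic": lr.statistic, "df": lr.df, "p": lr.p_value}
    # reference = lowest-risk label present
    order = ["1", "low"]
    ref = next((o for o in order if o in set(groups)), sorted(set(groups))[0])
    try:
        cox = cox_hr(df["pfs_months"], df["progressed"], groups, reference=ref)
        out["cox"] = {
            "reference": str(cox.reference),
            "hazard_ratios": {str(k): v for k, v in cox.hazard_ratios.items()},
            "ci_lower": {str(k): v for k, v in cox.ci_lower.items()},
            "ci_upper": {str(k): v for k, v in cox.ci_upper.items()},
            "p_values": {str(k): v for k, v in cox.p_values.items()},
        }
    except ValueError as exc:
        out["cox"] = {"error": str(exc)}
    return out


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute the enabled stages in order and return all stage outputs."""
    with _stage("simulate"):
        cohort = generate_cohort(cfg.cohort, with_volumes=cfg.use_images)

    with _stage("extract"):
        if cfg.use_images:
            features = _extract_image_features(cohort, cfg)
        else:
            features = cohort.features.copy()

    with _stage("batch_effects"):
        if cfg.apply_batch_effects:
            batch_map = {s.name: s for s in cfg.cohort.scanners}
            features = inject_batch_effects(features, batch_map)

    with _stage("harmonize"):
        if cfg.harmonization and features["scanner"].nunique() >= 2:
            harmonized, combat_model = combat_fit_apply(
                features.drop(columns=["patient_id", "scanner"]),
                features["scanner"],
                min_batch_size=cfg.min_batch_size,
            )
            harmonized.insert(0, "patient_id", features["patient_id"].to_numpy())
            harmonized["scanner"] = features["scanner"].to_numpy()
        else:
            harmonized, combat_model = features.copy(), None

    patients = cohort.patients

    selection = None
    if cfg.reselect:
        with _stage("select_signature"):
            candidate_cols = [
                c for c in ("suv_max", "suv_mean", "suv_peak", "tmtv_ml", "tlg",
                            *TEXTURE_FEATURE_NAMES)
                if c in harmonized.columns
            ]
            y = patients["pfs2y_event"].astype(int).to_numpy()
            uni = {}
            significant = []
            for c in candidate_cols:
                try:
                    fit = logistic_univariate(harmonized[c], y)
                except ValueError:
                    continue
                uni[c] = {"odds_ratio": fit.odds_ratio, "p": fit.p_value}
                if fit.p_value <= 0.05:
                    significant.append(c)
            fwd = (
                forward_select(harmonized[significant], y) if significant else None
            )
            selection = {
                "univariate": uni,
                "significant": significant,
                "forward_selected": fwd.selected if fwd else [],
            }

    with _stage("cutoffs"):
        if cfg.recut:
            y = patients["pfs2y_event"].astype(bool).to_numpy()
            suv_cut = roc_cutoff(harmonized["suv_mean"], y)
            ent_cut = roc_cutoff(harmonized["entropy"], y)
            sig = SignatureConfig(
                suvmean_cutoff=suv_cut.cutoff,
                entropy_cutoff=ent_cut.cutoff,
                n_categories=cfg.signature.n_categories,
            )
            cutoffs = {
                "suvmean": dataclasses.asdict(suv_cut),
                "entropy": dataclasses.asdict(ent_cut),
                "source": "roc_recut",
            }
        else:
            sig = cfg.signature
            cutoffs = {
                "suvmean": {"cutoff": sig.suvmean_cutoff},
                "entropy": {"cutoff": sig.entropy_cutoff},
                "source": "configured",
            }

    with _stage("risk_profiles"):
        profiles = build_risk_profiles(
            harmonized[["patient_id", "suv_mean", "entropy"]], patients, sig
        )

    with _stage("survival"):
        survival = {
            g: _survival_for_grouping(profiles, patients, g)
            for g in SURVIVAL_GROUPINGS
        }

    prediction = None
    if cfg.run_prediction:
        with _stage("predict"):
            res = run_prediction_experiment(
                harmonized[["patient_id", "suv_mean", "entropy"]],
                patients,
                mode="both",
                n_repeats=cfg.n_repeats,
                seed=cfg.cohort.seed,
            )
            prediction = {
                m: {
                    "median_auc": r.median_auc,
                    "auc_range": list(r.auc_range),
                    "median_train_acc": r.median_train_acc,
                    "median_val_acc": r.median_val_acc,
                    "repeats": r.repeats.to_dict(orient="records"),
                }
                for m, r in res.items()
            }

    manifest: dict = {
        "mclrad_version": __version__,
        "config": json.loads(json.dumps(dataclasses.asdict(cfg), default=str)),
        "n_patients": int(len(patients)),
        "stages": ["simulate", "extract", "batch_effects", "harmonize",
                   "cutoffs", "risk_profiles", "survival"]
        + (["select_signature"] if cfg.reselect else [])
        + (["predict"] if cfg.run_prediction else []),
        "artifacts": {},
    }

    if cfg.outdir is not None:
        with _stage("write_artifacts"):
            outdir = Path(cfg.outdir)
            outdir.mkdir(parents=True, exist_ok=True)
            tables = {
                "patients.csv": patients,
                "features.csv": features,
                "harmonized.csv": harmonized,
                "risk_profiles.csv": profiles,
            }
            for name, df in tables.items():
                p = outdir / name
                df.to_csv(p, index=False, float_format="%.10g")
                manifest["artifacts"][name] = _sha256_file(p)
            blobs = {"survival.json": survival, "cutoffs.json": cutoffs}
            if selection is not None:
                blobs["selection.json"] = selection
            if prediction is not None:
                blobs["prediction.json"] = prediction
            for name, obj in blobs.items():
                p = outdir / name
                p.write_text(json.dumps(obj, indent=1, default=str))
                manifest["artifacts"][name] = _sha256_file(p)
            (outdir / "manifest.json").write_text(
                json.dumps(manifest, indent=1, default=str)
            )

    return PipelineResult(
        features=features,
        harmonized=harmonized,
        profiles=profiles,
        survival=survival,
        cutoffs=cutoffs,
        selection=selection,
        prediction=prediction,
        manifest=manifest,
        cohort=cohort,
    )
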
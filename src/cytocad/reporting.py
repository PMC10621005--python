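"""End-to-end pipeline assembly and figure-ready exports.

Runs cohort statistics, the differential panel, cross-cohort concordance,
classifiability, sub-cohort selection and the SVM signature in order,
writing each stage's output as delimited text plus a JSON run manifest
whose digests make reruns verifiable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .association import SubsetAssociationModel
from .classifiability import ClassifiabilityModel, CVPlan, select_subcohort
from .cohort_stats import build_table1
from .concordance import concordance_test, fold_change_of_means, hierarchical_cluster
from .datatypes import (
    AnalysisConfig,
    PatientRecord,
    ProportionsMatrix,
    SubsetCatalog,
    records_to_frame,
)
from .signature import SignatureSVMModel, compare_feature_sets


@dataclass
class RunManifest:
    seed: int
    config_digest: str
    input_digests: dict[str, str]
    version: str
    stages: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _digest(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def _frame_digest(df: pd.DataFrame) -> str:
    return _digest(df.to_csv(index=True, float_format="%.10g"))


def export_boxplot_data(
    matrix: ProportionsMatrix,
    records: Sequence[PatientRecord],
    subset_ids: Sequence[str],
) -> pd.DataFrame:
    """Per-subset, per-CAD-group box-plot summaries.

    Emits mean, median, quartiles and Tukey whisker bounds (1.5 IQR rule,
    clamped to the data range), plus the values of the SMuRFless patients
    listed separately so they can be over-plotted.
    """
    df = records_to_frame(records)
    values = matrix.aligned_to(list(df.index)).values
    unknown = [s for s in subset_ids if s not in values.columns]
    if unknown:
        raise KeyError(f"unknown subsets: {unknown}")
    rows = []
    for sid in subset_ids:
        for cad in (False, True):
            mask = (df["cad_status"] == cad).to_numpy()
            v = values.loc[mask, sid].to_numpy(dtype=float)
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            iqr = q3 - q1
            lo = max(v.min(), q1 - 1.5 * iqr)
            hi = min(v.max(), q3 + 1.5 * iqr)
            smurfless = values.loc[mask & df["smurfless"].to_numpy(), sid]
            rows.append(
                {
                    "subset_id": sid,
                    "group": "CAD+" if cad else "CAD-",
                    "n": int(mask.sum()),
                    "mean": float(v.mean()),
                    "median": float(med),
                    "q1": float(q1),
                    "q3": float(q3),
                    "whisker_low": float(lo),
                    "whisker_high": float(hi),
                    "smurfless_values": ";".join(f"{x:.4f}" for x in smurfless),
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(
    records: Sequence[PatientRecord],
    matrix: ProportionsMatrix,
    catalog: SubsetCatalog,
    cfg: AnalysisConfig,
    outdir: str | Path,
) -> RunManifest:
    """Execute every analysis stage and write outputs + manifest to outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = records_to_frame(records)
    manifest = RunManifest(
        seed=cfg.seed,
        config_digest=_digest(json.dumps(vars(cfg), sort_keys=True, default=str)),
        input_digests={
            "patients": _frame_digest(df.drop(columns=["patient_id"])),
            "proportions": _frame_digest(matrix.values),
            "catalog": _frame_digest(catalog.to_frame()),
        },
        version=__version__,
    )

    disc_mask = (df["cohort"] == "discovery").to_numpy()
    disc_records = [r for r in records if r.cohort == "discovery"]
    has_validation = (~disc_mask).any()
    disc_matrix = ProportionsMatrix(matrix.values.loc[disc_mask])

    def stage(name: str) -> None:
        manifest.stages.append(name)

    try:
        # 1. baseline characteristics (discovery cohort)
        table1 = build_table1(disc_records, rule=cfg.table1_test_rule)
        table1.to_csv(outdir / "table1.csv", index=False)
        stage("table1")

        # heat-map clustering of %total proportions
        total_cols = [c for c in catalog.total_live_ids() if c in matrix.values.columns]
        cluster = hierarchical_cluster(disc_matrix.values[total_cols])
        pd.DataFrame(
            {"patient_id": cluster.patient_order}
        ).to_csv(outdir / "cluster_patient_order.csv", index=False)
        stage("cluster")

        # 2. differential panel, both models
        assoc = SubsetAssociationModel(
            disc_matrix, disc_records, catalog, cfg
        ).fit(adjust="both")
        assoc.frame().to_csv(outdir / "associations.csv", index=False)
        assoc.forest_table("unadjusted").to_csv(outdir / "forest.csv", index=False)
        stage("differential")
        signature_subsets = assoc.significant_subsets("unadjusted", alpha=0.05)
        if len(signature_subsets) < 2:  # degenerate null panels: keep pipeline alive
            signature_subsets = list(matrix.values.columns[: cfg.screen_top_m])
            manifest.notes.append("fewer than 2 significant subsets; using leading columns")

        # 3. concordance (needs both cohorts)
        if has_validation:
            fc = fold_change_of_means(matrix, records)
            pd.DataFrame(
                {
                    "subset_id": [r.subset_id for r in fc],
                    "fc_discovery": [r.fc_discovery for r in fc],
                    "fc_validation": [r.fc_validation for r in fc],
                }
            ).to_csv(outdir / "fold_changes.csv", index=False)
            conc = concordance_test(
                fc, scale=cfg.fold_change_scale, subset_ids=signature_subsets
            )
            (outdir / "concordance.json").write_text(
                json.dumps(asdict(conc), indent=2)
            )
            stage("concordance")
        else:
            manifest.notes.append("no validation cohort: concordance skipped")

        # 4. classifiability on the discovery cohort
        clf_model = ClassifiabilityModel.from_cohort(disc_matrix, disc_records)
        clf_res = clf_model.fit(
            folds=cfg.cv_folds,
            repeats=cfg.cv_repeats,
            m=cfg.screen_top_m,
            seed=cfg.seed,
            rank_key=cfg.screen_rank_key,
            n_lambda=cfg.n_lambda,
        )
        clf_res.profile.frame().to_csv(outdir / "classifiability.csv", index=False)
        mods = clf_res.modifiers()
        pd.DataFrame(
            {
                "covariate": [m.covariate for m in mods],
                "coefficient": [m.coefficient for m in mods],
                "se": [m.se for m in mods],
                "p": [m.p for m in mods],
                "note": [m.note for m in mods],
            }
        ).to_csv(outdir / "modifiers.csv", index=False)
        stage("classifiability")

        # 5. age >= cutoff sub-cohort
        sub_d = select_subcohort(disc_records, cfg.age_cutoff)
        manifest.notes.append(
            f"sub-cohort age>={cfg.age_cutoff:g}: discovery n={int(sub_d.sum())}"
        )
        stage("subcohort")

        # 6. SVM signature on the sub-cohort, three feature sets
        yd = df.loc[disc_mask, "cad_status"].to_numpy(int)[sub_d]
        Xd = disc_matrix.values.to_numpy(float)[sub_d]
        age_d = df.loc[disc_mask, "age"].to_numpy(float)[sub_d]
        male_d = (df.loc[disc_mask, "sex"] == "male").to_numpy(float)[sub_d]
        plan = CVPlan.build(
            len(yd), yd, folds=cfg.cv_folds, repeats=cfg.cv_repeats, seed=cfg.seed
        )
        reports = compare_feature_sets(
            Xd, yd, age_d, male_d, plan, m=cfg.screen_top_m, cost=cfg.svm_cost
        )
        pd.DataFrame(
            {
                "feature_set": list(reports),
                "mean_auc": [r.mean_auc for r in reports.values()],
            }
        ).to_csv(outdir / "signature_aucs.csv", index=False)
        roc = pd.DataFrame({"fpr": reports["cytof_18"].fpr_grid})
        for name, rep in reports.items():
            roc[f"tpr_{name}"] = rep.mean_tpr
        roc.to_csv(outdir / "signature_roc.csv", index=False)
        stage("signature")

        # 7. validation + decision boundary (needs both cohorts)
        if has_validation:
            vali_records = [r for r in records if r.cohort == "validation"]
            sub_v = select_subcohort(vali_records, cfg.age_cutoff)
            manifest.notes.append(
                f"sub-cohort age>={cfg.age_cutoff:g}: validation n={int(sub_v.sum())}"
            )
            vdf = df.loc[~disc_mask]
            yv = vdf["cad_status"].to_numpy(int)[sub_v]
            Xv = matrix.values.loc[~disc_mask, signature_subsets].to_numpy(float)[sub_v]
            Xd_sig = disc_matrix.values[signature_subsets].to_numpy(float)[sub_d]
            sig = SignatureSVMModel(
                Xd_sig, yd, Xv, yv, feature_names=signature_subsets, cost=cfg.svm_cost
            ).fit(
                folds=cfg.cv_folds,
                repeats=cfg.cv_repeats,
                m=min(cfg.screen_top_m, len(signature_subsets)),
                seed=cfg.seed,
            )
            (outdir / "validation_auc.json").write_text(
                json.dumps(
                    {
                        "validation_auc": sig.validation_report.validation_auc,
                        "discovery_cv_mean_auc": sig.cv_report.mean_auc,
                        "backmap_method": sig.boundary.backmap_method,
                    },
                    indent=2,
                )
            )
            np.savetxt(
                outdir / "boundary_grid.csv",
                sig.boundary.predicted,
                fmt="%d",
                delimiter=",",
            )
            stage("boundary")
        else:
            manifest.notes.append("no validation cohort: train/validate skipped")

        # 8. box-plot exports for the signature subsets
        export_boxplot_data(disc_matrix, disc_records, signature_subsets).to_csv(
            outdir / "boxplot_data.csv", index=False
        )
        stage("boxplots")
    except Exception as e:  # noqa: BLE001 - abort with stage context
        manifest.notes.append(f"aborted: {type(e).__name__}: {e}")
        (outdir / "manifest.json").write_text(manifest.to_json())
        raise

    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest
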
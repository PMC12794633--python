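"""End-to-end orchestration: manifest in, fused feature table and evaluation out.

A cohort is described by a CSV manifest with one row per case:

    case_id, dwi, lesion, vessel, affected_side, mrs

where the three path columns point at NIfTI volumes (relative paths are
resolved against the manifest's directory) and ``mrs`` is the 90-day mRS
score (dichotomized internally: < 3 good, >= 3 poor).  ``label`` may be
given directly instead of ``mrs``.

``run_all`` executes extraction -> univariate screening -> 2:1 split ->
penalty tuning / feature selection -> SRC fit -> evaluation for the vessel,
DWI and fused feature sets, and writes all artifacts (feature table,
selection report, models, metrics report, ROC and decision-curve plots)
under the configured output directory.  All randomness flows from the single
seed in the config, and every artifact embeds the resolved config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .evaluation_stats import EvalReport, SplitPlan, run_protocol, t_test_screen
from .imaging_core import CaseRecord, label_from_mrs, read_mask, read_volume
from .lesion_radiomics import extract_dwi_features
from .sparse_models import FeatureTable, SRCModel
from .vessel_morphometry import extract_vascular_features

logger = logging.getLogger(__name__)

VESSEL_PREFIXES = ("v3d_", "v2d_", "asym3d_", "asym2d_")
DWI_PREFIXES = ("lesion.", "ring.")


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run."""

    ring_px: int = 10
    n_bins: int = 32
    wavelet: str = "haar"
    prune_length: int = 2
    lambda_grid: List[float] = field(
        default_factory=lambda: list(np.geomspace(0.01, 0.5, 12)))
    lam_code: float = 0.01
    folds: int = 10
    test_fraction: float = 1.0 / 3.0
    seed: int = 0
    positive_class: str = "poor"
    n_features_override: Optional[int] = None
    outdir: str = "strokeprog_out"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["lambda_grid"] = [float(x) for x in d["lambda_grid"]]
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


# ---------------------------------------------------------------------------
# Feature assembly
# ---------------------------------------------------------------------------

def load_manifest(path: str | Path) -> List[CaseRecord]:
    """Read a case manifest CSV and load the referenced NIfTI volumes."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"manifest {path} has no cases")
    base = path.parent
    cases = []
    for _, row in df.iterrows():
        label = row["label"] if "label" in df.columns else label_from_mrs(row["mrs"])
        cases.append(CaseRecord(
            case_id=str(row["case_id"]),
            dwi=read_volume(base / row["dwi"]),
            lesion=read_mask(base / row["lesion"]),
            vessel=read_mask(base / row["vessel"]),
            affected_side=str(row["affected_side"]),
            label=str(label),
        ))
    return cases


def extract_case_features(case: CaseRecord, config: RunConfig) -> Dict[str, float]:
    """40 vascular + 1,026 radiomics features for one case, fused."""
    out = dict(extract_vascular_features(case, prune_length=config.prune_length))
    out.update(extract_dwi_features(case, ring_px=config.ring_px,
                                    n_bins=config.n_bins,
                                    wavelet=config.wavelet))
    return out


def assemble_features(cases: Sequence[CaseRecord],
                      config: Optional[RunConfig] = None) -> FeatureTable:
    """Build the fused cases x 1,066 feature table.

    Cases whose extraction fails are dropped with a logged reason; the run
    continues with the remainder.
    """
    config = config or RunConfig()
    if len(cases) == 0:
        raise ValueError("no cases to assemble")
    rows, ids, labels = [], [], []
    names: Optional[List[str]] = None
    for case in cases:
        try:
            feats = extract_case_features(case, config)
        except Exception as exc:
            logger.warning("case %s dropped: %s", case.case_id, exc)
            continue
        if names is None:
            names = list(feats.keys())
        rows.append([feats[k] for k in names])
        ids.append(case.case_id)
        labels.append(case.label)
    if not rows:
        raise RuntimeError("feature extraction failed for every case")
    return FeatureTable(ids, names, np.asarray(rows), np.asarray(labels, dtype=object))


def modality_feature_sets(feature_names: Sequence[str]) -> Dict[str, List[str]]:
    """Partition fused column names into vessel / dwi / vessel+dwi sets."""
    vessel = [n for n in feature_names if n.startswith(VESSEL_PREFIXES)]
    dwi = [n for n in feature_names if n.startswith(DWI_PREFIXES)]
    return {"vessel": vessel, "dwi": dwi, "vessel+dwi": vessel + dwi}


# ---------------------------------------------------------------------------
# Model persistence (structured text)
# ---------------------------------------------------------------------------

def save_model(model: SRCModel, path: str | Path) -> None:
    payload = {
        "selected_names": model.selected_names,
        "mean": model.mean_.tolist(),
        "sd": model.sd_.tolist(),
        "dictionary": model.dictionary.tolist(),
        "column_labels": model.column_labels.tolist(),
        "lam_code": model.lam_code,
        "majority_label": model.majority_label,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> SRCModel:
    payload = json.loads(Path(path).read_text())
    return SRCModel(
        dictionary=np.asarray(payload["dictionary"]),
        column_labels=np.asarray(payload["column_labels"], dtype=object),
        selected_names=payload["selected_names"],
        mean_=np.asarray(payload["mean"]),
        sd_=np.asarray(payload["sd"]),
        lam_code=payload["lam_code"],
        majority_label=payload["majority_label"],
    )


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

def _write_plots(report: EvalReport, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, m in report.models.items():
        ax.plot(m.roc_points[:, 0], m.roc_points[:, 1],
                label=f"{name} (AUC={m.test_auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend()
    fig.savefig(outdir / "roc_test.png", dpi=120, bbox_inches="tight")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    for name, dc in report.decision_curves.items():
        ax.plot(dc["threshold"], dc["model"], label=name)
    any_dc = next(iter(report.decision_curves.values()))
    ax.plot(any_dc["threshold"], any_dc["treat_all"], "k:", label="treat all")
    ax.plot(any_dc["threshold"], any_dc["treat_none"], "k-", lw=0.8,
            label="treat none")
    ax.set_ylim(-0.2, 0.6)
    ax.set_xlabel("threshold probability")
    ax.set_ylabel("net benefit")
    ax.legend()
    fig.savefig(outdir / "decision_curves_test.png", dpi=120,
                bbox_inches="tight")
    plt.close(fig)


def run_all(config: RunConfig, cases: Sequence[CaseRecord] | str | Path
            ) -> EvalReport:
    """Execute the whole pipeline and write artifacts to ``config.outdir``."""
    if isinstance(cases, (str, Path)):
        cases = load_manifest(cases)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(json.dumps(config.to_dict(), indent=1))

    table = assemble_features(cases, config)
    df = pd.DataFrame(table.X, index=table.case_ids,
                      columns=table.feature_names)
    df.insert(0, "label", table.labels)
    df.to_csv(outdir / "features.csv")

    pvals = t_test_screen(table)
    pvals.to_csv(outdir / "screening_pvalues.csv")
    n_sig = int((pvals < 0.05).sum())
    logger.info("screening: %d of %d features with p < 0.05", n_sig,
                len(pvals))

    plan = SplitPlan(seed=config.seed, test_fraction=config.test_fraction,
                     folds=config.folds)
    report = run_protocol(
        table, plan, modality_feature_sets(table.feature_names),
        lambda_grid=config.lambda_grid, lam_code=config.lam_code,
        positive=config.positive_class,
        n_features_override=config.n_features_override,
    )
    payload = report.to_dict()
    payload["config"] = config.to_dict()
    payload["screening_significant"] = n_sig
    (outdir / "report.json").write_text(json.dumps(payload, indent=1))
    _write_plots(report, outdir)
    return report
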
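"""Per-arm analysis pipeline: screen, cluster, characterize, landmark survival.

The orchestration follows the study design the package implements:

1. screen candidate covariates with the linear mixed model and backward
   elimination; survivors condition the growth mixture model,
2. choose the number of latent classes by BIC under the class-proportion
   and entropy admissibility rules,
3. compare class characteristics (chi-square / Kruskal-Wallis),
4. landmark Kaplan-Meier and log-rank across modal classes,
5. Cox models: class indicators adjusted for sex and ECOG (with Harrell's
   C), and separately the per-subject growth factors (baseline, slope,
   quadratic).

Every run is reproducible bit-for-bit from (inputs, config, seed); the
report records exclusion counts so input n reconciles with analyzed n.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort_stats import class_characteristics_report
from .data import QoLPanel, SurvivalData, ValidationError
from .design import build_covariate_design
from .gmm import GrowthMixtureSpec, ModelSelectionReport, select_num_classes
from .lmm import screening_report
from .survival import (
    CoxFit,
    KMCurve,
    LandmarkResult,
    c_index,
    cox_fit,
    km_estimate,
    landmark_filter,
    logrank_test,
)


@dataclass
class PipelineConfig:
    """Tunable knobs of one pipeline run (defaults mirror the shipped study design)."""

    landmark_weeks: float = 16.0
    k_range: tuple[int, ...] = (1, 2, 3, 4, 5)
    covariate_candidates: tuple[str, ...] = ("sex", "ecog", "age", "arm")
    alpha: float = 0.05
    polynomial_order: int = 2
    covariance_mode: str = "shared"
    n_starts: int = 20
    max_iter: int = 500
    tol: float = 1e-6
    min_prop: float = 0.10
    entropy_floor: float = 0.7
    enforce_entropy: bool = True
    include_arm_in_growth_cox: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if self.landmark_weeks < 0:
            raise ValidationError("landmark must be non-negative")
        self.k_range = tuple(int(k) for k in self.k_range)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("k_range", "covariate_candidates"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["k_range"] = list(d["k_range"])
        d["covariate_candidates"] = list(d["covariate_candidates"])
        return d


@dataclass
class ArmReport:
    """Assembled results of one arm's end-to-end run."""

    config: PipelineConfig
    n_input: int
    screening: pd.DataFrame
    selected_covariates: list[str]
    selection: ModelSelectionReport
    characteristics: pd.DataFrame
    landmark: LandmarkResult | None
    km_curves: dict[int, KMCurve]
    logrank: tuple[float, int, float] | None
    cox_class: CoxFit | None
    cox_growth: CoxFit | None
    notices: list[str] = field(default_factory=list)

    @property
    def fit(self):
        return self.selection.chosen_fit

    def accounting(self) -> dict[str, int]:
        analyzed = self.landmark.data.n_subjects if self.landmark else 0
        excluded = self.landmark.n_excluded if self.landmark else 0
        return {
            "n_input": self.n_input,
            "n_panel": len(self.fit.subject_ids),
            "n_landmark_excluded": excluded,
            "n_landmark_analyzed": analyzed,
        }


def run_arm_analysis(
    panel: QoLPanel, surv: SurvivalData, config: PipelineConfig | None = None
) -> ArmReport:
    """Run the full per-arm analysis; see the module docstring for the steps."""
    config = config or PipelineConfig()
    missing = set(panel.subject_ids) ^ set(surv.subject_ids)
    if missing:
        raise ValidationError(
            f"panel/survival subject mismatch, offenders: {sorted(missing)[:10]}"
        )
    surv = surv.subset(panel.subject_ids)
    notices: list[str] = []

    # 1. LMM screen
    candidates = [c for c in config.covariate_candidates if c in panel.covariates.columns]
    screening = screening_report(panel, candidates, alpha=config.alpha)
    selected = [c for c in candidates if bool(screening.loc[c, "selected"])]
    if not selected:
        notices.append("no covariate survived screening; GMM fit unconditionally")

    # 2. class enumeration
    spec = GrowthMixtureSpec(
        n_classes=max(config.k_range),
        polynomial_order=config.polynomial_order,
        growth_covariates=tuple(selected),
        covariance_mode=config.covariance_mode,
    )
    selection = select_num_classes(
        panel,
        spec,
        k_range=config.k_range,
        min_prop=config.min_prop,
        entropy_floor=config.entropy_floor,
        enforce_entropy=config.enforce_entropy,
        n_starts=config.n_starts,
        max_iter=config.max_iter,
        tol=config.tol,
        seed=config.seed,
    )
    fit = selection.chosen_fit
    if selection.constraint_violated:
        notices.append("no candidate K satisfied the class-size/entropy rules; "
                       "unconstrained BIC minimizer reported")

    # 3. class characteristics
    characteristics = class_characteristics_report(panel, fit.modal_class + 1, seed=config.seed)

    # 4-5. landmark survival
    km_curves: dict[int, KMCurve] = {}
    logrank = cox_class = cox_growth = None
    landmark = landmark_filter(surv, config.landmark_weeks)
    lm_ids = landmark.data.subject_ids
    pos = {s: i for i, s in enumerate(panel.subject_ids)}
    lm_idx = np.array([pos[s] for s in lm_ids])
    lm_classes = fit.modal_class[lm_idx]

    if fit.spec.n_classes == 1 or len(np.unique(lm_classes)) < 2:
        notices.append("single class at the landmark; survival comparisons skipped")
        km_curves[1] = km_estimate(landmark.data, label="all")
    else:
        for k in np.unique(lm_classes):
            sel = [s for s, c in zip(lm_ids, lm_classes) if c == k]
            km_curves[int(k) + 1] = km_estimate(landmark.data.subset(sel), label=f"class {k+1}")
        logrank = logrank_test(landmark.data, lm_classes)

        # Cox: class indicators + sex + ECOG
        Xadj, adj_names, _ = build_covariate_design(
            panel.covariates.loc[lm_ids],
            tuple(c for c in ("sex", "ecog") if c in panel.covariates.columns),
        )
        cols = {}
        for k in np.unique(lm_classes)[1:]:
            cols[f"class[{k+1}]"] = (lm_classes == k).astype(float)
        for j, nm in enumerate(adj_names):
            cols[nm] = Xadj[:, j]
        cox_class = cox_fit(landmark.data, pd.DataFrame(cols, index=lm_ids))

    growth_cols = pd.DataFrame(
        fit.growth_factors[lm_idx],
        columns=["baseline", "slope", "quadratic"],
        index=lm_ids,
    )
    if fit.spec.polynomial_order < 2:
        growth_cols = growth_cols.drop(columns="quadratic")
    if config.include_arm_in_growth_cox and "arm" in panel.covariates.columns:
        Xarm, arm_names, _ = build_covariate_design(panel.covariates.loc[lm_ids], ("arm",))
        if np.ptp(Xarm[:, 0]) > 0:
            growth_cols[arm_names[0]] = Xarm[:, 0]
    const = [c for c in growth_cols.columns if np.ptp(growth_cols[c].to_numpy()) == 0]
    if const:
        notices.append(f"constant growth factor(s) dropped from Cox: {const}")
        growth_cols = growth_cols.drop(columns=const)
    try:
        cox_growth = cox_fit(landmark.data, growth_cols)
    except ValidationError as exc:
        notices.append(f"growth-factor Cox skipped: {exc}")

    return ArmReport(
        config=config,
        n_input=panel.n_subjects,
        screening=screening,
        selected_covariates=selected,
        selection=selection,
        characteristics=characteristics,
        landmark=landmark,
        km_curves=km_curves,
        logrank=logrank,
        cox_class=cox_class,
        cox_growth=cox_growth,
        notices=notices,
    )


def write_arm_report(report: ArmReport, outdir) -> list[Path]:
    """Serialize an ArmReport to CSV/text files; returns the files written."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def save(df: pd.DataFrame, name: str, index=False):
        p = out / name
        df.to_csv(p, index=index, float_format="%.6g")
        written.append(p)

    save(report.selection.table.reset_index(), "model_table.csv")
    save(report.fit.assignments_frame(), "assignments.csv")
    save(report.screening.reset_index(), "screening.csv")
    save(report.characteristics, "class_characteristics.csv")
    km = pd.concat(
        [c.to_frame().assign(group=k) for k, c in report.km_curves.items()],
        ignore_index=True,
    )
    save(km, "km_curves.csv")
    cox_frames = []
    if report.cox_class is not None:
        cox_frames.append(report.cox_class.summary_frame().assign(model="class+sex+ecog"))
    if report.cox_growth is not None:
        cox_frames.append(report.cox_growth.summary_frame().assign(model="growth_factors"))
    if cox_frames:
        save(pd.concat(cox_frames).rename_axis("term").reset_index(), "cox.csv")

    tlines = []
    if report.landmark is not None:
        tlines.append(
            f"landmark {report.landmark.landmark_weeks:g} weeks: "
            f"excluded {report.landmark.n_excluded}"
        )
    if report.logrank is not None:
        stat, df_, pval = report.logrank
        tlines.append(f"log-rank chi2={stat:.6g} df={df_} p={pval:.6g}")
    for name in ("sex", "ecog", "age"):
        sel = report.characteristics.loc[
            report.characteristics["covariate"] == name, "test_p"
        ]
        if len(sel):
            tlines.append(f"class comparison {name}: {sel.iloc[0]}")
    p = out / "tests.txt"
    p.write_text("\n".join(tlines) + "\n")
    written.append(p)

    lines = ["pipeline report", "================", ""]
    lines.append("config:")
    for k, v in report.config.to_dict().items():
        lines.append(f"  {k}: {v}")
    lines.append("")
    acc = report.accounting()
    lines.append("accounting: " + ", ".join(f"{k}={v}" for k, v in acc.items()))
    fit = report.fit
    ent = "n/a" if fit.entropy is None else f"{fit.entropy:.3f}"
    lines.append(f"selected K: {fit.spec.n_classes} (BIC {fit.bic:.1f}, entropy {ent})")
    lines.append(f"class proportions: {np.round(fit.class_proportions, 3).tolist()}")
    if report.logrank is not None:
        stat, df_, p = report.logrank
        lines.append(f"landmark log-rank: chi2={stat:.4g}, df={df_}, p={p:.4g}")
    if report.cox_class is not None:
        lines.append(f"class Cox C-index: {report.cox_class.c_index:.3f}")
    if report.cox_growth is not None:
        cg = report.cox_growth
        hrs = ", ".join(
            f"{t}={cg.hazard_ratios[t]:.3g} (95% CI {cg.ci_low[t]:.3g}-{cg.ci_high[t]:.3g})"
            for t in cg.hazard_ratios.index
        )
        lines.append(f"growth-factor Cox HRs: {hrs}")
    for n in report.notices:
        lines.append(f"notice: {n}")
    p = out / "report.txt"
    p.write_text("\n".join(lines) + "\n")
    written.append(p)
    return written
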
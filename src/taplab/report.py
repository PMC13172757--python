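"""End-to-end orchestration, selection-flow accounting and report output.

``apply_selection_flow`` reproduces the flow-diagram bookkeeping of a
retrospective cohort build: candidates pass through a fixed sequence of
exclusion stages (duplicates → non-PD diagnosis → imaging-window violation
→ low video quality); a record failing several criteria is counted once,
at the earliest stage, and counts are conserved at every stage.

``run_pipeline`` wires the whole package together: simulate (or ingest) a
cohort, run QC and feature extraction, compute the diagnostic and
correlation statistics, and write tidy CSV tables plus a JSON run manifest.
Re-running with the same configuration and seed reproduces byte-identical
numeric tables.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import InvalidArgumentError
from .stats import (bh_adjust, group_compare_suite, logistic_fit, roc_analysis,
                    spearman_bootstrap)
from .synthetic import HC_LIKE, PD_LIKE, GroupSpec, simulate_cohort

#: Exclusion stages in flow-diagram order: (stage name, boolean flag column).
FLOW_STAGES = (
    ("duplicates", "duplicate"),
    ("non_pd_diagnosis", "non_pd"),
    ("dat_window", "dat_window_exceeded"),
    ("low_quality", "low_quality"),
)

FEATURES = ("V", "delta_a", "aCoV", "ifCoV")
CLINICAL_ANCHORS = ("updrs3_total", "item_3_4", "duration_y")


@dataclass(frozen=True)
class FlowRecord:
    stage_name: str
    n_in: int
    n_excluded: int
    exclusion_reason: str
    n_out: int

    def __post_init__(self) -> None:
        if self.n_out != self.n_in - self.n_excluded or self.n_out < 0:
            raise InvalidArgumentError("flow record does not conserve counts")


def apply_selection_flow(records: pd.DataFrame) -> list[FlowRecord]:
    """Sequentially filter candidate records through the exclusion stages.

    ``records`` carries one row per candidate with boolean flag columns
    ``duplicate``, ``non_pd``, ``dat_window_exceeded``, ``low_quality``.
    A record with several flags is excluded at the first matching stage.
    The returned chain ends with a ``final_cohort`` record whose ``n_out``
    is the retained cohort size.
    """
    for _, col in FLOW_STAGES:
        if col not in records.columns:
            raise InvalidArgumentError(f"records missing flag column {col!r}")
    remaining = records.copy()
    chain: list[FlowRecord] = []
    for stage, col in FLOW_STAGES:
        n_in = len(remaining)
        excluded = remaining[col].astype(bool)
        chain.append(FlowRecord(stage_name=stage, n_in=n_in,
                                n_excluded=int(excluded.sum()),
                                exclusion_reason=col,
                                n_out=n_in - int(excluded.sum())))
        remaining = remaining[~excluded]
    chain.append(FlowRecord(stage_name="final_cohort", n_in=len(remaining),
                            n_excluded=0, exclusion_reason="", n_out=len(remaining)))
    return chain


def flow_table(chain: list[FlowRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in chain])


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh) or {}
    return dict(config or {})


def _group_from_config(spec: dict, default: GroupSpec) -> GroupSpec:
    def triple(key, fallback):
        v = spec.get(key)
        return tuple(float(x) for x in v) if v is not None else fallback

    return GroupSpec(
        label=spec.get("label", default.label),
        n_subjects=int(spec.get("n_subjects", default.n_subjects)),
        acov=triple("acov", default.acov),
        ifcov=triple("ifcov", default.ifcov),
        velocity=triple("velocity", default.velocity),
        decrement_mean=float(spec.get("decrement_mean", default.decrement_mean)),
        decrement_sd=float(spec.get("decrement_sd", default.decrement_sd)),
    )


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Execute simulate → QC → features → statistics and write all tables.

    The configuration (dict or YAML path) may override the seed, group
    specifications, sampling rate, bout duration, measurement noise and
    bootstrap size.  Outputs: ``features.csv``, ``exclusions.csv``,
    ``group_tests.csv``, ``roc.csv``, ``logistic.csv``,
    ``correlations.csv``, ``manifest.json`` and a human-readable
    ``summary.txt``.  Returns the results bundle as a dict of DataFrames.
    """
    cfg = _load_config(config)
    out_dir = Path(out_dir or cfg.get("out_dir", "taplab_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    n_boot = int(cfg.get("n_boot", 1000))

    pd_spec = _group_from_config(cfg.get("pd_group", {}), PD_LIKE)
    hc_spec = _group_from_config(cfg.get("hc_group", {}), HC_LIKE)
    cohort = simulate_cohort(
        [pd_spec, hc_spec], seed=seed,
        fps=float(cfg.get("fps", 30.0)),
        duration_s=float(cfg.get("duration_s", 15.0)),
        noise_sd=float(cfg.get("noise_sd", 0.005)),
    )

    excluded = cohort[~cohort["qc_pass"].astype(bool)].copy()
    kept = cohort[cohort["qc_pass"].astype(bool)].copy()
    if kept["group"].nunique() < 2:
        raise InvalidArgumentError("QC left fewer than two groups; cannot run stats")

    group_tests = group_compare_suite(kept, variables=list(FEATURES))

    pos_label = pd_spec.label
    labels = (kept["group"] == pos_label).to_numpy()
    roc_rows = []
    for feat in FEATURES:
        r = roc_analysis(kept[feat].to_numpy(float), labels)
        roc_rows.append({"feature": feat, "auc": r.auc, "se": r.se,
                         "ci_lo": r.ci95[0], "ci_hi": r.ci95[1],
                         "p_vs_half": r.p_vs_half, "cutoff": r.cutoff,
                         "sensitivity": r.sensitivity, "specificity": r.specificity,
                         "accuracy": r.accuracy})
    roc = pd.DataFrame(roc_rows)

    logit = logistic_fit(kept[list(FEATURES)], labels.astype(int))
    coef_rows = [{"term": "intercept", "coefficient": logit.coefficients[0],
                  "wald": logit.wald_stats[0], "p": logit.p_values[0],
                  "odds_ratio": logit.odds_ratios[0]}]
    for i, feat in enumerate(FEATURES, start=1):
        coef_rows.append({"term": feat, "coefficient": logit.coefficients[i],
                          "wald": logit.wald_stats[i], "p": logit.p_values[i],
                          "odds_ratio": logit.odds_ratios[i]})
    logistic_table = pd.DataFrame(coef_rows)

    pd_rows = kept[kept["group"] == pos_label]
    corr_rows = []
    for anchor in CLINICAL_ANCHORS:
        fam = []
        for feat in FEATURES:
            try:
                c = spearman_bootstrap(pd_rows[feat], pd_rows[anchor],
                                       n_boot=n_boot, seed=seed)
                fam.append({"anchor": anchor, "feature": feat, "rho": c.rho,
                            "p": c.p, "ci_lo": c.ci95[0], "ci_hi": c.ci95[1],
                            "n": c.n})
            except Exception:  # degenerate anchor in a tiny simulated cohort
                fam.append({"anchor": anchor, "feature": feat, "rho": np.nan,
                            "p": np.nan, "ci_lo": np.nan, "ci_hi": np.nan, "n": 0})
        fam_df = pd.DataFrame(fam)
        ok = fam_df["p"].notna()
        fam_df["q"] = np.nan
        if ok.any():  # BH within one clinical-anchor family
            fam_df.loc[ok, "q"] = bh_adjust(fam_df.loc[ok, "p"].to_numpy())
        corr_rows.append(fam_df)
    correlations = pd.concat(corr_rows, ignore_index=True)

    cohort.to_csv(out_dir / "features.csv", index=False)
    excluded.to_csv(out_dir / "exclusions.csv", index=False)
    group_tests.to_csv(out_dir / "group_tests.csv", index=False)
    roc.to_csv(out_dir / "roc.csv", index=False)
    logistic_table.to_csv(out_dir / "logistic.csv", index=False)
    correlations.to_csv(out_dir / "correlations.csv", index=False)

    manifest = {
        "taplab_version": __version__,
        "seed": seed,
        "n_boot": n_boot,
        "pd_group": asdict(pd_spec),
        "hc_group": asdict(hc_spec),
        "n_simulated": int(len(cohort)),
        "n_excluded_qc": int(len(excluded)),
        "omnibus_chi2": logit.omnibus_chi2,
        "omnibus_p": logit.omnibus_p,
        "cox_snell_r2": logit.cox_snell_r2,
        "nagelkerke_r2": logit.nagelkerke_r2,
        "pct_correct": logit.pct_correct,
        "logistic_converged": logit.converged,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    lines = [f"taplab cohort report (seed={seed})",
             f"subjects simulated: {len(cohort)}  (QC-excluded: {len(excluded)})", ""]
    for row in roc_rows:
        lines.append(f"  {row['feature']:<8s} AUC={row['auc']:.3f} "
                     f"[{row['ci_lo']:.3f}-{row['ci_hi']:.3f}] "
                     f"cutoff={row['cutoff']:.3f} acc={row['accuracy'] * 100:.1f}%")
    lines.append("")
    lines.append(f"logistic: omnibus chi2({logit.omnibus_df})={logit.omnibus_chi2:.2f} "
                 f"p={logit.omnibus_p:.4g}; Nagelkerke R2={logit.nagelkerke_r2:.3f}; "
                 f"correct={logit.pct_correct * 100:.1f}%")
    (out_dir / "summary.txt").write_text("\n".join(lines) + "\n")

    return {"cohort": cohort, "excluded": excluded, "group_tests": group_tests,
            "roc": roc, "logistic": logistic_table, "logistic_fit": logit,
            "correlations": correlations, "manifest": manifest}
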
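"""End-to-end pipeline: simulate -> PRS -> association -> meta -> ROC -> reclassification.

``run_pipeline`` executes the full analysis on the three simulated study
cohorts and writes five summary TSVs (per-SNP associations with the pooled
column; PRS associations with the pooled column; discrimination; the
reclassification block; per-individual PRS) plus ROC coordinates and a run
manifest.  All randomness flows from the single configured seed, and the
emitted files are byte-identical across runs with the same configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .assoc import SeparationError, prs_association, single_snp_association
from .discrim import MODEL_NAMES, build_model_suite, roc_coordinates
from .io import write_cohort_tsv
from .meta import dersimonian_laird
from .panel import SnpPanel, default_panel
from .prs import compute_prs
from .published import STUDY_SIZES
from .reclass import idi, nri_from_probabilities
from .synth import SCHEMES, simulate_three_studies

_FLOAT_FMT = "%.6g"


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str | Path = "melprs_out"
    panel: SnpPanel = field(default_factory=default_panel)
    sizes: dict[str, tuple[int, int]] = field(default_factory=lambda: dict(STUDY_SIZES))
    missing_policy: str = "mean"
    cutpoints: tuple[float, float] = (0.20, 0.50)
    index_snp: str = "rs12913832"
    pigmentation_r2: float = 0.03
    baseline_log_odds: float = -2.5

    def digest(self) -> str:
        payload = {
            "seed": self.seed,
            "sizes": {k: list(v) for k, v in self.sizes.items()},
            "missing_policy": self.missing_policy,
            "cutpoints": list(self.cutpoints),
            "index_snp": self.index_snp,
            "pigmentation_r2": self.pigmentation_r2,
            "baseline_log_odds": self.baseline_log_odds,
            "panel": self.panel.to_dicts(),
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def _estimate_row(study: str, label: str, est) -> dict:
    lo, hi = est.ci95
    return {
        "study": study,
        "label": label,
        "or": est.or_point,
        "ci_low": lo,
        "ci_high": hi,
        "p": est.p,
        "n_used": est.n_used,
        "model_spec": est.model_spec,
    }


def _meta_row(label: str, meta) -> dict:
    lo, hi = meta.ci95
    return {
        "study": "pooled",
        "label": label,
        "or": meta.pooled_or,
        "ci_low": lo,
        "ci_high": hi,
        "p": meta.p_pooled,
        "n_used": 0,
        "model_spec": f"DL random effects; Q={meta.q:.4f} p_Q={meta.p_q:.4f} I2={meta.i2:.2f}",
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns the results dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohorts = simulate_three_studies(
        config.seed,
        panel=config.panel,
        sizes=config.sizes,
        pigmentation_r2=config.pigmentation_r2,
        baseline_log_odds=config.baseline_log_odds,
    )
    prs_results = {}
    for scheme, cohort in cohorts.items():
        write_cohort_tsv(cohort, out / f"cohort_{scheme}.tsv")
        prs_results[scheme] = compute_prs(
            cohort[config.panel.snp_ids], config.panel, config.missing_policy
        )
        prs_results[scheme].to_frame().to_csv(
            out / f"prs_{scheme}.tsv", sep="\t", index=False, float_format=_FLOAT_FMT, na_rep="NA"
        )

    # --- per-SNP associations + pooled column (single-variant summary) ----
    snp_rows = []
    for snp in config.panel.snp_ids:
        effects = []
        for scheme in SCHEMES:
            try:
                est = single_snp_association(cohorts[scheme], snp, config.panel)
            except SeparationError as exc:
                raise RuntimeError(f"stage=association snp={snp} study={scheme}: {exc}") from exc
            snp_rows.append(_estimate_row(scheme, snp, est))
            effects.append(est.as_effect())
        snp_rows.append(_meta_row(snp, dersimonian_laird(effects)))
    pd.DataFrame(snp_rows).to_csv(
        out / "single_snp_associations.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )

    # --- PRS associations (continuous + tertile, both adjustments) --------
    prs_rows = []
    for form in ("continuous", "tertile31"):
        for adjust in (False, True):
            label = f"prs_{form}_{'multivariate' if adjust else 'univariate'}"
            effects = []
            for scheme in SCHEMES:
                est = prs_association(
                    cohorts[scheme], prs_results[scheme], form=form, adjust=adjust, scheme=scheme
                )
                prs_rows.append(_estimate_row(scheme, label, est))
                effects.append(est.as_effect())
            prs_rows.append(_meta_row(label, dersimonian_laird(effects)))
    # extreme-score groupings, discovery cohort only
    for form in ("band", "top5pct"):
        try:
            est = prs_association(
                cohorts["mdacc"], prs_results["mdacc"], form=form,
                adjust=(form == "top5pct"), scheme="mdacc",
            )
        except SeparationError as exc:
            # the >=15-allele band can be unpopulated under the default
            # risk-allele-frequency configuration; report, don't abort
            prs_rows.append(
                {"study": "mdacc", "label": f"prs_{form}", "or": float("nan"),
                 "ci_low": float("nan"), "ci_high": float("nan"), "p": float("nan"),
                 "n_used": 0, "model_spec": f"not estimable: {exc}"}
            )
            continue
        prs_rows.append(_estimate_row("mdacc", f"prs_{form}", est))
    pd.DataFrame(prs_rows).to_csv(
        out / "prs_associations.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )

    # --- discrimination suite on the discovery cohort ---------------------
    suite = build_model_suite(
        cohorts["mdacc"], prs_results["mdacc"], config.panel, index_snp=config.index_snp
    )
    contrasts = {
        "prs_only-single_snp": suite.contrast("single_snp", "prs_only"),
        "sex_age_pigment-sex_age": suite.contrast("sex_age", "sex_age_pigment"),
        "sex_age_pigment_prs-sex_age_pigment": suite.contrast(
            "sex_age_pigment", "sex_age_pigment_prs"
        ),
    }
    disc_rows = []
    for name in MODEL_NAMES:
        lo, hi = suite.auc_ci[name]
        disc_rows.append(
            {"model": name, "auc": suite.auc[name], "ci_low": lo, "ci_high": hi,
             "contrast": "", "delta_auc": "", "delta_p": ""}
        )
    for cname, c in contrasts.items():
        disc_rows.append(
            {"model": "", "auc": "", "ci_low": "", "ci_high": "", "contrast": cname,
             "delta_auc": c["delta_auc"], "delta_p": c["p"]}
        )
    pd.DataFrame(disc_rows).to_csv(
        out / "discrimination.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    for name in MODEL_NAMES:
        roc_coordinates(suite.probabilities[name], suite.outcome).to_csv(
            out / f"roc_{name}.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
        )

    # --- reclassification: phenotype model vs phenotype + PRS -------------
    p_old = suite.probabilities["sex_age_pigment"]
    p_new = suite.probabilities["sex_age_pigment_prs"]
    rr = nri_from_probabilities(p_old, p_new, suite.outcome, config.cutpoints)
    idi_val, idi_z, idi_p = idi(p_old, p_new, suite.outcome)
    reclass_rows = [
        {"quantity": "up_events", "value": rr.up_events},
        {"quantity": "down_events", "value": rr.down_events},
        {"quantity": "up_nonevents", "value": rr.up_nonevents},
        {"quantity": "down_nonevents", "value": rr.down_nonevents},
        {"quantity": "nri_events", "value": rr.nri_events},
        {"quantity": "nonevents_up_minus_down", "value": rr.nonevents_up_minus_down},
        {"quantity": "total_nri", "value": rr.total_nri},
        {"quantity": "p_nri", "value": rr.p_nri},
        {"quantity": "idi", "value": idi_val},
        {"quantity": "p_idi", "value": idi_p},
    ]
    pd.DataFrame(reclass_rows).to_csv(
        out / "reclassification.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )

    manifest = {
        "melprs_version": __version__,
        "seed": config.seed,
        "config_sha256": config.digest(),
        "outputs": sorted(p.name for p in out.glob("*.tsv")),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return {
        "cohorts": cohorts,
        "prs": prs_results,
        "suite": suite,
        "contrasts": contrasts,
        "reclassification": rr,
        "idi": (idi_val, idi_z, idi_p),
    }
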
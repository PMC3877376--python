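"""Synthetic case-control cohorts with the structure the pipeline assumes.

Genotypes are drawn independently per SNP under Hardy-Weinberg equilibrium
(two Bernoulli(p) draws summed), matching a panel chosen to be free of
linkage disequilibrium.  Disease follows an additive logistic model on the
dosages; cases and controls accrue by rejection sampling from that
population model, so fitted odds ratios are directly comparable to the
simulation truth (logistic ORs are invariant to outcome-dependent
sampling).

Three study templates mirror the real cohorts' structure: a case-control
discovery study with both sexes and full pigmentation phenotyping (mdacc),
an all-female prospective cohort with hair colour, tanning ability and
family history (nhs), and an all-male cohort with hair colour, eye colour
and family history (hpfs).  Pigmentation traits are cut from a latent
Gaussian "fairness" score that mixes a standardized-PRS component with
noise, calibrated so the squared correlation with the weighted PRS equals
``pigmentation_r2``; category marginals match the published control
distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .panel import SnpPanel, default_panel
from .prs import weighted_prs
from .published import STUDY_SIZES

SCHEMES = ("mdacc", "nhs", "hpfs")

# Covariates observed under each study template; anything else is missing.
SCHEME_COVARIATES: dict[str, tuple[str, ...]] = {
    "mdacc": ("sex", "age", "skin_color", "eye_color", "hair_color", "tanning"),
    "nhs": ("age", "hair_color", "tanning", "family_history"),
    "hpfs": ("age", "eye_color", "hair_color", "family_history"),
}

SKIN_LEVELS = ("light", "medium", "dark")
EYE_LEVELS = ("blue/gray", "hazel/green", "brown/black")
HAIR_LEVELS = ("blonde", "red", "brown", "black")
TANNING_LEVELS = ("practically_none", "light_tan", "average_tan", "deep_tan")

# Control-group category marginals per scheme, ordered fairest-first (the
# latent fairness score is cut at these cumulative proportions).
_PIGMENT_MARGINALS: dict[str, dict[str, tuple[float, ...]]] = {
    "mdacc": {
        "skin_color": (0.445, 0.478, 0.077),
        "eye_color": (0.341, 0.354, 0.305),
        "hair_color": (0.189, 0.037, 0.718, 0.056),
        "tanning": (0.117, 0.303, 0.314, 0.266),
    },
    "nhs": {
        "hair_color": (0.114, 0.034, 0.826, 0.026),
        "tanning": (0.074, 0.213, 0.463, 0.251),
    },
    "hpfs": {
        "eye_color": (0.358, 0.318, 0.324),
        "hair_color": (0.116, 0.026, 0.763, 0.094),
    },
}

_PIGMENT_LEVELS = {
    "skin_color": SKIN_LEVELS,
    "eye_color": EYE_LEVELS,
    "hair_color": HAIR_LEVELS,
    "tanning": TANNING_LEVELS,
}

# Age mean/sd (cases, controls) and family-history rates (cases, controls).
_AGE_PARAMS = {
    "mdacc": ((52.1, 14.5), (51.3, 12.6)),
    "nhs": ((56.8, 6.8), (57.2, 6.7)),
    "hpfs": ((61.2, 9.3), (61.3, 8.5)),
}
_FAMHIST_RATES = {"nhs": (0.199, 0.079), "hpfs": (0.124, 0.049)}
_MALE_PROB_MDACC = (0.587, 0.598)  # cases, controls

COVARIATE_COLUMNS = (
    "sex",
    "age",
    "skin_color",
    "eye_color",
    "hair_color",
    "tanning",
    "family_history",
)


@dataclass
class CohortConfig:
    """Parameters for one simulated case-control cohort."""

    n_cases: int
    n_controls: int
    panel: SnpPanel = field(default_factory=default_panel)
    per_snp_log_or: np.ndarray | None = None  # defaults to the panel weights
    baseline_log_odds: float = -2.5
    covariate_scheme: str = "mdacc"
    pigmentation_r2: float = 0.03
    seed: int = 0
    max_attempts: int = 500  # multiples of (n_cases + n_controls) drawn before failing

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("n_cases and n_controls must be >= 1")
        if self.covariate_scheme not in SCHEMES:
            raise ValueError(f"unknown covariate scheme {self.covariate_scheme!r}")
        if not (0.0 <= self.pigmentation_r2 <= 0.05):
            raise ValueError("pigmentation_r2 must lie in [0, 0.05]")
        if self.per_snp_log_or is None:
            self.per_snp_log_or = np.asarray(self.panel.weights, dtype=float)
        else:
            self.per_snp_log_or = np.asarray(self.per_snp_log_or, dtype=float)
            if self.per_snp_log_or.shape != (len(self.panel),):
                raise ValueError("per_snp_log_or length must match the panel")


def simulate_genotypes(
    panel: SnpPanel, n: int, seed: int | np.random.Generator
) -> pd.DataFrame:
    """HWE dosages: each SNP is the sum of two Bernoulli(freq) draws.

    SNPs are mutually independent (no linkage disequilibrium by design).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = np.asarray(panel.freqs, dtype=float)
    dosages = rng.binomial(2, p, size=(n, len(panel)))
    return pd.DataFrame(dosages, columns=panel.snp_ids)


def _cut_latent(latent: np.ndarray, marginals: tuple[float, ...], levels: tuple[str, ...]) -> pd.Categorical:
    """Assign categories by cutting a ~N(0,1) latent at fixed quantiles.

    ``marginals`` are the target proportions ordered fairest-first; the
    fairest category is the *upper* tail of the latent fairness score.
    """
    cum = np.cumsum(marginals)
    cum = cum / cum[-1]
    # upper-tail thresholds: the fairest category occupies the top marginals[0]
    thresholds = norm.ppf(1.0 - cum[:-1])  # strictly decreasing
    idx = np.searchsorted(-thresholds, -latent, side="right")
    return pd.Categorical(np.array(levels, dtype=object)[idx], categories=list(levels))


def _pigment_latent(
    z_prs: np.ndarray, r2: float, rng: np.random.Generator
) -> np.ndarray:
    a = math.sqrt(r2)
    return a * z_prs + math.sqrt(1.0 - r2) * rng.standard_normal(z_prs.shape[0])


def _generate_covariates(
    df: pd.DataFrame, config: CohortConfig, rng: np.random.Generator
) -> pd.DataFrame:
    scheme = config.covariate_scheme
    observed = SCHEME_COVARIATES[scheme]
    n = len(df)
    case = df["case"].to_numpy()

    out = {}
    # sex is always recorded: mixed in mdacc, constant in the single-sex cohorts
    if scheme == "mdacc":
        p_male = np.where(case == 1, _MALE_PROB_MDACC[0], _MALE_PROB_MDACC[1])
        sexes = np.where(rng.random(n) < p_male, "male", "female")
    else:
        sexes = np.repeat("female" if scheme == "nhs" else "male", n)
    out["sex"] = pd.Categorical(sexes, categories=["female", "male"])

    (mu_ca, sd_ca), (mu_co, sd_co) = _AGE_PARAMS[scheme]
    mu = np.where(case == 1, mu_ca, mu_co)
    sd = np.where(case == 1, sd_ca, sd_co)
    out["age"] = np.clip(np.round(mu + sd * rng.standard_normal(n), 1), 18.0, 95.0)

    score, _ = weighted_prs(df[config.panel.snp_ids], config.panel, "mean")
    z = score.to_numpy()
    z = (z - z.mean()) / (z.std() if z.std() > 0 else 1.0)
    for trait, marg in _PIGMENT_MARGINALS[scheme].items():
        latent = _pigment_latent(z, config.pigmentation_r2, rng)
        out[trait] = _cut_latent(latent, marg, _PIGMENT_LEVELS[trait])

    if "family_history" in observed:
        r_ca, r_co = _FAMHIST_RATES[scheme]
        rate = np.where(case == 1, r_ca, r_co)
        out["family_history"] = pd.array((rng.random(n) < rate).astype(int), dtype="Int64")

    cov = pd.DataFrame(out, index=df.index)
    for col in COVARIATE_COLUMNS:
        # covariates absent under this scheme are explicitly missing (sex
        # is always recorded, even where it is constant)
        if col not in observed and col != "sex":
            cov[col] = pd.NA
    return cov[list(COVARIATE_COLUMNS)]


def simulate_case_control(config: CohortConfig) -> pd.DataFrame:
    """One cohort with exactly ``n_cases`` cases and ``n_controls`` controls.

    Disease probability per individual is
    ``logistic(baseline_log_odds + Σ_j per_snp_log_or_j * dosage_j)``;
    batches are drawn from the population model until both groups fill.
    Raises ``RuntimeError`` if the target counts are unattainable within
    ``config.max_attempts * (n_cases + n_controls)`` population draws.
    """
    rng = np.random.default_rng(config.seed)
    beta = config.per_snp_log_or
    n_total = config.n_cases + config.n_controls
    budget = config.max_attempts * n_total

    cases, controls = [], []
    drawn = 0
    batch = max(1024, n_total)
    while (
        sum(len(x) for x in cases) < config.n_cases
        or sum(len(x) for x in controls) < config.n_controls
    ):
        if drawn >= budget:
            raise RuntimeError(
                f"could not accrue {config.n_cases} cases / {config.n_controls} controls "
                f"within {budget} draws (baseline_log_odds={config.baseline_log_odds}); "
                "adjust the baseline or raise max_attempts"
            )
        g = simulate_genotypes(config.panel, batch, rng)
        p = expit(config.baseline_log_odds + g.to_numpy() @ beta)
        y = rng.random(batch) < p
        drawn += batch
        cases.append(g[y])
        controls.append(g[~y])

    case_df = pd.concat(cases, ignore_index=True).iloc[: config.n_cases]
    ctrl_df = pd.concat(controls, ignore_index=True).iloc[: config.n_controls]
    df = pd.concat([case_df, ctrl_df], ignore_index=True)
    df.insert(0, "case", np.r_[np.ones(config.n_cases, int), np.zeros(config.n_controls, int)])
    df.insert(0, "study", config.covariate_scheme)

    cov = _generate_covariates(df, config, rng)
    for col in cov.columns:
        df[col] = cov[col]
    # column order: study, case, covariates, dosages
    return df[["study", "case", *COVARIATE_COLUMNS, *config.panel.snp_ids]]


def simulate_three_studies(
    master_seed: int,
    panel: SnpPanel | None = None,
    sizes: dict[str, tuple[int, int]] | None = None,
    pigmentation_r2: float = 0.03,
    baseline_log_odds: float = -2.5,
) -> dict[str, pd.DataFrame]:
    """The three-study ensemble with default sizes 1804/1025, 317/3376, 177/2251.

    Per-study seeds are derived deterministically from ``master_seed`` via
    ``numpy.random.SeedSequence`` spawning, so the ensemble is reproducible
    from the single seed.
    """
    panel = panel if panel is not None else default_panel()
    sizes = sizes if sizes is not None else STUDY_SIZES
    children = np.random.SeedSequence(master_seed).spawn(len(SCHEMES))
    out: dict[str, pd.DataFrame] = {}
    for scheme, ss in zip(SCHEMES, children):
        n_cases, n_controls = sizes[scheme]
        cfg = CohortConfig(
            n_cases=n_cases,
            n_controls=n_controls,
            panel=panel,
            baseline_log_odds=baseline_log_odds,
            covariate_scheme=scheme,
            pigmentation_r2=pigmentation_r2,
            seed=int(ss.generate_state(1)[0] % (2**31)),
        )
        out[scheme] = simulate_case_control(cfg)
    return out
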
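"""Two-sample GWAS summary-statistic simulator with known ground truth.

The generator realizes the pleiotropy structures that motivate the analysis:

* ``V`` (vertical): every SNP affects the outcome only through the exposure
  (beta_zy = theta * gamma_j) — the valid-instrument benchmark.
* ``H-directional`` / ``H-balanced`` (horizontal): a fraction of SNPs carries
  a direct outcome effect alpha_j drawn independently of gamma_j (InSIDE
  holds); directional pleiotropy has E[alpha] != 0.
* ``C-inside-violation``: alpha_j correlated with gamma_j (corr = rho).
* ``TRIANGLE``: an education-like exposure, a bipolar-like confounder with
  its own SNP set feeding both the exposure and a schizophrenia-like
  outcome — the structure under which a univariable analysis shows a
  spurious exposure effect that multivariable adjustment removes.

Everything is simulated at the summary level: true per-SNP effects gamma_j
are drawn as |Normal(0, gamma_sd^2)| (instruments coded so the effect allele
increases the exposure, the convention under which "directional" pleiotropy
is directional), standard errors follow the single-SNP regression form
se = 1/sqrt(2 eaf (1-eaf) n), and observed betas add independent noise per
study (non-overlapping samples).  Binary outcomes use the same normal
sampling model on the log-odds scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .summary_io import GwasSummaryTable, write_summary_table

SCENARIOS = ("V", "H-directional", "H-balanced", "C-inside-violation",
             "TRIANGLE")

#: non-palindromic allele pairs used for simulated variants
_ALLELE_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"))


@dataclass(frozen=True)
class ScenarioConfig:
    """Generative parameters for one pleiotropy-DAG simulation.

    ``theta`` is the causal effect of exposure on outcome; for TRIANGLE it
    is the arrow triple (direct exposure->outcome, confounder->exposure,
    confounder->outcome) and for bidirectional use it is (theta_ab,
    theta_ba).  ``k`` counts SNPs per core instrument set.  Defaults are the
    package's reference study conditions: 50 strong instruments measured in
    samples of 50,000.
    """

    scenario: str = "V"
    k: int = 50
    theta: float | tuple = 0.3
    gamma_sd: float = 0.2
    alpha_mean: float = 0.05
    alpha_sd: float = 0.02
    prop_invalid: float = 0.4
    rho: float = 0.5
    n_exp: int = 50_000
    n_out: int = 50_000
    maf_range: tuple[float, float] = (0.1, 0.5)
    binary_outcome: bool = False
    flip_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ConfigurationError(f"unknown scenario {self.scenario!r}")
        if self.k < 3:
            raise ConfigurationError("k must be >= 3")
        if self.n_exp <= 0 or self.n_out <= 0:
            raise ConfigurationError("sample sizes must be positive")
        if abs(self.rho) > 1:
            raise ConfigurationError("|rho| must be <= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        if not 0 <= self.prop_invalid <= 1:
            raise ConfigurationError("prop_invalid must lie in [0,1]")
        if not 0 <= self.flip_fraction <= 1:
            raise ConfigurationError("flip_fraction must lie in [0,1]")


@dataclass
class GroundTruth:
    """True generative quantities backing parameter-recovery tests."""

    scenario: str
    seed: int
    theta: dict
    gamma: dict
    alpha: np.ndarray | None = None
    invalid: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, dict):
                return {k: conv(v) for k, v in x.items()}
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            return x
        return json.dumps({k: conv(v) for k, v in self.__dict__.items()},
                          indent=1)


def _se_from_freq(eaf: np.ndarray, n: int) -> np.ndarray:
    """Standard error of a per-allele regression coefficient on a
    standardized trait: 1/sqrt(2 eaf (1-eaf) n)."""
    return 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n)


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return np.clip(p, np.nextafter(0, 1), 1.0)


def _make_table(rng: np.random.Generator, trait_id: str, trait_type: str,
                rsids: Sequence[str], alleles: np.ndarray, eaf: np.ndarray,
                true_beta: np.ndarray, n: int,
                flip_fraction: float = 0.0) -> GwasSummaryTable:
    se = _se_from_freq(eaf, n)
    beta = rng.normal(true_beta, se)
    ea, oa = alleles[:, 0].copy(), alleles[:, 1].copy()
    eaf = eaf.copy()
    if flip_fraction > 0:
        # report some SNPs on the opposite effect allele; harmonization
        # must undo this
        flip = rng.random(len(rsids)) < flip_fraction
        ea[flip], oa[flip] = alleles[flip, 1], alleles[flip, 0]
        beta = np.where(flip, -beta, beta)
        eaf = np.where(flip, 1.0 - eaf, eaf)
    data = pd.DataFrame({
        "rsid": rsids, "effect_allele": ea, "other_allele": oa,
        "eaf": eaf, "beta": beta, "se": se, "pval": _pvals(beta, se),
        "n": float(n)})
    return GwasSummaryTable(trait_id=trait_id, trait_type=trait_type,
                            data=data, sample_n=n)


def _panel(rng: np.random.Generator, k: int, maf_range: tuple[float, float],
           prefix: str = "rs") -> tuple[list[str], np.ndarray, np.ndarray]:
    rsids = [f"{prefix}{i + 1:06d}" for i in range(k)]
    alleles = np.array([_ALLELE_PAIRS[i] for i in
                        rng.integers(0, len(_ALLELE_PAIRS), k)])
    eaf = rng.uniform(*maf_range, k)
    return rsids, alleles, eaf


def _gammas(rng: np.random.Generator, k: int, sd: float) -> np.ndarray:
    return np.abs(rng.normal(0.0, sd, k))


def simulate_pair(config: ScenarioConfig) -> tuple[GwasSummaryTable,
                                                   GwasSummaryTable,
                                                   GroundTruth]:
    """One exposure/outcome pair under scenario V, H-*, or C."""
    if config.scenario == "TRIANGLE":
        raise ConfigurationError("use simulate_triangle for scenario TRIANGLE")
    rng = np.random.default_rng(config.seed)
    k = config.k
    rsids, alleles, eaf = _panel(rng, k, config.maf_range)
    gamma = _gammas(rng, k, config.gamma_sd)
    alpha = np.zeros(k)
    invalid = np.zeros(k, dtype=bool)
    m = int(round(config.prop_invalid * k))
    if config.scenario in ("H-directional", "H-balanced") and m:
        invalid[rng.choice(k, size=m, replace=False)] = True
        mean = config.alpha_mean if config.scenario == "H-directional" else 0.0
        alpha[invalid] = rng.normal(mean, config.alpha_sd, m)
    elif config.scenario == "C-inside-violation":
        invalid[:] = True
        z_g = (gamma - gamma.mean()) / (gamma.std() or 1.0)
        z_e = rng.normal(0.0, 1.0, k)
        mix = config.rho * z_g + np.sqrt(1 - config.rho ** 2) * z_e
        alpha = config.alpha_mean + config.alpha_sd * mix
    theta = float(config.theta)
    exposure = _make_table(rng, "exposure", "continuous", rsids, alleles, eaf,
                           gamma, config.n_exp, config.flip_fraction)
    outcome = _make_table(rng, "outcome",
                          "binary" if config.binary_outcome else "continuous",
                          rsids, alleles, eaf, theta * gamma + alpha,
                          config.n_out, config.flip_fraction)
    truth = GroundTruth(scenario=config.scenario, seed=config.seed,
                        theta={"exposure": theta},
                        gamma={"exposure": gamma}, alpha=alpha,
                        invalid=invalid)
    return exposure, outcome, truth


#: TRIANGLE arrows: (direct exposure->outcome, confounder->exposure,
#: confounder->outcome)
TRIANGLE_THETA = (0.0, 0.4, 0.5)


def simulate_triangle(config: ScenarioConfig) -> tuple[GwasSummaryTable,
                                                       GwasSummaryTable,
                                                       GwasSummaryTable,
                                                       GroundTruth]:
    """Confounding triangle: exposure, confounder, outcome tables.

    The confounder (bipolar-like) has its own k SNPs feeding the
    education-like exposure (arrow delta1) and the schizophrenia-like
    outcome (delta2); the exposure has k further SNPs of its own with direct
    outcome effect theta1 (0 by default).  Instruments selected from the
    exposure table alone pick up confounder-driven SNPs, creating the
    spurious univariable association that multivariable adjustment removes.
    """
    if config.scenario != "TRIANGLE":
        config = replace(config, scenario="TRIANGLE")
    theta = config.theta if isinstance(config.theta, tuple) else TRIANGLE_THETA
    theta1, delta1, delta2 = (float(t) for t in theta)
    rng = np.random.default_rng(config.seed)
    k = config.k
    rsids_c, alleles_c, eaf_c = _panel(rng, k, config.maf_range, "rsC")
    rsids_e, alleles_e, eaf_e = _panel(rng, k, config.maf_range, "rsE")
    gamma_c = _gammas(rng, k, config.gamma_sd)
    gamma_e = _gammas(rng, k, config.gamma_sd)
    rsids = rsids_c + rsids_e
    alleles = np.vstack([alleles_c, alleles_e])
    eaf = np.concatenate([eaf_c, eaf_e])
    beta_exposure = np.concatenate([delta1 * gamma_c, gamma_e])
    beta_confounder = np.concatenate([gamma_c, np.zeros(k)])
    beta_outcome = np.concatenate([(theta1 * delta1 + delta2) * gamma_c,
                                   theta1 * gamma_e])
    exposure = _make_table(rng, "education", "continuous", rsids, alleles,
                           eaf, beta_exposure, config.n_exp,
                           config.flip_fraction)
    confounder = _make_table(rng, "bipolar", "continuous", rsids, alleles,
                             eaf, beta_confounder, config.n_exp,
                             config.flip_fraction)
    outcome = _make_table(rng, "schizophrenia",
                          "binary" if config.binary_outcome else "continuous",
                          rsids, alleles, eaf, beta_outcome, config.n_out,
                          config.flip_fraction)
    truth = GroundTruth(scenario="TRIANGLE", seed=config.seed,
                        theta={"direct_exposure": theta1,
                               "confounder_to_exposure": delta1,
                               "confounder_to_outcome": delta2},
                        gamma={"confounder": gamma_c, "exposure": gamma_e})
    return exposure, confounder, outcome, truth


#: default mutual-causation coefficients (trait A -> B, trait B -> A)
BIDIRECTIONAL_THETA = (0.45, 0.3)


def simulate_bidirectional(config: ScenarioConfig) -> tuple[GwasSummaryTable,
                                                            GwasSummaryTable,
                                                            GroundTruth]:
    """Two traits with mutual causation and disjoint core SNP sets.

    Each trait's summary betas include the other's transmitted signal
    (one-step transmission), so a strong SNP can reach genome-wide
    significance for both traits; the ground truth flags such SNPs for
    overlap-exclusion tests.
    """
    theta = (config.theta if isinstance(config.theta, tuple)
             else BIDIRECTIONAL_THETA)
    theta_ab, theta_ba = (float(t) for t in theta)
    rng = np.random.default_rng(config.seed)
    k = config.k
    rsids_a, alleles_a, eaf_a = _panel(rng, k, config.maf_range, "rsA")
    rsids_b, alleles_b, eaf_b = _panel(rng, k, config.maf_range, "rsB")
    gamma_a = _gammas(rng, k, config.gamma_sd)
    gamma_b = _gammas(rng, k, config.gamma_sd)
    rsids = rsids_a + rsids_b
    alleles = np.vstack([alleles_a, alleles_b])
    eaf = np.concatenate([eaf_a, eaf_b])
    beta_a = np.concatenate([gamma_a, theta_ba * gamma_b])
    beta_b = np.concatenate([theta_ab * gamma_a, gamma_b])
    table_a = _make_table(rng, "trait_a", "continuous", rsids, alleles, eaf,
                          beta_a, config.n_exp, config.flip_fraction)
    table_b = _make_table(rng, "trait_b", "continuous", rsids, alleles, eaf,
                          beta_b, config.n_out, config.flip_fraction)
    z = stats.norm.isf(2.5e-8)  # genome-wide threshold on the true effects
    gws_a = np.abs(beta_a) / _se_from_freq(eaf, config.n_exp) > z
    gws_b = np.abs(beta_b) / _se_from_freq(eaf, config.n_out) > z
    truth = GroundTruth(scenario="BIDIRECTIONAL", seed=config.seed,
                        theta={"a_on_b": theta_ab, "b_on_a": theta_ba},
                        gamma={"trait_a": gamma_a, "trait_b": gamma_b},
                        extras={"significant_both":
                                [r for r, f in zip(rsids, gws_a & gws_b) if f]})
    return table_a, table_b, truth


def write_fixture(tables: Sequence[GwasSummaryTable], truth: GroundTruth,
                  out_dir: str | Path) -> None:
    """Write summary TSVs plus a ground-truth JSON into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for table in tables:
        write_summary_table(table, out_dir / f"{table.trait_id}.tsv")
    (out_dir / "truth.json").write_text(truth.to_json())
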
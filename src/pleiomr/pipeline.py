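"""Orchestration of univariable, multivariable, and bidirectional MR tests.

A test plan is an ordered batch (the study design here comprises 14 such
tests): each univariable test runs instrument selection, harmonization,
radial outlier removal, heterogeneity diagnostics, the IVW estimate, and the
full sensitivity battery (MR-Egger, SIMEX-corrected Egger, weighted median,
weighted mode); multivariable tests report per-exposure direct effects;
bidirectional tests exclude shared/LD-linked instruments before estimating
both directions.  Raw IVW p-values across the batch receive a
Benjamini-Hochberg FDR adjustment.  Individual test failures are recorded
and never abort the batch.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from statsmodels.stats.multitest import multipletests

from . import __version__
from .errors import PleiomrError, ConfigurationError
from .estimators import (MrEstimate, egger, ivw, mv_ivw, simex_egger,
                         weighted_median, weighted_mode)
from .instruments import (InstrumentDiagnostics, LdMatrix, cochran_q,
                          exclude_overlap, instrument_strength,
                          radial_outliers, select_instrument)
from .summary_io import (GwasSummaryTable, HarmonizedSet, build_mv_set,
                         harmonize, read_summary_table, results_frame)


@dataclass(frozen=True)
class MrOptions:
    """Global analysis options shared by all tests in a plan."""

    p_threshold: float = 5e-8
    r2_threshold: float = 0.01
    ld: LdMatrix | None = None
    palindrome_policy: str = "infer_by_eaf"
    eaf_ambiguity_band: tuple[float, float] = (0.42, 0.58)
    ivw_model: str = "multiplicative_random"
    radial_alpha: float = 0.05
    radial_correction: str = "bonferroni"
    remove_outliers: bool = True
    run_sensitivity: bool = True
    simex_lambda_grid: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5, 2.0)
    simex_reps: int = 1000
    n_boot: int = 1000
    seed: int = 0


@dataclass
class TestReport:
    """One MR test's diagnostics, estimates, and multiplicity-adjusted p."""

    test_id: str
    test_type: str
    exposure_ids: list[str]
    outcome_id: str
    diagnostics: InstrumentDiagnostics | None = None
    estimates: list[MrEstimate] = field(default_factory=list)
    harmonized: HarmonizedSet | None = None
    concordance_flag: bool | None = None
    raw_pval: float | None = None
    fdr_pval: float | None = None
    error: str | None = None

    @property
    def failed(self) -> bool:
        return self.error is not None

    def estimate(self, method: str, exposure_id: str | None = None) -> MrEstimate | None:
        for e in self.estimates:
            if e.method == method and (exposure_id is None
                                       or e.exposure_id == exposure_id):
                return e
        return None


def _concordant(estimates: list[MrEstimate]) -> bool | None:
    ref = next((e for e in estimates if e.method == "ivw"), None)
    if ref is None:
        return None
    others = [e for e in estimates
              if e.method not in ("ivw",) and e.beta is not None]
    return all(np.sign(e.beta) == np.sign(ref.beta) for e in others)


def run_univariable(exposure: GwasSummaryTable, outcome: GwasSummaryTable,
                    options: MrOptions | None = None,
                    test_id: str | None = None,
                    snps: Sequence[str] | None = None) -> TestReport:
    """Select -> harmonize -> outlier-remove -> estimate, with the battery.

    ``snps`` injects a pre-selected instrument (used by the bidirectional
    driver after overlap exclusion).  Failures are captured on the report.
    """
    opt = options or MrOptions()
    report = TestReport(
        test_id=test_id or f"{exposure.trait_id}->{outcome.trait_id}",
        test_type="univariable",
        exposure_ids=[exposure.trait_id], outcome_id=outcome.trait_id)
    try:
        if snps is None:
            snps = select_instrument(exposure, opt.p_threshold, opt.ld,
                                     opt.r2_threshold)
        h = harmonize(exposure, outcome, snps, opt.palindrome_policy,
                      opt.eaf_ambiguity_band)
        if opt.remove_outliers and h.k >= 3:
            out = radial_outliers(h, opt.radial_alpha, opt.radial_correction)
            if out:
                h = h.without(out)
        report.harmonized = h
        per_snp_n = h.rows["rsid"].map(
            exposure.data.set_index("rsid")["n"]).to_numpy(dtype=float)
        n_exp = (float(np.nanmedian(per_snp_n))
                 if np.isfinite(per_snp_n).any() else float(exposure.sample_n))
        diag = instrument_strength(h.beta_zx, h.se_zx,
                                   h.eaf_exposure, n_exp, h.k)
        if h.k >= 2:
            diag.q_stat, diag.q_df, diag.q_pval = cochran_q(h)
        if opt.remove_outliers and h.k >= 3:
            diag.outlier_rsids = sorted(
                h.table.loc[h.table["action"] == "dropped-outlier", "rsid"])
        report.diagnostics = diag
        estimates = [ivw(h, model=opt.ivw_model)]
        if opt.run_sensitivity and h.k >= 3:
            estimates.append(egger(h))
            estimates.append(simex_egger(h, opt.simex_lambda_grid,
                                         opt.simex_reps, seed=opt.seed))
            estimates.append(weighted_median(h, opt.n_boot, seed=opt.seed))
            estimates.append(weighted_mode(h, n_boot=opt.n_boot, seed=opt.seed))
        report.estimates = estimates
        report.concordance_flag = _concordant(estimates)
        report.raw_pval = estimates[0].pval
    except PleiomrError as exc:
        report.error = f"{type(exc).__name__}: {exc}"
    return report


def run_multivariable(exposures: Sequence[GwasSummaryTable],
                      outcome: GwasSummaryTable,
                      options: MrOptions | None = None,
                      test_id: str | None = None) -> TestReport:
    """Union instrument across exposures, joint harmonization, mv-IVW.

    The first exposure is the focal one; its direct-effect p-value is the
    test's raw p for the FDR step.
    """
    opt = options or MrOptions()
    if len(exposures) < 2:
        raise ConfigurationError("multivariable test needs >= 2 exposures")
    ids = [t.trait_id for t in exposures]
    report = TestReport(
        test_id=test_id or f"{'+'.join(ids)}->{outcome.trait_id}",
        test_type="multivariable", exposure_ids=ids,
        outcome_id=outcome.trait_id)
    try:
        union: list[str] = []
        for t in exposures:
            for rsid in select_instrument(t, opt.p_threshold, opt.ld,
                                          opt.r2_threshold):
                if rsid not in union and rsid in exposures[0].rsids:
                    union.append(rsid)
        m = build_mv_set(exposures, outcome, union, opt.palindrome_policy,
                         opt.eaf_ambiguity_band)
        report.estimates = mv_ivw(m)
        report.raw_pval = report.estimates[0].pval
    except PleiomrError as exc:
        report.error = f"{type(exc).__name__}: {exc}"
    return report


def run_bidirectional(trait_a: GwasSummaryTable, trait_b: GwasSummaryTable,
                      options: MrOptions | None = None,
                      test_id: str | None = None) -> tuple[TestReport, TestReport]:
    """Both causal directions after excluding shared/LD-linked instruments."""
    opt = options or MrOptions()
    stem = test_id or f"{trait_a.trait_id}<->{trait_b.trait_id}"
    try:
        instr_a = select_instrument(trait_a, opt.p_threshold, opt.ld,
                                    opt.r2_threshold)
        instr_b = select_instrument(trait_b, opt.p_threshold, opt.ld,
                                    opt.r2_threshold)
        instr_a, instr_b = exclude_overlap(instr_a, instr_b, opt.ld,
                                           opt.r2_threshold)
    except PleiomrError as exc:
        failed = TestReport(test_id=stem, test_type="bidirectional",
                            exposure_ids=[trait_a.trait_id],
                            outcome_id=trait_b.trait_id,
                            error=f"{type(exc).__name__}: {exc}")
        return failed, replace_report_direction(failed, trait_b, trait_a)
    rep_ab = run_univariable(trait_a, trait_b, opt,
                             test_id=f"{stem}:forward", snps=instr_a)
    rep_ba = run_univariable(trait_b, trait_a, opt,
                             test_id=f"{stem}:reverse", snps=instr_b)
    rep_ab.test_type = rep_ba.test_type = "bidirectional"
    return rep_ab, rep_ba


def replace_report_direction(report: TestReport, a: GwasSummaryTable,
                             b: GwasSummaryTable) -> TestReport:
    return TestReport(test_id=report.test_id, test_type=report.test_type,
                      exposure_ids=[a.trait_id], outcome_id=b.trait_id,
                      error=report.error)


def fdr_adjust(reports: Sequence[TestReport]) -> Sequence[TestReport]:
    """Benjamini-Hochberg adjustment over the tests' raw IVW p-values."""
    idx = [i for i, r in enumerate(reports) if r.raw_pval is not None]
    if not idx:
        return reports
    raw = [reports[i].raw_pval for i in idx]
    _, adj, _, _ = multipletests(raw, method="fdr_bh")
    for i, p in zip(idx, adj):
        reports[i].fdr_pval = float(p)
    return reports


# ---------------------------------------------------------------------------
# batch plans

@dataclass
class AnalysisPlan:
    """Declarative batch: registered summary tables plus an ordered test list.

    ``tables`` maps trait id -> GwasSummaryTable; each test spec is a dict
    with ``id``, ``type`` (univariable | multivariable | bidirectional) and
    trait references (``exposure``/``exposures``/``outcome`` or
    ``trait_a``/``trait_b``).
    """

    tables: dict[str, GwasSummaryTable]
    tests: list[dict]
    options: MrOptions = field(default_factory=MrOptions)

    def __post_init__(self):
        if not self.tests:
            raise ConfigurationError("plan contains no tests")
        ids = [t.get("id") for t in self.tests]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("test ids must be unique")
        for t in self.tests:
            for trait in self._traits_of(t):
                if trait not in self.tables:
                    raise ConfigurationError(
                        f"test {t.get('id')!r} references unregistered "
                        f"trait {trait!r}")

    @staticmethod
    def _traits_of(t: dict) -> list[str]:
        kind = t.get("type")
        if kind == "univariable":
            return [t["exposure"], t["outcome"]]
        if kind == "multivariable":
            return [*t["exposures"], t["outcome"]]
        if kind == "bidirectional":
            return [t["trait_a"], t["trait_b"]]
        raise ConfigurationError(f"unknown test type {kind!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisPlan":
        spec = yaml.safe_load(Path(path).read_text())
        tables = {}
        for tid, meta in spec.get("tables", {}).items():
            tables[tid] = read_summary_table(
                meta["path"], meta.get("columns"), trait_id=tid,
                trait_type=meta.get("trait_type", "continuous"),
                sample_n=meta.get("sample_n"))
        opts = MrOptions(**spec.get("options", {}))
        return cls(tables=tables, tests=spec.get("tests", []), options=opts)


def run_plan(plan: AnalysisPlan, out_dir: str | Path | None = None) -> list[TestReport]:
    """Execute every test, FDR-adjust, and render the report tables."""
    reports: list[TestReport] = []
    for t in plan.tests:
        kind, tid = t["type"], t.get("id")
        opt = plan.options
        if t.get("seed") is not None:
            opt = replace(opt, seed=int(t["seed"]))
        if kind == "univariable":
            reports.append(run_univariable(plan.tables[t["exposure"]],
                                           plan.tables[t["outcome"]],
                                           opt, test_id=tid))
        elif kind == "multivariable":
            reports.append(run_multivariable(
                [plan.tables[e] for e in t["exposures"]],
                plan.tables[t["outcome"]], opt, test_id=tid))
        elif kind == "bidirectional":
            reports.extend(run_bidirectional(plan.tables[t["trait_a"]],
                                             plan.tables[t["trait_b"]],
                                             opt, test_id=tid))
    fdr_adjust(reports)
    if out_dir is not None:
        write_report_tables(reports, plan, Path(out_dir))
    return reports


def report_table(reports: Sequence[TestReport]) -> pd.DataFrame:
    """Long-format battery table: one row per test x estimator."""
    frames = []
    for r in reports:
        if not r.estimates:
            frames.append(pd.DataFrame([{"test_id": r.test_id,
                                         "test_type": r.test_type,
                                         "error": r.error}]))
            continue
        df = results_frame(r.estimates)
        df.insert(0, "test_id", r.test_id)
        df.insert(1, "test_type", r.test_type)
        df["concordant"] = r.concordance_flag
        df["raw_pval"] = r.raw_pval
        df["fdr_pval"] = r.fdr_pval
        if r.diagnostics is not None:
            df["f_stat"] = r.diagnostics.f_stat
            df["instrument_r2"] = r.diagnostics.r2
            df["weak_instrument"] = r.diagnostics.weak
            df["q_pval"] = r.diagnostics.q_pval
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def comparison_table(reports: Sequence[TestReport]) -> pd.DataFrame:
    """Total (univariable) vs direct (multivariable) effects per
    exposure/outcome pair appearing in both kinds of test."""
    total = {}
    for r in reports:
        if r.test_type in ("univariable", "bidirectional") and not r.failed:
            e = r.estimate("ivw") or r.estimate("wald_ratio")
            if e is not None:
                total[(e.exposure_id, e.outcome_id)] = e
    rows = []
    for r in reports:
        if r.test_type != "multivariable" or r.failed:
            continue
        for e in r.estimates:
            t = total.get((e.exposure_id, e.outcome_id))
            rows.append({
                "exposure": e.exposure_id, "outcome": e.outcome_id,
                "adjusted_for": ",".join(e.info.get("adjusted_for", [])),
                "total_beta": t.beta if t else np.nan,
                "total_ci_low": t.ci_low if t else np.nan,
                "total_ci_high": t.ci_high if t else np.nan,
                "direct_beta": e.beta, "direct_ci_low": e.ci_low,
                "direct_ci_high": e.ci_high, "direct_pval": e.pval})
    return pd.DataFrame(rows)


def write_report_tables(reports: Sequence[TestReport], plan: AnalysisPlan,
                        out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    full = report_table(reports)
    uni = full[full["test_type"] == "univariable"]
    bidi = full[full["test_type"] == "bidirectional"]
    fmt = dict(sep="\t", index=False, float_format="%.6g")
    uni.to_csv(out_dir / "univariable_report.tsv", **fmt)
    bidi.to_csv(out_dir / "bidirectional_report.tsv", **fmt)
    comparison_table(reports).to_csv(
        out_dir / "univariable_vs_multivariable.tsv", **fmt)
    full.to_csv(out_dir / "all_tests.tsv", **fmt)
    log = {"pleiomr_version": __version__,
           "python": platform.python_version(),
           "numpy": np.__version__, "pandas": pd.__version__,
           "seed": plan.options.seed,
           "options": {k: v for k, v in plan.options.__dict__.items()
                       if k != "ld"},
           "tests": [t.get("id") for t in plan.tests]}
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=1,
                                                     default=str))
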
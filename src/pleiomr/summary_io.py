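"""GWAS summary-statistics tables, allele harmonization, and result serialization.

Two-sample Mendelian randomization consumes per-SNP association estimates for an
exposure and an outcome measured in non-overlapping samples.  This module reads
and validates such tables, aligns the outcome rows to the exposure's effect
alleles (harmonization, including strand complements and palindromic A/T-C/G
variants), and writes the estimator results in a flat report table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyInputError, EmptyInstrumentError

#: two-sided 95% normal quantile used for every confidence interval
Z95 = 1.959964

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
VALID_ALLELES = frozenset("ACGT")

#: canonical column names of a summary table
SUMMARY_COLUMNS = ("rsid", "effect_allele", "other_allele", "eaf",
                   "beta", "se", "pval", "n")

RESULT_COLUMNS = ("estimator", "exposure", "outcome", "n_snps", "beta", "se",
                  "ci_low", "ci_high", "pval", "or_", "or_ci_low",
                  "or_ci_high", "intercept", "intercept_pval")


def is_palindromic(a1: str, a2: str) -> bool:
    """A/T and C/G pairs are their own strand complement."""
    return COMPLEMENT.get(a1) == a2


@dataclass
class GwasSummaryTable:
    """Per-SNP association estimates for one trait in one sample.

    ``data`` holds one row per SNP with the canonical ``SUMMARY_COLUMNS``;
    betas are per effect-allele copy, in SD units for continuous traits and
    log-odds for binary ones.  ``rejected`` is the per-row audit of inputs
    that failed validation.
    """

    trait_id: str
    trait_type: str = "continuous"
    data: pd.DataFrame = None
    sample_n: int | None = None
    rejected: pd.DataFrame | None = None

    def __post_init__(self):
        if self.trait_type not in ("continuous", "binary"):
            raise ConfigurationError(
                f"trait_type must be continuous or binary, got {self.trait_type!r}")
        if self.data is not None and self.data["rsid"].duplicated().any():
            dup = self.data.loc[self.data["rsid"].duplicated(), "rsid"].iloc[0]
            raise ConfigurationError(f"duplicate rsid in table: {dup}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def rsids(self) -> list[str]:
        return self.data["rsid"].tolist()

    def rows_for(self, rsids: Sequence[str]) -> pd.DataFrame:
        sub = self.data.set_index("rsid", drop=False)
        return sub.loc[[r for r in rsids if r in sub.index]]


def _validate_rows(df: pd.DataFrame, sample_n: int | None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Row-wise invariant enforcement with a per-row reason log."""
    keep, rejects = [], []
    seen: set[str] = set()
    for _, row in df.iterrows():
        rsid = str(row["rsid"])
        reason = None
        ea = str(row["effect_allele"]).upper()
        oa = str(row["other_allele"]).upper()
        eaf = row.get("eaf", np.nan)
        n = row.get("n", np.nan)
        if rsid in seen:
            reason = "duplicate rsid"
        elif ea not in VALID_ALLELES or oa not in VALID_ALLELES:
            reason = "invalid allele"
        elif ea == oa:
            reason = "identical alleles"
        elif not math.isfinite(row["beta"]):
            reason = "nonfinite beta"
        elif not (math.isfinite(row["se"]) and row["se"] > 0):
            reason = "nonpositive SE"
        elif not (0 < row["pval"] <= 1):
            reason = "pval outside (0,1]"
        elif not (pd.isna(eaf) or 0 < eaf < 1):
            reason = "eaf outside (0,1)"
        if reason is None:
            seen.add(rsid)
            keep.append({
                "rsid": rsid, "effect_allele": ea, "other_allele": oa,
                "eaf": float(eaf) if not pd.isna(eaf) else np.nan,
                "beta": float(row["beta"]), "se": float(row["se"]),
                "pval": float(row["pval"]),
                # study-level fallback when the file omits per-SNP n
                "n": float(n) if not pd.isna(n) else
                     (float(sample_n) if sample_n else np.nan),
            })
        else:
            rejects.append({"rsid": rsid, "reason": reason})
    return (pd.DataFrame(keep, columns=list(SUMMARY_COLUMNS)),
            pd.DataFrame(rejects, columns=["rsid", "reason"]))


def read_summary_table(path: str | Path,
                       column_map: Mapping[str, str] | None = None,
                       trait_id: str = "",
                       trait_type: str = "continuous",
                       sample_n: int | None = None) -> GwasSummaryTable:
    """Read a delimited summary-statistics file into a validated table.

    ``column_map`` maps canonical names (rsid, effect_allele, other_allele,
    eaf, beta, se, pval, n) to the file's header names; eaf and n are
    optional.  Invalid rows are dropped and logged on ``table.rejected``.
    """
    raw = pd.read_csv(path, sep=None, engine="python")
    column_map = {c: c for c in SUMMARY_COLUMNS} | dict(column_map or {})
    required = ("rsid", "effect_allele", "other_allele", "beta", "se", "pval")
    for key in required:
        if column_map[key] not in raw.columns:
            raise ConfigurationError(
                f"mapped column {column_map[key]!r} for {key!r} not in {path}")
    renamed = pd.DataFrame({key: raw[src] for key, src in column_map.items()
                            if src in raw.columns})
    for opt in ("eaf", "n"):
        if opt not in renamed.columns:
            renamed[opt] = np.nan
    clean, rejects = _validate_rows(renamed, sample_n)
    if clean.empty:
        raise EmptyInputError(f"no valid summary rows in {path}")
    return GwasSummaryTable(trait_id=trait_id or str(path), trait_type=trait_type,
                            data=clean, sample_n=sample_n, rejected=rejects)


def write_summary_table(table: GwasSummaryTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# harmonization

#: actions recorded per SNP
ACTION_UNCHANGED = "unchanged"
ACTION_FLIPPED = "flipped"
ACTION_DROP_PALINDROMIC = "dropped-palindromic"
ACTION_DROP_INCOMPATIBLE = "dropped-incompatible"
ACTION_DROP_OUTLIER = "dropped-outlier"


@dataclass
class HarmonizedSet:
    """Allele-aligned exposure/outcome rows; the unit every estimator consumes.

    ``table`` keeps one audit row per requested SNP (retained or dropped);
    the array accessors expose only retained rows.
    """

    exposure_id: str
    outcome_id: str
    table: pd.DataFrame
    outcome_type: str = "continuous"

    @property
    def rows(self) -> pd.DataFrame:
        return self.table[~self.table["action"].str.startswith("dropped")]

    @property
    def k(self) -> int:
        return len(self.rows)

    @property
    def rsids(self) -> list[str]:
        return self.rows["rsid"].tolist()

    def _col(self, name: str) -> np.ndarray:
        return self.rows[name].to_numpy(dtype=float)

    @property
    def beta_zx(self) -> np.ndarray:
        return self._col("beta_zx")

    @property
    def se_zx(self) -> np.ndarray:
        return self._col("se_zx")

    @property
    def beta_zy(self) -> np.ndarray:
        return self._col("beta_zy")

    @property
    def se_zy(self) -> np.ndarray:
        return self._col("se_zy")

    @property
    def eaf_exposure(self) -> np.ndarray:
        return self._col("eaf_exposure")

    def without(self, rsids: Iterable[str], action: str = ACTION_DROP_OUTLIER,
                reason: str = "radial outlier") -> "HarmonizedSet":
        """New set with the given SNPs marked dropped (audit preserved)."""
        rsids = set(rsids)
        table = self.table.copy()
        mask = table["rsid"].isin(rsids)
        table.loc[mask, "action"] = action
        table.loc[mask, "reason"] = reason
        return HarmonizedSet(self.exposure_id, self.outcome_id, table,
                             self.outcome_type)

    def write_audit(self, path: str | Path) -> None:
        self.table[["rsid", "action", "reason"]].to_csv(path, sep="\t", index=False)


def _align_to_reference(ref_ea: str, ref_oa: str, ref_eaf: float,
                        ea: str, oa: str, eaf: float,
                        palindrome_policy: str,
                        band: tuple[float, float]) -> tuple[int, str, str]:
    """Orient one table's row onto reference alleles.

    Returns ``(sign, action, reason)`` where ``sign`` multiplies the row's
    beta (+1 aligned, -1 flipped, 0 dropped).  Strand complements are tried
    before declaring incompatibility; palindromic pairs carry no allele-label
    information and are resolved by the configured policy.
    """
    if is_palindromic(ref_ea, ref_oa):
        if {ea, oa} != {ref_ea, ref_oa}:
            return 0, ACTION_DROP_INCOMPATIBLE, "allele mismatch"
        if palindrome_policy == "drop":
            return 0, ACTION_DROP_PALINDROMIC, "palindromic SNP (policy drop)"
        if palindrome_policy != "infer_by_eaf":
            raise ConfigurationError(
                f"unknown palindrome policy {palindrome_policy!r}")
        if pd.isna(ref_eaf) or pd.isna(eaf):
            return 0, ACTION_DROP_PALINDROMIC, "palindromic SNP, eaf missing"
        # take the labels at face value, then let frequency decide the strand
        eaf_aligned = eaf if ea == ref_ea else 1.0 - eaf
        lo, hi = band
        if lo < ref_eaf < hi or lo < eaf_aligned < hi:
            return 0, ACTION_DROP_PALINDROMIC, "palindromic SNP, ambiguous eaf"
        if (ref_eaf - 0.5) * (eaf_aligned - 0.5) > 0:
            sign = 1 if ea == ref_ea else -1
        else:
            sign = -1 if ea == ref_ea else 1
        return (sign, ACTION_UNCHANGED if sign == 1 else ACTION_FLIPPED,
                "palindromic SNP, oriented by eaf")
    if (ea, oa) == (ref_ea, ref_oa):
        return 1, ACTION_UNCHANGED, ""
    if (ea, oa) == (ref_oa, ref_ea):
        return -1, ACTION_FLIPPED, "effect allele swapped"
    cea, coa = COMPLEMENT[ea], COMPLEMENT[oa]
    if (cea, coa) == (ref_ea, ref_oa):
        return 1, ACTION_UNCHANGED, "strand complement"
    if (cea, coa) == (ref_oa, ref_ea):
        return -1, ACTION_FLIPPED, "strand complement, effect allele swapped"
    return 0, ACTION_DROP_INCOMPATIBLE, "irreconcilable alleles"


def harmonize(exposure: GwasSummaryTable, outcome: GwasSummaryTable,
              snps: Sequence[str] | None = None,
              palindrome_policy: str = "infer_by_eaf",
              eaf_ambiguity_band: tuple[float, float] = (0.42, 0.58)) -> HarmonizedSet:
    """Align outcome rows to the exposure's effect alleles for the given SNPs.

    Matching alleles pass unchanged; swapped alleles flip the outcome beta
    (and complement its frequency); strand complements are resolved first;
    palindromic SNPs follow ``palindrome_policy`` (``drop`` or
    ``infer_by_eaf`` with the ambiguity band around 0.5).
    """
    if snps is None:
        snps = exposure.rsids
    missing = set(snps) - set(exposure.rsids)
    if missing:
        raise ConfigurationError(
            f"requested SNPs absent from exposure table: {sorted(missing)[:5]}")
    exp = exposure.data.set_index("rsid", drop=False)
    out = outcome.data.set_index("rsid", drop=False)
    records = []
    for rsid in snps:
        e = exp.loc[rsid]
        rec = {"rsid": rsid, "beta_zx": e["beta"], "se_zx": e["se"],
               "beta_zy": np.nan, "se_zy": np.nan,
               "eaf_exposure": e["eaf"], "action": "", "reason": ""}
        if rsid not in out.index:
            rec["action"] = ACTION_DROP_INCOMPATIBLE
            rec["reason"] = "absent from outcome"
            records.append(rec)
            continue
        o = out.loc[rsid]
        sign, action, reason = _align_to_reference(
            e["effect_allele"], e["other_allele"], e["eaf"],
            o["effect_allele"], o["other_allele"], o["eaf"],
            palindrome_policy, eaf_ambiguity_band)
        rec["action"], rec["reason"] = action, reason
        if sign != 0:
            rec["beta_zy"] = sign * o["beta"]
            rec["se_zy"] = o["se"]
        records.append(rec)
    table = pd.DataFrame(records)
    h = HarmonizedSet(exposure.trait_id, outcome.trait_id, table,
                      outcome_type=outcome.trait_type)
    if h.k == 0:
        raise EmptyInstrumentError(
            f"no usable SNP after harmonizing {exposure.trait_id} with "
            f"{outcome.trait_id}")
    return h


@dataclass
class MvHarmonizedSet:
    """Per-SNP effects for K >= 2 exposures aligned to one outcome."""

    exposure_ids: list[str]
    outcome_id: str
    table: pd.DataFrame
    outcome_type: str = "continuous"
    dropped: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def k(self) -> int:
        return len(self.table)

    @property
    def n_exposures(self) -> int:
        return len(self.exposure_ids)

    @property
    def rsids(self) -> list[str]:
        return self.table["rsid"].tolist()

    @property
    def beta_zx(self) -> np.ndarray:
        """k x K matrix of exposure effects."""
        cols = [f"beta_zx_{i}" for i in range(self.n_exposures)]
        return self.table[cols].to_numpy(dtype=float)

    @property
    def se_zx(self) -> np.ndarray:
        cols = [f"se_zx_{i}" for i in range(self.n_exposures)]
        return self.table[cols].to_numpy(dtype=float)

    @property
    def beta_zy(self) -> np.ndarray:
        return self.table["beta_zy"].to_numpy(dtype=float)

    @property
    def se_zy(self) -> np.ndarray:
        return self.table["se_zy"].to_numpy(dtype=float)


def build_mv_set(exposures: Sequence[GwasSummaryTable],
                 outcome: GwasSummaryTable,
                 snps: Sequence[str],
                 palindrome_policy: str = "infer_by_eaf",
                 eaf_ambiguity_band: tuple[float, float] = (0.42, 0.58)) -> MvHarmonizedSet:
    """Harmonize every exposure and the outcome to the first exposure's alleles.

    A SNP failing in any table (absent, incompatible, unresolvable
    palindrome) is dropped from the whole set and logged.
    """
    if len(exposures) < 2:
        raise ConfigurationError("multivariable set needs at least 2 exposures")
    ref = exposures[0].data.set_index("rsid", drop=False)
    others = [t.data.set_index("rsid", drop=False) for t in exposures[1:]]
    out = outcome.data.set_index("rsid", drop=False)
    records, dropped = [], []
    for rsid in snps:
        if rsid not in ref.index:
            dropped.append({"rsid": rsid, "reason": "absent from reference exposure"})
            continue
        r = ref.loc[rsid]
        rec = {"rsid": rsid, "beta_zx_0": r["beta"], "se_zx_0": r["se"]}
        ok = True
        for i, tab in enumerate([*others, out]):
            label = (f"exposure {exposures[i + 1].trait_id}" if i < len(others)
                     else f"outcome {outcome.trait_id}")
            if rsid not in tab.index:
                dropped.append({"rsid": rsid, "reason": f"absent from {label}"})
                ok = False
                break
            row = tab.loc[rsid]
            sign, action, reason = _align_to_reference(
                r["effect_allele"], r["other_allele"], r["eaf"],
                row["effect_allele"], row["other_allele"], row["eaf"],
                palindrome_policy, eaf_ambiguity_band)
            if sign == 0:
                dropped.append({"rsid": rsid, "reason": f"{reason} in {label}"})
                ok = False
                break
            if i < len(others):
                rec[f"beta_zx_{i + 1}"] = sign * row["beta"]
                rec[f"se_zx_{i + 1}"] = row["se"]
            else:
                rec["beta_zy"] = sign * row["beta"]
                rec["se_zy"] = row["se"]
        if ok:
            records.append(rec)
    return MvHarmonizedSet(
        exposure_ids=[t.trait_id for t in exposures],
        outcome_id=outcome.trait_id,
        table=pd.DataFrame(records),
        outcome_type=outcome.trait_type,
        dropped=pd.DataFrame(dropped, columns=["rsid", "reason"]))


# ---------------------------------------------------------------------------
# result serialization

def results_frame(results: Sequence) -> pd.DataFrame:
    """Flatten MrEstimate objects into the report schema.

    Odds-ratio columns are populated only for binary outcomes (effects on the
    log-odds scale), as ``exp(beta)`` and exponentiated CI bounds.
    """
    rows = []
    for r in results:
        binary = getattr(r, "outcome_type", "continuous") == "binary"
        rows.append({
            "estimator": r.method,
            "exposure": r.exposure_id,
            "outcome": r.outcome_id,
            "n_snps": r.n_snps,
            "beta": r.beta, "se": r.se,
            "ci_low": r.ci_low, "ci_high": r.ci_high, "pval": r.pval,
            "or_": math.exp(r.beta) if binary else np.nan,
            "or_ci_low": math.exp(r.ci_low) if binary else np.nan,
            "or_ci_high": math.exp(r.ci_high) if binary else np.nan,
            "intercept": r.intercept if r.intercept is not None else np.nan,
            "intercept_pval": (r.intercept_pval
                               if r.intercept_pval is not None else np.nan),
        })
    return pd.DataFrame(rows, columns=list(RESULT_COLUMNS))


def write_results(results: Sequence, path: str | Path) -> None:
    """Write the flat estimator report as TSV (6 significant digits)."""
    if not results:
        raise ConfigurationError("no results to write")
    results_frame(results).to_csv(path, sep="\t", index=False,
                                  float_format="%.6g")
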
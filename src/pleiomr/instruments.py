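"""Instrument selection, strength diagnostics, heterogeneity, and outliers.

Instruments are genome-wide-significant SNPs (P < 5e-8 by default) pruned to
approximate linkage-equilibrium (pairwise r^2 < 0.01 against every accepted
SNP).  Strength is summarized by the variance explained R^2 and the
F-statistic F = R^2 (n - 1 - k) / ((1 - R^2) k); F < 10 is conventionally a
weak instrument.  Heterogeneity between the per-SNP Wald ratios is measured
by Cochran's Q, and its radial per-SNP decomposition flags outlier variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (ConfigurationError, DegreesOfFreedomError, DivisionError,
                     EmptyInstrumentError, InsufficientSnpsError)
from .summary_io import GwasSummaryTable, HarmonizedSet

WEAK_F_THRESHOLD = 10.0


@dataclass
class LdMatrix:
    """Pairwise squared-correlation (r^2) matrix over named SNPs."""

    rsids: list[str]
    r2: np.ndarray

    def __post_init__(self):
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(self.rsids)
        if self.r2.shape != (n, n):
            raise ConfigurationError("LD matrix shape does not match rsids")
        if not np.allclose(self.r2, self.r2.T):
            raise ConfigurationError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise ConfigurationError("LD matrix diagonal must be 1")
        off = self.r2[~np.eye(n, dtype=bool)]
        if off.size and (off.min() < 0 or off.max() > 1):
            raise ConfigurationError("off-diagonal r2 must lie in [0,1]")
        self._index = {r: i for i, r in enumerate(self.rsids)}

    def lookup(self, a: str, b: str) -> float:
        """r^2 between two SNPs; SNPs absent from the panel are treated as
        unlinked (0)."""
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return 0.0
        return float(self.r2[ia, ib])

    @classmethod
    def read(cls, path: str | Path) -> "LdMatrix":
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
        return cls(rsids=[str(c) for c in df.columns], r2=df.to_numpy())

    def write(self, path: str | Path) -> None:
        pd.DataFrame(self.r2, index=self.rsids, columns=self.rsids).to_csv(
            path, sep="\t", float_format="%.6g")


@dataclass
class InstrumentDiagnostics:
    """Strength and heterogeneity summary for one instrument."""

    r2: float
    f_stat: float
    k: int
    n: float
    q_stat: float | None = None
    q_df: int | None = None
    q_pval: float | None = None
    outlier_rsids: list[str] = dc_field(default_factory=list)

    @property
    def weak(self) -> bool:
        """Conventional weak-instrument label (F below 10)."""
        return self.f_stat < WEAK_F_THRESHOLD

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "r2": self.r2, "f_stat": self.f_stat, "k": self.k, "n": self.n,
            "weak": self.weak, "q_stat": self.q_stat, "q_df": self.q_df,
            "q_pval": self.q_pval,
            "outliers": ",".join(self.outlier_rsids)}])


def select_instrument(table: GwasSummaryTable, p_threshold: float = 5e-8,
                      ld: LdMatrix | None = None,
                      r2_threshold: float = 0.01) -> list[str]:
    """Greedy LD pruning of genome-wide-significant SNPs.

    Survivors (pval < threshold) are visited by ascending p-value (ties
    broken by rsid) and accepted iff their r^2 with every already-accepted
    SNP is below ``r2_threshold``.  Without an LD matrix all SNPs are
    treated as independent.
    """
    if not 0 < p_threshold < 1:
        raise ConfigurationError("p_threshold must lie in (0,1)")
    if not 0 < r2_threshold <= 1:
        raise ConfigurationError("r2_threshold must lie in (0,1]")
    df = table.data[table.data["pval"] < p_threshold]
    if df.empty:
        raise EmptyInstrumentError(
            f"no SNP in {table.trait_id} passes p < {p_threshold:g}")
    ordered = df.sort_values(["pval", "rsid"], kind="stable")
    accepted: list[str] = []
    for rsid in ordered["rsid"]:
        if ld is None or all(ld.lookup(rsid, a) < r2_threshold for a in accepted):
            accepted.append(rsid)
    return accepted


def instrument_strength(betas: Sequence[float], ses: Sequence[float],
                        eafs: Sequence[float] | None, n: float,
                        k: int | None = None) -> InstrumentDiagnostics:
    """Variance explained and F-statistic from summary data.

    Per-SNP variance explained is 2 eaf (1-eaf) beta^2 when frequencies are
    available, otherwise the summary approximation beta^2/(beta^2 + n se^2).
    """
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    k = int(k if k is not None else len(betas))
    if n <= k + 1:
        raise DegreesOfFreedomError(
            f"need n > k + 1 for the F-statistic (n={n}, k={k})")
    if eafs is not None and not np.any(pd.isna(eafs)):
        eafs = np.asarray(eafs, dtype=float)
        r2_j = 2.0 * eafs * (1.0 - eafs) * betas ** 2
    else:
        r2_j = betas ** 2 / (betas ** 2 + n * ses ** 2)
    r2 = float(min(r2_j.sum(), 1.0 - 1e-12))
    f = r2 * (n - 1 - k) / ((1.0 - r2) * k)
    return InstrumentDiagnostics(r2=r2, f_stat=float(f), k=k, n=float(n))


def _wald_ratios_weights(h: HarmonizedSet) -> tuple[np.ndarray, np.ndarray]:
    bzx, bzy, se_zy = h.beta_zx, h.beta_zy, h.se_zy
    zero = np.flatnonzero(bzx == 0.0)
    if zero.size:
        raise DivisionError(
            f"SNP-exposure effect is zero for {h.rsids[zero[0]]}")
    return bzy / bzx, bzx ** 2 / se_zy ** 2


def cochran_q(h: HarmonizedSet,
              beta_ref: float | None = None) -> tuple[float, int, float]:
    """Cochran's Q over the Wald ratios around ``beta_ref`` (default: the
    set's fixed-effects IVW estimate); p from chi-square with k-1 df."""
    if h.k < 2:
        raise InsufficientSnpsError("Cochran's Q needs >= 2 SNPs")
    ratios, w = _wald_ratios_weights(h)
    if beta_ref is None:
        beta_ref = float((w * ratios).sum() / w.sum())
    q = float((w * (ratios - beta_ref) ** 2).sum())
    df = h.k - 1
    return q, df, float(stats.chi2.sf(q, df))


def radial_outliers(h: HarmonizedSet, alpha: float = 0.05,
                    correction: str = "bonferroni") -> list[str]:
    """Per-SNP radial-Q outlier flags.

    The radial form regresses ratio_j * sqrt(w_j) on sqrt(w_j) without
    intercept (slope = IVW estimate); each SNP's contribution
    Q_j = w_j (ratio_j - slope)^2 is referred to chi-square(1), at level
    ``alpha`` (divided by k under Bonferroni).
    """
    if h.k < 3:
        raise InsufficientSnpsError("radial outlier scan needs >= 3 SNPs")
    if correction not in ("none", "bonferroni"):
        raise ConfigurationError(f"unknown correction {correction!r}")
    ratios, w = _wald_ratios_weights(h)
    slope = float((w * ratios).sum() / w.sum())
    q_j = w * (ratios - slope) ** 2
    cut = alpha / h.k if correction == "bonferroni" else alpha
    flagged = stats.chi2.sf(q_j, 1) < cut
    return [r for r, f in zip(h.rsids, flagged) if f]


def radial_q_contributions(h: HarmonizedSet) -> pd.DataFrame:
    """Per-SNP radial Q_j; their sum is the total Q at the radial estimate."""
    ratios, w = _wald_ratios_weights(h)
    slope = float((w * ratios).sum() / w.sum())
    q_j = w * (ratios - slope) ** 2
    return pd.DataFrame({"rsid": h.rsids, "q_j": q_j,
                         "p": stats.chi2.sf(q_j, 1)})


def exclude_overlap(instr_a: Sequence[str], instr_b: Sequence[str],
                    ld: LdMatrix | None = None,
                    r2_threshold: float = 0.01) -> tuple[list[str], list[str]]:
    """Drop SNPs shared between two instruments, or LD-linked across them.

    Used before bidirectional MR: a SNP genome-wide significant for both
    traits (or tagging one in each list) cannot orient causal direction.
    """
    if not 0 < r2_threshold <= 1:
        raise ConfigurationError("r2_threshold must lie in (0,1]")
    shared = set(instr_a) & set(instr_b)
    drop_a, drop_b = set(shared), set(shared)
    if ld is not None:
        for a in instr_a:
            for b in instr_b:
                if a != b and ld.lookup(a, b) >= r2_threshold:
                    drop_a.add(a)
                    drop_b.add(b)
    return ([r for r in instr_a if r not in drop_a],
            [r for r in instr_b if r not in drop_b])
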
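import numpy as np
import pandas as pd
import pytest

from pleiomr.summary_io import GwasSummaryTable, HarmonizedSet


def make_hset(bzx, bzy, se_zy, se_zx=None, rsids=None,
              exposure_id="X", outcome_id="Y", outcome_type="continuous",
              eaf=None) -> HarmonizedSet:
    """Directly assemble a harmonized set from effect arrays."""
    bzx = np.asarray(bzx, dtype=float)
    k = len(bzx)
    table = pd.DataFrame({
        "rsid": rsids if rsids is not None else [f"rs{i + 1}" for i in range(k)],
        "beta_zx": bzx,
        "se_zx": np.asarray(se_zx, dtype=float) if se_zx is not None
                 else np.full(k, 0.01),
        "beta_zy": np.asarray(bzy, dtype=float),
        "se_zy": np.asarray(se_zy, dtype=float),
        "eaf_exposure": np.asarray(eaf, dtype=float) if eaf is not None
                        else np.full(k, 0.3),
        "action": "unchanged",
        "reason": "",
    })
    return HarmonizedSet(exposure_id, outcome_id, table,
                         outcome_type=outcome_type)


def make_table(trait_id, rsids, betas, ses, pvals=None, eafs=None,
               effect_alleles=None, other_alleles=None, n=10_000.0,
               trait_type="continuous") -> GwasSummaryTable:
    k = len(rsids)
    from scipy import stats
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if pvals is None:
        pvals = np.clip(2 * stats.norm.sf(np.abs(betas / ses)),
                        np.nextafter(0, 1), 1.0)
    data = pd.DataFrame({
        "rsid": rsids,
        "effect_allele": effect_alleles if effect_alleles is not None
                         else ["A"] * k,
        "other_allele": other_alleles if other_alleles is not None
                        else ["G"] * k,
        "eaf": np.asarray(eafs, dtype=float) if eafs is not None
               else np.full(k, 0.3),
        "beta": betas, "se": ses, "pval": np.asarray(pvals, dtype=float),
        "n": float(n),
    })
    return GwasSummaryTable(trait_id=trait_id, trait_type=trait_type,
                            data=data, sample_n=int(n))


@pytest.fixture
def hset_factory():
    return make_hset


@pytest.fixture
def table_factory():
    return make_table
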
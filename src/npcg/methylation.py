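"""Coverage filtering, global methylation, and per-CpG differential tests.

Differentially methylated cytosines (DMC) are called site-by-site with a
grouped-binomial logistic regression of (methylated, unmethylated)
counts on the group indicator (optionally plus an age covariate), using
the likelihood-ratio test of the group term — stabler than Wald at four
samples per group with extreme proportions.  Raw p-values are converted
to q-values by Benjamini-Hochberg (a pluggable hook accepts alternative
q-value estimators) and sites with q below the threshold are labelled
hyper- or hypomethylated in the non-reference group by the sign of the
group log-odds coefficient.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .containers import CpGMatrix, SampleTable
from .glm import logistic_lrt
from .multitest import adjust_pvalues

__all__ = ["global_methylation", "filter_coverage", "test_dmc"]

logger = logging.getLogger(__name__)


def global_methylation(data: CpGMatrix, sample_id: str) -> float:
    """Percent global CpG methylation of one sample.

    Defined as 100 x (sum of methylated cytosine reads) / (sum of all
    cytosine reads) over every covered site, i.e. read-weighted.
    """
    j = data.sample_index(sample_id)
    total = int(data.coverage[:, j].sum())
    if total == 0:
        raise ValueError(f"sample {sample_id!r} has zero total coverage; "
                         "global methylation undefined")
    return 100.0 * float(data.methylated[:, j].sum()) / total


def filter_coverage(
    data: CpGMatrix,
    min_cov: int = 10,
    upper_quantile: float = 0.999,
) -> CpGMatrix:
    """Discard low-coverage and clonal-read sites.

    Per sample, cells with coverage below ``min_cov`` or above that
    sample's ``upper_quantile`` empirical coverage quantile (linear
    interpolation) are masked; a site is retained only if it is unmasked
    in every sample, so the per-site regression sees a complete design.
    """
    if min_cov < 0:
        raise ValueError("min_cov must be >= 0")
    if not 0 < upper_quantile <= 1:
        raise ValueError("upper_quantile must lie in (0, 1]")
    cov = data.coverage
    hi = np.quantile(cov, upper_quantile, axis=0)  # per-sample cutoffs
    ok = (cov >= min_cov) & (cov <= hi)
    keep = ok.all(axis=1)
    if not keep.any():
        warnings.warn("coverage filter removed every site", stacklevel=2)
    logger.info("coverage filter: %d of %d sites retained",
                int(keep.sum()), data.n_sites)
    return data.subset_sites(keep)


def test_dmc(
    data: CpGMatrix,
    samples: SampleTable,
    qvalue_threshold: float = 0.05,
    covariates: list[str] | None = None,
    qvalue_method: str = "bh",
) -> pd.DataFrame:
    """Call DMC by per-site binomial logistic regression.

    Parameters
    ----------
    data:
        Coverage-filtered CpG matrix (every cell must have coverage > 0).
    samples:
        Two-group sample sheet, ordered like ``data.samples``.
    qvalue_threshold:
        Sites with q below this are called (default 0.05).
    covariates:
        Optional numeric covariate columns of the sample sheet (e.g.
        ``["age_days"]``) added to the per-site design.
    qvalue_method:
        Registered q-value procedure; default Benjamini-Hochberg.

    Returns
    -------
    pandas.DataFrame
        One row per site: ``chrom``, ``pos``, ``strand``, ``coef``
        (group log-odds ratio), ``meth_diff`` (non-reference minus
        reference mean proportion, percentage points), ``p_value``,
        ``q_value``, ``degenerate`` and ``status`` in
        {``hyper``, ``hypo``, ``ns``}.
    """
    st = samples.ordered_like(data.samples)
    X = st.design_matrix(covariates=covariates)
    res = logistic_lrt(data.methylated, data.coverage, X, test_col=1)

    group = st.group_indicator().astype(bool)
    props = data.proportions()
    diff = 100.0 * (props[:, group].mean(axis=1)
                    - props[:, ~group].mean(axis=1))
    qval = adjust_pvalues(res.pvalue, method=qvalue_method)
    sig = qval < qvalue_threshold
    status = np.where(sig & (res.coef[:, 1] > 0), "hyper",
                      np.where(sig & (res.coef[:, 1] <= 0), "hypo", "ns"))

    out = data.sites[["chrom", "pos", "strand"]].copy()
    out["coef"] = res.coef[:, 1]
    out["meth_diff"] = diff
    out["p_value"] = res.pvalue
    out["q_value"] = qval
    out["degenerate"] = res.degenerate
    out["status"] = status
    return out
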
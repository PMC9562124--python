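"""Library-size normalisation, NB differential expression, and power.

Genes are tested one at a time (batched) with a negative-binomial GLM:
log link, offset log(size factor), design intercept + group (+ optional
age covariate), per-gene dispersion estimated by Cox-Reid adjusted
profile maximum likelihood (floored at 1e-8), and a two-sided Wald test
on the group coefficient with observed-information standard errors.
Benjamini-Hochberg controls the FDR over the tested genes; all-zero
genes are reported with NA p-values and excluded from the adjustment.
No dispersion shrinkage across genes is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import SampleTable, validate_counts
from .glm import nb_wald
from .multitest import bh_adjust

__all__ = ["size_factors", "test_deg", "estimate_power", "PowerSpec"]

_LN2 = np.log(2.0)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (DESeq-style).

    factor_j = median over genes of count_gj / geometric-mean_g, where
    genes containing any zero are excluded from the median.  Raises if
    no gene is expressed in every sample; pass total-count-scaled
    pseudo-references upstream in that case.
    """
    counts = validate_counts(counts)
    arr = counts.to_numpy(dtype=float)
    all_pos = (arr > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; median-of-ratios "
            "undefined — use a total-count fallback normalisation")
    log_ratios = np.log(arr[all_pos]) - np.log(arr[all_pos]).mean(axis=1,
                                                                  keepdims=True)
    sf = np.exp(np.median(log_ratios, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def test_deg(
    counts: pd.DataFrame,
    samples: SampleTable,
    fdr_threshold: float = 0.05,
    covariates: list[str] | None = None,
    labels: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-gene NB Wald test of the group effect.

    Returns a DataFrame indexed by gene id with ``log2fc`` (non-reference
    vs reference), ``wald_stat``, ``p_value``, ``fdr``, ``dispersion``
    and ``status`` in {``up``, ``down``, ``ns``}.  ``labels`` optionally
    overrides the group assignment (permutation engine); dispersions are
    re-estimated under the supplied labelling.
    """
    counts = validate_counts(counts)
    st = samples.ordered_like(list(counts.columns))
    X = st.design_matrix(labels=labels, covariates=covariates)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design matrix")
    sf = size_factors(counts)
    offset = np.log(sf.to_numpy())
    fit, z, pval = nb_wald(counts.to_numpy(), X, offset=offset, test_col=1)

    fdr = bh_adjust(pval)
    lfc = fit.coef[:, 1] / _LN2
    sig = fdr < fdr_threshold
    status = np.where(~np.isfinite(pval), "ns",
                      np.where(sig & (lfc > 0), "up",
                               np.where(sig & (lfc < 0), "down", "ns")))
    return pd.DataFrame({
        "log2fc": lfc,
        "wald_stat": z,
        "p_value": pval,
        "fdr": fdr,
        "dispersion": fit.alpha,
        "status": status,
    }, index=counts.index)


@dataclass
class PowerSpec:
    """Gene-population spec for the a-posteriori power simulation.

    ``mean_counts`` and ``dispersion`` may be scalars or arrays sampled
    per gene; ``lfc`` is the log2 fold change given to truly-DE genes.
    """

    n_genes: int = 1000
    pi0: float = 0.9  # proportion of non-DE genes
    mean_counts: float | np.ndarray = 100.0
    dispersion: float | np.ndarray = 0.1
    lfc: float | np.ndarray = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi0 <= 1.0:
            raise ValueError("pi0 must lie in [0, 1]")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        for name in ("mean_counts", "dispersion"):
            v = np.asarray(getattr(self, name), dtype=float)
            if np.any(v <= 0):
                raise ValueError(f"{name} must be positive")


def estimate_power(
    n_per_group: int,
    spec: PowerSpec,
    alpha_fdr: float = 0.05,
    n_sim: int = 10,
    seed: int = 0,
) -> dict:
    """Monte-Carlo power of the NB Wald + BH pipeline at a sample size.

    Simulates ``n_sim`` two-group datasets from ``spec``, runs
    :func:`test_deg`, and reports the mean fraction of truly-DE genes
    passing BH at ``alpha_fdr``, with a normal-approximation binomial CI
    over all simulated truly-DE genes.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    labels = ["A"] * n_per_group + ["B"] * n_per_group
    st = SampleTable(pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)], "group": labels,
    }), reference="A")
    group = np.array([0.0] * n_per_group + [1.0] * n_per_group)

    detected = 0
    total_de = 0
    for _ in range(n_sim):
        G = spec.n_genes
        mean = np.broadcast_to(np.asarray(spec.mean_counts, float), (G,))
        disp = np.broadcast_to(np.asarray(spec.dispersion, float), (G,))
        lfc = np.broadcast_to(np.asarray(spec.lfc, float), (G,))
        is_de = rng.random(G) >= spec.pi0
        mu = mean[:, None] * np.exp(np.outer(np.where(is_de, lfc, 0.0) * _LN2,
                                             group))
        r = 1.0 / np.maximum(disp, 1e-8)[:, None]
        y = rng.negative_binomial(r, r / (r + mu))
        counts = pd.DataFrame(y, index=[f"g{i}" for i in range(G)],
                              columns=st.sample_ids)
        res = test_deg(counts, st, fdr_threshold=alpha_fdr)
        detected += int((res["status"][is_de] != "ns").sum())
        total_de += int(is_de.sum())
    if total_de == 0:
        return {"power": np.nan, "ci": (np.nan, np.nan), "n_true_de": 0}
    power = detected / total_de
    se = np.sqrt(power * (1 - power) / total_de)
    return {"power": power, "ci": (max(power - 1.96 * se, 0.0),
                                   min(power + 1.96 * se, 1.0)),
            "n_true_de": total_de}
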
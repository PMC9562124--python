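"""Pathway-level NB regression of expression on methylation and group.

For a declared gene set, every member's (gene, sample) observation is
stacked into one long table and the read counts are modelled as

    log E[count] = b0 + b_meth * MP + b_group * 1[group]
                   (+ b_int * MP * 1[group])

by a negative-binomial regression, MP being the gene's methylation
proportion in that sample (0-1 scale; a percent axis is display only).
If the interaction term is not significant at ``alpha`` it is dropped
and the model refitted — the reported fit then has no interaction term.
Prediction curves are evaluated on an MP grid from 0.10 to 0.90.

All pathway genes enter regardless of their own differential status.
By default a single pooled regression is fitted with no gene term; a
gene-level intercept option exists for users who want within-gene
effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import SampleTable
from .glm import nb_fit

__all__ = ["assemble_pathway", "fit_pathway_model", "predict_curve",
           "PathwayFit"]

logger = logging.getLogger(__name__)

DEFAULT_MP_GRID = np.round(np.arange(0.10, 0.91, 0.10), 2)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round halves away from zero (so 12.5 -> 13), unlike banker's."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def assemble_pathway(
    pathway_genes: list[str],
    gene_meth: pd.DataFrame,
    counts: pd.DataFrame,
    pathway_id: str = "pathway",
) -> pd.DataFrame:
    """Stack a pathway's genes into a long (gene, sample) table.

    ``gene_meth`` is gene x sample methylation proportions;``counts``
    gene x sample read counts.  Duplicate gene ids (several regions or
    transcripts mapping to one id) have their methylation proportions
    averaged and their counts averaged then rounded half-away-from-zero.
    Genes missing either omic are dropped (count logged).

    Returns columns: pathway, gene_id, sample_id, meth, count.
    """
    meth_avg = gene_meth.groupby(level=0).mean()
    cnt_avg = _round_half_away(
        counts.groupby(level=0).mean().to_numpy())
    cnt_avg = pd.DataFrame(cnt_avg, index=counts.groupby(level=0).mean().index,
                           columns=counts.columns)
    usable = [g for g in pathway_genes
              if g in meth_avg.index and g in cnt_avg.index]
    dropped = len(set(pathway_genes)) - len(set(usable))
    if dropped:
        logger.info("pathway %s: %d gene(s) missing an omic, dropped",
                    pathway_id, dropped)
    if not usable:
        raise ValueError(f"pathway {pathway_id!r} has no gene present in "
                         "both omics")
    samples = [c for c in cnt_avg.columns if c in meth_avg.columns]
    rows = []
    for g in usable:
        for s in samples:
            rows.append((pathway_id, g, s,
                         float(meth_avg.loc[g, s]),
                         int(cnt_avg.loc[g, s])))
    df = pd.DataFrame(rows, columns=["pathway", "gene_id", "sample_id",
                                     "meth", "count"])
    if ((df["meth"] < 0) | (df["meth"] > 1)).any():
        raise ValueError("methylation proportions outside [0, 1]")
    return df


@dataclass
class PathwayFit:
    """Pooled NB fit of a pathway with its prediction grid."""

    pathway: str
    coef: pd.Series  # index: intercept, meth, group[, interaction]
    se: pd.Series
    p_values: pd.Series
    dispersion: float
    interaction_dropped: bool
    predictions: pd.DataFrame = field(default_factory=pd.DataFrame)
    group_levels: tuple[str, str] = ("ref", "other")  # (reference, other)
    mean_mp: dict = field(default_factory=dict)  # group -> sample-average MP


def _design(df: pd.DataFrame, samples: SampleTable,
            interaction: bool, gene_intercepts: bool):
    st = samples.table.set_index("sample_id")
    grp = (df["sample_id"].map(st["group"]) != samples.reference).astype(float)
    cols = [np.ones(len(df)), df["meth"].to_numpy(), grp.to_numpy()]
    names = ["intercept", "meth", "group"]
    if interaction:
        cols.append(df["meth"].to_numpy() * grp.to_numpy())
        names.append("interaction")
    if gene_intercepts:
        genes = sorted(df["gene_id"].unique())
        for g in genes[1:]:
            cols.append((df["gene_id"] == g).to_numpy(float))
            names.append(f"gene[{g}]")
    return np.column_stack(cols), names


def _fit_once(df, samples, interaction, gene_intercepts):
    X, names = _design(df, samples, interaction, gene_intercepts)
    y = df["count"].to_numpy(dtype=float)[None, :]
    fit = nb_fit(y, X)
    if not fit.converged[0]:
        raise RuntimeError("NB dispersion/mean alternation did not converge "
                           f"within budget (pathway rows={len(df)})")
    coef = fit.coef[0]
    se = fit.se[0]
    z = coef / se
    df_resid = max(len(df) - X.shape[1], 1)
    p = 2.0 * stats.t.sf(np.abs(z), df=df_resid)
    return (pd.Series(coef, index=names), pd.Series(se, index=names),
            pd.Series(p, index=names), float(fit.alpha[0]))


def fit_pathway_model(
    data: pd.DataFrame,
    samples: SampleTable,
    alpha: float = 0.05,
    gene_intercepts: bool = False,
    mp_grid: np.ndarray = DEFAULT_MP_GRID,
) -> PathwayFit:
    """Fit the pooled NB model with the interaction-drop rule.

    The full model (methylation + group + interaction) is fitted first;
    if the interaction's p-value is >= ``alpha`` the model is refitted
    without it and ``interaction_dropped`` is set.  Requires both groups
    and non-constant methylation in ``data``.
    """
    st = samples.table.set_index("sample_id")
    present = set(st.loc[data["sample_id"].unique(), "group"])
    if len(present) != 2:
        raise ValueError("both groups must be present in the pathway data")
    if data["meth"].nunique() < 2:
        raise ValueError("methylation is constant; slope unidentifiable")

    coef, se, p, disp = _fit_once(data, samples, True, gene_intercepts)
    dropped = bool(p["interaction"] >= alpha)
    if dropped:
        coef, se, p, disp = _fit_once(data, samples, False, gene_intercepts)

    grp_col = data["sample_id"].map(st["group"])
    mean_mp = data.groupby(grp_col)["meth"].mean().to_dict()
    fit = PathwayFit(
        pathway=str(data["pathway"].iloc[0]),
        coef=coef, se=se, p_values=p, dispersion=disp,
        interaction_dropped=dropped,
        group_levels=(samples.reference, samples.other),
        mean_mp=mean_mp,
    )
    fit.predictions = predict_curve(fit, mp_grid)
    return fit


def predict_curve(fit: PathwayFit, mp_grid: np.ndarray = DEFAULT_MP_GRID
                  ) -> pd.DataFrame:
    """Predicted counts per group over a methylation-proportion grid.

    Also evaluates each group's prediction at its own sample-average MP
    (the crosshair point of the curve plots).  Predictions are exp of
    the linear predictor, hence strictly positive.
    """
    rows = []
    ref, other = fit.group_levels
    for grp, ind in ((ref, 0.0), (other, 1.0)):
        for mp in mp_grid:
            eta = (fit.coef["intercept"] + fit.coef["meth"] * mp
                   + fit.coef["group"] * ind)
            if "interaction" in fit.coef.index:
                eta += fit.coef["interaction"] * mp * ind
            rows.append((grp, float(mp), float(np.exp(eta)), False))
        if grp in fit.mean_mp:
            mp = fit.mean_mp[grp]
            eta = (fit.coef["intercept"] + fit.coef["meth"] * mp
                   + fit.coef["group"] * ind)
            if "interaction" in fit.coef.index:
                eta += fit.coef["interaction"] * mp * ind
            rows.append((grp, float(mp), float(np.exp(eta)), True))
    return pd.DataFrame(rows, columns=["group", "mp", "predicted_count",
                                       "at_mean_mp"])


def plot_prediction_curves(fit: PathwayFit, path) -> None:
    """Two prediction curves (one per group) over the MP grid, with
    crosshairs at each group's sample-average MP."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    pred = fit.predictions
    for grp, color in zip(fit.group_levels, ("tab:green", "tab:red")):
        sub = pred[(pred["group"] == grp) & ~pred["at_mean_mp"]]
        ax.plot(100 * sub["mp"], sub["predicted_count"], color=color,
                label=grp)
        at_mean = pred[(pred["group"] == grp) & pred["at_mean_mp"]]
        if len(at_mean):
            mp = 100 * at_mean["mp"].iloc[0]
            cnt = at_mean["predicted_count"].iloc[0]
            ax.axvline(mp, color=color, lw=0.6, ls=":")
            ax.axhline(cnt, color=color, lw=0.6, ls=":")
    ax.set_xlabel("methylation proportion (%)")
    ax.set_ylabel("predicted read count")
    ax.set_title(fit.pathway)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
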
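"""Target de-repression upon AGO depletion.

RNA-seq and ribosome-footprint count tables (control vs depleted, >= 2
replicates each) are size-normalised by median-of-ratios, converted to
per-gene log2 fold changes with a pseudocount, and the translational
efficiency change is defined as TE = RiboFP log2FC - RNA log2FC.  Target
strata (by reproducible-prediction count, by seed-match type among
single-site genes, by miRNA) are compared against the non-target
background with the two-sided two-sample Kolmogorov-Smirnov test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError

logger = logging.getLogger(__name__)

SEED_TYPE_GROUPS = {
    "6mer": "6mer",
    "7mer-A1": "7mer",
    "7mer-m8": "7mer",
    "8mer-A1": "8mer",
}

MEASURES = ("rna_log2fc", "ribo_log2fc", "te_log2fc")


def median_of_ratios(counts: pd.DataFrame) -> pd.DataFrame:
    """Size-factor normalisation: per-library median ratio to the
    per-gene geometric mean (genes with any zero are excluded from the
    factor estimate, not from the output)."""
    log_counts = np.log(counts.where(counts > 0))
    log_geo = log_counts.mean(axis=1)
    usable = log_geo.notna()
    if usable.sum() < 1:
        raise ConfigurationError("no gene has positive counts in every "
                                 "library; cannot estimate size factors")
    ratios = log_counts.loc[usable].sub(log_geo.loc[usable], axis=0)
    size = np.exp(ratios.median(axis=0))
    return counts / size


def log2_fold_changes(
    rna_control: pd.DataFrame,
    rna_depleted: pd.DataFrame,
    ribo_control: pd.DataFrame,
    ribo_depleted: pd.DataFrame,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene RNA, RiboFP and TE log2 fold changes (depleted vs control).

    All four tables must share one gene universe; each modality is
    median-of-ratios normalised across its control+depleted libraries
    jointly, so global shifts are absorbed.
    """
    universe = rna_control.index
    for name, df in (("rna_depleted", rna_depleted),
                     ("ribo_control", ribo_control),
                     ("ribo_depleted", ribo_depleted)):
        if not df.index.equals(universe):
            offenders = sorted(set(df.index).symmetric_difference(universe))
            raise ConfigurationError(
                f"gene universe mismatch in {name}: {offenders[:10]}"
                + ("..." if len(offenders) > 10 else "")
            )
    if rna_control.shape[1] < 2 or rna_depleted.shape[1] < 2:
        raise ConfigurationError("need >= 2 replicates per condition")

    def lfc(ctl, dep):
        joint = median_of_ratios(
            pd.concat([ctl.add_prefix("c_"), dep.add_prefix("d_")], axis=1))
        nc = joint[[f"c_{c}" for c in ctl.columns]].mean(axis=1)
        nd = joint[[f"d_{c}" for c in dep.columns]].mean(axis=1)
        return np.log2(nd + pseudocount) - np.log2(nc + pseudocount), nc

    rna, rna_mean = lfc(rna_control, rna_depleted)
    ribo, _ = lfc(ribo_control, ribo_depleted)
    return pd.DataFrame({
        "rna_log2fc": rna,
        "ribo_log2fc": ribo,
        "te_log2fc": ribo - rna,
        "mean_expression": rna_mean,
    })


def ks_compare(
    group: np.ndarray, background: np.ndarray, method: str = "asymp"
) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov comparison.

    ``method='exact'`` (sensible for n <= 20 per group) computes the exact
    permutation distribution of D; the default is the classical asymptotic
    p-value.
    """
    x = np.asarray(group, dtype=float)
    y = np.asarray(background, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ConfigurationError("KS comparison needs >= 3 values per group")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConfigurationError("degenerate single-value group in KS test")
    res = stats.ks_2samp(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class StratumSummary:
    stratum: str
    n_genes: int
    genes: tuple[str, ...]
    means: dict
    ks: dict  # measure -> (D, p) against the non-target background


def _summarise(fc: pd.DataFrame, genes, background_genes, label):
    sub = fc.loc[sorted(genes)]
    bg = fc.loc[sorted(background_genes)]
    means = {m: float(sub[m].mean()) for m in MEASURES}
    ks = {}
    if len(sub) >= 3 and len(bg) >= 3:
        for m in MEASURES:
            if np.ptp(sub[m]) > 0 and np.ptp(bg[m]) > 0:
                ks[m] = ks_compare(sub[m].to_numpy(), bg[m].to_numpy())
    return StratumSummary(label, len(sub), tuple(sorted(genes)), means, ks)


def stratify_targets(
    fc: pd.DataFrame, predictions: pd.DataFrame
) -> dict[str, list[StratumSummary]]:
    """De-repression strata against the zero-prediction background.

    ``predictions`` needs columns ``gene``, ``mirna_id`` and ``seed_type``
    (one row per reproducible collapsed prediction).  Strata: by prediction
    count {1,2,3,4,>4}; by seed-match class (6mer/7mer/8mer) among genes
    with exactly one prediction; by miRNA.  Empty strata are reported with
    n=0 and no test.
    """
    for col in ("gene", "mirna_id", "seed_type"):
        if col not in predictions.columns:
            raise ConfigurationError(f"predictions need a {col!r} column")
    predictions = predictions[predictions["gene"].isin(fc.index)]
    per_gene = predictions.groupby("gene").size()
    background = sorted(set(fc.index) - set(per_gene.index))
    out: dict[str, list[StratumSummary]] = {"count": [], "seedtype": [],
                                            "mirna": []}
    for label, sel in (
        ("1", per_gene == 1), ("2", per_gene == 2), ("3", per_gene == 3),
        ("4", per_gene == 4), (">4", per_gene > 4),
    ):
        genes = list(per_gene.index[sel])
        out["count"].append(_summarise(fc, genes, background, label))
    single = set(per_gene.index[per_gene == 1])
    single_preds = predictions[predictions["gene"].isin(single)]
    for cls in ("6mer", "7mer", "8mer"):
        genes = sorted(
            single_preds.loc[
                single_preds["seed_type"].map(SEED_TYPE_GROUPS) == cls, "gene"
            ].unique()
        )
        out["seedtype"].append(_summarise(fc, genes, background, cls))
    for mid, sub in sorted(predictions.groupby("mirna_id")):
        genes = sorted(sub["gene"].unique())
        out["mirna"].append(_summarise(fc, genes, background, mid))
    return out


def strata_table(strata: dict[str, list[StratumSummary]]) -> pd.DataFrame:
    """Flat summary frame of all strata (one row per stratum/measure)."""
    rows = []
    for kind, summaries in strata.items():
        for s in summaries:
            for m in MEASURES:
                d, p = s.ks.get(m, (np.nan, np.nan))
                rows.append({
                    "kind": kind, "stratum": s.stratum, "n_genes": s.n_genes,
                    "measure": m, "mean": s.means.get(m, np.nan),
                    "ks_D": d, "ks_p": p,
                })
    return pd.DataFrame(rows)
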
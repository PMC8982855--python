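"""Ectopic-expression calling on RPKM matrices.

Ectopic expression means a gene turns on in a tissue where it is silent in
the wild type. The decision is two-staged: (1) a gene is transcriptionally
inert (silent) in wild type when its mean WT RPKM is below 2.0 and a
one-sided rank test supports the replicates sitting below that floor at
p < 0.1; (2) among inert genes, those whose mutant/WT mean fold-change
(with a 0.01 pseudocount) exceeds 2 enter a one-sided Mann-Whitney U test of
mutant > WT, BH-corrected over exactly that entering set, with q < 0.25
calling the gene ectopic. The lenient q threshold matches the tiny
attainable p at 2-3 replicates (min one-sided MW p at 3 vs 3 is 0.05).

The inertness test's comparator is ambiguous as published; the default is a
one-sided Wilcoxon signed-rank of (replicate RPKM - 2.0) using the normal
approximation, which is the only reading that can reject at n = 3 (the
exact test's smallest p at n = 3 is 0.125). The exact variant and a
two-sample Mann-Whitney comparator are available through the config.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust

__all__ = ["EctopicConfig", "EctopicExpressionModel", "EctopicResults",
           "call_silent_wt", "call_ectopic"]

FOLD_PSEUDOCOUNT = 0.01


@dataclass(frozen=True)
class EctopicConfig:
    """Thresholds of the two-stage ectopic call.

    silent_rpkm_max / silent_p_max gate stage 1 (WT inertness); fold_min and
    ectopic_q_max gate stage 2. ``silent_test`` selects the inertness test:
    "signed_rank_approx" (default), "signed_rank_exact", or "mannwhitney"
    (one-sided WT-below-mutant two-sample test).
    """

    silent_rpkm_max: float = 2.0
    silent_p_max: float = 0.1
    fold_min: float = 2.0
    ectopic_q_max: float = 0.25
    silent_test: str = "signed_rank_approx"

    def __post_init__(self) -> None:
        if min(self.silent_rpkm_max, self.fold_min) <= 0:
            raise ValueError("thresholds must be positive")
        if not (0 < self.silent_p_max < 1 and 0 < self.ectopic_q_max < 1):
            raise ValueError("p/q thresholds must be in (0, 1)")
        if self.silent_test not in {
            "signed_rank_approx", "signed_rank_exact", "mannwhitney"
        }:
            raise ValueError(f"unknown silent_test {self.silent_test!r}")


def _silent_p(
    wt: np.ndarray, mut: np.ndarray | None, config: EctopicConfig
) -> float:
    """One-sided p-value that the WT replicates sit below the silence floor."""
    diffs = wt - config.silent_rpkm_max
    if config.silent_test == "mannwhitney":
        if mut is None:
            raise ValueError("mannwhitney silent test needs mutant replicates")
        return stats.mannwhitneyu(wt, mut, alternative="less").pvalue
    if np.all(diffs == 0):
        return 1.0
    method = "exact" if config.silent_test == "signed_rank_exact" else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.wilcoxon(
            diffs, alternative="less", method=method, correction=False,
            zero_method="wilcox",
        )
    return float(res.pvalue)


def call_silent_wt(
    wt_rpkm: pd.DataFrame,
    config: EctopicConfig | None = None,
    mut_rpkm: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Stage 1: flag genes transcriptionally inert in wild type.

    ``wt_rpkm`` is genes x replicates. A gene is silent iff mean WT RPKM <
    silent_rpkm_max AND the configured one-sided test yields p <
    silent_p_max. Returns a frame with wt_mean_rpkm, silent_p, silent_in_wt.
    """
    config = config or EctopicConfig()
    if wt_rpkm.shape[1] < 2:
        raise ValueError("silent call requires >= 2 WT replicates")
    means = wt_rpkm.mean(axis=1)
    pvals = np.ones(len(wt_rpkm))
    wt_arr = wt_rpkm.to_numpy(dtype=float)
    mut_arr = None if mut_rpkm is None else mut_rpkm.to_numpy(dtype=float)
    below = means < config.silent_rpkm_max
    for i in np.flatnonzero(below.to_numpy()):
        pvals[i] = _silent_p(
            wt_arr[i], None if mut_arr is None else mut_arr[i], config
        )
    out = pd.DataFrame(
        {
            "wt_mean_rpkm": means,
            "silent_p": np.where(below, pvals, np.nan),
            "silent_in_wt": below.to_numpy() & (pvals < config.silent_p_max),
        },
        index=wt_rpkm.index,
    )
    return out


class EctopicExpressionModel:
    """Two-stage ectopic-expression model over matched WT/mutant RPKM."""

    def __init__(
        self,
        wt_rpkm: pd.DataFrame,
        mut_rpkm: pd.DataFrame,
        config: EctopicConfig | None = None,
    ) -> None:
        if not wt_rpkm.index.equals(mut_rpkm.index):
            raise ValueError("WT and mutant RPKM matrices cover different genes")
        if wt_rpkm.shape[1] < 2 or mut_rpkm.shape[1] < 2:
            raise ValueError("need >= 2 replicates on each side")
        self.wt = wt_rpkm.astype(float)
        self.mut = mut_rpkm.astype(float)
        self.config = config or EctopicConfig()

    def fit(self) -> "EctopicResults":
        cfg = self.config
        silent = call_silent_wt(self.wt, cfg, mut_rpkm=self.mut)
        wt_mean = silent["wt_mean_rpkm"]
        mut_mean = self.mut.mean(axis=1)
        fold = (mut_mean + FOLD_PSEUDOCOUNT) / (wt_mean + FOLD_PSEUDOCOUNT)

        entering = silent["silent_in_wt"] & (fold > cfg.fold_min)
        mw_p = pd.Series(np.nan, index=self.wt.index)
        for gene in self.wt.index[entering]:
            mw_p[gene] = stats.mannwhitneyu(
                self.mut.loc[gene], self.wt.loc[gene], alternative="greater"
            ).pvalue
        q = pd.Series(bh_adjust(mw_p.to_numpy()), index=self.wt.index)
        is_ectopic = entering & (q < cfg.ectopic_q_max)

        frame = pd.DataFrame(
            {
                "wt_mean_rpkm": wt_mean,
                "mut_mean_rpkm": mut_mean,
                "silent_in_wt": silent["silent_in_wt"],
                "silent_p": silent["silent_p"],
                "fold_change": fold,
                "mw_p": mw_p,
                "q": q,
                "is_ectopic": is_ectopic.fillna(False),
            }
        )
        return EctopicResults(frame, cfg, bh_family_size=int(entering.sum()))


class EctopicResults:
    """Per-gene ectopic calls plus the size of the BH family actually used."""

    def __init__(self, frame: pd.DataFrame, config: EctopicConfig,
                 bh_family_size: int):
        self.frame = frame
        self.config = config
        self.bh_family_size = bh_family_size

    @property
    def ectopic_genes(self) -> pd.Index:
        return self.frame.index[self.frame["is_ectopic"]]

    def summary(self) -> str:
        f = self.frame
        return "\n".join(
            [
                "Ectopic-expression calls",
                f"  genes: {len(f)}",
                f"  silent in WT: {int(f['silent_in_wt'].sum())}",
                f"  entered BH family (silent, fold > "
                f"{self.config.fold_min:g}): {self.bh_family_size}",
                f"  ectopic (q < {self.config.ectopic_q_max:g}): "
                f"{int(f['is_ectopic'].sum())}",
            ]
        )


def call_ectopic(
    wt_rpkm: pd.DataFrame,
    mut_rpkm: pd.DataFrame,
    config: EctopicConfig | None = None,
) -> pd.DataFrame:
    """Functional wrapper: fit the model and return the per-gene frame."""
    return EctopicExpressionModel(wt_rpkm, mut_rpkm, config).fit().frame
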
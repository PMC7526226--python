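"""Transcript-protein concordance statistics.

Paired log2 fold-changes are classified into quadrants by sign
(I: both up, III: both down — concordant; II/IV: opposite signs —
discordant), summarized as percent concordance, and scored with a
rank-based concordance estimate derived from Somers' delta D,
rescaled to (D + 1)/2 so that 1 is perfect agreement, 0 perfect
anti-correlation, and 0.5 chance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConcordanceSummary",
    "build_lfc_pairs",
    "percent_concordant",
    "somers_concordance",
]


@dataclass(frozen=True)
class ConcordanceSummary:
    n_pairs: int
    percent_concordant: float
    somers_concordance: float
    p_value: float
    gene_subset_label: str


def build_lfc_pairs(
    transcript_de: pd.DataFrame,
    protein_de: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pair per-gene transcript and protein log2 fold-changes.

    Input tables need columns ``feature_id``, ``log2fc``, ``fdr``; the
    pairing keeps genes present in both. Quadrants follow the sign
    convention above; a gene with an exactly-zero fold-change in either
    modality gets no quadrant and a null ``concordant`` flag.
    """
    t = transcript_de.set_index("feature_id")
    p = protein_de.set_index("feature_id")
    shared = t.index.intersection(p.index)
    pairs = pd.DataFrame(
        {
            "gene_id": shared,
            "transcript_lfc": t.loc[shared, "log2fc"].to_numpy(),
            "protein_lfc": p.loc[shared, "log2fc"].to_numpy(),
            "transcript_sig": (t.loc[shared, "fdr"] < alpha).to_numpy(),
            "protein_sig": (p.loc[shared, "fdr"] < alpha).to_numpy(),
        }
    )
    tl, pl = pairs["transcript_lfc"], pairs["protein_lfc"]
    quadrant = np.select(
        [
            (tl > 0) & (pl > 0),
            (tl < 0) & (pl > 0),
            (tl < 0) & (pl < 0),
            (tl > 0) & (pl < 0),
        ],
        ["I", "II", "III", "IV"],
        default="",
    )
    pairs["quadrant"] = quadrant
    pairs["concordant"] = pd.array(
        np.isin(quadrant, ["I", "III"]), dtype="boolean"
    )
    pairs.loc[quadrant == "", "concordant"] = pd.NA
    return pairs


def percent_concordant(
    pairs: pd.DataFrame, subset: str = "transcript_sig"
) -> ConcordanceSummary:
    """Percent same-direction pairs plus the Somers concordance.

    ``subset`` is ``"all"``, ``"transcript_sig"`` (pairs whose
    transcript is significant) or ``"both_sig"``. Pairs without a
    quadrant (a zero fold-change) are excluded from the percentage;
    their count is reported via a warning.
    """
    if subset == "all":
        sel = pairs
    elif subset == "transcript_sig":
        sel = pairs[pairs["transcript_sig"]]
    elif subset == "both_sig":
        sel = pairs[pairs["transcript_sig"] & pairs["protein_sig"]]
    else:
        raise ValueError(f"unknown subset {subset!r}")
    if len(sel) == 0:
        raise ValueError(f"no pairs in subset {subset!r}")
    classified = sel["concordant"].notna()
    n_dropped = int((~classified).sum())
    if n_dropped:
        warnings.warn(f"{n_dropped} pair(s) with zero fold-change excluded")
    conc = sel.loc[classified, "concordant"]
    percent = 100.0 * float(conc.sum()) / len(conc)
    est, p = somers_concordance(
        sel["protein_lfc"].to_numpy(), sel["transcript_lfc"].to_numpy()
    )
    return ConcordanceSummary(
        n_pairs=len(sel),
        percent_concordant=percent,
        somers_concordance=est,
        p_value=p,
        gene_subset_label=subset,
    )


def somers_concordance(x, y) -> tuple[float, float]:
    """Concordance estimate (D + 1)/2 from Somers' delta of y on x.

    Over all unordered pairs with distinct x: concordant pairs minus
    discordant pairs over the number of such pairs, with y-ties
    contributing half to each side (so they cancel in the numerator but
    stay in the denominator). Computed through the Kendall tau-b
    identity C - D = tau_b * sqrt((n0 - Tx)(n0 - Ty)) in O(n log n).
    Returns (estimate, p); the p-value is the asymptotic normal test of
    D = 0. All-tied x is degenerate and returns (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")

    def tie_term(v):
        _, counts = np.unique(v, return_counts=True)
        return float((counts * (counts - 1) // 2).sum())

    n0 = n * (n - 1) / 2.0
    tx, ty = tie_term(x), tie_term(y)
    if n0 - tx == 0:
        warnings.warn("all x values tied; concordance undefined")
        return float("nan"), float("nan")
    tau = stats.kendalltau(x, y)
    cd = tau.statistic * np.sqrt((n0 - tx) * (n0 - ty))  # C - D
    d_yx = cd / (n0 - tx)
    return (d_yx + 1.0) / 2.0, float(tau.pvalue)
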
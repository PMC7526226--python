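"""Amplifying vs. protective annotation of expression changes.

A Tau-induced expression change is *amplifying* when recapitulating it
genetically worsens neurotoxicity (or reversing it helps), and
*protective* when recapitulating it helps (or reversing it worsens).
Concretely, a manipulation that mimics the observed direction
(up-regulation <-> overexpression, down-regulation <-> loss of
function) and enhances toxicity implies amplifying; one that mimics and
suppresses implies protective. A manipulation opposing the observed
direction maps symmetrically: opposing + suppresses -> amplifying,
opposing + enhances -> protective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ModifierEvidence", "classify_change", "annotate_catalog"]

MANIPULATIONS = ("loss_of_function", "overexpression")
OUTCOMES = ("suppresses", "enhances")
DIRECTIONS = ("up", "down")


@dataclass(frozen=True)
class ModifierEvidence:
    gene_id: str
    manipulation: str
    outcome: str
    source: str = ""

    def __post_init__(self):
        if self.manipulation not in MANIPULATIONS:
            raise ValueError(f"unknown manipulation {self.manipulation!r}")
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")


def classify_change(de_direction: str, evidence: ModifierEvidence) -> str:
    """Map (direction, manipulation, outcome) to amplifying/protective."""
    if de_direction not in DIRECTIONS:
        raise ValueError(f"unknown direction {de_direction!r}")
    mimics = (de_direction == "up") == (evidence.manipulation == "overexpression")
    if mimics:
        return "amplifying" if evidence.outcome == "enhances" else "protective"
    return "amplifying" if evidence.outcome == "suppresses" else "protective"


def annotate_catalog(
    de_table: pd.DataFrame,
    modifiers: pd.DataFrame,
    human_sets=None,
    homology: pd.DataFrame | None = None,
    min_score: int = 5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Annotate every (DE gene x modifier-evidence) combination.

    ``de_table`` needs ``feature_id``, ``log2fc``, ``fdr`` (the
    age-adjusted joint model by default upstream); only significant
    genes at FDR < ``alpha`` are annotated. Each evidence record yields
    one row with its own call; the ``gene_call`` column reports the
    per-gene summary (``amplifying``/``protective``/``conflicting``).
    With ``human_sets`` (iterable of
    :class:`~tauomics.enrichment.HumanGeneSet`) and a homology table,
    each row is further annotated with the human homologs present in
    each set and whether any changes in the same direction.
    """
    sig = de_table[(de_table["fdr"] < alpha)].set_index("feature_id")
    rows = []
    for rec in modifiers.itertuples(index=False):
        if rec.gene_id not in sig.index:
            continue
        direction = "up" if sig.loc[rec.gene_id, "log2fc"] > 0 else "down"
        ev = ModifierEvidence(
            rec.gene_id, rec.manipulation, rec.outcome, getattr(rec, "source", "")
        )
        rows.append(
            {
                "gene_id": rec.gene_id,
                "de_direction": direction,
                "manipulation": rec.manipulation,
                "outcome": rec.outcome,
                "source": getattr(rec, "source", ""),
                "call": classify_change(direction, ev),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["gene_id", "de_direction", "manipulation", "outcome", "source", "call"],
    )
    if len(out):
        summary = out.groupby("gene_id")["call"].agg(
            lambda c: c.iloc[0] if c.nunique() == 1 else "conflicting"
        )
        out["gene_call"] = out["gene_id"].map(summary)
    else:
        out["gene_call"] = pd.Series(dtype=object)

    if human_sets is not None and homology is not None and len(out):
        pairs = homology.groupby(["human_id", "fly_id"], as_index=False)["score"].max()
        pairs = pairs[pairs["score"] >= min_score]
        fly_dir = np.sign(sig["log2fc"])
        for hs in human_sets:
            directions = hs.genes.set_index("gene_id")["direction"]
            hits, concordant = [], []
            for g in out["gene_id"]:
                humans = pairs.loc[pairs["fly_id"] == g, "human_id"]
                in_set = [h for h in humans if h in directions.index]
                hits.append(",".join(sorted(in_set)))
                concordant.append(
                    any(np.sign(directions[h]) == fly_dir[g] for h in in_set)
                )
            out[f"{hs.label}_homologs"] = hits
            out[f"{hs.label}_concordant"] = concordant
    return out
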
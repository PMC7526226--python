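"""Gene-set over-representation and cross-species overlap testing.

Over-representation of a query gene list in annotated categories uses a
one-sided Fisher exact test against a stated background with BH
adjustment. Cross-species comparisons map human differentially
expressed genes onto fly genes through a scored homology table (DIOPT-
style integer confidence scores, minimum 5 by default, keeping every
passing homolog), then test the overlap of the mapped set with the fly
Tau- and aging-responsive sets against fixed background parameters with
an upper-tail hypergeometric test computed in log space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust

__all__ = [
    "read_gmt",
    "fisher_ora",
    "map_homologs",
    "hypergeom_overlap",
    "cross_species_summary",
    "TRANSCRIPTOME_BACKGROUND",
    "PROTEOME_BACKGROUND",
]

#: (population size, population successes): unique and differentially
#: expressed fly genes, for human-to-fly overlap tests.
TRANSCRIPTOME_BACKGROUND = (17104, 5716)
PROTEOME_BACKGROUND = (2742, 548)


def read_gmt(path) -> dict[str, set]:
    """Parse a GMT gene-set file (name <tab> description <tab> genes...)."""
    sets: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def fisher_ora(
    query,
    collection: dict,
    background,
    min_size: int = 5,
) -> pd.DataFrame:
    """One-sided Fisher exact over-representation per category.

    Categories are restricted to the background and must have at least
    ``min_size`` members there to be tested; BH is applied across the
    tested categories. Query genes outside the background are an error
    upstream of the statistic, so they raise.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background")
    query = set(query)
    if not query <= background:
        raise ValueError("query must be a subset of the background")
    rows = []
    for name, members in collection.items():
        cat = set(members) & background
        if len(cat) < min_size:
            continue
        k = len(query & cat)
        table = [
            [k, len(query) - k],
            [len(cat) - k, len(background) - len(cat) - (len(query) - k)],
        ]
        _, p = stats.fisher_exact(table, alternative="greater")
        rows.append(
            {
                "category": name,
                "overlap_count": k,
                "category_size": len(cat),
                "query_size": len(query),
                "background_size": len(background),
                "p_value": p,
            }
        )
    result = pd.DataFrame(
        rows,
        columns=[
            "category",
            "overlap_count",
            "category_size",
            "query_size",
            "background_size",
            "p_value",
        ],
    )
    if len(result):
        result["fdr"] = bh_adjust(result["p_value"].to_numpy())
    else:
        result["fdr"] = pd.Series(dtype=float)
    return result


def map_homologs(
    genes,
    homology: pd.DataFrame,
    min_score: int = 5,
    strict: bool = False,
    source_col: str = "human_id",
    target_col: str = "fly_id",
) -> set:
    """Map genes across species through a scored homology table.

    Keeps every (source, target) pair whose score passes ``min_score``
    (``>=`` by default; ``strict=True`` uses ``>``); a source gene with
    several passing homologs contributes all of them. Duplicate pairs
    collapse to their maximum score. Unmapped sources are counted in a
    warning. Returns the set of target genes.
    """
    genes = set(genes)
    if not len(homology):
        return set()
    pairs = (
        homology.groupby([source_col, target_col], as_index=False)["score"].max()
    )
    passing = pairs["score"] > min_score if strict else pairs["score"] >= min_score
    pairs = pairs[passing & pairs[source_col].isin(genes)]
    mapped_sources = set(pairs[source_col])
    n_unmapped = len(genes - mapped_sources)
    if n_unmapped:
        warnings.warn(f"{n_unmapped} source gene(s) had no passing homolog")
    return set(pairs[target_col])


def hypergeom_overlap(
    population_size: int,
    population_successes: int,
    sample_size: int,
    sample_successes: int,
) -> float:
    """Upper-tail hypergeometric overlap probability P(X >= k).

    X ~ Hypergeometric(N=population_size, K=population_successes,
    n=sample_size). Computed through the log survival function so that
    extreme tails (p ~ 1e-60) keep full relative precision.
    """
    N, K, n, k = population_size, population_successes, sample_size, sample_successes
    if min(N, K, n, k) < 0 or K > N or n > N or k > min(n, K):
        raise ValueError("inconsistent hypergeometric counts")
    return float(np.exp(stats.hypergeom.logsf(k - 1, N, K, n)))


@dataclass(frozen=True)
class HumanGeneSet:
    """A labeled human DE gene list with per-gene direction (+1/-1)."""

    label: str
    genes: pd.DataFrame  # columns: gene_id, direction
    modality: str = "transcriptome"


def cross_species_summary(
    human_sets,
    homology: pd.DataFrame,
    fly_tau_de: pd.DataFrame,
    fly_aging_de: pd.DataFrame,
    backgrounds: dict | None = None,
    min_score: int = 5,
) -> pd.DataFrame:
    """Per human DE set: conservation, fly-overlap counts and percents,
    hypergeometric p, and cross-species direction concordance.

    ``fly_tau_de`` / ``fly_aging_de`` need columns ``feature_id``,
    ``log2fc`` and ``significant``. Percentages are relative to the
    conserved gene count (human genes with >= 1 passing homolog). A
    human gene is direction-concordant when at least one passing,
    Tau-significant homolog changes in the same direction.
    """
    if backgrounds is None:
        backgrounds = {
            "transcriptome": TRANSCRIPTOME_BACKGROUND,
            "proteome": PROTEOME_BACKGROUND,
        }
    tau_sig = fly_tau_de[fly_tau_de["significant"]]
    aging_sig = fly_aging_de[fly_aging_de["significant"]]
    tau_set = set(tau_sig["feature_id"])
    aging_set = set(aging_sig["feature_id"])
    tau_dir = np.sign(tau_sig.set_index("feature_id")["log2fc"])

    pairs = homology.groupby(["human_id", "fly_id"], as_index=False)["score"].max()
    pairs = pairs[pairs["score"] >= min_score]

    rows = []
    for hs in human_sets:
        genes = hs.genes
        gene_ids = set(genes["gene_id"])
        sub = pairs[pairs["human_id"].isin(gene_ids)]
        conserved = sub.groupby("human_id")["fly_id"].apply(set)
        n_conserved = len(conserved)
        tau_overlap = conserved.apply(lambda s: bool(s & tau_set))
        aging_overlap = conserved.apply(lambda s: bool(s & aging_set))
        n_tau = int(tau_overlap.sum())
        n_aging = int(aging_overlap.sum())

        N, K = backgrounds[hs.modality]
        if n_conserved > 0:
            p = hypergeom_overlap(N, K, n_conserved, min(n_tau, K, n_conserved))
        else:
            p = float("nan")

        # direction concordance among tau-overlapping human genes
        directions = genes.set_index("gene_id")["direction"]
        n_concordant = 0
        overlapping = [h for h in conserved.index if tau_overlap[h]]
        for h in overlapping:
            flies = conserved[h] & set(tau_dir.index)
            if any(tau_dir[f] == np.sign(directions[h]) for f in flies):
                n_concordant += 1
        rows.append(
            {
                "human_set_label": hs.label,
                "n_human_genes": len(gene_ids),
                "n_conserved": n_conserved,
                "tau_overlap": n_tau,
                "tau_overlap_percent": 100.0 * n_tau / n_conserved if n_conserved else 0.0,
                "aging_overlap": n_aging,
                "aging_overlap_percent": 100.0 * n_aging / n_conserved if n_conserved else 0.0,
                "hypergeom_p": p,
                "direction_concordant_percent": (
                    100.0 * n_concordant / len(overlapping) if overlapping else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows)
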
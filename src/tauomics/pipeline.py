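"""End-to-end orchestration of the analysis stages.

``run_all`` executes, in dependency order: data simulation (or
ingestion), proteome preparation, the differential expression suite,
permutation-FDR audit, transcript-protein concordance, clustering with
NMF rank selection, gene-set enrichment of the leading cluster,
cross-species overlap, and modifier annotation. Every stage writes TSV
outputs prefixed with a comment line recording the stage, seed, and a
parameter hash, and the run emits a manifest sufficient to reproduce
it.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering as cl
from . import concordance as cc
from . import de as de_mod
from . import enrichment as en
from . import modifiers as md
from . import proteome as pp
from . import synthetic as syn
from .core import ExpressionMatrix, StudyDesign
from .permutation import empirical_fdr

__all__ = ["RunConfig", "run_all"]

STAGES = (
    "simulate",
    "proteome_prep",
    "de",
    "permute_fdr",
    "concordance",
    "clustering",
    "enrichment",
    "overlap",
    "modifiers",
)


@dataclass
class RunConfig:
    """Flat, per-stage configuration for a full run."""

    out_dir: str = "tauomics_run"
    seed: int = 0
    alpha: float = 0.05
    min_avg_count: float = 50.0
    n_genes: int = 1000
    frac_genotype_de: float = 0.1
    frac_age_de: float = 0.3
    replicates_per_cell: int = 3
    n_permutations: int = 100
    downshift_sd: float = 1.8
    width_sd: float = 0.3
    nmf_ranks: tuple = (2, 3, 4, 5, 6)
    nmf_runs: int = 10
    cluster_k: int | None = None  # None -> use surveyed rank
    n_human_genes: int = 800
    n_human_de: int = 200
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "nmf_ranks" in raw:
            raw["nmf_ranks"] = tuple(raw["nmf_ranks"])
        if "stages" in raw:
            stages = {s: True for s in STAGES}
            bad = set(raw["stages"]) - set(STAGES)
            if bad:
                raise ValueError(f"unknown stages: {sorted(bad)}")
            stages.update(raw["stages"])
            raw["stages"] = stages
        return cls(**raw)

    def params_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")  # a location, not a parameter
        payload = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write(df: pd.DataFrame, path: Path, stage: str, seed: int, cfg: RunConfig, index=False):
    with open(path, "w") as fh:
        fh.write(f"# stage={stage} seed={seed} params_hash={cfg.params_hash()}\n")
        df.to_csv(fh, sep="\t", index=index)


def run_all(config: RunConfig) -> dict:
    """Run the enabled stages and return the manifest."""
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "params_hash": cfg.params_hash(),
        "seed": cfg.seed,
        "stages": {},
    }

    def record(stage, status, rows=None, outputs=(), note=None):
        entry = {"status": status, "outputs": list(map(str, outputs))}
        if rows is not None:
            entry["rows"] = int(rows)
        if note:
            entry["note"] = note
        manifest["stages"][stage] = entry

    enabled = {s: cfg.stages.get(s, True) for s in STAGES}
    state: dict = {}

    # --- simulate -----------------------------------------------------
    if enabled["simulate"]:
        design = StudyDesign(replicates_per_cell=cfg.replicates_per_cell)
        sim = syn.SimParams(
            n_genes=cfg.n_genes,
            frac_genotype_de=cfg.frac_genotype_de,
            frac_age_de=cfg.frac_age_de,
            seed=cfg.seed,
        )
        transcriptome, truth = syn.simulate_transcriptome(sim, design)
        prot_params = syn.ProteomeSimParams(seed=cfg.seed + 1)
        proteome_raw, prot_truth = syn.simulate_proteome(
            transcriptome, truth, prot_params, design
        )
        homology = syn.simulate_homology(
            n_fly=cfg.n_genes, n_human=cfg.n_human_genes, seed=cfg.seed + 2
        )
        modifier_catalog = syn.simulate_modifiers(
            transcriptome.feature_ids, n_records=40, seed=cfg.seed + 3
        )
        state.update(
            design=design,
            transcriptome=transcriptome,
            truth=truth,
            proteome_raw=proteome_raw,
            prot_truth=prot_truth,
            homology=homology,
            modifier_catalog=modifier_catalog,
        )
        paths = [out / "counts.tsv", out / "metadata.tsv", out / "lfq.tsv",
                 out / "truth.tsv", out / "homology.tsv", out / "modifier_catalog.tsv"]
        _write(transcriptome.values, paths[0], "simulate", cfg.seed, cfg, index=True)
        _write(transcriptome.metadata, paths[1], "simulate", cfg.seed, cfg)
        _write(proteome_raw.values, paths[2], "simulate", cfg.seed, cfg, index=True)
        _write(truth.reset_index(), paths[3], "simulate", cfg.seed, cfg)
        _write(homology, paths[4], "simulate", cfg.seed, cfg)
        _write(modifier_catalog, paths[5], "simulate", cfg.seed, cfg)
        record("simulate", "completed", rows=cfg.n_genes, outputs=paths)
    else:
        record("simulate", "skipped")

    # --- proteome prep ------------------------------------------------
    if enabled["proteome_prep"] and "proteome_raw" in state:
        raw = state["proteome_raw"]
        filtered = pp.filter_complete_in_group(raw, state["design"])
        log2 = ExpressionMatrix(
            np.log2(filtered.values), filtered.metadata.copy(), "proteome"
        )
        imputed_log2 = pp.impute_downshift(
            log2, pp.ImputationParams(cfg.downshift_sd, cfg.width_sd, cfg.seed + 4)
        )
        prepared = ExpressionMatrix(
            2.0 ** imputed_log2.values, imputed_log2.metadata.copy(), "proteome"
        )
        no_missing, lt50 = pp.missingness_subsets(filtered)
        state["proteome"] = prepared
        tally = filtered.values.notna().sum(axis=1).rename("n_observed").reset_index()
        paths = [out / "lfq_prepared.tsv", out / "protein_observed_tally.tsv"]
        _write(prepared.values, paths[0], "proteome_prep", cfg.seed + 4, cfg, index=True)
        _write(tally, paths[1], "proteome_prep", cfg.seed + 4, cfg)
        record(
            "proteome_prep", "completed", rows=prepared.n_features, outputs=paths,
            note=f"no_missing={no_missing.n_features} lt50={lt50.n_features}",
        )
    else:
        record("proteome_prep", "skipped")

    # --- differential expression --------------------------------------
    if enabled["de"] and "transcriptome" in state:
        designs = de_mod.default_designs(state["transcriptome"].metadata)
        de_table = de_mod.run_de_suite(
            state["transcriptome"],
            state.get("proteome"),
            designs,
            alpha=cfg.alpha,
            min_avg=cfg.min_avg_count,
        )
        state["de_table"] = de_table
        path = out / "de_results.tsv"
        _write(de_table, path, "de", cfg.seed, cfg)
        record("de", "completed", rows=len(de_table), outputs=[path])
    else:
        record("de", "skipped")

    # --- permutation FDR ----------------------------------------------
    if enabled["permute_fdr"] and "de_table" in state:
        de_table = state["de_table"]
        joint = de_table[
            (de_table["analysis"] == "joint_genotype")
            & (de_table["modality"] == "transcriptome")
        ]
        sig = joint[joint["significant"]]
        if len(sig):
            threshold = float(sig["pvalue"].max())
            matrix = de_mod.filter_low_counts(
                state["transcriptome"], cfg.min_avg_count
            )
            perm = empirical_fdr(
                matrix,
                de_mod.DesignSpec("genotype_plus_age"),
                p_threshold=threshold,
                n_permutations=cfg.n_permutations,
                seed=cfg.seed + 5,
            )
            path = out / "permutation_fdr.tsv"
            _write(perm.as_frame(), path, "permute_fdr", cfg.seed + 5, cfg)
            record("permute_fdr", "completed", rows=1, outputs=[path])
            state["permutation"] = perm
        else:
            record("permute_fdr", "skipped", note="no significant genes")
    else:
        record("permute_fdr", "skipped")

    # --- concordance ---------------------------------------------------
    if enabled["concordance"] and "de_table" in state and "proteome" in state:
        de_table = state["de_table"]
        t = de_table[
            (de_table["analysis"] == "joint_genotype")
            & (de_table["modality"] == "transcriptome")
        ]
        p = de_table[
            (de_table["analysis"] == "joint_genotype")
            & (de_table["modality"] == "proteome")
        ]
        pairs = cc.build_lfc_pairs(t, p, alpha=cfg.alpha)
        summaries = []
        for subset in ("all", "transcript_sig", "both_sig"):
            try:
                s = cc.percent_concordant(pairs, subset)
                summaries.append(asdict(s))
            except ValueError:
                continue
        state["pairs"] = pairs
        paths = [out / "lfc_pairs.tsv", out / "concordance_summary.tsv"]
        _write(pairs, paths[0], "concordance", cfg.seed, cfg)
        _write(pd.DataFrame(summaries), paths[1], "concordance", cfg.seed, cfg)
        record("concordance", "completed", rows=len(pairs), outputs=paths)
    else:
        record("concordance", "skipped")

    # --- clustering ----------------------------------------------------
    if enabled["clustering"] and "de_table" in state:
        de_table = state["de_table"]
        joint = de_table[
            (de_table["analysis"] == "joint_genotype")
            & (de_table["modality"] == "transcriptome")
        ]
        de_genes = list(joint.loc[joint["significant"], "feature_id"])
        if len(de_genes) >= 3:
            expr = cl.normalized_log2(
                state["transcriptome"].subset_features(de_genes)
            )
            linkage = cl.hcluster_genes(expr)
            survey = cl.nmf_rank_survey(
                expr, ranks=cfg.nmf_ranks, n_runs=cfg.nmf_runs, seed=cfg.seed + 6
            )
            k = cfg.cluster_k or survey.chosen_rank
            assignment = cl.cut_to_k(linkage, k)
            traj = cl.cluster_trajectories(
                assignment, expr, state["transcriptome"].metadata
            )
            aging_sets = [
                set(
                    de_table.loc[
                        (de_table["analysis"] == f"control_age_{a}v{b}")
                        & (de_table["modality"] == "transcriptome")
                        & de_table["significant"],
                        "feature_id",
                    ]
                )
                for a, b in ((1, 10), (10, 20), (1, 20))
            ]
            overlap_frac = cl.cluster_aging_overlap(assignment, aging_sets)
            eigs = []
            for c in sorted(assignment.unique()):
                genes = assignment.index[assignment == c]
                if len(genes) < 2:
                    continue
                e = cl.module_eigengene(
                    expr, genes, state["transcriptome"].metadata, label=f"cluster{c}"
                )
                eigs.append(
                    {
                        "module": e.module_label,
                        "genotype_correlation": e.genotype_correlation,
                        "p_value": e.p_value,
                    }
                )
            state["assignment"] = assignment
            paths = [
                out / "clusters.tsv",
                out / "rank_survey.tsv",
                out / "trajectories.tsv",
                out / "eigengenes.tsv",
                out / "cluster_aging_overlap.tsv",
            ]
            _write(assignment.rename_axis("gene_id").reset_index(), paths[0], "clustering", cfg.seed + 6, cfg)
            _write(survey.survey, paths[1], "clustering", cfg.seed + 6, cfg)
            _write(traj, paths[2], "clustering", cfg.seed + 6, cfg)
            _write(pd.DataFrame(eigs), paths[3], "clustering", cfg.seed + 6, cfg)
            _write(
                overlap_frac.rename_axis("cluster").reset_index(),
                paths[4], "clustering", cfg.seed + 6, cfg,
            )
            record("clustering", "completed", rows=len(assignment), outputs=paths,
                   note=f"chosen_rank={survey.chosen_rank}")
        else:
            record("clustering", "skipped", note="too few DE genes")
    else:
        record("clustering", "skipped")

    # --- enrichment (of the leading cluster) ---------------------------
    if enabled["enrichment"] and "assignment" in state:
        assignment = state["assignment"]
        rng = np.random.default_rng(cfg.seed + 7)
        universe = list(state["transcriptome"].feature_ids)
        # synthetic annotation: random categories plus one seeded with
        # genes from the largest cluster so enrichment has signal
        largest = assignment.value_counts().idxmax()
        cluster_genes = list(assignment.index[assignment == largest])
        collection = {
            f"random_set_{i}": set(rng.choice(universe, size=40, replace=False))
            for i in range(10)
        }
        planted = set(rng.choice(cluster_genes, size=min(25, len(cluster_genes)), replace=False))
        planted |= set(rng.choice(universe, size=15, replace=False))
        collection["planted_cluster_set"] = planted
        enr = en.fisher_ora(set(cluster_genes), collection, set(universe))
        path = out / "enrichment.tsv"
        _write(enr, path, "enrichment", cfg.seed + 7, cfg)
        record("enrichment", "completed", rows=len(enr), outputs=[path])
    elif enabled["enrichment"]:
        warnings.warn("enrichment needs clustering output; skipping")
        record("enrichment", "skipped", note="requires clustering")
    else:
        record("enrichment", "skipped")

    # --- cross-species overlap -----------------------------------------
    if enabled["overlap"] and "de_table" in state and "homology" in state:
        de_table = state["de_table"]
        joint = de_table[
            (de_table["analysis"] == "joint_genotype")
            & (de_table["modality"] == "transcriptome")
        ].copy()
        aging_frames = [
            de_table[
                (de_table["analysis"] == f"control_age_{a}v{b}")
                & (de_table["modality"] == "transcriptome")
            ]
            for a, b in ((1, 10), (10, 20), (1, 20))
        ]
        aging = (
            pd.concat(aging_frames)
            .sort_values("significant", ascending=False)
            .drop_duplicates("feature_id")
        )
        homology = state["homology"]
        rng = np.random.default_rng(cfg.seed + 8)
        humans = sorted(set(homology["human_id"]))
        chosen = rng.choice(humans, size=min(cfg.n_human_de, len(humans)), replace=False)
        human_set = en.HumanGeneSet(
            label="synthetic_AD",
            genes=pd.DataFrame(
                {"gene_id": chosen, "direction": rng.choice([-1, 1], size=len(chosen))}
            ),
        )
        background = (
            len(joint),
            int(joint["significant"].sum()),
        )
        summary = en.cross_species_summary(
            [human_set], homology, joint, aging,
            backgrounds={"transcriptome": background},
        )
        path = out / "cross_species_overlap.tsv"
        _write(summary, path, "overlap", cfg.seed + 8, cfg)
        record("overlap", "completed", rows=len(summary), outputs=[path])
    else:
        record("overlap", "skipped")

    # --- modifier annotation -------------------------------------------
    if enabled["modifiers"] and "de_table" in state and "modifier_catalog" in state:
        de_table = state["de_table"]
        joint = de_table[
            (de_table["analysis"] == "joint_genotype")
            & (de_table["modality"] == "transcriptome")
        ]
        annotations = md.annotate_catalog(
            joint, state["modifier_catalog"], alpha=cfg.alpha
        )
        path = out / "modifier_annotations.tsv"
        _write(annotations, path, "modifiers", cfg.seed, cfg)
        record("modifiers", "completed", rows=len(annotations), outputs=[path])
    else:
        record("modifiers", "skipped")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
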
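"""Config-driven orchestration of the full analysis.

Stage order: rarefy -> alpha/beta diversity + ordination + group tests ->
source tracking -> primary-source selection -> low-count filter / TMM /
NB-GLM / BH / calls -> seed sets -> competition matrix -> cooccurrence ->
Mantel and partial Mantel.  Every stage consuming randomness takes an
explicit seed from the config; reruns with the same config are
bit-identical.  A JSON manifest records parameters, seeds, and input
checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffabund, diversity, io, revecol, sourcetracking
from ._errors import DomainError, SeabiomeError
from .containers import OtuTable

logger = logging.getLogger("seabiome.pipeline")

# constants of the reference analysis; deviations are flagged by validate
PAPER_DEFAULTS = {
    "rarefaction_depth": 2500,
    "n_permutations": 1000,
    "alpha": 0.01,
    "min_total": 5,
}


@dataclass
class SourceTrackingParams:
    alpha1: float = 0.001
    alpha2: float = 0.1
    beta: float = 10.0
    n_burnin: int = 100
    n_draws: int = 25
    thin: int = 10
    restarts: int = 10


@dataclass
class PipelineConfig:
    otu_table: str = ""
    metadata: str = ""
    tree: str = ""
    reactions: str = ""
    output_dir: str = "seabiome_out"
    rarefaction_depth: int = 2500
    n_permutations: int = 1000
    alpha: float = 0.01
    min_total: int = 5
    source_tracking: SourceTrackingParams = field(
        default_factory=SourceTrackingParams
    )
    host_types: list[str] = field(default_factory=lambda: ["leaf", "root"])
    env_types: list[str] = field(default_factory=lambda: ["water", "sediment"])
    seeds: dict[str, int] = field(
        default_factory=lambda: {
            "rarefaction": 1,
            "anosim": 2,
            "permdisp": 3,
            "centroid": 4,
            "source_tracking": 5,
            "mantel": 6,
        }
    )
    stages: dict[str, bool] = field(
        default_factory=lambda: {
            "diversity": True,
            "source_tracking": True,
            "differential_abundance": True,
            "reverse_ecology": True,
        }
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        st = raw.pop("source_tracking", {})
        cfg = cls(**raw)
        cfg.source_tracking = SourceTrackingParams(**st)
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


def validate_config(config: PipelineConfig) -> list[str]:
    """Return findings (missing files, label inconsistencies, divergences
    from the reference constants); never raises."""
    findings = []
    for name in ("otu_table", "metadata", "tree", "reactions"):
        path = getattr(config, name)
        if path and not Path(path).exists():
            findings.append(f"missing file: {name} = {path}")
    for key, ref in PAPER_DEFAULTS.items():
        if getattr(config, key) != ref:
            findings.append(
                f"divergent: {key} = {getattr(config, key)} "
                f"(reference analysis used {ref})"
            )
    for stage, seed_key in [("rarefaction", "rarefaction")]:
        if seed_key not in config.seeds:
            findings.append(f"missing seed for stage {stage}")
    if config.otu_table and config.metadata and Path(config.otu_table).exists() \
            and Path(config.metadata).exists():
        try:
            table = io.read_otu_table(config.otu_table)
            meta = io.read_metadata(config.metadata)
            for s in table.sample_ids:
                if s not in meta:
                    findings.append(f"sample {s!r} missing from metadata")
        except SeabiomeError as exc:
            findings.append(f"parse failure: {exc}")
    return findings


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every enabled stage; returns the manifest dictionary."""
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.StreamHandler(sys.stderr)
    logger.setLevel(logging.INFO)

    manifest: dict = {
        "config": config.to_dict(),
        "inputs": {},
        "stages": {},
    }
    for name in ("otu_table", "metadata", "tree", "reactions"):
        path = getattr(config, name)
        if path and Path(path).exists():
            manifest["inputs"][name] = {"path": path, "sha256": _sha256(path)}

    table = io.read_otu_table(config.otu_table)
    metadata = io.read_metadata(config.metadata)
    tree = io.read_newick(config.tree) if config.tree else None
    for s in table.sample_ids:
        if s not in metadata:
            raise DomainError(f"sample {s!r} missing from metadata")

    def stage(name, enabled, fn):
        if not enabled:
            manifest["stages"][name] = {"status": "disabled"}
            return None
        start = time.time()
        logger.info("stage %s: starting", name)
        try:
            info = fn()
        except Exception:
            manifest["stages"][name] = {"status": "failed"}
            _write_manifest(manifest, out)
            logger.exception("stage %s failed", name)
            raise
        info = info or {}
        info["status"] = "ok"
        info["seconds"] = round(time.time() - start, 3)
        manifest["stages"][name] = info
        return info

    # --- rarefaction -------------------------------------------------------
    state: dict = {}

    def do_rarefy():
        rarefied, dropped = diversity.rarefy(
            table, config.rarefaction_depth, config.seeds["rarefaction"]
        )
        if not rarefied.sample_ids:
            raise DomainError(
                f"every sample fell below the rarefaction depth "
                f"{config.rarefaction_depth}"
            )
        state["rarefied"] = rarefied
        io.write_otu_table(rarefied, out / "rarefied_otu_table.tsv")
        return {"n_samples": len(rarefied.sample_ids), "dropped": dropped}

    stage("rarefaction", True, do_rarefy)
    rarefied = state["rarefied"]
    sample_ids = rarefied.sample_ids
    groups = metadata.community_types(sample_ids)
    sites = metadata.site_ids(sample_ids)

    # --- diversity ---------------------------------------------------------
    def do_diversity():
        alpha = diversity.alpha_diversity_table(rarefied, tree)
        io.write_results(alpha, out / "alpha_diversity.tsv")
        dm = diversity.canberra_matrix(rarefied)
        state["canberra"] = dm
        io.write_distance_matrix(dm, out / "canberra.tsv")
        info = {}
        matrices = {"canberra": dm}
        if tree is not None:
            uf = diversity.unifrac_matrix(rarefied, tree)
            state["unifrac"] = uf
            io.write_distance_matrix(uf, out / "unifrac.tsv")
            matrices["unifrac"] = uf
        reports = {}
        for name, matrix in matrices.items():
            ordination = diversity.pcoa(matrix)
            coords = pd.DataFrame(
                ordination.coordinates,
                index=ordination.sample_ids,
            )
            coords.index.name = "sample_id"
            io.write_results(coords, out / f"pcoa_{name}.tsv")
            anosim_res = diversity.anosim(
                matrix, groups, strata=sites,
                n_perm=config.n_permutations,
                seed=config.seeds["anosim"],
            )
            permdisp_res = diversity.permdisp(
                matrix, groups,
                n_perm=config.n_permutations,
                seed=config.seeds["permdisp"],
            )
            reports[name] = {
                "anosim_r": anosim_res.statistic,
                "anosim_p": anosim_res.p_value,
                "permdisp_f": permdisp_res.statistic,
                "permdisp_p": permdisp_res.p_value,
            }
            # within- vs between-bed centroid proximity per host/env pairing
            for host_type, env_type in zip(
                config.host_types, config.env_types
            ):
                host_beds: dict[str, list[str]] = {}
                env_beds: dict[str, list[str]] = {}
                for s in sample_ids:
                    rec = metadata[s]
                    if rec.community_type == host_type:
                        host_beds.setdefault(rec.bed_id, []).append(s)
                    elif rec.community_type == env_type:
                        env_beds.setdefault(rec.bed_id, []).append(s)
                shared = set(host_beds) & set(env_beds)
                if len(shared) >= 2:
                    res = diversity.centroid_proximity_test(
                        ordination, host_beds, env_beds,
                        n_perm=config.n_permutations,
                        seed=config.seeds["centroid"],
                    )
                    reports[name][f"centroid_{host_type}_{env_type}"] = {
                        "statistic": res.statistic,
                        "p_value": res.p_value,
                    }
        io.write_results(reports, out / "group_tests.json")
        return info

    stage("diversity", config.stages.get("diversity", True), do_diversity)

    # --- source tracking ---------------------------------------------------
    primary: dict[str, dict] = {}

    def do_sourcetracking():
        host_samples = [
            s for s in sample_ids
            if metadata[s].community_type in config.host_types
        ]
        env_tables = {
            env: rarefied.select_samples(
                [s for s in sample_ids
                 if metadata[s].community_type == env]
            )
            for env in config.env_types
        }
        sinks = rarefied.select_samples(host_samples)
        st = config.source_tracking
        attributions = sourcetracking.fit_sources(
            sinks, env_tables,
            alpha1=st.alpha1, alpha2=st.alpha2, beta=st.beta,
            n_burnin=st.n_burnin, n_draws=st.n_draws, thin=st.thin,
            restarts=st.restarts, seed=config.seeds["source_tracking"],
        )
        rows = []
        for att in attributions:
            row = {"sink_id": att.sink_id}
            row.update(att.proportions)
            row.update({f"{k}_sd": v for k, v in att.posterior_sd.items()})
            rows.append(row)
        df = pd.DataFrame(rows).set_index("sink_id")
        io.write_results(df, out / "source_proportions.tsv")
        primary.update(
            sourcetracking.select_primary_source(attributions, metadata)
        )
        io.write_results(primary, out / "primary_sources.json")
        return {"primary_sources": {k: v["source"] for k, v in primary.items()}}

    stage(
        "source_tracking",
        config.stages.get("source_tracking", True),
        do_sourcetracking,
    )

    # --- differential abundance -------------------------------------------
    enriched_by_type: dict[str, list[str]] = {}

    def do_diffabund():
        if not primary:
            raise DomainError(
                "differential_abundance requires the source_tracking stage"
            )
        info = {}
        for host_type, sel in primary.items():
            env_type = sel["source"]
            host_ids = [
                s for s in table.sample_ids
                if s in metadata and metadata[s].community_type == host_type
            ]
            env_ids = [
                s for s in table.sample_ids
                if s in metadata and metadata[s].community_type == env_type
            ]
            combined = table.select_samples(host_ids + env_ids)
            filtered, removed = diffabund.filter_low_count(
                combined, config.min_total
            )
            factors = diffabund.tmm_factors(filtered)
            host_tab = filtered.select_samples(host_ids)
            env_tab = filtered.select_samples(env_ids)
            results = diffabund.nb_glm_lrt(host_tab, env_tab, factors)
            results = diffabund.call_enrichment(results, config.alpha)
            io.write_results(
                results, out / f"enrichment_{host_type}_vs_{env_type}.tsv"
            )
            summary = diffabund.enrichment_summary(results)
            summary["n_filtered"] = len(removed)
            info[host_type] = summary
            enriched_by_type[host_type] = list(
                results.index[results["call"] == "enriched"]
            )
        io.write_results(info, out / "enrichment_summary.json")
        return info

    stage(
        "differential_abundance",
        config.stages.get("differential_abundance", True),
        do_diffabund,
    )

    # --- reverse ecology ---------------------------------------------------
    def do_revecol():
        if not enriched_by_type:
            raise DomainError(
                "reverse_ecology requires the differential_abundance stage"
            )
        if not config.reactions:
            raise DomainError("reverse_ecology requires a reactions file")
        reactions = io.read_reactions_by_otu(config.reactions)
        info = {}
        for host_type, enriched in enriched_by_type.items():
            usable = [o for o in enriched if o in reactions]
            if len(usable) < 4:
                info[host_type] = {
                    "status": "skipped",
                    "reason": f"only {len(usable)} enriched OTUs with networks",
                }
                continue
            seed_sets = [
                revecol.seed_set(
                    revecol.build_compound_graph(reactions[o], o)
                )
                for o in usable
            ]
            comp = revecol.competition_matrix(seed_sets)
            io.write_distance_matrix(
                comp, out / f"competition_{host_type}.tsv"
            )
            seeds_df = pd.DataFrame(
                [
                    {
                        "otu_id": ss.otu_id,
                        "compound": c,
                        "confidence": conf,
                        "component_id": next(
                            i for i, mem in enumerate(ss.components)
                            if c in mem
                        ),
                    }
                    for ss in seed_sets
                    for c, conf in sorted(ss.seeds.items())
                ]
            ).set_index("otu_id")
            io.write_results(seeds_df, out / f"seed_sets_{host_type}.tsv")
            cooc = revecol.cooccurrence_matrix(rarefied.select_taxa(usable))
            io.write_distance_matrix(
                cooc, out / f"cooccurrence_{host_type}.tsv"
            )
            mres = revecol.mantel(
                cooc, comp,
                n_perm=config.n_permutations,
                seed=config.seeds["mantel"],
            )
            entry = {
                "mantel_r": mres.r,
                "mantel_p": mres.p_value,
                "n_otus": len(usable),
            }
            if tree is not None:
                tips = {t.name for t in tree.tips()}
                if all(o in tips for o in usable):
                    phylo = revecol.phylo_distance_matrix(tree, usable)
                    pres = revecol.partial_mantel(
                        cooc, comp, phylo,
                        n_perm=config.n_permutations,
                        seed=config.seeds["mantel"],
                    )
                    entry["partial_mantel_r"] = pres.r
                    entry["partial_mantel_p"] = pres.p_value
            info[host_type] = entry
        io.write_results(info, out / "mantel_reports.json")
        return info

    stage(
        "reverse_ecology",
        config.stages.get("reverse_ecology", True),
        do_revecol,
    )

    manifest["wall_seconds"] = round(time.time() - t0, 3)
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
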
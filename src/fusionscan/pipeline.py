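"""End-to-end orchestration from a single flat configuration.

Stages run in a fixed order: simulate/ingest -> site filters -> allele
frequencies and F_ST -> f3 admixture test -> supervised ancestry ->
diagnostic panel and genomic profiles -> ancestry cline -> topology tallies.
Every output is stamped with the config hash and root seed; all stage
randomness derives from the root seed through named substreams, so adding a
stage never perturbs another stage's draws and a fixed seed reproduces the
bundle byte-for-byte. Optional stages that come up empty (e.g. a panel with
no qualifying loci) are logged and skipped, not fatal.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import admixtest, ancestry, clines, diffstats, profiles, simdata, topology
from .popio import (
    GenotypeMatrix,
    read_metadata,
    read_vcf_genotypes,
    validate_joint,
    write_metadata,
    write_vcf,
)
from .sitefilters import FilterReport, apply_site_filters

log = logging.getLogger("fusionscan")

# substream tags: one per stage, so seeds never collide across stages
_STREAMS = {"filters": 101, "ancestry": 102, "phist": 103, "uncouple": 104}


class PipelineConfigError(ValueError):
    pass


@dataclasses.dataclass
class RunConfig:
    """Flat run configuration; thresholds default to the study constants."""

    # input: either a simulator config or paths
    sim: dict | None = None
    vcf: str | None = None
    metadata: str | None = None
    # grouping (population labels)
    ref_cal_pops: list[str] = dataclasses.field(default_factory=list)
    ref_hol_pops: list[str] = dataclasses.field(default_factory=list)
    target_pops: list[str] = dataclasses.field(default_factory=list)
    chi_pop: str = "CHI"
    exclude_pops: list[str] = dataclasses.field(default_factory=list)
    # filters: list of [name, params] pairs
    filters: list = dataclasses.field(
        default_factory=lambda: [
            ["thin_bp", {"min_bp": 50}],
            ["missingness", {"max_missing": 0.5}],
            ["hwe", {"alpha": 0.001}],
            ["ld_prune", {"r2_threshold": 0.8, "window_bp": 1000}],
        ]
    )
    # thresholds
    assignment_threshold: float = 0.7
    panel_rule: str = "fst_gt"
    panel_threshold: float = 0.58
    fst_subset_threshold: float = 0.2
    f3_block_size: int = 500
    topo_block_size: int = 50
    anchor: tuple[float, float] = clines.SAN_DIEGO
    seed: int = 0

    def validate(self) -> None:
        for name in ("assignment_threshold", "panel_threshold",
                     "fst_subset_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise PipelineConfigError(f"{name}={v} outside [0,1]")
        if self.sim is None and (self.vcf is None or self.metadata is None):
            raise PipelineConfigError("need either sim config or vcf+metadata paths")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineConfigError(f"unknown config keys: {sorted(unknown)}")
        if "anchor" in raw:
            raw["anchor"] = tuple(raw["anchor"])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclasses.dataclass
class RunBundle:
    config: RunConfig
    genotypes: GenotypeMatrix
    metadata: pd.DataFrame
    filter_report: FilterReport
    fst: diffstats.FstResult | None
    f3: admixtest.F3Result | None
    f3_chi: admixtest.F3Result | None
    ancestry: pd.DataFrame | None
    panel: profiles.DiagnosticPanel | None
    profile_table: pd.DataFrame | None
    cline_series: clines.ClineSeries | None
    cline_trend: clines.ClineTrend | None
    tally_all: topology.TopologyTally | None
    tally_subset: topology.TopologyTally | None
    manifest: dict


def _pops_to_samples(meta: pd.DataFrame, pops: list[str]) -> list[str]:
    return meta.loc[meta["population"].isin(pops), "sample"].tolist()


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> RunBundle:
    """Run every stage; optionally write the TSV/VCF result bundle."""
    config.validate()
    seed = int(config.seed) % (2**31)

    # --- ingest -----------------------------------------------------------
    if config.sim is not None:
        sim_cfg = simdata.SimConfig(**{**config.sim, "seed": config.sim.get("seed", seed)})
        sim = simdata.simulate_fusion_dataset(sim_cfg)
        G, meta = sim.genotypes, sim.metadata
    else:
        meta = read_metadata(config.metadata)
        sex_map = dict(zip(meta["sample"], meta["sex"]))
        G = read_vcf_genotypes(config.vcf, sex_map=sex_map)
    validate_joint(G, meta)

    ref_cal = _pops_to_samples(meta, config.ref_cal_pops)
    ref_hol = _pops_to_samples(meta, config.ref_hol_pops)
    targets = _pops_to_samples(meta, config.target_pops)
    chi = _pops_to_samples(meta, [config.chi_pop])
    for name, group in (("ref_cal_pops", ref_cal), ("ref_hol_pops", ref_hol)):
        if getattr(config, name) and not group:
            raise PipelineConfigError(f"{name} matched no samples")

    # --- site filters -----------------------------------------------------
    steps = [(name, dict(params)) for name, params in config.filters]
    G, report = apply_site_filters(G, steps, seed=seed + _STREAMS["filters"])
    log.info("filters: %d loci retained", G.n_loci)

    fst = f3 = f3_chi = None
    anc_table = panel = prof_table = series = trend = None
    tally_all = tally_sub = None

    if ref_cal and ref_hol:
        fst = diffstats.wc_fst(G, ref_cal, ref_hol)
        if targets:
            try:
                f3 = admixtest.f3_test(G, targets, ref_cal, ref_hol,
                                       block_size=config.f3_block_size)
            except admixtest.F3Error as exc:
                log.warning("f3 stage skipped: %s", exc)
        if chi:
            try:
                f3_chi = admixtest.f3_test(G, chi, ref_cal, ref_hol,
                                           block_size=config.f3_block_size)
            except admixtest.F3Error as exc:
                log.warning("f3 (CHI target) skipped: %s", exc)

        # --- ancestry -----------------------------------------------------
        tab = diffstats.allele_frequencies(G, {"CAL": ref_cal, "HOL": ref_hol})
        p_cal, p_hol = tab.freq[0], tab.freq[1]
        nuclear = meta.loc[meta["population"] != config.chi_pop, "sample"].tolist()
        idx = G.sample_index(nuclear)
        q_hol = ancestry.supervised_q_batch(
            G.dosage[idx], G.ploidy[idx], p_cal, p_hol
        )
        assignments = [
            ancestry.classify_assignment(
                [1 - q, q], ("CAL", "HOL"), config.assignment_threshold
            )
            for q in q_hol
        ]
        anc_table = pd.DataFrame(
            {"sample": nuclear, "q_CAL": 1 - q_hol, "q_HOL": q_hol,
             "assignment": assignments}
        )

        # --- diagnostic panel and profiles --------------------------------
        panel = profiles.build_diagnostic_panel(
            G, ref_cal, ref_hol, rule=config.panel_rule,
            threshold=config.panel_threshold,
        )
        if len(panel) == 0:
            log.warning("diagnostic panel is empty; profile stage skipped")
            panel_ok = False
        else:
            panel_ok = True
        if panel_ok:
            mt_map = dict(zip(meta["sample"], meta["mt_lineage"]))
            z_panel = panel.loci[
                G.loci.iloc[panel.loci["locus_index"]]["z_linked"].to_numpy()
            ]
            rows = []
            for s, q in zip(nuclear, q_hol):
                prof = profiles.snp_profile(G, s, panel)
                snp_q = profiles.snp_layer_q_hol(prof)
                z_call = None
                if len(z_panel):
                    z_call = profiles.z_layer_assignment(
                        G, s, int(z_panel.iloc[0]["locus_index"]),
                        str(z_panel.iloc[0]["cal_allele"]),
                    )
                try:
                    rows.append(
                        profiles.genomic_profile(
                            s,
                            mt_map.get(s, "missing").replace("missing", "") or None,
                            z_call,
                            [1 - q, q],
                            [1 - snp_q, snp_q] if np.isfinite(snp_q) else None,
                        )
                    )
                except profiles.ProfileError as exc:
                    log.info("profile excluded: %s", exc)
            prof_table = profiles.profile_table(rows)

        # --- cline --------------------------------------------------------
        try:
            series = clines.ancestry_cline_series(
                meta[meta["population"] != config.chi_pop],
                dict(zip(nuclear, q_hol)),
                anchor=config.anchor,
                exclude_pops=config.exclude_pops,
            )
            trend = clines.cline_trend(series)
        except clines.ClineError as exc:
            log.warning("cline stage skipped: %s", exc)

        # --- topology -----------------------------------------------------
        if chi:
            tab3 = diffstats.allele_frequencies(
                G, {"CAL": ref_cal, "HOL": ref_hol, "CHI": chi}
            )
            try:
                tally_all = topology.topology_tally(
                    tab3, block_size=config.topo_block_size, subset_tag="all"
                )
                mask = topology.fst_subset_mask(
                    fst.theta, config.fst_subset_threshold
                )
                tally_sub = topology.topology_tally(
                    tab3, block_size=config.topo_block_size,
                    subset_mask=mask,
                    subset_tag=f"fst_gt_{config.fst_subset_threshold}",
                )
            except topology.TopologyError as exc:
                log.warning("topology stage skipped: %s", exc)

    manifest = {
        "config_hash": config.config_hash(),
        "seed": seed,
        "n_samples": G.n_samples,
        "n_loci_after_filters": G.n_loci,
        "stages": {
            "fst": fst is not None,
            "f3": f3 is not None,
            "ancestry": anc_table is not None,
            "panel": panel is not None and len(panel) > 0,
            "profiles": prof_table is not None,
            "cline": trend is not None,
            "topology": tally_all is not None,
        },
    }
    bundle = RunBundle(
        config=config, genotypes=G, metadata=meta, filter_report=report,
        fst=fst, f3=f3, f3_chi=f3_chi, ancestry=anc_table, panel=panel,
        profile_table=prof_table, cline_series=series, cline_trend=trend,
        tally_all=tally_all, tally_subset=tally_sub, manifest=manifest,
    )
    if outdir is not None:
        write_bundle(bundle, outdir)
    return bundle


def write_bundle(bundle: RunBundle, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_vcf(bundle.genotypes, out / "filtered.vcf")
    write_metadata(bundle.metadata, out / "metadata.tsv")
    bundle.filter_report.to_frame().to_csv(out / "filter_report.tsv", sep="\t",
                                           index=False)
    if bundle.fst is not None:
        per_snp = bundle.fst.loci[["chrom", "pos"]].copy()
        per_snp["theta"] = bundle.fst.theta
        per_snp.to_csv(out / "fst_per_snp.tsv", sep="\t", index=False)
    if bundle.f3 is not None:
        rows = [dataclasses.asdict(bundle.f3) | {"target": "admixed"}]
        if bundle.f3_chi is not None:
            rows.append(dataclasses.asdict(bundle.f3_chi) | {"target": "CHI"})
        pd.DataFrame(rows).to_csv(out / "f3.tsv", sep="\t", index=False)
    if bundle.ancestry is not None:
        bundle.ancestry.to_csv(out / "ancestry.tsv", sep="\t", index=False)
    if bundle.panel is not None and len(bundle.panel):
        bundle.panel.loci.to_csv(out / "panel.tsv", sep="\t", index=False)
    if bundle.profile_table is not None:
        bundle.profile_table.to_csv(out / "profiles.tsv", sep="\t", index=False)
    if bundle.cline_series is not None:
        bundle.cline_series.table.to_csv(out / "cline_series.tsv", sep="\t",
                                         index=False)
    if bundle.cline_trend is not None:
        pd.DataFrame([dataclasses.asdict(bundle.cline_trend)]).to_csv(
            out / "cline_trend.tsv", sep="\t", index=False
        )
    if bundle.tally_all is not None:
        frames = [bundle.tally_all.to_frame().assign(subset=bundle.tally_all.subset)]
        if bundle.tally_subset is not None:
            frames.append(
                bundle.tally_subset.to_frame().assign(
                    subset=bundle.tally_subset.subset
                )
            )
        pd.concat(frames).to_csv(out / "topology.tsv", sep="\t", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, sort_keys=True)
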
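"""Pipeline orchestration: simulate -> scan -> associate -> prioritize.

Each stage reads only its declared inputs, writes to its own subdirectory of
the output folder, and records row counts, timings and input digests in a
run manifest.  One global seed expands deterministically into per-stage
seeds so stages can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genotypes import read_marker_map, read_vcf
from .phenotypes import build_category_table
from .prioritize import (candidates_to_frame, concordance_filter, rank_candidates,
                         read_exons, read_variant_vcf)
from .scan import assign_carrier_status, merge_significant_windows, records_to_frame, scan
from .simulate import (SimulationConfig, config_from_dict, days_to_date, emulate_chip,
                       simulate_population, simulate_variant_calls, write_variant_vcf)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "scan", "associate", "prioritize")


class PipelineConfigError(ValueError):
    """Configuration problem, reported with the stage and field name."""


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise PipelineConfigError("config root must be a mapping of stage blocks")
    unknown = set(cfg) - set(STAGES)
    if unknown:
        raise PipelineConfigError(f"unknown stage blocks: {sorted(unknown)}")
    return cfg


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _require(cfg: dict, stage: str, field: str) -> object:
    if field not in cfg or cfg[field] is None:
        raise PipelineConfigError(f"{stage}: missing required field '{field}'")
    return cfg[field]


def _resolve(base: Path, value: str) -> Path:
    p = Path(value)
    return p if p.is_absolute() else base / p


def run_pipeline(config_path: str | Path, out_dir: str | Path, *,
                 seed: int | None = None,
                 stages: tuple[str, ...] | None = None) -> Path:
    """Execute the requested stages in order, writing a run manifest.

    Later stages default their inputs to the outputs of earlier stages in
    the same output directory, so a full run needs no file paths in the
    config.  Existing stage outputs are reused when a stage is not requested.
    """
    t0 = time.time()
    cfg = load_config(config_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base = Path(config_path).resolve().parent
    stages = tuple(stages) if stages else STAGES
    for s in stages:
        if s not in STAGES:
            raise PipelineConfigError(f"unknown stage '{s}'")

    manifest: dict = {
        "package_version": __version__,
        "seed": seed,
        "config": cfg,
        "stages": {},
    }

    sim_dir = out_dir / "simulate"
    scan_dir = out_dir / "scan"
    assoc_dir = out_dir / "associate"
    prio_dir = out_dir / "prioritize"

    if "simulate" in stages:
        t = time.time()
        sim_cfg = dict(cfg.get("simulate") or {})
        if seed is not None:
            sim_cfg["rng_seed"] = int(seed)
        config = config_from_dict(sim_cfg)
        result = simulate_population(config)
        sim_dir.mkdir(exist_ok=True)
        vcf_path, map_path = emulate_chip(result.phased, sim_dir)
        ped = result.pedigree.copy()
        ped["birth_date"] = days_to_date(ped["birth_date"]).dt.date
        ped.to_csv(sim_dir / "pedigree.csv", index=False)
        matings = result.matings.copy()
        matings["date"] = days_to_date(matings["date"]).dt.date
        matings.to_csv(sim_dir / "matings.csv", index=False)
        foals = result.foals.copy()
        foals["birth_date"] = days_to_date(foals["birth_date"]).dt.date
        foals["death_date"] = days_to_date(foals["death_date"]).dt.date
        foals.loc[result.foals["death_date"].isna(), "death_date"] = ""
        foals.to_csv(sim_dir / "foals.csv", index=False)
        with open(sim_dir / "truth.json", "w") as fh:
            json.dump(result.true_state.to_json_dict(), fh, indent=1)
        variants, flags = simulate_variant_calls(result.phased, result.true_state,
                                                 config)
        write_variant_vcf(variants, flags, config, sim_dir / "sequenced_sires.vcf")
        pd.DataFrame({"animal_id": sorted(flags),
                      "carrier": [int(flags[s]) for s in sorted(flags)]}
                     ).to_csv(sim_dir / "sequenced_carriers.csv", index=False)
        manifest["stages"]["simulate"] = {
            "seconds": round(time.time() - t, 2),
            "config": dataclasses.asdict(config),
            "n_genotyped": result.phased.n_animals,
            "n_markers": result.phased.n_markers,
            "n_matings": len(result.matings),
            "n_foals": len(result.foals),
        }

    if "scan" in stages:
        t = time.time()
        scan_cfg = dict(cfg.get("scan") or {})
        vcf_in = _resolve(base, scan_cfg.pop("vcf")) if "vcf" in scan_cfg \
            else sim_dir / "genotypes.vcf"
        map_in = _resolve(base, scan_cfg.pop("map")) if "map" in scan_cfg \
            else sim_dir / "genotypes.map.tsv"
        if not Path(vcf_in).exists():
            raise PipelineConfigError(f"scan: input VCF not found: {vcf_in}")
        phased = read_vcf(vcf_in)
        if Path(map_in).exists():
            # cross-check the marker map against the VCF records
            ext = read_marker_map(map_in)
            if not np.array_equal(ext["pos_bp"].to_numpy(),
                                  phased.markers["pos_bp"].to_numpy()):
                raise PipelineConfigError("scan: marker map does not match the VCF")
        sizes = tuple(int(s) for s in scan_cfg.pop("window_sizes", (1_000_000,
                                                                   2_000_000)))
        records = scan(phased, window_sizes=sizes, **scan_cfg)
        regions = merge_significant_windows(records)
        scan_dir.mkdir(exist_ok=True)
        records_to_frame(records).to_csv(scan_dir / "haplotypes.tsv", sep="\t",
                                         index=False)
        pd.DataFrame([{
            "region_id": f"R{i + 1}", "chrom": r.chrom,
            "start_bp": r.start, "end_bp": r.end,
            "n_windows": len(r.records),
            "p_adj": r.representative.p_adj,
        } for i, r in enumerate(regions)],
            columns=["region_id", "chrom", "start_bp", "end_bp",
                     "n_windows", "p_adj"]).to_csv(
            scan_dir / "regions.tsv", sep="\t", index=False)
        carrier_frames = []
        for i, region in enumerate(regions):
            tab = assign_carrier_status(phased, region)
            tab.insert(0, "region_id", f"R{i + 1}")
            carrier_frames.append(tab)
        carriers = pd.concat(carrier_frames, ignore_index=True) if carrier_frames \
            else pd.DataFrame(columns=["region_id", "animal_id", "status"])
        carriers.to_csv(scan_dir / "carriers.csv", index=False)
        manifest["stages"]["scan"] = {
            "seconds": round(time.time() - t, 2),
            "inputs": {"vcf": str(vcf_in), "digest": _digest(Path(vcf_in))},
            "n_tested_haplotypes": len(records),
            "n_significant": sum(r.significant for r in records),
            "n_regions": len(regions),
        }

    if "associate" in stages:
        t = time.time()
        assoc_cfg = dict(cfg.get("associate") or {})
        paths = {}
        for name, default in (("matings", sim_dir / "matings.csv"),
                              ("foals", sim_dir / "foals.csv"),
                              ("pedigree", sim_dir / "pedigree.csv"),
                              ("carriers", scan_dir / "carriers.csv")):
            p = _resolve(base, assoc_cfg.pop(name)) if name in assoc_cfg else default
            if not Path(p).exists():
                raise PipelineConfigError(f"associate: missing input file "
                                          f"'{name}': {p}")
            paths[name] = Path(p)
        matings = pd.read_csv(paths["matings"])
        foals = pd.read_csv(paths["foals"])
        pedigree = pd.read_csv(paths["pedigree"], keep_default_na=False)
        carriers = pd.read_csv(paths["carriers"])
        gestation = (int(assoc_cfg.pop("gestation_min", 300)),
                     int(assoc_cfg.pop("gestation_max", 400)))
        window = int(assoc_cfg.pop("remating_window", 10))
        assoc_dir.mkdir(exist_ok=True)
        tables = []
        for region_id, sub in carriers.groupby("region_id"):
            tab = build_category_table(matings, foals, sub, pedigree,
                                       remating_window=window,
                                       gestation_window=gestation)
            tab.insert(0, "region_id", region_id)
            tables.append(tab)
        result_tab = pd.concat(tables, ignore_index=True) if tables else \
            pd.DataFrame()
        result_tab.to_csv(assoc_dir / "phenotypes.tsv", sep="\t", index=False)
        manifest["stages"]["associate"] = {
            "seconds": round(time.time() - t, 2),
            "inputs": {k: str(v) for k, v in paths.items()},
            "n_regions": carriers["region_id"].nunique() if len(carriers) else 0,
        }

    if "prioritize" in stages:
        t = time.time()
        prio_cfg = dict(cfg.get("prioritize") or {})
        vcf_in = _resolve(base, prio_cfg["vcf"]) if "vcf" in prio_cfg \
            else sim_dir / "sequenced_sires.vcf"
        flags_in = _resolve(base, prio_cfg["carriers"]) if "carriers" in prio_cfg \
            else sim_dir / "sequenced_carriers.csv"
        regions_in = _resolve(base, prio_cfg["regions"]) if "regions" in prio_cfg \
            else scan_dir / "regions.tsv"
        for name, p in (("vcf", vcf_in), ("carriers", flags_in),
                        ("regions", regions_in)):
            if not Path(p).exists():
                raise PipelineConfigError(f"prioritize: missing input file "
                                          f"'{name}': {p}")
        variants = read_variant_vcf(vcf_in,
                                    consequence_key=prio_cfg.get("consequence_key",
                                                                 "CSQ"))
        flags_tab = pd.read_csv(flags_in)
        flags = dict(zip(flags_tab["animal_id"], flags_tab["carrier"].astype(bool)))
        regions_tab = pd.read_csv(regions_in, sep="\t", dtype={"chrom": str})
        exons = read_exons(_resolve(base, prio_cfg["exons"])) \
            if "exons" in prio_cfg else None
        margin = int(prio_cfg.get("margin", 4_000_000))
        prio_dir.mkdir(exist_ok=True)
        frames = []
        for row in regions_tab.itertuples(index=False):
            try:
                cands = concordance_filter(variants, flags, str(row.chrom),
                                           int(row.start_bp), int(row.end_bp),
                                           margin=margin)
            except ValueError as err:
                logger.warning("region %s skipped: %s", row.region_id, err)
                continue
            ranked = rank_candidates(cands, exons=exons)
            tab = candidates_to_frame(ranked)
            tab.insert(0, "region_id", row.region_id)
            frames.append(tab)
        out_tab = pd.concat(frames, ignore_index=True) if frames else \
            pd.DataFrame(columns=["region_id", "chrom", "pos", "ref", "alt",
                                  "class", "tier"])
        out_tab.to_csv(prio_dir / "candidates.tsv", sep="\t", index=False)
        manifest["stages"]["prioritize"] = {
            "seconds": round(time.time() - t, 2),
            "inputs": {"vcf": str(vcf_in), "digest": _digest(Path(vcf_in))},
            "n_variants": len(variants),
            "n_candidates": len(out_tab),
        }

    manifest["total_seconds"] = round(time.time() - t0, 2)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return out_dir
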
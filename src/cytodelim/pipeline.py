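"""End-to-end orchestration of the niche and variant stages.

Each runner executes its stage chain from one declarative configuration,
writes per-stage artifacts plus a JSON summary embedding the seed, a config
hash, and the package version, and is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .extraction import extract_at_points, prune_correlated, zscore
from .fragments import fragment_sampler, write_fragment_fastas
from .niche_space import pca_fit
from .overlap import permutation_test
from .rasters import EnvLayer
from .thinning import OccurrenceSet, thin
from .variants import FilterConfig, run_cascade, write_structure
from .vcfio import read_bed, read_gff_cds, read_vcf, write_vcf


def config_hash(cfg) -> str:
    """Hash of the analysis-relevant configuration (output location excluded,
    so reruns into different directories compare equal)."""
    payload = dataclasses.asdict(cfg)
    payload.pop("out_dir", None)
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _write_json(path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
        fh.write("\n")


@dataclass
class NicheRunConfig:
    occurrences: str
    rasters: list[str]
    out_dir: str
    threshold_km: float = 1.0
    per_species_thinning: bool = True
    r_threshold: float = 0.8
    keep_list: list[str] = field(default_factory=list)
    grid_size: int = 100
    bandwidth: str = "scott"
    replicates: int = 1000
    seed: int = 0


def run_niche(cfg: NicheRunConfig) -> dict:
    """thin -> extract -> prune -> zscore -> PCA -> KDE overlap -> permutation.

    Writes ``thinned.csv``, ``env_matrix.csv``, ``scores.csv`` and
    ``niche_summary.json`` under ``cfg.out_dir`` and returns the summary.
    """
    os.makedirs(cfg.out_dir, exist_ok=True)
    occ = OccurrenceSet.read_csv(cfg.occurrences)
    layers = [EnvLayer.read_ascii(p) for p in cfg.rasters]

    thinned, thin_report = thin(occ, cfg.threshold_km, cfg.per_species_thinning)
    thinned.write_csv(os.path.join(cfg.out_dir, "thinned.csv"))

    env = extract_at_points(layers, thinned)
    env = prune_correlated(env, cfg.r_threshold, cfg.keep_list)
    env = zscore(env)
    env.data.assign(species=env.species).to_csv(
        os.path.join(cfg.out_dir, "env_matrix.csv"), index_label="record"
    )

    pca = pca_fit(env, n_components=2)
    pca.scores.assign(species=pca.species).to_csv(
        os.path.join(cfg.out_dir, "scores.csv"), index_label="record"
    )

    result = permutation_test(
        pca.scores.to_numpy(),
        pca.species.to_numpy(),
        grid_size=cfg.grid_size,
        bandwidth_rule=cfg.bandwidth,
        replicates=cfg.replicates,
        seed=cfg.seed,
    )
    summary = {
        "version": __version__,
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "n_input_records": len(occ),
        "n_thinned": len(thinned),
        "n_dropped_thinning": len(thin_report.dropped),
        "n_dropped_extraction": len(env.dropped_records),
        "pruned_variables": env.pruned,
        "retained_variables": env.variables,
        "explained_variance_ratio": pca.explained_variance_ratio.tolist(),
        "overlap": result.to_dict(),
    }
    _write_json(os.path.join(cfg.out_dir, "niche_summary.json"), summary)
    return summary


@dataclass
class VariantRunConfig:
    vcf: str
    out_dir: str
    cds: str | None = None        # BED or GFF3 (CDS features)
    te: str | None = None         # BED
    depth_low_factor: float = 1.0 / 3.0
    depth_high_factor: float = 2.0
    depth_mode: str = "site_total"
    flank: int = 2000
    min_dist: int = 20000
    remove_singletons: bool = True
    write_structure_file: bool = True
    consensus_dir: str | None = None   # per-sample FASTA (records = chromosomes)
    fragment_len: int = 1000
    fragment_interval: int = 20000
    fragment_max_n: int = 50
    seed: int = 0


def _read_intervals(path: str | None) -> dict[str, np.ndarray]:
    if path is None:
        return {}
    if path.endswith((".gff", ".gff3")):
        return read_gff_cds(path)
    return read_bed(path)


def _read_consensus_dir(path: str) -> dict[str, dict[str, str]]:
    from Bio import SeqIO

    out: dict[str, dict[str, str]] = {}
    for fn in sorted(os.listdir(path)):
        if not fn.endswith((".fa", ".fasta")):
            continue
        sample = os.path.splitext(fn)[0]
        out[sample] = {
            rec.id: str(rec.seq) for rec in SeqIO.parse(os.path.join(path, fn), "fasta")
        }
    return out


def run_variants(cfg: VariantRunConfig) -> dict:
    """Filter cascade, then optional STRUCTURE export and fragment sampling."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    vm = read_vcf(cfg.vcf)
    fc = FilterConfig(
        depth_low_factor=cfg.depth_low_factor,
        depth_high_factor=cfg.depth_high_factor,
        depth_mode=cfg.depth_mode,
        flank=cfg.flank,
        min_dist=cfg.min_dist,
        remove_singletons=cfg.remove_singletons,
    )
    filtered, report = run_cascade(
        vm, fc, _read_intervals(cfg.cds), _read_intervals(cfg.te)
    )
    write_vcf(filtered, os.path.join(cfg.out_dir, "filtered.vcf"))
    if cfg.write_structure_file:
        write_structure(filtered, os.path.join(cfg.out_dir, "structure.txt"))

    frag_report = None
    if cfg.consensus_dir:
        seqs = _read_consensus_dir(cfg.consensus_dir)
        frags = fragment_sampler(
            seqs, cfg.fragment_len, cfg.fragment_interval, cfg.fragment_max_n
        )
        write_fragment_fastas(frags, os.path.join(cfg.out_dir, "fragments"))
        frag_report = frags.report()

    summary = {
        "version": __version__,
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "filter_report": report.to_dict(),
        "n_survivors": filtered.n_sites,
        "fragments": frag_report,
    }
    _write_json(os.path.join(cfg.out_dir, "variant_summary.json"), summary)
    return summary
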
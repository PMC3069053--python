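"""End-to-end orchestration: simulate/load -> MOTUs -> tree -> concordance ->
diversity -> community comparison, with one consolidated JSON report.

All randomness derives from a single pipeline seed through named
substreams (one per stochastic stage), so changing e.g. the number of
accumulation-curve permutations never perturbs the Mantel test.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import community as comm
from . import diversity as div
from .clustering import cluster_motus, motu_threshold_profile, pairwise_distances
from .concordance import concordance_analysis
from .errors import DegenerateInputError, ParameterError
from .io import (
    AlignedSeqSet,
    MotuPartition,
    ResultsReport,
    SpecimenTable,
    build_community_matrix,
    read_fasta,
    read_specimens,
    write_fasta,
    write_motus,
    write_specimens,
)
from .njtree import motu_tree, write_newick
from .simulate import SimConfig, simulate

log = logging.getLogger("motudiv")

# fixed substream tags: stage -> offset mixed into the pipeline seed
_STREAMS = {
    "accumulation_morphospecies": 11,
    "accumulation_motu": 12,
    "mantel": 21,
    "habitat_fit_morphospecies": 31,
    "habitat_fit_motu": 32,
}


@dataclass(frozen=True)
class PipelineConfig:
    """Inputs (simulation config or file paths) plus analysis settings."""

    seed: int
    simulation: SimConfig | None = None
    fasta: str | None = None
    specimens: str | None = None
    thresholds: tuple[int, ...] = (1, 2, 3)
    n_permutations: int = 1000
    include_failed_morphospecies: bool = True
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.simulation is None and (self.fasta is None or self.specimens is None):
            raise ParameterError(
                "provide either a simulation config or fasta + specimens paths"
            )
        if not self.thresholds:
            raise ParameterError("thresholds must be non-empty")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sim = raw.pop("simulation", None)
        if sim is not None:
            sim = SimConfig(**sim)
        if "thresholds" in raw:
            raw["thresholds"] = tuple(int(t) for t in raw["thresholds"])
        return cls(simulation=sim, **raw)


def _rng(cfg: PipelineConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, _STREAMS[stage]])


def run_pipeline(cfg: PipelineConfig) -> ResultsReport:
    """Run every analysis stage and return (and optionally write) the report."""
    out = Path(cfg.out_dir) if cfg.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    # ---- inputs ----------------------------------------------------------
    if cfg.simulation is not None:
        log.info("simulating community (seed=%d)", cfg.simulation.seed)
        specimens, seqs, truth = simulate(cfg.simulation)
        if out:
            write_fasta(seqs, out / "seqs.fasta")
            write_specimens(specimens, out / "specimens.tsv")
            truth.save(out / "ground_truth.json")
            cfg.simulation.to_yaml(out / "sim_config.yaml")
    else:
        seqs = read_fasta(cfg.fasta)
        specimens = read_specimens(cfg.specimens)
    specimens.validate_against(seqs)

    report = ResultsReport()
    report["config"] = {
        "seed": cfg.seed,
        "thresholds": list(cfg.thresholds),
        "n_permutations": cfg.n_permutations,
        "linkage": "single",
        "ci_method": "permutation-percentile",
        "include_failed_morphospecies": cfg.include_failed_morphospecies,
    }
    report["sequencing"] = {
        "n_attempted": specimens.n_attempted,
        "n_success": specimens.n_success,
        "success_rate_percent": specimens.success_rate_percent,
    }

    # ---- MOTU delimitation ----------------------------------------------
    dm = pairwise_distances(seqs)
    seq2spec = specimens.sequence_to_specimen()
    partitions: dict[int, MotuPartition] = {
        t: cluster_motus(dm, t, id_map=seq2spec) for t in sorted(cfg.thresholds)
    }
    profile = motu_threshold_profile(dm, cfg.thresholds)
    report["motus"] = {
        "n_motus_by_threshold": {str(t): n for t, n in profile.items()}
    }
    primary_t = sorted(cfg.thresholds)[0]
    partition = partitions[primary_t]
    if out:
        seq_of = {spec: seq for seq, spec in seq2spec.items()}
        for t, part in partitions.items():
            write_motus(part, out / f"motus_t{t}.tsv", sequence_of=seq_of)
    n_morpho = specimens.df["morphospecies_id"].nunique()
    report["n_morphospecies"] = int(n_morpho)

    # ---- NJ tree over MOTU representatives ------------------------------
    if partition.n_motus >= 3:
        tree = motu_tree(seqs, partition, specimens)
        if out:
            write_newick(tree, out / "tree.nwk")
        report["tree"] = {"n_leaves": partition.n_motus}
    else:
        warnings.warn("fewer than 3 MOTUs; skipping NJ tree")
        report["tree"] = None

    # ---- concordance -----------------------------------------------------
    conc = concordance_analysis(specimens, partition)
    report["concordance"] = {
        k: v for k, v in conc.to_dict().items() if k != "components"
    }
    if out:
        with open(out / "concord.json", "w") as fh:
            json.dump(conc.to_dict(), fh, indent=2, sort_keys=True)

    # ---- community matrices ---------------------------------------------
    mats = {}
    for source in ("morphospecies", "motu"):
        kw = dict(
            taxon_source=source,
            partition=partition if source == "motu" else None,
            include_failed=cfg.include_failed_morphospecies,
        )
        mats[source] = {
            "trap": build_community_matrix(specimens, unit_level="trap", **kw),
            "transect": build_community_matrix(specimens, unit_level="transect", **kw),
        }
    trap2transect = specimens.trap_to_transect()
    transect_habitat = specimens.transect_to_habitat()

    # ---- diversity -------------------------------------------------------
    diversity = {}
    rd = {}
    for source in ("morphospecies", "motu"):
        cm_trap = mats[source]["trap"]
        cm_tr = mats[source]["transect"]
        rd[source] = div.richness_and_density(cm_trap, cm_tr, trap2transect)
        jack = div.jackknife1(cm_trap)
        curve = div.accumulation_curve(
            cm_trap, n_permutations=cfg.n_permutations,
            rng=_rng(cfg, f"accumulation_{source}"),
        )
        habitats = rd[source].transect_richness.index.map(transect_habitat)
        rich = rd[source].transect_richness
        dens = rd[source].transect_density
        welch_rich = div.welch_t(
            rich[habitats == "primary"], rich[habitats == "secondary"]
        )
        welch_dens = div.welch_t(
            dens[habitats == "primary"], dens[habitats == "secondary"]
        )
        diversity[source] = {
            "richness_per_transect": rich.to_dict(),
            "density_per_transect": dens.to_dict(),
            "jackknife1": {
                "s_obs": jack.s_obs, "f1": jack.f1, "m": jack.m,
                "estimate": jack.estimate, "se": jack.se,
            },
            "accumulation_curve": {
                "h": curve.h.tolist(),
                "mean_richness": curve.mean_richness.tolist(),
                "ci_low": curve.ci_low.tolist(),
                "ci_high": curve.ci_high.tolist(),
            },
            "welch_richness_primary_vs_secondary": welch_rich.to_dict(),
            "welch_density_primary_vs_secondary": welch_dens.to_dict(),
        }
    order = sorted(rd["morphospecies"].transect_richness.index)
    diversity["paired_t_richness_morpho_vs_motu"] = div.paired_t(
        rd["morphospecies"].transect_richness[order],
        rd["motu"].transect_richness[order],
    ).to_dict()
    diversity["paired_t_density_morpho_vs_motu"] = div.paired_t(
        rd["morphospecies"].transect_density[order],
        rd["motu"].transect_density[order],
    ).to_dict()
    report["diversity"] = diversity
    if out:
        with open(out / "div.json", "w") as fh:
            json.dump(diversity, fh, indent=2, sort_keys=True)

    # ---- community structure --------------------------------------------
    compare = {}
    bc = {}
    for source in ("morphospecies", "motu"):
        cm_tr = mats[source]["transect"]
        bc[source] = comm.bray_curtis(cm_tr)
        try:
            ord_res = comm.dca(cm_tr)
            groups = [transect_habitat[u] for u in ord_res.site_scores.index]
            fit = comm.fit_factor(
                ord_res.site_scores, groups,
                n_perm=cfg.n_permutations,
                rng=_rng(cfg, f"habitat_fit_{source}"),
            )
            compare[source] = {
                "bray_curtis": bc[source].as_frame().round(10).to_dict(),
                "dca_eigenvalues": list(ord_res.eigenvalues),
                "dca_site_scores": ord_res.site_scores.round(10).to_dict(),
                "habitat_fit": {
                    "r_squared": fit.r_squared, "p": fit.p,
                    "n_perm": fit.n_perm, "method": fit.method,
                },
            }
        except DegenerateInputError as exc:
            warnings.warn(f"ordination skipped for {source}: {exc}")
            compare[source] = {
                "bray_curtis": bc[source].as_frame().round(10).to_dict(),
                "dca_site_scores": None, "habitat_fit": None,
            }
    mres = comm.mantel(
        bc["morphospecies"], bc["motu"],
        n_perm=cfg.n_permutations, rng=_rng(cfg, "mantel"),
    )
    compare["mantel_morpho_vs_motu"] = {
        "r": mres.r, "p": mres.p, "n_perm": mres.n_perm, "method": mres.method,
    }
    report["community"] = compare
    if out:
        with open(out / "compare.json", "w") as fh:
            json.dump(compare, fh, indent=2, sort_keys=True)
        report.save(out / "report.json")
    return report
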
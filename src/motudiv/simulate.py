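"""Synthetic pitfall-trap communities with known taxonomic ground truth.

The generator emulates a standardized tropical pitfall survey: six 200 m
transects (three per habitat, primary vs secondary forest), ten traps per
transect, morphospecies sorting of every catch, and one specimen per
morphospecies per trap entering sequencing of a short nuclear marker
(~180 bp).  Ground truth is engineered at the species-pool level:

* *cryptic pairs* — two true species (prototype sequences at least
  ``min_interspecific_bp`` apart) sharing one morphospecies label; a
  correct pipeline reports them as lumpings (one morphospecies, >= 2 MOTUs);
* *dimorphic species* — one true species sorted into two morphospecies
  labels (e.g. strong sexual dimorphism); reported as splittings;
* *habitat structure* — a configurable fraction of species is restricted
  to one habitat; specialists are assigned to habitats alternately so the
  per-habitat pools stay balanced.

Abundances follow a Fisher log-series per habitat (the standard null for
insect pitfall data): each species receives a log-series abundance score
in the habitats it occupies, and each trap draws a Poisson total split
multinomially by the normalised scores.  Per-trap species weights are
additionally multiplied by gamma noise (shape ``trap_aggregation``,
mean 1), emulating the strong spatial clumping of leaf-litter arthropods:
without it every trap would sample the same habitat-level community and
per-trap richness would be unrealistically even.  Intraspecific sequence variants
mutate at most ``floor((min_interspecific_bp - 1) / 2)`` sites, keeping
single-linkage ground truth unambiguous.  Mutations are substitutions
only; gap handling in the distance layer is exercised by hand-built
fixtures instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import yaml
from scipy import stats

from .errors import GenerationError, ParameterError
from .io import SEQUENCING_FAILED, AlignedSeqSet, SpecimenTable
import pandas as pd

_BASES = np.array(list("ACGT"))

HABITATS = ("primary", "secondary")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic survey; defaults mirror the study scale."""

    n_species: int
    seed: int
    seq_length: int = 180
    min_interspecific_bp: int = 3
    intraspecific_variant_rate: float = 0.02
    n_cryptic_pairs: int = 0
    n_dimorphic_species: int = 0
    n_transects_per_habitat: int = 3
    traps_per_transect: int = 10
    abundance_model: Mapping[str, float] = field(
        default_factory=lambda: {"primary": 0.999, "secondary": 0.999}
    )
    habitat_specialist_fraction: float = 0.5
    failure_rate: float = 0.009
    one_per_morphospecies_per_trap: bool = True
    mean_trap_abundance: float = 25.0
    trap_aggregation: float = 0.1

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ParameterError("n_species must be >= 1")
        if self.min_interspecific_bp < 1:
            raise ParameterError("min_interspecific_bp must be >= 1")
        for name in ("intraspecific_variant_rate", "habitat_specialist_fraction",
                     "failure_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        if 2 * self.n_cryptic_pairs + self.n_dimorphic_species > self.n_species:
            raise ParameterError(
                "2*n_cryptic_pairs + n_dimorphic_species exceeds n_species"
            )
        for h in HABITATS:
            p = self.abundance_model[h]
            if not 0.0 < p < 1.0:
                raise ParameterError(f"log-series parameter for {h} must be in (0,1)")
        if self.trap_aggregation <= 0:
            raise ParameterError("trap_aggregation (gamma shape) must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "seed" not in raw:
            raise ParameterError("simulation config must set an explicit seed")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["abundance_model"] = dict(d["abundance_model"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


@dataclass(frozen=True)
class SpeciesPool:
    prototypes: dict[str, str]              # species -> prototype sequence
    morpho_labels: dict[str, tuple[str, ...]]  # species -> 1 or 2 labels
    habitat_pref: dict[str, str]            # species -> primary|secondary|both
    cryptic_pairs: tuple[tuple[str, str, str], ...]  # (sp_a, sp_b, shared label)
    dimorphic: tuple[str, ...]              # species with two labels


@dataclass(frozen=True)
class GroundTruth:
    true_species: dict[str, str]            # specimen -> species
    pool: SpeciesPool
    trap_to_transect: dict[str, str]
    transect_to_habitat: dict[str, str]

    def to_dict(self) -> dict:
        return {
            "true_species": dict(self.true_species),
            "prototypes": dict(self.pool.prototypes),
            "morpho_labels": {k: list(v) for k, v in self.pool.morpho_labels.items()},
            "habitat_pref": dict(self.pool.habitat_pref),
            "cryptic_pairs": [list(t) for t in self.pool.cryptic_pairs],
            "dimorphic": list(self.pool.dimorphic),
            "trap_to_transect": dict(self.trap_to_transect),
            "transect_to_habitat": dict(self.transect_to_habitat),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# species pool
# ---------------------------------------------------------------------------

def generate_species_pool(cfg: SimConfig, rng: np.random.Generator) -> SpeciesPool:
    """Draw prototype sequences, morphospecies labels and habitat preferences.

    All prototype pairs differ by at least ``min_interspecific_bp``
    positions; a bounded retry loop raises :class:`GenerationError` (advising
    a larger ``seq_length``) if the constraint cannot be met.
    """
    species = [f"SPC{i + 1:03d}" for i in range(cfg.n_species)]
    max_tries = 200
    placed = np.empty((0, cfg.seq_length), dtype=np.int8)
    for sp in species:
        for _ in range(max_tries):
            cand = rng.integers(0, 4, size=cfg.seq_length, dtype=np.int8)
            if placed.size == 0 or (
                (placed != cand).sum(axis=1).min() >= cfg.min_interspecific_bp
            ):
                placed = np.vstack([placed, cand])
                break
        else:
            raise GenerationError(
                f"could not place species {sp} at >= {cfg.min_interspecific_bp} bp "
                f"from the pool after {max_tries} tries; increase seq_length"
            )
    prototypes = {
        sp: "".join(_BASES[row]) for sp, row in zip(species, placed)
    }

    morpho_labels: dict[str, tuple[str, ...]] = {}
    cryptic: list[tuple[str, str, str]] = []
    dimorphic: list[str] = []
    label_no = 0

    def next_label() -> str:
        nonlocal label_no
        label_no += 1
        return f"MSP{label_no:03d}"

    idx = 0
    for _ in range(cfg.n_cryptic_pairs):
        shared = next_label()
        a, b = species[idx], species[idx + 1]
        morpho_labels[a] = (shared,)
        morpho_labels[b] = (shared,)
        cryptic.append((a, b, shared))
        idx += 2
    for _ in range(cfg.n_dimorphic_species):
        sp = species[idx]
        morpho_labels[sp] = (next_label(), next_label())
        dimorphic.append(sp)
        idx += 1
    for sp in species[idx:]:
        morpho_labels[sp] = (next_label(),)

    # habitat preferences: specialists alternate habitats -> balanced pools
    specialist = rng.random(cfg.n_species) < cfg.habitat_specialist_fraction
    habitat_pref: dict[str, str] = {}
    k = 0
    for sp, is_spec in zip(species, specialist):
        if is_spec:
            habitat_pref[sp] = HABITATS[k % 2]
            k += 1
        else:
            habitat_pref[sp] = "both"

    return SpeciesPool(
        prototypes=prototypes,
        morpho_labels=morpho_labels,
        habitat_pref=habitat_pref,
        cryptic_pairs=tuple(cryptic),
        dimorphic=tuple(dimorphic),
    )


# ---------------------------------------------------------------------------
# community sampling
# ---------------------------------------------------------------------------

def _mutate(seq: str, n_sites: int, rng: np.random.Generator) -> str:
    if n_sites < 1:
        return seq
    pos = rng.choice(len(seq), size=n_sites, replace=False)
    chars = list(seq)
    for p in pos:
        alts = [b for b in "ACGT" if b != chars[p]]
        chars[p] = alts[rng.integers(0, 3)]
    return "".join(chars)


def sample_community(
    cfg: SimConfig, pool: SpeciesPool, rng: np.random.Generator
) -> tuple[SpecimenTable, AlignedSeqSet, GroundTruth]:
    """Sample trap catches and emit the sequenced specimens.

    Per trap the total catch is Poisson(``mean_trap_abundance``) split
    multinomially by the habitat's log-series abundance scores.  With
    ``one_per_morphospecies_per_trap`` only one specimen per
    (trap, morphospecies) enters sequencing — the study's subsampling rule —
    and only those specimens appear in the output table.  Dimorphic species
    alternate their two morph labels across successive individuals, so any
    such species caught at least twice expresses both labels.
    """
    species = list(pool.prototypes)
    transects: list[str] = []
    transect_habitat: dict[str, str] = {}
    for h in HABITATS:
        for i in range(cfg.n_transects_per_habitat):
            tid = f"{h[:3].upper()}{i + 1}"
            transects.append(tid)
            transect_habitat[tid] = h
    trap_transect: dict[str, str] = {}
    for tid in transects:
        for j in range(cfg.traps_per_transect):
            trap_transect[f"{tid}_T{j + 1:02d}"] = tid

    # per-habitat abundance scores (log-series), zero outside the preference
    scores = {h: np.zeros(len(species)) for h in HABITATS}
    for si, sp in enumerate(species):
        pref = pool.habitat_pref[sp]
        for h in HABITATS:
            if pref in (h, "both"):
                scores[h][si] = stats.logser.rvs(
                    cfg.abundance_model[h], random_state=rng
                )
    probs = {}
    for h in HABITATS:
        tot = scores[h].sum()
        if tot <= 0:
            raise GenerationError(f"no species can occur in habitat {h!r}")
        probs[h] = scores[h] / tot

    n_variant_sites = (cfg.min_interspecific_bp - 1) // 2
    rows: list[tuple[str, ...]] = []
    records: dict[str, str] = {}
    true_species: dict[str, str] = {}
    morph_counter = {sp: 0 for sp in pool.dimorphic}
    spec_no = 0
    seq_no = 0

    for trap, tid in trap_transect.items():
        h = transect_habitat[tid]
        n_ind = int(rng.poisson(cfg.mean_trap_abundance))
        # gamma-distributed per-trap weight noise (mean 1): spatial clumping
        clump = rng.gamma(cfg.trap_aggregation, 1.0 / cfg.trap_aggregation,
                          size=len(species))
        q = probs[h] * clump
        tot = q.sum()
        q = q / tot if tot > 0 else probs[h]
        if n_ind == 0:
            continue
        counts = rng.multinomial(n_ind, q)
        # individuals of this trap, grouped by morphospecies label
        by_label: dict[str, list[str]] = {}
        for si in np.flatnonzero(counts):
            sp = species[si]
            labels = pool.morpho_labels[sp]
            for _ in range(int(counts[si])):
                if len(labels) == 2:
                    label = labels[morph_counter[sp] % 2]
                    morph_counter[sp] += 1
                else:
                    label = labels[0]
                by_label.setdefault(label, []).append(sp)
        for label in sorted(by_label):
            members = by_label[label]
            chosen = members if not cfg.one_per_morphospecies_per_trap else members[:1]
            for sp in chosen:
                spec_no += 1
                sid = f"IND{spec_no:04d}"
                true_species[sid] = sp
                if rng.random() < cfg.failure_rate:
                    seq_id = SEQUENCING_FAILED
                else:
                    seq_no += 1
                    seq_id = f"SEQ{seq_no:04d}"
                    seq = pool.prototypes[sp]
                    if (
                        cfg.intraspecific_variant_rate > 0
                        and rng.random() < cfg.intraspecific_variant_rate
                    ):
                        seq = _mutate(seq, n_variant_sites, rng)
                    records[seq_id] = seq
                rows.append((sid, trap, tid, transect_habitat[tid], label, seq_id))

    if not rows:
        raise GenerationError("simulation produced no specimens; increase effort")
    table = SpecimenTable(
        pd.DataFrame(
            rows,
            columns=[
                "specimen_id", "trap_id", "transect_id",
                "habitat", "morphospecies_id", "sequence_id",
            ],
        )
    )
    seqs = AlignedSeqSet(records) if records else None
    truth = GroundTruth(
        true_species=true_species,
        pool=pool,
        trap_to_transect=trap_transect,
        transect_to_habitat=transect_habitat,
    )
    if seqs is None:
        raise GenerationError("all sequencing attempts failed; lower failure_rate")
    return table, seqs, truth


def simulate(cfg: SimConfig) -> tuple[SpecimenTable, AlignedSeqSet, GroundTruth]:
    """Generate a full synthetic survey from a config (seeded, reproducible)."""
    rng = np.random.default_rng(cfg.seed)
    pool = generate_species_pool(cfg, rng)
    return sample_community(cfg, pool, rng)
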
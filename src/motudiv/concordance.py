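"""Morphospecies vs MOTU concordance classification.

Terminology follows barcoding field usage for threshold-MOTU studies, which
inverts common systematic parlance: a *splitting* is one MOTU containing
members of two or more morphospecies (morphology split a molecular unit),
a *lumping* is one morphospecies distributed over two or more MOTUs.
Components of the bipartite morphospecies-MOTU overlap graph that involve
at least two of each are reported separately as *complex* rather than
double-counted, keeping the individual counts additive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .errors import ConsistencyError
from .io import MotuPartition, SpecimenTable

ComponentClass = Literal["consistent", "splitting", "lumping", "complex"]


@dataclass(frozen=True)
class ConcordanceComponent:
    morphospecies: frozenset[str]
    motus: frozenset[str]
    specimens: frozenset[str]
    klass: ComponentClass


@dataclass(frozen=True)
class ConcordanceReport:
    components: tuple[ConcordanceComponent, ...]

    def _count(self, klass: ComponentClass) -> int:
        return sum(len(c.specimens) for c in self.components if c.klass == klass)

    @property
    def n_consistent_taxa(self) -> int:
        """Components where one MOTU contains exactly one morphospecies
        and vice versa (a 1:1 taxon)."""
        return sum(1 for c in self.components if c.klass == "consistent")

    @property
    def n_splitting_components(self) -> int:
        return sum(1 for c in self.components if c.klass == "splitting")

    @property
    def n_lumping_components(self) -> int:
        return sum(1 for c in self.components if c.klass == "lumping")

    @property
    def n_split_individuals(self) -> int:
        return self._count("splitting")

    @property
    def n_lump_individuals(self) -> int:
        return self._count("lumping")

    @property
    def n_complex_individuals(self) -> int:
        return self._count("complex")

    def to_dict(self) -> dict:
        return {
            "n_consistent_taxa": self.n_consistent_taxa,
            "n_splitting_components": self.n_splitting_components,
            "n_lumping_components": self.n_lumping_components,
            "n_split_individuals": self.n_split_individuals,
            "n_lump_individuals": self.n_lump_individuals,
            "n_complex_individuals": self.n_complex_individuals,
            "components": [
                {
                    "class": c.klass,
                    "morphospecies": sorted(c.morphospecies),
                    "motus": sorted(c.motus),
                    "specimens": sorted(c.specimens),
                }
                for c in self.components
            ],
        }


def _classify(n_morpho: int, n_motu: int) -> ComponentClass:
    if n_morpho == 1 and n_motu == 1:
        return "consistent"
    if n_motu == 1:
        return "splitting"
    if n_morpho == 1:
        return "lumping"
    return "complex"


def concordance_analysis(
    specimens: SpecimenTable, partition: MotuPartition
) -> ConcordanceReport:
    """Classify connected components of the morphospecies-MOTU overlap graph.

    The graph links a morphospecies and a MOTU whenever they share at least
    one sequenced specimen; each connected component is classified by how
    many labels of each kind it contains.  Components partition the
    sequenced specimens, and every morphospecies (of a sequenced specimen)
    and every MOTU appears in exactly one component.
    """
    seqd = specimens.sequenced()
    known = set(seqd["specimen_id"])
    extra = sorted(set(partition.assignment) - known)
    if extra:
        raise ConsistencyError(
            f"partition contains specimen(s) absent from table: {extra[:5]}"
        )
    missing = sorted(known - set(partition.assignment))
    if missing:
        raise ConsistencyError(
            f"sequenced specimen(s) missing from partition: {missing[:5]}"
        )

    morpho_of = dict(zip(seqd["specimen_id"], seqd["morphospecies_id"]))
    # union-find over labels in two namespaces
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for spec, motu in partition.assignment.items():
        m = "m::" + morpho_of[spec]
        u = "u::" + motu
        parent.setdefault(m, m)
        parent.setdefault(u, u)
        union(m, u)

    groups: dict[str, dict[str, set[str]]] = {}
    for spec, motu in partition.assignment.items():
        root = find("u::" + motu)
        g = groups.setdefault(
            root, {"morpho": set(), "motu": set(), "spec": set()}
        )
        g["morpho"].add(morpho_of[spec])
        g["motu"].add(motu)
        g["spec"].add(spec)

    components = tuple(
        ConcordanceComponent(
            morphospecies=frozenset(g["morpho"]),
            motus=frozenset(g["motu"]),
            specimens=frozenset(g["spec"]),
            klass=_classify(len(g["morpho"]), len(g["motu"])),
        )
        for _, g in sorted(groups.items(), key=lambda kv: min(kv[1]["spec"]))
    )
    return ConcordanceReport(components)
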
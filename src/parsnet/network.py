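"""Domain model for annotated metabolic networks.

An *annotated global metabolic network* is the bipartite incidence structure
between metabolites and reactions, together with an enzyme→reaction
annotation.  Reactions are undirected hyperedges over metabolites (no
substrate/product distinction, no stoichiometry); enzymes annotated to two or
more reactions are *catalytically promiscuous* — they are the source of the
ambiguity the sampler resolves.

A *subnetwork* is a subset of reactions with its induced metabolite and
enzyme sets.  A subnetwork is *valid* when every enzyme of the parent network
still catalyzes at least one included reaction; the set of valid subnetworks
is the universe over which reaction marginal probabilities are defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

__all__ = [
    "Metabolite",
    "Reaction",
    "Enzyme",
    "AnnotatedMetabolicNetwork",
    "Subnetwork",
    "NetworkValidationError",
    "build_network",
    "is_valid",
    "induced_metabolite_count",
    "forced_reactions",
    "universe_size_upper_bound",
]


class NetworkValidationError(ValueError):
    """Raised when input tables violate the network invariants."""


@dataclass(frozen=True)
class Metabolite:
    """A compound, identified by an opaque string (e.g. a KEGG C number)."""

    id: str
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkValidationError("metabolite id must be non-empty")


@dataclass(frozen=True)
class Reaction:
    """An undirected reaction: a hyperedge over >=1 metabolites."""

    id: str
    metabolites: frozenset[str]

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkValidationError("reaction id must be non-empty")
        if not self.metabolites:
            raise NetworkValidationError(
                f"reaction {self.id!r} has an empty metabolite set"
            )


@dataclass(frozen=True)
class Enzyme:
    """An enzyme family (e.g. a KEGG ortholog) with its annotated reactions."""

    id: str
    reactions: frozenset[str]

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkValidationError("enzyme id must be non-empty")
        if not self.reactions:
            raise NetworkValidationError(
                f"enzyme {self.id!r} has an empty reaction set"
            )

    @property
    def is_promiscuous(self) -> bool:
        """True when the enzyme is annotated to catalyze >=2 reactions."""
        return len(self.reactions) >= 2


class AnnotatedMetabolicNetwork:
    """Validated container for metabolites, reactions and enzyme annotations.

    Every reaction is annotated by at least one enzyme (unannotated reactions
    are dropped by :func:`build_network`), and all cross-references among the
    three collections are checked at construction.
    """

    def __init__(
        self,
        metabolites: Mapping[str, Metabolite],
        reactions: Mapping[str, Reaction],
        enzymes: Mapping[str, Enzyme],
    ) -> None:
        self.metabolites: dict[str, Metabolite] = dict(metabolites)
        self.reactions: dict[str, Reaction] = dict(reactions)
        self.enzymes: dict[str, Enzyme] = dict(enzymes)
        self._validate()

    def _validate(self) -> None:
        for rxn in self.reactions.values():
            missing = rxn.metabolites - self.metabolites.keys()
            if missing:
                raise NetworkValidationError(
                    f"reaction {rxn.id!r} references unknown metabolites {sorted(missing)}"
                )
        annotated: set[str] = set()
        for enz in self.enzymes.values():
            missing = enz.reactions - self.reactions.keys()
            if missing:
                raise NetworkValidationError(
                    f"enzyme {enz.id!r} references unknown reactions {sorted(missing)}"
                )
            annotated |= enz.reactions
        orphans = self.reactions.keys() - annotated
        if orphans:
            raise NetworkValidationError(
                f"reactions with no annotating enzyme: {sorted(orphans)}"
            )

    # -- size accessors ----------------------------------------------------
    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def n_enzymes(self) -> int:
        return len(self.enzymes)

    @cached_property
    def promiscuous_enzymes(self) -> frozenset[str]:
        return frozenset(e.id for e in self.enzymes.values() if e.is_promiscuous)

    @cached_property
    def reaction_ids(self) -> tuple[str, ...]:
        """Reaction ids in deterministic (sorted) order."""
        return tuple(sorted(self.reactions))

    def full_subnetwork(self) -> "Subnetwork":
        """The subnetwork containing every reaction (always valid)."""
        return Subnetwork(self, frozenset(self.reactions))

    def subnetwork(self, included: Iterable[str]) -> "Subnetwork":
        return Subnetwork(self, frozenset(included))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotatedMetabolicNetwork):
            return NotImplemented
        return (
            self.metabolites == other.metabolites
            and self.reactions == other.reactions
            and self.enzymes == other.enzymes
        )

    def __repr__(self) -> str:
        return (
            f"AnnotatedMetabolicNetwork(k={self.n_metabolites} metabolites, "
            f"l={self.n_reactions} reactions, m={self.n_enzymes} enzymes, "
            f"{len(self.promiscuous_enzymes)} promiscuous)"
        )


@dataclass(frozen=True)
class Subnetwork:
    """A subset of a network's reactions with induced metabolites/enzymes."""

    parent: AnnotatedMetabolicNetwork = field(repr=False)
    included_reactions: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        unknown = self.included_reactions - self.parent.reactions.keys()
        if unknown:
            raise NetworkValidationError(
                f"subnetwork references unknown reactions {sorted(unknown)}"
            )

    @property
    def induced_metabolites(self) -> frozenset[str]:
        mets: set[str] = set()
        for rid in self.included_reactions:
            mets |= self.parent.reactions[rid].metabolites
        return frozenset(mets)

    @property
    def induced_enzymes(self) -> frozenset[str]:
        return frozenset(
            e.id
            for e in self.parent.enzymes.values()
            if e.reactions & self.included_reactions
        )

    def metabolite_count(self) -> int:
        return len(self.induced_metabolites)

    def is_valid(self) -> bool:
        return is_valid(self)

    def __len__(self) -> int:
        return len(self.included_reactions)


def build_network(
    reaction_table: Mapping[str, Iterable[str]] | Iterable[tuple[str, Iterable[str]]],
    annotation_table: Mapping[str, Iterable[str]] | Iterable[tuple[str, Iterable[str]]],
) -> AnnotatedMetabolicNetwork:
    """Build a validated network from reaction and annotation tables.

    Parameters
    ----------
    reaction_table
        Mapping (or id/value pairs) from reaction id to its metabolite ids.
    annotation_table
        Mapping (or id/value pairs) from enzyme id to its annotated reaction
        ids.  Every referenced reaction must exist in ``reaction_table``.

    Reactions annotated by no enzyme are dropped with a warning: the
    annotated network contains only enzyme-annotated reactions.  Duplicate
    reaction or enzyme ids, empty annotation sets and dangling reaction
    references raise :class:`NetworkValidationError`.
    """
    rxn_pairs = list(
        reaction_table.items() if isinstance(reaction_table, Mapping) else reaction_table
    )
    enz_pairs = list(
        annotation_table.items()
        if isinstance(annotation_table, Mapping)
        else annotation_table
    )
    if not rxn_pairs or not enz_pairs:
        raise NetworkValidationError("reaction and annotation tables must be non-empty")

    reactions: dict[str, Reaction] = {}
    for rid, mets in rxn_pairs:
        if rid in reactions:
            raise NetworkValidationError(f"duplicate reaction id {rid!r}")
        reactions[rid] = Reaction(rid, frozenset(mets))

    enzymes: dict[str, Enzyme] = {}
    for eid, rids in enz_pairs:
        if eid in enzymes:
            raise NetworkValidationError(f"duplicate enzyme id {eid!r}")
        enzymes[eid] = Enzyme(eid, frozenset(rids))
        missing = enzymes[eid].reactions - reactions.keys()
        if missing:
            raise NetworkValidationError(
                f"enzyme {eid!r} references unknown reactions {sorted(missing)}"
            )

    annotated = set().union(*(e.reactions for e in enzymes.values()))
    dropped = sorted(reactions.keys() - annotated)
    if dropped:
        logger.warning(
            "dropping %d reaction(s) with no annotating enzyme: %s",
            len(dropped),
            ", ".join(dropped),
        )
        reactions = {rid: r for rid, r in reactions.items() if rid in annotated}

    metabolite_ids = set().union(*(r.metabolites for r in reactions.values()))
    metabolites = {mid: Metabolite(mid) for mid in metabolite_ids}
    return AnnotatedMetabolicNetwork(metabolites, reactions, enzymes)


def is_valid(subnetwork: Subnetwork) -> bool:
    """True iff every enzyme of the parent catalyzes >=1 included reaction."""
    included = subnetwork.included_reactions
    return all(e.reactions & included for e in subnetwork.parent.enzymes.values())


def induced_metabolite_count(subnetwork: Subnetwork) -> int:
    """Number of distinct metabolites touched by the included reactions."""
    return subnetwork.metabolite_count()


def forced_reactions(network: AnnotatedMetabolicNetwork) -> frozenset[str]:
    """Reactions that are the sole annotated reaction of some enzyme.

    These can never be deleted from a valid subnetwork, so their marginal
    probability is exactly 1 under any distribution over valid subnetworks.
    """
    return frozenset(
        next(iter(e.reactions))
        for e in network.enzymes.values()
        if len(e.reactions) == 1
    )


def universe_size_upper_bound(network: AnnotatedMetabolicNetwork) -> int:
    """Upper bound on the number of valid subnetworks: prod_i (2^{r_i} - 1).

    Each enzyme i with r_i annotated reactions must keep a non-empty subset of
    them; when no two enzymes share a reaction the choices are independent and
    the bound is exact, otherwise shared reactions make it an over-count.
    Returned as an exact Python integer (can be astronomically large).
    """
    bound = 1
    for enz in network.enzymes.values():
        bound *= (1 << len(enz.reactions)) - 1
    return bound
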
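"""Seeded generators of annotated metabolic networks and sample cohorts.

Real inputs are metagenome assemblies annotated with KEGG ortholog families;
here networks with the same structural features are generated directly:
hundreds of reactions, a configurable fraction of catalytically promiscuous
enzymes, and preferential metabolite reuse so that reactions share compounds
and the parsimony weight actually discriminates between valid subnetworks
(with disjoint reactions the target law would be nearly uniform and the
sampler untestable).

Cohorts for the comparative machinery plant a *context* effect: group B
differs from group A only in the metabolite composition of one reaction of a
promiscuous enzyme, never in the enzyme or reaction lists — identical
annotation, different reaction likelihoods, which is exactly the phenomenon
presence/absence tests cannot see.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import exact
from .network import AnnotatedMetabolicNetwork, build_network, forced_reactions

__all__ = [
    "GeneratorParams",
    "PlantedEffect",
    "Cohort",
    "ToyFixture",
    "generate_network",
    "generate_tables",
    "generate_group_cohort",
    "design_context_effect",
    "toy_fixtures",
]


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the network generator.

    Defaults emulate a modest metagenome-scale network: 250 reactions over
    300 potential metabolites, 200 enzyme families of which 30% are
    promiscuous (the fraction observed in real annotated networks, e.g.
    362 promiscuous among 1183 enzymes), and a metabolite-sharing bias of 2
    (odds of drawing an already-used compound over a fresh one).
    """

    n_metabolites: int = 300
    n_reactions: int = 250
    metabolites_per_reaction: tuple[int, int] = (2, 5)
    n_enzymes: int = 200
    promiscuous_fraction: float = 0.3
    reactions_per_promiscuous_enzyme: tuple[int, int] = (2, 4)
    metabolite_sharing_bias: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_metabolites, self.n_reactions, self.n_enzymes) < 1:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.promiscuous_fraction <= 1.0:
            raise ValueError("promiscuous_fraction must be in [0, 1]")
        lo, hi = self.metabolites_per_reaction
        if not 1 <= lo <= hi:
            raise ValueError("invalid metabolites_per_reaction range")
        if hi > self.n_metabolites:
            raise ValueError("a reaction cannot use more metabolites than exist")
        plo, phi = self.reactions_per_promiscuous_enzyme
        if not 2 <= plo <= phi:
            raise ValueError(
                "reactions_per_promiscuous_enzyme must be a range with lower bound >= 2"
            )
        if phi > self.n_reactions:
            raise ValueError("more reactions per enzyme than reactions available")
        if self.metabolite_sharing_bias < 0:
            raise ValueError("metabolite_sharing_bias must be >= 0")


def generate_tables(
    params: GeneratorParams,
) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """Reaction and annotation tables for :func:`generate_network`.

    Exposed separately so cohort generation can edit the tables (planted
    effects, nuisance dropout) before building networks.
    """
    rng = np.random.default_rng(params.seed)
    lo, hi = params.metabolites_per_reaction
    bias = params.metabolite_sharing_bias
    reuse_prob = bias / (1.0 + bias)

    met_ids = [f"M{i:04d}" for i in range(params.n_metabolites)]
    used: list[str] = []  # with multiplicity: preferential attachment
    n_fresh = 0
    reactions: dict[str, set[str]] = {}
    for i in range(params.n_reactions):
        size = int(rng.integers(lo, hi + 1))
        mets: set[str] = set()
        while len(mets) < size:
            can_reuse = len(set(used) - mets) > 0
            fresh_left = n_fresh < params.n_metabolites
            if can_reuse and (not fresh_left or rng.random() < reuse_prob):
                m = used[int(rng.integers(len(used)))]
                if m in mets:
                    continue
            elif fresh_left:
                m = met_ids[n_fresh]
                n_fresh += 1
            else:
                continue  # pool exhausted and all used mets already in set
            mets.add(m)
            used.append(m)
        reactions[f"R{i:04d}"] = mets

    n_prom = round(params.promiscuous_fraction * params.n_enzymes)
    n_mono = params.n_enzymes - n_prom
    rids = list(reactions)
    order = list(rng.permutation(len(rids)))
    shuffled = [rids[i] for i in order]

    enzymes: dict[str, set[str]] = {}
    covered: set[str] = set()
    # mono-functional enzymes take distinct reactions while any remain
    for i in range(n_mono):
        if i < len(shuffled):
            rid = shuffled[i]
        else:
            rid = shuffled[int(rng.integers(len(shuffled)))]
        enzymes[f"K{i:04d}"] = {rid}
        covered.add(rid)

    uncovered = [r for r in shuffled if r not in covered]
    plo, phi = params.reactions_per_promiscuous_enzyme
    sizes = [int(rng.integers(plo, phi + 1)) for _ in range(n_prom)]
    if sum(sizes) < len(uncovered):
        raise ValueError(
            f"infeasible params: {len(uncovered)} reactions cannot be covered "
            f"by {n_prom} promiscuous enzymes with at most {phi} reactions each"
        )
    assignments: list[set[str]] = [set() for _ in range(n_prom)]
    # deal uncovered reactions round-robin, then fill with random reactions
    j = 0
    for rid in uncovered:
        while len(assignments[j % n_prom]) >= sizes[j % n_prom]:
            j += 1
        assignments[j % n_prom].add(rid)
        j += 1
    for k in range(n_prom):
        while len(assignments[k]) < sizes[k]:
            assignments[k].add(rids[int(rng.integers(len(rids)))])
    for k in range(n_prom):
        enzymes[f"K{n_mono + k:04d}"] = assignments[k]
    return reactions, enzymes


def generate_network(params: GeneratorParams) -> AnnotatedMetabolicNetwork:
    """Generate a validated annotated network; deterministic given the seed.

    The realized number of promiscuous enzymes equals
    round(promiscuous_fraction * n_enzymes) by construction.
    """
    reactions, enzymes = generate_tables(params)
    return build_network(reactions, enzymes)


# ---------------------------------------------------------------------------
# Grouped cohorts with planted effects
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedEffect:
    """A context effect on one reaction of a promiscuous enzyme.

    In group B the target reaction's metabolites are replaced by compounds
    already used by other (always-present) reactions, making the reaction
    metabolically cheap and raising its marginal probability; in group A it
    keeps private compounds and stays unlikely.  Enzyme and reaction lists
    are identical in both groups.
    """

    target_reaction: str
    shared_metabolites: tuple[str, ...]

    def apply(self, reactions: dict[str, set[str]]) -> dict[str, set[str]]:
        if self.target_reaction not in reactions:
            raise ValueError(
                f"planted effect targets unknown reaction {self.target_reaction!r}"
            )
        missing = set(self.shared_metabolites) - set().union(
            *(m for r, m in reactions.items() if r != self.target_reaction)
        )
        if missing:
            raise ValueError(
                f"planted effect uses metabolites absent elsewhere: {sorted(missing)}"
            )
        out = {r: set(m) for r, m in reactions.items()}
        out[self.target_reaction] = set(self.shared_metabolites)
        return out


@dataclass
class Cohort:
    """Two groups of per-sample networks plus ground truth."""

    group_a: list[AnnotatedMetabolicNetwork]
    group_b: list[AnnotatedMetabolicNetwork]
    ground_truth: dict = field(default_factory=dict)


def _dropout_tables(
    reactions: dict[str, set[str]],
    enzymes: dict[str, set[str]],
    dropout: float,
    rng: np.random.Generator,
) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """Remove each enzyme with probability ``dropout`` (detection failure).

    Reactions left with no annotating enzyme are dropped downstream by
    ``build_network``; at least one enzyme is always retained.
    """
    keep = {e: r for e, r in enzymes.items() if rng.random() >= dropout}
    if not keep:
        keep = dict([next(iter(enzymes.items()))])
    annotated = set().union(*keep.values())
    return {r: m for r, m in reactions.items() if r in annotated}, keep


def generate_group_cohort(
    base_params: GeneratorParams,
    n_samples_per_group: int,
    effect: PlantedEffect | None = None,
    nuisance_dropout: float = 0.0,
    verify_margin: float | None = None,
    oracle_lambda: float = 1.0,
) -> Cohort:
    """Two groups of sample networks from one base topology.

    Group A samples use the base tables; group B applies the planted effect.
    ``nuisance_dropout`` removes each enzyme independently per sample
    (group-independent noise, so presence varies under the null).  With
    ``verify_margin`` set and a small enough network, the exact oracle checks
    at generation time that the target reaction's marginal differs between
    the two table versions by at least that margin.
    """
    if n_samples_per_group < 1:
        raise ValueError("need at least one sample per group")
    reactions_a, enzymes = generate_tables(base_params)
    reactions_b = effect.apply(reactions_a) if effect else reactions_a
    truth: dict = {"effect": None}
    if effect is not None:
        truth["effect"] = {
            "target_reaction": effect.target_reaction,
            "shared_metabolites": list(effect.shared_metabolites),
        }
        if verify_margin is not None:
            ma = exact.exact_marginals(
                build_network(reactions_a, enzymes), oracle_lambda
            )[effect.target_reaction]
            mb = exact.exact_marginals(
                build_network(reactions_b, enzymes), oracle_lambda
            )[effect.target_reaction]
            if abs(mb - ma) < verify_margin:
                raise ValueError(
                    f"planted effect margin {abs(mb - ma):.4f} below "
                    f"requested {verify_margin}"
                )
            truth["effect"]["exact_marginal_group_a"] = ma
            truth["effect"]["exact_marginal_group_b"] = mb
    rng = np.random.default_rng(base_params.seed + 777)
    groups: list[list[AnnotatedMetabolicNetwork]] = [[], []]
    for gi, tables in enumerate((reactions_a, reactions_b)):
        for _ in range(n_samples_per_group):
            rx, ez = tables, enzymes
            if nuisance_dropout > 0:
                rx, ez = _dropout_tables(rx, ez, nuisance_dropout, rng)
            groups[gi].append(build_network(rx, ez))
    truth["labels"] = {
        "group_a": [f"A{i}" for i in range(n_samples_per_group)],
        "group_b": [f"B{i}" for i in range(n_samples_per_group)],
    }
    truth["nuisance_dropout"] = nuisance_dropout
    return Cohort(group_a=groups[0], group_b=groups[1], ground_truth=truth)


def design_context_effect(
    base_params: GeneratorParams,
    min_margin: float = 0.2,
    oracle_lambda: float = 1.0,
) -> PlantedEffect:
    """Find a context effect with an oracle-verified marginal margin.

    Scans reactions of promiscuous enzymes (non-forced, so their marginal is
    free to move) and, for each, tries replacing its metabolites with
    compounds of forced reactions — compounds that are present in every
    valid subnetwork, so in group B the rewired reaction costs no extra
    metabolites and its marginal rises.  Returns the first candidate whose
    exact-marginal difference between the two table versions reaches
    ``min_margin``.  Requires a network small enough for the exact oracle.
    """
    reactions, enzymes = generate_tables(base_params)
    base_net = build_network(reactions, enzymes)
    forced = forced_reactions(base_net)
    forced_mets = sorted(set().union(*(reactions[r] for r in forced)) if forced else [])
    if not forced_mets:
        raise ValueError("base network has no forced reactions to borrow metabolites from")
    base_marg = exact.exact_marginals(base_net, oracle_lambda)
    candidates = sorted(
        rid
        for e in base_net.enzymes.values()
        if e.is_promiscuous
        for rid in e.reactions
        if rid not in forced
    )
    for rid in candidates:
        k = min(len(reactions[rid]), len(forced_mets))
        effect = PlantedEffect(rid, tuple(forced_mets[:k]))
        alt = exact.exact_marginals(
            build_network(effect.apply(reactions), enzymes), oracle_lambda
        )
        if abs(alt[rid] - base_marg[rid]) >= min_margin:
            return effect
    raise ValueError(
        f"no context effect with margin >= {min_margin} found; "
        "increase network size or lower the margin"
    )


# ---------------------------------------------------------------------------
# Toy fixtures with known exact answers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ToyFixture:
    network: AnnotatedMetabolicNetwork
    description: str
    exact_marginals_lambda1: dict[str, float] | None = None
    notes: dict = field(default_factory=dict)


def toy_fixtures() -> dict[str, ToyFixture]:
    """Small named networks with hand-derivable exact answers.

    ``t1``: one promiscuous enzyme, two reactions sharing metabolite A;
    P(r1) = P(r2) = (1 + e^-1)/(2 + e^-1) at lambda = 1.
    ``t1_disjoint``: same annotation, disjoint metabolites;
    P(r1) = (1 + e^-2)/(2 + e^-2).
    ``shared_chain``: two promiscuous enzymes sharing reaction r2 (5 valid
    subnetworks).  ``forced``: r2 is the sole reaction of one enzyme, so its
    marginal is exactly 1.  ``promiscuous5``: one enzyme annotated to five
    reactions, the typical multi-function ambiguity of e.g. a cycloisomerase
    family (31 valid subnetworks).
    """
    e1 = math.exp(-1.0)
    e2 = math.exp(-2.0)
    p_t1 = (1 + e1) / (2 + e1)
    p_t1d = (1 + e2) / (2 + e2)
    fixtures = {
        "t1": ToyFixture(
            build_network({"r1": {"A", "B"}, "r2": {"A", "C"}}, {"e1": {"r1", "r2"}}),
            "one promiscuous enzyme, overlapping metabolites",
            {"r1": p_t1, "r2": p_t1},
        ),
        "t1_disjoint": ToyFixture(
            build_network({"r1": {"A", "B"}, "r2": {"C", "D"}}, {"e1": {"r1", "r2"}}),
            "one promiscuous enzyme, disjoint metabolites",
            {"r1": p_t1d, "r2": p_t1d},
        ),
        "shared_chain": ToyFixture(
            build_network(
                {"r1": {"A", "B"}, "r2": {"B", "C"}, "r3": {"C", "D"}},
                {"e1": {"r1", "r2"}, "e2": {"r2", "r3"}},
            ),
            "two promiscuous enzymes sharing reaction r2",
            None,
            {"n_valid_subnetworks": 5},
        ),
        "forced": ToyFixture(
            build_network(
                {"r1": {"A", "B"}, "r2": {"B", "C"}},
                {"e1": {"r1", "r2"}, "e2": {"r2"}},
            ),
            "r2 forced by a mono-functional enzyme",
            None,
            {"forced": ["r2"]},
        ),
        "promiscuous5": ToyFixture(
            build_network(
                {
                    "r1": {"A", "B"},
                    "r2": {"A", "C"},
                    "r3": {"B", "C", "D"},
                    "r4": {"D", "E"},
                    "r5": {"A", "E"},
                },
                {"e1": {"r1", "r2", "r3", "r4", "r5"}},
            ),
            "single enzyme annotated to five reactions",
            None,
            {"n_valid_subnetworks": 31},
        ),
    }
    for name, fx in fixtures.items():
        assert fx.network.full_subnetwork().is_valid(), name
        if "forced" in fx.notes:
            assert set(fx.notes["forced"]) == set(forced_reactions(fx.network)), name
    return fixtures
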
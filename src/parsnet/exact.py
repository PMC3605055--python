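"""Brute-force enumeration of the valid-subnetwork universe.

For small networks the universe of valid subnetworks can be enumerated
exhaustively, giving exact marginal probabilities under the parsimony law

    pi(N) ∝ exp(-lambda * |metabolites(N)|)

and the exact minimum-metabolite subnetwork.  This module is the test oracle
for the MCMC sampler; it is capped by design (no #P counting tricks).

Enumeration iterates only over subsets of *non-forced* reactions: a reaction
that is the sole annotation of some enzyme is pinned to 1 in every valid
subnetwork, shrinking the space from 2^l to 2^(l - n_forced).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .network import (
    AnnotatedMetabolicNetwork,
    Subnetwork,
    forced_reactions,
)

__all__ = [
    "EnumerationCapError",
    "ExactDistribution",
    "enumerate_valid_subnetworks",
    "exact_distribution",
    "exact_marginals",
    "exact_min_metabolite_subnetwork",
    "uncorrected_chain_stationary_marginals",
]

DEFAULT_MAX_FREE_REACTIONS = 20


class EnumerationCapError(ValueError):
    """Raised when a network has too many non-forced reactions to enumerate."""


@dataclass(frozen=True)
class ExactDistribution:
    """The full enumerated distribution over valid subnetworks.

    ``membership`` is a (n_valid, n_reactions) boolean matrix in the order of
    ``reaction_ids`` (lexicographic subnetwork order); ``metabolite_counts``
    and ``probabilities`` are aligned with its rows.
    """

    reaction_ids: tuple[str, ...]
    membership: np.ndarray
    metabolite_counts: np.ndarray
    probabilities: np.ndarray
    lam: float

    @property
    def n_valid(self) -> int:
        return self.membership.shape[0]


def _check_cap(network: AnnotatedMetabolicNetwork, max_free_reactions: int) -> list[str]:
    forced = forced_reactions(network)
    free = sorted(set(network.reactions) - forced)
    if len(free) > max_free_reactions:
        raise EnumerationCapError(
            f"network has {len(free)} non-forced reactions; enumeration is "
            f"capped at {max_free_reactions} (raise max_free_reactions "
            "deliberately, or use the MCMC sampler)"
        )
    return free


def enumerate_valid_subnetworks(
    network: AnnotatedMetabolicNetwork,
    max_free_reactions: int = DEFAULT_MAX_FREE_REACTIONS,
) -> list[Subnetwork]:
    """All valid subnetworks, in lexicographic order of the free-reaction bits.

    Every returned subnetwork contains all forced reactions and satisfies
    validity (each enzyme catalyzes >=1 included reaction).
    """
    forced = forced_reactions(network)
    free = _check_cap(network, max_free_reactions)
    # Enzymes containing a forced reaction are always covered; only the rest
    # need checking against each candidate subset.
    at_risk = [
        e.reactions
        for e in network.enzymes.values()
        if not (e.reactions & forced)
    ]
    out: list[Subnetwork] = []
    n_free = len(free)
    for bits in range(1 << n_free):
        chosen = frozenset(free[i] for i in range(n_free) if bits >> i & 1)
        included = chosen | forced
        if not included:
            continue
        if all(rxns & included for rxns in at_risk):
            out.append(Subnetwork(network, included))
    return out


def exact_distribution(
    network: AnnotatedMetabolicNetwork,
    lam: float = 1.0,
    max_free_reactions: int = DEFAULT_MAX_FREE_REACTIONS,
) -> ExactDistribution:
    """Enumerate the universe and normalize exp(-lam * n_metabolites).

    Probabilities are computed in log-space (max-subtracted) so networks with
    many metabolites do not underflow.
    """
    if not np.isfinite(lam) or lam < 0:
        raise ValueError(f"lambda must be finite and >= 0, got {lam!r}")
    subnets = enumerate_valid_subnetworks(network, max_free_reactions)
    rids = network.reaction_ids
    pos = {rid: i for i, rid in enumerate(rids)}
    membership = np.zeros((len(subnets), len(rids)), dtype=bool)
    counts = np.empty(len(subnets), dtype=np.int64)
    for row, sn in enumerate(subnets):
        for rid in sn.included_reactions:
            membership[row, pos[rid]] = True
        counts[row] = sn.metabolite_count()
    logw = -lam * counts.astype(float)
    probs = np.exp(logw - logsumexp(logw))
    probs /= probs.sum()  # renormalize away rounding residue
    return ExactDistribution(rids, membership, counts, probs, lam)


def exact_marginals(
    network: AnnotatedMetabolicNetwork,
    lam: float = 1.0,
    max_free_reactions: int = DEFAULT_MAX_FREE_REACTIONS,
) -> dict[str, float]:
    """Exact marginal probability of each reaction under the parsimony law.

    P(r) = sum over valid N containing r of w(N) / sum over valid N of w(N),
    with w(N) = exp(-lam * |metabolites(N)|).  Every reaction has marginal in
    (0, 1]: it appears at least in the full subnetwork, which is always valid.
    """
    dist = exact_distribution(network, lam, max_free_reactions)
    marg = np.clip(dist.probabilities @ dist.membership, 0.0, 1.0)
    return {rid: float(marg[i]) for i, rid in enumerate(dist.reaction_ids)}


def exact_min_metabolite_subnetwork(
    network: AnnotatedMetabolicNetwork,
    max_free_reactions: int = DEFAULT_MAX_FREE_REACTIONS,
) -> tuple[Subnetwork, int, int]:
    """Global minimum-metabolite valid subnetwork, its count, and tie count.

    Ties are broken by lexicographic enumeration order (first minimum wins).
    """
    subnets = enumerate_valid_subnetworks(network, max_free_reactions)
    counts = [sn.metabolite_count() for sn in subnets]
    best = min(counts)
    n_ties = counts.count(best)
    return subnets[counts.index(best)], best, n_ties


def uncorrected_chain_stationary_marginals(
    network: AnnotatedMetabolicNetwork,
    lam: float = 1.0,
    max_free_reactions: int = 16,
) -> dict[str, float]:
    """Exact stationary marginals of the *uncorrected* Metropolis chain.

    The retry-until-valid single-toggle proposal draws candidates uniformly
    from the d(N) valid neighbours of the current subnetwork N; without the
    Hastings factor d(N)/d(N') the stationary law deviates from
    pi ∝ exp(-lam*|C|) wherever d varies between neighbours.  This builds
    the full transition matrix over the enumerated universe and solves for
    its stationary vector — the reference against which the
    ``paper_faithful`` sampler is unbiased, and the measure of its
    asymmetry bias relative to :func:`exact_marginals`.
    """
    subnets = enumerate_valid_subnetworks(network, max_free_reactions)
    keys = [sn.included_reactions for sn in subnets]
    pos = {k: i for i, k in enumerate(keys)}
    counts = np.array([sn.metabolite_count() for sn in subnets], dtype=float)
    n = len(subnets)
    free = sorted(set(network.reactions) - forced_reactions(network))
    P = np.zeros((n, n))
    for i, k in enumerate(keys):
        neigh = []
        for rid in free:
            cand = k - {rid} if rid in k else k | {rid}
            j = pos.get(cand)
            if j is not None:
                neigh.append(j)
        if not neigh:
            P[i, i] = 1.0
            continue
        q = 1.0 / len(neigh)
        for j in neigh:
            a = min(1.0, math.exp(-lam * (counts[j] - counts[i])))
            P[i, j] += q * a
        P[i, i] += 1.0 - P[i].sum()
    # stationary vector: left eigenvector of P for eigenvalue 1
    w, v = np.linalg.eig(P.T)
    k_ev = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, k_ev])
    pi = np.abs(pi) / np.abs(pi).sum()
    marg = {rid: 0.0 for rid in network.reaction_ids}
    for weight, k in zip(pi, keys):
        for rid in k:
            marg[rid] += float(weight)
    return marg
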
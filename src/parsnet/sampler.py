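"""Metropolis-Hastings sampling of valid metabolic subnetworks.

The chain walks over valid subnetworks of an annotated metabolic network by
toggling one reaction at a time (insert or delete), redrawing until the
candidate is valid.  A transition that lowers the induced metabolite count is
always accepted; otherwise it is accepted with the exponential candidate
probability exp(-lambda * delta_n), where delta_n is the metabolite-count
difference.  Under a symmetric proposal this leaves the parsimony law

    pi(N) ∝ exp(-lambda * |metabolites(N)|)

stationary over the universe of valid subnetworks.  Because the
retry-until-valid proposal is in fact mildly asymmetric (the number of valid
single-toggle neighbours d(N) varies), a ``hastings_corrected`` mode
multiplies the acceptance ratio by d(current)/d(candidate); the default
``paper_faithful`` mode omits the correction.

Stored samples are thinned with a deterministic batch size B, after a burn-in
period; one "step" is one *valid* proposal (accepted or rejected), and
invalid redraws are counted separately and excluded from the acceptance-rate
denominator.  Marginal probabilities are estimated as inclusion frequencies
over the stored samples.
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .network import (
    AnnotatedMetabolicNetwork,
    Subnetwork,
    forced_reactions,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ChainConfig",
    "SampleSet",
    "MarginalProfile",
    "DegenerateSamplingSpaceError",
    "acceptance_probability",
    "valid_neighbors",
    "propose",
    "run_chain",
    "estimate_marginals",
    "ergodic_average_trace",
    "effective_sample_size",
    "batch_autocorrelation",
    "max_likelihood_subnetwork",
]

PAPER_FAITHFUL = "paper_faithful"
HASTINGS_CORRECTED = "hastings_corrected"


class DegenerateSamplingSpaceError(RuntimeError):
    """No valid single-toggle move exists (all reactions forced)."""


@dataclass(frozen=True)
class ChainConfig:
    """All MCMC tunables.

    Defaults are the production settings for real-size networks (batch size
    10,000; burn-in 10^7 steps; 10,000 stored samples); toy networks in the
    test-suite use much smaller, explicitly passed values.

    lam
        Scale of the exponential candidate probability (>= 0; 0 gives the
        uniform law over valid subnetworks, every valid proposal accepted).
    batch_size
        Thinning interval B: one subnetwork is stored every B valid steps.
    burn_in_steps
        Valid proposals discarded before sampling starts.
    n_samples
        Number S of stored subnetworks.
    proposal_mode
        ``paper_faithful`` (no asymmetry correction) or
        ``hastings_corrected`` (exact detailed balance, costs O(l) per step).
    init_mode
        ``full_network`` starts at the always-valid full subnetwork;
        ``random_valid`` greedily deletes random non-forced reactions while
        validity holds, for dispersion diagnostics.
    """

    lam: float = 1.0
    batch_size: int = 10_000
    burn_in_steps: int = 10_000_000
    n_samples: int = 10_000
    seed: int = 0
    proposal_mode: str = PAPER_FAITHFUL
    init_mode: str = "full_network"

    def __post_init__(self) -> None:
        if not math.isfinite(self.lam) or self.lam < 0:
            raise ValueError(f"lambda must be finite and >= 0, got {self.lam!r}")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.burn_in_steps < 0:
            raise ValueError("burn_in_steps must be >= 0")
        if self.proposal_mode not in (PAPER_FAITHFUL, HASTINGS_CORRECTED):
            raise ValueError(f"unknown proposal_mode {self.proposal_mode!r}")
        if self.init_mode not in ("full_network", "random_valid"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")


@dataclass
class SampleSet:
    """Thinned chain output: S stored subnetworks as 0/1 inclusion rows."""

    samples: np.ndarray  # (S, n_reactions) uint8, column order = reaction_ids
    reaction_ids: tuple[str, ...]
    network: AnnotatedMetabolicNetwork = field(repr=False)
    config: ChainConfig
    acceptance_rate: float
    n_valid_proposals: int
    n_invalid_draws: int
    min_subnetwork: Subnetwork = field(repr=False)
    min_metabolite_count: int

    def __post_init__(self) -> None:
        if self.samples.shape[0] != self.config.n_samples:
            raise ValueError("sample matrix row count does not match n_samples")

    def inclusion_series(self, reaction_id: str) -> np.ndarray:
        try:
            col = self.reaction_ids.index(reaction_id)
        except ValueError:
            raise KeyError(f"unknown reaction {reaction_id!r}") from None
        return self.samples[:, col]


@dataclass(frozen=True)
class MarginalProfile:
    """Per-reaction marginal probabilities for one sample/metagenome."""

    probabilities: dict[str, float]
    sample_id: str = ""
    config_summary: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {r: p for r, p in self.probabilities.items() if not 0.0 <= p <= 1.0}
        if bad:
            raise ValueError(f"marginal probabilities outside [0, 1]: {bad}")

    def __getitem__(self, reaction_id: str) -> float:
        return self.probabilities[reaction_id]

    def aligned_vector(self, reaction_ids: Sequence[str]) -> np.ndarray:
        """Probabilities in the given order; absent reactions impute 0."""
        return np.array(
            [self.probabilities.get(r, 0.0) for r in reaction_ids], dtype=float
        )


def acceptance_probability(
    delta_n: int,
    lam: float,
    mode: str = PAPER_FAITHFUL,
    asymmetry_ratio: float = 1.0,
) -> float:
    """Metropolis(-Hastings) acceptance probability for a metabolite change.

    ``paper_faithful``: min(1, exp(-lam * delta_n)) — a candidate with fewer
    metabolites is always accepted.  ``hastings_corrected`` multiplies by the
    proposal-asymmetry ratio d(current)/d(candidate) of valid-neighbour
    counts.
    """
    ratio = math.exp(-lam * delta_n)
    if mode == HASTINGS_CORRECTED:
        ratio *= asymmetry_ratio
    return min(1.0, ratio)


# ---------------------------------------------------------------------------
# Indexed representation used by the fast chain loop
# ---------------------------------------------------------------------------


class _Indexed:
    """Integer-indexed view of a network for the inner sampling loop."""

    def __init__(self, network: AnnotatedMetabolicNetwork) -> None:
        self.network = network
        self.rids = list(network.reaction_ids)
        rpos = {r: i for i, r in enumerate(self.rids)}
        mids = sorted(network.metabolites)
        mpos = {m: i for i, m in enumerate(mids)}
        eids = sorted(network.enzymes)
        self.n_rxn = len(self.rids)
        self.n_met = len(mids)
        self.n_enz = len(eids)
        self.rxn_mets: list[list[int]] = [
            [mpos[m] for m in sorted(network.reactions[r].metabolites)]
            for r in self.rids
        ]
        self.rxn_enzs: list[list[int]] = [[] for _ in self.rids]
        self.enz_sizes = []
        for ei, eid in enumerate(eids):
            rxns = network.enzymes[eid].reactions
            self.enz_sizes.append(len(rxns))
            for r in rxns:
                self.rxn_enzs[rpos[r]].append(ei)
        forced = forced_reactions(network)
        self.forced_idx = frozenset(rpos[r] for r in forced)
        self.pool = [i for i in range(self.n_rxn) if i not in self.forced_idx]


class _State:
    """Mutable chain state: inclusion bits plus incremental counters."""

    def __init__(self, idx: _Indexed, included: Sequence[int]) -> None:
        self.idx = idx
        self.included = bytearray(self.n_rxn_bits(idx))
        self.met_count = [0] * idx.n_met
        self.enz_cov = [0] * idx.n_enz
        self.n_mets = 0
        for r in included:
            self._insert(r)

    @staticmethod
    def n_rxn_bits(idx: _Indexed) -> int:
        return idx.n_rxn

    def _insert(self, r: int) -> None:
        assert not self.included[r]
        self.included[r] = 1
        for m in self.idx.rxn_mets[r]:
            if self.met_count[m] == 0:
                self.n_mets += 1
            self.met_count[m] += 1
        for e in self.idx.rxn_enzs[r]:
            self.enz_cov[e] += 1

    def _delete(self, r: int) -> None:
        assert self.included[r]
        self.included[r] = 0
        for m in self.idx.rxn_mets[r]:
            self.met_count[m] -= 1
            if self.met_count[m] == 0:
                self.n_mets -= 1
        for e in self.idx.rxn_enzs[r]:
            self.enz_cov[e] -= 1

    def deletable(self, r: int) -> bool:
        return self.included[r] and all(
            self.enz_cov[e] >= 2 for e in self.idx.rxn_enzs[r]
        )

    def n_valid_moves(self) -> int:
        d = 0
        for r in self.idx.pool:
            if self.included[r]:
                if all(self.enz_cov[e] >= 2 for e in self.idx.rxn_enzs[r]):
                    d += 1
            else:
                d += 1
        return d

    def subnetwork(self) -> Subnetwork:
        return Subnetwork(
            self.idx.network,
            frozenset(r for i, r in enumerate(self.idx.rids) if self.included[i]),
        )


class _NeighborCountTracker:
    """Incremental count of valid single-toggle moves d(N).

    d(N) = (#absent pool reactions) + (#present pool reactions deletable
    without uncovering an enzyme).  Toggling reaction r only changes the
    deletable status of reactions sharing an enzyme whose coverage crosses
    the 1<->2 boundary, so updates are local.
    """

    def __init__(self, state: _State) -> None:
        self.state = state
        idx = state.idx
        self.pool_set = frozenset(idx.pool)
        # enzyme -> pool reactions it annotates
        self.enz_pool_rxns: list[list[int]] = [[] for _ in range(idx.n_enz)]
        for r in idx.pool:
            for e in idx.rxn_enzs[r]:
                self.enz_pool_rxns[e].append(r)
        self.del_ok = bytearray(idx.n_rxn)
        self.n_del = 0
        self.n_present_pool = 0
        for r in idx.pool:
            if state.included[r]:
                self.n_present_pool += 1
                if state.deletable(r):
                    self.del_ok[r] = 1
                    self.n_del += 1

    def count(self) -> int:
        return (len(self.pool_set) - self.n_present_pool) + self.n_del

    def _recheck(self, q: int) -> None:
        ok = 1 if self.state.deletable(q) else 0
        if ok != self.del_ok[q]:
            self.del_ok[q] = ok
            self.n_del += 1 if ok else -1

    def apply_insert(self, r: int, crossed_up: list[int]) -> None:
        """Call after state._insert(r); crossed_up = enzymes whose cov hit 2."""
        self.n_present_pool += 1
        self._recheck(r)
        for e in crossed_up:
            for q in self.enz_pool_rxns[e]:
                if q != r and self.state.included[q] and not self.del_ok[q]:
                    self._recheck(q)

    def apply_delete(self, r: int, crossed_down: list[int]) -> None:
        """Call after state._delete(r); crossed_down = enzymes whose cov hit 1."""
        self.n_present_pool -= 1
        if self.del_ok[r]:
            self.del_ok[r] = 0
            self.n_del -= 1
        for e in crossed_down:
            for q in self.enz_pool_rxns[e]:
                if self.state.included[q] and self.del_ok[q]:
                    self.del_ok[q] = 0
                    self.n_del -= 1


def _initial_state(idx: _Indexed, config: ChainConfig, rng: random.Random) -> _State:
    state = _State(idx, range(idx.n_rxn))
    if config.init_mode == "random_valid":
        order = list(idx.pool)
        rng.shuffle(order)
        for r in order:
            if state.deletable(r):
                state._delete(r)
    return state


# ---------------------------------------------------------------------------
# Public single-step proposal (reference implementation used in tests/API;
# run_chain uses an inlined copy of the same logic for speed)
# ---------------------------------------------------------------------------


def valid_neighbors(subnetwork: Subnetwork) -> list[Subnetwork]:
    """All valid subnetworks differing from this one by one reaction toggle."""
    parent = subnetwork.parent
    out = []
    for rid in parent.reaction_ids:
        if rid in subnetwork.included_reactions:
            cand = Subnetwork(parent, subnetwork.included_reactions - {rid})
        else:
            cand = Subnetwork(parent, subnetwork.included_reactions | {rid})
        if cand.is_valid():
            out.append(cand)
    return out


def propose(
    subnetwork: Subnetwork, rng: random.Random, max_redraws: int = 10_000
) -> tuple[Subnetwork, int, int]:
    """Draw one valid candidate by uniform reaction toggling with redraws.

    Returns ``(candidate, delta_n, n_invalid_draws)``.  Raises
    :class:`DegenerateSamplingSpaceError` when no toggle can yield a valid
    subnetwork (every reaction forced — no promiscuous enzyme ambiguity).
    """
    parent = subnetwork.parent
    pool = [r for r in parent.reaction_ids if r not in forced_reactions(parent)]
    if not pool:
        raise DegenerateSamplingSpaceError(
            "every reaction is forced; the chain has no valid move — "
            "use exact enumeration instead"
        )
    n_invalid = 0
    n0 = subnetwork.metabolite_count()
    for _ in range(max_redraws):
        rid = pool[rng.randrange(len(pool))]
        if rid in subnetwork.included_reactions:
            cand = Subnetwork(parent, subnetwork.included_reactions - {rid})
        else:
            cand = Subnetwork(parent, subnetwork.included_reactions | {rid})
        if cand.is_valid():
            return cand, cand.metabolite_count() - n0, n_invalid
        n_invalid += 1
    raise DegenerateSamplingSpaceError(
        f"no valid candidate found in {max_redraws} redraws"
    )


# ---------------------------------------------------------------------------
# The chain
# ---------------------------------------------------------------------------


def run_chain(
    network: AnnotatedMetabolicNetwork, config: ChainConfig
) -> SampleSet:
    """Run the Metropolis-Hastings chain and return thinned samples.

    The chain starts from a valid subnetwork (see ``init_mode``), performs
    ``burn_in_steps`` valid proposals, then stores the current subnetwork
    every ``batch_size`` valid proposals until ``n_samples`` are collected.
    Deterministic given ``config.seed``.  The minimum-metabolite subnetwork
    seen anywhere in the run (burn-in included) is tracked.
    """
    idx = _Indexed(network)
    if not idx.pool:
        raise DegenerateSamplingSpaceError(
            "every reaction is forced (no promiscuous enzyme); "
            "the sampling space is a single subnetwork — use exact mode"
        )
    rng = random.Random(config.seed)
    state = _initial_state(idx, config, rng)
    corrected = config.proposal_mode == HASTINGS_CORRECTED
    lam = config.lam

    # locals for the hot loop
    pool = idx.pool
    n_pool = len(pool)
    rxn_mets = idx.rxn_mets
    rxn_enzs = idx.rxn_enzs
    met_count = state.met_count
    enz_cov = state.enz_cov
    included = state.included
    rnd = rng.random
    randrange = rng.randrange
    # exp(-lam * d) lookup for small positive deltas
    max_rxn_size = max((len(m) for m in rxn_mets), default=1)
    exp_tab = [math.exp(-lam * d) for d in range(max_rxn_size + 1)]

    tracker = _NeighborCountTracker(state) if corrected else None

    def _toggle(r: int, insert: bool) -> None:
        """Apply one toggle, keeping metabolite/enzyme counters and the
        neighbour-count tracker consistent."""
        mets = rxn_mets[r]
        enzs = rxn_enzs[r]
        crossed: list[int] = []
        if insert:
            included[r] = 1
            for m in mets:
                if met_count[m] == 0:
                    state.n_mets += 1
                met_count[m] += 1
            for e in enzs:
                enz_cov[e] += 1
                if enz_cov[e] == 2:
                    crossed.append(e)
            if tracker is not None:
                tracker.apply_insert(r, crossed)
        else:
            included[r] = 0
            for m in mets:
                met_count[m] -= 1
                if met_count[m] == 0:
                    state.n_mets -= 1
            for e in enzs:
                enz_cov[e] -= 1
                if enz_cov[e] == 1:
                    crossed.append(e)
            if tracker is not None:
                tracker.apply_delete(r, crossed)

    S, B = config.n_samples, config.batch_size
    out = np.empty((S, idx.n_rxn), dtype=np.uint8)
    total_steps = config.burn_in_steps + S * B
    n_accepted = 0
    n_invalid = 0
    best_n = state.n_mets
    best_bits = bytes(included)
    next_record = config.burn_in_steps + B
    stored = 0
    step = 0
    while step < total_steps:
        r = pool[randrange(n_pool)]
        enzs = rxn_enzs[r]
        mets = rxn_mets[r]
        if included[r]:
            ok = True
            for e in enzs:
                if enz_cov[e] == 1:
                    ok = False
                    break
            if not ok:
                n_invalid += 1
                continue
            delta = 0
            for m in mets:
                if met_count[m] == 1:
                    delta -= 1
            insert = False
        else:
            delta = 0
            for m in mets:
                if met_count[m] == 0:
                    delta += 1
            insert = True
        step += 1
        if corrected:
            d_cur = tracker.count()
            _toggle(r, insert)
            d_cand = tracker.count()
            ratio = math.exp(-lam * delta) * d_cur / d_cand
            if ratio >= 1.0 or rnd() < ratio:
                n_accepted += 1
            else:
                _toggle(r, not insert)
        else:
            if delta <= 0 or rnd() < exp_tab[delta]:
                n_accepted += 1
                if insert:
                    included[r] = 1
                    for m in mets:
                        if met_count[m] == 0:
                            state.n_mets += 1
                        met_count[m] += 1
                    for e in enzs:
                        enz_cov[e] += 1
                else:
                    included[r] = 0
                    for m in mets:
                        met_count[m] -= 1
                        if met_count[m] == 0:
                            state.n_mets -= 1
                    for e in enzs:
                        enz_cov[e] -= 1
        if state.n_mets < best_n:
            best_n = state.n_mets
            best_bits = bytes(included)
        if step == next_record:
            out[stored] = np.frombuffer(bytes(included), dtype=np.uint8)
            stored += 1
            next_record += B

    acceptance_rate = n_accepted / step if step else 1.0
    if not 0.1 <= acceptance_rate <= 0.5 and step:
        logger.warning(
            "acceptance rate %.3f outside [0.10, 0.50]; consider adjusting "
            "lambda for this network",
            acceptance_rate,
        )
    logger.info(
        "chain finished: %d valid steps, %d invalid redraws, acceptance %.3f",
        step,
        n_invalid,
        acceptance_rate,
    )
    min_sub = Subnetwork(
        network, frozenset(r for i, r in enumerate(idx.rids) if best_bits[i])
    )
    return SampleSet(
        samples=out,
        reaction_ids=tuple(idx.rids),
        network=network,
        config=config,
        acceptance_rate=acceptance_rate,
        n_valid_proposals=step,
        n_invalid_draws=n_invalid,
        min_subnetwork=min_sub,
        min_metabolite_count=best_n,
    )


def estimate_marginals(
    sample_set: SampleSet, sample_id: str = ""
) -> MarginalProfile:
    """Inclusion frequency of each reaction over the stored samples."""
    if sample_set.samples.shape[0] == 0:
        raise ValueError("empty sample set")
    freqs = sample_set.samples.mean(axis=0)
    cfg = sample_set.config
    return MarginalProfile(
        probabilities={
            rid: float(freqs[i]) for i, rid in enumerate(sample_set.reaction_ids)
        },
        sample_id=sample_id,
        config_summary={
            "lambda": cfg.lam,
            "batch_size": cfg.batch_size,
            "burn_in_steps": cfg.burn_in_steps,
            "n_samples": cfg.n_samples,
            "seed": cfg.seed,
            "proposal_mode": cfg.proposal_mode,
            "acceptance_rate": sample_set.acceptance_rate,
        },
    )


def ergodic_average_trace(sample_set: SampleSet, reaction_id: str) -> np.ndarray:
    """Running mean of a reaction's inclusion indicator over stored samples.

    Element t is the estimate after the first t+1 samples; the final element
    equals the marginal estimate.  Monitored for convergence.
    """
    series = sample_set.inclusion_series(reaction_id).astype(float)
    return np.cumsum(series) / np.arange(1, len(series) + 1)


def effective_sample_size(series: np.ndarray, max_lag: int = 100) -> float:
    """Effective sample size of a 0/1 inclusion series.

    Uses the initial-positive-sequence estimator of the integrated
    autocorrelation time (pair sums of autocorrelations accumulated while
    positive), which is robust to correlation extending past lag 1.
    Constant series return n.
    """
    s = np.asarray(series, dtype=float)
    n = len(s)
    if n < 3 or s.std() == 0:
        return float(n)
    c = s - s.mean()
    denom = float(np.dot(c, c))
    max_lag = min(max_lag, n - 2)
    tau = 1.0
    k = 1
    while k + 1 <= max_lag:
        pair = (
            float(np.dot(c[:-k], c[k:])) + float(np.dot(c[: -(k + 1)], c[k + 1 :]))
        ) / denom
        if pair <= 0:
            break
        tau += 2.0 * pair
        k += 2
    return max(n / tau, 1.0)


def batch_autocorrelation(
    network: AnnotatedMetabolicNetwork,
    config: ChainConfig,
    reaction_id: str,
    batch_sizes: Sequence[int],
    n_points: int = 2000,
) -> dict[int, float]:
    """Lag-1 autocorrelation of a reaction's inclusion at several thinnings.

    One chain is run at batch size 1 and thinned in post-processing, so all
    batch sizes see the same underlying trajectory.  A constant series has no
    defined correlation and maps to NaN (degenerate, zero variance).
    """
    if any(b < 1 for b in batch_sizes):
        raise ValueError("batch sizes must be >= 1")
    if n_points < 3:
        raise ValueError("need at least 3 stored samples per batch size")
    base_cfg = replace(
        config, batch_size=1, n_samples=max(batch_sizes) * n_points
    )
    base = run_chain(network, base_cfg)
    series = base.inclusion_series(reaction_id).astype(float)
    out: dict[int, float] = {}
    for b in batch_sizes:
        thinned = series[b - 1 :: b][:n_points]
        if thinned.std() == 0:
            out[b] = float("nan")
            logger.info("batch size %d: degenerate (zero variance)", b)
        else:
            out[b] = float(np.corrcoef(thinned[:-1], thinned[1:])[0, 1])
    return out


def max_likelihood_subnetwork(sample_set: SampleSet) -> tuple[Subnetwork, int]:
    """The visited subnetwork with the fewest metabolites (max likelihood).

    Under the parsimony law the most likely subnetwork is the one with the
    smallest induced metabolite count; the chain tracks the best subnetwork
    seen across the whole run (ties resolved by earliest occurrence).
    """
    return sample_set.min_subnetwork, sample_set.min_metabolite_count
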
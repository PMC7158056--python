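"""Generative model of olefin profiles from fatty-acyl precursors.

OleA condenses two acyl chains head-to-head; after reduction,
lactonization and decarboxylation the olefin carries
``n_i + n_j - 1`` carbons and one branch state per end. Modelling the
two substrate draws as independent with effective probability
proportional to ``w_s * f_s`` (specificity weight x pool abundance)
gives the product distribution over (chain length, isomer class):

    P{i,j} ∝ w_i f_i * w_j f_j * (2 - [i = j])

Weights are identified only up to scale; the anchor is
``sum_s w_s f_s = 1`` over the reference pool. Fitting maximizes the
multinomial likelihood of observed category counts by EM over the latent
substrate pair, which never decreases the likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lipids import BRANCH_TYPES, LipidProfile, classify_isomer, compare_profiles, profile_from_series

SpeciesKey = tuple[int, str]  # (chain_length, branch)


@dataclass(frozen=True)
class FattySpecies:
    chain_length: int
    branch: str  # iso | anteiso | straight
    abundance: float

    def __post_init__(self):
        if self.branch not in BRANCH_TYPES:
            raise ValueError(f"unknown branch {self.branch!r}")
        if self.chain_length < 2:
            raise ValueError("chain length must be >= 2 carbons")
        if self.abundance < 0:
            raise ValueError("abundance must be >= 0")

    @property
    def key(self) -> SpeciesKey:
        return (self.chain_length, self.branch)


def normalize_pool(pool: list[FattySpecies]) -> list[FattySpecies]:
    total = sum(s.abundance for s in pool)
    if total <= 0:
        raise ValueError("pool abundances sum to zero")
    return [FattySpecies(s.chain_length, s.branch, s.abundance / total) for s in pool]


@dataclass(frozen=True)
class SpecificityWeights:
    w: dict[SpeciesKey, float]

    def __post_init__(self):
        if not any(v > 0 for v in self.w.values()):
            raise ValueError("weights must not all be zero")
        if any(v < 0 for v in self.w.values()):
            raise ValueError("weights must be non-negative")

    def anchored(self, pool: list[FattySpecies]) -> "SpecificityWeights":
        """Rescale so that sum_s w_s f_s = 1 over the (normalized) pool."""
        pool = normalize_pool(pool)
        z = sum(self.w[s.key] * s.abundance for s in pool)
        if z <= 0:
            raise ValueError("weights give zero mass on the pool")
        return SpecificityWeights({k: v / z for k, v in self.w.items()})


def uniform_weights(pool: list[FattySpecies]) -> SpecificityWeights:
    return SpecificityWeights({s.key: 1.0 for s in pool}).anchored(pool)


def _pair_category(si: FattySpecies, sj: FattySpecies) -> tuple[int, str]:
    return (si.chain_length + sj.chain_length - 1, classify_isomer(si.branch, sj.branch))


def predict(pool: list[FattySpecies], weights: SpecificityWeights) -> LipidProfile:
    """Predicted olefin distribution over (chain length, isomer class).

    Unordered pair {i,j} has probability proportional to
    w_i f_i * w_j f_j * (2 - [i=j]); pairs landing in the same category sum.
    Returned as a LipidProfile whose amounts are the probabilities.
    """
    pool = normalize_pool(pool)
    if not pool:
        raise ValueError("empty pool")
    missing = [s.key for s in pool if s.key not in weights.w]
    if missing:
        raise ValueError(f"weights missing for pool species {missing}")
    q = np.array([weights.w[s.key] * s.abundance for s in pool])
    if q.sum() <= 0:
        raise ValueError("all effective substrate probabilities are zero")
    pi = q / q.sum()
    cat: dict[tuple[int, str], float] = {}
    for i, si in enumerate(pool):
        for j in range(i, len(pool)):
            sj = pool[j]
            p = pi[i] * pi[j] * (1.0 if i == j else 2.0)
            if p <= 0:
                continue
            key = _pair_category(si, sj)
            cat[key] = cat.get(key, 0.0) + p
    return profile_from_series(cat)


@dataclass
class FitReport:
    log_likelihood: float
    n_iterations: int
    converged: bool
    unachievable: list[tuple[int, str]] = field(default_factory=list)
    log_likelihood_path: list[float] = field(default_factory=list)


def fit_weights(
    pool: list[FattySpecies],
    observed: dict[tuple[int, str], float],
    max_iter: int = 5000,
    tol: float = 1e-10,
    allow_slack: bool = False,
) -> tuple[SpecificityWeights, FitReport]:
    """Maximum-likelihood specificity weights from observed olefin counts.

    EM over the latent substrate pair, from the uniform start: the E-step
    splits each category's count across its contributing pairs in
    proportion to current pair probabilities; the M-step sets the
    substrate draw probability of species s proportional to its expected
    draw count. Observed categories unreachable from the pool are an
    error unless ``allow_slack``, in which case they are dropped and
    listed in the report.
    """
    pool = normalize_pool(pool)
    n = len(pool)
    # category -> list of (i, j) contributing unordered pairs
    cat_pairs: dict[tuple[int, str], list[tuple[int, int]]] = {}
    for i in range(n):
        for j in range(i, n):
            cat_pairs.setdefault(_pair_category(pool[i], pool[j]), []).append((i, j))
    unachievable = sorted(k for k in observed if k not in cat_pairs)
    if unachievable and not allow_slack:
        raise ValueError(f"observed categories unreachable from pool: {unachievable}")
    counts = {k: float(v) for k, v in observed.items() if k in cat_pairs and v > 0}
    if any(v < 0 for v in observed.values()):
        raise ValueError("observed counts must be non-negative")
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("observed counts sum to zero")

    pi = np.full(n, 1.0 / n)
    ll_path: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: expected draws of each species
        draws = np.zeros(n)
        ll = 0.0
        for key, cnt in counts.items():
            pairs = cat_pairs[key]
            probs = np.array(
                [pi[i] * pi[j] * (1.0 if i == j else 2.0) for i, j in pairs]
            )
            pcat = probs.sum()
            if pcat <= 0:
                # category currently impossible; restart its pairs uniformly
                probs = np.ones(len(pairs))
                pcat = probs.sum()
                ll += cnt * np.log(1e-300)
            else:
                ll += cnt * np.log(pcat)
            share = cnt * probs / pcat
            for (i, j), s in zip(pairs, share):
                draws[i] += s * (2.0 if i == j else 1.0)
                if i != j:
                    draws[j] += s
        ll_path.append(ll)
        # M-step
        new_pi = draws / draws.sum()
        delta = float(np.abs(new_pi - pi).max())
        pi = new_pi
        if delta < tol:
            converged = True
            break
    weights = SpecificityWeights(
        {s.key: (pi[i] / s.abundance if s.abundance > 0 else 0.0) for i, s in enumerate(pool)}
    ).anchored(pool)
    report = FitReport(
        log_likelihood=ll_path[-1],
        n_iterations=it,
        converged=converged,
        unachievable=unachievable,
        log_likelihood_path=ll_path,
    )
    return weights, report


def swap_experiment(
    host_pool: list[FattySpecies],
    host_weights: SpecificityWeights,
    donor_weights: SpecificityWeights,
) -> dict:
    """In-silico oleA exchange: donor specificity on the host precursor pool.

    Mirrors moving a foreign oleA into a host — the enzyme changes, the
    fatty-acid supply does not. Product classes requiring substrates the
    host pool lacks stay at zero share (pool-limited).
    """
    host_pool = normalize_pool(host_pool)
    for name, wts in (("host", host_weights), ("donor", donor_weights)):
        missing = [s.key for s in host_pool if s.key not in wts.w]
        if missing:
            raise ValueError(f"{name} weights missing for host pool species {missing}")
    profile_host = predict(host_pool, host_weights)
    profile_swapped = predict(host_pool, donor_weights)
    return {
        "profile_host": profile_host,
        "profile_swapped": profile_swapped,
        "shift": compare_profiles(profile_host, profile_swapped),
    }
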
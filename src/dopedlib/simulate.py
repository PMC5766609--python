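"""Generative biopanning simulator for doped peptide libraries.

The simulator plays the role of the wet lab: it samples a physical phage
library from a doped design, assigns each variant a latent two-receptor
potency under a stated additive model, and runs alternating rounds of
depletion / receptor capture / wash / amplification, so that every
downstream analysis stage can be exercised against known ground truth.

The potency model is deliberately the simplest one consistent with the
biology of closely related class B GPCR peptide hormones: mutations act
additively on log10 EC50, each (position, residue) substitution has one
effect per receptor shared by every variant carrying it, and a small
fraction of substitutions yield binding without receptor activation
(selection sees binding; activity screens do not).  All of its parameters
are explicit and none is fitted to data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

from .design import AMINO_ACIDS, DopedDesign
from .screen import GLUCAGON

__all__ = [
    "Variant",
    "ActivityModelParams",
    "PanningParams",
    "PoolState",
    "PoolExtinctError",
    "sample_library",
    "assign_potencies",
    "panning_round",
    "run_scheme",
    "simulate_readout",
    "RECEPTORS",
]

RECEPTORS = ("GCGR", "GLP1R")

MutKey = tuple[tuple[int, str], ...]  # sorted ((position, residue), ...)


@dataclass(frozen=True)
class Variant:
    """A library member, identified by its mutation set vs the parent."""

    mutations: MutKey
    log_ec50: tuple[float, ...] | None = None  # log10 nM, order RECEPTORS
    binder_only: bool = False

    def peptide(self, parent: str = GLUCAGON) -> str:
        from .screen import MutationCall, apply_mutations

        calls = [MutationCall(position=p, wt=None if p < 0 else parent[p - 1],
                              observed=aa) for p, aa in self.mutations]
        return apply_mutations(parent, calls)


@dataclass(frozen=True)
class ActivityModelParams:
    """Additive latent-potency model.

    ``wt_log_ec50`` anchors the parent: potent on GCGR, weak on GLP1R
    (log10 nM).  Each (position, residue) mutation draws one Normal
    effect per receptor, cached so identical mutations act identically
    across variants, plus a Bernoulli flag making it bind-only.
    """

    wt_log_ec50: tuple[float, float] = (math.log10(0.05), math.log10(200.0))
    effect_mean: tuple[float, float] = (0.0, 0.0)
    effect_sd: tuple[float, float] = (1.0, 1.0)
    binder_only_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if any(sd < 0 for sd in self.effect_sd):
            raise ValueError("effect sd must be >= 0")
        if not 0.0 <= self.binder_only_fraction <= 1.0:
            raise ValueError("binder_only_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class PanningParams:
    """Stochastic model of one depletion/capture/wash/amplification round.

    Depletion on naive cells removes nonspecifically bound phage; the
    model has no per-variant stickiness trait, so depletion enters as the
    uniform pass probability ``1 - depletion_efficiency *
    nonspecific_binding`` (a hook, not a driver of composition).  Capture
    is logistic in binding strength b = -log10 EC50[nM] for the target
    receptor; captured phage survive the washes with ``wash_binder``,
    uncaptured with ``wash_nonbinder``; ``carryover`` is an additive
    nonspecific floor.  Survivors are amplified by multinomial resampling
    to ``amplification_size`` (no growth bias).
    """

    depletion_efficiency: float = 0.9
    nonspecific_binding: float = 0.1
    capture_midpoint: float = 0.0   # b at half-capture (EC50 = 1 nM)
    capture_width: float = 0.5
    wash_binder: float = 0.5
    wash_nonbinder: float = 0.01
    carryover: float = 1e-4
    amplification_size: int = 1_000_000
    rounds: int = 4
    scheme: int = 1
    seed: int = 0

    def __post_init__(self):
        for name in ("depletion_efficiency", "nonspecific_binding",
                     "wash_binder", "wash_nonbinder", "carryover"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.rounds < 0:
            raise ValueError("rounds must be >= 0")
        if self.scheme not in (1, 2):
            raise ValueError("scheme must be 1 or 2")


@dataclass
class PoolState:
    """Multiset of variants at one selection round."""

    round_index: int
    variants: dict[MutKey, Variant]
    counts: dict[MutKey, int]

    def __post_init__(self):
        if any(c <= 0 for c in self.counts.values()):
            raise ValueError("counts must be positive integers")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def n_unique(self) -> int:
        return len(self.counts)

    def frequency(self, key: MutKey) -> float:
        return self.counts.get(key, 0) / self.total


class PoolExtinctError(RuntimeError):
    pass


def sample_library(design: DopedDesign, N: int | None = None,
                   seed: int | None = 0) -> PoolState:
    """Sample ``N`` physical clones from the doped distribution.

    Per clone the mutation count is Binomial(m, 1 - p_wt), the mutated
    positions are uniform without replacement among the randomized
    positions, and each substituted residue is uniform over the non-wt,
    non-Cys alternatives.
    """
    N = design.library_size if N is None else N
    rng = np.random.default_rng(seed)
    m = design.m
    positions = np.asarray(design.randomized_positions)
    # alternatives per randomized position
    alts = []
    for p in positions:
        if p < 0:
            alts.append([a for a in AMINO_ACIDS if a != "C"])
        else:
            wt = design.parent[p - 1]
            alts.append([a for a in AMINO_ACIDS
                         if a not in ("C", wt)][: design.n_alternatives])
    ks = rng.binomial(m, 1.0 - design.p_wt, size=N)
    counts: dict[MutKey, int] = {}
    for k in range(m + 1):
        n_k = int((ks == k).sum())
        if n_k == 0:
            continue
        if k == 0:
            counts[()] = counts.get((), 0) + n_k
            continue
        # mutated position indices: first k of a random permutation
        perm = np.argsort(rng.random((n_k, m)), axis=1)[:, :k]
        # residue pick per mutated slot
        pick = rng.integers(0, [len(alts[j]) for j in range(m)],
                            size=(n_k, m))
        for row in range(n_k):
            muts = tuple(sorted(
                (int(positions[j]), alts[j][pick[row, j]])
                for j in perm[row]))
            counts[muts] = counts.get(muts, 0) + 1
    variants = {key: Variant(mutations=key) for key in counts}
    return PoolState(round_index=0, variants=variants, counts=counts)


def _mutation_streams(params: ActivityModelParams, pos: int, aa: str):
    """Deterministic per-mutation RNG, independent of iteration order."""
    # position labels start at -2; shift into nonnegative entropy words
    return np.random.default_rng(
        (params.seed, pos + 8, AMINO_ACIDS.index(aa)))


class MutationEffects:
    """Cache of per-(position, residue) effects and binder-only flags."""

    def __init__(self, params: ActivityModelParams):
        self.params = params
        self._cache: dict[tuple[int, str], tuple[np.ndarray, bool]] = {}

    def get(self, pos: int, aa: str) -> tuple[np.ndarray, bool]:
        key = (pos, aa)
        got = self._cache.get(key)
        if got is None:
            rng = _mutation_streams(self.params, pos, aa)
            eff = rng.normal(self.params.effect_mean, self.params.effect_sd)
            binder_only = bool(rng.random() < self.params.binder_only_fraction)
            got = (eff, binder_only)
            self._cache[key] = got
        return got


def assign_potencies(pool: PoolState,
                     params: ActivityModelParams) -> PoolState:
    """Attach latent log10 EC50 pairs (and binder-only flags) to a pool.

    Deterministic given ``params.seed``; the wild-type variant receives
    exactly the anchor potencies.  A variant is binder-only if any of its
    mutations carries the binder-only flag.
    """
    effects = MutationEffects(params)
    wt = np.asarray(params.wt_log_ec50, dtype=float)
    variants = {}
    for key, v in pool.variants.items():
        total = wt.copy()
        binder_only = False
        for pos, aa in key:
            eff, bo = effects.get(pos, aa)
            total = total + eff
            binder_only = binder_only or bo
        variants[key] = replace(v, log_ec50=tuple(float(x) for x in total),
                                binder_only=binder_only)
    return PoolState(round_index=pool.round_index, variants=variants,
                     counts=dict(pool.counts))


def _survival_probs(pool: PoolState, receptor: str,
                    params: PanningParams) -> np.ndarray:
    ri = RECEPTORS.index(receptor)
    keys = list(pool.counts)
    b = np.array([-pool.variants[k].log_ec50[ri] for k in keys])
    capture = expit((b - params.capture_midpoint) / params.capture_width)
    depletion_pass = 1.0 - params.depletion_efficiency * params.nonspecific_binding
    p = depletion_pass * (capture * params.wash_binder
                          + (1.0 - capture) * params.wash_nonbinder)
    return np.clip(p + params.carryover, 0.0, 1.0)


def panning_round(pool: PoolState, receptor: str, params: PanningParams,
                  seed: int | None = None) -> PoolState:
    """One depletion/capture/wash/amplification round against ``receptor``.

    Per clone: survival ~ Bernoulli(p) with p from the capture model
    (binder-only variants use the same latent binding strength — selection
    sees binding, not activation); survivors are multinomially resampled
    to the amplification target.
    """
    if receptor not in RECEPTORS:
        raise ValueError(f"unknown receptor {receptor!r}")
    if not pool.counts:
        raise PoolExtinctError("input pool is empty")
    if any(v.log_ec50 is None for v in pool.variants.values()):
        raise ValueError("pool has no latent potencies; "
                         "run assign_potencies first")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    keys = list(pool.counts)
    n = np.array([pool.counts[k] for k in keys])
    p = _survival_probs(pool, receptor, params)
    survivors = rng.binomial(n, p)
    total = int(survivors.sum())
    if total == 0:
        raise PoolExtinctError(
            f"pool extinguished in round vs {receptor}")
    amplified = rng.multinomial(params.amplification_size, survivors / total)
    counts = {k: int(c) for k, c in zip(keys, amplified) if c > 0}
    variants = {k: pool.variants[k] for k in counts}
    return PoolState(round_index=pool.round_index + 1,
                     variants=variants, counts=counts)


def classify_variant(v: Variant, potency_cutoff_nm: float = 20.0) -> str:
    """Latent truth class: dual / single potent activator, binder-only,
    or inert, at an EC50 cutoff (nM) on each receptor."""
    cut = math.log10(potency_cutoff_nm)
    potent = [x <= cut for x in v.log_ec50]
    if v.binder_only:
        return "binder_only"
    if all(potent):
        return "dual_potent"
    if any(potent):
        return "single_potent"
    return "inert"


def pool_summary(pool: PoolState, potency_cutoff_nm: float = 20.0) -> dict:
    """Pool-weighted class fractions and mean binding strengths."""
    total = pool.total
    frac = {c: 0.0 for c in
            ("dual_potent", "single_potent", "binder_only", "inert")}
    mean_b = np.zeros(len(RECEPTORS))
    for key, c in pool.counts.items():
        v = pool.variants[key]
        frac[classify_variant(v, potency_cutoff_nm)] += c / total
        mean_b += (c / total) * -np.asarray(v.log_ec50)
    out = {"round": pool.round_index, "total": total,
           "n_unique": pool.n_unique, **frac}
    for r, b in zip(RECEPTORS, mean_b):
        out[f"mean_binding_{r}"] = float(b)
    return out


def scheme_order(scheme: int, rounds: int) -> list[str]:
    """Receptor order: scheme 1 starts on GCGR, scheme 2 on GLP1R."""
    first = 0 if scheme == 1 else 1
    return [RECEPTORS[(first + r) % 2] for r in range(rounds)]


def run_scheme(design: DopedDesign,
               model: ActivityModelParams,
               panning: PanningParams,
               scheme: int | None = None,
               N: int | None = None,
               seed: int | None = None):
    """Sample, assign potencies, and run the alternating selection.

    Returns ``(pools, summaries)``: pool states for rounds 0..rounds and
    one summary dict per round.  All randomness derives from ``seed``
    (default ``panning.seed``) via spawned child streams.
    """
    scheme = panning.scheme if scheme is None else scheme
    seed = panning.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(panning.rounds + 1)
    pool = sample_library(design, N=N, seed=child[0])
    pool = assign_potencies(pool, model)
    pools = [pool]
    summaries = [pool_summary(pool)]
    for r, receptor in enumerate(scheme_order(scheme, panning.rounds)):
        pool = panning_round(pool, receptor, panning, seed=child[r + 1])
        pools.append(pool)
        summaries.append(pool_summary(pool))
    return pools, summaries


def simulate_readout(pool: PoolState, receptor: str,
                     phage_conc_nm: float = 1.0,
                     noise_sd: float = 0.2,
                     seed: int | None = 0) -> dict[MutKey, float]:
    """Optional noisy cAMP-style readout per variant (log-normal noise).

    Activating variants produce a fractional response
    ``1 / (1 + EC50 / conc)``; binder-only and inert variants produce
    zero signal (plus nothing to corrupt multiplicatively).
    """
    ri = RECEPTORS.index(receptor)
    rng = np.random.default_rng(seed)
    out = {}
    for key, v in pool.variants.items():
        if v.binder_only:
            signal = 0.0
        else:
            ec50 = 10.0 ** v.log_ec50[ri]
            signal = 1.0 / (1.0 + ec50 / phage_conc_nm)
        noise = math.exp(rng.normal(0.0, noise_sd))
        out[key] = signal * noise
    return out
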
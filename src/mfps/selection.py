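"""Probe-set selection by simulated annealing.

Two objectives are supported.  The taxonomy-aware fidelity cost scores a
probe set by how well its distinct fingerprints stay confined to single
taxonomic groups:

    C = 1/2 * sum_f sum_i  P_i * gamma_{i,f} * (gamma_{i,f} - 1)

where f runs over the distinct fingerprints, i over the taxonomic levels
(OTU, genus, phylum), gamma_{i,f} is the number of groups at level i in
which fingerprint f occurs and P_i the penalty for level i.  A
fingerprint confined to one group at a level (gamma = 1) accrues no
penalty from that level.  The legacy distinguishing cost instead counts
pairs of sequences left with identical fingerprints:

    C = 1/2 * sum_f  n_f * (n_f - 1)

with n_f the number of sequences bearing fingerprint f; it ignores
taxonomy entirely.  Setting every sequence as its own singleton "OTU"
with penalties (1, 0, 0) makes the two objectives coincide exactly.

Fingerprints are bit-packed per sequence so a cost evaluation is a byte
sort; annealing moves update the packed matrix in place by XOR, which is
bit-identical to recomputation from scratch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log
from typing import Mapping

import numpy as np

from .core import LEVELS
from .errors import ConfigError, InfeasibleError
from .probe_matrix import ProbeMatrix

_UPHILL_ACCEPT_TARGET = 0.8  # initial-temperature calibration
_WARMUP_MOVES = 200


@dataclass(frozen=True)
class PenaltyConfig:
    """Per-level penalties P_i; defaults are OTU 1, genus 30, phylum 0."""

    p_otu: float = 1.0
    p_genus: float = 30.0
    p_phylum: float = 0.0

    def __post_init__(self) -> None:
        if min(self.p_otu, self.p_genus, self.p_phylum) < 0:
            raise ConfigError("penalties must be nonnegative")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.p_otu, self.p_genus, self.p_phylum)


@dataclass(frozen=True)
class AnnealingConfig:
    """Schedule and constraints for one selection job.

    ``steps=None`` means 200 * k moves per restart; ``t_initial=None``
    calibrates the start temperature so roughly 80% of uphill moves
    would be accepted over a short warm-up.  ``retained`` probes are
    always in the set; ``avoided`` probes never are.
    """

    steps: int | None = None
    t_initial: float | None = None
    cooling: float = 0.995
    restarts: int = 10
    seed: int = 0
    retained: frozenset[int] = frozenset()
    avoided: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if not (0 < self.cooling < 1):
            raise ConfigError("cooling factor must be in (0, 1)")
        if self.restarts < 1:
            raise ConfigError("restarts must be >= 1")
        if set(self.retained) & set(self.avoided):
            raise ConfigError("retained and avoided probes overlap")


@dataclass
class FidelityAccounting:
    """Distinct-fingerprint census: N and gamma per level."""

    n_distinct: int
    gamma: dict[str, np.ndarray]
    cost: float | None = None


@dataclass
class AnnealResult:
    probe_indices: tuple[int, ...]
    probes: tuple[str, ...]
    cost: float
    restart: int
    trace: list[tuple[int, float]]
    accounting: FidelityAccounting


# ---------------------------------------------------------------------------
# Fingerprints
# ---------------------------------------------------------------------------


def fingerprint_all(probe_indices, pm: ProbeMatrix) -> dict[str, np.ndarray]:
    """Fingerprint per sequence: bit j = incidence of probe j in the set."""
    idx = list(probe_indices)
    sub = pm.incidence[idx] if idx else np.zeros((0, pm.n_sequences), np.uint8)
    return {sid: sub[:, i].copy() for i, sid in enumerate(pm.seq_ids)}


def _pack(pm: ProbeMatrix, probe_indices) -> np.ndarray:
    """Bit-pack the k x S incidence submatrix to ceil(k/8) x S bytes."""
    idx = list(probe_indices)
    sub = pm.incidence[idx] if idx else np.zeros((0, pm.n_sequences), np.uint8)
    return np.packbits(sub, axis=0)


def _distinct(packed: np.ndarray, n_seq: int) -> tuple[int, np.ndarray]:
    """Distinct fingerprints of a packed matrix: (N, inverse index per seq)."""
    if packed.shape[0] == 0:
        return 1, np.zeros(n_seq, dtype=np.intp)
    a = np.ascontiguousarray(packed.T)
    view = a.view(np.dtype((np.void, a.shape[1]))).ravel()
    uniq, inv = np.unique(view, return_inverse=True)
    return len(uniq), inv


def _gamma_of_level(inv: np.ndarray, n_distinct: int, codes: np.ndarray) -> np.ndarray:
    """gamma_f = number of distinct groups whose sequences bear fingerprint f."""
    n_groups = int(codes.max()) + 1 if codes.size else 1
    pairs = np.unique(inv.astype(np.int64) * n_groups + codes)
    return np.bincount(pairs // n_groups, minlength=n_distinct)


def gamma_counts(fps: Mapping[str, np.ndarray], pm: ProbeMatrix) -> FidelityAccounting:
    """Census of distinct fingerprints against the taxonomy in ``pm``."""
    mat = np.stack([fps[sid] for sid in pm.seq_ids]).astype(np.uint8)
    packed = np.packbits(mat.T, axis=0) if mat.shape[1] else np.zeros((0, len(pm.seq_ids)), np.uint8)
    n, inv = _distinct(packed, len(pm.seq_ids))
    gamma = {lvl: _gamma_of_level(inv, n, pm.codes(lvl)) for lvl in LEVELS}
    return FidelityAccounting(n_distinct=n, gamma=gamma)


def accounting_for(probe_indices, pm: ProbeMatrix) -> FidelityAccounting:
    """Fast path: census straight from the probe matrix."""
    packed = _pack(pm, probe_indices)
    n, inv = _distinct(packed, pm.n_sequences)
    gamma = {lvl: _gamma_of_level(inv, n, pm.codes(lvl)) for lvl in LEVELS}
    return FidelityAccounting(n_distinct=n, gamma=gamma)


# ---------------------------------------------------------------------------
# Costs
# ---------------------------------------------------------------------------


def mfps_cost(acct: FidelityAccounting, pen: PenaltyConfig) -> float:
    """C = 1/2 sum_f sum_i P_i gamma(gamma - 1)."""
    total = 0.0
    for lvl, p in zip(LEVELS, pen.as_tuple()):
        g = acct.gamma[lvl].astype(np.float64)
        total += p * float((g * (g - 1.0)).sum())
    return 0.5 * total


def mdps_cost(fps: Mapping[str, np.ndarray]) -> float:
    """C = 1/2 sum_f n_f (n_f - 1): pairs of undistinguished sequences."""
    seen: dict[bytes, int] = {}
    for v in fps.values():
        key = np.asarray(v, dtype=np.uint8).tobytes()
        seen[key] = seen.get(key, 0) + 1
    return 0.5 * sum(n * (n - 1) for n in seen.values())


def _cost_from_packed(
    packed: np.ndarray, pm: ProbeMatrix, cost: str, pen: PenaltyConfig
) -> float:
    n, inv = _distinct(packed, pm.n_sequences)
    if cost == "mdps":
        counts = np.bincount(inv, minlength=n)
        return 0.5 * float((counts * (counts - 1.0)).sum())
    total = 0.0
    for lvl, p in zip(LEVELS, pen.as_tuple()):
        if p == 0:
            continue
        g = _gamma_of_level(inv, n, pm.codes(lvl)).astype(np.float64)
        total += p * float((g * (g - 1.0)).sum())
    return 0.5 * total


# ---------------------------------------------------------------------------
# Simulated annealing
# ---------------------------------------------------------------------------


def _anneal_once(
    pm: ProbeMatrix,
    k: int,
    cost: str,
    pen: PenaltyConfig,
    cfg: AnnealingConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float, list[tuple[int, float]]]:
    retained = sorted(cfg.retained)
    pool = np.array(
        [j for j in range(pm.n_probes) if j not in cfg.avoided and j not in cfg.retained],
        dtype=np.intp,
    )
    n_free = k - len(retained)
    current = np.concatenate(
        [np.asarray(retained, dtype=np.intp), rng.choice(pool, size=n_free, replace=False)]
    )
    in_set = set(int(j) for j in current)
    packed = _pack(pm, current)
    cost_now = _cost_from_packed(packed, pm, cost, pen)

    inc = pm.incidence

    def propose():
        """Pick a replaceable slot and a fresh probe not in the set."""
        pos = len(retained) + int(rng.integers(n_free))
        while True:
            new = int(pool[int(rng.integers(pool.size))])
            if new not in in_set:
                return pos, new

    def xor_swap(pos: int, a: int, b: int) -> None:
        """Flip bit ``pos`` of every sequence whose incidence differs a->b."""
        packed[pos // 8] ^= (inc[a] ^ inc[b]) << np.uint8(7 - pos % 8)

    # temperature calibration: trial moves from the initial state
    t0 = cfg.t_initial
    if t0 is None:
        uphill = []
        for _ in range(_WARMUP_MOVES):
            pos, new = propose()
            old = int(current[pos])
            xor_swap(pos, old, new)
            delta = _cost_from_packed(packed, pm, cost, pen) - cost_now
            xor_swap(pos, old, new)  # revert (XOR is its own inverse)
            if delta > 0:
                uphill.append(delta)
        t0 = (sum(uphill) / len(uphill)) / -log(_UPHILL_ACCEPT_TARGET) if uphill else 1.0

    steps = cfg.steps if cfg.steps is not None else 200 * k
    best = current.copy()
    best_cost = cost_now
    trace: list[tuple[int, float]] = [(0, best_cost)]
    temp = t0
    for step in range(steps):
        if best_cost == 0.0:
            break
        pos, new = propose()
        old = int(current[pos])
        xor_swap(pos, old, new)
        cost_new = _cost_from_packed(packed, pm, cost, pen)
        delta = cost_new - cost_now
        if delta <= 0 or rng.random() < np.exp(-delta / max(temp, 1e-300)):
            current[pos] = new
            in_set.discard(old)
            in_set.add(new)
            cost_now = cost_new
            if cost_now < best_cost:
                best_cost = cost_now
                best = current.copy()
                trace.append((step + 1, best_cost))
        else:
            xor_swap(pos, old, new)  # revert
        temp *= cfg.cooling
    return best, best_cost, trace


def anneal(
    pm: ProbeMatrix,
    k: int,
    cost: str = "mfps",
    pen: PenaltyConfig | None = None,
    cfg: AnnealingConfig | None = None,
) -> AnnealResult:
    """Best probe set over ``cfg.restarts`` independent annealing runs.

    Each restart draws its generator from ``seed + restart_index`` so runs
    are individually reproducible; ties across restarts go to the lowest
    restart index.  A run whose best cost hits zero stops early (zero is
    the global minimum of both objectives).
    """
    if cost not in ("mfps", "mdps"):
        raise ConfigError(f"unknown cost function: {cost!r}")
    pen = pen or PenaltyConfig()
    cfg = cfg or AnnealingConfig()
    if any(j < 0 or j >= pm.n_probes for j in (*cfg.retained, *cfg.avoided)):
        raise ConfigError("retained/avoided indices out of range")
    if len(cfg.retained) > k:
        raise InfeasibleError(f"|retained| = {len(cfg.retained)} exceeds k = {k}")
    available = pm.n_probes - len(cfg.avoided)
    if k > available:
        raise InfeasibleError(f"k = {k} exceeds {available} available probes")

    if len(cfg.retained) == k:
        # fully constrained: no search
        chosen = np.asarray(sorted(cfg.retained), dtype=np.intp)
        packed = _pack(pm, chosen)
        c = _cost_from_packed(packed, pm, cost, pen)
        acct = accounting_for(chosen, pm)
        acct.cost = c
        return AnnealResult(
            probe_indices=tuple(int(j) for j in chosen),
            probes=tuple(pm.probes[j] for j in chosen),
            cost=c,
            restart=-1,
            trace=[(0, c)],
            accounting=acct,
        )

    best: tuple[float, int, np.ndarray, list] | None = None
    for r in range(cfg.restarts):
        rng = np.random.default_rng(cfg.seed + r)
        state, c, trace = _anneal_once(pm, k, cost, pen, cfg, rng)
        if best is None or c < best[0]:
            best = (c, r, state, trace)
        if best[0] == 0.0:
            break

    c, r, state, trace = best
    chosen = np.sort(state)
    acct = accounting_for(chosen, pm)
    acct.cost = c
    return AnnealResult(
        probe_indices=tuple(int(j) for j in chosen),
        probes=tuple(pm.probes[j] for j in chosen),
        cost=float(c),
        restart=r,
        trace=trace,
        accounting=acct,
    )
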
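"""Evaluation metrics and experiment harnesses.

Two metrics: the High Fidelity Ratio (HFR) — the fraction of distinct
fingerprints confined to a single group at a taxonomic level — and the
average pairwise sequence distance of low-fidelity fingerprints, binned
at 1%.  Harnesses cover 20%/100% cross-validation, phylum holdout,
random-control probe sets, positional bias and the genus-penalty sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import AlignmentSet, LEVELS
from .errors import ConfigError
from .otu_cluster import pairwise_distances
from .probe_matrix import ProbeMatrix
from .selection import (
    AnnealingConfig,
    PenaltyConfig,
    accounting_for,
    anneal,
)


@dataclass
class HFRResult:
    """HFR at one taxonomic level: high-fidelity / all distinct fingerprints."""

    level: str
    n_distinct: int
    n_high_fidelity: int
    ratio: float


@dataclass
class DistanceHistogram:
    """Mean (and SD) per-1%-bin count of low-fidelity fingerprint distances."""

    bin_width: float
    counts: np.ndarray  # mean count per bin across probe sets
    dispersion: np.ndarray  # per-bin standard deviation
    hf_max_avg_distance: float  # largest average distance seen for a high-fidelity fp


@dataclass(frozen=True)
class CrossValPlan:
    folds: int = 5
    train_fraction: float = 0.20
    validate_fraction: float = 1.00
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ConfigError("folds must be >= 2")
        if not (0 < self.train_fraction <= 1 and 0 < self.validate_fraction <= 1):
            raise ConfigError("fractions must lie in (0, 1]")
        if self.folds * self.train_fraction > 1 + 1e-9:
            raise ConfigError("disjoint folds require folds * train_fraction <= 1")


@dataclass
class SelectArgs:
    """Selection settings shared by the experiment harnesses."""

    k: int = 40
    cost: str = "mfps"
    pen: PenaltyConfig = field(default_factory=PenaltyConfig)
    cfg: AnnealingConfig = field(default_factory=AnnealingConfig)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def hfr(probe_indices, pm: ProbeMatrix, level: str) -> HFRResult:
    """High Fidelity Ratio of a probe set at one taxonomic level."""
    if pm.n_sequences == 0:
        raise ValueError("HFR undefined on an empty sequence set")
    acct = accounting_for(probe_indices, pm)
    gamma = acct.gamma[level]
    n_high = int((gamma == 1).sum())
    return HFRResult(
        level=level,
        n_distinct=acct.n_distinct,
        n_high_fidelity=n_high,
        ratio=n_high / acct.n_distinct,
    )


def hfr_all_levels(probe_indices, pm: ProbeMatrix) -> dict[str, HFRResult]:
    return {lvl: hfr(probe_indices, pm, lvl) for lvl in LEVELS}


def low_fidelity_distance_histogram(
    probe_sets,
    pm: ProbeMatrix,
    aln: AlignmentSet,
    level: str = "otu",
    n_bins: int = 100,
) -> DistanceHistogram:
    """Histogram of average pairwise distances of low-fidelity fingerprints.

    For each probe set and each distinct fingerprint occurring in more
    than one group at ``level``, the average pairwise distance of the
    sequences bearing it is binned at 1%; counts are averaged (with SD)
    across probe sets.  A probe set with no low-fidelity fingerprints
    contributes a row of zeros.
    """
    if list(aln.ids) != list(pm.seq_ids):
        aln = aln.subset_sequences(pm.seq_ids)
    dm = pairwise_distances(aln)
    per_set = np.zeros((len(probe_sets), n_bins), dtype=float)
    hf_max = 0.0
    for si, ps in enumerate(probe_sets):
        idx = list(ps)
        sub = pm.incidence[idx] if idx else np.zeros((0, pm.n_sequences), np.uint8)
        packed = np.packbits(sub, axis=0) if idx else sub
        if packed.shape[0]:
            a = np.ascontiguousarray(packed.T)
            view = a.view(np.dtype((np.void, a.shape[1]))).ravel()
            _, inv = np.unique(view, return_inverse=True)
        else:
            inv = np.zeros(pm.n_sequences, dtype=np.intp)
        codes = pm.codes(level)
        for f in range(int(inv.max()) + 1):
            rows = np.flatnonzero(inv == f)
            n_groups = len(np.unique(codes[rows]))
            if rows.size < 2:
                avg = 0.0
            else:
                sub_d = dm.d[np.ix_(rows, rows)]
                iu = np.triu_indices(rows.size, k=1)
                avg = float(sub_d[iu].mean())
            if n_groups > 1:
                b = min(int(avg / 0.01), n_bins - 1)
                per_set[si, b] += 1
            else:
                hf_max = max(hf_max, avg)
    return DistanceHistogram(
        bin_width=0.01,
        counts=per_set.mean(axis=0),
        dispersion=per_set.std(axis=0),
        hf_max_avg_distance=hf_max,
    )


# ---------------------------------------------------------------------------
# Harnesses
# ---------------------------------------------------------------------------


def _select(pm: ProbeMatrix, args: SelectArgs, seed: int):
    cfg = replace(args.cfg, seed=seed)
    return anneal(pm, args.k, cost=args.cost, pen=args.pen, cfg=cfg)


@dataclass
class CrossValResult:
    per_fold: list[dict[str, HFRResult]]
    mean: dict[str, float]
    probe_sets: list[tuple[int, ...]]


def crossval(pm: ProbeMatrix, plan: CrossValPlan, select_args: SelectArgs) -> CrossValResult:
    """Train on disjoint ``train_fraction`` samples, validate on 100%.

    Each fold selects a probe set on its own sequence sample and scores
    HFR on the full matrix; the mean over folds is reported per level.
    """
    rng = np.random.default_rng(plan.seed)
    perm = rng.permutation(pm.n_sequences)
    fold_size = int(round(pm.n_sequences * plan.train_fraction))
    per_fold, probe_sets = [], []
    for f in range(plan.folds):
        train_idx = np.sort(perm[f * fold_size : (f + 1) * fold_size])
        if train_idx.size == 0:
            raise ConfigError("fold contains no sequences")
        pm_train = pm.subset_sequences(train_idx)
        res = _select(pm_train, select_args, seed=select_args.cfg.seed + 7919 * f)
        probe_sets.append(res.probe_indices)
        per_fold.append(hfr_all_levels(res.probe_indices, pm))
    mean = {
        lvl: float(np.mean([fold[lvl].ratio for fold in per_fold])) for lvl in LEVELS
    }
    return CrossValResult(per_fold=per_fold, mean=mean, probe_sets=probe_sets)


def phylum_holdout(
    pm: ProbeMatrix, phylum: str, select_args: SelectArgs
) -> dict[str, dict[str, HFRResult]]:
    """Train without one phylum's sequences, evaluate on the full matrix.

    Returns HFRs for both conditions ("with" = trained on everything,
    "without" = the named phylum excluded from training); evaluation
    always uses all sequences.
    """
    names = pm.group_names["phylum"]
    if phylum not in names:
        raise ValueError(f"unknown phylum: {phylum!r} (have {names})")
    code = names.index(phylum)
    keep = pm.codes("phylum") != code
    res_with = _select(pm, select_args, seed=select_args.cfg.seed)
    pm_train = pm.subset_sequences(keep) if keep.sum() < pm.n_sequences else pm
    res_without = _select(pm_train, select_args, seed=select_args.cfg.seed)
    return {
        "with": hfr_all_levels(res_with.probe_indices, pm),
        "without": hfr_all_levels(res_without.probe_indices, pm),
    }


def random_probe_sets(
    pm: ProbeMatrix, k: int, n_sets: int, seed: int = 0
) -> list[tuple[int, ...]]:
    """Uniform probe sets without replacement (the random control)."""
    if k > pm.n_probes:
        raise ValueError(f"k = {k} exceeds {pm.n_probes} probes")
    rng = np.random.default_rng(seed)
    return [
        tuple(int(j) for j in np.sort(rng.choice(pm.n_probes, size=k, replace=False)))
        for _ in range(n_sets)
    ]


def positional_bias(
    probe_sets, pm: ProbeMatrix, aln: AlignmentSet
) -> dict[int, int]:
    """Frequency of probe start positions on the degapped consensus.

    Each probe in each set contributes its first match position; a probe
    absent from the consensus falls back to its first match in the first
    sequence containing it, and is skipped (with a warning) if it matches
    nowhere.
    """
    import warnings

    cons = aln.consensus_string().replace("-", "")
    seqs = [aln.degapped(sid) for sid in aln.ids]
    freq: dict[int, int] = {}
    for ps in probe_sets:
        for j in ps:
            probe = pm.probes[j]
            pos = cons.find(probe)
            if pos < 0:
                for s in seqs:
                    pos = s.find(probe)
                    if pos >= 0:
                        break
            if pos < 0:
                warnings.warn(f"probe {probe!r} matches no sequence; skipped")
                continue
            freq[pos] = freq.get(pos, 0) + 1
    return freq


def penalty_sweep(
    pm: ProbeMatrix,
    genus_penalties,
    select_args: SelectArgs,
    n_sets: int = 100,
) -> pd.DataFrame:
    """Vary the genus penalty with the OTU penalty held at its default.

    For each penalty value, ``n_sets`` probe sets are annealed from
    distinct seeds; the table reports mean and SD of the OTU and genus
    HFR per penalty (tidy: one row per penalty x level).
    """
    rows = []
    for pen_g in genus_penalties:
        if pen_g < 0:
            raise ConfigError("penalties must be nonnegative")
        pen = PenaltyConfig(
            p_otu=select_args.pen.p_otu, p_genus=float(pen_g), p_phylum=select_args.pen.p_phylum
        )
        args = SelectArgs(k=select_args.k, cost="mfps", pen=pen, cfg=select_args.cfg)
        ratios = {lvl: [] for lvl in ("otu", "genus")}
        for s in range(n_sets):
            res = _select(pm, args, seed=select_args.cfg.seed + 104729 * s)
            for lvl in ratios:
                ratios[lvl].append(hfr(res.probe_indices, pm, lvl).ratio)
        for lvl, vals in ratios.items():
            rows.append(
                {
                    "genus_penalty": float(pen_g),
                    "level": lvl,
                    "mean": float(np.mean(vals)),
                    "sd": float(np.std(vals)),
                    "n": n_sets,
                }
            )
    return pd.DataFrame(rows)
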
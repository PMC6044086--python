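"""Monte-Carlo simulation of PCR amplification, UMI errors, and sequencing.

The simulator asks how well UMIs identify PCR duplicates as a function of
seven experimental knobs: starting molecules, UMI length, PCR cycles,
minimum amplification probability *m*, PCR error rate, sequencing error
rate, and sequencing depth.  Each trial:

1. creates ``n_initial`` molecules, each tagged with a uniform-random UMI;
2. runs ``n_cycles`` of PCR — each molecule duplicates in a cycle with a
   probability drawn fresh from Uniform(m, 1) (marginally a
   Bernoulli((1+m)/2) event), and every newly synthesised copy acquires
   independent per-base UMI substitutions at ``pcr_error_rate``;
3. draws ``seq_depth`` molecules without replacement and reads their UMIs
   through a per-base substitution channel at ``seq_error_rate``;
4. counts truth (distinct founder molecules among the reads) against the
   uncorrected (distinct observed UMI strings) and corrected
   (directional-graph clusters) estimates.

The default engine tracks the pool as (founder, UMI) groups with counts —
binomial draws replace per-molecule coin flips, which is distributionally
identical because molecules within a group are exchangeable.  A literal
per-molecule engine is kept for cross-checking and for the
"per-lifetime" amplification-probability variant, where each molecule
keeps one p for all cycles (under per-cycle redrawing the two engines
match in distribution; per-lifetime p makes molecules non-exchangeable,
so only the per-molecule engine supports it).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .graph import count_unique

SWEEPABLE = (
    "n_initial",
    "umi_length",
    "n_cycles",
    "min_amp_prob",
    "pcr_error_rate",
    "seq_error_rate",
    "seq_depth",
)


class TrialError(RuntimeError):
    """A trial could not be completed (e.g. depth exceeds the pool)."""


@dataclass(frozen=True)
class SimParams:
    """Simulation parameters; defaults are the baseline condition."""

    n_initial: int = 100
    umi_length: int = 18
    n_cycles: int = 10
    min_amp_prob: float = 0.8
    pcr_error_rate: float = 3e-5
    seq_error_rate: float = 1e-3
    seq_depth: int = 100
    n_trials: int = 10_000
    seed: int = 0
    amp_prob_mode: str = "per-cycle"  # or "per-lifetime"
    engine: str = "compressed"  # or "per-molecule"

    def __post_init__(self) -> None:
        for name in ("min_amp_prob", "pcr_error_rate", "seq_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("n_initial", "umi_length", "n_cycles", "seq_depth", "n_trials"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.amp_prob_mode not in ("per-cycle", "per-lifetime"):
            raise ValueError("amp_prob_mode must be 'per-cycle' or 'per-lifetime'")
        if self.engine not in ("compressed", "per-molecule"):
            raise ValueError("engine must be 'compressed' or 'per-molecule'")

    @property
    def expected_pool_size(self) -> float:
        """Analytic mean pool size n_initial * ((3+m)/2)^n_cycles (per-cycle mode)."""
        return self.n_initial * ((3.0 + self.min_amp_prob) / 2.0) ** self.n_cycles


@dataclass
class MoleculeGroup:
    """Count-compressed pool entry: molecules sharing a founder and UMI."""

    ancestor_id: int
    umi: bytes  # base codes 0..3, one byte per position
    count: int


@dataclass
class Pool:
    """The molecule pool as parallel arrays over groups."""

    ancestors: np.ndarray  # int64 (g,)
    umis: np.ndarray  # uint8 (g, umi_length), values 0..3
    counts: np.ndarray  # int64 (g,)

    @property
    def size(self) -> int:
        return int(self.counts.sum())

    def groups(self) -> Iterator[MoleculeGroup]:
        for a, u, c in zip(self.ancestors, self.umis, self.counts):
            yield MoleculeGroup(int(a), u.tobytes(), int(c))


@dataclass(frozen=True)
class TrialResult:
    pool_size: int
    truth: int
    est_uncorrected: int
    est_corrected: int
    dup_frac_truth: float
    dup_frac_uncorrected: float
    dup_frac_corrected: float
    rel_err_uncorrected: float
    rel_err_corrected: float

    METRICS = (
        "pool_size",
        "truth",
        "est_uncorrected",
        "est_corrected",
        "dup_frac_truth",
        "dup_frac_uncorrected",
        "dup_frac_corrected",
        "rel_err_uncorrected",
        "rel_err_corrected",
    )


def init_pool(params: SimParams, rng: np.random.Generator) -> Pool:
    """n_initial founder molecules, distinct ancestor ids, uniform-random UMIs."""
    n, L = params.n_initial, params.umi_length
    return Pool(
        ancestors=np.arange(n, dtype=np.int64),
        umis=rng.integers(0, 4, size=(n, L), dtype=np.uint8),
        counts=np.ones(n, dtype=np.int64),
    )


@lru_cache(maxsize=32)
def _truncated_error_count_probs(length: int, rate: float) -> np.ndarray:
    """P(j errors | >=1 error) for j = 1..length under Binomial(length, rate)."""
    j = np.arange(1, length + 1)
    logpmf = (
        np.array([math.lgamma(length + 1) - math.lgamma(k + 1) - math.lgamma(length - k + 1) for k in j])
        + j * math.log(rate)
        + (length - j) * math.log1p(-rate)
    )
    pmf = np.exp(logpmf)
    return pmf / pmf.sum()


def _mutate_rows(umis: np.ndarray, umi_length: int, rate: float, rng: np.random.Generator) -> None:
    """Apply >=1 substitutions per row, error counts truncated-binomial (in place).

    Substitutions are uniform over the 3 alternative bases; the common
    single-error case is fully vectorised.
    """
    k_rows = len(umis)
    probs = _truncated_error_count_probs(umi_length, rate)
    kcounts = rng.choice(umi_length, size=k_rows, p=probs) + 1
    one = np.flatnonzero(kcounts == 1)
    if one.size:
        pos = rng.integers(0, umi_length, size=one.size)
        umis[one, pos] = (umis[one, pos] + rng.integers(1, 4, size=one.size)) % 4
    for i in np.flatnonzero(kcounts > 1):
        k = int(kcounts[i])
        pos = rng.choice(umi_length, size=k, replace=False)
        umis[i, pos] = (umis[i, pos] + rng.integers(1, 4, size=k)) % 4


def pcr_cycle(
    pool: Pool,
    m: float,
    pcr_error_rate: float,
    umi_length: int,
    rng: np.random.Generator,
) -> Pool:
    """One PCR cycle on the group-compressed pool (in place; pool returned).

    Each molecule duplicates with marginal probability (1+m)/2; error-free
    copies stay in their group, erroneous copies found new groups with the
    mutated UMI.  Group-level binomial draws are distributionally identical
    to per-molecule simulation because group members are exchangeable.
    """
    p_dup = (1.0 + m) / 2.0
    n_new = rng.binomial(pool.counts, p_dup)
    if pcr_error_rate > 0.0:
        p_any = 1.0 - (1.0 - pcr_error_rate) ** umi_length
        n_err = rng.binomial(n_new, p_any)
    else:
        n_err = np.zeros_like(n_new)
    pool.counts += n_new - n_err

    err_groups = np.flatnonzero(n_err)
    if err_groups.size:
        src = np.repeat(err_groups, n_err[err_groups])
        new_umis = pool.umis[src].copy()
        _mutate_rows(new_umis, umi_length, pcr_error_rate, rng)
        pool.ancestors = np.concatenate([pool.ancestors, pool.ancestors[src]])
        pool.umis = np.vstack([pool.umis, new_umis])
        pool.counts = np.concatenate([pool.counts, np.ones(len(src), dtype=np.int64)])
    return pool


def sequence_pool(
    pool: Pool,
    seq_depth: int,
    seq_error_rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample seq_depth molecules without replacement and read their UMIs.

    Returns (ancestor_ids, observed_umis) with one row per read; observed
    UMIs carry independent per-base substitutions at seq_error_rate.
    """
    total = pool.size
    if seq_depth > total:
        raise TrialError(f"seq_depth {seq_depth} exceeds pool size {total}")
    drawn = rng.multivariate_hypergeometric(pool.counts, seq_depth)
    idx = np.repeat(np.arange(len(drawn)), drawn)
    ancestors = pool.ancestors[idx]
    umis = pool.umis[idx].copy()
    if seq_error_rate > 0.0 and umis.size:
        err_mask = rng.random(umis.shape) < seq_error_rate
        n_err = int(err_mask.sum())
        if n_err:
            umis[err_mask] = (umis[err_mask] + rng.integers(1, 4, size=n_err)) % 4
    return ancestors, umis


# ---------------------------------------------------------------------------
# literal per-molecule engine (cross-check; supports per-lifetime p)


def _run_trial_per_molecule(params: SimParams, rng: np.random.Generator) -> Pool:
    n, L = params.n_initial, params.umi_length
    ancestors = np.arange(n, dtype=np.int64)
    umis = rng.integers(0, 4, size=(n, L), dtype=np.uint8)
    lifetime = params.amp_prob_mode == "per-lifetime"
    p = rng.uniform(params.min_amp_prob, 1.0, size=n) if lifetime else None
    for _ in range(params.n_cycles):
        n_mol = len(ancestors)
        p_cycle = p if lifetime else rng.uniform(params.min_amp_prob, 1.0, size=n_mol)
        dup = rng.random(n_mol) < p_cycle
        new_umis = umis[dup].copy()
        if params.pcr_error_rate > 0.0 and new_umis.size:
            mask = rng.random(new_umis.shape) < params.pcr_error_rate
            k = int(mask.sum())
            if k:
                new_umis[mask] = (new_umis[mask] + rng.integers(1, 4, size=k)) % 4
        ancestors = np.concatenate([ancestors, ancestors[dup]])
        umis = np.vstack([umis, new_umis])
        if lifetime:
            p = np.concatenate([p, rng.uniform(params.min_amp_prob, 1.0, size=int(dup.sum()))])
    return Pool(ancestors, umis, np.ones(len(ancestors), dtype=np.int64))


# ---------------------------------------------------------------------------
# trials and experiments


def run_trial(params: SimParams, trial_seed) -> TrialResult:
    """One full trial: amplify, sequence, and score both estimators."""
    rng = np.random.default_rng(trial_seed)
    if params.engine == "per-molecule" or params.amp_prob_mode == "per-lifetime":
        pool = _run_trial_per_molecule(params, rng)
    else:
        pool = init_pool(params, rng)
        for _ in range(params.n_cycles):
            pcr_cycle(pool, params.min_amp_prob, params.pcr_error_rate, params.umi_length, rng)
    pool_size = pool.size
    ancestors, umis = sequence_pool(pool, params.seq_depth, params.seq_error_rate, rng)

    truth = len(np.unique(ancestors))
    counts: dict[bytes, int] = {}
    for row in umis:
        key = row.tobytes()
        counts[key] = counts.get(key, 0) + 1
    est_uncorrected = len(counts)
    est_corrected = count_unique(
        {k.decode("latin1"): v for k, v in counts.items()}, correct_errors=True
    )
    d = params.seq_depth
    return TrialResult(
        pool_size=pool_size,
        truth=truth,
        est_uncorrected=est_uncorrected,
        est_corrected=est_corrected,
        dup_frac_truth=(d - truth) / d,
        dup_frac_uncorrected=(d - est_uncorrected) / d,
        dup_frac_corrected=(d - est_corrected) / d,
        rel_err_uncorrected=(est_uncorrected - truth) / truth,
        rel_err_corrected=(est_corrected - truth) / truth,
    )


@dataclass(frozen=True)
class ExperimentSummary:
    """Per-metric mean and SD over an experiment's trials."""

    params: SimParams
    n_trials: int
    n_failed: int
    mean: dict[str, float]
    sd: dict[str, float]
    varied: tuple[str, float] | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for metric in TrialResult.METRICS:
            row = {"metric": metric, "mean": self.mean[metric], "sd": self.sd[metric]}
            if self.varied is not None:
                row["parameter"], row["value"] = self.varied
            rows.append(row)
        return pd.DataFrame(rows)


def trial_seeds(params: SimParams) -> list[np.random.SeedSequence]:
    """Deterministic independent per-trial seeds spawned from the master seed."""
    return np.random.SeedSequence(params.seed).spawn(params.n_trials)


def run_experiment(
    params: SimParams, varied: tuple[str, float] | None = None
) -> ExperimentSummary:
    """Run n_trials independent trials and summarise every trial metric."""
    results: list[TrialResult] = []
    n_failed = 0
    for ss in trial_seeds(params):
        try:
            results.append(run_trial(params, ss))
        except TrialError:
            n_failed += 1
    if not results:
        raise TrialError("every trial failed (seq_depth exceeds all pool sizes?)")
    arr = {
        m: np.array([getattr(r, m) for r in results], dtype=float)
        for m in TrialResult.METRICS
    }
    return ExperimentSummary(
        params=params,
        n_trials=len(results),
        n_failed=n_failed,
        mean={m: float(v.mean()) for m, v in arr.items()},
        sd={m: float(v.std(ddof=1)) if len(v) > 1 else 0.0 for m, v in arr.items()},
        varied=varied,
    )


def run_sweep(
    base: SimParams, parameter: str, grid: Sequence[float]
) -> list[ExperimentSummary]:
    """Vary one parameter over a grid, holding the other six at ``base``.

    Each grid point gets its own full experiment (same master seed, so a
    sweep is reproducible end to end).  A value whose trials all fail —
    e.g. a sequencing depth no pool can reach — is skipped with its slot
    omitted from the output.
    """
    if parameter not in SWEEPABLE:
        raise ValueError(f"unknown sweep parameter {parameter!r}; choose from {SWEEPABLE}")
    caster = int if isinstance(getattr(base, parameter), int) else float
    out: list[ExperimentSummary] = []
    for value in grid:
        params = replace(base, **{parameter: caster(value)})
        try:
            out.append(run_experiment(params, varied=(parameter, float(value))))
        except TrialError:
            continue
    return out


def sweep_frame(summaries: Sequence[ExperimentSummary]) -> pd.DataFrame:
    """Stack sweep summaries into one tidy table (one row per value x metric)."""
    if not summaries:
        return pd.DataFrame(columns=["parameter", "value", "metric", "mean", "sd"])
    return pd.concat([s.to_frame() for s in summaries], ignore_index=True)
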
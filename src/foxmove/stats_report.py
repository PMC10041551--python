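"""Permutation t-tests and cohort summary helpers.

Group comparisons use two-sided permutation tests on the t statistic
(default 9999 label permutations; exhaustive enumeration is substituted
automatically for small samples, where it is exact). Mixed-model and Cox
fitting are deliberately not implemented here — the pipeline exports
model-ready tables instead.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

DEFAULT_N_PERM = 9999
MAX_EXHAUSTIVE = 20000  # enumerate when the permutation space is this small


@dataclass(frozen=True)
class PermutationResult:
    t_observed: float
    n_perm: int
    p_two_sided: float
    seed: int | None
    exhaustive: bool
    paired: bool


def _finish_t(diff: float, denom: float) -> float:
    # zero spread with a real mean difference is infinitely extreme, not NaN
    if denom == 0:
        return math.nan if diff == 0 else math.copysign(math.inf, diff)
    return diff / denom


def _welch_t(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    return _finish_t(float(a.mean() - b.mean()), math.sqrt(va / na + vb / nb))


def _pooled_t(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return _finish_t(float(a.mean() - b.mean()), math.sqrt(sp2 * (1.0 / na + 1.0 / nb)))


def _paired_t(d: np.ndarray) -> float:
    return _finish_t(float(d.mean()), d.std(ddof=1) / math.sqrt(len(d)))


def permutation_t_test(
    group_a,
    group_b,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    paired: bool = False,
    statistic: str = "welch",
) -> PermutationResult:
    """Two-sided permutation test on the two-sample t statistic.

    Unpaired: group labels are permuted; paired: pair differences have their
    signs flipped. When the full permutation space is small (always the case
    for total n <= 10) it is enumerated exhaustively and the p-value is
    exact, p = #{|t*| >= |t_obs|} / n_all; otherwise n_perm random draws give
    p = (1 + #{|t*| >= |t_obs|}) / (n_perm + 1). If both groups have zero
    variance the statistic is undefined and returned as NaN with p = NaN.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    tfun = {"welch": _welch_t, "pooled": _pooled_t}[statistic]

    if paired:
        if len(a) != len(b):
            raise ValueError("paired test needs equal-length groups")
        if len(a) < 2:
            raise ValueError("need at least 2 pairs")
        d = a - b
        t_obs = _paired_t(d)
        if math.isnan(t_obs):
            return PermutationResult(math.nan, 0, math.nan, seed, False, True)
        n = len(d)
        if 2**n <= MAX_EXHAUSTIVE:
            stats = [
                _paired_t(d * np.array(signs))
                for signs in itertools.product((1.0, -1.0), repeat=n)
            ]
            count = sum(1 for t in stats if _ge(abs(t), abs(t_obs)))
            return PermutationResult(t_obs, len(stats), count / len(stats), seed, True, True)
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            signs = rng.choice((1.0, -1.0), size=n)
            if _ge(abs(_paired_t(d * signs)), abs(t_obs)):
                count += 1
        return PermutationResult(
            t_obs, n_perm, (1 + count) / (n_perm + 1), seed, False, True
        )

    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    t_obs = tfun(a, b)
    if math.isnan(t_obs):
        return PermutationResult(math.nan, 0, math.nan, seed, False, False)

    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)
    if math.comb(n, na) <= MAX_EXHAUSTIVE:
        idx = set(range(n))
        count, total = 0, 0
        for combo in itertools.combinations(range(n), na):
            sel = np.array(combo)
            rest = np.array(sorted(idx - set(combo)))
            t = tfun(pooled[sel], pooled[rest])
            if _ge(abs(t), abs(t_obs)):
                count += 1
            total += 1
        return PermutationResult(t_obs, total, count / total, seed, True, False)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        t = tfun(pooled[perm[:na]], pooled[perm[na:]])
        if _ge(abs(t), abs(t_obs)):
            count += 1
    return PermutationResult(t_obs, n_perm, (1 + count) / (n_perm + 1), seed, False, False)


def _ge(x: float, y: float, rel: float = 1e-12) -> bool:
    # tolerate float jitter when a permuted statistic equals the observed one
    if math.isnan(x) or math.isinf(x):
        return True  # degenerate or infinitely extreme permutation
    if math.isinf(y):
        return False
    return x >= y - rel * max(abs(x), abs(y), 1.0)
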
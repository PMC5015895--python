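"""Exact validation statistics for biallelic genotype panels.

Implements the Genepop-style battery used to validate SNP discoveries:

* allele and genotype frequencies per breed per locus;
* the exact Hardy–Weinberg *probability test* — the p-value is the total
  conditional probability, given the allele counts, of all genotype arrays no
  more probable than the observed one — by full enumeration or by a
  genotype-switching Markov chain with a Monte-Carlo standard error;
* exact genic (allele-count) and genotypic (genotype-count) differentiation
  tests across breeds on the breeds x categories contingency table with fixed
  margins, by enumeration or a Metropolis chain over tables;
* Fisher's combined probability test aggregating per-locus p-values.

Conditional on allele counts ``n_A`` and ``n_B`` in ``n`` diploids, a genotype
array ``(n_AA, n_AB, n_BB)`` has probability

    P = n! / (n_AA! n_AB! n_BB!) * 2**n_AB * n_A! n_B! / (2n)!

and a contingency table with fixed margins has the multivariate
hypergeometric probability

    P = prod_i(r_i!) prod_j(c_j!) / (N! prod_ij(n_ij!)).

All probability arithmetic is done with log-factorials; tie comparison uses a
relative tolerance of 1e-12 so numerically equal tables are never
misclassified.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

from .model import GenotypeMatrix

TIE_REL_TOL = 1e-12


def _tie_threshold(log_p_obs: float) -> float:
    return log_p_obs + TIE_REL_TOL * max(1.0, abs(log_p_obs))


@dataclass(frozen=True)
class ChainSettings:
    """Markov-chain schedule (Genepop-like defaults)."""

    dememorization: int = 1000
    batches: int = 20
    iterations_per_batch: int = 5000

    def __post_init__(self) -> None:
        if min(self.dememorization, self.batches, self.iterations_per_batch) < 1:
            raise ValueError("chain settings must be positive")


DEFAULT_CHAIN = ChainSettings()


@dataclass(frozen=True)
class ExactTestResult:
    p_value: float
    method: str                      # 'enumeration' or 'markov_chain'
    mc_std_error: float = 0.0
    chain: ChainSettings | None = None
    monomorphic: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 + 1e-12):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class CombinedTestResult:
    chi_square: float
    df: int
    p_value: float
    n_floored: int = 0


# --------------------------------------------------------------------------
# allele / genotype frequencies

def allele_frequencies(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Frequency of the normal (A) allele per locus (rows) per breed (columns).

    Missing genotypes are excluded from denominators; a locus with no scored
    genotypes in a breed gets NaN (undefined, flagged by absence).
    """
    data: dict[str, list[float]] = {}
    for breed in matrix.breed_labels:
        col = []
        for locus in matrix.loci:
            n_aa, n_ab, n_bb = matrix.genotype_counts(locus, breed)
            total = 2 * (n_aa + n_ab + n_bb)
            col.append((2 * n_aa + n_ab) / total if total else math.nan)
        data[breed] = col
    return pd.DataFrame(data, index=pd.Index(matrix.loci, name="locus"))


def locus_allele_counts(matrix: GenotypeMatrix, locus: str) -> dict[str, tuple[int, int]]:
    """(n_A, n_B) per breed at *locus*, complete cases only."""
    out = {}
    for breed in matrix.breed_labels:
        n_aa, n_ab, n_bb = matrix.genotype_counts(locus, breed)
        out[breed] = (2 * n_aa + n_ab, 2 * n_bb + n_ab)
    return out


# --------------------------------------------------------------------------
# Hardy-Weinberg exact probability test

def _log_array_prob(n_aa: int, n_ab: int, n_bb: int) -> float:
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    return (
        gammaln(n + 1) - gammaln(n_aa + 1) - gammaln(n_ab + 1) - gammaln(n_bb + 1)
        + n_ab * math.log(2)
        + gammaln(n_a + 1) + gammaln(n_b + 1) - gammaln(2 * n + 1)
    )


def _feasible_heterozygote_counts(n: int, n_a: int) -> range:
    """All n_AB compatible with *n* diploids carrying *n_a* copies of A."""
    n_b = 2 * n - n_a
    hi = min(n_a, n_b)
    return range(hi % 2, hi + 1, 2)


def hwe_exact(
    counts: tuple[int, int, int],
    method: str = "auto",
    chain: ChainSettings = DEFAULT_CHAIN,
    seed: int = 0,
) -> ExactTestResult:
    """Exact HWE probability test for one breed's genotype counts.

    ``method`` is ``"enum"`` (full enumeration over heterozygote counts),
    ``"mc"`` (genotype-switching Markov chain with batch standard error), or
    ``"auto"`` (enumeration — always feasible for biallelic data).
    A monomorphic sample returns p = 1 with the ``monomorphic`` flag.
    """
    n_aa, n_ab, n_bb = counts
    if min(counts) < 0 or sum(counts) < 1:
        raise ValueError(f"invalid genotype counts {counts}")
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    if n_a == 0 or n_a == 2 * n:
        return ExactTestResult(p_value=1.0, method="enumeration", monomorphic=True)
    if method in ("auto", "enum"):
        return _hwe_enumerate(n, n_a, n_ab)
    if method == "mc":
        return _hwe_markov_chain(counts, chain, seed)
    raise ValueError(f"unknown method {method!r}")


def _hwe_enumerate(n: int, n_a: int, n_ab_obs: int) -> ExactTestResult:
    log_p_obs = _log_array_prob((n_a - n_ab_obs) // 2, n_ab_obs,
                                (2 * n - n_a - n_ab_obs) // 2)
    thr = _tie_threshold(log_p_obs)
    total = 0.0
    for n_ab in _feasible_heterozygote_counts(n, n_a):
        lp = _log_array_prob((n_a - n_ab) // 2, n_ab, (2 * n - n_a - n_ab) // 2)
        if lp <= thr:
            total += math.exp(lp)
    return ExactTestResult(p_value=min(total, 1.0), method="enumeration")


def _hwe_markov_chain(counts: tuple[int, int, int], chain: ChainSettings,
                      seed: int) -> ExactTestResult:
    """Genotype-switching chain: AA+BB <-> AB+AB moves with Metropolis odds.

    The state space is one-dimensional (the heterozygote count), so the
    tail-membership indicator is precomputed for every feasible state and each
    step is O(1).
    """
    n_aa, n_ab, n_bb = counts
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    thr = _tie_threshold(_log_array_prob(n_aa, n_ab, n_bb))
    hit = {
        ab: _log_array_prob((n_a - ab) // 2, ab, (2 * n - n_a - ab) // 2) <= thr
        for ab in _feasible_heterozygote_counts(n, n_a)
    }
    rng = np.random.default_rng(seed)

    ab = n_ab
    total_steps = chain.dememorization + chain.batches * chain.iterations_per_batch
    coin = rng.random(total_steps)
    accept = rng.random(total_steps)

    def step(t: int, ab: int) -> int:
        aa = (n_a - ab) // 2
        bb = (2 * n - n_a - ab) // 2
        if coin[t] < 0.5:                # AA + BB -> AB + AB
            if aa >= 1 and bb >= 1 and \
                    accept[t] * (ab + 2) * (ab + 1) < 4.0 * aa * bb:
                return ab + 2
        else:                            # AB + AB -> AA + BB
            if ab >= 2 and accept[t] * 4.0 * (aa + 1) * (bb + 1) < ab * (ab - 1):
                return ab - 2
        return ab

    t = 0
    for _ in range(chain.dememorization):
        ab = step(t, ab)
        t += 1
    batch_means = []
    for _ in range(chain.batches):
        hits = 0
        for _ in range(chain.iterations_per_batch):
            ab = step(t, ab)
            t += 1
            if hit[ab]:
                hits += 1
        batch_means.append(hits / chain.iterations_per_batch)
    p = float(np.mean(batch_means))
    se = float(np.std(batch_means, ddof=1) / math.sqrt(chain.batches))
    return ExactTestResult(p_value=p, method="markov_chain", mc_std_error=se,
                           chain=chain)


# --------------------------------------------------------------------------
# exact contingency-table differentiation tests

def _log_table_prob(table: np.ndarray) -> float:
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = table.sum()
    return float(
        gammaln(rows + 1).sum() + gammaln(cols + 1).sum()
        - gammaln(n + 1) - gammaln(table + 1).sum()
    )


def _enumerate_tables(rows: np.ndarray, cols: np.ndarray):
    """Yield every non-negative integer table with the given margins."""
    r, c = len(rows), len(cols)

    def fill(i: int, remaining_cols: np.ndarray, acc: list[list[int]]):
        if i == r - 1:
            yield acc + [list(remaining_cols)]
            return
        target = rows[i]
        ranges = [range(min(target, remaining_cols[j]) + 1) for j in range(c - 1)]
        for head in itertools.product(*ranges):
            s = sum(head)
            if s > target:
                continue
            last = target - s
            if last > remaining_cols[c - 1]:
                continue
            row = list(head) + [last]
            yield from fill(i + 1, remaining_cols - np.array(row), acc + [row])

    yield from fill(0, cols.copy(), [])


def exact_table_test(
    table: np.ndarray,
    method: str = "auto",
    chain: ChainSettings = DEFAULT_CHAIN,
    seed: int = 0,
    max_enum_tables: int = 2_000_000,
) -> ExactTestResult:
    """Exact probability test on a contingency table with fixed margins.

    p = total probability (multivariate hypergeometric) of tables no more
    probable than the observed one.  Enumeration for small tables; otherwise a
    Metropolis chain over +/-1 moves on 2x2 subtables (Raymond–Rousset style)
    with a batch-based standard error.
    """
    table = np.asarray(table, dtype=np.int64)
    if table.ndim != 2 or (table < 0).any():
        raise ValueError("need a non-negative 2-D table")
    # drop all-zero rows/columns: breeds with no observations, unseen categories
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return ExactTestResult(p_value=1.0, method="enumeration", monomorphic=True)
    if method == "auto":
        method = "enum" if _enum_size_bound(table) <= max_enum_tables else "mc"
    if method == "enum":
        return _table_enumerate(table)
    if method == "mc":
        return _table_markov_chain(table, chain, seed)
    raise ValueError(f"unknown method {method!r}")


def _enum_size_bound(table: np.ndarray) -> float:
    rows = table.sum(axis=1)
    c = table.shape[1]
    bound = 1.0
    for ri in rows[:-1]:
        bound *= math.comb(int(ri) + c - 1, c - 1)
        if bound > 1e12:
            return bound
    return bound


def _table_enumerate(table: np.ndarray) -> ExactTestResult:
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    log_p_obs = _log_table_prob(table)
    thr = _tie_threshold(log_p_obs)
    total = 0.0
    for cand in _enumerate_tables(rows, cols):
        lp = _log_table_prob(np.array(cand, dtype=np.int64))
        if lp <= thr:
            total += math.exp(lp)
    return ExactTestResult(p_value=min(total, 1.0), method="enumeration")


def _table_markov_chain(table: np.ndarray, chain: ChainSettings,
                        seed: int) -> ExactTestResult:
    log_p_obs = _log_table_prob(table)
    thr = _tie_threshold(log_p_obs)
    rng = np.random.default_rng(seed)
    state = table.copy()
    r, c = state.shape
    state_lp = _log_table_prob(state)
    lgamma = math.lgamma

    def step() -> None:
        nonlocal state_lp
        i, j = rng.choice(r, size=2, replace=False)
        k, l = rng.choice(c, size=2, replace=False)
        a, b_, cc, dd = state[i, k], state[i, l], state[j, k], state[j, l]
        if b_ == 0 or cc == 0:
            return
        ratio = (b_ * cc) / ((a + 1) * (dd + 1))
        if rng.random() < min(1.0, ratio):
            # margins are fixed, so only the four cell factorials change
            state_lp += (
                lgamma(a + 1) - lgamma(a + 2) + lgamma(dd + 1) - lgamma(dd + 2)
                + lgamma(b_ + 1) - lgamma(b_) + lgamma(cc + 1) - lgamma(cc)
            )
            state[i, k] += 1
            state[j, l] += 1
            state[i, l] -= 1
            state[j, k] -= 1

    for _ in range(chain.dememorization):
        step()
    batch_means = []
    for _ in range(chain.batches):
        hits = 0
        for _ in range(chain.iterations_per_batch):
            step()
            if state_lp <= thr:
                hits += 1
        batch_means.append(hits / chain.iterations_per_batch)
    p = float(np.mean(batch_means))
    se = float(np.std(batch_means, ddof=1) / math.sqrt(chain.batches))
    return ExactTestResult(p_value=p, method="markov_chain", mc_std_error=se,
                           chain=chain)


def genic_differentiation(
    matrix: GenotypeMatrix,
    locus: str,
    method: str = "auto",
    chain: ChainSettings = DEFAULT_CHAIN,
    seed: int = 0,
) -> ExactTestResult:
    """Exact test of allele-frequency homogeneity across breeds at *locus*."""
    counts = locus_allele_counts(matrix, locus)
    rows = []
    for breed, (n_a, n_b) in counts.items():
        if n_a + n_b == 0:
            warnings.warn(f"breed {breed!r} has no scored genotypes at {locus}; dropped")
            continue
        rows.append([n_a, n_b])
    if len(rows) < 2:
        raise ValueError(f"need >= 2 breeds with data at {locus}")
    return exact_table_test(np.array(rows), method=method, chain=chain, seed=seed)


def genotypic_differentiation(
    matrix: GenotypeMatrix,
    locus: str,
    method: str = "auto",
    chain: ChainSettings = DEFAULT_CHAIN,
    seed: int = 0,
) -> ExactTestResult:
    """Exact test of genotype-distribution homogeneity across breeds at *locus*."""
    rows = []
    for breed in matrix.breed_labels:
        n_aa, n_ab, n_bb = matrix.genotype_counts(locus, breed)
        if n_aa + n_ab + n_bb == 0:
            warnings.warn(f"breed {breed!r} has no scored genotypes at {locus}; dropped")
            continue
        rows.append([n_aa, n_ab, n_bb])
    if len(rows) < 2:
        raise ValueError(f"need >= 2 breeds with data at {locus}")
    return exact_table_test(np.array(rows), method=method, chain=chain, seed=seed)


# --------------------------------------------------------------------------
# Fisher's combined probability test

def fisher_combined(p_values: list[float], floor: float = 1e-16) -> CombinedTestResult:
    """Aggregate per-locus p-values: chi2 = -2 sum ln(p) against df = 2L.

    Zeros (impossible for exact tests, possible after rounding) are floored at
    *floor* with a warning so the statistic stays finite.
    """
    if not p_values:
        raise ValueError("need at least one p-value")
    floored = 0
    clean = []
    for p in p_values:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value {p} outside [0, 1]")
        if p < floor:
            floored += 1
            p = floor
        clean.append(p)
    if floored:
        warnings.warn(f"{floored} p-value(s) below {floor} floored")
    stat = -2.0 * sum(math.log(p) for p in clean)
    df = 2 * len(clean)
    return CombinedTestResult(chi_square=stat, df=df,
                              p_value=float(chi2.sf(stat, df)), n_floored=floored)
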
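"""Quenched Markov charge sequences and their exact ensemble statistics.

A statistically neutral polyampholyte is modelled as a chain of N monomers of
which a fraction f are ionic (charge +1 or -1, in units of e); the ionic sites
are spaced equidistantly along the backbone.  The sign sequence is a quenched
realization of a stationary two-state first-order Markov chain whose
conditional probabilities are symmetric, p(+|+) = p(-|-) = (1 + lam)/2, so the
ensemble-average net charge is zero for every correlation parameter lam in
[-1, 1].  lam is the second eigenvalue of the transition matrix: lam = -1
gives a strictly alternating sequence, lam = 0 independent random signs, and
lam -> 1 single-sign chains (a stoichiometric mixture of polyanions and
polycations).

The key derived quantity is the blockiness Lambda = (1 + lam)/(1 - lam): the
mean net charge of a run of consecutive like charges is 1 + Lambda, a chain
carries about f*N/(1 + Lambda) charge blocks, and the characteristic global
charge of a single realization is sqrt(f*N*Lambda).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional

import numpy as np

__all__ = [
    "MarkovSequenceSpec",
    "ChargeSequence",
    "BlockDecomposition",
    "SequenceStatistics",
    "LambdaEstimate",
    "transition_probabilities",
    "blockiness",
    "generate_sequence",
    "decompose_blocks",
    "net_charge_variance",
    "net_charge_moments",
    "characteristic_charge",
    "sequence_statistics",
    "estimate_lambda",
    "conditioned_ensemble",
]


class DegenerateSequenceWarning(UserWarning):
    """Emitted for single-sign (lam = 1) chains and single-block estimates."""


def _validate_lambda(lam: float, *, allow_one: bool = False) -> float:
    lam = float(lam)
    hi_ok = lam <= 1.0 if allow_one else lam < 1.0
    if not (-1.0 <= lam and hi_ok):
        hi = "1" if allow_one else "1 (exclusive)"
        raise ValueError(f"correlation parameter lam must lie in [-1, {hi}]; got {lam}")
    return lam


@dataclass(frozen=True)
class MarkovSequenceSpec:
    """Parameters of one quenched Markov charge sequence.

    N    -- chain length in monomers.
    f    -- ionic fraction in (0, 1]; N*f must be an integer.
    lam  -- Markov correlation parameter, -1 <= lam <= 1.
    seed -- RNG seed making the realization reproducible.
    """

    N: int
    f: float = 1.0
    lam: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError(f"N must be a positive integer; got {self.N}")
        if not (0.0 < self.f <= 1.0):
            raise ValueError(f"ionic fraction f must lie in (0, 1]; got {self.f}")
        _validate_lambda(self.lam, allow_one=True)
        if self.n_ionic < 1:
            raise ValueError("spec describes no ionic monomers (N*f < 1)")

    @property
    def n_ionic(self) -> int:
        """Number of ionic monomers N*f; raises if N*f is not an integer."""
        nf = Fraction(self.f).limit_denominator(10**6) * self.N
        if nf.denominator != 1:
            raise ValueError(f"N*f must be an integer; got N={self.N}, f={self.f}")
        return int(nf)

    def ionic_positions(self) -> np.ndarray:
        """0-based monomer indices of the ionic sites, spaced 1/f apart."""
        k = np.arange(self.n_ionic)
        return np.ceil((k + 0.5) / self.f).astype(int) - 1


@dataclass
class ChargeSequence:
    """Per-monomer charges in {-1, 0, +1} for one chain realization."""

    charges: np.ndarray
    spec: Optional[MarkovSequenceSpec] = None

    def __post_init__(self) -> None:
        self.charges = np.asarray(self.charges, dtype=np.int8)
        if self.charges.ndim != 1:
            raise ValueError("charges must be a 1-D array")
        if not np.isin(self.charges, (-1, 0, 1)).all():
            raise ValueError("charges must take values in {-1, 0, +1}")
        if self.spec is not None:
            if len(self.charges) != self.spec.N:
                raise ValueError("sequence length does not match spec N")
            if int(np.count_nonzero(self.charges)) != self.spec.n_ionic:
                raise ValueError("ionic monomer count does not match spec N*f")

    def __len__(self) -> int:
        return len(self.charges)

    @property
    def net_charge(self) -> int:
        return int(self.charges.sum())

    @property
    def n_ionic(self) -> int:
        return int(np.count_nonzero(self.charges))

    def ionic_signs(self) -> np.ndarray:
        """The +-1 subsequence at ionic sites, in chain order."""
        return self.charges[self.charges != 0].astype(np.int8)


@dataclass
class BlockDecomposition:
    """Run-length encoding of the ionic-sign subsequence."""

    block_lengths: np.ndarray
    block_signs: np.ndarray

    @property
    def n_blocks(self) -> int:
        return len(self.block_lengths)

    @property
    def mean_block_length(self) -> float:
        return float(np.mean(self.block_lengths))


@dataclass(frozen=True)
class SequenceStatistics:
    """Exact Markov-ensemble quantities for given (lam, f, N)."""

    Lambda: float
    mean_block_charge: float
    n_blocks_expected: float
    var_Q: float
    char_Q: float


@dataclass(frozen=True)
class LambdaEstimate:
    lam_hat: float
    se: float
    n_transitions: int
    degenerate: bool = False


def transition_probabilities(lam: float) -> np.ndarray:
    """Conditional sign-transition table of the Markov charge process.

    Returns the 2x2 row-stochastic matrix P with state order (+, -):
    P[j, i] = p(i | j), the probability that the next ionic monomer has sign i
    given the previous one has sign j.  Statistical neutrality requires
    p(+|+) = p(-|-) = (1 + lam)/2, and the second eigenvalue of P equals lam.
    """
    lam = _validate_lambda(lam, allow_one=True)
    p_same = (1.0 + lam) / 2.0
    return np.array([[p_same, 1.0 - p_same], [1.0 - p_same, p_same]])


def blockiness(lam: float) -> float:
    """Block-charge parameter Lambda = (1 + lam)/(1 - lam).

    The mean net charge of a block of consecutive like charges is 1 + Lambda:
    0 for alternating sequences (lam = -1), 1 for ideally random ones
    (lam = 0).  Raises ValueError at lam = 1 where Lambda diverges.
    """
    lam = _validate_lambda(lam, allow_one=True)
    if lam == 1.0:
        raise ValueError(
            "Lambda diverges at lam = 1 (stoichiometric mixture of "
            "polyanions and polycations)"
        )
    return (1.0 + lam) / (1.0 - lam)


def lambda_from_blockiness(Lambda: float) -> float:
    """Inverse of :func:`blockiness`: lam = (Lambda - 1)/(Lambda + 1)."""
    if Lambda < 0:
        raise ValueError("Lambda must be non-negative")
    return (Lambda - 1.0) / (Lambda + 1.0)


def _markov_signs(n: int, lam: float, rng: np.random.Generator) -> np.ndarray:
    """n stationary Markov +-1 signs; vectorized via cumulative sign flips."""
    first = rng.choice((-1, 1))
    if n == 1:
        return np.array([first], dtype=np.int8)
    if lam == 1.0:
        return np.full(n, first, dtype=np.int8)
    p_flip = (1.0 - lam) / 2.0
    flips = rng.random(n - 1) < p_flip
    steps = np.where(flips, -1, 1).astype(np.int8)
    out = np.empty(n, dtype=np.int8)
    out[0] = first
    out[1:] = first * np.cumprod(steps)
    return out


def generate_sequence(spec: MarkovSequenceSpec,
                      rng: Optional[np.random.Generator] = None) -> ChargeSequence:
    """Draw one quenched charge sequence from the Markov ensemble.

    The first ionic sign is drawn from the stationary (1/2, 1/2) distribution;
    each subsequent ionic sign follows :func:`transition_probabilities`.
    Neutral monomers are interleaved deterministically so that ionic sites sit
    at equidistant positions.  Reproducible given ``spec.seed`` (or an
    explicitly supplied generator).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.n_ionic
    if spec.lam == 1.0:
        warnings.warn(
            "lam = 1 is degenerate: the chain carries a single sign",
            DegenerateSequenceWarning,
            stacklevel=2,
        )
    signs = _markov_signs(n, spec.lam, rng)
    charges = np.zeros(spec.N, dtype=np.int8)
    charges[spec.ionic_positions()] = signs
    return ChargeSequence(charges=charges, spec=spec)


def decompose_blocks(seq: ChargeSequence) -> BlockDecomposition:
    """Run-length encode the ionic subsequence into like-charge blocks."""
    signs = seq.ionic_signs()
    if len(signs) == 0:
        raise ValueError("cannot decompose an all-neutral sequence into blocks")
    boundaries = np.flatnonzero(np.diff(signs)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(signs)]))
    return BlockDecomposition(
        block_lengths=(ends - starts).astype(int),
        block_signs=signs[starts].astype(int),
    )


def net_charge_variance(lam: float, f: float, N: int) -> float:
    """Exact finite-N variance of the global charge Q = sum of ionic signs.

    For a stationary symmetric Markov chain of n = N*f signs with correlation
    lam, Cov(s_i, s_j) = lam^|i-j|, hence

        Var(Q) = n (1+lam)/(1-lam) - 2 lam (1 - lam^n) / (1-lam)^2

    which reduces to n at lam = 0 and to (1 - (-1)^n)/2 at lam = -1.
    Asymptotically Var(Q)/(f N) -> Lambda.
    """
    lam = _validate_lambda(lam, allow_one=True)
    n = MarkovSequenceSpec(N=N, f=f, lam=lam).n_ionic
    if lam == 1.0:
        return float(n * n)
    return float(n * (1.0 + lam) / (1.0 - lam)
                 - 2.0 * lam * (1.0 - lam**n) / (1.0 - lam) ** 2)


# Spec-facing alias: the first two moments are (0, Var) by neutrality.
net_charge_moments = net_charge_variance


def characteristic_charge(lam: float, f: float, N: int) -> float:
    """Characteristic global charge sqrt(f N Lambda) of a single realization.

    Grows from 0 for alternating sequences (Lambda = 0) through sqrt(f N) for
    ideally random ones to ~ f N when the block length reaches the chain
    length (Lambda ~ f N).
    """
    return math.sqrt(f * N * blockiness(lam))


def sequence_statistics(lam: float, f: float, N: int) -> SequenceStatistics:
    """Bundle the exact ensemble quantities for (lam, f, N)."""
    Lam = blockiness(lam)
    return SequenceStatistics(
        Lambda=Lam,
        mean_block_charge=1.0 + Lam,
        n_blocks_expected=f * N / (1.0 + Lam),
        var_Q=net_charge_variance(lam, f, N),
        char_Q=characteristic_charge(lam, f, N),
    )


def estimate_lambda(seq: ChargeSequence) -> LambdaEstimate:
    """Maximum-likelihood lam from ionic-subsequence transition counts.

    lam_hat = (n_same - n_diff)/(n_same + n_diff); the standard error follows
    from the binomial variance of the same-sign transition frequency.  A
    single-block sequence gives lam_hat = 1 with a degenerate-estimate flag.
    """
    signs = seq.ionic_signs()
    if len(signs) < 2:
        raise ValueError("need at least 2 ionic monomers to estimate lam")
    same = signs[1:] == signs[:-1]
    n = len(same)
    n_same = int(same.sum())
    lam_hat = (2.0 * n_same - n) / n
    p_hat = n_same / n
    se = 2.0 * math.sqrt(max(p_hat * (1.0 - p_hat), 0.0) / n)
    degenerate = n_same == n
    if degenerate:
        warnings.warn(
            "sequence is a single like-charge block; lam_hat = 1 is degenerate",
            DegenerateSequenceWarning,
            stacklevel=2,
        )
    return LambdaEstimate(lam_hat=lam_hat, se=se, n_transitions=n,
                          degenerate=degenerate)


def conditioned_ensemble(
    spec: MarkovSequenceSpec,
    Q_target: int,
    n_chains: int,
    *,
    acceptance_floor: float = 1e-6,
    rng: Optional[np.random.Generator] = None,
    batch: int = 1024,
) -> tuple[list[ChargeSequence], float]:
    """Rejection-sample n_chains sequences with net charge exactly Q_target.

    Plain rejection from the unconditioned Markov ensemble keeps the quenched
    measure exactly the conditional one.  Returns (sequences, acceptance
    rate).  Raises if the running acceptance rate falls below
    ``acceptance_floor`` (check |Q_target| <= N*f and parity: Q and N*f must
    have equal parity).
    """
    n = spec.n_ionic
    if abs(Q_target) > n:
        raise ValueError(f"|Q_target| = {abs(Q_target)} exceeds N*f = {n}")
    if (Q_target - n) % 2 != 0:
        raise ValueError(
            f"Q_target = {Q_target} and N*f = {n} have different parity; "
            "the net charge of a fully ionic block count is infeasible"
        )
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    accepted: list[ChargeSequence] = []
    attempts = 0
    positions = spec.ionic_positions()
    p_flip = (1.0 - spec.lam) / 2.0
    while len(accepted) < n_chains:
        firsts = rng.choice((-1, 1), size=batch).astype(np.int8)
        if spec.lam == 1.0:
            signs = np.repeat(firsts[:, None], n, axis=1)
        else:
            flips = rng.random((batch, n - 1)) < p_flip
            steps = np.where(flips, -1, 1).astype(np.int8)
            signs = np.empty((batch, n), dtype=np.int8)
            signs[:, 0] = firsts
            signs[:, 1:] = firsts[:, None] * np.cumprod(steps, axis=1)
        attempts += batch
        hits = np.flatnonzero(signs.sum(axis=1, dtype=np.int64) == Q_target)
        for idx in hits:
            if len(accepted) >= n_chains:
                break
            charges = np.zeros(spec.N, dtype=np.int8)
            charges[positions] = signs[idx]
            accepted.append(ChargeSequence(charges=charges, spec=spec))
        if attempts >= max(batch * 16, n_chains / acceptance_floor):
            rate = len(accepted) / attempts
            if rate < acceptance_floor:
                raise RuntimeError(
                    f"acceptance rate {rate:.2e} below floor "
                    f"{acceptance_floor:.0e}; check feasibility/parity of "
                    f"Q_target = {Q_target} for N*f = {n}, lam = {spec.lam}"
                )
    return accepted, len(accepted) / attempts
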
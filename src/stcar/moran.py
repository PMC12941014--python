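"""Global Moran's I and its permutation test on areal lattices.

Moran's I measures spatial autocorrelation of per-tract values (here,
visit rates ``Y_i / P_i``):

    I = (N / S0) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2

with ``S0 = sum_ij w_ij``.  Under the randomization null its expectation is
``-1/(N-1)``; inference uses a one-sided ("greater") permutation test with
the conservative ``(1 + #{I_perm >= I_obs}) / (1 + n_perm)`` p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lattice import TractLattice

__all__ = ["MoranResult", "morans_i", "moran_test", "expected_i"]


@dataclass(frozen=True)
class MoranResult:
    I: float
    expected_I: float
    p_value: float
    n_perm: int
    weight_scheme: str

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p_value must be in (0, 1]")


def expected_i(n: int) -> float:
    """Null expectation ``-1/(N-1)`` for ``N`` regions."""
    if n < 2:
        raise ValueError("need at least two regions")
    return -1.0 / (n - 1)


def _weights(lattice: TractLattice, scheme: str,
             allow_zero_rows: bool = False) -> np.ndarray:
    W = lattice.adjacency_matrix()
    if scheme == "binary":
        return W
    if scheme == "row-standardized":
        rows = W.sum(axis=1)
        if (rows == 0).any() and not allow_zero_rows:
            bad = [lattice.tract_ids[i] for i in np.where(rows == 0)[0]]
            raise ValueError(
                f"isolated tracts {bad} under row-standardized weights; "
                "pass allow_zero_rows=True to keep their rows at zero"
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            W = np.where(rows[:, None] > 0, W / rows[:, None], 0.0)
        return W
    raise ValueError("scheme must be 'binary' or 'row-standardized'")


def morans_i(
    values: np.ndarray,
    lattice: TractLattice,
    scheme: str = "binary",
    allow_zero_rows: bool = False,
) -> float:
    """Moran's I for per-tract values under the chosen weight scheme."""
    x = np.asarray(values, dtype=float)
    if x.shape != (lattice.n,):
        raise ValueError("values must have one entry per tract")
    if lattice.n < 2:
        raise ValueError("need at least two tracts")
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0.0:
        raise ValueError("Moran's I undefined: values have zero variance")
    W = _weights(lattice, scheme, allow_zero_rows)
    S0 = W.sum()
    if S0 == 0:
        raise ValueError("lattice has no edges")
    return float(lattice.n / S0 * (xc @ W @ xc) / denom)


def moran_test(
    values: np.ndarray,
    lattice: TractLattice,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
    scheme: str = "binary",
    allow_zero_rows: bool = False,
) -> MoranResult:
    """One-sided (positive-autocorrelation) permutation test for Moran's I.

    The observed statistic is compared against ``n_perm`` random relabelings
    of the values over the tracts; ties count toward the numerator.
    Deterministic given the seed.
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = np.asarray(values, dtype=float)
    obs = morans_i(x, lattice, scheme, allow_zero_rows)
    W = _weights(lattice, scheme, allow_zero_rows)
    S0 = W.sum()
    xc = x - x.mean()
    denom = float(xc @ xc)
    n_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(xc)
        stat = lattice.n / S0 * (perm @ W @ perm) / denom
        if stat >= obs - 1e-15:
            n_ge += 1
    p = (1 + n_ge) / (1 + n_perm)
    return MoranResult(
        I=obs, expected_I=expected_i(lattice.n), p_value=p,
        n_perm=n_perm, weight_scheme=scheme,
    )
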
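"""Trial-data generation for the MBFD under a random-intercept model.

The outcome of participant ``i`` in period ``j`` is generated from the
multi-arm parameterization

    Y_ij = u + beta_t * j + beta_a * Z_Aij + beta_b * Z_Bij + beta_c * Z_Cij
           + alpha_i + eps_ij,

where Z_A, Z_B, Z_C are mutually exclusive indicators for the A-only, B-only
and combined (AB) phases, ``alpha_i ~ N(0, tau^2)`` is a participant-level
random intercept drawn once per participant, and ``eps_ij ~ N(0, sigma^2)``
are independent residuals. The within-participant intraclass correlation is
``icc = tau^2 / (tau^2 + sigma^2)`` (compound symmetry).

The additive and interaction parameterizations used by the analysis models
are linked through the identity ``beta_c = beta_a + beta_b + beta_i``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import Allocation, Condition, Design

__all__ = [
    "EffectParameters",
    "VarianceComponents",
    "icc_to_tau",
    "simulate_trial",
    "TRIAL_COLUMNS",
    "validate_trial_data",
]

#: mandatory columns of a long-format trial dataset
TRIAL_COLUMNS = (
    "participant",
    "sequence",
    "period",
    "condition",
    "x_a",
    "x_b",
    "z_a",
    "z_b",
    "z_c",
    "y",
)


@dataclass(frozen=True)
class EffectParameters:
    """Fixed-effect coefficients of the data-generating model.

    ``beta_c`` is the effect of the sequentially combined intervention versus
    control; the implied departure from additivity is ``beta_i``.
    """

    u: float = 0.0
    beta_t: float = 1.0
    beta_a: float = 0.0
    beta_b: float = 0.0
    beta_c: float = 0.0

    @property
    def beta_i(self) -> float:
        """Interaction implied by the multi-arm coefficients."""
        return self.beta_c - self.beta_a - self.beta_b


@dataclass(frozen=True)
class VarianceComponents:
    """Random-intercept SD ``tau`` and residual SD ``sigma``."""

    tau: float
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def icc(self) -> float:
        return self.tau**2 / (self.tau**2 + self.sigma**2)

    @classmethod
    def from_icc(cls, icc: float, sigma: float = 1.0) -> "VarianceComponents":
        return cls(tau=icc_to_tau(icc, sigma), sigma=sigma)


def icc_to_tau(icc: float, sigma: float = 1.0) -> float:
    """Random-intercept SD achieving a target intraclass correlation.

    Inverts ``icc = tau^2 / (tau^2 + sigma^2)``:
    ``tau = sigma * sqrt(icc / (1 - icc))``.
    """
    if not 0 <= icc < 1:
        raise ValueError(f"icc must be in [0, 1), got {icc}")
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    return sigma * math.sqrt(icc / (1.0 - icc))


_INDICATORS = {
    # condition -> (x_a, x_b, z_a, z_b, z_c)
    Condition.CONTROL: (0, 0, 0, 0, 0),
    Condition.A: (1, 0, 1, 0, 0),
    Condition.B: (0, 1, 0, 1, 0),
    Condition.AB: (1, 1, 0, 0, 1),
}


def simulate_trial(
    design: Design,
    allocation: Allocation,
    effects: EffectParameters,
    var: VarianceComponents,
    seed: int | np.random.SeedSequence | np.random.Generator,
    keep_latent: bool = False,
) -> pd.DataFrame:
    """Generate one long-format trial dataset.

    Each participant contributes one record per period of their sequence
    (periods are 1-based). With ``keep_latent=True`` the latent draws
    ``alpha`` and ``epsilon`` are retained as extra columns for testing.
    """
    if allocation.n_sequences != design.n_sequences:
        raise ValueError("allocation does not match the design")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    seqs = np.asarray(allocation.sequence_of)
    n = len(seqs)
    lengths = np.array([design.sequence_length(int(s)) for s in seqs])
    total = int(lengths.sum())

    participant = np.repeat(np.arange(n), lengths)
    sequence = np.repeat(seqs, lengths)
    period = np.concatenate([np.arange(1, L + 1) for L in lengths])
    conditions = [
        design.condition(int(s), int(j)) for s, j in zip(sequence, period)
    ]
    ind = np.array([_INDICATORS[c] for c in conditions], dtype=np.int8)

    alpha = rng.normal(0.0, var.tau, size=n)
    eps = rng.normal(0.0, var.sigma, size=total)
    mean = (
        effects.u
        + effects.beta_t * period
        + effects.beta_a * ind[:, 2]
        + effects.beta_b * ind[:, 3]
        + effects.beta_c * ind[:, 4]
    )
    y = mean + alpha[participant] + eps

    data = pd.DataFrame(
        {
            "participant": participant,
            "sequence": sequence,
            "period": period,
            "condition": [c.value for c in conditions],
            "x_a": ind[:, 0],
            "x_b": ind[:, 1],
            "z_a": ind[:, 2],
            "z_b": ind[:, 3],
            "z_c": ind[:, 4],
            "y": y,
        }
    )
    if keep_latent:
        data["alpha"] = alpha[participant]
        data["epsilon"] = eps
    return data


def validate_trial_data(data: pd.DataFrame) -> None:
    """Check the long-format trial schema, naming offending columns/rows."""
    missing = [c for c in TRIAL_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"trial data is missing columns: {missing}")
    cond = data["condition"].astype(str)
    bad = ~cond.isin([c.value for c in Condition])
    if bad.any():
        raise ValueError(
            f"unknown condition labels at rows {list(data.index[bad][:5])}"
        )
    expected = np.array([_INDICATORS[Condition(c)] for c in cond])
    actual = data[["x_a", "x_b", "z_a", "z_b", "z_c"]].to_numpy()
    mism = (expected != actual).any(axis=1)
    if mism.any():
        raise ValueError(
            "treatment indicators inconsistent with condition at rows "
            f"{list(data.index[mism][:5])}"
        )
    per_pt = data.groupby("participant")["period"].apply(
        lambda s: (np.sort(s) == np.arange(1, len(s) + 1)).all()
    )
    if not per_pt.all():
        bad_pt = list(per_pt.index[~per_pt][:5])
        raise ValueError(f"participants with non-contiguous periods: {bad_pt}")
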
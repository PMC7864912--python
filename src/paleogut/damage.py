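"""Postmortem-damage model, per-read PMD scoring and positional damage profiles.

Ancient DNA carries cytosine deamination: C->T substitutions concentrated at
the 5' end of a fragment (and, read on the reference forward strand, G->A at
the 3' end), decaying toward the read interior. This module defines the
position-dependent deamination probability ``D(z)``, the per-read postmortem
degradation score (PMDS) -- a log-likelihood ratio of a damage model against
a damage-free null -- and empirical misincorporation profiles of the kind
mapDamage reports.

The same :class:`DamageModelParams` parameterises both the read simulator and
the scorer, so simulated data and scoring assumptions stay in sync.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .alignio import AlignedRead

__all__ = [
    "DamageModelParams",
    "PMDResult",
    "DamageProfile",
    "damage_probability",
    "pmd_score",
    "classify_pmds",
    "estimate_damage_profile",
    "ct5_rate",
]

#: Base-error probabilities below this floor are clamped so a q=inf base
#: cannot produce an infinite log-ratio.
EPSILON_FLOOR = 1e-6


@dataclass(frozen=True)
class DamageModelParams:
    """Parameters of the terminal-deamination probability D(z).

    D(z) = d_max * gamma**z + d_const for a base z positions from the
    relevant fragment end (z = 0 is the terminal base). With ``udg_half``
    (libraries where internal deaminated bases were enzymatically removed,
    leaving damage only in the single-stranded terminal overhangs) positions
    at ``z >= window`` fall back to the residual rate ``d_const``.

    d_max : amplitude of terminal deamination (probability added at z=0).
    gamma : per-base geometric decay of the terminal excess, in (0, 1).
    d_const : residual interior deamination probability.
    udg_half : restrict the terminal excess to ``z < window``.
    window : number of positions from a read end treated as terminal.
    """

    d_max: float = 0.3
    gamma: float = 0.5
    d_const: float = 0.01
    udg_half: bool = False
    window: int = 10

    def __post_init__(self) -> None:
        if not (0.0 <= self.d_const <= self.d_const + self.d_max <= 1.0):
            raise ValueError(
                "require 0 <= d_const <= d_const + d_max <= 1, got "
                f"d_max={self.d_max}, d_const={self.d_const}"
            )
        if not (0.0 < self.gamma < 1.0):
            raise ValueError(f"gamma must be in (0, 1), got {self.gamma}")
        if self.window < 1:
            raise ValueError(f"window must be >= 1, got {self.window}")


@dataclass(frozen=True)
class PMDResult:
    """Per-read PMD score (natural-log likelihood ratio)."""

    read_id: str
    pmds: float
    n_informative: int


@dataclass
class DamageProfile:
    """Positional C->T (5') and G->A (3') misincorporation frequencies.

    Frequencies are mismatch counts divided by the number of reference C
    (resp. G) bases observed at that distance from the read end. Positions
    with a zero denominator are NaN and flagged in ``undefined5``/``undefined3``.
    """

    ct5: np.ndarray
    ga3: np.ndarray
    n_ct5: np.ndarray
    n_refC: np.ndarray
    n_ga3: np.ndarray
    n_refG: np.ndarray
    undefined5: np.ndarray = field(default=None)  # type: ignore[assignment]
    undefined3: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.undefined5 is None:
            self.undefined5 = self.n_refC == 0
        if self.undefined3 is None:
            self.undefined3 = self.n_refG == 0

    @property
    def window(self) -> int:
        return len(self.ct5)


def damage_probability(z: int, params: DamageModelParams) -> float:
    """Deamination probability for a base ``z`` positions from a fragment end.

    Monotone non-increasing in z; with ``udg_half`` the terminal excess is
    zeroed outside the overhang window.
    """
    if z < 0:
        raise ValueError(f"z must be >= 0, got {z}")
    if params.udg_half and z >= params.window:
        return params.d_const
    d = params.d_max * params.gamma**z + params.d_const
    return min(max(d, 0.0), 1.0)


def _column_log_ratio(
    ref_base: str, read_base: str, z: int, epsilon: float, params: DamageModelParams
) -> float | None:
    """ln(P_damage / P_null) for one aligned column, or None if uninformative.

    For a reference C at distance z from the 5' end, the damage model emits
    T with probability D(z)(1-eps) + (1-D(z)) eps/3 and C with probability
    (1-D(z))(1-eps) + D(z) eps/3; the null uses D=0. Reference G columns are
    treated symmetrically using the distance from the 3' end (handled by the
    caller passing the appropriate z). Other ref/read combinations carry no
    damage information.
    """
    eps = max(epsilon, EPSILON_FLOOR)
    d = damage_probability(z, params)
    if ref_base == "C":
        mismatch = read_base == "T"
        match = read_base == "C"
    elif ref_base == "G":
        mismatch = read_base == "A"
        match = read_base == "G"
    else:
        return None
    if mismatch:
        p_d = d * (1.0 - eps) + (1.0 - d) * eps / 3.0
        p_n = eps / 3.0
    elif match:
        p_d = (1.0 - d) * (1.0 - eps) + d * eps / 3.0
        p_n = 1.0 - eps
    else:
        return None
    return math.log(p_d / p_n)


def pmd_score(read: "AlignedRead", params: DamageModelParams | None = None) -> PMDResult:
    """Postmortem degradation score of one aligned read.

    Sums ln(P_damage/P_null) over damage-informative columns: reference C
    scored with D at the 5' distance ``z5``, reference G with D at the 3'
    distance ``z3``. Columns with no informative ref/read pairing contribute
    nothing; a read with no informative column scores exactly 0.
    """
    if params is None:
        params = DamageModelParams()
    total = 0.0
    n_inf = 0
    for col in read.columns:
        if col.ref_base == "C":
            z = col.z5
        elif col.ref_base == "G":
            z = col.z3
        else:
            continue
        lr = _column_log_ratio(col.ref_base, col.read_base, z, col.epsilon, params)
        if lr is None:
            continue
        total += lr
        n_inf += 1
    return PMDResult(read_id=read.read_id, pmds=total if n_inf else 0.0, n_informative=n_inf)


def classify_pmds(
    results: Iterable[PMDResult], threshold: float = 5.0
) -> tuple[list[PMDResult], list[PMDResult]]:
    """Partition reads into (ancient, other) by strict ``pmds > threshold``.

    The conventional threshold of 5 keeps the probability of a modern read
    being called ancient low; threshold 1 selects the weak-damage-support
    set used for per-taxon evidence statistics.
    """
    ancient: list[PMDResult] = []
    other: list[PMDResult] = []
    for r in results:
        (ancient if r.pmds > threshold else other).append(r)
    return ancient, other


def estimate_damage_profile(reads: Iterable["AlignedRead"], window: int = 10) -> DamageProfile:
    """Empirical misincorporation profile over the first ``window`` bases.

    ct5[z] = #(ref C, read T at z5 = z) / #(ref C at z5 = z), and ga3[z]
    likewise for G->A counted from the 3' end. Zero denominators yield NaN
    and are flagged rather than reported as 0.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n_ct = np.zeros(window, dtype=np.int64)
    n_refC = np.zeros(window, dtype=np.int64)
    n_ga = np.zeros(window, dtype=np.int64)
    n_refG = np.zeros(window, dtype=np.int64)
    for read in reads:
        for col in read.columns:
            if col.ref_base == "C" and col.z5 < window:
                n_refC[col.z5] += 1
                if col.read_base == "T":
                    n_ct[col.z5] += 1
            if col.ref_base == "G" and col.z3 < window:
                n_refG[col.z3] += 1
                if col.read_base == "A":
                    n_ga[col.z3] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        ct5 = np.where(n_refC > 0, n_ct / np.maximum(n_refC, 1), np.nan)
        ga3 = np.where(n_refG > 0, n_ga / np.maximum(n_refG, 1), np.nan)
    return DamageProfile(ct5=ct5, ga3=ga3, n_ct5=n_ct, n_refC=n_refC, n_ga3=n_ga, n_refG=n_refG)


def ct5_rate(profile: DamageProfile) -> float:
    """Pooled 5' C->T frequency over the profile window.

    Sum of mismatch counts divided by the sum of reference-C counts across
    positions 0..window-1 (the per-read-end statistic reported alongside
    taxon evidence). NaN if no reference C was observed at all.
    """
    denom = int(profile.n_refC.sum())
    if denom == 0:
        return float("nan")
    return float(profile.n_ct5.sum()) / denom


def profile_to_frame(profile: DamageProfile):
    """Damage profile as a tidy DataFrame (position, ct5, ga3, denominators)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "position": np.arange(profile.window),
            "ct5": profile.ct5,
            "n_refC": profile.n_refC,
            "ga3": profile.ga3,
            "n_refG": profile.n_refG,
        }
    )
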
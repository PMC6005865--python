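"""Group-level resampling statistics.

Paired Monte-Carlo permutation tests based on within-subject sign flips,
a synchronized-rearrangement 2x2 within-subject factorial, the probability
of superiority for dependent samples (PS_dep) as a non-parametric effect
size, and the adaptive two-stage linear step-up FDR procedure of
Benjamini, Krieger & Yekutieli (2006).

All tests use the difference in sample means as the test statistic and the
plain two-sided proportion p = Pr(|T*| >= |T_obs|) over the Monte-Carlo
resamples.  An optional add-one correction ((k+1)/(n+1)) is available to
avoid literal zero p-values in reports; it is off by default so that the
proportion convention is exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

__all__ = [
    "PermutationResult",
    "FactorialResult",
    "paired_permutation_test",
    "ps_dep",
    "factorial_2x2_permutation",
    "fdr_two_stage",
    "sign_flip_pvalues",
]


@dataclass
class PermutationResult:
    """Outcome of a paired two-condition permutation test.

    ``observed_stat`` is mean(x) - mean(y) in the units of the input;
    ``ps_dep`` is Pr(y_i > x_i) over matched pairs (ties count 0.5).
    """

    observed_stat: float
    p_value: float
    n_rearrangements: int
    ps_dep: float
    seed: int | None = None
    null_distribution: np.ndarray = field(default=None, repr=False)

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("null_distribution")
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


@dataclass
class FactorialResult:
    """P-values and observed contrasts of a within-subject 2x2 factorial."""

    p_main_A: float
    p_main_B: float
    p_interaction: float
    observed_A: float
    observed_B: float
    observed_AB: float
    n_rearrangements: int
    seed: int | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _as_paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("NaN values are not allowed in paired inputs")
    return x, y


def ps_dep(x, y) -> float:
    """Probability of superiority for dependent samples, Pr(y_i > x_i).

    Ties contribute 0.5 each, so ps_dep(x, x) == 0.5 and
    ps_dep(x, y) == 1 - ps_dep(y, x).
    """
    x, y = _as_paired(x, y)
    if x.size == 0:
        raise ValueError("empty input")
    return float((np.sum(y > x) + 0.5 * np.sum(y == x)) / x.size)


def _sign_flip_null(d: np.ndarray, n_rearrangements: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Null distribution of the mean of d under random per-pair sign flips."""
    flips = rng.integers(0, 2, size=(n_rearrangements, d.size)) * 2 - 1
    return (flips @ d) / d.size


def _exhaustive_flip_null(d: np.ndarray) -> np.ndarray:
    n = d.size
    if n > 20:
        raise ValueError("exhaustive enumeration limited to n <= 20 pairs")
    signs = np.array(
        [[1 if (i >> j) & 1 else -1 for j in range(n)] for i in range(2 ** n)],
        dtype=float,
    )
    return (signs @ d) / n


def _prop_p(null: np.ndarray, observed: float, add_one: bool) -> float:
    k = int(np.sum(np.abs(null) >= abs(observed)))
    if add_one:
        return (k + 1) / (null.size + 1)
    return k / null.size


def paired_permutation_test(
    x,
    y,
    n_rearrangements: int = 5000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    exhaustive: bool = False,
    add_one: bool = False,
) -> PermutationResult:
    """Paired two-sided Monte-Carlo permutation test.

    The observed statistic is mean(x) - mean(y).  The null distribution is
    built by independently flipping the sign of each subject's difference
    d_i = x_i - y_i (the exchangeable relabelling for paired data); the
    p-value is the proportion of resampled statistics whose absolute value
    is at least the observed one.

    Parameters
    ----------
    exhaustive : enumerate all 2**n sign patterns instead of Monte-Carlo
        sampling (n <= 20); ``n_rearrangements`` is then ignored.
    """
    x, y = _as_paired(x, y)
    if x.size < 2:
        raise ValueError("need at least 2 subject pairs")
    d = x - y
    observed = float(d.mean())
    if exhaustive:
        null = _exhaustive_flip_null(d)
    else:
        if rng is None:
            rng = np.random.default_rng(seed)
        null = _sign_flip_null(d, n_rearrangements, rng)
    return PermutationResult(
        observed_stat=observed,
        p_value=_prop_p(null, observed, add_one),
        n_rearrangements=int(null.size),
        ps_dep=ps_dep(x, y),
        seed=seed,
        null_distribution=null,
    )


def sign_flip_pvalues(
    diffs: np.ndarray,
    n_rearrangements: int = 5000,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    add_one: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized paired sign-flip test over many variables at once.

    ``diffs`` has shape (n_subjects, n_points); each subject's whole row is
    flipped with one sign per rearrangement (a synchronized relabelling, so
    the spatial correlation structure of the null is preserved).

    Returns ``(observed_means, p_values)``, both of length n_points.
    """
    diffs = np.asarray(diffs, dtype=float)
    if diffs.ndim != 2:
        raise ValueError("diffs must be (n_subjects, n_points)")
    n = diffs.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if rng is None:
        rng = np.random.default_rng(seed)
    observed = diffs.mean(axis=0)
    flips = rng.integers(0, 2, size=(n_rearrangements, n)) * 2 - 1
    null = (flips @ diffs) / n  # (n_rearrangements, n_points)
    count = np.sum(np.abs(null) >= np.abs(observed)[None, :], axis=0)
    if add_one:
        p = (count + 1) / (n_rearrangements + 1)
    else:
        p = count / n_rearrangements
    return observed, p


def factorial_2x2_permutation(
    cells: np.ndarray,
    n_rearrangements: int = 5000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    add_one: bool = False,
) -> FactorialResult:
    """Within-subject 2x2 non-parametric factorial via synchronized rearrangements.

    ``cells`` has shape (n_subjects, 2, 2): axis 1 indexes factor A's levels,
    axis 2 factor B's levels, and every subject contributes all four cells.

    Each effect is carried by its orthogonal within-subject contrast

    - A:  (y11 + y12 - y21 - y22) / 2
    - B:  (y11 - y12 + y21 - y22) / 2
    - AB:  y11 - y12 - y21 + y22

    and tested by flipping the contrast's sign per subject (one flip per
    subject per effect, synchronized across that subject's cells).  For a
    balanced within-subject design each contrast is symmetric about zero
    under its own null hypothesis, so the three tests are exact and
    mutually orthogonal.
    """
    cells = np.asarray(cells, dtype=float)
    if cells.ndim != 3 or cells.shape[1:] != (2, 2):
        raise ValueError("cells must have shape (n_subjects, 2, 2)")
    if cells.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    if np.isnan(cells).any():
        raise ValueError("missing cells (NaN) are not allowed")
    if rng is None:
        rng = np.random.default_rng(seed)

    c_a = (cells[:, 0, 0] + cells[:, 0, 1] - cells[:, 1, 0] - cells[:, 1, 1]) / 2
    c_b = (cells[:, 0, 0] - cells[:, 0, 1] + cells[:, 1, 0] - cells[:, 1, 1]) / 2
    c_ab = cells[:, 0, 0] - cells[:, 0, 1] - cells[:, 1, 0] + cells[:, 1, 1]

    stats, ps = [], []
    for c in (c_a, c_b, c_ab):
        observed = float(c.mean())
        null = _sign_flip_null(c, n_rearrangements, rng)
        stats.append(observed)
        ps.append(_prop_p(null, observed, add_one))

    return FactorialResult(
        p_main_A=ps[0],
        p_main_B=ps[1],
        p_interaction=ps[2],
        observed_A=stats[0],
        observed_B=stats[1],
        observed_AB=stats[2],
        n_rearrangements=n_rearrangements,
        seed=seed,
    )


def _bh_stepup(p: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Hochberg linear step-up at level q; returns rejection mask."""
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    crit = q * np.arange(1, m + 1) / m
    below = np.nonzero(sorted_p <= crit)[0]
    mask = np.zeros(m, dtype=bool)
    if below.size:
        mask[order[: below[-1] + 1]] = True
    return mask


def fdr_two_stage(p_values: Sequence[float], q: float = 0.05
                  ) -> tuple[float, np.ndarray]:
    """Adaptive two-stage linear step-up FDR control (BKY 2006, definition 6).

    Stage 1 runs the linear step-up at q' = q/(1+q) and uses the rejection
    count r1 to estimate the number of true nulls m0 = m - r1; stage 2
    reruns the step-up at q'·m/m0.  If stage 1 rejects nothing the
    procedure stops with no rejections; if it rejects everything, all
    hypotheses are rejected.

    Returns ``(p_thr, mask)`` where ``p_thr`` is the corrected threshold
    p-value — the largest rejected p, reported as 0.0 when nothing is
    rejected.
    """
    p = np.asarray(p_values, dtype=float)
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    if p.size == 0 or np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must be in [0, 1]")
    m = p.size
    q1 = q / (1.0 + q)
    stage1 = _bh_stepup(p, q1)
    r1 = int(stage1.sum())
    if r1 == 0:
        return 0.0, np.zeros(m, dtype=bool)
    if r1 == m:
        return float(p.max()), np.ones(m, dtype=bool)
    m0 = m - r1
    mask = _bh_stepup(p, q1 * m / m0)
    p_thr = float(p[mask].max()) if mask.any() else 0.0
    return p_thr, mask
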
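"""Co-transduction statistics for three-colour vector marking.

Cells exposed to a mixture of red, green and blue marker vectors acquire
integrations of each vector independently, with per-vector copy numbers
following Poisson distributions whose means are the per-vector MOIs.
A cell's colour class is the subset of vectors with at least one copy:
single (R, G, B), double (RG, GB, RB) or triple (RGB) positive.  This
module provides the analytic class distribution conditional on a cell
being transduced at all, a Monte-Carlo simulator, maximum-likelihood
inference of the transduction rate from observed class counts, a
goodness-of-fit test, and functional titre estimation from a dilution
series.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

#: The seven labelled colour classes, in canonical order.
LABELLED_CLASSES: tuple[str, ...] = ("R", "G", "B", "RG", "GB", "RB", "RGB")

#: All classes including non-transduced cells.
ALL_CLASSES: tuple[str, ...] = LABELLED_CLASSES + ("unlabelled",)

#: Channel-presence pattern (r, g, b) for each labelled class.
CLASS_PATTERNS: dict[str, tuple[bool, bool, bool]] = {
    "R": (True, False, False),
    "G": (False, True, False),
    "B": (False, False, True),
    "RG": (True, True, False),
    "GB": (False, True, True),
    "RB": (True, False, True),
    "RGB": (True, True, True),
}

_PATTERN_TO_CLASS = {v: k for k, v in CLASS_PATTERNS.items()}
_PATTERN_TO_CLASS[(False, False, False)] = "unlabelled"


def class_of_pattern(r: bool, g: bool, b: bool) -> str:
    """Colour class named by the channels present, ``unlabelled`` if none."""
    return _PATTERN_TO_CLASS[(bool(r), bool(g), bool(b))]


@dataclass(frozen=True)
class VectorSet:
    """Parameters of the three colour-coded vectors applied to a population.

    Parameters
    ----------
    moi_r, moi_g, moi_b
        Mean integrations per cell for each vector (multiplicity of
        infection); non-negative and dimensionless.
    mix_ratio
        Relative particle doses of the three vectors.  The default 1:1:1
        is the standard injection mixture.
    expr_r, expr_g, expr_b
        Channel intensity contributed per vector copy, in 8-bit display
        units; strictly positive.
    """

    moi_r: float
    moi_g: float
    moi_b: float
    mix_ratio: tuple[float, float, float] = (1.0, 1.0, 1.0)
    expr_r: float = 80.0
    expr_g: float = 80.0
    expr_b: float = 80.0

    def __post_init__(self) -> None:
        if min(self.moi_r, self.moi_g, self.moi_b) < 0:
            raise ValueError("MOIs must be non-negative")
        if min(self.expr_r, self.expr_g, self.expr_b) <= 0:
            raise ValueError("expression strengths must be positive")
        if len(self.mix_ratio) != 3 or min(self.mix_ratio) <= 0:
            raise ValueError("mix_ratio must be three positive numbers")

    @property
    def mois(self) -> np.ndarray:
        return np.array([self.moi_r, self.moi_g, self.moi_b], dtype=float)

    @property
    def expr(self) -> np.ndarray:
        return np.array([self.expr_r, self.expr_g, self.expr_b], dtype=float)

    def scaled(self, factor: float) -> "VectorSet":
        """Rescale the overall dose; per-vector MOIs scale together."""
        if factor < 0:
            raise ValueError("dose factor must be non-negative")
        return VectorSet(
            self.moi_r * factor, self.moi_g * factor, self.moi_b * factor,
            mix_ratio=self.mix_ratio,
            expr_r=self.expr_r, expr_g=self.expr_g, expr_b=self.expr_b,
        )

    @classmethod
    def from_probabilities(cls, p_r: float, p_g: float, p_b: float,
                           **kwargs) -> "VectorSet":
        """Build a set whose MOIs yield the given transduction probabilities."""
        return cls(moi_from_probability(p_r), moi_from_probability(p_g),
                   moi_from_probability(p_b), **kwargs)


def transduction_probability(moi):
    """Probability that a cell receives at least one copy of a vector.

    Copy numbers are Poisson with mean ``moi``, so the zero class has
    probability ``exp(-moi)`` and the transduction probability is
    ``1 - exp(-moi)``.  Accepts scalars or arrays.
    """
    moi_arr = np.asarray(moi, dtype=float)
    if np.any(moi_arr < 0):
        raise ValueError("moi must be non-negative")
    out = -np.expm1(-moi_arr)
    return float(out) if np.isscalar(moi) or moi_arr.ndim == 0 else out


def moi_from_probability(p):
    """Inverse of :func:`transduction_probability`: ``-ln(1 - p)``."""
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr < 0) | (p_arr > 1)):
        raise ValueError("probability must be in [0, 1]")
    out = -np.log1p(-p_arr)
    return float(out) if np.isscalar(p) or p_arr.ndim == 0 else out


@dataclass
class ClassDistribution:
    """Counts (and derived fractions) of colour classes in a population.

    Fractions are always computed over labelled cells only, i.e.
    excluding non-transduced cells, matching how combinatorial-marking
    distributions are reported.
    """

    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {cls: int(self.counts.get(cls, 0)) for cls in ALL_CLASSES}
        unknown = set(self.counts) - set(ALL_CLASSES)
        if unknown:
            raise ValueError(f"unknown colour classes: {sorted(unknown)}")
        if any(v < 0 for v in clean.values()):
            raise ValueError("counts must be non-negative")
        self.counts = clean

    @property
    def labelled_total(self) -> int:
        return sum(self.counts[c] for c in LABELLED_CLASSES)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def has_labelled(self) -> bool:
        return self.labelled_total > 0

    @property
    def fractions(self) -> dict[str, float]:
        """Fractions of each labelled class among labelled cells.

        Raises
        ------
        ValueError
            If the population contains no labelled cells (the conditional
            distribution is undefined).
        """
        n = self.labelled_total
        if n == 0:
            raise ValueError("no labelled cells: fractions are undefined")
        return {c: self.counts[c] / n for c in LABELLED_CLASSES}

    def grouped_fractions(self) -> dict[str, float]:
        """Fractions aggregated into single/double/triple positives."""
        f = self.fractions
        return {
            "single": f["R"] + f["G"] + f["B"],
            "double": f["RG"] + f["GB"] + f["RB"],
            "triple": f["RGB"],
        }

    def labelled_counts(self) -> np.ndarray:
        return np.array([self.counts[c] for c in LABELLED_CLASSES], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        row = {c: self.counts[c] for c in ALL_CLASSES}
        return pd.DataFrame([row], columns=list(ALL_CLASSES))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ClassDistribution":
        if len(frame) != 1:
            raise ValueError("expected a single-row class-count table")
        row = frame.iloc[0]
        return cls({c: int(row[c]) for c in ALL_CLASSES if c in frame.columns})

    @classmethod
    def from_classes(cls, classes) -> "ClassDistribution":
        """Tally a sequence of per-cell class labels."""
        counts = dict.fromkeys(ALL_CLASSES, 0)
        for c in classes:
            counts[c] += 1
        return cls(counts)


def expected_class_distribution(p_r: float, p_g: float, p_b: float) -> dict[str, float]:
    """Analytic colour-class fractions among transduced cells.

    Each vector transduces independently with its own probability, so the
    probability of an exact presence pattern is a product of ``p`` and
    ``1 - p`` factors; conditioning on at least one vector divides by
    ``1 - (1-p_r)(1-p_g)(1-p_b)``.

    Returns a dict over the seven labelled classes summing to 1.
    """
    p = np.array([p_r, p_g, p_b], dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    denom = 1.0 - (1 - p_r) * (1 - p_g) * (1 - p_b)
    if denom <= 0:
        raise ValueError(
            "all transduction probabilities are zero: the distribution over "
            "labelled cells is undefined"
        )
    out: dict[str, float] = {}
    for cls, pattern in CLASS_PATTERNS.items():
        prob = 1.0
        for pc, present in zip(p, pattern):
            prob *= pc if present else (1 - pc)
        out[cls] = prob / denom
    return out


def class_curves(p_values) -> pd.DataFrame:
    """Model curves of single/double/triple fractions versus equal rate p.

    Produces a tidy table (p, single, double, triple) suitable for
    overlaying observed distributions on the theoretical curves.
    """
    rows = []
    for p in np.asarray(p_values, dtype=float):
        f = expected_class_distribution(p, p, p)
        rows.append({
            "p": p,
            "single": f["R"] + f["G"] + f["B"],
            "double": f["RG"] + f["GB"] + f["RB"],
            "triple": f["RGB"],
        })
    return pd.DataFrame(rows, columns=["p", "single", "double", "triple"])


def simulate_class_counts(vector_set: VectorSet, n_cells: int,
                          rng) -> ClassDistribution:
    """Monte-Carlo class counts: Poisson copies per vector, pattern of nonzeros.

    ``rng`` is a :class:`numpy.random.Generator` or an integer seed.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    rng = np.random.default_rng(rng)
    copies = rng.poisson(vector_set.mois, size=(int(n_cells), 3))
    present = copies > 0
    # pattern index: r + 2 g + 4 b
    idx = present[:, 0] + 2 * present[:, 1] + 4 * present[:, 2]
    order = [(False, False, False), (True, False, False), (False, True, False),
             (True, True, False), (False, False, True), (True, False, True),
             (False, True, True), (True, True, True)]
    tallies = np.bincount(idx, minlength=8)
    counts = {class_of_pattern(*order[i]): int(tallies[i]) for i in range(8)}
    return ClassDistribution(counts)


def _loglik_equal(p: float, counts: np.ndarray) -> float:
    f = expected_class_distribution(p, p, p)
    probs = np.array([f[c] for c in LABELLED_CLASSES])
    with np.errstate(divide="ignore"):
        logp = np.where(counts > 0, np.log(np.clip(probs, 1e-300, None)), 0.0)
    return float(np.sum(counts * logp))


def _loglik_vector(p: np.ndarray, counts: np.ndarray) -> float:
    f = expected_class_distribution(*p)
    probs = np.array([f[c] for c in LABELLED_CLASSES])
    with np.errstate(divide="ignore"):
        logp = np.where(counts > 0, np.log(np.clip(probs, 1e-300, None)), 0.0)
    return float(np.sum(counts * logp))


@dataclass
class FitResult:
    """Maximum-likelihood transduction-rate estimate from class counts."""

    mode: str
    estimate: float | tuple[float, float, float]
    ci: tuple[float, float] | tuple[tuple[float, float], ...]
    loglik: float
    n_labelled: int
    at_boundary: bool

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "estimate": self.estimate,
            "ci": self.ci,
            "loglik": self.loglik,
            "n_labelled": self.n_labelled,
            "at_boundary": self.at_boundary,
        }


_CHI2_95_1DF_HALF = stats.chi2.ppf(0.95, df=1) / 2.0  # 1.9207...
_P_FLOOR = 1e-9


def _profile_ci(loglik, p_hat: float, ll_hat: float,
                lo: float = _P_FLOOR, hi: float = 1.0) -> tuple[float, float]:
    """95% profile-likelihood interval for a 1-D (profile) log-likelihood."""
    target = ll_hat - _CHI2_95_1DF_HALF

    def f(p):
        return loglik(p) - target

    if p_hat - lo < 1e-12 or f(lo) >= 0:
        lower = lo
    else:
        lower = optimize.brentq(f, lo, p_hat, xtol=1e-10)
    if hi - p_hat < 1e-12 or f(hi) >= 0:
        upper = hi
    else:
        upper = optimize.brentq(f, p_hat, hi, xtol=1e-10)
    return (float(lower), float(upper))


def fit_transduction_rate(observed: ClassDistribution,
                          mode: str = "equal") -> FitResult:
    """Fit per-vector transduction probability to observed class counts.

    Maximises the multinomial likelihood of the seven labelled-class
    counts under :func:`expected_class_distribution`.

    Parameters
    ----------
    observed
        Class counts; only labelled classes enter the likelihood (the
        model conditions on transduction).
    mode
        ``"equal"`` fits a single rate shared by the three vectors;
        ``"per-vector"`` fits (p_r, p_g, p_b) separately.

    Returns
    -------
    FitResult
        Point estimate(s), 95% profile-likelihood interval(s), and a
        boundary flag when the optimum sits on p = 1 (e.g. every labelled
        cell triple-positive) or the lower floor.
    """
    counts = observed.labelled_counts()
    n = observed.labelled_total
    if n < 1:
        raise ValueError("need at least one labelled cell to fit")

    if mode == "equal":
        res = optimize.minimize_scalar(
            lambda p: -_loglik_equal(p, counts),
            bounds=(_P_FLOOR, 1.0), method="bounded",
            options={"xatol": 1e-10},
        )
        p_hat = float(res.x)
        # the bounded optimiser cannot land exactly on the boundary;
        # compare against the endpoint explicitly
        if _loglik_equal(1.0, counts) >= _loglik_equal(p_hat, counts):
            p_hat = 1.0
        ll_hat = _loglik_equal(p_hat, counts)
        ci = _profile_ci(lambda p: _loglik_equal(p, counts), p_hat, ll_hat)
        boundary = p_hat >= 1.0 - 1e-7 or p_hat <= _P_FLOOR * 2
        return FitResult("equal", p_hat, ci, ll_hat, n, boundary)

    if mode == "per-vector":
        bounds = [(_P_FLOOR, 1.0)] * 3
        best = None
        for start in ([0.5, 0.5, 0.5], [0.2, 0.2, 0.2], [0.8, 0.8, 0.8]):
            res = optimize.minimize(
                lambda p: -_loglik_vector(p, counts), start,
                method="L-BFGS-B", bounds=bounds,
                options={"ftol": 1e-14, "gtol": 1e-10},
            )
            if best is None or res.fun < best.fun:
                best = res
        p_hat = np.clip(best.x, _P_FLOOR, 1.0)
        # snap to the upper boundary when it is at least as likely
        for i in range(3):
            trial = p_hat.copy()
            trial[i] = 1.0
            if _loglik_vector(trial, counts) >= _loglik_vector(p_hat, counts):
                p_hat = trial
        ll_hat = _loglik_vector(p_hat, counts)
        cis = []
        for i in range(3):
            def prof(v, i=i):
                others = [j for j in range(3) if j != i]

                def nll(q):
                    full = np.empty(3)
                    full[i] = v
                    full[others[0]], full[others[1]] = q
                    return -_loglik_vector(full, counts)

                r = optimize.minimize(nll, p_hat[others], method="L-BFGS-B",
                                      bounds=[(_P_FLOOR, 1.0)] * 2,
                                      options={"ftol": 1e-12})
                return -r.fun

            cis.append(_profile_ci(prof, float(p_hat[i]), ll_hat))
        boundary = bool(np.any(p_hat >= 1.0 - 1e-7) or
                        np.any(p_hat <= _P_FLOOR * 2))
        return FitResult("per-vector", tuple(float(v) for v in p_hat),
                         tuple(cis), ll_hat, n, boundary)

    raise ValueError(f"unknown mode {mode!r}; use 'equal' or 'per-vector'")


@dataclass
class GofResult:
    statistic: float
    dof: int
    p_value: float
    method: str
    min_expected: float


def goodness_of_fit(observed: ClassDistribution,
                    expected_fractions: dict[str, float],
                    n_monte_carlo: int | None = None,
                    rng=None) -> GofResult:
    """Pearson chi-square of observed class counts against model fractions.

    The statistic runs over the seven labelled classes.  When any expected
    count falls below 5 the asymptotic chi-square reference is unreliable;
    pass ``n_monte_carlo`` to replace the p-value by a multinomial
    Monte-Carlo estimate (it is also honoured unconditionally).

    A class with zero expected fraction but nonzero observed count yields
    an infinite statistic with p-value 0, reported as such.
    """
    counts = observed.labelled_counts()
    n = observed.labelled_total
    if n <= 0:
        raise ValueError("labelled total must be positive")
    probs = np.array([expected_fractions[c] for c in LABELLED_CLASSES],
                     dtype=float)
    if not math.isclose(probs.sum(), 1.0, rel_tol=0, abs_tol=1e-9):
        raise ValueError("expected fractions must sum to 1 over the 7 classes")
    exp_counts = n * probs
    dof = len(LABELLED_CLASSES) - 1

    impossible = (exp_counts == 0) & (counts > 0)
    if np.any(impossible):
        return GofResult(float("inf"), dof, 0.0, "degenerate", 0.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(exp_counts > 0,
                         (counts - exp_counts) ** 2 / exp_counts, 0.0)
    statistic = float(terms.sum())
    min_expected = float(exp_counts[probs > 0].min())

    if n_monte_carlo:
        rng = np.random.default_rng(rng)
        sims = rng.multinomial(n, probs, size=int(n_monte_carlo))
        with np.errstate(invalid="ignore", divide="ignore"):
            sim_stats = np.where(exp_counts > 0,
                                 (sims - exp_counts) ** 2 / exp_counts,
                                 0.0).sum(axis=1)
        # add-one estimator keeps the p-value away from exactly 0
        p_value = (1 + np.sum(sim_stats >= statistic - 1e-12)) / (n_monte_carlo + 1)
        method = "monte-carlo"
    else:
        if min_expected < 5:
            warnings.warn(
                "expected count below 5 in at least one class; consider a "
                "Monte-Carlo p-value (n_monte_carlo=...)", stacklevel=2)
        p_value = float(stats.chi2.sf(statistic, dof))
        method = "asymptotic"
    return GofResult(statistic, dof, float(p_value), method, min_expected)


def titre_from_dilution(cells_plated, volume_ml, fraction_positive,
                        poisson_correct: bool = False,
                        linear_range_max: float = 0.3) -> pd.DataFrame:
    """Functional titre (transducing units per ml) from a dilution series.

    For each well, ``TU/ml = cells_plated * f / volume`` where ``f`` is the
    transduced fraction.  With ``poisson_correct`` the multiplicity is
    recovered from the untransduced fraction, ``TU/ml = cells_plated *
    (-ln(1 - f)) / volume``, which accounts for cells hit more than once.
    Wells with ``f`` above ``linear_range_max`` (default 0.3) are flagged
    as outside the linear range of the assay.

    All arguments broadcast; returns one row per well.
    """
    cells = np.atleast_1d(np.asarray(cells_plated, dtype=float))
    vol = np.atleast_1d(np.asarray(volume_ml, dtype=float))
    f = np.atleast_1d(np.asarray(fraction_positive, dtype=float))
    cells, vol, f = np.broadcast_arrays(cells, vol, f)
    if np.any(vol <= 0):
        raise ValueError("volume_ml must be positive")
    if np.any((f < 0) | (f > 1)):
        raise ValueError("fraction_positive must be in [0, 1]")
    if poisson_correct:
        if np.any(f >= 1):
            raise ValueError("fraction_positive must be < 1 with Poisson "
                             "correction (MOI diverges)")
        hits = -np.log1p(-f)
    else:
        hits = f
    tu_per_ml = cells * hits / vol
    return pd.DataFrame({
        "cells_plated": cells,
        "volume_ml": vol,
        "fraction_positive": f,
        "tu_per_ml": tu_per_ml,
        "poisson_corrected": poisson_correct,
        "outside_linear_range": f > linear_range_max,
    })
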
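"""Estimation of (M, kappa) from multi-level hypercapnia responses.

The measurement for one subject and region is a set of hypercapnia levels,
each carrying the end-tidal CO2 rise, the fractional BOLD response and the
CBF ratio.  :class:`HypercapniaCalibration` is the model object built from
those levels; its :meth:`~HypercapniaCalibration.fit` solves the graded
forward model for the calibration parameter M and the CMRO2 dose-response
kappa by bounded nonlinear least squares, while
:meth:`~HypercapniaCalibration.fit_isometabolic` performs the classical
one-parameter fit with kappa fixed at zero.  Both return a
:class:`CalibrationResult`.

:func:`solve_two_level_exact` solves the two-level system by bracketed 1-D
root finding and serves as an independent oracle for the least-squares path.
Group-level inference (mean +/- SEM, Wilcoxon signed-rank tests, exclusion
of fits that ran into the parameter bounds) lives in :func:`group_summary`.

Internal units are fractions throughout: M as a BOLD fraction, kappa as
fraction per mmHg.  Percent conversions belong to the I/O layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .model import AlphaBetaPairing, get_pairing, graded_bold

__all__ = [
    "HypercapniaLevel",
    "FitBounds",
    "CalibrationResult",
    "HypercapniaCalibration",
    "TwoLevelSolution",
    "NoSolutionError",
    "FitComparison",
    "GroupSummary",
    "fit_graded",
    "fit_isometabolic",
    "solve_two_level_exact",
    "compare_fits",
    "group_summary",
    "wilcoxon_signed_rank",
]

#: A parameter counts as "at" a bound when within this distance of it
#: (internal fraction units).
BOUNDARY_TOL = 1e-6

#: Floor kept between 1 + kappa*dPETCO2 and zero when the bounds alone do not
#: guarantee positivity of the CMRO2 ratio.
_POSITIVITY_EPS = 1e-6


@dataclass(frozen=True)
class HypercapniaLevel:
    """Responses measured at one hypercapnia dose.

    Parameters
    ----------
    delta_petco2 : float
        End-tidal CO2 rise above normocapnia, mmHg (> 0).
    bold_frac : float
        Fractional BOLD response (e.g. 0.016 for 1.6 %).
    cbf_ratio : float
        CBF during hypercapnia over baseline CBF (> 0).
    """

    delta_petco2: float
    bold_frac: float
    cbf_ratio: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.delta_petco2, self.bold_frac, self.cbf_ratio]).all():
            raise ValueError(f"non-finite level: {self}")
        if self.delta_petco2 <= 0.0:
            raise ValueError(f"delta_petco2 must be positive, got {self.delta_petco2}")
        if self.cbf_ratio <= 0.0:
            raise ValueError(f"cbf_ratio must be positive, got {self.cbf_ratio}")


@dataclass(frozen=True)
class FitBounds:
    """Box constraints on (M, kappa), fraction units.

    Defaults cover 1 % < M < 20 % and -5 < kappa < +5 %/mmHg, broad enough
    to include the physiologically plausible range for ROI-averaged data;
    fits that run into them are treated as noise-driven and flagged.
    """

    m_low: float = 0.01
    m_high: float = 0.20
    kappa_low: float = -0.05
    kappa_high: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.m_low < self.m_high):
            raise ValueError(f"invalid M bounds ({self.m_low}, {self.m_high})")
        if not self.kappa_low < self.kappa_high:
            raise ValueError(
                f"invalid kappa bounds ({self.kappa_low}, {self.kappa_high})"
            )

    def effective_kappa_low(self, max_delta_petco2: float) -> float:
        """Kappa lower bound that also keeps 1 + kappa*dP positive."""
        positivity = (_POSITIVITY_EPS - 1.0) / max_delta_petco2
        return max(self.kappa_low, positivity)


@dataclass
class CalibrationResult:
    """Fitted calibration parameters for one subject/region.

    Attributes
    ----------
    m, kappa : float
        Estimates in fraction units (kappa is identically 0 for the
        iso-metabolic fit).
    kappa_fixed : bool
        True for the one-parameter (iso-metabolic) fit.
    hit_boundary_m, hit_boundary_kappa : bool
        Whether the estimate lies within tolerance of a box constraint.
    residual_norm : float
        Sum of squared BOLD-fraction residuals at the solution.
    """

    m: float
    kappa: float
    kappa_fixed: bool
    hit_boundary_m: bool
    hit_boundary_kappa: bool
    residual_norm: float
    n_levels: int
    pairing: AlphaBetaPairing
    bounds: FitBounds
    levels: tuple[HypercapniaLevel, ...] = field(repr=False, default=())

    @property
    def hit_any_boundary(self) -> bool:
        return self.hit_boundary_m or self.hit_boundary_kappa

    @property
    def m_percent(self) -> float:
        return 100.0 * self.m

    @property
    def kappa_percent_per_mmhg(self) -> float:
        return 100.0 * self.kappa

    def predict(self, delta_petco2: float, cbf_ratio: float) -> float:
        """Model BOLD fraction at a hypercapnia dose given the fitted params."""
        return graded_bold(self.m, self.kappa, cbf_ratio, delta_petco2, self.pairing)

    def summary(self) -> str:
        kind = "iso-metabolic (kappa = 0)" if self.kappa_fixed else "graded two-parameter"
        lines = [
            "Hypercapnia calibration fit",
            "===========================",
            f"fit:            {kind}",
            f"pairing:        {self.pairing.name} "
            f"(alpha={self.pairing.alpha}, beta={self.pairing.beta})",
            f"levels:         {self.n_levels}",
            f"M:              {self.m_percent:.2f} %"
            + ("  [at bound]" if self.hit_boundary_m else ""),
        ]
        if not self.kappa_fixed:
            lines.append(
                f"kappa:          {self.kappa_percent_per_mmhg:+.2f} %/mmHg"
                + ("  [at bound]" if self.hit_boundary_kappa else "")
            )
        lines.append(f"residual norm:  {self.residual_norm:.3e}")
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Plot measured BOLD responses against the fitted dose curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        dps = np.array([lv.delta_petco2 for lv in self.levels])
        bolds = np.array([lv.bold_frac for lv in self.levels])
        ax.plot(dps, 100 * bolds, "ko", label="measured")
        if len(self.levels) >= 2:
            order = np.argsort(dps)
            fs = np.array([lv.cbf_ratio for lv in self.levels])[order]
            grid = np.linspace(dps.min(), dps.max(), 50)
            f_interp = np.interp(grid, dps[order], fs)
            curve = [self.predict(dp, f) for dp, f in zip(grid, f_interp)]
            ax.plot(grid, 100 * np.asarray(curve), "C0-", label="fit")
        ax.set_xlabel(r"$\Delta P_{ET}CO_2$ (mmHg)")
        ax.set_ylabel("BOLD response (%)")
        ax.legend()
        return ax

    def to_dict(self) -> dict:
        """Percent-scale record for serialization."""
        return {
            "m_percent": float(self.m_percent),
            "kappa_percent_per_mmhg": float(self.kappa_percent_per_mmhg),
            "kappa_fixed": bool(self.kappa_fixed),
            "hit_boundary_m": bool(self.hit_boundary_m),
            "hit_boundary_kappa": bool(self.hit_boundary_kappa),
            "residual_norm": float(self.residual_norm),
            "n_levels": int(self.n_levels),
            "pairing": {
                "name": self.pairing.name,
                "alpha": self.pairing.alpha,
                "beta": self.pairing.beta,
            },
        }


class HypercapniaCalibration:
    """Calibration model for one subject/region's hypercapnia levels.

    Parameters
    ----------
    levels : sequence of HypercapniaLevel
        At least two levels with distinct doses for the two-parameter fit;
        a single level suffices for the iso-metabolic fit.
    pairing : AlphaBetaPairing or str
        Exponent convention; "empirical" (0.14, 0.91), "3T" (0.2, 1.3) or
        "simplified" (0.06, 1.0).
    bounds : FitBounds, optional
    """

    def __init__(
        self,
        levels: Sequence[HypercapniaLevel],
        pairing: "AlphaBetaPairing | str" = "empirical",
        bounds: Optional[FitBounds] = None,
    ) -> None:
        self.levels = tuple(levels)
        if not self.levels:
            raise ValueError("at least one hypercapnia level is required")
        self.pairing = get_pairing(pairing)
        self.bounds = bounds if bounds is not None else FitBounds()

    @classmethod
    def from_dataframe(
        cls,
        df,
        pairing: "AlphaBetaPairing | str" = "empirical",
        bounds: Optional[FitBounds] = None,
        percent: bool = True,
    ) -> "HypercapniaCalibration":
        """Build from a table with one row per hypercapnia level.

        Expects columns ``delta_petco2_mmhg`` plus either
        ``bold_percent``/``cbf_percent`` (percent change, default) or
        ``bold_frac``/``cbf_ratio`` when ``percent=False``.
        """
        required = (
            ["delta_petco2_mmhg", "bold_percent", "cbf_percent"]
            if percent
            else ["delta_petco2_mmhg", "bold_frac", "cbf_ratio"]
        )
        for col in required:
            if col not in df.columns:
                raise KeyError(f"missing column {col!r} in level table")
        levels = []
        for _, row in df.iterrows():
            if percent:
                levels.append(
                    HypercapniaLevel(
                        delta_petco2=float(row["delta_petco2_mmhg"]),
                        bold_frac=float(row["bold_percent"]) / 100.0,
                        cbf_ratio=1.0 + float(row["cbf_percent"]) / 100.0,
                    )
                )
            else:
                levels.append(
                    HypercapniaLevel(
                        delta_petco2=float(row["delta_petco2_mmhg"]),
                        bold_frac=float(row["bold_frac"]),
                        cbf_ratio=float(row["cbf_ratio"]),
                    )
                )
        return cls(levels, pairing=pairing, bounds=bounds)

    # ------------------------------------------------------------------
    def _check_multi_level(self) -> None:
        if len(self.levels) < 2:
            raise ValueError("the two-parameter fit needs at least 2 levels")
        dps = [lv.delta_petco2 for lv in self.levels]
        if len(set(dps)) != len(dps):
            raise ValueError(f"duplicate delta_petco2 among levels: {dps}")

    def _arrays(self):
        dps = np.array([lv.delta_petco2 for lv in self.levels])
        bolds = np.array([lv.bold_frac for lv in self.levels])
        fs = np.array([lv.cbf_ratio for lv in self.levels])
        return dps, bolds, fs

    def fit(
        self,
        init: Optional[tuple[float, float]] = None,
        multistart: bool = False,
    ) -> CalibrationResult:
        """Two-parameter bounded least-squares fit for (M, kappa).

        Minimises the sum of squared BOLD-fraction residuals across levels
        subject to the box constraints.  ``init`` overrides the default
        interior start (M = 0.05, kappa = 0); ``multistart`` additionally
        tries a 3x3 grid of starts and keeps the lowest-cost solution.
        """
        self._check_multi_level()
        dps, bolds, fs = self._arrays()
        b = self.bounds
        klo = b.effective_kappa_low(dps.max())
        lower = np.array([b.m_low, klo])
        upper = np.array([b.m_high, b.kappa_high])

        a_mb = self.pairing.alpha - self.pairing.beta
        beta = self.pairing.beta
        f_pow = fs**a_mb

        def residuals(x):
            m, kappa = x
            u = np.maximum(1.0 + kappa * dps, _POSITIVITY_EPS)
            return bolds - m * (1.0 - f_pow * u**beta)

        starts: list[np.ndarray]
        if init is not None:
            starts = [np.clip(np.asarray(init, float), lower, upper)]
        else:
            starts = [np.array([0.05, 0.0])]
        if multistart:
            for m0 in (0.02, 0.05, 0.15):
                for k0 in (-0.03, 0.0, 0.03):
                    starts.append(np.clip(np.array([m0, k0]), lower, upper))

        best = None
        for x0 in starts:
            sol = optimize.least_squares(
                residuals,
                np.clip(x0, lower, upper),
                bounds=(lower, upper),
                method="trf",
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
            if best is None or sol.cost < best.cost:
                best = sol
        m_hat, kappa_hat = best.x
        # LM polish for interior solutions: the bounded trust-region solver
        # can stall ~1e-8 short of the optimum on well-conditioned problems
        if np.all(best.x > lower + BOUNDARY_TOL) and np.all(
            best.x < upper - BOUNDARY_TOL
        ):
            try:
                polished = optimize.least_squares(
                    residuals, best.x, method="lm", xtol=1e-15, ftol=1e-15
                )
                if (
                    polished.cost <= best.cost
                    and np.all(polished.x >= lower)
                    and np.all(polished.x <= upper)
                ):
                    m_hat, kappa_hat = polished.x
            except Exception:
                pass  # keep the bounded solution
        return CalibrationResult(
            m=float(m_hat),
            kappa=float(kappa_hat),
            kappa_fixed=False,
            hit_boundary_m=_at_bound(m_hat, b.m_low, b.m_high),
            hit_boundary_kappa=_at_bound(kappa_hat, b.kappa_low, b.kappa_high),
            residual_norm=float(np.sum(residuals(best.x) ** 2)),
            n_levels=len(self.levels),
            pairing=self.pairing,
            bounds=b,
            levels=self.levels,
        )

    def fit_isometabolic(self) -> CalibrationResult:
        """One-parameter fit of M with kappa fixed at zero.

        With kappa = 0 the model is linear in M, so the least-squares
        solution is closed form: M = sum(b_i c_i) / sum(c_i^2) with
        c_i = 1 - f_i**(alpha-beta), clipped to the bounds.
        """
        dps, bolds, fs = self._arrays()
        c = 1.0 - fs ** (self.pairing.alpha - self.pairing.beta)
        denom = float(np.sum(c * c))
        if denom == 0.0:
            raise ValueError(
                "M is unidentifiable: all CBF ratios equal 1 (no vascular response)"
            )
        m_hat = float(np.sum(bolds * c) / denom)
        b = self.bounds
        m_hat = min(max(m_hat, b.m_low), b.m_high)
        resid = bolds - m_hat * c
        return CalibrationResult(
            m=m_hat,
            kappa=0.0,
            kappa_fixed=True,
            hit_boundary_m=_at_bound(m_hat, b.m_low, b.m_high),
            hit_boundary_kappa=False,
            residual_norm=float(np.sum(resid**2)),
            n_levels=len(self.levels),
            pairing=self.pairing,
            bounds=b,
            levels=self.levels,
        )


def _at_bound(value: float, low: float, high: float) -> bool:
    return bool(abs(value - low) <= BOUNDARY_TOL or abs(value - high) <= BOUNDARY_TOL)


# ----------------------------------------------------------------------
# Functional entry points mirroring the model methods.


def fit_graded(
    levels: Sequence[HypercapniaLevel],
    pairing: "AlphaBetaPairing | str" = "empirical",
    bounds: Optional[FitBounds] = None,
    init: Optional[tuple[float, float]] = None,
    multistart: bool = False,
) -> CalibrationResult:
    """Two-parameter (M, kappa) fit; see :meth:`HypercapniaCalibration.fit`."""
    return HypercapniaCalibration(levels, pairing, bounds).fit(
        init=init, multistart=multistart
    )


def fit_isometabolic(
    levels: Sequence[HypercapniaLevel],
    pairing: "AlphaBetaPairing | str" = "empirical",
    bounds: Optional[FitBounds] = None,
) -> CalibrationResult:
    """One-parameter M fit with kappa = 0."""
    return HypercapniaCalibration(levels, pairing, bounds).fit_isometabolic()


# ----------------------------------------------------------------------
# Exact two-level solver (independent oracle for the least-squares path).


class NoSolutionError(ValueError):
    """The two-level system has no solution in the kappa search domain."""


@dataclass(frozen=True)
class TwoLevelSolution:
    m: float
    kappa: float
    n_roots: int
    roots: tuple[float, ...] = ()


def solve_two_level_exact(
    level1: HypercapniaLevel,
    level2: HypercapniaLevel,
    pairing: "AlphaBetaPairing | str" = "empirical",
    kappa_max: float = 0.5,
    n_grid: int = 2001,
) -> TwoLevelSolution:
    """Solve the two-level system exactly by 1-D bracketed root finding.

    Taking the two model equations and eliminating M leaves a single
    equation in kappa,

        b2 * [1 - f1**(a-b) * (1 + kappa*dP1)**b]
          = b1 * [1 - f2**(a-b) * (1 + kappa*dP2)**b],

    which is scanned for sign changes over the positivity domain of the
    CMRO2 ratio and each bracket polished with Brent's method.  M follows
    by back-substitution.  When several roots exist the one of smallest
    |kappa| is returned along with the root count; when none exists a
    :class:`NoSolutionError` is raised (never a silent clamp).
    """
    p = get_pairing(pairing)
    if level1.delta_petco2 == level2.delta_petco2:
        raise ValueError("the two levels must have distinct delta_petco2")
    if level1.bold_frac == 0.0 or level2.bold_frac == 0.0:
        raise ValueError("both BOLD responses must be nonzero")
    dp1, b1, f1 = level1.delta_petco2, level1.bold_frac, level1.cbf_ratio
    dp2, b2, f2 = level2.delta_petco2, level2.bold_frac, level2.cbf_ratio
    a_mb = p.alpha - p.beta
    g1, g2 = f1**a_mb, f2**a_mb

    def g(kappa):
        u1 = 1.0 + kappa * dp1
        u2 = 1.0 + kappa * dp2
        return b2 * (1.0 - g1 * u1**p.beta) - b1 * (1.0 - g2 * u2**p.beta)

    kappa_min = (_POSITIVITY_EPS - 1.0) / max(dp1, dp2)
    grid = np.linspace(kappa_min, kappa_max, n_grid)
    vals = np.array([g(k) for k in grid])

    found: list[float] = []
    found.extend(float(k) for k in grid[vals == 0.0])
    sign_change = np.nonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)[0]
    for i in sign_change:
        found.append(
            float(
                optimize.brentq(
                    g, grid[i], grid[i + 1], xtol=1e-15, rtol=4 * np.finfo(float).eps
                )
            )
        )
    # merge near-identical roots at full precision
    roots: list[float] = []
    for r in sorted(found):
        if not roots or abs(r - roots[-1]) > 1e-10:
            roots.append(r)
    roots.sort(key=abs)
    if not roots:
        raise NoSolutionError(
            "no kappa in the search domain satisfies the two-level system "
            f"(domain [{kappa_min:.4g}, {kappa_max:.4g}])"
        )
    kappa_hat = roots[0]
    denom = 1.0 - g1 * (1.0 + kappa_hat * dp1) ** p.beta
    if denom == 0.0:
        raise NoSolutionError("degenerate root: M denominator vanishes")
    m_hat = b1 / denom
    return TwoLevelSolution(
        m=float(m_hat),
        kappa=float(kappa_hat),
        n_roots=len(roots),
        roots=tuple(roots),
    )


# ----------------------------------------------------------------------
# Paired comparison and group statistics.


@dataclass(frozen=True)
class FitComparison:
    """Paired two- vs one-parameter M for one subject/region."""

    m_two: float
    m_one: float
    delta_m: float
    included: bool


def compare_fits(
    two_param: CalibrationResult, one_param: CalibrationResult
) -> FitComparison:
    """Pair a graded and an iso-metabolic fit of the same data.

    ``included`` is True only when neither fit ran into a parameter bound,
    mirroring the boundary-exclusion rule used at group level.
    """
    if two_param.kappa_fixed or not one_param.kappa_fixed:
        raise ValueError("expected (two-parameter, one-parameter) in that order")
    if two_param.pairing != one_param.pairing:
        raise ValueError(
            f"pairing mismatch: {two_param.pairing} vs {one_param.pairing}"
        )
    if two_param.levels != one_param.levels:
        raise ValueError("the two fits were not made from the same levels")
    return FitComparison(
        m_two=two_param.m,
        m_one=one_param.m,
        delta_m=two_param.m - one_param.m,
        included=not (two_param.hit_any_boundary or one_param.hit_any_boundary),
    )


def wilcoxon_signed_rank(values: Sequence[float], mu: float = 0.0) -> float:
    """Two-sided Wilcoxon signed-rank p-value for location ``mu``.

    Zero differences are dropped (Wilcoxon's original treatment).  For
    n <= 25 the null is enumerated exactly by dynamic programming over the
    2**n sign assignments (ties handled through midranks); above that a
    normal approximation with tie correction is used.
    """
    d = np.asarray(values, dtype=float) - mu
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero; the test is undefined")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= 25:
        return _exact_signed_rank_p(w_plus, ranks)
    # normal approximation; tie correction reduces the null variance
    mean = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (w_plus - mean) / math.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def _exact_signed_rank_p(w_plus: float, ranks: np.ndarray) -> float:
    # doubled ranks are integers even with midranks
    r2 = np.rint(2.0 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(2.0 * w_plus))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


@dataclass
class GroupSummary:
    """Across-subject summary after boundary exclusion."""

    mode: str
    included_n: int
    total_n: int
    mean_m: float
    sem_m: float
    mean_kappa: Optional[float] = None
    sem_kappa: Optional[float] = None
    wilcoxon_p_kappa: Optional[float] = None
    mean_m_one: Optional[float] = None
    sem_m_one: Optional[float] = None
    mean_delta_m: Optional[float] = None
    sem_delta_m: Optional[float] = None
    wilcoxon_p_m_paired: Optional[float] = None

    def summary(self) -> str:
        lines = [
            f"Group summary ({self.mode}), N = {self.included_n}/{self.total_n}",
            f"M (two-parameter): {100 * self.mean_m:.1f} +/- {100 * self.sem_m:.1f} %",
        ]
        if self.mode == "kappa-test":
            lines.append(
                f"kappa: {100 * self.mean_kappa:+.2f} +/- {100 * self.sem_kappa:.2f} "
                f"%/mmHg (Wilcoxon p = {self.wilcoxon_p_kappa:.3g} vs 0)"
            )
        else:
            lines.append(
                f"M (iso-metabolic): {100 * self.mean_m_one:.1f} "
                f"+/- {100 * self.sem_m_one:.1f} %"
            )
            lines.append(
                f"delta M: {100 * self.mean_delta_m:+.2f} "
                f"+/- {100 * self.sem_delta_m:.2f} % "
                f"(Wilcoxon p = {self.wilcoxon_p_m_paired:.3g})"
            )
        return "\n".join(lines)


def _mean_sem(x: np.ndarray) -> tuple[float, float]:
    mean = float(np.mean(x))
    sem = float(np.std(x, ddof=1) / math.sqrt(x.size)) if x.size > 1 else float("nan")
    return mean, sem


def group_summary(
    results: "Sequence[CalibrationResult] | Sequence[FitComparison]",
    mode: str = "kappa-test",
) -> GroupSummary:
    """Across-subject statistics with boundary-hit exclusion.

    ``mode="kappa-test"`` consumes two-parameter :class:`CalibrationResult`
    objects and tests kappa against zero; ``mode="paired-M-test"`` consumes
    :class:`FitComparison` records and tests the paired M differences.
    Subjects whose fit reached a parameter bound are excluded before any
    statistic is computed.
    """
    total_n = len(results)
    if mode == "kappa-test":
        included = [r for r in results if not r.hit_any_boundary]
        if not included:
            raise ValueError("no subjects remain after boundary exclusion")
        ms = np.array([r.m for r in included])
        kappas = np.array([r.kappa for r in included])
        mean_m, sem_m = _mean_sem(ms)
        mean_k, sem_k = _mean_sem(kappas)
        return GroupSummary(
            mode=mode,
            included_n=len(included),
            total_n=total_n,
            mean_m=mean_m,
            sem_m=sem_m,
            mean_kappa=mean_k,
            sem_kappa=sem_k,
            wilcoxon_p_kappa=wilcoxon_signed_rank(kappas),
        )
    if mode == "paired-M-test":
        pairs = [c for c in results if c.included]
        if not pairs:
            raise ValueError("no subjects remain after boundary exclusion")
        m_two = np.array([c.m_two for c in pairs])
        m_one = np.array([c.m_one for c in pairs])
        delta = np.array([c.delta_m for c in pairs])
        mean_m, sem_m = _mean_sem(m_two)
        mean_m1, sem_m1 = _mean_sem(m_one)
        mean_d, sem_d = _mean_sem(delta)
        return GroupSummary(
            mode=mode,
            included_n=len(pairs),
            total_n=total_n,
            mean_m=mean_m,
            sem_m=sem_m,
            mean_m_one=mean_m1,
            sem_m_one=sem_m1,
            mean_delta_m=mean_d,
            sem_delta_m=sem_d,
            wilcoxon_p_m_paired=wilcoxon_signed_rank(delta),
        )
    raise ValueError(f"unknown mode {mode!r}")
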
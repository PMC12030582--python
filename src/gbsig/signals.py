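"""Disproportionality statistics for spontaneous adverse-event reports.

Everything here works on the 2x2 contingency table of one drug-event pair,

    ============  ===========  ===========
    .             target event other event
    ============  ===========  ===========
    target drug        a            b
    other drugs        c            d
    ============  ===========  ===========

and implements the four classical signal-detection algorithms used in
pharmacovigilance:

* **ROR** -- reporting odds ratio ``ad/(bc)`` with a Woolf (log-normal)
  confidence interval.
* **PRR** -- proportional reporting ratio ``[a/(a+b)] / [c/(c+d)]`` with its
  log-normal interval and the (uncorrected) Pearson chi-square statistic.
* **BCPNN** -- the Bayesian information component
  ``IC = log2( a*N / ((a+b)(a+c)) )`` together with its posterior expectation
  ``E(IC)``, variance ``V(IC)`` and the lower bound ``IC - 2*sqrt(V(IC))``.
* **MGPS-style EBGM** -- here the unshrunk relative reporting ratio
  ``a*N/((a+b)(a+c))`` (identical to ``2**IC``) with a log-normal lower bound
  ``EBGM05``.

The module also provides :func:`invert_contingency`, which recovers the full
table ``(b, c, d)`` from a published ``(a, ROR, PRR, chi2)`` triple -- useful
for auditing ranked signal tables that print statistics but not denominators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import InversionError, UndefinedStatisticError, UsageError

__all__ = [
    "ContingencyTable",
    "BcpnnPriors",
    "CriteriaThresholds",
    "CriteriaFlags",
    "SignalResult",
    "build_contingency",
    "compute_ror",
    "compute_prr_chi2",
    "compute_bcpnn",
    "compute_ebgm",
    "apply_criteria",
    "evaluate_signal",
    "rank_signals",
    "invert_contingency",
    "format_signal_table",
]

#: two-sided 95% normal quantile as conventionally printed in the
#: pharmacovigilance literature
Z_95 = 1.96
#: one-sided 5th-percentile quantile used for EBGM05
Z_90_ONE_SIDED = 1.645

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 drug-event contingency table.

    Counts are usually integers, but real values are allowed so that tables
    recovered by :func:`invert_contingency` (continuous by construction) can
    flow through the same statistics.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise UsageError(f"cell {name} must be a finite non-negative number, got {v!r}")
        if self.n <= 0:
            raise UsageError("contingency table is empty (N = 0)")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    def with_continuity(self, k: float = 0.5) -> "ContingencyTable":
        """Haldane-Anscombe correction: add ``k`` to every cell."""
        return ContingencyTable(self.a + k, self.b + k, self.c + k, self.d + k)

    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0


@dataclass(frozen=True)
class BcpnnPriors:
    """Prior hyper-parameters of the BCPNN information component.

    The defaults are the standard single-event/single-drug choice:
    ``alpha1 = beta1 = 1``, ``alpha = beta = 2``, ``gamma11 = 1``, with
    ``gamma`` derived from the margins so that E(IC) = 0 under independence.
    """

    alpha1: float = 1.0
    beta1: float = 1.0
    alpha: float = 2.0
    beta: float = 2.0
    gamma11: float = 1.0

    def gamma(self, t: ContingencyTable) -> float:
        n = t.n
        return (
            self.gamma11
            * (n + self.alpha)
            * (n + self.beta)
            / ((t.a + t.b + self.alpha1) * (t.a + t.c + self.beta1))
        )


@dataclass(frozen=True)
class CriteriaThresholds:
    """Signal criteria of the four algorithms.

    ROR: a >= min_cases and the 95% CI lower bound > ror_ci_lower.
    PRR: a >= min_cases, PRR >= prr_min and chi2 >= chi2_min.
    BCPNN: IC - 2*sqrt(V(IC)) > ic2sd_min.
    EBGM: EBGM05 > ebgm05_min.
    """

    min_cases: int = 3
    ror_ci_lower: float = 1.0
    prr_min: float = 2.0
    chi2_min: float = 4.0
    ic2sd_min: float = 0.0
    ebgm05_min: float = 2.0


@dataclass(frozen=True)
class CriteriaFlags:
    ror: bool
    prr: bool
    bcpnn: bool
    ebgm: bool

    @property
    def overall(self) -> bool:
        return self.ror and self.prr and self.bcpnn and self.ebgm


@dataclass
class SignalResult:
    """All four disproportionality statistics for one drug-event pair."""

    drug: str
    table: ContingencyTable
    ror: float
    ror_low: float
    ror_high: float
    prr: float
    prr_low: float
    prr_high: float
    chi2: float
    ic: float
    e_ic: float
    v_ic: float
    ic_2sd: float
    ebgm: float
    ebgm05: float
    flags: CriteriaFlags | None = None

    @property
    def a(self) -> float:
        return self.table.a


def _require_positive_cells(t: ContingencyTable) -> None:
    if t.has_zero_cell():
        raise UndefinedStatisticError(
            "table has a zero cell; enable the continuity correction to proceed"
        )


def _se_log_or(t: ContingencyTable) -> float:
    return math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)


def compute_ror(
    t: ContingencyTable, z: float = Z_95, continuity: bool = False
) -> tuple[float, float, float]:
    """Reporting odds ratio with its two-sided 95% confidence interval.

    Returns ``(ROR, lower, upper)`` where the interval is
    ``exp(ln ROR +/- z * sqrt(1/a + 1/b + 1/c + 1/d))``.
    """
    if continuity and t.has_zero_cell():
        t = t.with_continuity()
    _require_positive_cells(t)
    ror = (t.a * t.d) / (t.b * t.c)
    se = _se_log_or(t)
    return ror, ror * math.exp(-z * se), ror * math.exp(z * se)


def compute_prr_chi2(
    t: ContingencyTable, z: float = Z_95, continuity: bool = False
) -> tuple[float, float, float, float]:
    """Proportional reporting ratio, its 95% CI and the Pearson chi-square.

    Returns ``(PRR, lower, upper, chi2)``.  The chi-square is the classical
    uncorrected statistic ``(ad-bc)^2 * N / ((a+b)(a+c)(c+d)(b+d))``; the PRR
    interval uses ``exp(ln PRR +/- z*sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d)))``.
    """
    if continuity and t.has_zero_cell():
        t = t.with_continuity()
    if min(t.a + t.b, t.c + t.d, t.a + t.c, t.b + t.d) == 0:
        raise UndefinedStatisticError("a zero margin makes PRR/chi-square undefined")
    if t.a == 0 or t.c == 0:
        raise UndefinedStatisticError(
            "PRR undefined with a zero numerator/denominator cell; "
            "enable the continuity correction to proceed"
        )
    prr = (t.a / (t.a + t.b)) / (t.c / (t.c + t.d))
    se = math.sqrt(1 / t.a - 1 / (t.a + t.b) + 1 / t.c - 1 / (t.c + t.d))
    chi2 = pearson_chi2(t)
    return prr, prr * math.exp(-z * se), prr * math.exp(z * se), chi2


def pearson_chi2(t: ContingencyTable) -> float:
    """Uncorrected Pearson chi-square of the 2x2 table."""
    num = (t.a * t.d - t.b * t.c) ** 2 * t.n
    den = (t.a + t.b) * (t.a + t.c) * (t.c + t.d) * (t.b + t.d)
    if den == 0:
        raise UndefinedStatisticError("a zero margin makes the chi-square undefined")
    return num / den


def relative_reporting_ratio(t: ContingencyTable) -> float:
    """Observed/expected ratio ``a*N / ((a+b)(a+c))`` shared by IC and EBGM."""
    den = (t.a + t.b) * (t.a + t.c)
    if den == 0:
        raise UndefinedStatisticError("a zero margin makes the RRR undefined")
    return t.a * t.n / den


@dataclass(frozen=True)
class BcpnnResult:
    ic: float
    e_ic: float
    v_ic: float
    ic_2sd: float


def compute_bcpnn(
    t: ContingencyTable,
    priors: BcpnnPriors | None = None,
    mode: str = "point",
    continuity: bool = False,
) -> BcpnnResult:
    """BCPNN information component with Bayesian expectation and variance.

    ``IC = log2( a*N / ((a+b)(a+c)) )`` is the point (observed/expected)
    information component.  ``E(IC)`` and ``V(IC)`` are the standard
    closed-form posterior moments under the Dirichlet priors in *priors*.

    The lower bound ``IC-2SD`` depends on *mode*:

    * ``"point"`` (default): ``IC - 2*sqrt(V(IC))``, i.e. the point IC minus
      two posterior standard deviations -- the convention that matches signal
      tables which print the point IC.
    * ``"posterior"``: ``E(IC) - 2*sqrt(V(IC))``, the fully Bayesian bound.
    """
    if mode not in ("point", "posterior"):
        raise UsageError(f"unknown BCPNN mode {mode!r}")
    if continuity and t.has_zero_cell():
        t = t.with_continuity()
    if t.a == 0:
        raise UndefinedStatisticError(
            "point IC undefined at a = 0; enable the continuity correction"
        )
    priors = priors or BcpnnPriors()
    n = t.n
    ic = math.log2(relative_reporting_ratio(t))

    g = priors.gamma(t)
    e_ic = math.log2(
        (t.a + priors.gamma11)
        * (n + priors.alpha)
        * (n + priors.beta)
        / ((n + g) * (t.a + t.b + priors.alpha1) * (t.a + t.c + priors.beta1))
    )
    v_ic = (
        (n - t.a + g - priors.gamma11) / ((t.a + priors.gamma11) * (1 + n + g))
        + (n - t.a - t.b + priors.alpha - priors.alpha1)
        / ((t.a + t.b + priors.alpha1) * (1 + n + priors.alpha))
        + (n - t.a - t.c + priors.beta - priors.beta1)
        / ((t.a + t.c + priors.beta1) * (1 + n + priors.beta))
    ) / (_LN2**2)
    centre = ic if mode == "point" else e_ic
    return BcpnnResult(ic=ic, e_ic=e_ic, v_ic=v_ic, ic_2sd=centre - 2.0 * math.sqrt(v_ic))


def compute_ebgm(
    t: ContingencyTable, z: float = Z_90_ONE_SIDED, continuity: bool = False
) -> tuple[float, float]:
    """Empirical Bayes geometric mean (relative reporting ratio) and EBGM05.

    ``EBGM = a*N/((a+b)(a+c))``; the lower bound is
    ``EBGM / exp(z * sqrt(1/a + 1/b + 1/c + 1/d))``.  The default ``z`` is the
    one-sided 5th-percentile quantile 1.645.
    """
    if continuity and t.has_zero_cell():
        t = t.with_continuity()
    _require_positive_cells(t)
    ebgm = relative_reporting_ratio(t)
    return ebgm, ebgm * math.exp(-z * _se_log_or(t))


def apply_criteria(
    result: SignalResult, thresholds: CriteriaThresholds | None = None
) -> CriteriaFlags:
    """Evaluate the four per-algorithm signal criteria on computed statistics."""
    th = thresholds or CriteriaThresholds()
    enough = result.a >= th.min_cases
    return CriteriaFlags(
        ror=enough and result.ror_low > th.ror_ci_lower,
        prr=enough
        and result.prr_low > th.ror_ci_lower
        and result.prr >= th.prr_min
        and result.chi2 >= th.chi2_min,
        bcpnn=result.ic_2sd > th.ic2sd_min,
        ebgm=result.ebgm05 > th.ebgm05_min,
    )


def evaluate_signal(
    t: ContingencyTable,
    drug: str = "",
    priors: BcpnnPriors | None = None,
    thresholds: CriteriaThresholds | None = None,
    ic_mode: str = "point",
    ebgm_z: float = Z_90_ONE_SIDED,
    continuity: bool = False,
) -> SignalResult:
    """Compute all four algorithms and criteria flags for one table."""
    ror, ror_lo, ror_hi = compute_ror(t, continuity=continuity)
    prr, prr_lo, prr_hi, chi2 = compute_prr_chi2(t, continuity=continuity)
    bc = compute_bcpnn(t, priors=priors, mode=ic_mode, continuity=continuity)
    ebgm, ebgm05 = compute_ebgm(t, z=ebgm_z, continuity=continuity)
    res = SignalResult(
        drug=drug,
        table=t,
        ror=ror,
        ror_low=ror_lo,
        ror_high=ror_hi,
        prr=prr,
        prr_low=prr_lo,
        prr_high=prr_hi,
        chi2=chi2,
        ic=bc.ic,
        e_ic=bc.e_ic,
        v_ic=bc.v_ic,
        ic_2sd=bc.ic_2sd,
        ebgm=ebgm,
        ebgm05=ebgm05,
    )
    res.flags = apply_criteria(res, thresholds)
    return res


def build_contingency(report_set, drug: str, event: str) -> ContingencyTable:
    """Report-level 2x2 table for one drug-event pair.

    Each deduplicated report contributes exactly once to exactly one cell, so
    ``a+b+c+d`` equals the number of reports.  Matching is case-insensitive
    (and hyphen/whitespace-insensitive for the event preferred term).  Absent
    drugs or events simply yield ``a = 0``.
    """
    from .faers import normalize_term  # local import to avoid a cycle

    drug_key = drug.strip().lower()
    event_key = normalize_term(event)
    a = b = c = d = 0
    for rec in report_set:
        has_drug = any(g.strip().lower() == drug_key for g, _ in rec.drugs)
        has_event = any(normalize_term(r) == event_key for r in rec.reactions)
        if has_drug and has_event:
            a += 1
        elif has_drug:
            b += 1
        elif has_event:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def rank_signals(
    results: list[SignalResult], top: int | None = None
) -> pd.DataFrame:
    """Filter to signals with all four criteria met, rank by ROR descending.

    Ties are broken alphabetically by drug name.  Returns a numeric frame; use
    :func:`format_signal_table` for the 2-decimal publication layout.
    """
    flagged = [r for r in results if r.flags is not None and r.flags.overall]
    flagged.sort(key=lambda r: (-r.ror, r.drug))
    if top is not None:
        flagged = flagged[:top]
    return pd.DataFrame(
        {
            "drug": [r.drug for r in flagged],
            "cases": [r.a for r in flagged],
            "ror": [r.ror for r in flagged],
            "ror_low": [r.ror_low for r in flagged],
            "ror_high": [r.ror_high for r in flagged],
            "prr": [r.prr for r in flagged],
            "prr_low": [r.prr_low for r in flagged],
            "prr_high": [r.prr_high for r in flagged],
            "chi2": [r.chi2 for r in flagged],
            "ic": [r.ic for r in flagged],
            "ic_2sd": [r.ic_2sd for r in flagged],
            "ebgm": [r.ebgm for r in flagged],
            "ebgm05": [r.ebgm05 for r in flagged],
        }
    )


def format_signal_table(df: pd.DataFrame) -> pd.DataFrame:
    """Publication-shaped signal table with 2-decimal composite columns."""
    out = pd.DataFrame()
    out["Drug"] = df["drug"]
    out["Cases"] = df["cases"].astype(int)
    out["ROR (95% CI)"] = [
        f"{r:.2f} ({lo:.2f}, {hi:.2f})"
        for r, lo, hi in zip(df["ror"], df["ror_low"], df["ror_high"])
    ]
    out["PRR (95% CI)"] = [
        f"{r:.2f} ({lo:.2f}, {hi:.2f})"
        for r, lo, hi in zip(df["prr"], df["prr_low"], df["prr_high"])
    ]
    out["chi2"] = [f"{v:.2f}" for v in df["chi2"]]
    out["IC (IC-2SD)"] = [f"{i:.2f} ({l:.2f})" for i, l in zip(df["ic"], df["ic_2sd"])]
    out["EBGM (EBGM05)"] = [f"{e:.2f} ({l:.2f})" for e, l in zip(df["ebgm"], df["ebgm05"])]
    return out


# ---------------------------------------------------------------------------
# inversion of published statistics
# ---------------------------------------------------------------------------


def _forward_stats(a: float, b: float, c: float, d: float) -> tuple[float, float, float]:
    t = ContingencyTable(a, b, c, d)
    ror = (t.a * t.d) / (t.b * t.c)
    prr = (t.a / (t.a + t.b)) / (t.c / (t.c + t.d))
    return ror, prr, pearson_chi2(t)


def invert_contingency(
    a: float,
    ror: float,
    prr: float,
    chi2: float,
    rel_tol: float = 1e-6,
) -> ContingencyTable:
    """Recover the continuous cells ``(b, c, d)`` from published statistics.

    Given the case count ``a`` and the printed ``ROR``, ``PRR`` and Pearson
    chi-square of a 2x2 table, this solves the three forward equations for the
    remaining cells.  Two of the three unknowns have a closed form: writing
    ``p1 = a/(a+b)`` and ``p0 = c/(c+d)``,

        ``ROR/PRR = (1-p0)/(1-p1)``  and  ``PRR = p1/p0``

    give ``p1 = (ROR-PRR)/(ROR-1)``, hence ``b``; the total ``N`` is then the
    single root of the (monotone, bounded) chi-square equation, located by
    bracketing on a log grid and polished by Levenberg-Marquardt least squares
    on ``(log b, log c, log d)``.

    Returns a table whose forward statistics match the inputs to *rel_tol*
    in relative terms; raises :class:`InversionError` (carrying the best
    residual) otherwise.  Cells are real-valued, not integers: printed inputs
    are rounded, so the exact integer table is generally not identifiable.
    """
    if a < 1:
        raise UsageError("inversion requires a >= 1")
    if ror <= 0 or prr <= 0 or chi2 <= 0:
        raise UsageError("ROR, PRR and chi-square must all be positive")

    starts: list[tuple[float, float, float]] = []

    if ror != 1.0:
        # ROR/PRR = (1-p0)/(1-p1) and PRR = p1/p0 jointly pin the row rates
        p1 = (ror - prr) / (ror - 1.0)
        p0 = p1 / prr
        if 0 < p0 < 1 and 0 < p1 < 1:
            b0 = a * (1 - p1) / p1
            u = a + b0

            def chi2_at(n_total: float) -> float:
                rest = n_total - u
                c_ = p0 * rest
                d_ = (1 - p0) * rest
                return pearson_chi2(ContingencyTable(a, b0, c_, d_))

            grid = np.logspace(math.log10(u * 1.0001 + a), 12, 400)
            vals = np.array([chi2_at(g) - chi2 for g in grid])
            sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
            if sign_change.size:
                i = sign_change[0]
                n_root = optimize.brentq(
                    lambda n: chi2_at(n) - chi2, grid[i], grid[i + 1], xtol=1e-6, rtol=1e-14
                )
            else:  # no crossing: start from the closest grid point
                n_root = grid[int(np.argmin(np.abs(vals)))]
            rest = n_root - u
            starts.append((b0, p0 * rest, (1 - p0) * rest))

    # generic multi-start fallback covering totals from 1e3 to 1e10
    for n0 in np.logspace(3, 10, 8):
        c0 = max(a, a * n0 / (chi2 * 10.0))
        b0 = max(a / prr, 1.0)
        d0 = max(n0 - a - b0 - c0, 1.0)
        starts.append((b0, c0, d0))

    target = np.log([ror, prr, chi2])

    def residuals(x: np.ndarray) -> np.ndarray:
        b_, c_, d_ = np.exp(np.clip(x, -30.0, 40.0))
        with np.errstate(all="ignore"):
            f = np.array(_forward_stats(a, b_, c_, d_))
            if not np.all(np.isfinite(f)) or np.any(f <= 0):
                return np.full(3, 1e6)
            return np.log(f) - target

    best: tuple[float, np.ndarray] | None = None
    for b0, c0, d0 in starts:
        x0 = np.log([max(b0, 1e-9), max(c0, 1e-9), max(d0, 1e-9)])
        try:
            sol = optimize.least_squares(residuals, x0, method="lm", xtol=1e-15, ftol=1e-15)
        except (ValueError, FloatingPointError):
            continue
        res_norm = float(np.max(np.abs(sol.fun)))
        if best is None or res_norm < best[0]:
            best = (res_norm, sol.x)
        if res_norm < rel_tol:
            break

    if best is None or best[0] >= rel_tol:
        raise InversionError(
            f"no table reproduces (ROR={ror}, PRR={prr}, chi2={chi2}) at a={a} "
            f"within relative tolerance {rel_tol:g}",
            best_residual=None if best is None else best[0],
        )
    b, c, d = np.exp(best[1])
    return ContingencyTable(a, float(b), float(c), float(d))
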
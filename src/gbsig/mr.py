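"""Two-sample Mendelian randomization with sensitivity analyses.

The causal effect of a plasma protein (exposure) on a binary outcome is
estimated from per-SNP summary statistics: the Wald ratio for a single
instrument, inverse-variance weighting (IVW) for two or more, and -- with at
least three instruments -- the MR-Egger, weighted-median, weighted-mode and
simple-mode sensitivity suite.  Heterogeneity is assessed with Cochran's Q
(IVW and Egger variants), directional pleiotropy with the Egger intercept,
and each protein receives a robustness verdict combining the two tests with
cross-estimator direction consistency.  Standard errors use first-order
(delta) weights that ignore exposure uncertainty, the conventional default
in two-sample MR software.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import NoInstrumentsError, UsageError
from .meta import harmonize_variants

logger = logging.getLogger(__name__)

__all__ = [
    "Instrument",
    "GeneLocus",
    "HarmonizedInstrumentSet",
    "MethodEstimate",
    "SensitivityStats",
    "MRResult",
    "select_instruments",
    "harmonize_exposure_outcome",
    "estimate_effects",
    "heterogeneity_and_pleiotropy",
    "fdr_adjust",
    "robustness_verdict",
    "proteome_scan",
    "overlap_summary",
    "Panel",
]

CIS_WINDOW = 1_000_000  # bp around the encoding gene
P_GENOME_WIDE = 5e-8
F_MIN = 10.0
LD_R2_MAX = 0.1


@dataclass(frozen=True)
class GeneLocus:
    chrom: int
    start: int
    end: int
    gene: str = ""


@dataclass(frozen=True)
class Instrument:
    snp: str
    beta_exp: float
    se_exp: float
    p_exp: float
    beta_out: float
    se_out: float
    p_out: float
    distance_bp: float
    ea: str = "?"
    nea: str = "?"

    @property
    def f_stat(self) -> float:
        return (self.beta_exp / self.se_exp) ** 2

    @property
    def ratio(self) -> float:
        if self.beta_exp == 0:
            raise UsageError(f"Wald ratio undefined for {self.snp}: exposure beta is zero")
        return self.beta_out / self.beta_exp

    @property
    def ratio_se(self) -> float:
        return self.se_out / abs(self.beta_exp)


@dataclass
class HarmonizedInstrumentSet:
    protein: str
    locus: GeneLocus | None
    instruments: tuple[Instrument, ...]
    max_pairwise_r2: float = 0.0

    def __len__(self) -> int:
        return len(self.instruments)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        bx = np.array([i.beta_exp for i in self.instruments])
        sx = np.array([i.se_exp for i in self.instruments])
        by = np.array([i.beta_out for i in self.instruments])
        sy = np.array([i.se_out for i in self.instruments])
        return bx, sx, by, sy


@dataclass(frozen=True)
class MethodEstimate:
    method: str
    beta: float
    se: float
    p: float
    n_snp: int

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)

    @property
    def ci(self) -> tuple[float, float]:
        return math.exp(self.beta - 1.96 * self.se), math.exp(self.beta + 1.96 * self.se)


@dataclass
class SensitivityStats:
    q_ivw: float | None = None
    q_ivw_df: int | None = None
    q_ivw_p: float | None = None
    q_egger: float | None = None
    q_egger_df: int | None = None
    q_egger_p: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None


@dataclass
class MRResult:
    protein: str
    dataset: str = ""
    estimates: dict[str, MethodEstimate] = field(default_factory=dict)
    sensitivity: SensitivityStats = field(default_factory=SensitivityStats)
    fdr_p: float | None = None
    verdict: bool | None = None
    verdict_reasons: list[str] = field(default_factory=list)

    @property
    def primary(self) -> MethodEstimate:
        """IVW when available, otherwise the Wald ratio."""
        return self.estimates.get("ivw") or self.estimates["wald"]


# ---------------------------------------------------------------------------
# instrument selection and harmonization
# ---------------------------------------------------------------------------


def select_instruments(
    exposure: pd.DataFrame,
    locus: GeneLocus | None,
    ld: pd.DataFrame | None = None,
    p_threshold: float = P_GENOME_WIDE,
    f_threshold: float = F_MIN,
    r2_threshold: float = LD_R2_MAX,
    cis_window: int = CIS_WINDOW,
    protein: str = "",
) -> HarmonizedInstrumentSet:
    """Filter exposure SNPs to valid instruments and LD-prune them.

    Filters, in order: cis position (within ``cis_window`` of the locus,
    skipped when *locus* is None, e.g. for a disease exposure in reverse MR),
    genome-wide significance ``P < p_threshold``, strength ``F > f_threshold``
    with ``F = (beta/se)^2``.  Survivors are greedily pruned: keep the
    smallest-p SNP, discard everything with pairwise R-squared at or above
    ``r2_threshold`` against it, repeat.  Raises
    :class:`NoInstrumentsError` when nothing survives.
    """
    df = exposure.copy()
    if locus is not None:
        lo = locus.start - cis_window
        hi = locus.end + cis_window
        df = df[(df["CHR"] == locus.chrom) & (df["BP"] >= lo) & (df["BP"] <= hi)]
    df = df[df["P"] < p_threshold]
    f = (df["BETA"] / df["SE"]) ** 2
    df = df[f > f_threshold]
    if df.empty:
        raise NoInstrumentsError(
            f"protein {protein or '?'}: no SNP passes cis/significance/strength filters"
        )

    df = df.sort_values(["P", "SNP"])
    kept: list[str] = []
    max_r2 = 0.0
    candidates = list(df["SNP"])
    while candidates:
        best = candidates.pop(0)
        kept.append(best)
        if ld is None:
            continue
        still = []
        for snp in candidates:
            r2 = float(ld.at[best, snp]) if (best in ld.index and snp in ld.columns) else 0.0
            if r2 >= r2_threshold:
                continue
            max_r2 = max(max_r2, r2)
            still.append(snp)
        candidates = still

    df = df[df["SNP"].isin(kept)]
    mid = 0.5 * (locus.start + locus.end) if locus is not None else np.nan
    instruments = tuple(
        Instrument(
            snp=row.SNP,
            beta_exp=float(row.BETA),
            se_exp=float(row.SE),
            p_exp=float(row.P),
            beta_out=np.nan,
            se_out=np.nan,
            p_out=np.nan,
            distance_bp=float(row.BP - mid) if locus is not None else 0.0,
            ea=row.EA,
            nea=row.NEA,
        )
        for row in df.itertuples(index=False)
    )
    return HarmonizedInstrumentSet(
        protein=protein, locus=locus, instruments=instruments, max_pairwise_r2=max_r2
    )


def harmonize_exposure_outcome(
    hset: HarmonizedInstrumentSet, outcome: pd.DataFrame
) -> HarmonizedInstrumentSet:
    """Attach allele-aligned outcome effects to the selected instruments.

    Uses the same allele policy as the GWAS harmonizer (sign flip on swapped
    alleles, strand-ambiguous palindromic SNPs dropped).  Instruments absent
    from the outcome are dropped and logged.
    """
    exp_df = pd.DataFrame(
        {
            "SNP": [i.snp for i in hset.instruments],
            "EA": [i.ea for i in hset.instruments],
            "NEA": [i.nea for i in hset.instruments],
            "EAF": np.nan,
            "BETA": [i.beta_exp for i in hset.instruments],
            "SE": [i.se_exp for i in hset.instruments],
        }
    )
    aligned, drop_log = harmonize_variants(exp_df, outcome, how="inner")
    if len(drop_log):
        logger.info("protein %s: %d instrument(s) dropped in harmonization", hset.protein, len(drop_log))
    by_snp = {i.snp: i for i in hset.instruments}
    out: list[Instrument] = []
    for row in aligned.itertuples(index=False):
        base = by_snp[row.SNP]
        out.append(
            Instrument(
                snp=base.snp,
                beta_exp=base.beta_exp,
                se_exp=base.se_exp,
                p_exp=base.p_exp,
                beta_out=float(row.BETA_2),
                se_out=float(row.SE_2),
                p_out=float(getattr(row, "P_2", getattr(row, "P", np.nan))),
                distance_bp=base.distance_bp,
                ea=base.ea,
                nea=base.nea,
            )
        )
    missing = set(by_snp) - {i.snp for i in out}
    if missing:
        logger.info("protein %s: %d instrument(s) absent from outcome", hset.protein, len(missing))
    return HarmonizedInstrumentSet(
        protein=hset.protein,
        locus=hset.locus,
        instruments=tuple(out),
        max_pairwise_r2=hset.max_pairwise_r2,
    )


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


def _normal_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def _ivw(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> tuple[float, float]:
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx**2))
    beta = float(np.sum(w * bx * by)) / denom
    return beta, 1.0 / math.sqrt(denom)


def _egger(
    bx: np.ndarray, by: np.ndarray, sy: np.ndarray
) -> tuple[float, float, float, float, float, float]:
    """MR-Egger via weighted least squares, orienting each SNP so the
    exposure effect is positive.  Returns (slope, slope_se, slope_p,
    intercept, intercept_se, intercept_p) with multiplicative
    overdispersion (phi >= 1) and t(n-2) inference."""
    sign = np.sign(bx)
    x = bx * sign
    y = by * sign
    w = 1.0 / sy**2
    n = len(x)
    X = np.column_stack([np.ones(n), x])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ y)
    resid = y - X @ coef
    phi = max(1.0, float(np.sum(w * resid**2)) / (n - 2))
    cov = phi * np.linalg.inv(xtwx)
    se = np.sqrt(np.diag(cov))
    tdist = stats.t(df=n - 2)
    p = 2.0 * tdist.sf(np.abs(coef / se))
    return coef[1], se[1], float(p[1]), coef[0], se[0], float(p[0])


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w) - 0.5 * w
    if cum[0] >= 0.5:
        return float(r[0])
    if cum[-1] <= 0.5:
        return float(r[-1])
    return float(np.interp(0.5, cum, r))


def _mode_estimate(ratios: np.ndarray, weights: np.ndarray, phi: float = 1.0) -> float:
    """Mode of the smoothed empirical density of ratio estimates
    (normal kernel, modified Silverman bandwidth scaled by phi)."""
    s = np.std(ratios, ddof=1)
    mad = stats.median_abs_deviation(ratios, scale="normal")
    disp = min(s, mad) if mad > 0 else s
    n = len(ratios)
    h = max(phi * 0.9 * disp * n ** (-1 / 5), 1e-12)
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 2048)
    dens = np.zeros_like(grid)
    wn = weights / weights.sum()
    for r, w in zip(ratios, wn):
        dens += w * np.exp(-0.5 * ((grid - r) / h) ** 2)
    return float(grid[np.argmax(dens)])


def _bootstrap_se(
    estimator, ratios: np.ndarray, ratio_ses: np.ndarray, weights: np.ndarray,
    n_boot: int, seed: int,
) -> float:
    rng = np.random.default_rng(seed)
    draws = np.empty(n_boot)
    for b in range(n_boot):
        perturbed = ratios + ratio_ses * rng.standard_normal(len(ratios))
        draws[b] = estimator(perturbed, weights)
    return float(np.std(draws, ddof=1))


def estimate_effects(
    h: HarmonizedInstrumentSet,
    methods: list[str] | None = None,
    n_boot: int = 200,
    seed: int = 0,
    mode_phi: float = 1.0,
) -> dict[str, MethodEstimate]:
    """Run the estimator suite appropriate to the instrument count.

    1 instrument: Wald ratio.  >=2: IVW (fixed-effect weighted regression
    through the origin).  >=3: additionally MR-Egger, weighted median,
    weighted mode and simple mode.  Bootstrap standard errors (parametric,
    seeded) are used for the median/mode estimators.
    """
    n = len(h)
    if n == 0:
        raise NoInstrumentsError(f"protein {h.protein}: no harmonized instruments")
    bx, sx, by, sy = h.arrays()
    if np.any(bx == 0):
        raise UsageError("an instrument has zero exposure beta; Wald ratio undefined")

    wanted = methods
    out: dict[str, MethodEstimate] = {}

    def want(m: str) -> bool:
        return wanted is None or m in wanted

    if n == 1 and want("wald"):
        beta = float(by[0] / bx[0])
        se = float(sy[0] / abs(bx[0]))
        out["wald"] = MethodEstimate("wald", beta, se, _normal_p(beta / se), 1)
    if n >= 2 and want("ivw"):
        beta, se = _ivw(bx, by, sy)
        out["ivw"] = MethodEstimate("ivw", beta, se, _normal_p(beta / se), n)
    if n >= 3:
        ratios = by / bx
        ratio_ses = sy / np.abs(bx)
        inv_var = 1.0 / ratio_ses**2
        if want("egger"):
            slope, se_s, p_s, *_ = _egger(bx, by, sy)
            out["egger"] = MethodEstimate("egger", float(slope), float(se_s), p_s, n)
        if want("weighted_median"):
            beta = _weighted_median(ratios, inv_var)
            se = _bootstrap_se(_weighted_median, ratios, ratio_ses, inv_var, n_boot, seed)
            out["weighted_median"] = MethodEstimate(
                "weighted_median", beta, se, _normal_p(beta / se), n
            )
        if want("weighted_mode"):
            beta = _mode_estimate(ratios, inv_var, mode_phi)
            se = _bootstrap_se(
                lambda r, w: _mode_estimate(r, w, mode_phi), ratios, ratio_ses, inv_var,
                n_boot, seed + 1,
            )
            out["weighted_mode"] = MethodEstimate(
                "weighted_mode", beta, se, _normal_p(beta / se), n
            )
        if want("simple_mode"):
            ones = np.ones_like(ratios)
            beta = _mode_estimate(ratios, ones, mode_phi)
            se = _bootstrap_se(
                lambda r, w: _mode_estimate(r, w, mode_phi), ratios, ratio_ses, ones,
                n_boot, seed + 2,
            )
            out["simple_mode"] = MethodEstimate("simple_mode", beta, se, _normal_p(beta / se), n)
    return out


def heterogeneity_and_pleiotropy(
    h: HarmonizedInstrumentSet, estimates: dict[str, MethodEstimate]
) -> SensitivityStats:
    """Cochran's Q (IVW and Egger flavours) and the Egger intercept test.

    Q = sum w_i (ratio_i - beta)^2 with first-order weights
    ``w_i = beta_x^2 / se_y^2``; chi-square reference with n-1 df for IVW and
    n-2 for Egger.  With fewer instruments than the relevant df the fields
    stay None (not applicable).
    """
    n = len(h)
    out = SensitivityStats()
    if n < 2:
        return out
    bx, sx, by, sy = h.arrays()
    ratios = by / bx
    w = bx**2 / sy**2
    ivw_beta = estimates["ivw"].beta if "ivw" in estimates else _ivw(bx, by, sy)[0]
    q = float(np.sum(w * (ratios - ivw_beta) ** 2))
    out.q_ivw = q
    out.q_ivw_df = n - 1
    out.q_ivw_p = float(stats.chi2.sf(q, n - 1))
    if n >= 3:
        slope, _, _, icept, icept_se, icept_p = _egger(bx, by, sy)
        sign = np.sign(bx)
        resid = by * sign - icept - slope * bx * sign
        q_e = float(np.sum(resid**2 / sy**2))
        out.q_egger = q_e
        out.q_egger_df = n - 2
        out.q_egger_p = float(stats.chi2.sf(q_e, n - 2))
        out.egger_intercept = float(icept)
        out.egger_intercept_se = float(icept_se)
        out.egger_intercept_p = float(icept_p)
    return out


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone in rank)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise UsageError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def robustness_verdict(r: MRResult) -> tuple[bool, list[str]]:
    """Pleiotropy/heterogeneity/consistency verdict for one protein.

    True iff the Egger intercept p > 0.05, Cochran's Q p > 0.05 (both
    vacuously true when too few instruments exist to compute them) and the
    sign of the primary (IVW/Wald) estimate is shared by at least two other
    estimators -- or by all available ones when fewer than three instruments
    limit the suite.
    """
    reasons: list[str] = []
    s = r.sensitivity
    if s.egger_intercept_p is not None and s.egger_intercept_p <= 0.05:
        reasons.append("pleiotropy")
    if s.q_ivw_p is not None and s.q_ivw_p <= 0.05:
        reasons.append("heterogeneity")
    primary = r.primary
    others = [e for m, e in r.estimates.items() if m not in ("ivw", "wald")]
    agree = sum(1 for e in others if np.sign(e.beta) == np.sign(primary.beta))
    needed = 2 if len(others) >= 2 else len(others)
    if agree < needed:
        reasons.append("direction")
    return (not reasons), reasons


# ---------------------------------------------------------------------------
# proteome-wide scan
# ---------------------------------------------------------------------------


@dataclass
class Panel:
    """One protein's exposure summary statistics and gene locus."""

    protein: str
    dataset: str
    exposure: pd.DataFrame
    locus: GeneLocus | None
    ld: pd.DataFrame | None = None


def run_mr(
    panel: Panel,
    outcome: pd.DataFrame,
    p_threshold: float = P_GENOME_WIDE,
    f_threshold: float = F_MIN,
    r2_threshold: float = LD_R2_MAX,
    n_boot: int = 200,
    seed: int = 0,
) -> MRResult:
    """Full single-protein chain: select, harmonize, estimate, sensitivity,
    verdict (FDR is applied at the scan level)."""
    hset = select_instruments(
        panel.exposure, panel.locus, panel.ld,
        p_threshold=p_threshold, f_threshold=f_threshold, r2_threshold=r2_threshold,
        protein=panel.protein,
    )
    hset = harmonize_exposure_outcome(hset, outcome)
    if len(hset) == 0:
        raise NoInstrumentsError(f"protein {panel.protein}: no instrument found in outcome")
    estimates = estimate_effects(hset, n_boot=n_boot, seed=seed)
    sens = heterogeneity_and_pleiotropy(hset, estimates)
    result = MRResult(
        protein=panel.protein, dataset=panel.dataset, estimates=estimates, sensitivity=sens
    )
    result.verdict, result.verdict_reasons = robustness_verdict(result)
    return result


def proteome_scan(
    panels: list[Panel],
    outcome: pd.DataFrame,
    direction: str = "forward",
    fdr_level: float = 0.05,
    p_threshold: float = P_GENOME_WIDE,
    f_threshold: float = F_MIN,
    r2_threshold: float = LD_R2_MAX,
    n_boot: int = 200,
    seed: int = 0,
) -> tuple[list[MRResult], dict]:
    """Run the per-protein chain across exposure panels.

    FDR families are per exposure dataset.  A protein is *significant* when
    its FDR-adjusted primary p < ``fdr_level`` and its robustness verdict is
    true.  ``direction="reverse"`` documents role-swapped panels (disease as
    exposure, proteins as outcomes); the same thresholds apply, with no cis
    restriction expected (locus=None).

    Returns the per-protein results and a summary with per-dataset
    significant sets plus union/intersection counts.
    """
    if direction not in ("forward", "reverse"):
        raise UsageError(f"unknown direction {direction!r}")
    results: list[MRResult] = []
    for k, panel in enumerate(panels):
        try:
            results.append(
                run_mr(
                    panel, outcome,
                    p_threshold=p_threshold, f_threshold=f_threshold,
                    r2_threshold=r2_threshold, n_boot=n_boot, seed=seed + k,
                )
            )
        except NoInstrumentsError as exc:
            logger.info("skipped: %s", exc)

    for dataset in sorted({r.dataset for r in results}):
        group = [r for r in results if r.dataset == dataset]
        adj = fdr_adjust([r.primary.p for r in group])
        for r, q in zip(group, adj):
            r.fdr_p = float(q)

    sig_sets = {
        ds: {r.protein for r in results if r.dataset == ds and r.fdr_p < fdr_level and r.verdict}
        for ds in sorted({r.dataset for r in results})
    }
    summary = {"direction": direction, "per_dataset": {ds: sorted(s) for ds, s in sig_sets.items()}}
    if len(sig_sets) == 2:
        (da, sa), (db, sb) = sig_sets.items()
        summary.update(overlap_summary(sa, sb, da, db))
    else:
        all_sig = set().union(*sig_sets.values()) if sig_sets else set()
        summary["n_union"] = len(all_sig)
    return results, summary


def overlap_summary(set_a, set_b, name_a: str = "A", name_b: str = "B") -> dict:
    """Counts of two significant-protein sets and their overlap/union."""
    set_a, set_b = set(set_a), set(set_b)
    return {
        f"n_{name_a}": len(set_a),
        f"n_{name_b}": len(set_b),
        "n_shared": len(set_a & set_b),
        "n_union": len(set_a | set_b),
        "shared": sorted(set_a & set_b),
    }


def results_table(results: list[MRResult]) -> pd.DataFrame:
    """One row per protein per method, with ORs, CIs and sensitivity stats."""
    rows = []
    for r in results:
        for m, e in r.estimates.items():
            lo, hi = e.ci
            rows.append(
                {
                    "protein": r.protein,
                    "dataset": r.dataset,
                    "method": m,
                    "n_snp": e.n_snp,
                    "beta": e.beta,
                    "se": e.se,
                    "p": e.p,
                    "OR": e.odds_ratio,
                    "OR_low": lo,
                    "OR_high": hi,
                    "q_ivw_p": r.sensitivity.q_ivw_p,
                    "egger_intercept_p": r.sensitivity.egger_intercept_p,
                    "fdr_p": r.fdr_p,
                    "verdict": r.verdict,
                }
            )
    return pd.DataFrame(rows)
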
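"""Synthetic inputs with the statistical structure the pipeline assumes.

Four generators cover the four data families the analysis consumes:

* :func:`gen_reports` -- spontaneous-report tables (DEMO/DRUG/REAC/INDI) with
  planted drug-event signals at a target relative reporting ratio (RRR),
  realistic demographic margins and injected duplicate case versions;
* :func:`gen_gwas_pair` -- two GWAS summary-statistic sets sharing true SNP
  effects, with effect alleles randomly swapped between studies to exercise
  harmonization;
* :func:`gen_pqtl_study` -- per-protein cis-instrument summary statistics with
  a known causal effect on the outcome, optional pleiotropy and an LD block
  structure;
* :func:`gen_network_fixtures` -- a scored protein-interaction edge list with
  planted cross-set edges, a GMT pathway collection and a gene-by-tissue
  expression matrix.

All generators are deterministic under a fixed seed: identical configs give
byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "ReportSimConfig",
    "GwasSimConfig",
    "StudyArm",
    "PqtlSimConfig",
    "gen_reports",
    "gen_gwas_pair",
    "gen_pqtl_study",
    "gen_network_fixtures",
    "write_faers_tables",
    "write_reports_tsv",
    "default_report_config",
    "GWAS_COLUMNS",
]

GWAS_COLUMNS = ["SNP", "CHR", "BP", "EA", "NEA", "EAF", "BETA", "SE", "P", "N"]

_QUARTERS = [f"{y}Q{q}" for y in range(2004, 2024) for q in (1, 2, 3, 4)] + ["2024Q1", "2024Q2"]

# Demographic margins mirror the composition of a large spontaneous-report
# extract: roughly half male, a quarter elderly, a quarter of ages missing,
# physicians the most common reporter, US the most common origin.
_DEFAULT_DEMOGRAPHICS: dict[str, dict[str, float]] = {
    "sex": {"Female": 0.3886, "Male": 0.4998, "Unknown": 0.1116},
    "age_group": {"<=18": 0.0386, "19-40": 0.1229, "41-64": 0.3131, ">=65": 0.2496, "Unknown": 0.2758},
    "reporter": {"Physician": 0.4101, "Consumer": 0.1935, "Others": 0.3490, "Unknown": 0.0474},
    "country": {
        "United States": 0.2494,
        "France": 0.0650,
        "United Kingdom": 0.0491,
        "Japan": 0.1300,
        "Germany": 0.1303,
        "Canada": 0.1300,
        "Unknown": 0.2462,
    },
}

_AGE_RANGES = {"<=18": (0.0, 18.0), "19-40": (19.0, 40.0), "41-64": (41.0, 64.0), ">=65": (65.0, 95.0)}

_DEFAULT_INDICATIONS = [
    "Rheumatoid arthritis",
    "Psoriasis",
    "Plasma cell myeloma",
    "Multiple sclerosis",
    "Malignant melanoma",
    "Crohn's disease",
    "Immunosuppression",
    "Urinary tract infection",
]


def _check_distribution(name: str, dist: dict[str, float]) -> None:
    if not dist:
        raise ConfigurationError(f"{name} distribution is empty")
    if any(p < 0 for p in dist.values()):
        raise ConfigurationError(f"{name} distribution has negative mass")
    if abs(sum(dist.values()) - 1.0) > 1e-9:
        raise ConfigurationError(f"{name} probabilities must sum to 1 within 1e-9")


@dataclass
class ReportSimConfig:
    """Configuration of the spontaneous-report generator.

    ``drugs`` maps drug names to relative background-use weights (normalized
    internally); ``events`` maps preferred terms to per-report occurrence
    probabilities.  Each ``planted_signals`` entry ``(drug, event, rrr)``
    tilts the event probability in reports containing the drug so that the
    expected relative reporting ratio a*N/((a+b)(a+c)) equals ``rrr``.
    """

    n_reports: int
    drugs: dict[str, float]
    events: dict[str, float]
    planted_signals: list[tuple[str, str, float]] = field(default_factory=list)
    demographic_mix: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_DEMOGRAPHICS.items()}
    )
    indications: list[str] = field(default_factory=lambda: list(_DEFAULT_INDICATIONS))
    clear_indication_rate: float = 0.8249
    mean_extra_drugs: float = 1.0  # drugs per case = 1 + Poisson(mean_extra_drugs)
    duplicate_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_reports < 1:
            raise ConfigurationError("n_reports must be >= 1")
        if not self.drugs:
            raise ConfigurationError("at least one drug is required")
        if any(w <= 0 for w in self.drugs.values()):
            raise ConfigurationError("drug weights must be positive")
        if not self.events:
            raise ConfigurationError("at least one event is required")
        if any(not (0 < p < 1) for p in self.events.values()):
            raise ConfigurationError("event probabilities must lie in (0, 1)")
        if not (0 <= self.duplicate_rate < 1):
            raise ConfigurationError("duplicate_rate must lie in [0, 1)")
        if not (0 <= self.clear_indication_rate <= 1):
            raise ConfigurationError("clear_indication_rate must lie in [0, 1]")
        for drug, event, rrr in self.planted_signals:
            if drug not in self.drugs:
                raise ConfigurationError(f"planted signal references unknown drug {drug!r}")
            if event not in self.events:
                raise ConfigurationError(f"planted signal references unknown event {event!r}")
            if rrr <= 0:
                raise ConfigurationError("target relative reporting ratio must be > 0")
        for name, dist in self.demographic_mix.items():
            _check_distribution(name, dist)


def default_report_config(
    n_reports: int = 50_000,
    planted_signals: list[tuple[str, str, float]] | None = None,
    seed: int = 0,
) -> ReportSimConfig:
    """A ready-to-run report scenario: 20 drugs, a rare neurological event
    among a dozen background preferred terms."""
    drugs = {f"Drug{chr(65 + i)}": 1.0 + 0.25 * (i % 5) for i in range(20)}
    events = {"Guillain-Barre syndrome": 0.001}
    for i in range(12):
        events[f"Background event {i + 1}"] = 0.08 + 0.01 * (i % 4)
    return ReportSimConfig(
        n_reports=n_reports,
        drugs=drugs,
        events=events,
        planted_signals=planted_signals or [],
        seed=seed,
    )


def _sample_categorical(rng: np.random.Generator, dist: dict[str, float], n: int) -> np.ndarray:
    cats = np.array(list(dist.keys()))
    probs = np.array(list(dist.values()), dtype=float)
    probs = probs / probs.sum()
    return cats[rng.choice(len(cats), size=n, p=probs)]


def gen_reports(config: ReportSimConfig) -> dict[str, pd.DataFrame]:
    """Generate linked DEMO/DRUG/REAC/INDI tables.

    Cases are built demographics-first; each case receives ``1 + Poisson``
    drugs (distinct, drawn by background weight via Gumbel top-k) and a
    Bernoulli draw per event with probabilities tilted by the planted
    signals, with a weighted fallback event where none fired so every report
    has at least one reaction.  A ``duplicate_rate`` fraction of cases is
    re-emitted as an extra, content-identical case version.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports

    drug_names = list(config.drugs.keys())
    drug_w = np.array([config.drugs[d] for d in drug_names], dtype=float)
    drug_w /= drug_w.sum()
    n_drug_cols = len(drug_names)

    # distinct drugs per case via Gumbel top-k without replacement
    k = 1 + rng.poisson(config.mean_extra_drugs, size=n)
    np.clip(k, 1, n_drug_cols, out=k)
    gumbel = rng.gumbel(size=(n, n_drug_cols))
    scores = np.log(drug_w)[None, :] + gumbel
    order = np.argsort(-scores, axis=1)
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(n_drug_cols)[None, :].repeat(n, 0), axis=1)
    drug_matrix = ranks < k[:, None]  # n x n_drugs membership

    event_names = list(config.events.keys())
    base_p = np.array([config.events[e] for e in event_names], dtype=float)
    event_prob = np.tile(base_p, (n, 1))

    # calibrate the tilt so the expected RRR matches the target given the
    # realized drug prevalence pi: lambda = rrr*(1-pi)/(1-rrr*pi)
    for drug, event, rrr in config.planted_signals:
        di = drug_names.index(drug)
        ei = event_names.index(event)
        pi = float(drug_matrix[:, di].mean())
        if rrr * pi >= 1.0:
            raise ConfigurationError(
                f"target RRR {rrr} unreachable: drug {drug!r} present in fraction {pi:.3f} of reports"
            )
        lam = rrr * (1.0 - pi) / (1.0 - rrr * pi)
        event_prob[drug_matrix[:, di], ei] *= lam
    np.clip(event_prob, 0.0, 0.95, out=event_prob)

    event_matrix = rng.random(size=event_prob.shape) < event_prob
    empty = ~event_matrix.any(axis=1)
    if empty.any():
        # fallback: one event drawn proportionally to the per-case weights,
        # preserving the planted tilt for reports lacking any reaction
        w = event_prob[empty]
        g = rng.gumbel(size=w.shape)
        pick = np.argmax(np.log(w + 1e-300) + g, axis=1)
        event_matrix[np.nonzero(empty)[0], pick] = True

    sex = _sample_categorical(rng, config.demographic_mix["sex"], n)
    age_group = _sample_categorical(rng, config.demographic_mix["age_group"], n)
    reporter = _sample_categorical(rng, config.demographic_mix["reporter"], n)
    country = _sample_categorical(rng, config.demographic_mix["country"], n)
    quarter = np.array(_QUARTERS)[rng.integers(0, len(_QUARTERS), size=n)]

    age = np.full(n, "", dtype=object)
    for label, (lo, hi) in _AGE_RANGES.items():
        mask = age_group == label
        if mask.any():
            age[mask] = np.round(rng.uniform(lo, hi, size=int(mask.sum())), 1).astype(str)

    has_indication = rng.random(n) < config.clear_indication_rate
    indi_choice = np.array(config.indications)[
        rng.integers(0, len(config.indications), size=n)
    ]

    case_ids = np.array([f"C{i:08d}" for i in range(n)])
    dup_mask = rng.random(n) < config.duplicate_rate

    def long_table(case_idx: np.ndarray, columns: dict[str, np.ndarray]) -> pd.DataFrame:
        """Emit version-0 rows plus an identical version-1 copy for
        duplicated cases."""
        dup_rows = np.nonzero(dup_mask[case_idx])[0]
        idx = np.concatenate([np.arange(len(case_idx)), dup_rows])
        version = np.concatenate(
            [np.zeros(len(case_idx), dtype=int), np.ones(len(dup_rows), dtype=int)]
        )
        data = {"caseid": case_ids[case_idx[idx]], "caseversion": version}
        for name, values in columns.items():
            data[name] = values[idx]
        return pd.DataFrame(data)

    demo = long_table(
        np.arange(n),
        {
            "quarter": quarter,
            "sex": sex,
            "age": age,
            "reporter": reporter,
            "country": country,
        },
    )

    d_case, d_col = np.nonzero(drug_matrix)
    first_drug = drug_matrix.argmax(axis=1)
    roles = np.where(d_col == first_drug[d_case], "PS", "SS")
    drug_tbl = long_table(
        d_case, {"drugname": np.array(drug_names)[d_col], "role_cod": roles}
    )

    e_case, e_col = np.nonzero(event_matrix)
    reac = long_table(e_case, {"pt": np.array(event_names)[e_col]})

    i_case = np.nonzero(has_indication)[0]
    indi = long_table(i_case, {"indi_pt": indi_choice[i_case]})

    tables = {"DEMO": demo, "DRUG": drug_tbl, "REAC": reac, "INDI": indi}
    for t in tables.values():
        t.sort_values(list(t.columns[:2]), inplace=True, kind="mergesort")
        t.reset_index(drop=True, inplace=True)
    return tables


def write_faers_tables(tables: dict[str, pd.DataFrame], outdir) -> None:
    """Write the four linked tables as ``$``-delimited ASCII files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.txt", sep="$", index=False, lineterminator="\n")


def write_reports_tsv(tables: dict[str, pd.DataFrame], path) -> None:
    """Flatten the linked tables into the single-table TSV dialect."""
    demo = tables["DEMO"].copy()
    key = ["caseid", "caseversion"]

    def packed(df: pd.DataFrame, fmt) -> pd.Series:
        return df.groupby(key, sort=False).apply(fmt, include_groups=False)

    drugs = packed(tables["DRUG"], lambda g: ";".join(f"{n}:{r}" for n, r in zip(g.drugname, g.role_cod)))
    reacs = packed(tables["REAC"], lambda g: ";".join(g.pt))
    indis = packed(tables["INDI"], lambda g: ";".join(g.indi_pt)) if len(tables["INDI"]) else pd.Series(dtype=object)

    demo = demo.set_index(key)
    flat = pd.DataFrame(
        {
            "case_id": [i[0] for i in demo.index],
            "case_version": [i[1] for i in demo.index],
            "quarter": demo["quarter"].values,
            "sex": demo["sex"].values,
            "age_years": demo["age"].values,
            "reporter": demo["reporter"].values,
            "country": demo["country"].values,
            "drugs": drugs.reindex(demo.index).fillna("").values,
            "reactions": reacs.reindex(demo.index).fillna("").values,
            "indications": indis.reindex(demo.index).fillna("Unknown").values if len(indis) else "Unknown",
        }
    )
    flat.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# GWAS pair
# ---------------------------------------------------------------------------

_NONPALINDROMIC = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "A")]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class StudyArm:
    """Case/control sizes of one GWAS study."""

    n_cases: int
    n_controls: int

    @property
    def n(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def n_eff(self) -> float:
        return 4.0 / (1.0 / self.n_cases + 1.0 / self.n_controls)


@dataclass
class GwasSimConfig:
    """Two binary-trait GWAS sets sharing true log-odds effects.

    Default sample sizes mirror a small-case biobank pairing (155/361,039 and
    489/445,865).  ``frac_nonnull`` SNPs carry effects drawn with scale
    ``effect_scale``; a ``swap_rate`` fraction of study-2 rows has effect and
    other alleles swapped (with sign/EAF adjusted) and ``palindromic_rate``
    of SNPs get strand-ambiguous alleles, both to exercise harmonization.
    """

    n_snps: int = 10_000
    study1: StudyArm = field(default_factory=lambda: StudyArm(155, 361_039))
    study2: StudyArm = field(default_factory=lambda: StudyArm(489, 445_865))
    frac_nonnull: float = 0.0
    effect_scale: float = 0.5
    eaf_range: tuple[float, float] = (0.05, 0.95)
    swap_rate: float = 0.5
    palindromic_rate: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_snps < 1:
            raise ConfigurationError("n_snps must be >= 1")
        lo, hi = self.eaf_range
        if not (0.0 < lo < hi < 1.0):
            raise ConfigurationError("allele frequencies must lie strictly inside (0, 1)")
        if not (0.0 <= self.frac_nonnull <= 1.0):
            raise ConfigurationError("frac_nonnull must lie in [0, 1]")
        for arm in (self.study1, self.study2):
            if arm.n_cases <= 0 or arm.n_controls <= 0:
                raise ConfigurationError("study sample sizes must be positive")


def _study_table(
    rng: np.random.Generator,
    snp: np.ndarray,
    chrom: np.ndarray,
    bp: np.ndarray,
    ea: np.ndarray,
    nea: np.ndarray,
    eaf: np.ndarray,
    beta_true: np.ndarray,
    arm: StudyArm,
) -> pd.DataFrame:
    from scipy import stats

    se = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * arm.n_eff)
    beta = beta_true + se * rng.standard_normal(len(snp))
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return pd.DataFrame(
        {
            "SNP": snp,
            "CHR": chrom,
            "BP": bp,
            "EA": ea,
            "NEA": nea,
            "EAF": eaf,
            "BETA": beta,
            "SE": se,
            "P": np.clip(p, np.nextafter(0, 1), 1.0),
            "N": arm.n,
        }
    )


def gen_gwas_pair(config: GwasSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two summary-statistic tables over the same SNPs and true effects."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    m = config.n_snps

    snp = np.array([f"rs{i + 1:07d}" for i in range(m)])
    chrom = rng.integers(1, 23, size=m)
    bp = rng.integers(1, 250_000_001, size=m)
    lo, hi = config.eaf_range
    eaf = rng.uniform(lo, hi, size=m)

    pal = rng.random(m) < config.palindromic_rate
    pairs = np.array(_NONPALINDROMIC, dtype=object)[rng.integers(0, len(_NONPALINDROMIC), size=m)]
    pal_pairs = np.array(_PALINDROMIC, dtype=object)[rng.integers(0, len(_PALINDROMIC), size=m)]
    pairs[pal] = pal_pairs[pal]
    ea = np.array([p[0] for p in pairs])
    nea = np.array([p[1] for p in pairs])

    beta_true = np.zeros(m)
    nonnull = rng.random(m) < config.frac_nonnull
    beta_true[nonnull] = rng.normal(0.0, config.effect_scale, size=int(nonnull.sum()))

    df1 = _study_table(rng, snp, chrom, bp, ea, nea, eaf, beta_true, config.study1)
    df2 = _study_table(rng, snp, chrom, bp, ea, nea, eaf, beta_true, config.study2)

    swap = rng.random(m) < config.swap_rate
    df2.loc[swap, ["EA", "NEA"]] = df2.loc[swap, ["NEA", "EA"]].values
    df2.loc[swap, "BETA"] = -df2.loc[swap, "BETA"]
    df2.loc[swap, "EAF"] = 1.0 - df2.loc[swap, "EAF"]
    return df1, df2


# ---------------------------------------------------------------------------
# pQTL exposure / outcome pair
# ---------------------------------------------------------------------------


@dataclass
class PqtlSimConfig:
    """One protein's cis-instrument panel and a binary outcome.

    Exposure effects are strong by construction (plasma-proteomics scale:
    n = 35,559 by default) so the F > 10 relevance filter is comfortably met;
    ``beta_causal`` is the true log-odds effect of the protein on the
    outcome.  ``pleiotropy`` is one of ``none`` / ``balanced`` /
    ``directional`` with per-SNP direct effects of scale
    ``pleiotropy_scale``.  ``ld_blocks`` lists ``(size, r2)`` pairs; SNPs
    within a block share pairwise R-squared ``r2``.
    """

    n_instruments: int = 50
    beta_causal: float = 0.0
    exposure_scale: float = 0.15
    n_exposure: int = 35_559
    outcome_cases: int = 644
    outcome_controls: int = 806_904
    pleiotropy: str = "none"
    pleiotropy_scale: float = 0.05
    ld_blocks: list[tuple[int, float]] | None = None
    gene_chrom: int = 1
    gene_start: int = 10_000_000
    gene_end: int = 10_050_000
    seed: int = 0

    def validate(self) -> None:
        if self.n_instruments < 1:
            raise ConfigurationError("n_instruments must be >= 1")
        if self.n_exposure <= 0 or self.outcome_cases <= 0 or self.outcome_controls <= 0:
            raise ConfigurationError("sample sizes must be positive")
        if self.pleiotropy not in ("none", "balanced", "directional"):
            raise ConfigurationError(f"unknown pleiotropy model {self.pleiotropy!r}")
        if self.ld_blocks is not None:
            if sum(s for s, _ in self.ld_blocks) != self.n_instruments:
                raise ConfigurationError("ld_blocks sizes must sum to n_instruments")
            if any(not (0.0 <= r2 < 1.0) for _, r2 in self.ld_blocks):
                raise ConfigurationError("within-block R2 must lie in [0, 1)")


def gen_pqtl_study(
    config: PqtlSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Exposure table, outcome table and LD (R-squared) matrix.

    Wald ratios of non-pleiotropic instruments have expectation
    ``beta_causal``; the LD matrix is symmetric positive-semidefinite with
    the configured block structure.
    """
    from scipy import stats

    config.validate()
    rng = np.random.default_rng(config.seed)
    m = config.n_instruments

    snp = np.array([f"rs9{i + 1:06d}" for i in range(m)])
    chrom = np.full(m, config.gene_chrom)
    span = config.gene_end - config.gene_start
    bp = config.gene_start + rng.integers(-span * 4, span * 5, size=m)
    eaf = rng.uniform(0.1, 0.9, size=m)
    pairs = np.array(_NONPALINDROMIC, dtype=object)[rng.integers(0, len(_NONPALINDROMIC), size=m)]
    ea = np.array([p[0] for p in pairs])
    nea = np.array([p[1] for p in pairs])

    # effect alleles oriented to the exposure-increasing direction, the
    # convention under which directional pleiotropy keeps a consistent sign
    beta_x_true = np.abs(
        rng.normal(config.exposure_scale, config.exposure_scale / 4.0, size=m)
    )
    se_x = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * config.n_exposure)
    beta_x = beta_x_true + se_x * rng.standard_normal(m)
    p_x = 2.0 * stats.norm.sf(np.abs(beta_x / se_x))

    alpha = np.zeros(m)
    if config.pleiotropy == "balanced":
        alpha = rng.normal(0.0, config.pleiotropy_scale, size=m)
    elif config.pleiotropy == "directional":
        alpha = rng.normal(config.pleiotropy_scale, config.pleiotropy_scale / 2.0, size=m)

    arm = StudyArm(config.outcome_cases, config.outcome_controls)
    se_y = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * arm.n_eff)
    beta_y = config.beta_causal * beta_x_true + alpha + se_y * rng.standard_normal(m)
    p_y = 2.0 * stats.norm.sf(np.abs(beta_y / se_y))

    exposure = pd.DataFrame(
        {
            "SNP": snp, "CHR": chrom, "BP": bp, "EA": ea, "NEA": nea, "EAF": eaf,
            "BETA": beta_x, "SE": se_x,
            "P": np.clip(p_x, np.nextafter(0, 1), 1.0), "N": config.n_exposure,
        }
    )
    outcome = pd.DataFrame(
        {
            "SNP": snp, "CHR": chrom, "BP": bp, "EA": ea, "NEA": nea, "EAF": eaf,
            "BETA": beta_y, "SE": se_y,
            "P": np.clip(p_y, np.nextafter(0, 1), 1.0), "N": arm.n,
        }
    )

    ld = np.eye(m)
    if config.ld_blocks:
        start = 0
        for size, r2 in config.ld_blocks:
            block = np.full((size, size), r2)
            np.fill_diagonal(block, 1.0)
            ld[start : start + size, start : start + size] = block
            start += size
    ld_df = pd.DataFrame(ld, index=snp, columns=snp)
    return exposure, outcome, ld_df


# ---------------------------------------------------------------------------
# network / enrichment fixtures
# ---------------------------------------------------------------------------


def gen_network_fixtures(
    seed: int = 0,
    n_susceptibility: int = 10,
    n_targets: int = 20,
    n_cross_edges: int = 5,
    n_pathways: int = 6,
    n_tissues: int = 8,
) -> tuple[pd.DataFrame, dict[str, list[str]], pd.DataFrame]:
    """Edge list, GMT gene sets and a gene-by-tissue expression matrix.

    Exactly ``n_cross_edges`` edges connect the susceptibility set to the
    target set (all with scores above the default 400 threshold); one GMT
    pathway contains the full susceptibility set so it enriches maximally;
    each gene gets one designated high-expression tissue.
    """
    rng = np.random.default_rng(seed)
    set_a = [f"GBS{i + 1:03d}" for i in range(n_susceptibility)]
    set_b = [f"TGT{i + 1:03d}" for i in range(n_targets)]

    edges: list[tuple[str, str, int]] = []
    # planted cross edges, biased so the first susceptibility gene is the hub
    a_idx = np.minimum(rng.integers(0, max(n_susceptibility // 2, 1), size=n_cross_edges), n_susceptibility - 1)
    b_idx = rng.choice(n_targets, size=n_cross_edges, replace=False)
    for i, (ai, bi) in enumerate(zip(a_idx, b_idx)):
        edges.append((set_a[int(ai)], set_b[int(bi)], int(rng.integers(500, 1000))))
    # background within-set edges, half of them below the score threshold
    for _ in range(3 * n_targets):
        x, y = rng.choice(n_targets, size=2, replace=False)
        edges.append((set_b[int(x)], set_b[int(y)], int(rng.integers(150, 1000))))
    edge_df = pd.DataFrame(edges, columns=["protein1", "protein2", "combined_score"])
    edge_df.drop_duplicates(subset=["protein1", "protein2"], inplace=True)
    edge_df.reset_index(drop=True, inplace=True)

    universe = set_a + set_b
    gmt: dict[str, list[str]] = {"SUSCEPTIBILITY_CORE": list(set_a)}
    for j in range(n_pathways - 1):
        size = int(rng.integers(4, 10))
        members = list(rng.choice(universe, size=size, replace=False))
        gmt[f"PATHWAY_{j + 1}"] = sorted(members)

    tissues = [f"tissue_{t + 1}" for t in range(n_tissues)]
    expr = rng.uniform(0.0, 2.0, size=(len(universe), n_tissues))
    high = rng.integers(0, n_tissues, size=len(universe))
    expr[np.arange(len(universe)), high] += 8.0
    expr_df = pd.DataFrame(np.round(expr, 4), index=universe, columns=tissues)
    expr_df.index.name = "gene"
    return edge_df, gmt, expr_df
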
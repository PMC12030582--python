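"""Fixed-effect meta-analysis of two GWAS summary-statistic sets.

Tables use the conventional tab-delimited header
``SNP CHR BP EA NEA EAF BETA SE P N`` with betas on the log-odds scale.
Pooling is inverse-variance (effect-size) weighted, the scheme appropriate
when downstream analyses consume pooled betas rather than z-scores.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FormatError

logger = logging.getLogger(__name__)

__all__ = [
    "GWAS_COLUMNS",
    "read_gwas",
    "write_gwas",
    "harmonize_variants",
    "fixed_effect_meta",
    "genomic_lambda",
    "LambdaResult",
    "significant_loci",
    "qq_manhattan_tables",
]

GWAS_COLUMNS = ["SNP", "CHR", "BP", "EA", "NEA", "EAF", "BETA", "SE", "P", "N"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: chi-square(1 df) median, the denominator of the genomic inflation factor
CHI2_1DF_MEDIAN = 0.4549


def read_gwas(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in GWAS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing mandatory column(s) {missing} in {path}")
    return df


def write_gwas(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.6g")


def _complement(allele: str) -> str:
    return "".join(_COMPLEMENT.get(b, b) for b in allele)


def _is_palindromic(ea: str, nea: str) -> bool:
    return len(ea) == 1 and len(nea) == 1 and _COMPLEMENT.get(ea) == nea


def harmonize_variants(
    study1: pd.DataFrame,
    study2: pd.DataFrame,
    palindromic_window: tuple[float, float] = (0.42, 0.58),
    how: str = "outer",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align study-2 effects to study-1 effect alleles.

    Rules, applied per shared SNP id:

    * identical allele pair -> keep as is;
    * swapped (study 2 lists NEA/EA) -> flip the study-2 beta sign and
      complement its EAF;
    * strand-flipped (complementary alleles) -> treated as identical/swapped
      after complementing;
    * palindromic (A/T or C/G) variants whose EAF in either study falls in
      ``palindromic_window`` (or is missing) -> dropped as strand-ambiguous;
    * any other allele combination -> dropped as mismatched.

    Returns ``(aligned, drop_log)``.  With ``how="outer"`` SNPs present in a
    single study are retained with the other study's columns missing, so the
    meta-analysis can pass them through flagged; ``how="inner"`` keeps the
    intersection only.
    """
    lo, hi = palindromic_window
    merged = study1.merge(study2, on="SNP", how=how, suffixes=("_1", "_2"), indicator=True)

    drops: list[tuple[str, str]] = []
    keep = np.ones(len(merged), dtype=bool)
    beta2 = merged.get("BETA_2", pd.Series(np.nan, index=merged.index)).to_numpy(float).copy()
    eaf2 = merged.get("EAF_2", pd.Series(np.nan, index=merged.index)).to_numpy(float).copy()

    both = merged["_merge"].to_numpy() == "both"
    snp_arr = merged["SNP"].to_numpy(object)
    ea1_arr = merged["EA_1"].to_numpy(object)
    nea1_arr = merged["NEA_1"].to_numpy(object)
    ea2_arr = merged["EA_2"].to_numpy(object)
    nea2_arr = merged["NEA_2"].to_numpy(object)
    eaf1_arr = merged.get("EAF_1", pd.Series(np.nan, index=merged.index)).to_numpy(float)

    for i in np.nonzero(both)[0]:
        ea1, nea1, ea2, nea2 = ea1_arr[i], nea1_arr[i], ea2_arr[i], nea2_arr[i]
        if _is_palindromic(ea1, nea1):
            ambiguous = any(
                np.isnan(f) or lo <= f <= hi for f in (eaf1_arr[i], eaf2[i])
            )
            if ambiguous:
                keep[i] = False
                drops.append((snp_arr[i], "palindromic_ambiguous"))
                continue
            # palindromic but frequency-resolvable: complementary spelling is
            # equivalent, so compare on the raw pair and trust EAF agreement
            if (ea2, nea2) == (nea1, ea1):
                beta2[i] = -beta2[i]
                eaf2[i] = 1.0 - eaf2[i]
            elif (ea2, nea2) != (ea1, nea1):
                keep[i] = False
                drops.append((snp_arr[i], "allele_mismatch"))
            continue
        if (ea2, nea2) == (ea1, nea1) or (_complement(ea2), _complement(nea2)) == (ea1, nea1):
            continue
        if (ea2, nea2) == (nea1, ea1) or (_complement(ea2), _complement(nea2)) == (nea1, ea1):
            beta2[i] = -beta2[i]
            eaf2[i] = 1.0 - eaf2[i]
            continue
        keep[i] = False
        drops.append((snp_arr[i], "allele_mismatch"))

    merged["BETA_2"] = beta2
    merged["EAF_2"] = eaf2
    merged["in_study1"] = merged["_merge"].isin(["both", "left_only"])
    merged["in_study2"] = merged["_merge"].isin(["both", "right_only"])
    merged.drop(columns=["_merge"], inplace=True)
    aligned = merged.loc[keep].reset_index(drop=True)
    drop_log = pd.DataFrame(drops, columns=["SNP", "reason"])
    if len(drop_log):
        logger.info("harmonization dropped %d variant(s)", len(drop_log))
    return aligned, drop_log


def fixed_effect_meta(aligned: pd.DataFrame) -> pd.DataFrame:
    """Inverse-variance-weighted fixed-effect pooling.

    ``beta = sum(b_i/se_i^2)/sum(1/se_i^2)``, ``se = 1/sqrt(sum(1/se_i^2))``,
    two-sided normal p.  SNPs present in one study only are passed through
    with their single-study estimate and flagged via ``n_studies``.  Records
    with non-positive standard errors are rejected and logged.
    """
    df = aligned.copy()
    for col in ("SE_1", "SE_2"):
        if col in df.columns:
            bad = df[col].notna() & (df[col] <= 0)
            if bad.any():
                logger.warning("rejecting %d record(s) with non-positive %s", int(bad.sum()), col)
                df.loc[bad, col.replace("SE", "BETA")] = np.nan
                df.loc[bad, col] = np.nan

    w1 = 1.0 / df["SE_1"].to_numpy(float) ** 2
    w2 = 1.0 / df["SE_2"].to_numpy(float) ** 2
    b1 = df["BETA_1"].to_numpy(float)
    b2 = df["BETA_2"].to_numpy(float)
    w1 = np.where(np.isfinite(w1) & np.isfinite(b1), w1, 0.0)
    w2 = np.where(np.isfinite(w2) & np.isfinite(b2), w2, 0.0)
    wsum = w1 + w2
    valid = wsum > 0
    beta = np.where(valid, (np.nan_to_num(b1) * w1 + np.nan_to_num(b2) * w2) / np.where(valid, wsum, 1.0), np.nan)
    se = np.where(valid, 1.0 / np.sqrt(np.where(valid, wsum, 1.0)), np.nan)
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))

    out = pd.DataFrame(
        {
            "SNP": df["SNP"],
            "CHR": df["CHR_1"].fillna(df.get("CHR_2")).astype("Int64") if "CHR_2" in df else df["CHR_1"],
            "BP": df["BP_1"].fillna(df.get("BP_2")).astype("Int64") if "BP_2" in df else df["BP_1"],
            "EA": df["EA_1"].fillna(df.get("EA_2")) if "EA_2" in df else df["EA_1"],
            "NEA": df["NEA_1"].fillna(df.get("NEA_2")) if "NEA_2" in df else df["NEA_1"],
            "BETA": beta,
            "SE": se,
            "P": np.clip(p, np.nextafter(0, 1), 1.0),
            "n_studies": (w1 > 0).astype(int) + (w2 > 0).astype(int),
            "in_study1": w1 > 0,
            "in_study2": w2 > 0,
        }
    )
    return out.loc[valid].reset_index(drop=True)


@dataclass(frozen=True)
class LambdaResult:
    value: float
    n: int
    low_confidence: bool


def genomic_lambda(p_values) -> LambdaResult:
    """Genomic inflation factor: median chi-square over the null median.

    ``lambda = median(qchisq(1 - p, 1)) / 0.4549``, reported to 3 decimals.
    Fewer than 100 p-values yields a low-confidence flag plus a warning.
    """
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    low_conf = len(p) < 100
    if low_conf:
        warnings.warn(
            f"genomic lambda computed from only {len(p)} p-values; estimate is unstable",
            stacklevel=2,
        )
    chi = stats.chi2.isf(p, df=1)
    lam = float(np.median(chi) / CHI2_1DF_MEDIAN)
    return LambdaResult(value=round(lam, 3), n=len(p), low_confidence=low_conf)


def significant_loci(
    meta: pd.DataFrame, threshold: float = 5e-8, merge_window: int = 500_000
) -> pd.DataFrame:
    """Group genome-wide-significant SNPs into loci.

    Hits on the same chromosome are chained into one locus while consecutive
    hits lie within ``merge_window`` base pairs.  The lead SNP is the
    smallest-p member.
    """
    hits = meta.loc[meta["P"] < threshold].copy()
    if hits.empty:
        return pd.DataFrame(
            columns=["locus", "CHR", "start", "end", "n_snps", "lead_snp", "lead_p"]
        )
    hits.sort_values(["CHR", "BP"], inplace=True)
    loci: list[dict] = []
    current: list[pd.Series] = []

    def flush() -> None:
        if not current:
            return
        block = pd.DataFrame(current)
        lead = block.loc[block["P"].idxmin()]
        loci.append(
            {
                "locus": len(loci) + 1,
                "CHR": int(lead["CHR"]),
                "start": int(block["BP"].min()),
                "end": int(block["BP"].max()),
                "n_snps": len(block),
                "lead_snp": lead["SNP"],
                "lead_p": float(lead["P"]),
            }
        )

    prev_chr: int | None = None
    prev_bp: int | None = None
    for _, row in hits.iterrows():
        if prev_chr is not None and (row["CHR"] != prev_chr or row["BP"] - prev_bp > merge_window):
            flush()
            current = []
        current.append(row)
        prev_chr, prev_bp = row["CHR"], row["BP"]
    flush()
    return pd.DataFrame(loci)


def qq_manhattan_tables(meta: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plot-ready QQ and Manhattan tables.

    QQ: observed ``-log10 p`` sorted descending against expected quantiles
    ``-log10((i - 0.5)/n)``.  Manhattan: per-SNP ``-log10 p`` over a
    cumulative genome coordinate.
    """
    if meta.empty:
        return (
            pd.DataFrame(columns=["expected", "observed"]),
            pd.DataFrame(columns=["SNP", "CHR", "BP", "cum_pos", "neglog10p"]),
        )
    p = np.sort(meta["P"].to_numpy(float))
    n = len(p)
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    observed = -np.log10(p)
    qq = pd.DataFrame({"expected": expected, "observed": observed})

    man = meta[["SNP", "CHR", "BP", "P"]].copy()
    man.sort_values(["CHR", "BP"], inplace=True)
    offsets: dict[int, int] = {}
    cum = 0
    for chrom, group in man.groupby("CHR", sort=True):
        offsets[chrom] = cum
        cum += int(group["BP"].max()) + 1
    man["cum_pos"] = man["BP"] + man["CHR"].map(offsets)
    man["neglog10p"] = -np.log10(man["P"])
    man.drop(columns=["P"], inplace=True)
    return qq, man.reset_index(drop=True)
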
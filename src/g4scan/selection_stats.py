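"""Population-genetic comparison suite for rG4-altering variants.

Variant tables are pandas DataFrames with the documented column dictionary:

    variant_id  str     unique key
    maf         float   alternate allele frequency in [0, 1]
    an          int     observed allele count
    constraint_z float  genomic constraint Z-score (matching covariate)
    cadd_raw    float   raw CADD deleteriousness score
    region      str     FIVE_UTR | THREE_UTR
    category    str     BREAKING | NON_BREAKING | FORMING | OTHER
    subtype     str     rG4 subtype of the host motif
    rg4_length  float   host rG4 length in nt
    delta       float   delta prediction score of the variant
    clinsig     str     BENIGN | PATHOGENIC (optional)

Depressed allele frequency (or an excess of rare alleles) in a variant
class is read as negative selection; groups are compared after matching on
constraint-score quartiles so that constraint differences do not confound
the frequency contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

MAX_SEQUENCED_ALLELES = 152_312

VARIANT_COLUMNS = ["variant_id", "maf", "an", "constraint_z", "cadd_raw",
                   "region", "category", "subtype", "rg4_length", "delta",
                   "clinsig"]


def filter_call_rate(rows: pd.DataFrame,
                     max_alleles: int = MAX_SEQUENCED_ALLELES,
                     frac: float = 0.8) -> pd.DataFrame:
    """Keep variants with allele count >= frac x the sequencing maximum."""
    return rows[rows["an"] >= frac * max_alleles].copy()


def constraint_matched_sample(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    n_bins: int = 4,
    seed: int = 0,
    column: str = "constraint_z",
) -> pd.DataFrame:
    """Subsample group_b to match group_a's constraint-quartile occupancy.

    Quartile boundaries come from group_a's empirical quantiles, ties going
    to the lower bin; from each occupied bin, exactly group_a's count is
    drawn from group_b without replacement. An occupied bin that group_b
    cannot fill raises an error naming the bin.
    """
    if group_a.empty or group_b.empty:
        raise ValueError("both groups must be non-empty")
    rng = np.random.default_rng(seed)
    edges = np.quantile(group_a[column], np.linspace(0, 1, n_bins + 1)[1:-1])
    bins_a = np.searchsorted(edges, group_a[column].to_numpy(), side="left")
    bins_b = np.searchsorted(edges, group_b[column].to_numpy(), side="left")
    pieces = []
    for b in range(n_bins):
        need = int((bins_a == b).sum())
        if need == 0:
            continue
        pool = group_b.index[bins_b == b]
        if len(pool) < need:
            raise ValueError(
                f"group_b has {len(pool)} variants in constraint bin {b}, "
                f"need {need}")
        take = rng.choice(len(pool), size=need, replace=False)
        pieces.append(group_b.loc[pool[np.sort(take)]])
    return pd.concat(pieces)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    n_a: int
    n_b: int
    test: str


def compare_maf(breaking, nonbreaking, test: str = "ks") -> TestResult:
    """One-tailed test of 'breaking MAFs stochastically smaller'.

    ``test`` is ``"ks"`` (one-tailed Kolmogorov-Smirnov, D statistic) or
    ``"mwu"`` (one-tailed Mann-Whitney U).
    """
    a = np.asarray(breaking, dtype=float)
    b = np.asarray(nonbreaking, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need >= 2 observations")
    if test == "ks":
        # ECDF of the breaking group lies above when its values are smaller
        res = stats.ks_2samp(a, b, alternative="greater")
    elif test == "mwu":
        res = stats.mannwhitneyu(a, b, alternative="less")
    else:
        raise ValueError(f"unknown test {test!r}")
    return TestResult(float(res.statistic), float(res.pvalue), len(a), len(b), test)


def rare_fraction(maf, threshold: float = 0.001) -> float:
    """Fraction of variants with MAF strictly below the rare threshold."""
    maf = np.asarray(maf, dtype=float)
    if maf.size == 0:
        raise ValueError("empty input")
    return float((maf < threshold).mean())


def length_stratify(rows: pd.DataFrame, short_max: float = 22,
                    long_min: float = 28) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Short (<= short_max nt) and long (>= long_min nt) strata; lengths in
    between are excluded from both."""
    length = rows["rg4_length"]
    return rows[length <= short_max].copy(), rows[length >= long_min].copy()


def cadd_bin_trend(rows: pd.DataFrame, n_bins: int = 10) -> pd.DataFrame:
    """Mean +/- SD of the delta score per equal-width raw-CADD bin; empty
    bins are absent from the output."""
    cadd = rows["cadd_raw"].to_numpy(dtype=float)
    delta = rows["delta"].to_numpy(dtype=float)
    edges = np.linspace(cadd.min(), cadd.max(), n_bins + 1)
    idx = np.clip(np.digitize(cadd, edges[1:-1]), 0, n_bins - 1)
    out = []
    for b in range(n_bins):
        sel = idx == b
        if not sel.any():
            continue
        out.append({
            "bin": b,
            "cadd_low": edges[b], "cadd_high": edges[b + 1],
            "mean_delta": float(delta[sel].mean()),
            "sd_delta": float(delta[sel].std(ddof=0)),
            "n": int(sel.sum()),
        })
    return pd.DataFrame(out)


def subtype_distribution_shift(counts_a: dict[str, int],
                               counts_b: dict[str, int]) -> TestResult:
    """Chi-square test on the 2xK contingency of two subtype count vectors.
    Categories with zero combined count are dropped with a warning."""
    cats = sorted(set(counts_a) | set(counts_b))
    a = np.array([counts_a.get(c, 0) for c in cats], dtype=float)
    b = np.array([counts_b.get(c, 0) for c in cats], dtype=float)
    keep = (a + b) > 0
    if keep.sum() < len(cats):
        import warnings

        warnings.warn(f"dropping {len(cats) - int(keep.sum())} empty "
                      "categories", stacklevel=2)
    a, b = a[keep], b[keep]
    if len(a) < 2:
        raise ValueError("need at least two non-empty categories")
    if np.array_equal(a, b):
        return TestResult(0.0, 1.0, int(a.sum()), int(b.sum()), "chi2")
    chi2, p, _, _ = stats.chi2_contingency(np.vstack([a, b]))
    return TestResult(float(chi2), float(p), int(a.sum()), int(b.sum()), "chi2")


@dataclass
class GroupComparison:
    omnibus_statistic: float
    omnibus_p: float
    method: str
    pairwise: pd.DataFrame  # columns: group_a, group_b, statistic, p_adjusted


def delta_by_subtype_test(groups: dict[str, np.ndarray],
                          method: str = "welch") -> GroupComparison:
    """Omnibus + post hoc comparison of delta scores across subtypes.

    ``method="welch"``: Welch's ANOVA with Games-Howell pairwise contrasts
    (heteroscedastic groups). ``method="dunn"``: Kruskal-Wallis omnibus with
    Dunn's rank test, Benjamini-Hochberg adjusted — the rank-based route
    used for MAF-by-subtype contrasts. The two adjustment styles are never
    mixed.
    """
    names = sorted(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    for name in names:
        if len(groups[name]) < 3:
            raise ValueError(f"group {name!r} has fewer than 3 observations")
    long = pd.DataFrame({
        "value": np.concatenate([np.asarray(groups[n], float) for n in names]),
        "group": np.concatenate([[n] * len(groups[n]) for n in names]),
    })
    if method == "welch":
        if all(np.ptp(groups[n]) == 0 for n in names) and \
           len({float(np.mean(groups[n])) for n in names}) == 1:
            # all groups constant and equal: no effect by construction
            pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
            pw = pd.DataFrame([{"group_a": a, "group_b": b,
                                "statistic": 0.0, "p_adjusted": 1.0}
                               for a, b in pairs])
            return GroupComparison(0.0, 1.0, "welch+games-howell", pw)
        aov = pg.welch_anova(data=long, dv="value", between="group")
        gh = pg.pairwise_gameshowell(data=long, dv="value", between="group")
        pw = gh.rename(columns={"A": "group_a", "B": "group_b", "T": "statistic",
                                "pval": "p_adjusted"})[
            ["group_a", "group_b", "statistic", "p_adjusted"]]
        return GroupComparison(float(aov["F"][0]), float(aov["p_unc"][0]),
                               "welch+games-howell", pw)
    if method == "dunn":
        samples = [np.asarray(groups[n], float) for n in names]
        H, p = stats.kruskal(*samples)
        pw = _dunn_posthoc(samples, names)
        return GroupComparison(float(H), float(p), "kruskal+dunn-bh", pw)
    raise ValueError(f"unknown method {method!r}")


def _dunn_posthoc(samples: list[np.ndarray], names: list[str]) -> pd.DataFrame:
    """Dunn's z test on mean ranks with tie correction and BH adjustment."""
    from statsmodels.stats.multitest import multipletests

    pooled = np.concatenate(samples)
    N = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes, start = [], [], 0
    for s in samples:
        mean_ranks.append(ranks[start : start + len(s)].mean())
        sizes.append(len(s))
        start += len(s)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (N - 1))
    rows = []
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            se = np.sqrt((N * (N + 1) / 12.0 - tie_term)
                         * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2 * stats.norm.sf(abs(z))
            rows.append({"group_a": names[i], "group_b": names[j],
                         "statistic": float(z), "p": float(p)})
    df = pd.DataFrame(rows)
    df["p_adjusted"] = multipletests(df["p"], method="fdr_bh")[1]
    return df[["group_a", "group_b", "statistic", "p_adjusted"]]


@dataclass
class PathogenicityContrast:
    mwu_statistic: float
    mwu_p: float
    fold_enrichment: float | None  # None when no disrupting rows exist
    binomial_p: float | None
    n_disrupting: int
    n_total: int
    baseline_rate: float


def pathogenicity_contrast(clinvar_rows: pd.DataFrame,
                           disrupt_thr: float = -0.5) -> PathogenicityContrast:
    """Pathogenic-vs-benign contrast of delta scores, plus the fold
    enrichment for pathogenicity among strongly disrupting variants.

    (i) one-sided Mann-Whitney U: pathogenic deltas more negative than
    benign; (ii) fold = P(pathogenic | delta <= disrupt_thr) / P(pathogenic)
    over all rows; (iii) binomial tail probability of the observed
    pathogenic count in the disrupting subset at the baseline rate.
    """
    rows = clinvar_rows.dropna(subset=["clinsig", "delta"])
    path = rows.loc[rows["clinsig"] == "PATHOGENIC", "delta"].to_numpy()
    benign = rows.loc[rows["clinsig"] == "BENIGN", "delta"].to_numpy()
    if len(path) == 0 or len(benign) == 0:
        raise ValueError("need both pathogenic and benign variants")
    mwu = stats.mannwhitneyu(path, benign, alternative="less")
    baseline = len(path) / len(rows)
    disrupting = rows[rows["delta"] <= disrupt_thr]
    if disrupting.empty:
        fold = binom_p = None
    else:
        k = int((disrupting["clinsig"] == "PATHOGENIC").sum())
        n = len(disrupting)
        fold = (k / n) / baseline
        binom_p = float(stats.binomtest(k, n, baseline,
                                        alternative="greater").pvalue)
    return PathogenicityContrast(
        float(mwu.statistic), float(mwu.pvalue), fold, binom_p,
        len(disrupting), len(rows), baseline)
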
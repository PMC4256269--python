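"""Sweep-detection statistics on multi-locus haplotype samples.

Compares allele/haplotype samples taken at different time points:
G-test heterogeneity with iterative swept-allele identification through
adjusted standardized residuals, variance-components F_ST with permutation
significance, allelic and nucleotide diversity, locus-pair linkage
disequilibrium tests, and Holm ("sequential Bonferroni") correction.

All Monte-Carlo p-values use the add-one estimator ``(1 + #{T* >= T}) /
(B + 1)``, which is exactly valid as a test, and take explicit seeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, random_table
from statsmodels.stats.multitest import multipletests

__all__ = [
    "HaplotypeSample",
    "GTestResult",
    "SweptAlleleResult",
    "FstResult",
    "DiversityStats",
    "LdTestResult",
    "SweepReport",
    "allele_counts",
    "count_table",
    "g_heterogeneity",
    "adjusted_residuals",
    "identify_swept_alleles",
    "fst",
    "effective_allele_number",
    "sequence_diversity",
    "ld_significance",
    "sequential_bonferroni",
    "sweep_report",
]

DEFAULT_RESAMPLES = 100_000


@dataclass
class HaplotypeSample:
    """Phased multi-locus haplotypes for n diploid individuals.

    ``haplotypes`` is a wide DataFrame indexed by ``(individual, slot)``
    with ``slot`` in {0, 1} (the two phased chromosomes) and one column per
    locus; entries are allele labels (strings) or NaN for missing.
    ``sequences`` optionally maps locus -> allele label -> aligned sequence,
    enabling nucleotide-diversity statistics.
    """

    sample_id: str
    haplotypes: pd.DataFrame
    sequences: dict[str, dict[str, str]] | None = None

    def __post_init__(self) -> None:
        idx = self.haplotypes.index
        if idx.nlevels != 2:
            raise ValueError("haplotypes index must be (individual, slot)")
        slots = idx.get_level_values(1)
        if not set(slots) <= {0, 1}:
            raise ValueError("slot level must contain only 0 and 1")

    @property
    def loci(self) -> list[str]:
        return list(self.haplotypes.columns)

    @property
    def individuals(self) -> list[str]:
        return list(self.haplotypes.index.get_level_values(0).unique())

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def locus_alleles(self, locus: str) -> pd.Series:
        """Non-missing allele copies at a locus."""
        if locus not in self.haplotypes.columns:
            raise KeyError(f"locus {locus!r} not in sample {self.sample_id!r}")
        return self.haplotypes[locus].dropna()


def allele_counts(sample: HaplotypeSample, locus: str) -> pd.Series:
    """Counts of allele copies at one locus (missing slots excluded)."""
    col = sample.locus_alleles(locus)
    if col.empty:
        warnings.warn(f"no scored alleles at {locus!r} in {sample.sample_id!r}")
    counts = col.value_counts().sort_index()
    counts.name = sample.sample_id
    return counts


def count_table(samples: list[HaplotypeSample], locus: str) -> pd.DataFrame:
    """Samples x alleles count table for one locus (absent alleles 0)."""
    rows = [allele_counts(s, locus) for s in samples]
    tab = pd.DataFrame(rows).fillna(0.0)
    tab.index = [s.sample_id for s in samples]
    return tab


def _g_statistic(obs: np.ndarray) -> tuple[float, int]:
    obs = np.asarray(obs, dtype=float)
    keep = obs.sum(axis=0) > 0
    obs = obs[:, keep]
    n = obs.sum()
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / exp), 0.0)
    g = 2.0 * terms.sum()
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return float(max(g, 0.0)), df


@dataclass
class GTestResult:
    g: float
    df: int
    p_asymptotic: float
    p_monte_carlo: float | None
    residuals: pd.DataFrame
    table: pd.DataFrame
    n_resamples: int | None = None


def adjusted_residuals(table: pd.DataFrame) -> pd.DataFrame:
    """Adjusted standardized residuals of an r x c contingency table.

    Each cell residual ``(O - E)`` is divided by its estimated standard
    error under independence, ``sqrt(E (1 - row/n)(1 - col/n))``, so the
    residuals are approximately standard normal.
    """
    obs = table.to_numpy(dtype=float)
    n = obs.sum()
    r = obs.sum(axis=1) / n
    c = obs.sum(axis=0) / n
    exp = np.outer(r, c) * n
    se = np.sqrt(exp * np.outer(1 - r, 1 - c))
    with np.errstate(divide="ignore", invalid="ignore"):
        res = np.where(se > 0, (obs - exp) / se, 0.0)
    return pd.DataFrame(res, index=table.index, columns=table.columns)


def g_heterogeneity(
    t1_row: pd.Series | np.ndarray,
    t2_row: pd.Series | np.ndarray,
    method: str = "both",
    n_resamples: int = DEFAULT_RESAMPLES,
    seed: int | np.random.Generator | None = None,
) -> GTestResult:
    """G test of allele-frequency heterogeneity between two samples.

    ``G = 2 sum O ln(O/E)`` over non-zero cells; the asymptotic p-value
    uses chi-square with (rows-1)(cols-1) df, and the Monte-Carlo p-value
    resamples tables with both margins fixed (Patefield's algorithm).
    """
    if isinstance(t1_row, pd.Series) or isinstance(t2_row, pd.Series):
        tab = pd.DataFrame([pd.Series(t1_row), pd.Series(t2_row)]).fillna(0.0)
    else:
        tab = pd.DataFrame([t1_row, t2_row])
    tab = tab.loc[:, tab.sum(axis=0) > 0]
    if (tab.sum(axis=1) <= 0).any():
        raise ValueError("each sample must contain at least one scored allele")
    if tab.shape[1] < 2:
        raise ValueError("need >= 2 alleles pooled across samples")

    g, df = _g_statistic(tab.to_numpy())
    p_asym = float(chi2.sf(g, df)) if df > 0 else 1.0
    p_mc = None
    if method in ("both", "monte-carlo"):
        if seed is None:
            raise ValueError("Monte-Carlo method requires an explicit seed")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        rows = tab.sum(axis=1).to_numpy()
        cols = tab.sum(axis=0).to_numpy()
        sims = random_table(rows, cols).rvs(n_resamples, random_state=rng)
        gs = _g_many(np.asarray(sims))
        p_mc = float((1 + (gs >= g - 1e-12).sum()) / (n_resamples + 1))
    elif method != "asymptotic":
        raise ValueError(f"unknown method {method!r}")
    return GTestResult(
        g=g,
        df=df,
        p_asymptotic=p_asym,
        p_monte_carlo=p_mc,
        residuals=adjusted_residuals(tab),
        table=tab,
        n_resamples=n_resamples if p_mc is not None else None,
    )


def _g_many(tables: np.ndarray) -> np.ndarray:
    """G statistics for a (B, r, c) stack of tables with common margins."""
    n = tables[0].sum()
    exp = np.einsum("bi,bj->bij", tables.sum(axis=2), tables.sum(axis=1)) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(tables > 0, tables * np.log(tables / exp), 0.0)
    return 2.0 * terms.sum(axis=(1, 2))


@dataclass
class SweptAlleleResult:
    swept_alleles: list[str]
    homogeneous_after_removal: bool
    steps: list[GTestResult] = field(default_factory=list)


def identify_swept_alleles(
    t1_row: pd.Series,
    t2_row: pd.Series,
    alpha: float = 0.05,
    n_resamples: int = DEFAULT_RESAMPLES,
    seed: int | np.random.Generator | None = None,
    use: str = "asymptotic",
) -> SweptAlleleResult:
    """Iteratively identify the allele(s) driving sample heterogeneity.

    At each step the adjusted standardized residuals of the 2 x k table
    are computed; among alleles whose frequency increased from t1 to t2,
    the one with the largest residual is declared swept and its column
    removed, and the reduced table is retested.  The iteration stops when
    the samples are homogeneous at ``alpha`` or fewer than 3 alleles
    remain.  With only two alleles the procedure is undefined (each allele
    contributes equally to heterogeneity) and an error is raised.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator) or seed is None
        else np.random.default_rng(seed)
    )
    t1 = pd.Series(t1_row, dtype=float)
    t2 = pd.Series(t2_row, dtype=float)
    alleles = sorted(set(t1.index) | set(t2.index))
    t1 = t1.reindex(alleles, fill_value=0.0)
    t2 = t2.reindex(alleles, fill_value=0.0)
    present = (t1 + t2) > 0
    t1, t2 = t1[present], t2[present]
    if len(t1) < 3:
        raise ValueError(
            "swept-allele identification needs >= 3 alleles; with 2 alleles "
            "each contributes equally to heterogeneity"
        )

    def pval(res: GTestResult) -> float:
        return res.p_monte_carlo if use == "monte-carlo" else res.p_asymptotic

    method = "monte-carlo" if use == "monte-carlo" else "asymptotic"
    first = g_heterogeneity(t1, t2, method=method, n_resamples=n_resamples, seed=rng)
    if pval(first) >= alpha:
        raise ValueError(
            f"samples are homogeneous at alpha={alpha} (p={pval(first):.4g}); "
            "no swept allele to identify"
        )

    swept: list[str] = []
    steps = [first]
    cur = first
    homogeneous = False
    while True:
        f1 = cur.table.iloc[0] / cur.table.iloc[0].sum()
        f2 = cur.table.iloc[1] / cur.table.iloc[1].sum()
        increased = f2 > f1
        if not increased.any():
            break
        resid = cur.residuals.iloc[1][increased]
        pick = resid.idxmax()
        swept.append(str(pick))
        remaining = [a for a in cur.table.columns if a != pick]
        if len(remaining) < 3:
            break
        nxt = g_heterogeneity(
            t1[remaining], t2[remaining], method=method,
            n_resamples=n_resamples, seed=rng,
        )
        steps.append(nxt)
        if pval(nxt) >= alpha:
            homogeneous = True
            break
        cur = nxt
    return SweptAlleleResult(swept, homogeneous, steps)


@dataclass
class FstResult:
    theta: float
    p_permutation: float | None
    nei_gst: float
    monomorphic: bool = False
    n_resamples: int | None = None


def _wc_theta(counts: np.ndarray) -> float:
    """Weir-Cockerham-style variance-components F_ST on haploid counts.

    ``counts`` is an (r, k) table of allele-copy counts for r samples.
    Per-allele between- and within-sample mean squares are combined over
    alleles: theta = sum_a sigma2_a / sum_a (sigma2_a + sigma2_w).
    """
    counts = np.asarray(counts, dtype=float)
    r, _ = counts.shape
    n_i = counts.sum(axis=1)
    n_tot = n_i.sum()
    p_i = counts / n_i[:, None]
    p_bar = counts.sum(axis=0) / n_tot
    n_c = (n_tot - (n_i**2).sum() / n_tot) / (r - 1)
    msp = (n_i[:, None] * (p_i - p_bar) ** 2).sum(axis=0) / (r - 1)
    msg = (n_i[:, None] * p_i * (1 - p_i)).sum(axis=0) / (n_tot - r)
    sigma_a = (msp - msg) / n_c
    denom = (sigma_a + msg).sum()
    if denom == 0.0:
        return float("nan")
    return float(sigma_a.sum() / denom)


def _nei_gst(counts: np.ndarray) -> float:
    counts = np.asarray(counts, dtype=float)
    p_i = counts / counts.sum(axis=1, keepdims=True)
    hs = (1 - (p_i**2).sum(axis=1)).mean()
    p_bar = p_i.mean(axis=0)
    ht = 1 - (p_bar**2).sum()
    return float((ht - hs) / ht) if ht > 0 else float("nan")


def fst(
    t1_row: pd.Series | np.ndarray,
    t2_row: pd.Series | np.ndarray,
    n_resamples: int = DEFAULT_RESAMPLES,
    seed: int | np.random.Generator | None = None,
) -> FstResult:
    """F_ST between two samples of allele copies, with permutation p-value.

    The estimator is the haploid-count variance-components (Weir-Cockerham
    style) form; significance comes from permuting allele copies between
    the samples.  A pooled-monomorphic locus has undefined F_ST and is
    flagged.
    """
    tab = pd.DataFrame([pd.Series(t1_row), pd.Series(t2_row)]).fillna(0.0)
    tab = tab.loc[:, tab.sum(axis=0) > 0]
    counts = tab.to_numpy(dtype=float)
    if (counts.sum(axis=1) <= 0).any():
        raise ValueError("both samples must contain scored alleles")
    if counts.shape[1] < 2:
        return FstResult(float("nan"), None, float("nan"), monomorphic=True)
    theta = _wc_theta(counts)
    gst = _nei_gst(counts)
    p_perm = None
    if seed is not None:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        n1 = int(counts[0].sum())
        pool = np.repeat(np.arange(counts.shape[1]), counts.sum(axis=0).astype(int))
        k = counts.shape[1]
        sims = np.empty(n_resamples)
        for b in range(n_resamples):
            rng.shuffle(pool)
            c1 = np.bincount(pool[:n1], minlength=k)
            c2 = np.bincount(pool[n1:], minlength=k)
            sims[b] = _wc_theta(np.vstack([c1, c2]))
        p_perm = float((1 + (sims >= theta - 1e-12).sum()) / (n_resamples + 1))
    return FstResult(theta, p_perm, gst, n_resamples=n_resamples if p_perm else None)


def effective_allele_number(freqs) -> float:
    """Effective number of alleles, A_E = 1 / sum p_i^2."""
    p = np.asarray(freqs, dtype=float)
    if p.size == 0:
        raise ValueError("empty frequency vector")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"frequencies must sum to 1, got {p.sum()}")
    return float(1.0 / (p**2).sum())


@dataclass
class DiversityStats:
    """Per-locus diversity summary for one sample."""

    n_sequences: int
    n_sites: int
    s_sites: int
    n_haplotypes: int
    a_e: float
    hd: float
    k_avg: float
    pi: float
    theta_w: float
    tajima_d: float  # NaN when S = 0


def _drop_gap_columns(seqs: list[str]) -> list[str]:
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("aligned sequences must all have equal length")
    keep = [
        j for j in range(length)
        if all(s[j] not in "-." for s in seqs)
    ]
    return ["".join(s[j] for j in keep) for s in seqs]


def sequence_diversity(seqs: list[str], counts=None) -> DiversityStats:
    """Standard DNA polymorphism statistics on aligned haplotype sequences.

    ``seqs`` are distinct (or repeated) aligned haplotypes; ``counts``
    optionally gives the number of copies of each.  Alignment columns
    containing a gap in any sequence are excluded (indel variation is not
    used).  Returns segregating sites S, number of distinct haplotypes,
    haplotype diversity Hd (with the n/(n-1) sample-size correction),
    average pairwise differences k, per-site pi and Watterson's theta, and
    Tajima's D (NaN when S = 0).
    """
    if not seqs:
        raise ValueError("no sequences supplied")
    counts = [1] * len(seqs) if counts is None else list(counts)
    if len(counts) != len(seqs):
        raise ValueError("counts must match sequences")
    seqs = _drop_gap_columns([s.upper() for s in seqs])
    n = int(sum(counts))
    if n < 2:
        raise ValueError("need at least two sequences")
    sites = len(seqs[0])

    arr = np.array([list(s) for s in seqs])
    w = np.asarray(counts, dtype=float)
    s_sites = 0
    for j in range(sites):
        col = arr[:, j]
        present = w > 0
        if len(set(col[present])) > 1:
            s_sites += 1

    # pairwise differences between distinct haplotypes
    m = len(seqs)
    diff = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            d = sum(a != b for a, b in zip(seqs[i], seqs[j]))
            diff[i, j] = diff[j, i] = d
    pair_w = np.outer(w, w) - np.diag(w)  # ordered pairs of distinct copies
    k_avg = float((pair_w * diff).sum() / (n * (n - 1)))
    pi = k_avg / sites if sites else 0.0

    hap_freq = w / n
    distinct = int((w > 0).sum())
    hd = float(n / (n - 1) * (1.0 - (hap_freq**2).sum()))
    a_e = float(1.0 / (hap_freq**2).sum())

    a1 = float(np.sum(1.0 / np.arange(1, n)))
    theta_w = (s_sites / a1) / sites if sites else 0.0

    if s_sites == 0:
        tajima = float("nan")
    else:
        a2 = float(np.sum(1.0 / np.arange(1, n) ** 2))
        b1 = (n + 1) / (3.0 * (n - 1))
        b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
        c1 = b1 - 1.0 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1 = c1 / a1
        e2 = c2 / (a1**2 + a2)
        var = e1 * s_sites + e2 * s_sites * (s_sites - 1)
        tajima = float((k_avg - s_sites / a1) / np.sqrt(var)) if var > 0 else float("nan")

    return DiversityStats(
        n_sequences=n,
        n_sites=sites,
        s_sites=s_sites,
        n_haplotypes=distinct,
        a_e=a_e,
        hd=hd,
        k_avg=k_avg,
        pi=pi,
        theta_w=theta_w,
        tajima_d=tajima,
    )


@dataclass
class LdTestResult:
    g: float
    df: int
    p: float | None
    monomorphic: bool = False
    n_haplotypes: int = 0


def ld_significance(
    sample: HaplotypeSample,
    locus_a: str,
    locus_b: str,
    n_resamples: int = DEFAULT_RESAMPLES,
    seed: int | np.random.Generator | None = None,
) -> LdTestResult:
    """Permutation test of linkage disequilibrium between two loci.

    The statistic is the log-likelihood-ratio (G) of independence on the
    two-locus haplotype count table; the null distribution is generated by
    permuting the alleles of one locus across haplotypes.  Only the
    significance is reported: the magnitude of LD is not standardized
    across allele-frequency distributions.
    """
    a = sample.locus_alleles(locus_a)
    b = sample.locus_alleles(locus_b)
    both = pd.concat([a, b], axis=1, join="inner").dropna()
    if both.empty:
        return LdTestResult(0.0, 0, None, monomorphic=True)
    av = both.iloc[:, 0].to_numpy()
    bv = both.iloc[:, 1].to_numpy()
    if len(set(av)) < 2 or len(set(bv)) < 2:
        return LdTestResult(0.0, 0, None, monomorphic=True, n_haplotypes=len(av))
    tab = pd.crosstab(av, bv).to_numpy(dtype=float)
    g, df = _g_statistic(tab)
    if seed is None:
        raise ValueError("ld_significance requires an explicit seed")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a_codes = pd.factorize(av)[0]
    b_codes = pd.factorize(bv)[0]
    ka, kb = a_codes.max() + 1, b_codes.max() + 1
    count = 0
    for _ in range(n_resamples):
        perm = rng.permutation(a_codes)
        t = np.zeros((ka, kb))
        np.add.at(t, (perm, b_codes), 1.0)
        gs, _ = _g_statistic(t)
        if gs >= g - 1e-12:
            count += 1
    p = float((1 + count) / (n_resamples + 1))
    return LdTestResult(g, df, p, n_haplotypes=len(av))


def sequential_bonferroni(pvals, alpha: float = 0.05) -> np.ndarray:
    """Holm step-down decisions (the standard 'sequential Bonferroni')."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p, alpha=alpha, method="holm")
    return reject


@dataclass
class SweepReport:
    """Full locus-panel comparison between two time-point samples."""

    pre_id: str
    post_id: str
    alpha: float
    per_locus: pd.DataFrame
    ld: dict[str, pd.DataFrame]
    diversity: pd.DataFrame | None = None


def sweep_report(
    pre: HaplotypeSample,
    post: HaplotypeSample,
    panel: list[str] | None = None,
    alpha: float = 0.05,
    seed: int | None = None,
    n_resamples: int = 10_000,
    ld_loci: list[str] | None = None,
    compute_ld: bool = True,
) -> SweepReport:
    """Per-locus heterogeneity, swept alleles, F_ST, diversity and LD.

    Novel alleles (present post, absent pre) are flagged as candidate
    introduced variants.  Holm correction is applied across the locus panel
    to the Monte-Carlo heterogeneity p-values.
    """
    if panel is None:
        panel = [l for l in pre.loci if l in post.loci]
    if not panel:
        raise ValueError("pre and post samples share no loci")
    missing = [l for l in panel if l not in pre.loci or l not in post.loci]
    if missing:
        raise ValueError(f"panel loci absent from a sample: {missing}")
    if seed is None:
        raise ValueError("sweep_report requires an explicit seed")
    seeds = np.random.SeedSequence(seed).spawn(len(panel) * 2 + 2)

    rows = []
    for i, locus in enumerate(panel):
        c1 = allele_counts(pre, locus)
        c2 = allele_counts(post, locus)
        pooled = set(c1.index) | set(c2.index)
        if len(pooled) < 2:
            rows.append(
                {
                    "locus": locus,
                    "n_pre": int(c1.sum()),
                    "n_post": int(c2.sum()),
                    "g": 0.0,
                    "df": 0,
                    "p_asymptotic": 1.0,
                    "p_monte_carlo": 1.0,
                    "fst": float("nan"),
                    "fst_p": None,
                    "nei_gst": float("nan"),
                    "a_e_pre": 1.0,
                    "a_e_post": 1.0,
                    "swept_alleles": "",
                    "novel_alleles": "",
                }
            )
            continue
        het = g_heterogeneity(
            c1, c2, method="both", n_resamples=n_resamples,
            seed=np.random.default_rng(seeds[2 * i]),
        )
        fres = fst(
            c1, c2, n_resamples=n_resamples,
            seed=np.random.default_rng(seeds[2 * i + 1]),
        )
        novel = sorted(set(c2.index) - set(c1.index))
        f1 = (c1 / c1.sum()).to_numpy()
        f2 = (c2 / c2.sum()).to_numpy()
        swept: list[str] = []
        swept_applicable = len(het.table.columns) >= 3
        if swept_applicable and het.p_monte_carlo < alpha:
            try:
                swept = identify_swept_alleles(c1, c2, alpha=alpha).swept_alleles
            except ValueError:
                swept = []
        rows.append(
            {
                "locus": locus,
                "n_pre": int(c1.sum()),
                "n_post": int(c2.sum()),
                "g": het.g,
                "df": het.df,
                "p_asymptotic": het.p_asymptotic,
                "p_monte_carlo": het.p_monte_carlo,
                "fst": fres.theta,
                "fst_p": fres.p_permutation,
                "nei_gst": fres.nei_gst,
                "a_e_pre": effective_allele_number(f1),
                "a_e_post": effective_allele_number(f2),
                "swept_alleles": ",".join(swept),
                "novel_alleles": ",".join(novel),
            }
        )
    per_locus = pd.DataFrame(rows).set_index("locus")
    per_locus["holm_reject"] = sequential_bonferroni(
        per_locus["p_monte_carlo"], alpha=alpha
    )

    ld: dict[str, pd.DataFrame] = {}
    if compute_ld:
        targets = ld_loci if ld_loci is not None else panel
        for sample, sub_seed in ((pre, seeds[-2]), (post, seeds[-1])):
            rng = np.random.default_rng(sub_seed)
            mat = pd.DataFrame(np.nan, index=targets, columns=targets)
            for x in range(len(targets)):
                for y in range(x + 1, len(targets)):
                    res = ld_significance(
                        sample, targets[x], targets[y],
                        n_resamples=n_resamples, seed=rng,
                    )
                    if res.p is not None:
                        mat.iloc[x, y] = mat.iloc[y, x] = res.p
            ld[sample.sample_id] = mat

    diversity = None
    if pre.sequences and post.sequences:
        div_rows = []
        for sample in (pre, post):
            for locus in panel:
                seq_map = (sample.sequences or {}).get(locus)
                if not seq_map:
                    continue
                counts = allele_counts(sample, locus)
                alleles = [a for a in counts.index if a in seq_map]
                if len(alleles) < 1:
                    continue
                stats = sequence_diversity(
                    [seq_map[a] for a in alleles],
                    [int(counts[a]) for a in alleles],
                )
                div_rows.append(
                    {"sample": sample.sample_id, "locus": locus, **stats.__dict__}
                )
        if div_rows:
            diversity = pd.DataFrame(div_rows)

    return SweepReport(
        pre_id=pre.sample_id,
        post_id=post.sample_id,
        alpha=alpha,
        per_locus=per_locus,
        ld=ld,
        diversity=diversity,
    )
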
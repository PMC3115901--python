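"""Genotype QC and orthogonal two-locus variance decomposition.

The decomposition regresses a quantitative trait on orthogonal additive
and dominance genotype contrasts (Cockerham coding) at two loci plus
their four products, yielding the variance components

    V_A1, V_D1, V_A2, V_D2, V_AA, V_AD, V_DA, V_DD

whose sum equals the regression's explained variance when the predictors
are exactly orthogonal (which the coding guarantees under Hardy-Weinberg
equilibrium and linkage equilibrium).  Epistasis significance is the
joint 4-df F-test of the interaction block; single-SNP heritability is
(V_A + V_D)/V_P from the two-contrast regression.

QC covers allele frequencies, monomorphism, the exact conditional test
for Hardy-Weinberg equilibrium, and two-locus EM haplotype estimation
for pairwise linkage disequilibrium (D, D', r^2).
"""
from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .panel import MISSING, GenotypeMatrix

COMPONENTS = ("A1", "D1", "A2", "D2", "AA", "AD", "DA", "DD")
INTERACTION_COMPONENTS = ("AA", "AD", "DA", "DD")


# ---------------------------------------------------------------------------
# allele statistics
# ---------------------------------------------------------------------------

def allele_stats(G: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP counted-allele frequency, genotype counts and QC flags.

    Missing dosages are excluded from the counts.  A SNP is monomorphic
    when only one genotype class is present among the observed calls; an
    all-missing SNP is flagged (``all_missing``) rather than silently
    dropped and is counted as non-informative.
    """
    rows = []
    for j, snp in enumerate(G.snp_ids):
        g = G.dosages[:, j]
        obs = g[g != MISSING]
        n0 = int(np.sum(obs == 0))
        n1 = int(np.sum(obs == 1))
        n2 = int(np.sum(obs == 2))
        n = n0 + n1 + n2
        all_missing = n == 0
        p = np.nan if all_missing else (n1 + 2 * n2) / (2 * n)
        mono = (not all_missing) and (np.sum(np.array([n0, n1, n2]) > 0) <= 1)
        rows.append({"snp_id": snp, "p": p, "n_0": n0, "n_1": n1, "n_2": n2,
                     "n_called": n, "n_missing": int(np.sum(g == MISSING)),
                     "monomorphic": mono, "all_missing": all_missing,
                     "informative": (not all_missing) and (not mono)})
    return pd.DataFrame(rows).set_index("snp_id")


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n0: int, n1: int, n2: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    ``(n0, n1, n2)`` are counts of the dosage classes 0, 1 and 2.
    Conditional on the observed allele counts, the probability of each
    attainable heterozygote count is evaluated and the p-value is the sum
    of probabilities of tables no more probable than the observed one.
    Monomorphic samples admit a single table, hence p = 1.
    """
    n0, n1, n2 = int(n0), int(n1), int(n2)
    if min(n0, n1, n2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n0 + n1 + n2
    if n == 0:
        raise ValueError("Hardy-Weinberg test needs at least one subject")
    n_a = n1 + 2 * n2          # counted-allele copies
    n_b = n1 + 2 * n0
    if n_a == 0 or n_b == 0:
        return 1.0
    rare = min(n_a, n_b)
    # log P(n_het | n, n_rare) up to a common constant, over attainable
    # heterozygote counts of the same parity as the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    logp = np.empty(len(hets))
    for i, h in enumerate(hets):
        hom_rare = (rare - h) // 2
        hom_comm = n - h - hom_rare
        logp[i] = (math.lgamma(n + 1)
                   - math.lgamma(hom_rare + 1) - math.lgamma(h + 1)
                   - math.lgamma(hom_comm + 1) + h * math.log(2.0))
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs = prob[np.searchsorted(hets, n1)]
    return float(min(1.0, prob[prob <= obs * (1.0 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# two-locus EM linkage disequilibrium
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class LdResult:
    """Pairwise LD estimate from the two-locus haplotype EM."""

    hap_freqs: dict
    D: float
    Dprime: float
    r2: float
    p_value: float
    loglik: float
    n_used: int


def _ld_loglik(f11: float, p_a: float, p_b: float, counts: np.ndarray) -> float:
    """Log-likelihood of the 3x3 genotype table at haplotype freq f11.

    ``counts[i, j]`` is the number of subjects with dosage i at locus A
    and j at locus B.  Margins are fixed at (p_a, p_b).
    """
    f10 = p_a - f11
    f01 = p_b - f11
    f00 = 1.0 - f11 - f10 - f01
    f = np.array([f11, f10, f01, f00])
    if np.any(f < -1e-12):
        return -np.inf
    f = np.clip(f, 1e-300, None)
    f11, f10, f01, f00 = f
    # genotype-class probabilities under random union of haplotypes
    P = np.empty((3, 3))
    P[2, 2] = f11 ** 2
    P[2, 1] = 2 * f11 * f10
    P[2, 0] = f10 ** 2
    P[1, 2] = 2 * f11 * f01
    P[1, 1] = 2 * f11 * f00 + 2 * f10 * f01
    P[1, 0] = 2 * f10 * f00
    P[0, 2] = f01 ** 2
    P[0, 1] = 2 * f01 * f00
    P[0, 0] = f00 ** 2
    logP = np.log(np.clip(P, 1e-300, None))
    return float(np.sum(counts * logP))


def ld_pair(g_a: Sequence[int], g_b: Sequence[int],
            tol: float = 1e-12, max_iter: int = 2000) -> LdResult:
    """Pairwise linkage disequilibrium via two-locus haplotype EM.

    Haplotype frequencies are estimated from unphased genotypes; the
    double heterozygote is split between coupling and repulsion phases by
    the current phase odds.  Returns D, D' and r^2 on the counted
    alleles, and a 1-df likelihood-ratio p-value against independence.
    """
    g_a = np.asarray(g_a)
    g_b = np.asarray(g_b)
    ok = (g_a != MISSING) & (g_b != MISSING)
    g_a, g_b = g_a[ok], g_b[ok]
    n = len(g_a)
    if n == 0:
        raise ValueError("no shared complete-case subjects")
    counts = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            counts[i, j] = np.sum((g_a == i) & (g_b == j))
    p_a = (g_a.sum()) / (2 * n)
    p_b = (g_b.sum()) / (2 * n)
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise ValueError("LD undefined for a monomorphic SNP")

    # EM on f11 (margins are fixed by the observed allele counts)
    f11 = p_a * p_b
    for _ in range(max_iter):
        f10 = p_a - f11
        f01 = p_b - f11
        f00 = 1 - p_a - p_b + f11
        coup = f11 * f00
        rep = f10 * f01
        frac = coup / (coup + rep) if (coup + rep) > 0 else 0.5
        # expected count of A-B haplotypes
        n_ab = (2 * counts[2, 2] + counts[2, 1] + counts[1, 2]
                + frac * counts[1, 1])
        new = n_ab / (2 * n)
        lo = max(0.0, p_a + p_b - 1.0)
        hi = min(p_a, p_b)
        new = min(max(new, lo), hi)
        if abs(new - f11) < tol:
            f11 = new
            break
        f11 = new

    ll1 = _ld_loglik(f11, p_a, p_b, counts)
    ll0 = _ld_loglik(p_a * p_b, p_a, p_b, counts)
    lr = max(0.0, 2.0 * (ll1 - ll0))
    p_value = float(stats.chi2.sf(lr, df=1))
    D = f11 - p_a * p_b
    if D >= 0:
        dmax = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        dmax = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    dprime = 0.0 if dmax == 0 else D / dmax
    r2 = D * D / (p_a * (1 - p_a) * p_b * (1 - p_b))
    freqs = {"AB": f11, "Ab": p_a - f11, "aB": p_b - f11,
             "ab": 1 - p_a - p_b + f11}
    return LdResult(freqs, float(D), float(dprime), float(r2), p_value,
                    ll1, n)


def ld_report(G: GenotypeMatrix) -> pd.DataFrame:
    """HWE/LD QC table: per-SNP stats plus all pairwise LD estimates."""
    st = allele_stats(G)
    informative = [s for s in G.snp_ids if st.loc[s, "informative"]]
    rows = []
    for a, b in itertools.combinations(informative, 2):
        res = ld_pair(G.column(a), G.column(b))
        rows.append({"snp_a": a, "snp_b": b,
                     "gene_a": G.gene_of(a), "gene_b": G.gene_of(b),
                     "intragenic": G.gene_of(a) == G.gene_of(b),
                     "D": res.D, "Dprime": res.Dprime, "r2": res.r2,
                     "p": res.p_value, "n_used": res.n_used})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# orthogonal contrasts (Cockerham coding)
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class OrthogonalScores:
    """Additive and dominance contrast scores for one SNP.

    Under exact HWE weighting the scores have zero mean, zero mutual
    covariance, Var(w_A) = 2pq and Var(w_D) = (pq)^2.  Missing dosages
    map to NaN.
    """

    w_a: np.ndarray
    w_d: np.ndarray
    p: float


def contrast_maps(p: float) -> tuple[np.ndarray, np.ndarray]:
    """Contrast lookup tables indexed by dosage 0, 1, 2."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"monomorphic SNP (p={p}); contrasts undefined")
    q = 1.0 - p
    wa = np.array([-2.0 * p, q - p, 2.0 * q])
    wd = np.array([-p * p, p * q, -q * q])
    return wa, wd


def orthogonal_scores(g: Sequence[int], p: float) -> OrthogonalScores:
    """Cockerham additive/dominance contrast scores for dosage vector ``g``."""
    wa_map, wd_map = contrast_maps(p)
    g = np.asarray(g)
    w_a = np.full(len(g), np.nan)
    w_d = np.full(len(g), np.nan)
    ok = g != MISSING
    w_a[ok] = wa_map[g[ok]]
    w_d[ok] = wd_map[g[ok]]
    return OrthogonalScores(w_a, w_d, float(p))


# ---------------------------------------------------------------------------
# least-squares decomposition core
# ---------------------------------------------------------------------------

def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float]:
    """OLS with intercept; returns slopes and residual sum of squares."""
    n = len(y)
    X1 = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(X1, y, rcond=None)
    resid = y - X1 @ beta
    return beta[1:], float(resid @ resid)


@dataclasses.dataclass
class PairDecomposition:
    """Results of the two-locus orthogonal variance decomposition."""

    snp_a: str
    snp_b: str
    n_used: int
    coefficients: dict
    components: dict          # V_j in trait units^2, keyed by COMPONENTS
    V_P: float
    relative_epistasis: float
    p_epistasis: float
    component_p: dict         # per-term t-test p-values
    h2_a: float
    h2_b: float
    dropped: tuple
    testable: bool
    flags: tuple = ()

    @property
    def V_epistasis(self) -> float:
        return sum(self.components[c] for c in INTERACTION_COMPONENTS)

    @property
    def h2(self) -> dict:
        return {self.snp_a: self.h2_a, self.snp_b: self.h2_b}

    def summary(self) -> str:
        lines = [f"Two-locus decomposition: {self.snp_a} x {self.snp_b}",
                 f"  n = {self.n_used}, V_P = {self.V_P:.6g}",
                 f"  relative epistatic variance = {self.relative_epistasis:.4f}"
                 f"  (joint F p = {self.p_epistasis:.3g})"]
        for c in COMPONENTS:
            lines.append(f"  V_{c:<3} = {self.components[c]:.6g}"
                         f"   (p = {self.component_p.get(c, float('nan')):.3g})")
        if self.dropped:
            lines.append(f"  dropped predictors: {', '.join(self.dropped)}")
        return "\n".join(lines)


class TwoLocusModel:
    """Orthogonal-contrast regression of a trait on a SNP pair.

    Parameters
    ----------
    trait
        Continuous (or 0/1) trait vector.
    g_a, g_b
        Dosage vectors in {0, 1, 2, MISSING}.
    p_a, p_b
        Counted-allele frequencies used in the contrast coding; when
        omitted they are estimated from the complete-case sample (the
        stratum, in a subpopulation scan).
    """

    def __init__(self, trait, g_a, g_b, p_a: float | None = None,
                 p_b: float | None = None, snp_a: str = "snp_a",
                 snp_b: str = "snp_b"):
        self.trait = np.asarray(trait, dtype=float)
        self.g_a = np.asarray(g_a)
        self.g_b = np.asarray(g_b)
        if not len(self.trait) == len(self.g_a) == len(self.g_b):
            raise ValueError("trait and dosage vectors differ in length")
        self.p_a = p_a
        self.p_b = p_b
        self.snp_a = snp_a
        self.snp_b = snp_b

    def fit(self, min_n: int = 20) -> PairDecomposition:
        ok = (np.isfinite(self.trait) & (self.g_a != MISSING)
              & (self.g_b != MISSING))
        y = self.trait[ok]
        ga = self.g_a[ok]
        gb = self.g_b[ok]
        n = len(y)
        flags: list[str] = []
        if n < min_n:
            return self._untestable(n, "insufficient-n")
        p_a = self.p_a if self.p_a is not None else float(ga.mean() / 2)
        p_b = self.p_b if self.p_b is not None else float(gb.mean() / 2)
        if not (0.0 < p_a < 1.0) or not (0.0 < p_b < 1.0):
            return self._untestable(n, "monomorphic")

        sa = orthogonal_scores(ga, p_a)
        sb = orthogonal_scores(gb, p_b)
        cols = {"A1": sa.w_a, "D1": sa.w_d, "A2": sb.w_a, "D2": sb.w_d,
                "AA": sa.w_a * sb.w_a, "AD": sa.w_a * sb.w_d,
                "DA": sa.w_d * sb.w_a, "DD": sa.w_d * sb.w_d}

        # drop predictors that are constant in the analyzed sample
        scale = max(1.0, float(np.max(np.abs(y - y.mean()))) if n else 1.0)
        kept = [c for c in COMPONENTS if np.std(cols[c]) > 1e-12]
        dropped = tuple(c for c in COMPONENTS if c not in kept)
        kept_inter = [c for c in kept if c in INTERACTION_COMPONENTS]
        kept_marg = [c for c in kept if c not in INTERACTION_COMPONENTS]
        if not kept_inter:
            flags.append("no-interaction-predictor")

        V_P = float(np.var(y, ddof=1)) if n > 1 else 0.0
        if V_P <= 0:
            return self._untestable(n, "constant-trait")

        Xf = np.column_stack([cols[c] for c in kept])
        beta, rss_f = _ols(y, Xf)
        df_resid = n - len(kept) - 1
        if df_resid < 1:
            return self._untestable(n, "insufficient-df")

        components = {c: 0.0 for c in COMPONENTS}
        comp_p = {c: np.nan for c in COMPONENTS}
        sigma2 = rss_f / df_resid
        X1 = np.column_stack([np.ones(n), Xf])
        XtX_inv = np.linalg.pinv(X1.T @ X1)
        for i, c in enumerate(kept):
            components[c] = float(np.var(beta[i] * cols[c], ddof=1))
            se = math.sqrt(max(sigma2 * XtX_inv[i + 1, i + 1], 1e-300))
            tval = beta[i] / se
            comp_p[c] = float(2 * stats.t.sf(abs(tval), df_resid))

        # joint F-test of the interaction block
        if kept_inter:
            if kept_marg:
                _, rss_r = _ols(y, np.column_stack([cols[c] for c in kept_marg]))
            else:
                rss_r = float(np.sum((y - y.mean()) ** 2))
            df_num = len(kept_inter)
            F = ((rss_r - rss_f) / df_num) / (rss_f / df_resid)
            p_epi = float(stats.f.sf(max(F, 0.0), df_num, df_resid))
        else:
            p_epi = np.nan

        V_epi = sum(components[c] for c in INTERACTION_COMPONENTS)
        rel = min(1.0, V_epi / V_P)
        h2_a = min(1.0, (components["A1"] + components["D1"]) / V_P)
        h2_b = min(1.0, (components["A2"] + components["D2"]) / V_P)
        coeffs = {c: (float(beta[kept.index(c)]) if c in kept else 0.0)
                  for c in COMPONENTS}
        return PairDecomposition(self.snp_a, self.snp_b, n, coeffs, components,
                                 V_P, rel, p_epi, comp_p, h2_a, h2_b,
                                 dropped, True, tuple(flags))

    def _untestable(self, n: int, reason: str) -> PairDecomposition:
        comps = {c: 0.0 for c in COMPONENTS}
        return PairDecomposition(self.snp_a, self.snp_b, n,
                                 {c: 0.0 for c in COMPONENTS}, comps,
                                 np.nan, np.nan, np.nan,
                                 {c: np.nan for c in COMPONENTS},
                                 np.nan, np.nan, tuple(COMPONENTS), False,
                                 (reason,))


def decompose_pair(trait, g_a, g_b, p_a=None, p_b=None, *, snp_a="snp_a",
                   snp_b="snp_b", min_n: int = 20) -> PairDecomposition:
    """Convenience wrapper: build a :class:`TwoLocusModel` and fit it."""
    return TwoLocusModel(trait, g_a, g_b, p_a, p_b, snp_a, snp_b).fit(min_n)


def single_snp_heritability(trait, g, p: float | None = None,
                            min_n: int = 20) -> float:
    """Single-SNP heritability h^2 = (V_A + V_D)/V_P (a local quantity).

    From the two-contrast regression of the trait on w_A and w_D.
    """
    trait = np.asarray(trait, dtype=float)
    g = np.asarray(g)
    ok = np.isfinite(trait) & (g != MISSING)
    y, gg = trait[ok], g[ok]
    n = len(y)
    if n < min_n:
        raise ValueError(f"only {n} complete cases (minimum {min_n})")
    p = p if p is not None else float(gg.mean() / 2)
    sc = orthogonal_scores(gg, p)
    cols = [c for c in (sc.w_a, sc.w_d) if np.std(c) > 1e-12]
    if not cols:
        raise ValueError("SNP monomorphic in the analyzed sample")
    V_P = float(np.var(y, ddof=1))
    if V_P <= 0:
        raise ValueError("constant trait")
    X = np.column_stack(cols)
    beta, _ = _ols(y, X)
    V = sum(float(np.var(b * x, ddof=1)) for b, x in zip(beta, X.T))
    return min(1.0, V / V_P)


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bonferroni_threshold(alpha: float, n_pairs: int, n_subpops: int,
                         n_traits: int) -> float:
    """Family-wise threshold alpha / (n_pairs * n_subpops * n_traits)."""
    for name, v in (("n_pairs", n_pairs), ("n_subpops", n_subpops),
                    ("n_traits", n_traits)):
        if v < 1:
            raise ValueError(f"{name} must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / (n_pairs * n_subpops * n_traits)


# ---------------------------------------------------------------------------
# subpopulation scan
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ScanResult:
    """All-pairs decomposition over one stratum and one trait."""

    subpop_id: object
    trait_name: str
    n_subjects: int
    alpha_star: float
    table: pd.DataFrame          # one row per candidate pair
    stratum_qc: pd.DataFrame     # per-SNP stratum QC (p, HWE, exclusions)
    n_possible: int              # informative-SNP pairs m(m-1)/2
    flags: tuple = ()

    @property
    def significant(self) -> pd.DataFrame:
        """Significant inter-genic pairs at the scan threshold."""
        t = self.table
        if t.empty:
            return t
        return t[t["testable"] & ~t["intragenic"]
                 & (t["p_epistasis"] <= self.alpha_star)]

    @property
    def n_significant(self) -> int:
        return len(self.significant)

    @property
    def fraction_significant(self) -> float:
        return self.n_significant / self.n_possible if self.n_possible else 0.0

    def snp_degrees(self) -> pd.Series:
        """Number of significant interactions each SNP participates in."""
        sig = self.significant
        if sig.empty:
            return pd.Series(dtype=int)
        return pd.concat([sig["snp_a"], sig["snp_b"]]).value_counts()


_EMPTY_PAIR_COLUMNS = ["snp_a", "snp_b", "gene_a", "gene_b", "intragenic",
                       "n_used", *(f"V_{c}" for c in COMPONENTS),
                       *(f"beta_{c}" for c in COMPONENTS),
                       "V_P", "relative_epistasis", "p_epistasis",
                       "h2_a", "h2_b", "testable", "dropped", "flags"]


def scan_subpopulation(trait, G: GenotypeMatrix, members,
                       alpha_star: float, *, trait_name: str = "trait",
                       subpop_id=0, min_stratum: int = 20, min_pair_n: int = 20,
                       hwe_alpha: float = 0.05,
                       log: list | None = None) -> ScanResult:
    """All-pairs two-locus scan within one stratum.

    Allele frequencies, monomorphism and HWE are re-evaluated inside the
    stratum; SNPs failing the stratum Bonferroni-corrected HWE exact test
    (p < ``hwe_alpha``/m over m informative SNPs) are excluded from the
    decomposition.  Intragenic pairs are computed but flagged and kept
    out of the significant set.  Strata smaller than ``min_stratum``
    return an empty, flagged result.
    """
    members = np.asarray(members)
    if members.dtype == bool:
        idx = np.flatnonzero(members)
    else:
        idx = members.astype(int)
    y = np.asarray(trait, dtype=float)[idx]
    dos = G.dosages[idx]
    n = len(idx)

    def _logrec(**kw):
        if log is not None:
            log.append({"stage": "scan", "subpop": subpop_id,
                        "trait": trait_name, **kw})

    sub = GenotypeMatrix([G.subjects[i] for i in idx], G.panel, dos)
    qc = allele_stats(sub)
    if n < min_stratum:
        _logrec(event="stratum-skipped", reason="insufficient-n", n=n)
        return ScanResult(subpop_id, trait_name, n, alpha_star,
                          pd.DataFrame(columns=_EMPTY_PAIR_COLUMNS), qc, 0,
                          ("insufficient-n",))

    informative = [s for s in sub.snp_ids if qc.loc[s, "informative"]]
    m = len(informative)
    hwe_cut = hwe_alpha / m if m else hwe_alpha
    hwe_p = {}
    eligible = []
    for s in informative:
        r = qc.loc[s]
        pv = hwe_exact_test(r["n_0"], r["n_1"], r["n_2"])
        hwe_p[s] = pv
        if pv < hwe_cut:
            _logrec(event="snp-excluded", snp=s, reason="hwe", p=pv)
        else:
            eligible.append(s)
    qc = qc.assign(hwe_p=[hwe_p.get(s, np.nan) for s in sub.snp_ids],
                   hwe_excluded=[s in informative and s not in eligible
                                 for s in sub.snp_ids])
    for s in sub.snp_ids:
        if not qc.loc[s, "informative"]:
            _logrec(event="snp-excluded", snp=s,
                    reason="all-missing" if qc.loc[s, "all_missing"]
                    else "monomorphic-in-stratum")

    n_possible = m * (m - 1) // 2
    freqs = {s: float(qc.loc[s, "p"]) for s in eligible}

    rows = []
    for a, b in itertools.combinations(eligible, 2):
        dec = TwoLocusModel(y, sub.column(a), sub.column(b),
                            freqs[a], freqs[b], a, b).fit(min_pair_n)
        row = {"snp_a": a, "snp_b": b,
               "gene_a": sub.gene_of(a), "gene_b": sub.gene_of(b),
               "intragenic": sub.gene_of(a) == sub.gene_of(b),
               "n_used": dec.n_used, "V_P": dec.V_P,
               "relative_epistasis": dec.relative_epistasis,
               "p_epistasis": dec.p_epistasis,
               "h2_a": dec.h2_a, "h2_b": dec.h2_b,
               "testable": dec.testable,
               "dropped": ";".join(dec.dropped),
               "flags": ";".join(dec.flags)}
        for c in COMPONENTS:
            row[f"V_{c}"] = dec.components[c]
            row[f"beta_{c}"] = dec.coefficients[c]
        rows.append(row)
    table = pd.DataFrame(rows, columns=_EMPTY_PAIR_COLUMNS) if rows else \
        pd.DataFrame(columns=_EMPTY_PAIR_COLUMNS)
    return ScanResult(subpop_id, trait_name, n, alpha_star, table, qc,
                      n_possible)


def dichotomized_scan(diastolic, systolic, G: GenotypeMatrix,
                      alpha_star: float, thresholds=(90.0, 140.0),
                      **scan_kw) -> tuple[ScanResult, pd.DataFrame]:
    """Case-control contrast: scan a thresholded hypertension indicator.

    The binary trait is 1 when diastolic pressure exceeds
    ``thresholds[0]`` or systolic exceeds ``thresholds[1]`` (office
    140/90 mmHg definition by default).  The same orthogonal
    decomposition is applied to the 0/1 trait; a per-SNP heritability
    table accompanies the scan.
    """
    dia = np.asarray(diastolic, dtype=float)
    sys_ = np.asarray(systolic, dtype=float)
    binary = ((dia > thresholds[0]) | (sys_ > thresholds[1])).astype(float)
    binary[~(np.isfinite(dia) & np.isfinite(sys_))] = np.nan
    obs = binary[np.isfinite(binary)]
    if len(obs) == 0 or obs.min() == obs.max():
        raise ValueError("dichotomization produced an all-case or "
                         "all-control sample")
    scan_kw.setdefault("trait_name", "hypertension")
    res = scan_subpopulation(binary, G, np.arange(G.n_subjects), alpha_star,
                             **scan_kw)
    h2_rows = []
    for s in res.stratum_qc.index:
        if res.stratum_qc.loc[s, "informative"] and \
                not res.stratum_qc.loc[s, "hwe_excluded"]:
            try:
                h2 = single_snp_heritability(binary, G.column(s),
                                             float(res.stratum_qc.loc[s, "p"]))
            except ValueError:
                continue
            h2_rows.append({"snp_id": s, "gene": G.gene_of(s), "h2": h2})
    h2_table = pd.DataFrame(h2_rows, columns=["snp_id", "gene", "h2"])
    return res, h2_table
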
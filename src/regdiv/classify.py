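"""Eight-way classification of regulatory divergence from allele counts.

Three exact tests drive the classification, all on pooled replicate
counts within one tissue-by-sex-by-cross group:

* P — binomial test of the strain-1 vs strain-2 purebred counts against
  the library-size null proportion (expression divergence between breeds);
* H — binomial test of allele-1 vs allele-2 counts in the hybrids against
  0.5 (allelic imbalance, the signature of cis divergence);
* T — Fisher's exact test comparing the P and H ratios (a difference
  indicates trans-acting divergence: the purebred contrast contains
  cis + trans, the hybrid allelic contrast cis only).

Each test family is corrected to q-values (Storey FDR); a contrast is
called significant at q < 0.05. The pattern of significance, together
with the signs and magnitudes of the log2 ratios, places every gene in
exactly one of eight categories.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CATEGORIES = (
    "cis",
    "trans",
    "cis+trans(same)",
    "cis+trans(opposite)",
    "cisxtrans",
    "compensatory",
    "conserved",
    "ambiguous",
)

#: Categories whose call requires at least one significant test.
SIGNIFICANT_CATEGORIES = (
    "cis",
    "trans",
    "cis+trans(same)",
    "cis+trans(opposite)",
    "cisxtrans",
    "compensatory",
)


@dataclass(frozen=True)
class GeneCountSummary:
    """Pooled counts and normalized log2 ratios for one gene in one group."""

    gene_id: str
    P1: int
    P2: int
    H1: int
    H2: int
    p0_P: float = 0.5
    p0_H: float = 0.5
    ratio_P: float = float("nan")
    ratio_H: float = float("nan")

    def __post_init__(self) -> None:
        for label, v in (("p0_P", self.p0_P), ("p0_H", self.p0_H)):
            if not 0.0 < v < 1.0:
                raise ValueError(f"{label} must lie in (0,1), got {v}")
        if min(self.P1, self.P2, self.H1, self.H2) < 0:
            raise ValueError("counts must be nonnegative")


@dataclass(frozen=True)
class TestResults:
    gene_id: str
    p_P: float
    p_H: float
    p_T: float
    q_P: float
    q_H: float
    q_T: float
    sig_P: bool
    sig_H: bool
    sig_T: bool


@dataclass(frozen=True)
class CategoryCall:
    gene_id: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def binomial_two_sided(k: int, n: int, p0: float) -> float:
    """Exact two-sided binomial p-value (minlike convention).

    Sums the probabilities of all outcomes no more likely than the observed
    one. n = 0 is undefined (the caller routes such genes to ambiguous).
    """
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"null proportion must lie in (0,1), got {p0}")
    if n == 0:
        raise ValueError("binomial test undefined for n = 0")
    return float(stats.binomtest(k, n, p0, alternative="two-sided").pvalue)


def fisher_exact_2x2(P1: int, P2: int, H1: int, H2: int) -> float:
    """Two-sided Fisher exact p for the table [[P1, P2], [H1, H2]].

    A zero margin carries no information about the ratio difference and
    returns p = 1 (logged).
    """
    if min(P1, P2, H1, H2) < 0:
        raise ValueError("counts must be nonnegative")
    table = [[P1, P2], [H1, H2]]
    if (
        P1 + P2 == 0
        or H1 + H2 == 0
        or P1 + H1 == 0
        or P2 + H2 == 0
    ):
        logger.debug("Fisher table %s has a zero margin; p = 1", table)
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def estimate_pi0(pvalues: np.ndarray) -> float:
    """Storey estimate of the null fraction pi0 on the lambda grid 0.05..0.95.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is extrapolated to
    lambda -> 1 with a cubic smoother and clipped to (0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    lam = np.arange(0.05, 0.96, 0.05)
    pi0_lam = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lam])
    coeffs = np.polyfit(lam, pi0_lam, deg=3)
    pi0 = float(np.polyval(coeffs, lam[-1]))
    return min(max(pi0, 1.0 / m), 1.0)


def estimate_qvalues(pvalues, pi0: float | None = None) -> np.ndarray:
    """q-values for one family of p-values (Storey FDR).

    For families of fewer than 100 tests the pi0 smoother is unstable and
    pi0 = 1 is used, which reduces to Benjamini-Hochberg. q-values are
    monotone non-decreasing in p.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p-value family must be a non-empty 1-d array")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        pi0 = 1.0 if m < 100 else estimate_pi0(p)
    if not 0.0 < pi0 <= 1.0:
        raise ValueError(f"pi0 must lie in (0,1], got {pi0}")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * pi0 * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def log2_ratio(a: float, b: float, pseudocount: float = 0.5) -> float:
    return math.log2((a + pseudocount) / (b + pseudocount))


def summarize_gene_counts(
    purebred_pooled: pd.DataFrame,
    hybrid_pooled: pd.DataFrame,
    genes: list[str] | None = None,
    p0_P: float = 0.5,
    p0_H: float = 0.5,
    norm_P: tuple[float, float] = (1.0, 1.0),
) -> list[GeneCountSummary]:
    """Build per-gene summaries from pooled purebred and hybrid counts.

    Both inputs are indexed by gene_id with columns count_allele1 /
    count_allele2 (``AlleleCountTable.pooled()``). ``p0_P`` is the
    library-size null proportion for the purebred contrast, ``norm_P`` the
    per-strain pooled scale factors used for the (pseudocounted) log2 ratio.
    Hybrid alleles share a library, so p0_H is 0.5 unless overridden.
    """
    if genes is None:
        genes = sorted(set(purebred_pooled.index) & set(hybrid_pooled.index))
    s1, s2 = norm_P
    out = []
    for gene_id in genes:
        p_row = purebred_pooled.loc[gene_id]
        h_row = hybrid_pooled.loc[gene_id]
        P1, P2 = int(p_row["count_allele1"]), int(p_row["count_allele2"])
        H1, H2 = int(h_row["count_allele1"]), int(h_row["count_allele2"])
        out.append(
            GeneCountSummary(
                gene_id=gene_id,
                P1=P1,
                P2=P2,
                H1=H1,
                H2=H2,
                p0_P=p0_P,
                p0_H=p0_H,
                ratio_P=log2_ratio(P1 / s1, P2 / s2),
                ratio_H=log2_ratio(H1, H2),
            )
        )
    return out


def classify_gene(tr: TestResults, ratio_P: float, ratio_H: float) -> CategoryCall:
    """Place one gene in its regulatory category from the three tests.

    Decision table (sig = q < alpha for that test):

    =====================  ======================================
    cis                    sig P and H, not T
    trans                  sig P and T, not H
    cis+trans(same)        sig all; ratios same sign; |P| > |H|
    cis+trans(opposite)    sig all; ratios same sign; |H| > |P|
    cisxtrans              sig all; ratios opposite sign
    compensatory           sig H and T, not P
    conserved              none significant
    ambiguous              every other pattern
    =====================  ======================================

    A zero ratio (no directional information) or an exact magnitude tie
    within the cis+trans split routes to ambiguous.
    """
    sP, sH, sT = tr.sig_P, tr.sig_H, tr.sig_T
    if sP and sH and not sT:
        cat = "cis"
    elif sP and not sH and sT:
        cat = "trans"
    elif sP and sH and sT:
        if ratio_P * ratio_H > 0:
            if abs(ratio_P) > abs(ratio_H):
                cat = "cis+trans(same)"
            elif abs(ratio_H) > abs(ratio_P):
                cat = "cis+trans(opposite)"
            else:
                cat = "ambiguous"
        elif ratio_P * ratio_H < 0:
            cat = "cisxtrans"
        else:
            cat = "ambiguous"
    elif sH and not sP and sT:
        cat = "compensatory"
    elif not sP and not sH and not sT:
        cat = "conserved"
    else:
        cat = "ambiguous"
    return CategoryCall(tr.gene_id, cat)


def run_tests(
    summaries: list[GeneCountSummary], alpha: float = 0.05
) -> list[TestResults]:
    """Run the P, H and T tests per gene and correct each family separately.

    Genes with an empty contrast (n = 0 for a binomial test) get p = NaN
    for that test and are never called significant there; classification
    routes them to ambiguous via the decision table.
    """
    p_P, p_H, p_T = [], [], []
    for s in summaries:
        p_P.append(
            binomial_two_sided(s.P1, s.P1 + s.P2, s.p0_P)
            if s.P1 + s.P2 > 0
            else float("nan")
        )
        p_H.append(
            binomial_two_sided(s.H1, s.H1 + s.H2, s.p0_H)
            if s.H1 + s.H2 > 0
            else float("nan")
        )
        p_T.append(fisher_exact_2x2(s.P1, s.P2, s.H1, s.H2))

    def correct(ps: list[float]) -> np.ndarray:
        arr = np.asarray(ps, dtype=float)
        ok = ~np.isnan(arr)
        q = np.full(arr.shape, np.nan)
        if ok.sum():
            q[ok] = estimate_qvalues(arr[ok])
        return q

    q_P, q_H, q_T = correct(p_P), correct(p_H), correct(p_T)
    out = []
    for i, s in enumerate(summaries):
        out.append(
            TestResults(
                gene_id=s.gene_id,
                p_P=p_P[i],
                p_H=p_H[i],
                p_T=p_T[i],
                q_P=q_P[i],
                q_H=q_H[i],
                q_T=q_T[i],
                sig_P=bool(q_P[i] < alpha),
                sig_H=bool(q_H[i] < alpha),
                sig_T=bool(q_T[i] < alpha),
            )
        )
    return out


def classify_table(
    summaries: list[GeneCountSummary], alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every gene and summarize category counts and proportions.

    Returns (per_gene, summary): per_gene has one row per gene with the
    three p/q pairs, both ratios and the category; summary has one row per
    category with its count and proportion over classified genes.
    """
    if not summaries:
        logger.warning("empty count table; nothing to classify")
        per_gene = pd.DataFrame(
            columns=[
                "gene_id", "P1", "P2", "H1", "H2", "p_P", "p_H", "p_T",
                "q_P", "q_H", "q_T", "ratio_P", "ratio_H", "category",
            ]
        )
        summary = pd.DataFrame(
            {"category": CATEGORIES, "count": 0, "proportion": float("nan")}
        )
        return per_gene, summary

    results = run_tests(summaries, alpha)
    rows = []
    for s, tr in zip(summaries, results):
        call = classify_gene(tr, s.ratio_P, s.ratio_H)
        rows.append(
            {
                "gene_id": s.gene_id,
                "P1": s.P1,
                "P2": s.P2,
                "H1": s.H1,
                "H2": s.H2,
                "p_P": tr.p_P,
                "p_H": tr.p_H,
                "p_T": tr.p_T,
                "q_P": tr.q_P,
                "q_H": tr.q_H,
                "q_T": tr.q_T,
                "ratio_P": s.ratio_P,
                "ratio_H": s.ratio_H,
                "category": call.category,
            }
        )
    per_gene = pd.DataFrame(rows)
    counts = per_gene["category"].value_counts()
    summary = pd.DataFrame(
        {
            "category": CATEGORIES,
            "count": [int(counts.get(c, 0)) for c in CATEGORIES],
        }
    )
    summary["proportion"] = summary["count"] / summary["count"].sum()
    return per_gene, summary


def compare_category_proportions(
    counts_a: dict[str, int], counts_b: dict[str, int]
) -> dict[str, float]:
    """Per-category Fisher test of category-vs-rest between two groups."""
    total_a, total_b = sum(counts_a.values()), sum(counts_b.values())
    if total_a == 0 or total_b == 0:
        raise ValueError("both groups must contain classified genes")
    out = {}
    for cat in CATEGORIES:
        ka, kb = counts_a.get(cat, 0), counts_b.get(cat, 0)
        out[cat] = fisher_exact_2x2(ka, total_a - ka, kb, total_b - kb)
    return out
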
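"""Genotype-stratified gene-usage statistics.

Gene and J-family usage fractions, conditional P(J | D) tables restricted
to reads with confidently identified D segments (> 7 germline nt), a
functional / non-functional stratification, and group comparisons with a
two-tailed Mann-Whitney test Bonferroni-corrected over the genes of one
panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from trbkit.deletions import usage_table  # noqa: F401  (re-exported)
from trbkit.repertoire_io import Repertoire

MIN_D_LENGTH = 8  # "longer than 7 nt" rule for conditional D usage
TRBJ2_RESTRICTED_D = "TRBD2"  # TRBD2 rearranges only with TRBJ2 genes


@dataclass
class UsageComparison:
    gene: str
    groups: tuple[str, str]
    statistic: float
    p_raw: float
    p_adjusted: float
    significant: bool
    stars: str


def family_usage(repertoire: Repertoire, family: str) -> float:
    """Summed usage of a TRBJ family (``TRBJ1``/``TRBJ2``) over J-assigned reads.

    Multi-call reads are counted fractionally; TRBJ1 + TRBJ2 sum to 1.
    """
    calls = repertoire.df["j_call"].fillna("")
    calls = calls[calls != ""]
    total, hit = 0.0, 0.0
    for call in calls:
        names = call.split(",")
        w = 1.0 / len(names)
        for name in names:
            total += w
            if name.startswith(family) and name[len(family)] in "-*":
                hit += w
    if total == 0:
        return float("nan")
    return hit / total


def conditional_usage(
    repertoire: Repertoire,
    d_gene: str,
    min_d_length: int = MIN_D_LENGTH,
    productive_only: bool | None = None,
) -> pd.Series:
    """P(J gene | D gene) over reads with a confident D identification.

    Uses reads with a single D call matching ``d_gene`` and a germline-
    matched D length of at least ``min_d_length`` (i.e. longer than 7 nt).
    For TRBD2 the support is restricted to TRBJ2 genes, the only family it
    can biologically rearrange with.  Returns an empty series (with a
    warning from the caller's perspective: simply empty) when no read
    qualifies.
    """
    df = repertoire.df
    d = df["d_call"].fillna("")
    ok = (d == f"{d_gene}*01") | (d == f"{d_gene}*02") | (d == d_gene)
    ok |= d.str.match(rf"^{d_gene}\*\w+$")
    ok &= pd.to_numeric(df["d_matched_length"], errors="coerce").fillna(0) >= min_d_length
    ok &= (df["j_call"].fillna("") != "") & ~df["j_call"].fillna("").str.contains(",")
    if productive_only is not None:
        want = "T" if productive_only else "F"
        ok &= df["productive"].fillna("") == want
    sub = df[ok]
    j_genes = sub["j_call"].str.rpartition("*")[0]
    if d_gene == TRBJ2_RESTRICTED_D:
        j_genes = j_genes[j_genes.str.startswith("TRBJ2")]
    if len(j_genes) == 0:
        return pd.Series(dtype=float)
    return (j_genes.value_counts() / len(j_genes)).sort_index()


def stratify_productive(repertoire: Repertoire) -> tuple[Repertoire, Repertoire]:
    """Disjoint (productive, non-functional) sub-repertoires.

    Reads with unknown productivity are excluded from both strata.
    """
    df = repertoire.df
    prod = df[df["productive"].fillna("") == "T"]
    nonf = df[df["productive"].fillna("") == "F"]
    return (
        Repertoire(prod, sample_id=repertoire.sample_id,
                   protocol=repertoire.protocol, dedup=False),
        Repertoire(nonf, sample_id=repertoire.sample_id,
                   protocol=repertoire.protocol, dedup=False),
    )


_STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def compare_usage(
    usage: pd.DataFrame,
    grouping: dict[str, str],
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
) -> list[UsageComparison]:
    """Per-gene two-tailed Mann-Whitney between two genotype groups.

    ``usage`` is a sample x gene fraction table (see
    :func:`trbkit.deletions.usage_table`); ``grouping`` maps sample to
    genotype-group label.  Bonferroni correction is over the genes of this
    panel.  Genes where either group has fewer than two samples are
    skipped.
    """
    a_samples = [s for s in usage.index if grouping.get(s) == group_a]
    b_samples = [s for s in usage.index if grouping.get(s) == group_b]
    if len(a_samples) < 2 or len(b_samples) < 2:
        raise ValueError("each group needs at least 2 samples")
    genes = list(usage.columns)
    n_tests = len(genes)
    out = []
    for gene in genes:
        va = usage.loc[a_samples, gene].to_numpy(dtype=float)
        vb = usage.loc[b_samples, gene].to_numpy(dtype=float)
        if np.all(va == va[0]) and np.all(vb == vb[0]) and va[0] == vb[0]:
            stat, p_raw = float(len(va) * len(vb) / 2), 1.0
        else:
            res = stats.mannwhitneyu(va, vb, alternative="two-sided")
            stat, p_raw = float(res.statistic), float(res.pvalue)
        p_adj = min(1.0, p_raw * n_tests)
        stars = next((s for cut, s in _STAR_LEVELS if p_adj < cut), "n.s.")
        out.append(
            UsageComparison(
                gene=gene,
                groups=(group_a, group_b),
                statistic=stat,
                p_raw=p_raw,
                p_adjusted=p_adj,
                significant=p_adj < alpha,
                stars=stars,
            )
        )
    return out


def comparisons_frame(comparisons: list[UsageComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": c.gene,
                "group_a": c.groups[0],
                "group_b": c.groups[1],
                "statistic": c.statistic,
                "p_raw": c.p_raw,
                "p_adjusted": c.p_adjusted,
                "significant": "T" if c.significant else "F",
                "stars": c.stars,
            }
            for c in comparisons
        ]
    )
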
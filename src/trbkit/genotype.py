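"""Bayesian per-gene genotype calling from filtered assignment counts.

For each gene, candidate genotypes are all non-empty subsets (size <= 4) of
the top-4 observed alleles.  Under a genotype with k alleles, the carried
alleles are expected in equal proportions and a mis-assignment probability
epsilon accounts for reads attributed to alleles the genotype does not
contain.  The call is the maximum-marginal-likelihood genotype and its
confidence ``lk`` is the base-10 log Bayes factor against the runner-up.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import pandas as pd

from trbkit.repertoire_io import Repertoire, split_call

MAX_GENOTYPE_ALLELES = 4


class NoData(ValueError):
    """No usable reads to genotype a gene."""


@dataclass
class GenotypeCall:
    """Called allele set for one gene with log Bayes-factor confidence."""

    gene: str
    alleles: tuple[str, ...]
    counts: dict[str, int]
    lk: float
    total_reads: int
    epsilon: float = 0.0


def select_genotype_reads(repertoire: Repertoire, segment: str) -> pd.DataFrame:
    """Reads admissible for genotyping a segment.

    V: single best assignment and at most one mismatch inside the boundary
    window.  D: single assignment, no mismatches (exact-substring model) and
    a germline-matched D length of at least 9 nt.  J: single assignment.
    """
    df = repertoire.df
    if segment == "V":
        call = df["v_call"].fillna("")
        ok = (call != "") & ~call.str.contains(",")
        ok &= pd.to_numeric(df["v_mismatches"], errors="coerce").fillna(99) <= 1
    elif segment == "D":
        call = df["d_call"].fillna("")
        ok = (call != "") & ~call.str.contains(",")
        ok &= pd.to_numeric(df["d_matched_length"], errors="coerce").fillna(0) >= 9
    elif segment == "J":
        call = df["j_call"].fillna("")
        ok = (call != "") & ~call.str.contains(",")
    else:
        raise ValueError(f"unknown segment {segment!r}")
    return df[ok]


def _log_marginal(counts: list[int], probs: list[float]) -> float:
    """Multinomial log-likelihood (natural log); -inf on zero-probability."""
    ll = math.lgamma(sum(counts) + 1)
    for c, p in zip(counts, probs):
        ll -= math.lgamma(c + 1)
        if c:
            if p <= 0:
                return -math.inf
            ll += c * math.log(p)
    return ll


def bayes_genotype(
    allele_counts: dict[str, int], epsilon: float = 0.01, gene: str = ""
) -> GenotypeCall:
    """Call a genotype from per-allele unique-read counts.

    Alleles beyond the top 4 by count are pooled into the error mass.  With
    a single observed allele the only model is homozygous and ``lk`` is
    infinite.
    """
    if not allele_counts or sum(allele_counts.values()) == 0:
        raise NoData(f"no reads for gene {gene or '?'}")
    if not 0 <= epsilon < 0.5:
        raise ValueError("epsilon must be in [0, 0.5)")
    ranked = sorted(allele_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    top = ranked[:MAX_GENOTYPE_ALLELES]
    pooled = sum(c for _, c in ranked[MAX_GENOTYPE_ALLELES:])
    names = [a for a, _ in top]
    counts = [c for _, c in top] + [pooled]

    lls: list[tuple[float, tuple[str, ...]]] = []
    for k in range(1, len(names) + 1):
        for combo in itertools.combinations(range(len(names)), k):
            inside = set(combo)
            n_out = (len(names) - k) + (1 if pooled else 0)
            if n_out:
                probs = [
                    (1 - epsilon) / k if i in inside else epsilon / n_out
                    for i in range(len(names))
                ]
                probs.append(epsilon / n_out if pooled else 0.0)
            else:
                probs = [1.0 / k if i in inside else 0.0 for i in range(len(names))]
                probs.append(0.0)
            lls.append(
                (_log_marginal(counts, probs), tuple(names[i] for i in combo))
            )
    lls.sort(key=lambda t: -t[0])
    best_ll, best = lls[0]
    lk = (
        (best_ll - lls[1][0]) / math.log(10) if len(lls) > 1 else math.inf
    )
    return GenotypeCall(
        gene=gene,
        alleles=tuple(sorted(best)),
        counts=dict(top),
        lk=max(lk, 0.0),
        total_reads=sum(allele_counts.values()),
        epsilon=epsilon,
    )


def genotype_repertoire(
    repertoire: Repertoire, segment: str = "V", epsilon: float = 0.01
) -> pd.DataFrame:
    """Per-gene genotype table for one sample.

    Gene = everything before the ``*`` of the call (pattern or merged
    label); returns a TSV-ready frame (gene, alleles ';'-joined, counts,
    total, lk).
    """
    col = {"V": "v_call", "D": "d_call", "J": "j_call"}[segment]
    reads = select_genotype_reads(repertoire, segment)
    by_gene: dict[str, dict[str, int]] = {}
    for call in reads[col]:
        gene, allele = split_call(call)
        by_gene.setdefault(gene, {})
        by_gene[gene][allele] = by_gene[gene].get(allele, 0) + 1
    rows = []
    for gene in sorted(by_gene):
        gc = bayes_genotype(by_gene[gene], epsilon=epsilon, gene=gene)
        rows.append(
            {
                "sample_id": repertoire.sample_id,
                "gene": gene,
                "alleles": ";".join(gc.alleles),
                "counts": ";".join(
                    str(gc.counts.get(a, 0)) for a in gc.alleles
                ),
                "total": gc.total_reads,
                "lk": round(gc.lk, 4) if math.isfinite(gc.lk) else math.inf,
            }
        )
    return pd.DataFrame(
        rows, columns=["sample_id", "gene", "alleles", "counts", "total", "lk"]
    )
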
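"""Double-chromosome (repertoire-level) gene deletion inference.

A gene is declared deleted from a sample's expressed repertoire when its
read count X out of N total unique reads is binomially improbable under the
lowest usage rate P observed for that gene among samples that are not
themselves deletion candidates.  Deletions are statements about the
expressed repertoire, not the genome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from trbkit.repertoire_io import Repertoire, split_call

DEFAULT_MIN_CUTOFF = 0.0005
DEFAULT_ALPHA = 0.01


@dataclass
class DeletionTest:
    sample: str
    gene: str
    X: int
    N: int
    P: float
    p_value: float
    deleted: bool


def usage_table(
    repertoires: list[Repertoire],
    segment: str = "V",
    counting: str = "fractional",
) -> pd.DataFrame:
    """Sample x gene usage-fraction table over unique sequences.

    Multi-call reads are counted fractionally across their calls by default
    (``counting='first'`` attributes them to the first call).  Rows sum to 1
    over the counted genes; empty repertoires are excluded.
    """
    col = {"V": "v_call", "D": "d_call", "J": "j_call"}[segment]
    rows = {}
    for rep in repertoires:
        calls = rep.df[col].fillna("")
        calls = calls[calls != ""]
        if len(calls) == 0:
            continue
        counts: dict[str, float] = {}
        for call in calls:
            names = call.split(",")
            if counting == "first":
                names = names[:1]
            w = 1.0 / len(names)
            for name in names:
                gene = split_call(name)[0] or name
                counts[gene] = counts.get(gene, 0.0) + w
        total = sum(counts.values())
        rows[rep.sample_id] = {g: c / total for g, c in counts.items()}
    return pd.DataFrame.from_dict(rows, orient="index").fillna(0.0).sort_index(
        axis=0
    ).sort_index(axis=1)


def _read_counts(repertoires: list[Repertoire], segment: str, counting: str):
    """(sample x gene fractional counts, per-sample totals)."""
    col = {"V": "v_call", "D": "d_call", "J": "j_call"}[segment]
    counts, totals = {}, {}
    for rep in repertoires:
        calls = rep.df[col].fillna("")
        calls = calls[calls != ""]
        if len(calls) == 0:
            continue
        c: dict[str, float] = {}
        for call in calls:
            names = call.split(",")
            if counting == "first":
                names = names[:1]
            w = 1.0 / len(names)
            for name in names:
                gene = split_call(name)[0] or name
                c[gene] = c.get(gene, 0.0) + w
        counts[rep.sample_id] = c
        totals[rep.sample_id] = sum(c.values())
    return counts, totals


def deletion_test(
    usage: pd.DataFrame,
    totals: dict[str, float],
    sample: str,
    gene: str,
    min_cutoff: float = DEFAULT_MIN_CUTOFF,
    alpha: float = DEFAULT_ALPHA,
    n_tests: int = 1,
) -> DeletionTest:
    """Binomial deletion test for one (sample, gene) pair.

    P is the smallest usage of the gene above ``min_cutoff`` among
    non-candidate samples (samples whose own usage exceeds the cutoff);
    p_value = Pr[Binomial(N, P) <= X], flagged deleted when it clears the
    Bonferroni-adjusted alpha.  Raises ``ValueError`` when no sample
    exceeds the cutoff (the gene is untestable).
    """
    u = usage[gene]
    above = u[u > min_cutoff]
    if len(above) == 0:
        raise ValueError(f"gene {gene} untestable: no sample above cutoff")
    p_ref = float(above.min())
    n_total = int(round(totals[sample]))
    x = int(round(float(usage.loc[sample, gene]) * totals[sample]))
    p_value = float(stats.binom.cdf(x, n_total, p_ref))
    return DeletionTest(
        sample=sample,
        gene=gene,
        X=x,
        N=n_total,
        P=p_ref,
        p_value=p_value,
        deleted=bool(p_value < alpha / max(n_tests, 1)),
    )


def infer_deletions(
    repertoires: list[Repertoire],
    segment: str = "V",
    min_cutoff: float = DEFAULT_MIN_CUTOFF,
    alpha: float = DEFAULT_ALPHA,
    counting: str = "fractional",
) -> pd.DataFrame:
    """Deletion tests for every (sample, gene) pair in a population.

    Bonferroni correction is applied over all tested pairs.  Untestable
    genes (no sample above cutoff) are reported with ``deleted`` empty.
    """
    usage = usage_table(repertoires, segment=segment, counting=counting)
    _, totals = _read_counts(repertoires, segment, counting)
    pairs = [(s, g) for g in usage.columns for s in usage.index]
    n_tests = len(pairs)
    rows = []
    for sample, gene in pairs:
        try:
            t = deletion_test(
                usage, totals, sample, gene,
                min_cutoff=min_cutoff, alpha=alpha, n_tests=n_tests,
            )
        except ValueError:
            rows.append(
                {"sample_id": sample, "gene": gene, "X": np.nan, "N": np.nan,
                 "P": np.nan, "p_value": np.nan, "deleted": ""}
            )
            continue
        rows.append(
            {"sample_id": t.sample, "gene": t.gene, "X": t.X, "N": t.N,
             "P": t.P, "p_value": t.p_value, "deleted": "T" if t.deleted else "F"}
        )
    return pd.DataFrame(
        rows, columns=["sample_id", "gene", "X", "N", "P", "p_value", "deleted"]
    )
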
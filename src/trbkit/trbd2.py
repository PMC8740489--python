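"""TRBD2 genotype-group calling via Gaussian equilibrium points.

The two TRBD2 alleles differ by a single G/A SNP inside a G-rich stretch,
so exonuclease trimming plus G-biased N-addition causes asymmetric allele
mis-assignment.  Across a population, the per-sample fraction of TRBD2*01
among unambiguous TRBD2 assignments is tri-modal: homozygous *02 samples
peak near the *02->*01 error rate, heterozygotes near 0.5 shifted by the
asymmetric errors, and homozygous *01 samples just below 1.  Group borders
are the equilibrium points of adjacent Gaussian modes, where the two
tail probabilities are equal: x = (mu1*sigma2 + mu2*sigma1) / (sigma1 +
sigma2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from trbkit.repertoire_io import Repertoire

GROUPS = ("hom02", "het", "hom01")
COARSE_CUTS = (0.2, 0.8)  # initial coarse ranges ~0-0.2 / 0.2-0.8 / 0.8-1


@dataclass
class D2GroupModel:
    """Tri-modal model of per-sample TRBD2*01 fractions."""

    sample_fractions: dict[str, float]
    group_params: dict[str, tuple[float, float]]  # group -> (mu, sd)
    borders: tuple[float, float]
    group_calls: dict[str, str]
    eps_01_to_02: float  # P(*01 read mis-assigned *02) = 1 - mu(hom01)
    eps_02_to_01: float  # P(*02 read mis-assigned *01) = mu(hom02)
    corrected_het_usage: float  # corrected TRBD2*01 fraction in heterozygotes
    absent_groups: tuple[str, ...] = ()


def trbd2_fraction(repertoire: Repertoire, gene: str = "TRBD2") -> float:
    """Fraction of TRBD2*01 among reads unambiguously assigned to TRBD2.

    Raises ``ValueError`` when the sample has no unambiguous TRBD2 reads
    (callers exclude the sample with a warning).
    """
    calls = repertoire.df["d_call"].fillna("")
    unamb = calls[(calls != "") & ~calls.str.contains(",")]
    d2 = unamb[unamb.str.startswith(gene + "*")]
    if len(d2) == 0:
        raise ValueError(f"no unambiguous {gene} reads in {repertoire.sample_id}")
    return float((d2 == f"{gene}*01").sum() / len(d2))


def equilibrium_point(mu1: float, sigma1: float, mu2: float, sigma2: float) -> float:
    """Point where the two Gaussian tail probabilities are equal.

    Closed form (mu1*sigma2 + mu2*sigma1)/(sigma1 + sigma2); it satisfies
    Phi((mu1 - x)/sigma1) = Phi((x - mu2)/sigma2).
    """
    if sigma1 <= 0 or sigma2 <= 0:
        raise ValueError("sigma must be positive")
    return (mu1 * sigma2 + mu2 * sigma1) / (sigma1 + sigma2)


def _group_of(x: float, borders: tuple[float, float]) -> str:
    lo, hi = borders
    if x < lo:
        return "hom02"
    if x <= hi:
        return "het"
    return "hom01"


def _params(values: np.ndarray) -> tuple[float, float]:
    mu = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return mu, sd


def call_d2_groups(
    sample_fractions: dict[str, float], iterate: bool = False, max_iter: int = 10
) -> D2GroupModel:
    """Classify samples into TRBD2 genotype groups.

    Samples are first split at the coarse cut points (0.2, 0.8); group
    means/SDs define equilibrium-point borders which re-assign the samples
    (one pass by default, optionally iterated to convergence).  Empty coarse
    groups are marked absent and the corresponding border falls back to the
    coarse cut.  Mis-assignment rates come from the homozygous group means
    and the corrected heterozygote usage is the linear unmixing
    t = (f_het - eps21) / (1 - eps12 - eps21).
    """
    if len(sample_fractions) < 3:
        raise ValueError("need at least 3 samples with defined fractions")
    samples = list(sample_fractions)
    fr = np.array([sample_fractions[s] for s in samples], dtype=float)

    borders = COARSE_CUTS
    n_pass = max_iter if iterate else 1
    for _ in range(n_pass):
        labels = np.array([_group_of(x, borders) for x in fr])
        params: dict[str, tuple[float, float]] = {}
        absent = []
        for g in GROUPS:
            vals = fr[labels == g]
            if len(vals) == 0:
                absent.append(g)
                continue
            params[g] = _params(vals)
        new = list(borders)
        if "hom02" in params and "het" in params:
            (m1, s1), (m2, s2) = params["hom02"], params["het"]
            if s1 + s2 > 0:
                new[0] = equilibrium_point(m1, max(s1, 1e-9), m2, max(s2, 1e-9))
        else:
            warnings.warn("empty TRBD2 coarse group; border falls back to 0.2",
                          stacklevel=2)
        if "het" in params and "hom01" in params:
            (m1, s1), (m2, s2) = params["het"], params["hom01"]
            if s1 + s2 > 0:
                new[1] = equilibrium_point(m1, max(s1, 1e-9), m2, max(s2, 1e-9))
        elif "hom01" not in params or "het" not in params:
            warnings.warn("empty TRBD2 coarse group; border falls back to 0.8",
                          stacklevel=2)
        if tuple(new) == tuple(borders):
            borders = tuple(new)
            break
        borders = tuple(new)

    # final assignment by the computed borders
    labels = np.array([_group_of(x, borders) for x in fr])
    params = {}
    absent = []
    for g in GROUPS:
        vals = fr[labels == g]
        if len(vals):
            params[g] = _params(vals)
        else:
            absent.append(g)

    eps21 = params.get("hom02", (0.0, 0.0))[0]  # *02 reads mis-called *01
    eps12 = 1.0 - params.get("hom01", (1.0, 0.0))[0]  # *01 reads mis-called *02
    f_het = params.get("het", (np.nan, 0.0))[0]
    denom = 1.0 - eps12 - eps21
    corrected = (f_het - eps21) / denom if denom > 0 else np.nan

    return D2GroupModel(
        sample_fractions=dict(sample_fractions),
        group_params=params,
        borders=(float(borders[0]), float(borders[1])),
        group_calls={s: str(g) for s, g in zip(samples, labels)},
        eps_01_to_02=float(eps12),
        eps_02_to_01=float(eps21),
        corrected_het_usage=float(corrected),
        absent_groups=tuple(absent),
    )


def hwe(genotype_counts: tuple[int, int, int]):
    """Hardy-Weinberg check for a biallelic gene.

    ``genotype_counts`` is (hom1, het, hom2).  Returns observed genotype
    frequencies, allele frequencies (p, q), expected counts (p^2, 2pq,
    q^2) * n and the chi-square statistic with 1 df.
    """
    hom1, het, hom2 = genotype_counts
    if min(genotype_counts) < 0:
        raise ValueError("negative genotype count")
    n = hom1 + het + hom2
    if n == 0:
        raise ValueError("zero total genotype count")
    obs_freq = (hom1 / n, het / n, hom2 / n)
    p = (2 * hom1 + het) / (2 * n)
    q = 1 - p
    expected = (p * p * n, 2 * p * q * n, q * q * n)
    chi2 = sum(
        (o - e) ** 2 / e for o, e in zip(genotype_counts, expected) if e > 0
    )
    p_value = float(stats.chi2.sf(chi2, df=1))
    return {
        "observed_freq": obs_freq,
        "allele_freq": (p, q),
        "expected_counts": expected,
        "chi2": float(chi2),
        "p_value": p_value,
    }
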
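"""Undocumented (novel) germline allele discovery and filtering.

Candidates are recurrent exact mismatch-position patterns among a gene's
single-call alignments, restricted to the boundary window (from five
positions after the primer end / sequence start, to IMGT position 316).
A candidate battery of six filters then applies: minimum support (5% of
the gene's alignments), rearrangement diversity (>= 2 CDR3 lengths and
>= 2 TRBJ genes), a chimera rule (no two alleles of different genes can
splice into the candidate), an SNP-stretch rule (no two SNPs within four
adjacent positions), and a population-modality rule (usage fractions must
look bi-/tri-modal, as real heterozygous/homozygous carriers do).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from trbkit.reference import GermlineAllele, GermlineSet
from trbkit.repertoire_io import Repertoire, split_call

IMGT_BOUNDARY_END = 316  # 3' limit of the SNP-calling window (IMGT numbering)
BOUNDARY_MARGIN = 5  # SNPs counted from max(primer end, seq start) + 5
MIN_SUPPORT_FRACTION = 0.05
CANDIDATE_FLOOR_READS = 2
CANDIDATE_FLOOR_FRACTION = 0.01
MODALITY_CARRIER_MIN = 0.20
SNP_STRETCH = 4


class UnsupportedProtocol(ValueError):
    """Operation defined for the full (5'RACE) protocol only."""


@dataclass
class BoundaryWindow:
    """IMGT-position window in which suspected SNPs are counted."""

    start: int
    end: int = IMGT_BOUNDARY_END

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("boundary window start must precede end")

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass
class NovelCandidate:
    """One candidate undocumented allele of a gene."""

    base_allele: tuple[str, str]  # (gene, allele)
    snps: tuple[tuple[str, int, str], ...]  # (ref_nt, imgt_pos, alt_nt)
    support_fraction: float
    support_reads: int
    cdr3_length_count: int
    j_gene_count: int
    filter_flags: dict[str, bool] = field(default_factory=dict)
    population_fractions: dict[str, float] = field(default_factory=dict)

    @property
    def name(self) -> str:
        tokens = "_".join(f"{r}{p}{a}" for r, p, a in self.snps)
        return f"{self.base_allele[0]}*{self.base_allele[1]}_{tokens}"

    @property
    def passed(self) -> bool:
        return all(self.filter_flags.values()) if self.filter_flags else False


def _parse_snp(token: str) -> tuple[str, int, str]:
    return token[0], int(token[1:-1]), token[-1]


def detect_candidates(
    repertoire: Repertoire,
    gene: str,
    window: BoundaryWindow | None = None,
    min_reads: int = CANDIDATE_FLOOR_READS,
    min_fraction: float = CANDIDATE_FLOOR_FRACTION,
) -> list[NovelCandidate]:
    """Recurrent in-window SNP patterns among a gene's single-call reads.

    Reads are grouped by their base-allele call and exact mismatch-position
    pattern inside the boundary window (the assigner already restricts
    recorded SNP tokens to that window); each recurrent non-empty pattern
    yields one candidate.  ``support_fraction`` is the fraction of the
    gene's alignments exactly matching the candidate over the window, i.e.
    carrying exactly that SNP set.  Returns an empty list for a gene absent
    from the repertoire.
    """
    df = repertoire.df
    calls = df["v_call"].fillna("")
    mine = (calls != "") & ~calls.str.contains(",")
    mine &= calls.map(lambda c: split_call(c)[0] if c else "") == gene
    sub = df[mine]
    if len(sub) == 0:
        return []

    patterns: dict[tuple, list[pd.DataFrame]] = {}
    snp_col = sub["v_snps"].fillna("")
    for (base, key), grp in sub.groupby([sub["v_call"], snp_col]):
        if not key:
            continue
        snps = tuple(sorted((_parse_snp(t) for t in key.split(";")),
                            key=lambda s: s[1]))
        if window is not None and not all(p in window for _, p, _ in snps):
            snps = tuple(s for s in snps if s[1] in window)
            if not snps:
                continue
        patterns.setdefault((base, snps), []).append(grp)

    total = len(sub)
    out = []
    for (base, snps), grps in sorted(patterns.items()):
        b_gene, b_allele = split_call(base)
        grp = pd.concat(grps)
        n = len(grp)
        frac = n / total
        if n < min_reads or frac < min_fraction:
            continue
        j_genes = {
            split_call(c.split(",")[0])[0]
            for c in grp["j_call"].fillna("")
            if c
        }
        cdr3_lengths = set(grp["cdr3_length"].astype(int))
        out.append(
            NovelCandidate(
                base_allele=(b_gene, b_allele),
                snps=snps,
                support_fraction=frac,
                support_reads=n,
                cdr3_length_count=len(cdr3_lengths),
                j_gene_count=len(j_genes),
            )
        )
    return out


# ---------------------------------------------------------------------------
# filters


def _resolve_base(gset: GermlineSet, gene: str, allele: str) -> GermlineAllele:
    """Base allele lookup tolerating merged gene labels.

    A candidate on a merged gene (``TRBV6-2/TRBV6-3``) cannot be attributed
    to one member from repertoire data alone; the first member is used as
    the coordinate frame (the member sequences are identical over the
    window by construction).
    """
    if gene in gset:
        return gset.get(f"{gene}*{allele}")
    g0 = gene.split("/")[0]
    a0 = allele.split("/")[0]
    return gset.get(f"{g0}*{a0}")


def _candidate_window_sequence(
    candidate: NovelCandidate, base: GermlineAllele, window: BoundaryWindow
) -> str:
    """Candidate nucleotides over [window.start, window.end], IMGT frame."""
    snp_at = {p: alt for _, p, alt in candidate.snps}
    out = []
    for i, pos in enumerate(base.gapped_map):
        if pos in window:
            out.append(snp_at.get(pos, base.sequence[i]))
    return "".join(out)


def _allele_window_sequence(a: GermlineAllele, window: BoundaryWindow) -> str:
    return "".join(
        a.sequence[i] for i, pos in enumerate(a.gapped_map) if pos in window
    )


def chimera_check(
    candidate: NovelCandidate, gset: GermlineSet, window: BoundaryWindow
) -> bool:
    """True when NO splice of two different genes reproduces the candidate.

    Brute force over all ordered pairs of alleles from different genes and
    all breakpoints in the window: if a 5'-prefix of one allele joined to
    the 3'-suffix of an allele from another gene equals the candidate
    sequence over the window, the candidate can be a PCR chimera.
    """
    base = _resolve_base(gset, *candidate.base_allele)
    target = _candidate_window_sequence(candidate, base, window)
    windows: dict[str, list[str]] = {}
    for a in gset:
        w = _allele_window_sequence(a, window)
        if len(w) == len(target):
            windows.setdefault(a.gene, []).append(w)
    genes = sorted(windows)
    for ga in genes:
        for gb in genes:
            if ga == gb:
                continue
            for wa in windows[ga]:
                for wb in windows[gb]:
                    for k in range(1, len(target)):
                        if wa[:k] == target[:k] and wb[k:] == target[k:]:
                            return False
    return True


def _snp_stretch_ok(snps, stretch: int = SNP_STRETCH) -> bool:
    positions = sorted(p for _, p, _ in snps)
    return all(
        b - a >= stretch for a, b in zip(positions, positions[1:])
    )


def modality_check(
    population_fractions: dict[str, float],
    carrier_min: float = MODALITY_CARRIER_MIN,
    bin_width: float = 0.05,
    min_mode_mass: int = 2,
) -> bool:
    """Bi-/tri-modality screen on a candidate's population usage fractions.

    Real germline alleles appear at heterozygous (~0.3-0.5) or homozygous
    (~1.0) usage in their carriers, giving a multi-modal population
    distribution; sequencing-error artefacts sit in a single low-fraction
    mode.  Passes when any carrier reaches ``carrier_min`` or the histogram
    (bins of ``bin_width``) has >= 2 occupied runs of >= ``min_mode_mass``
    samples separated by an empty bin.
    """
    fr = np.array([f for f in population_fractions.values() if f > 0])
    if len(fr) == 0:
        return False
    if fr.max() >= carrier_min:
        return True
    bins = np.arange(0, 1 + bin_width, bin_width)
    hist, _ = np.histogram(fr, bins=bins)
    occupied = hist >= min_mode_mass
    # count runs of occupied bins separated by empty ones
    modes, in_run = 0, False
    for filled in occupied:
        if filled and not in_run:
            modes += 1
            in_run = True
        elif not filled:
            in_run = False
    return modes >= 2


def apply_filters(
    candidate: NovelCandidate,
    gset: GermlineSet,
    window: BoundaryWindow,
    population_fractions: dict[str, float] | None = None,
    chimera_filter: bool = True,
) -> dict[str, bool]:
    """Run the filter battery; sets and returns ``candidate.filter_flags``."""
    if population_fractions is not None:
        candidate.population_fractions = dict(population_fractions)
    flags = {
        "support": candidate.support_fraction >= MIN_SUPPORT_FRACTION,
        "diversity": candidate.cdr3_length_count >= 2
        and candidate.j_gene_count >= 2,
        "snp_stretch": _snp_stretch_ok(candidate.snps),
        "chimera": (
            chimera_check(candidate, gset, window) if chimera_filter else True
        ),
        "modality": modality_check(candidate.population_fractions)
        if candidate.population_fractions
        else True,
    }
    candidate.filter_flags = flags
    return flags


def discover_population(
    repertoires: list[Repertoire],
    gset: GermlineSet,
    window_start: int = 1 + BOUNDARY_MARGIN,
    chimera_filter: bool = True,
) -> list[NovelCandidate]:
    """Detect and filter candidates across a population of samples.

    Candidates with identical (gene, SNP set) are pooled across samples;
    population usage fractions feed the modality filter.  Returns all
    candidates with their flags (callers select ``passed``).
    """
    window = BoundaryWindow(start=window_start)
    merged: dict[tuple, NovelCandidate] = {}
    fractions: dict[tuple, dict[str, float]] = {}
    for rep in repertoires:
        genes = {
            split_call(c)[0]
            for c in rep.df["v_call"].fillna("")
            if c and "," not in c
        }
        for gene in sorted(genes):
            for cand in detect_candidates(rep, gene, window=window):
                key = (cand.base_allele, cand.snps)
                fractions.setdefault(key, {})[rep.sample_id] = (
                    cand.support_fraction
                )
                if key not in merged or (
                    cand.support_fraction
                    > merged[key].support_fraction
                ):
                    merged[key] = cand
    out = []
    for key, cand in sorted(merged.items()):
        apply_filters(
            cand, gset, window,
            population_fractions=fractions[key],
            chimera_filter=chimera_filter,
        )
        out.append(cand)
    return out


def augment_reference(
    gset: GermlineSet, candidates: list[NovelCandidate]
) -> GermlineSet:
    """Individual-specific reference: documented alleles + passing candidates."""
    out = GermlineSet(list(gset))
    for cand in candidates:
        if not cand.passed:
            continue
        base = _resolve_base(out, *cand.base_allele)
        seq = list(base.sequence)
        pos_of = {p: i for i, p in enumerate(base.gapped_map)}
        for ref_nt, pos, alt in cand.snps:
            i = pos_of[pos]
            if seq[i] != ref_nt:
                raise ValueError(
                    f"{cand.name}: reference has {seq[i]} at {pos}, not {ref_nt}"
                )
            seq[i] = alt
        tokens = "_".join(f"{r}{p}{a}" for r, p, a in cand.snps)
        out.add(
            replace(
                base,
                allele=f"{base.allele}_{tokens}",
                sequence="".join(seq),
            )
        )
    return out


# ---------------------------------------------------------------------------
# upstream (5'UTR) consensus


def upstream_consensus(
    reads_by_allele: dict[str, list[str]],
    protocol_name: str = "full",
    min_depth: int = 3,
    cluster_threshold: float = 0.3,
) -> dict[str, list[tuple[str, int]]]:
    """Position-wise majority consensus of 5'UTR reads per allele.

    Reads are upstream sequences aligned at their 3' ends (the V start /
    L-PART boundary).  When a secondary variant at some position exceeds
    ``cluster_threshold`` of the reads, the reads are split on that
    position and separate consensus variants are reported.  Only the full
    (5'RACE) protocol carries upstream sequence.
    """
    if protocol_name != "full":
        raise UnsupportedProtocol("upstream consensus requires 5'RACE data")
    out: dict[str, list[tuple[str, int]]] = {}
    for allele, reads in reads_by_allele.items():
        reads = [r for r in reads if r]
        if len(reads) < min_depth:
            continue
        out[allele] = _consensus_clusters(reads, cluster_threshold)
    return out


def _consensus_clusters(reads: list[str], threshold: float):
    maxlen = max(len(r) for r in reads)
    padded = [r.rjust(maxlen, "-") for r in reads]  # 3'-end aligned
    # find the strongest secondary variant across positions
    split_pos, split_nt = None, None
    best_second = 0.0
    for i in range(maxlen):
        col = [r[i] for r in padded if r[i] != "-"]
        if len(col) < 2:
            continue
        freq = pd.Series(col).value_counts(normalize=True)
        if len(freq) > 1 and freq.iloc[1] > best_second:
            best_second = float(freq.iloc[1])
            split_pos, split_nt = i, freq.index[1]
    if best_second >= threshold and split_pos is not None:
        a = [r for r in padded if r[split_pos] == split_nt]
        b = [r for r in padded if r[split_pos] != split_nt]
        return [_majority(b), _majority(a)]
    return [_majority(padded)]


def _majority(padded: list[str]) -> tuple[str, int]:
    maxlen = len(padded[0])
    out = []
    for i in range(maxlen):
        col = [r[i] for r in padded if r[i] != "-"]
        if not col:
            continue
        out.append(pd.Series(col).value_counts().index[0])
    return "".join(out), len(padded)
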
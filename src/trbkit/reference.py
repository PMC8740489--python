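"""Germline reference handling.

Loads gene/allele reference sets from FASTA (IMGT pipe-delimited headers or
bare ``>TRBV6-2*01`` headers), computes protocol-restricted sequence views,
merges genes that a sequencing protocol cannot distinguish, and collapses
alleles into partial allelic-variation pattern groups (``bp``/``ap`` names).

Coordinates follow IMGT unique numbering: sequences are stored ungapped
together with an explicit map from ungapped index to the 1-based position on
the gapped alignment, so that SNP names like ``T285C`` refer to the gapped
frame regardless of reference gaps.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from Bio import SeqIO

_VALID_NT = set("ACGT")

# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class GermlineAllele:
    """One germline allele: gene symbol, allele designator, ungapped sequence.

    ``gapped_map[i]`` is the 1-based IMGT-numbering position of ungapped
    nucleotide ``i``; it is strictly increasing and jumps across reference
    gaps.
    """

    gene: str
    allele: str
    sequence: str
    gapped_map: tuple[int, ...]
    functionality: str = "functional"
    segment: str = "V"

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"{self.name}: empty sequence")
        bad = set(self.sequence) - _VALID_NT
        if bad:
            raise ValueError(f"{self.name}: non-ACGT characters {sorted(bad)}")
        if len(self.gapped_map) != len(self.sequence):
            raise ValueError(f"{self.name}: gapped_map length mismatch")
        diffs = np.diff(self.gapped_map)
        if len(diffs) and not (diffs > 0).all():
            raise ValueError(f"{self.name}: gapped_map not strictly increasing")

    @property
    def name(self) -> str:
        return f"{self.gene}*{self.allele}"

    def imgt_position(self, ungapped_index: int) -> int:
        """1-based IMGT position of 0-based ungapped index."""
        return self.gapped_map[ungapped_index]

    def regap(self) -> str:
        """Reconstruct the gapped sequence (IMGT dots) from the map."""
        out = []
        prev = 0
        for nt, pos in zip(self.sequence, self.gapped_map):
            out.append("." * (pos - prev - 1))
            out.append(nt)
            prev = pos
        return "".join(out)


@dataclass
class ProtocolSpec:
    """Sequencing-protocol description.

    ``per_gene_primer_end`` maps a gene to the 1-based position N (on the
    allele's own ungapped coordinates) at which the V primer ends; the
    protocol-restricted view of an allele is everything 3' of N.  The full
    (5'RACE) protocol has no primers and an empty map.
    """

    name: str  # full | biomed2 | adaptive
    per_gene_primer_end: dict[str, int] = field(default_factory=dict)
    j_anchor_length: int | None = None
    merged_gene_pairs: list[tuple[str, ...]] = field(default_factory=list)

    PREFIX = {"full": "", "biomed2": "bp", "adaptive": "ap"}

    def __post_init__(self):
        if self.name not in self.PREFIX:
            raise ValueError(f"unknown protocol {self.name!r}")
        if self.name == "full" and self.per_gene_primer_end:
            raise ValueError("full protocol takes no primer positions")

    @property
    def pattern_prefix(self) -> str:
        return self.PREFIX[self.name]

    def primer_end(self, gene: str) -> int:
        """Primer end N for a (possibly slash-merged) gene; 0 for full."""
        if self.name == "full":
            return 0
        for part in gene.split("/"):
            if part in self.per_gene_primer_end:
                return self.per_gene_primer_end[part]
        raise MissingPrimer(gene, self.name)

    @classmethod
    def from_yaml(cls, source) -> "ProtocolSpec":
        data = yaml.safe_load(source if isinstance(source, str) else source.read())
        return cls(
            name=data["name"],
            per_gene_primer_end=dict(data.get("per_gene_primer_end") or {}),
            j_anchor_length=data.get("j_anchor_length"),
        )


class MissingPrimer(KeyError):
    """A partial protocol has no primer for the requested gene.

    Mirrors genes that a primer set simply cannot amplify; callers may drop
    the gene from the analysis.
    """

    def __init__(self, gene: str, protocol: str):
        super().__init__(f"no {protocol} primer configured for gene {gene}")
        self.gene = gene
        self.protocol = protocol


@dataclass
class AllelePatternGroup:
    """Alleles indistinguishable within a protocol window, under one name."""

    pattern_name: str
    members: list[tuple[str, str]]  # (gene, allele)
    representative: str  # windowed sequence of the longest full reference

    def __post_init__(self):
        if not self.members:
            raise ValueError("empty pattern group")


class GermlineSet:
    """Collection of germline alleles indexed by gene."""

    def __init__(self, alleles: list[GermlineAllele] = ()):  # noqa: B006
        self._by_gene: dict[str, list[GermlineAllele]] = {}
        self._names: set[tuple[str, str]] = set()
        for a in alleles:
            self.add(a)

    def add(self, allele: GermlineAllele) -> None:
        key = (allele.gene, allele.allele)
        if key in self._names:
            raise ValueError(f"duplicate allele {allele.name}")
        self._names.add(key)
        self._by_gene.setdefault(allele.gene, []).append(allele)

    @property
    def genes(self) -> list[str]:
        return sorted(self._by_gene)

    def alleles(self, gene: str) -> list[GermlineAllele]:
        return list(self._by_gene.get(gene, []))

    def __iter__(self):
        for gene in self.genes:
            yield from self._by_gene[gene]

    def __len__(self):
        return len(self._names)

    def __contains__(self, gene: str) -> bool:
        return gene in self._by_gene

    def get(self, name: str) -> GermlineAllele:
        """Look up by full ``gene*allele`` name."""
        gene, _, allele = name.partition("*")
        for a in self._by_gene.get(gene, []):
            if a.allele == allele:
                return a
        raise KeyError(name)


# ---------------------------------------------------------------------------
# loading


_HEADER_RE = re.compile(r"^([A-Za-z0-9/\-\.]+)\*([A-Za-z0-9_\-]+)$")


def _parse_header(description: str) -> tuple[str, str, str]:
    """Return (gene, allele, functionality) from a FASTA description.

    Accepts the IMGT pipe-delimited dialect (field 2 = gene*allele, field 4 =
    functionality) and the bare ``gene*allele`` dialect.  A bare gene with no
    ``*`` gets allele ``01``.
    """
    fields = description.split("|")
    functionality = "functional"
    if len(fields) >= 4:
        token = fields[1].strip()
        func = fields[3].strip().strip("()")
        functionality = {"F": "functional", "ORF": "ORF", "P": "pseudogene"}.get(
            func, functionality
        )
    else:
        token = fields[0].split()[0].strip()
    if "*" not in token:
        token = token + "*01"
    m = _HEADER_RE.match(token)
    if not m:
        raise ValueError(f"cannot parse gene*allele from header {description!r}")
    return m.group(1), m.group(2), functionality


def load_reference(fasta_source, segment: str = "V") -> GermlineSet:
    """Load a germline reference set from a FASTA stream or path.

    IMGT alignment gaps (``.``) are stripped into the allele's
    ``gapped_map``; duplicate (gene, allele) pairs and non-ACGT/non-gap
    characters are hard errors naming the offending record.
    """
    if isinstance(fasta_source, str) and "\n" in fasta_source:
        fasta_source = io.StringIO(fasta_source)
    out = GermlineSet()
    n = 0
    for rec in SeqIO.parse(fasta_source, "fasta"):
        n += 1
        gene, allele, functionality = _parse_header(rec.description)
        gapped = str(rec.seq).upper()
        seq, gmap = [], []
        for pos, nt in enumerate(gapped, start=1):
            if nt == ".":
                continue
            if nt not in _VALID_NT:
                raise ValueError(
                    f"record {gene}*{allele}: invalid character {nt!r} at {pos}"
                )
            seq.append(nt)
            gmap.append(pos)
        out.add(
            GermlineAllele(
                gene=gene,
                allele=allele,
                sequence="".join(seq),
                gapped_map=tuple(gmap),
                functionality=functionality,
                segment=segment,
            )
        )
    if n == 0:
        warnings.warn("empty reference stream", stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# protocol windows


def window(allele: GermlineAllele, protocol: ProtocolSpec) -> str:
    """Protocol-restricted view of an allele.

    full -> identity; partial protocols -> the 3' subsequence starting at the
    first position following the gene's primer end N.  Raises
    :class:`MissingPrimer` when a partial protocol has no primer for the gene.
    """
    n = protocol.primer_end(allele.gene)
    if n == 0:
        return allele.sequence
    if n >= len(allele.sequence):
        raise ValueError(
            f"{allele.name}: primer end {n} not inside sequence "
            f"(length {len(allele.sequence)})"
        )
    return allele.sequence[n:]


def window_offset(allele: GermlineAllele, protocol: ProtocolSpec) -> int:
    """Ungapped index at which the protocol window starts (0 for full)."""
    return protocol.primer_end(allele.gene) if protocol.name != "full" else 0


# ---------------------------------------------------------------------------
# distances and merging


def _pad_distance(a: str, b: str) -> int:
    """Edit cost with free leading gaps on either sequence.

    Unit cost for mismatch, insertion and deletion; the first row/column of
    the DP table is zero so a shorter sequence can be left-padded for free,
    but internal and trailing gaps pay.
    """
    n, m = len(a), len(b)
    prev = np.zeros(m + 1, dtype=np.int64)
    bv = np.frombuffer(b.encode(), dtype=np.uint8)
    av = np.frombuffer(a.encode(), dtype=np.uint8)
    for i in range(1, n + 1):
        cur = np.empty(m + 1, dtype=np.int64)
        cur[0] = 0  # free leading gaps in b
        sub = prev[:-1] + (bv != av[i - 1])
        # row-wise minimum of substitution and deletion, then scan insertions
        np.minimum(sub, prev[1:] + 1, out=cur[1:])
        acc = cur[0]
        for j in range(1, m + 1):  # insertion dependency is sequential
            acc = cur[j] = min(cur[j], acc + 1)
        prev = cur
    return int(prev[m])


def gene_pair_distance(
    windowed_alleles_a: list[str], windowed_alleles_b: list[str]
) -> int:
    """Minimum padded-beginning alignment cost between two genes' windows.

    The distance between two genes is the minimum over all allele pairs of
    the global alignment cost with unit mismatch/indel penalties and cost-free
    leading padding; two genes at distance 0 are indistinguishable under the
    protocol.
    """
    if not windowed_alleles_a or not windowed_alleles_b:
        raise ValueError("gene_pair_distance requires non-empty allele lists")
    return min(
        _pad_distance(a, b) for a in windowed_alleles_a for b in windowed_alleles_b
    )


def _natural_key(gene: str):
    return [int(t) if t.isdigit() else t for t in re.split(r"(\d+)", gene)]


def merge_indistinguishable(
    gset: GermlineSet, protocol: ProtocolSpec
) -> GermlineSet:
    """Union genes whose protocol windows are at distance 0.

    Merging is a transitive closure: components of the distance-0 graph are
    joined under a slash label (``TRBV6-2/TRBV6-3``).  Genes lacking a primer
    under a partial protocol are dropped with a warning (they cannot be
    amplified, so they cannot be genotyped).  Merged groups are recorded on
    ``protocol.merged_gene_pairs``.
    """
    windows: dict[str, list[str]] = {}
    for gene in gset.genes:
        try:
            windows[gene] = [window(a, protocol) for a in gset.alleles(gene)]
        except MissingPrimer:
            warnings.warn(
                f"gene {gene} has no {protocol.name} primer; dropped", stacklevel=2
            )
    genes = sorted(windows, key=_natural_key)
    parent = {g: g for g in genes}

    def find(g):
        while parent[g] != g:
            parent[g] = parent[parent[g]]
            g = parent[g]
        return g

    for i, ga in enumerate(genes):
        for gb in genes[i + 1 :]:
            if gene_pair_distance(windows[ga], windows[gb]) == 0:
                parent[find(ga)] = find(gb)

    groups: dict[str, list[str]] = {}
    for g in genes:
        groups.setdefault(find(g), []).append(g)

    merged = GermlineSet()
    pairs = []
    for members in groups.values():
        members = sorted(members, key=_natural_key)
        label = "/".join(members)
        if len(members) > 1:
            pairs.append(tuple(members))
        for gene in members:
            for a in gset.alleles(gene):
                allele_id = a.allele if len(members) == 1 else f"{gene}*{a.allele}"
                merged.add(replace(a, gene=label, allele=allele_id))
    protocol.merged_gene_pairs = sorted(pairs)
    return merged


# ---------------------------------------------------------------------------
# pattern collapsing


def collapse_patterns(
    gset: GermlineSet, protocol: ProtocolSpec
) -> list[AllelePatternGroup]:
    """Partition each gene's alleles by identical protocol window.

    Under a partial protocol, groups are named ``gene*bpNN`` / ``gene*apNN``
    with dense two-digit numbering; the representative sequence is the window
    of the member whose full reference is longest.  Under the full protocol,
    alleles with identical full sequences still collapse (merged-gene
    duplicates), named by the slash-joined member alleles.
    """
    out: list[AllelePatternGroup] = []
    for gene in sorted(gset.genes, key=_natural_key):
        buckets: dict[str, list[GermlineAllele]] = {}
        order: list[str] = []
        for a in sorted(gset.alleles(gene), key=lambda x: _natural_key(x.allele)):
            w = window(a, protocol)
            if w not in buckets:
                order.append(w)
            buckets.setdefault(w, []).append(a)
        for idx, w in enumerate(order, start=1):
            members = buckets[w]
            longest = max(members, key=lambda a: len(a.sequence))
            if protocol.name == "full":
                # merged-gene members carry qualified allele ids already
                pattern_name = "/".join(
                    m.allele if "*" in m.allele else f"{gene}*{m.allele}"
                    for m in members
                )
            else:
                pattern_name = f"{gene}*{protocol.pattern_prefix}{idx:02d}"
            out.append(
                AllelePatternGroup(
                    pattern_name=pattern_name,
                    members=[(gene, m.allele) for m in members],
                    representative=window(longest, protocol),
                )
            )
    return out


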
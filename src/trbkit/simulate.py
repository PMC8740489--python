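"""Ground-truthed synthetic TRB repertoire population generator.

Emulates the statistical structure the inference stages assume: individual
genotypes drawn in Hardy-Weinberg proportions, deletion polymorphisms
linked in cis to tag alleles (the TRBV7-2*02-linked TRBV4-3/TRBV3-2
deletion), linkage disequilibrium between TRBD2 and TRBJ1-6, V(D)J reads
built with exonuclease trimming, G-biased untemplated N-addition and
substitution errors, the TRBD2->TRBJ2 rearrangement constraint, and
protocol truncation.  Every read is reconstructable from the returned
ground truth; identical seeds give identical output.

A bundled toy germline set (24 V genes, 2 D, 13 J, echoing real TRB name
structure) is generated deterministically so no external reference is
needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from trbkit.reference import GermlineAllele, GermlineSet, ProtocolSpec

NT = np.array(list("ACGT"))

# real-allele sequences: a single G/A SNP inside a G run separates TRBD2*01/*02
TRBD1_SEQ = "GGGACAGGGGGC"
TRBD2_01_SEQ = "GGGACTAGCGGGGGGG"
TRBD2_02_SEQ = "GGGACTAGCGGGAGGG"

V_LENGTH = 60  # toy V window length, multiple of 3, Cys codon at index 54
J_LENGTH = 24  # toy J length, Phe-Gly motif at index 9
V_CYS = "TGTGCC"
J_PHE = "TTTGGC"

V_GENE_NAMES = [
    "TRBV2", "TRBV3-1", "TRBV3-2", "TRBV4-1", "TRBV4-3", "TRBV5-1",
    "TRBV5-6", "TRBV6-1", "TRBV6-2", "TRBV6-3", "TRBV7-2", "TRBV7-3",
    "TRBV9", "TRBV10-3", "TRBV11-1", "TRBV12-3", "TRBV12-4", "TRBV18",
    "TRBV19", "TRBV20-1", "TRBV24-1", "TRBV27", "TRBV28", "TRBV30",
]
J_GENE_NAMES = [f"TRBJ1-{i}" for i in range(1, 7)] + [
    f"TRBJ2-{i}" for i in range(1, 8)
]

BIOMED2_PRIMER_END = 12  # toy FR2-like primer 3' end, same for all V genes
ADAPTIVE_PRIMER_END = 30  # toy FR3-like coverage start


def _mk_allele(gene, allele, seq, segment, functionality="functional"):
    return GermlineAllele(
        gene=gene,
        allele=allele,
        sequence=seq,
        gapped_map=tuple(range(1, len(seq) + 1)),
        functionality=functionality,
        segment=segment,
    )


def toy_germline() -> tuple[GermlineSet, GermlineSet, GermlineSet]:
    """Deterministic toy V/D/J germline sets.

    Engineered relationships, echoing the real locus: TRBV6-2*01 and
    TRBV6-3*01 identical full-length; TRBV12-3/TRBV12-4 differ only 5' of
    the BIOMED-2-like primer; TRBV3-1/TRBV3-2 differ only 5' of the
    Adaptive-like coverage start; TRBV7-2 and TRBV24-1 have two alleles
    each; TRBJ1-6 is the only biallelic J gene.
    """
    rng = np.random.default_rng(20210106)
    v = GermlineSet()
    seqs: dict[str, str] = {}
    for gene in V_GENE_NAMES:
        if gene == "TRBV6-3":
            seqs[gene] = seqs["TRBV6-2"]
            continue
        body = "".join(rng.choice(NT, size=V_LENGTH - 6))
        seqs[gene] = body + V_CYS
    # differ only upstream of the biomed2 primer end
    seqs["TRBV12-4"] = _mutate(seqs["TRBV12-3"], {3: "A", 7: "C"}, rng)
    # differ only upstream of the adaptive coverage start (but inside biomed2)
    seqs["TRBV3-2"] = _mutate(seqs["TRBV3-1"], {18: "T", 24: "G"}, rng)
    for gene in V_GENE_NAMES:
        functionality = "pseudogene" if gene == "TRBV3-2" else "functional"
        v.add(_mk_allele(gene, "01", seqs[gene], "V", functionality))
    # second documented alleles, SNPs inside both partial windows
    v.add(_mk_allele("TRBV7-2", "02", _mutate(seqs["TRBV7-2"], {38: None, 50: None}, rng), "V"))
    v.add(_mk_allele("TRBV24-1", "02", _mutate(seqs["TRBV24-1"], {44: None}, rng), "V"))

    d = GermlineSet()
    d.add(_mk_allele("TRBD1", "01", TRBD1_SEQ, "D"))
    d.add(_mk_allele("TRBD2", "01", TRBD2_01_SEQ, "D"))
    d.add(_mk_allele("TRBD2", "02", TRBD2_02_SEQ, "D"))

    j = GermlineSet()
    jseqs = {}
    for gene in J_GENE_NAMES:
        body5 = "".join(rng.choice(NT, size=9))
        body3 = "".join(rng.choice(NT, size=J_LENGTH - 9 - len(J_PHE)))
        jseqs[gene] = body5 + J_PHE + body3
        j.add(_mk_allele(gene, "01", jseqs[gene], "J"))
    j.add(_mk_allele("TRBJ1-6", "02", _mutate(jseqs["TRBJ1-6"], {18: None}, rng), "J"))
    return v, d, j


def _mutate(seq: str, changes: dict[int, str | None], rng) -> str:
    out = list(seq)
    for pos, alt in changes.items():
        if alt is None:
            alt = str(rng.choice([n for n in "ACGT" if n != out[pos]]))
        out[pos] = alt
    return "".join(out)


def toy_protocol(name: str) -> ProtocolSpec:
    """Protocol spec matching the toy germline coordinates."""
    if name == "full":
        return ProtocolSpec("full")
    end = BIOMED2_PRIMER_END if name == "biomed2" else ADAPTIVE_PRIMER_END
    return ProtocolSpec(
        name,
        per_gene_primer_end={g: end for g in V_GENE_NAMES},
        j_anchor_length=87 if name == "adaptive" else None,
    )


# ---------------------------------------------------------------------------
# population configuration


@dataclass
class PopulationConfig:
    """Study-condition parameters of a simulated population."""

    n_individuals: int = 10
    depth: int = 3000  # unique reads per sample
    error_rate: float = 0.001  # per-base substitution rate
    protocol: str = "full"
    seed: int = 0
    #: gene -> {allele: frequency}; unlisted genes are monomorphic *01
    allele_frequencies: dict = field(
        default_factory=lambda: {
            "TRBV7-2": {"01": 0.7, "02": 0.3},
            "TRBV24-1": {"01": 0.75, "02": 0.25},
            "TRBD2": {"01": 0.5, "02": 0.5},
            "TRBJ1-6": {"01": 0.5, "02": 0.5},
        }
    )
    #: genes deleted in cis with a tag allele
    deletion_haplotypes: list = field(
        default_factory=lambda: [
            {"tag_gene": "TRBV7-2", "tag_allele": "02",
             "deleted": ["TRBV4-3", "TRBV3-2"]},
        ]
    )
    #: P(TRBJ1-6 allele is the TRBD2-coupled one) on a haplotype:
    #: TRBD2*01 couples with TRBJ1-6*02 and vice versa
    d2_j16_ld: float = 0.9
    #: per-chromosome P(recombine TRBD2 rather than TRBD1), by TRBD2 allele
    d2_selection: dict = field(
        default_factory=lambda: {"01": 0.55, "02": 0.66}
    )
    #: J families TRBD2 may rearrange with (biological constraint)
    d2_j_families: tuple = ("TRBJ2",)
    #: relative J-gene usage weights (unlisted genes weight 1)
    j_usage: dict = field(default_factory=dict)
    #: mean exonuclease trimming per segment end (truncated geometric)
    trim_means: dict = field(
        default_factory=lambda: {"v3": 1.2, "d5": 1.8, "d3": 1.8, "j5": 1.2}
    )
    n_insert_mean: float = 3.0  # Poisson N-addition length per junction side
    g_bias: float = 0.45  # per-base G probability in N additions
    #: planted undocumented alleles: (gene, base allele, 1-based pos, alt, freq)
    novel_alleles: list = field(default_factory=list)

    def __post_init__(self):
        if any(not f.startswith("TRBJ2") for f in self.d2_j_families):
            raise ValueError("TRBD2 can rearrange only with TRBJ2 genes")
        for gene, freqs in self.allele_frequencies.items():
            total = sum(freqs.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"{gene}: allele frequencies sum to {total}")


@dataclass
class SimulatedSample:
    sample_id: str
    reads: list[str]
    truth: dict  # genotypes, haplotypes, per-read records


# trimming caps keep the V Cys codon and the J Phe motif intact
_TRIM_CAPS = {"v3": 5, "d5": 7, "d3": 7, "j5": 6}


def _trunc_geom(rng, mean: float, cap: int) -> int:
    if mean <= 0:
        return 0
    p = 1.0 / (1.0 + mean)
    return min(int(rng.geometric(p) - 1), cap)


def _n_insert(rng, mean: float, g_bias: float) -> str:
    n = int(rng.poisson(mean))
    if n == 0:
        return ""
    rest = (1.0 - g_bias) / 3.0
    return "".join(rng.choice(NT, size=n, p=[rest, rest, g_bias, rest]))


def _haplotype_pair(cfg: PopulationConfig, genes_v, rng):
    """Two chromosomes: gene -> allele (or None for deleted)."""
    haps = [{}, {}]
    for h in haps:
        # TRBD2 first, then the LD-coupled TRBJ1-6 allele
        d2_freqs = cfg.allele_frequencies.get("TRBD2", {"01": 1.0})
        d2 = str(rng.choice(list(d2_freqs), p=list(d2_freqs.values())))
        h["TRBD2"] = d2
        h["TRBD1"] = "01"
        coupled = "02" if d2 == "01" else "01"
        if rng.random() < cfg.d2_j16_ld:
            h["TRBJ1-6"] = coupled
        else:
            h["TRBJ1-6"] = "01" if coupled == "02" else "02"
        for gene in genes_v:
            freqs = cfg.allele_frequencies.get(gene, {"01": 1.0})
            h[gene] = str(rng.choice(list(freqs), p=list(freqs.values())))
        for jg in J_GENE_NAMES:
            if jg == "TRBJ1-6":
                continue
            freqs = cfg.allele_frequencies.get(jg, {"01": 1.0})
            h[jg] = str(rng.choice(list(freqs), p=list(freqs.values())))
        for novel in cfg.novel_alleles:
            gene, base, pos, alt, freq = novel
            if h.get(gene) == base and rng.random() < freq:
                h[gene] = f"{base}_{pos}{alt}"
        for link in cfg.deletion_haplotypes:
            if h.get(link["tag_gene"]) == link["tag_allele"]:
                for dg in link["deleted"]:
                    h[dg] = None
    return haps


_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def novel_spec(gene: str, base: str, pos: int, freq: float,
               alt: str | None = None) -> tuple:
    """Planted-novel-allele spec with a guaranteed real substitution.

    When ``alt`` is omitted the transition partner of the reference base at
    ``pos`` is used, so the plant is never a no-op.
    """
    v_set, _, _ = toy_germline()
    ref_nt = v_set.get(f"{gene}*{base}").sequence[pos - 1]
    if alt is None:
        alt = _TRANSITION[ref_nt]
    if alt == ref_nt:
        raise ValueError(f"{gene}*{base} already has {alt} at {pos}")
    return (gene, base, pos, alt, freq)


def _resolve_v_seq(gene, allele, v_set: GermlineSet, cfg: PopulationConfig):
    """Sequence of a (possibly planted-novel) V allele."""
    if "_" in allele:
        base, token = allele.split("_", 1)
        pos, alt = int(token[:-1]), token[-1]
        seq = list(v_set.get(f"{gene}*{base}").sequence)
        if seq[pos - 1] == alt:
            raise ValueError(
                f"planted SNP {gene}*{allele} is a no-op: reference already "
                f"has {alt} at {pos}"
            )
        seq[pos - 1] = alt
        return "".join(seq)
    return v_set.get(f"{gene}*{allele}").sequence


def simulate_population(
    cfg: PopulationConfig,
) -> tuple[list[SimulatedSample], GermlineSet, GermlineSet, GermlineSet]:
    """Simulate a population; returns (samples, v_set, d_set, j_set).

    The returned germline sets are the documented reference (planted novel
    alleles are NOT in it); each sample's ground truth records genotypes,
    haplotypes and per-read segment/trim/insert choices.  Deterministic
    under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    v_set, d_set, j_set = toy_germline()
    primer_end = {
        "full": 0, "biomed2": BIOMED2_PRIMER_END, "adaptive": ADAPTIVE_PRIMER_END
    }[cfg.protocol]

    samples = []
    for idx in range(cfg.n_individuals):
        sample_id = f"S{idx:03d}"
        haps = _haplotype_pair(cfg, V_GENE_NAMES, rng)
        reads: list[str] = []
        seen: set[str] = set()
        records = []
        attempts = 0
        max_attempts = cfg.depth * 20
        while len(reads) < cfg.depth and attempts < max_attempts:
            attempts += 1
            chrom = int(rng.integers(2))
            hap = haps[chrom]
            v_genes = [g for g in V_GENE_NAMES if hap.get(g) is not None]
            v_gene = str(rng.choice(v_genes))
            v_allele = hap[v_gene]
            d2_allele = hap["TRBD2"]
            use_d2 = rng.random() < cfg.d2_selection[d2_allele]
            if use_d2:
                d_gene, d_allele = "TRBD2", d2_allele
                j_pool = [g for g in J_GENE_NAMES if g.startswith("TRBJ2")]
            else:
                d_gene, d_allele = "TRBD1", "01"
                j_pool = J_GENE_NAMES
            jw = np.array([cfg.j_usage.get(g, 1.0) for g in j_pool])
            j_gene = str(rng.choice(j_pool, p=jw / jw.sum()))
            j_allele = hap[j_gene]

            v_seq = _resolve_v_seq(v_gene, v_allele, v_set, cfg)
            d_seq = d_set.get(f"{d_gene}*{d_allele}").sequence
            j_seq = j_set.get(f"{j_gene}*{j_allele}").sequence

            t = {k: _trunc_geom(rng, cfg.trim_means[k], _TRIM_CAPS[k])
                 for k in cfg.trim_means}
            d_core = d_seq[t["d5"]: len(d_seq) - t["d3"]]
            n1 = _n_insert(rng, cfg.n_insert_mean, cfg.g_bias)
            n2 = _n_insert(rng, cfg.n_insert_mean, cfg.g_bias)
            read = (
                v_seq[: len(v_seq) - t["v3"]] + n1 + d_core + n2 + j_seq[t["j5"]:]
            )
            if cfg.error_rate > 0:
                arr = np.array(list(read))
                hits = np.flatnonzero(rng.random(len(arr)) < cfg.error_rate)
                for i in hits:
                    arr[i] = rng.choice([n for n in "ACGT" if n != arr[i]])
                read = "".join(arr)
            read = read[primer_end:]
            if read in seen:
                continue
            seen.add(read)
            reads.append(read)
            records.append(
                {
                    "chromosome": chrom,
                    "v": f"{v_gene}*{v_allele}",
                    "d": f"{d_gene}*{d_allele}",
                    "j": f"{j_gene}*{j_allele}",
                    "trims": t,
                    "n1": n1,
                    "n2": n2,
                }
            )
        genotypes = {}
        for gene in list(V_GENE_NAMES) + ["TRBD1", "TRBD2"] + J_GENE_NAMES:
            alleles = {h[gene] for h in haps if h.get(gene) is not None}
            genotypes[gene] = tuple(sorted(alleles))
        samples.append(
            SimulatedSample(
                sample_id=sample_id,
                reads=reads,
                truth={
                    "genotypes": genotypes,
                    "haplotypes": [dict(h) for h in haps],
                    "reads": records,
                },
            )
        )
    return samples, v_set, d_set, j_set
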
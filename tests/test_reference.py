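"""Reference loading, protocol windows, gene merging, pattern collapsing."""

import io

import edlib
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trbkit.reference import (
    GermlineAllele,
    MissingPrimer,
    ProtocolSpec,
    collapse_patterns,
    gene_pair_distance,
    load_reference,
    merge_indistinguishable,
    window,
)
from trbkit.simulate import toy_protocol

NT = st.sampled_from("ACGT")
SEQ = st.text(alphabet="ACGT", min_size=1, max_size=12)


def _allele(gene, allele, seq):
    return GermlineAllele(gene, allele, seq, tuple(range(1, len(seq) + 1)))


# ---------------------------------------------------------------------------
# loading


def test_bare_header_parse():
    gs = load_reference(">TRBV6-2*01\nGGGACTAGC\n", segment="V")
    a = gs.get("TRBV6-2*01")
    assert a.gene == "TRBV6-2" and a.allele == "01" and a.sequence == "GGGACTAGC"


def test_imgt_pipe_header_parse():
    fasta = ">X57607|TRBV6-2*01|Homo sapiens|F|V-REGION|1..9|9 nt|1| | | | |9+0=9| |\nGGGACTAGC\n"
    a = load_reference(fasta).get("TRBV6-2*01")
    assert a.gene == "TRBV6-2"
    assert a.functionality == "functional"


def test_empty_stream_warns_and_is_valid():
    with pytest.warns(UserWarning, match="empty"):
        gs = load_reference(io.StringIO(""))
    assert len(gs) == 0


def test_duplicate_allele_is_hard_error():
    fasta = ">TRBV1*01\nACGT\n>TRBV1*01\nACGT\n"
    with pytest.raises(ValueError, match="duplicate"):
        load_reference(fasta)


def test_invalid_character_names_record():
    with pytest.raises(ValueError, match="TRBV1"):
        load_reference(">TRBV1*01\nACNT\n")


def test_gap_stripping_roundtrip():
    gapped = "AC...GT..A"
    gs = load_reference(f">TRBV1*01\n{gapped}\n")
    a = gs.get("TRBV1*01")
    assert a.sequence == "ACGTA"
    assert a.gapped_map == (1, 2, 6, 7, 10)
    assert a.regap() == gapped  # regap oracle: reconstruct the input


# ---------------------------------------------------------------------------
# windows


def test_full_protocol_window_is_identity(toy_sets):
    v, _, _ = toy_sets
    a = v.get("TRBV7-2*01")
    assert window(a, ProtocolSpec("full")) == a.sequence


def test_partial_window_is_suffix_after_primer():
    a = _allele("TRBVX", "01", "A" * 60 + "C" * 40)
    proto = ProtocolSpec("biomed2", per_gene_primer_end={"TRBVX": 60})
    assert window(a, proto) == "C" * 40


def test_gene_without_primer_raises_missing_primer():
    a = _allele("TRBV12-2", "01", "ACGTACGT")
    proto = ProtocolSpec("biomed2", per_gene_primer_end={"TRBV1": 4})
    with pytest.raises(MissingPrimer):
        window(a, proto)


# ---------------------------------------------------------------------------
# distances


def test_identical_alleles_distance_zero():
    assert gene_pair_distance(["ACGTACGT"], ["ACGTACGT"]) == 0


def test_single_mismatch_distance_one():
    assert gene_pair_distance(["ACGT"], ["ACGA"]) == 1


def test_free_leading_padding():
    # the shorter window may be left-padded at no cost
    assert gene_pair_distance(["TTTACGT"], ["ACGT"]) == 0


def test_empty_list_rejected():
    with pytest.raises(ValueError):
        gene_pair_distance([], ["ACGT"])


def _oracle_distance(a: str, b: str) -> int:
    """Free leading gaps on one side == best global distance over all
    single-side prefix skips (independent edlib oracle)."""
    best = min(
        edlib.align(a[i:], b, task="distance", mode="NW")["editDistance"]
        for i in range(len(a))
    )
    best = min(
        best,
        min(
            edlib.align(a, b[j:], task="distance", mode="NW")["editDistance"]
            for j in range(len(b))
        ),
    )
    return best


@settings(max_examples=200, derandomize=True)
@given(SEQ, SEQ)
def test_distance_matches_bruteforce_oracle(a, b):
    assert gene_pair_distance([a], [b]) == _oracle_distance(a, b)
    assert gene_pair_distance([a], [b]) == gene_pair_distance([b], [a])


# ---------------------------------------------------------------------------
# merging and patterns


def test_identical_genes_merge_under_full(toy_sets):
    v, _, _ = toy_sets
    proto = ProtocolSpec("full")
    merged = merge_indistinguishable(v, proto)
    assert "TRBV6-2/TRBV6-3" in merged.genes
    assert ("TRBV6-2", "TRBV6-3") in proto.merged_gene_pairs


def test_merging_is_idempotent(toy_sets):
    v, _, _ = toy_sets
    proto = ProtocolSpec("full")
    once = merge_indistinguishable(v, proto)
    twice = merge_indistinguishable(once, ProtocolSpec("full"))
    assert sorted(once.genes) == sorted(twice.genes)


def test_merging_is_protocol_monotone(toy_sets):
    """Shorter windows can only merge more: full <= biomed2 <= adaptive."""
    v, _, _ = toy_sets
    merged_pairs = {}
    for name in ("full", "biomed2", "adaptive"):
        proto = toy_protocol(name)
        merge_indistinguishable(v, proto)
        merged_pairs[name] = set(proto.merged_gene_pairs)
    assert merged_pairs["full"] <= merged_pairs["biomed2"]
    assert merged_pairs["biomed2"] <= merged_pairs["adaptive"]
    # engineered relationships in the toy set
    assert ("TRBV12-3", "TRBV12-4") in merged_pairs["biomed2"]
    assert ("TRBV12-3", "TRBV12-4") not in merged_pairs["full"]
    assert ("TRBV3-1", "TRBV3-2") in merged_pairs["adaptive"]
    assert ("TRBV3-1", "TRBV3-2") not in merged_pairs["biomed2"]


def test_patterns_partition_each_gene(toy_sets):
    v, _, _ = toy_sets
    for name in ("full", "biomed2", "adaptive"):
        proto = toy_protocol(name)
        merged = merge_indistinguishable(v, proto)
        patterns = collapse_patterns(merged, proto)
        seen = set()
        for p in patterns:
            for m in p.members:
                assert m not in seen  # partition: no allele in two groups
                seen.add(m)
        assert len(seen) == len(merged)
        # within-group windows identical, across-group windows differ
        by_gene = {}
        for p in patterns:
            by_gene.setdefault(p.members[0][0], []).append(p.representative)
        for reps in by_gene.values():
            assert len(reps) == len(set(reps))


def test_pattern_naming_and_representative():
    gs = load_reference(
        ">TRBV5-6*01\nAAACCCGGGTTTACGTACGT\n"
        ">TRBV5-6*02\nCCCCCCGGGTTTACGTACGT\n"  # differs only 5' of primer
        ">TRBV5-6*03\nAAACCCGGGTTTACGTACGA\n"
    )
    proto = ProtocolSpec("biomed2", per_gene_primer_end={"TRBV5-6": 8})
    patterns = collapse_patterns(gs, proto)
    names = {p.pattern_name: p for p in patterns}
    assert set(names) == {"TRBV5-6*bp01", "TRBV5-6*bp02"}
    grp = names["TRBV5-6*bp01"]
    assert sorted(grp.members) == [("TRBV5-6", "01"), ("TRBV5-6", "02")]
    assert grp.representative == "GTTTACGTACGT"


def test_full_protocol_patterns_are_singletons(toy_sets):
    v, _, _ = toy_sets
    proto = ProtocolSpec("full")
    patterns = collapse_patterns(v, proto)  # unmerged set: all singletons
    assert all(len(p.members) == 1 for p in patterns)
    assert any(p.pattern_name == "TRBV7-2*02" for p in patterns)
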
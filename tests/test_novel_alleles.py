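"""Undocumented allele detection, the six-filter battery, 5'UTR consensus."""

import pandas as pd
import pytest

from trbkit.novel_alleles import (
    BoundaryWindow,
    NovelCandidate,
    UnsupportedProtocol,
    apply_filters,
    augment_reference,
    chimera_check,
    detect_candidates,
    discover_population,
    modality_check,
    upstream_consensus,
)
from trbkit.reference import load_reference
from trbkit.repertoire_io import Repertoire

WINDOW = BoundaryWindow(start=6)


def _rep(rows, sample_id="S"):
    df = pd.DataFrame(rows)
    df["sequence_id"] = [f"{sample_id}_{i}" for i in range(len(df))]
    df["sequence"] = [f"A{i}" for i in range(len(df))]
    return Repertoire(df, sample_id=sample_id, dedup=False)


def _read_row(v_call="TRBV6-3*01", v_snps="", j_call="TRBJ1-1*01",
              cdr3_length=36):
    return {
        "v_call": v_call, "v_snps": v_snps, "j_call": j_call,
        "cdr3_length": cdr3_length, "d_call": "",
    }


# ---------------------------------------------------------------------------
# detection


def test_recurrent_snp_pattern_becomes_candidate():
    rows = (
        [_read_row(v_snps="G47A", j_call="TRBJ1-1*01", cdr3_length=33)] * 20
        + [_read_row(v_snps="G47A", j_call="TRBJ2-2*01", cdr3_length=36)] * 20
        + [_read_row()] * 60
    )
    cands = detect_candidates(_rep(rows), "TRBV6-3", window=WINDOW)
    assert len(cands) == 1
    c = cands[0]
    assert c.name == "TRBV6-3*01_G47A"
    assert c.support_fraction == pytest.approx(0.40)
    assert c.j_gene_count == 2 and c.cdr3_length_count == 2


def test_no_mismatches_no_candidates():
    cands = detect_candidates(_rep([_read_row()] * 100), "TRBV6-3",
                              window=WINDOW)
    assert cands == []


def test_snp_inside_primer_region_not_counted():
    # position 3 < window start 6: outside the boundary window
    rows = [_read_row(v_snps="G3A")] * 50 + [_read_row()] * 50
    cands = detect_candidates(_rep(rows), "TRBV6-3", window=WINDOW)
    assert cands == []


def test_absent_gene_gives_empty_list():
    cands = detect_candidates(_rep([_read_row()]), "TRBV99", window=WINDOW)
    assert cands == []


def test_singleton_pattern_below_floor_is_dropped():
    rows = [_read_row(v_snps="G47A")] + [_read_row()] * 99
    assert detect_candidates(_rep(rows), "TRBV6-3", window=WINDOW) == []


# ---------------------------------------------------------------------------
# filters


def _candidate(snps=(("C", 8, "T"),), support=0.4, cdr3=3, jg=3):
    return NovelCandidate(
        base_allele=("TRBVA", "01"),
        snps=tuple(snps),
        support_fraction=support,
        support_reads=40,
        cdr3_length_count=cdr3,
        j_gene_count=jg,
    )


@pytest.fixture(scope="module")
def tiny_reference():
    # 20-nt toy genes over a window starting at 6
    return load_reference(
        ">TRBVA*01\nAAAAACCCCCGGGGGTTTTT\n"
        ">TRBVB*01\nAAAAACCCCCGGGGGTTTAG\n"
        ">TRBVC*01\nTTTTTGGGGGCCCCCAAAAA\n"
    )


def test_low_support_fails_support_filter(tiny_reference):
    c = _candidate(support=0.04)
    flags = apply_filters(c, tiny_reference,
                          BoundaryWindow(start=6, end=20),
                          population_fractions={"S": 0.04})
    assert not flags["support"]


def test_single_cdr3_length_fails_diversity(tiny_reference):
    c = _candidate(cdr3=1)
    flags = apply_filters(c, tiny_reference, BoundaryWindow(start=6, end=20),
                          population_fractions={"S": 0.4})
    assert not flags["diversity"]


def test_adjacent_snps_fail_stretch_rule(tiny_reference):
    c = _candidate(snps=(("C", 8, "T"), ("C", 10, "A")))
    flags = apply_filters(c, tiny_reference, BoundaryWindow(start=6, end=20),
                          population_fractions={"S": 0.4})
    assert not flags["snp_stretch"]
    # four-apart SNPs are acceptable
    c2 = _candidate(snps=(("C", 8, "T"), ("G", 12, "A")))
    assert apply_filters(c2, tiny_reference,
                         BoundaryWindow(start=6, end=20),
                         population_fractions={"S": 0.4})["snp_stretch"]


def test_splice_constructible_candidate_fails_chimera(tiny_reference):
    # candidate window = TRBVA[6:17] + TRBVB[18:20] over positions 6..20:
    # CCCCCGGGGGTTT + AG  -> differs from A only at 19/20, matches a
    # prefix/suffix splice of A and B exactly
    c = NovelCandidate(
        base_allele=("TRBVA", "01"),
        snps=(("T", 19, "A"), ("T", 20, "G")),
        support_fraction=0.4,
        support_reads=40,
        cdr3_length_count=3,
        j_gene_count=3,
    )
    assert not chimera_check(c, tiny_reference, BoundaryWindow(start=6, end=20))
    # a SNP no splice can produce passes
    c2 = _candidate(snps=(("C", 8, "T"),))
    c2 = NovelCandidate(("TRBVA", "01"), (("C", 8, "T"),), 0.4, 40, 3, 3)
    assert chimera_check(c2, tiny_reference, BoundaryWindow(start=6, end=20))


def test_unimodal_low_fractions_fail_modality():
    fr = {f"S{i}": 0.02 + 0.001 * i for i in range(10)}
    assert not modality_check(fr)


def test_carrier_at_heterozygous_usage_passes_modality():
    fr = {"S0": 0.02, "S1": 0.45, "S2": 0.03}
    assert modality_check(fr)


def test_bimodal_low_fractions_pass_modality():
    fr = {f"a{i}": 0.01 for i in range(4)} | {f"b{i}": 0.15 for i in range(4)}
    assert modality_check(fr)


# ---------------------------------------------------------------------------
# population discovery and reference augmentation


def test_planted_allele_discovered_and_augments_reference(
    small_pipeline_result,
):
    cfg, res = small_pipeline_result
    passing = [c for c in res["candidates"] if c.passed]
    names = {c.name for c in passing}
    gene, base, pos, alt, _ = cfg.novel_alleles[0]
    ref_nt = {
        a.name: a.sequence for a in res["reference"][0]
    }[f"{gene}*{base}"][pos - 1]
    assert f"{gene}*{base}_{ref_nt}{pos}{alt}" in names
    aug = res["augmented_reference"]
    assert any("_" in a.allele for a in aug.alleles(gene))


def test_augmented_sequence_carries_the_snp(toy_sets):
    v, _, _ = toy_sets
    c = NovelCandidate(("TRBV9", "01"), (("", 30, ""),), 0.4, 40, 3, 3)
    ref = v.get("TRBV9*01").sequence
    alt = "A" if ref[29] != "A" else "C"
    c = NovelCandidate(("TRBV9", "01"), ((ref[29], 30, alt),), 0.4, 40, 3, 3)
    c.filter_flags = {"support": True}
    aug = augment_reference(v, [c])
    novel = aug.get(f"TRBV9*01_{ref[29]}30{alt}")
    assert novel.sequence[29] == alt
    assert novel.sequence[:29] == ref[:29]


# ---------------------------------------------------------------------------
# upstream consensus


def test_identical_upstream_reads_give_that_consensus():
    out = upstream_consensus({"TRBV9*01": ["ACGTACGT"] * 50})
    assert out["TRBV9*01"] == [("ACGTACGT", 50)]


def test_split_position_yields_two_consensus_variants():
    reads = ["ACGTAC"] * 60 + ["ACTTAC"] * 40
    out = upstream_consensus({"TRBV9*01": reads}, cluster_threshold=0.3)
    variants = {seq for seq, _ in out["TRBV9*01"]}
    assert variants == {"ACGTAC", "ACTTAC"}
    depths = sorted(d for _, d in out["TRBV9*01"])
    assert depths == [40, 60]


def test_partial_protocol_rejected_for_upstream():
    with pytest.raises(UnsupportedProtocol):
        upstream_consensus({"TRBV9*01": ["ACGT"] * 5}, protocol_name="adaptive")
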
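"""End-to-end pipeline: simulate or load reads, then infer everything.

Stage order: assign -> novel-allele discovery -> reference augmentation ->
re-assign against the individual-specific reference -> genotype (V, D) ->
TRBD2 group calling -> deletion tests -> anchor haplotyping -> usage
comparison.  Each stage's row counts land in the run manifest; identical
configurations reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from trbkit import __version__
from trbkit.deletions import infer_deletions, usage_table
from trbkit.genotype import genotype_repertoire
from trbkit.haplotype import (
    HaplotypeConfig,
    NotHeterozygous,
    choose_epsilon,
    infer_haplotype,
)
from trbkit.novel_alleles import augment_reference, discover_population
from trbkit.repertoire_io import Assigner, write_airr
from trbkit.simulate import PopulationConfig, simulate_population, toy_protocol
from trbkit.trbd2 import call_d2_groups, trbd2_fraction
from trbkit.usage_stats import compare_usage, comparisons_frame


def run_pipeline(cfg: PopulationConfig, outdir: Path | None = None) -> dict:
    """Run the full pipeline on a simulated population.

    Returns a result dict holding the manifest plus the in-memory stage
    outputs (repertoires, candidates, genotype tables, TRBD2 model,
    deletion table, haplotype tables, usage comparisons).  When ``outdir``
    is given, stage TSVs and the manifest are written there.
    """
    samples, v_set, d_set, j_set = simulate_population(cfg)
    if not samples or not any(s.reads for s in samples):
        raise ValueError("empty input: simulation produced no reads")
    protocol = toy_protocol(cfg.protocol)
    stage_counts: dict[str, int] = {"reads": sum(len(s.reads) for s in samples)}

    assigner = Assigner(v_set, d_set, j_set, protocol=protocol)
    reps = [
        assigner.assign_repertoire(s.reads, sample_id=s.sample_id)
        for s in samples
    ]
    stage_counts["assigned"] = sum(len(r) for r in reps)

    candidates = discover_population(reps, v_set)
    passing = [c for c in candidates if c.passed]
    stage_counts["novel_candidates"] = len(candidates)
    stage_counts["novel_passing"] = len(passing)

    if passing:
        v_aug = augment_reference(v_set, candidates)
        assigner = Assigner(v_aug, d_set, j_set, protocol=protocol)
        reps = [
            assigner.assign_repertoire(s.reads, sample_id=s.sample_id)
            for s in samples
        ]
    else:
        v_aug = v_set

    genotypes_v = pd.concat(
        [genotype_repertoire(r, "V") for r in reps], ignore_index=True
    )
    genotypes_d = pd.concat(
        [genotype_repertoire(r, "D") for r in reps], ignore_index=True
    )
    stage_counts["genotyped_genes"] = len(genotypes_v) + len(genotypes_d)

    fractions = {}
    for rep in reps:
        try:
            fractions[rep.sample_id] = trbd2_fraction(rep)
        except ValueError:
            pass
    d2_model = call_d2_groups(fractions) if len(fractions) >= 3 else None

    deletion_table = infer_deletions(reps)
    stage_counts["deletion_tests"] = int(
        (deletion_table["deleted"] != "").sum()
    )

    genotypes_j = pd.concat(
        [genotype_repertoire(r, "J") for r in reps], ignore_index=True
    )
    het_anchor = set(
        genotypes_j.loc[
            (genotypes_j["gene"] == "TRBJ1-6")
            & (genotypes_j["alleles"] == "01;02"),
            "sample_id",
        ]
    )
    haplotypes = {}
    for rep in reps:
        if rep.sample_id not in het_anchor:
            continue
        eps = choose_epsilon(rep, "TRBJ1-6")
        hcfg = HaplotypeConfig(
            anchor_gene="TRBJ1-6", anchor_alleles=("01", "02"), epsilon=eps
        )
        try:
            haplotypes[rep.sample_id] = infer_haplotype(rep, hcfg)
        except NotHeterozygous:
            continue
    stage_counts["haplotyped_samples"] = len(haplotypes)

    usage_v = usage_table(reps, segment="V")
    usage_j = usage_table(reps, segment="J")
    comparisons = None
    if d2_model is not None:
        groups = d2_model.group_calls
        sizes = pd.Series(groups).value_counts()
        if sizes.get("hom01", 0) >= 2 and sizes.get("hom02", 0) >= 2:
            comparisons = compare_usage(usage_j, groups, "hom01", "hom02")

    manifest = {
        "tool_version": __version__,
        "seed": cfg.seed,
        "config_hash": hashlib.sha256(
            json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "stage_counts": stage_counts,
    }
    result = {
        "manifest": manifest,
        "samples": samples,
        "repertoires": reps,
        "reference": (v_set, d_set, j_set),
        "augmented_reference": v_aug,
        "candidates": candidates,
        "genotypes_v": genotypes_v,
        "genotypes_d": genotypes_d,
        "genotypes_j": genotypes_j,
        "d2_model": d2_model,
        "deletions": deletion_table,
        "haplotypes": haplotypes,
        "usage_v": usage_v,
        "usage_j": usage_j,
        "usage_comparisons": comparisons,
    }
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _write_outputs(result: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for rep in result["repertoires"]:
        write_airr(rep, outdir / f"{rep.sample_id}.airr.tsv")
    result["genotypes_v"].to_csv(outdir / "genotypes_v.tsv", sep="\t", index=False)
    result["genotypes_d"].to_csv(outdir / "genotypes_d.tsv", sep="\t", index=False)
    result["deletions"].to_csv(outdir / "deletions.tsv", sep="\t", index=False)
    result["usage_v"].to_csv(outdir / "usage_v.tsv", sep="\t")
    result["usage_j"].to_csv(outdir / "usage_j.tsv", sep="\t")
    for sid, table in result["haplotypes"].items():
        table.to_csv(outdir / f"haplotype_{sid}.tsv", sep="\t", index=False)
    if result["usage_comparisons"]:
        comparisons_frame(result["usage_comparisons"]).to_csv(
            outdir / "usage_comparison_j.tsv", sep="\t", index=False
        )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result["manifest"], fh, indent=1)
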
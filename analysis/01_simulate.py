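#!/usr/bin/env python
"""Generate the synthetic study inputs used by the downstream analyses.

Emits, under results/sim/, a full-scale simulated EST collection (14,310
reads with planted ORFs, group-specific GC, 12% redundancy), the homology
hit table against an incomplete reference (completeness 0.662), the
conserved single-copy copy-number table, and the 14-species gene-family
matrix, each beside its ground-truth JSON. The probe-intensity matrix is
large and regenerated in memory by 04_expression_support.py instead of
being written here.
"""

from pathlib import Path

from orphanaudit import synth

OUT = Path(__file__).resolve().parent.parent / "results" / "sim"
CONFIG = synth.SimConfig(seed=1)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    est = synth.gen_est_set(CONFIG)
    synth.write_fasta(est.records, OUT / "ests.fasta")
    est.truth.to_json(OUT / "ests.truth.json")
    n_dup = sum(len(d) for d in est.truth.duplicate_groups.values())
    print(
        f"EST set: {len(est.records)} reads, "
        f"{est.truth.extras['n_unique_transcripts']} unique transcripts, "
        f"{n_dup} duplicate reads, {len(est.truth.homologs)} true homologs"
    )

    hit = synth.gen_homology_table(CONFIG)
    synth.write_hits(hit.hits, OUT / "hits.tsv")
    hit.truth.to_json(OUT / "hits.truth.json")
    print(
        f"homology: {len(hit.hits)} hit rows; "
        f"{len(hit.truth.detected_homologs)} of {len(hit.truth.homologs)} "
        "homologs detectable by the incomplete reference"
    )

    scen = synth.gen_copy_number_scenario(CONFIG)
    synth.write_table(scen.table, OUT / "copies.tsv")
    scen.truth.to_json(OUT / "copies.truth.json")
    print(
        f"copy-number: {len(scen.table)} families, "
        f"{len(scen.truth.multicopy_families)} multi-copy, "
        f"injected failure rate {scen.truth.injected_failure_rate:.4f}"
    )

    fam = synth.gen_family_matrix(CONFIG)
    synth.write_family_matrix(fam.matrix, OUT / "families.tsv")
    fam.truth.to_json(OUT / "families.truth.json")
    print(f"family matrix: {fam.matrix.shape[0]} families x {fam.matrix.shape[1]} species")
    print(f"wrote inputs to {OUT}")


if __name__ == "__main__":
    main()
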
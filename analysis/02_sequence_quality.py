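#!/usr/bin/env python
"""Sequence-quality audit: are unannotated reads simply worse reads?

Reads the simulated EST collection from 01_simulate.py (regenerating it if
absent), measures per-read ORF length, read length, start-codon presence
and GC content, and contrasts the annotated (true-homolog) and unannotated
groups with Welch's t-tests — the synthetic analogue of the real study's
quality comparison, where the groups differ in ORF length and GC yet
overlap heavily. Writes per-read metrics, group summaries, the Welch
statistics, and ORF-length histogram data under results/quality/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from orphanaudit import synth
from orphanaudit.orf import est_metrics, summarize_metrics, welch_t

ROOT = Path(__file__).resolve().parent.parent / "results"
SIM = ROOT / "sim"
OUT = ROOT / "quality"
CONFIG = synth.SimConfig(seed=1)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    if (SIM / "ests.fasta").exists():
        records = synth.read_fasta(SIM / "ests.fasta")
        truth = synth.TruthBundle.from_json(SIM / "ests.truth.json")
    else:
        est = synth.gen_est_set(CONFIG)
        records, truth = list(est.records), est.truth

    homologs = set(truth.homologs)
    partition = {
        r.id: ("annotated" if r.id in homologs else "unannotated") for r in records
    }
    metrics = est_metrics(records)
    metrics["group"] = metrics["est_id"].map(partition)
    metrics.to_csv(OUT / "est_metrics.tsv", sep="\t", index=False)

    groups = summarize_metrics(metrics, partition)
    summary = pd.DataFrame([vars(g) for g in groups.values()])
    summary.to_csv(OUT / "group_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))

    rows = []
    for col in ("orf_length_nt", "length_nt", "gc_percent"):
        a = metrics.loc[metrics["group"] == "annotated", col]
        b = metrics.loc[metrics["group"] == "unannotated", col]
        res = welch_t(a, b)
        rows.append(
            {
                "metric": col,
                "t": res.t_statistic,
                "df": res.degrees_of_freedom,
                "p": res.p_value,
                "mean_annotated": res.mean_a,
                "mean_unannotated": res.mean_b,
            }
        )
        print(
            f"{col}: t = {res.t_statistic:.2f}, df = {res.degrees_of_freedom:.0f}, "
            f"p = {res.p_value:.3g}"
        )
    pd.DataFrame(rows).to_csv(OUT / "welch_tests.tsv", sep="\t", index=False)

    bins = np.arange(0, metrics["orf_length_nt"].max() + 60, 60)
    hist = (
        metrics.groupby("group")["orf_length_nt"]
        .apply(lambda s: pd.Series(np.histogram(s, bins=bins)[0], index=bins[:-1]))
        .rename("n_reads")
        .reset_index()
        .rename(columns={"level_1": "orf_length_bin_nt"})
    )
    hist.to_csv(OUT / "orf_length_histogram.tsv", sep="\t", index=False)
    print(f"wrote quality tables to {OUT}")


if __name__ == "__main__":
    main()
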
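#!/usr/bin/env python
"""Run the four-filter candidate screen on the simulated count tables.

Reads results/counts.tsv (from 01_simulate_counts.py), applies the full
classification (candidate / uv_artifact / native_mod / background /
excluded) and compares the calls against the generator's truth sidecar.
"""

import argparse
from pathlib import Path

import pandas as pd

from ribopal import sitecalls

parser = argparse.ArgumentParser()
parser.add_argument("--results", type=Path, default=Path("results"))
args = parser.parse_args()

records = sitecalls.load_counts(args.results / "counts.tsv")
truth = pd.read_csv(args.results / "counts_truth.tsv", sep="\t")
calls = sitecalls.call_sites(records)

calls.to_csv(args.results / "site_calls.tsv", sep="\t", index=False)
sitecalls.write_bed(calls, args.results / "site_calls.bed")

merged = calls.merge(truth[["position", "category"]], on="position", suffixes=("", "_true"))
print("category counts:")
print(calls["category"].value_counts().to_string())
for cat in ("planted", "native_mod", "uv_artifact"):
    want = "candidate" if cat == "planted" else cat
    sub = merged[merged["category_true"] == cat]
    hit = (sub["category"] == want).sum()
    print(f"{cat}: {hit}/{len(sub)} recovered as {want}")
fp = merged[(merged["category"] == "candidate") & (merged["category_true"] != "planted")]
print(f"false-positive candidates: {len(fp)}")
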
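#!/usr/bin/env python
"""Pharmacogenomic landscape: actionable phenotype tabulation, putative
LOF screen of the ten LOF-mechanism pharmacogenes, and the CDC Tier 1
disease-risk x pharmacogenetics intersection.

Outputs: results/pgx_phenotype_counts.tsv, results/pgx_summary.json.
"""

import argparse
import json
from pathlib import Path

from cohortscreen import load_bundle
from cohortscreen.pipeline import run_pipeline

ap = argparse.ArgumentParser(description=__doc__)
ap.add_argument("--bundle", type=Path, default=Path("scratch/bundle"))
ap.add_argument("--out", type=Path, default=Path("results"))
args = ap.parse_args()

r = run_pipeline(load_bundle(args.bundle))
s = r.pgx_summary
print(f"{s['n_with_actionable']}/{s['n_total']} individuals "
      f"({s['pct_with_actionable']}%) carry >=1 actionable pharmacogenetic "
      f"finding; median {s['median_findings']:.0f} findings per individual")
print(f"putative novel LOF variants in the 10 LOF-mechanism pharmacogenes: "
      f"{len(r.lof_screen)}")
t = r.tier1
print(f"CDC Tier 1 at-risk carriers: {t['overall']['at_risk']}, of whom "
      f"{t['overall']['joint']} ({t['overall']['pct']}%) also carry an "
      "actionable phenotype for drugs used in their condition:")
for cond, d in t["per_condition"].items():
    print(f"  {cond}: {d['joint']}/{d['at_risk']} ({d['pct']}%)")

args.out.mkdir(parents=True, exist_ok=True)
anc = dict(zip(r.bundle.samples.index, r.assigned))
counts = (r.phenotypes.assign(ancestry=r.phenotypes["sample_id"].map(anc))
          .groupby(["gene", "phenotype", "actionable", "ancestry"])
          .size().rename("carriers").reset_index())
counts.to_csv(args.out / "pgx_phenotype_counts.tsv", sep="\t", index=False)
(args.out / "pgx_summary.json").write_text(json.dumps({
    "actionable": {k: v for k, v in s.items() if k != "per_gene"},
    "per_gene": s["per_gene"],
    "tier1": {"overall": t["overall"],
              "per_condition": {c: {k: v for k, v in d.items()
                                    if k != "joint_ids"}
                                for c, d in t["per_condition"].items()}},
    "lof_screen": list(r.lof_screen["key"]),
}, indent=1))
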
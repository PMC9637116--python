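#!/usr/bin/env python
"""Ingest the bundle (with genotype QC), classify every retained variant,
and confirm gross deletions.

Outputs: results/classification.tsv, results/sv_filter.tsv.
"""

import argparse
from pathlib import Path

from cohortscreen import load_bundle
from cohortscreen.classifier import classify_all, filter_all_deletions

ap = argparse.ArgumentParser(description=__doc__)
ap.add_argument("--bundle", type=Path, default=Path("scratch/bundle"))
ap.add_argument("--out", type=Path, default=Path("results"))
args = ap.parse_args()

bundle = load_bundle(args.bundle)
classes = classify_all(bundle.variants, bundle.dosage, bundle.catalog,
                       bundle.evidence)
args.out.mkdir(parents=True, exist_ok=True)
classes.to_csv(args.out / "classification.tsv", sep="\t")

counts = classes["category"].value_counts()
print(f"retained variants: {len(classes)} of {len(bundle.variants)}")
print("categories:", dict(counts))
print("tiers:", dict(classes[classes.category == 'P/LP']
                     ["tier"].value_counts()))
print(f"flagged for manual review: "
      f"{int(classes['needs_manual_review'].sum())}")

svs = filter_all_deletions(bundle.svs, bundle.catalog)
svs.to_csv(args.out / "sv_filter.tsv", sep="\t", index=False)
print(f"gross deletions passing duphold/LOFi-exon filter: "
      f"{int(svs['pass'].sum())} of {len(svs)}")
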
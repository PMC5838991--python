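#!/usr/bin/env python
"""Match the cohort's reported alterations against the default knowledge base.

Encodes the curated actionable-alteration table as kept alterations, runs
the matcher, and reports the distinct actionable patients.  Writes
results/actionable_matches.tsv.
"""

from pathlib import Path

from escvar.actionability import (
    actionable_patients,
    load_knowledge_base,
    match_alterations,
    matches_to_frame,
)
from escvar.datasets import reported_actionable_alterations

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    rules = load_knowledge_base("default")
    variants, cnvs = reported_actionable_alterations()
    matches = match_alterations(variants, cnvs, rules)
    matches_to_frame(matches).to_csv(
        ROOT / "results" / "actionable_matches.tsv", sep="\t", index=False
    )
    patients = sorted(actionable_patients(matches), key=int)
    print(f"knowledge base: {len(rules)} rules over "
          f"{len({r.gene for r in rules})} genes")
    print(f"matches: {len(matches)} alteration-rule pairs")
    print(f"actionable patients: {len(patients)} of 15 -> {', '.join(patients)}")


if __name__ == "__main__":
    main()
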
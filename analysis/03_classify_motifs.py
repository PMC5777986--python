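"""Classify every screen hit by its N-terminal charge architecture.

Assigns each hit to E3K8 / E2K8 / K8_ONLY / TATB_LIKE / TATA_LIKE /
UNCHARGED_OTHER / OTHER_CHARGED / TOO_SHORT from its first eight residues,
writes classes.tsv, and compares the tallies against the generator's
ground truth.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from tatscan.motif import classify_full, classify_set, tallies_as_dict
from tatscan.records import SequenceSet, read_fasta

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    argparse.ArgumentParser(description=__doc__).parse_args()
    out = ROOT / "results" / "survey"
    db = read_fasta(out / "input" / "db.faa")
    hit_ids = list(pd.read_csv(out / "hits.tsv", sep="\t")["subject"])
    hits = SequenceSet(records=[db[rid] for rid in hit_ids])
    lines = ["record_id\tclass\tresidue8\tgly_glu_order\tcharges"]
    for rec in hits:
        full = classify_full(rec)
        charges = ";".join(f"{p}:{r}:{pol}" for p, r, pol in full.profile.charges)
        lines.append(f"{rec.record_id}\t{full.motif_class.value}"
                     f"\t{full.profile.residue8}\t{full.gly_glu_order}\t{charges}")
    (out / "classes.tsv").write_text("\n".join(lines) + "\n")
    classes, tallies = classify_set(hits)
    print("class tallies over", len(hits), "hits:")
    print(json.dumps(tallies_as_dict(tallies), indent=2))

    truth = dict(
        pd.read_csv(out / "input" / "truth.tsv", sep="\t").itertuples(index=False)
    )
    scored = [rid for rid in classes if rid in truth]
    agree = sum(1 for rid in scored if classes[rid].value == truth[rid])
    print(f"agreement with generator ground truth: {agree}/{len(scored)} "
          f"({100.0 * agree / len(scored):.1f}%)")


if __name__ == "__main__":
    main()
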
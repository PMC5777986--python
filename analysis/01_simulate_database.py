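"""Generate the synthetic survey database.

Builds the synthetic analogue of a TatA-family database survey -- a
TatE-type ortholog family with controlled Lys8/Glu3 conservation, paired
charged/uncharged Vibrionales paralogs, TatA-, TatB-, K8-only and
otherwise-charged subfamilies across several Orders, decoys and incomplete
entries -- and writes query.faa, db.faa, taxonomy.tsv and truth.tsv under
results/survey/input/.
"""

import argparse
from collections import Counter
from pathlib import Path

from tatscan.records import SequenceSet, write_fasta, write_taxonomy
from tatscan.simulate import build_survey_database

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    out = ROOT / "results" / "survey" / "input"
    out.mkdir(parents=True, exist_ok=True)
    sdb = build_survey_database(args.seed)
    write_fasta(SequenceSet(records=[sdb.query]), out / "query.faa")
    write_fasta(sdb.db, out / "db.faa")
    write_taxonomy(sdb.tax_rows, out / "taxonomy.tsv")
    lines = ["record_id\tclass"] + [f"{rid}\t{cls.value}" for rid, cls in sdb.truth.items()]
    (out / "truth.tsv").write_text("\n".join(lines) + "\n")
    tally = Counter(cls.value for cls in sdb.truth.values())
    print(f"wrote {len(sdb.db)} records ({len(sdb.truth)} family members) to {out}")
    print("ground-truth class composition:", dict(sorted(tally.items())))


if __name__ == "__main__":
    main()
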
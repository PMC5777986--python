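"""Aggregate motif classes by taxonomy and detect dual-paralog genomes.

Produces the per-(Class, Order) tally table (survey.tsv) and the list of
organisms encoding both a charged-motif TatA-family paralog and an
uncharged TatA-type one (dual_paralogs.tsv) -- the TatA_1/TatA_2 pattern.
"""

import argparse
from pathlib import Path

import pandas as pd

from tatscan.motif import classify_set
from tatscan.records import SequenceSet, attach_taxonomy, read_fasta, read_taxonomy
from tatscan.survey import tabulate

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    argparse.ArgumentParser(description=__doc__).parse_args()
    out = ROOT / "results" / "survey"
    db = attach_taxonomy(
        read_fasta(out / "input" / "db.faa"), read_taxonomy(out / "input" / "taxonomy.tsv")
    )
    hit_ids = list(pd.read_csv(out / "hits.tsv", sep="\t")["subject"])
    hits = SequenceSet(records=[db[rid] for rid in hit_ids])
    classes, _ = classify_set(hits)
    report = tabulate(hits, classes)
    (out / "survey.tsv").write_text(report.to_tsv())
    (out / "dual_paralogs.tsv").write_text(report.dual_paralogs_tsv())
    print(f"{'Class':<24}{'Order':<20}{'total':>6}{'charged':>8}")
    for row in report.rows:
        print(f"{row.class_:<24}{row.order:<20}{row.total:>6}{row.n_charged:>8}")
    print(f"{'all':<24}{'all':<20}{report.grand_total:>6}{report.grand_charged:>8}")
    print(f"\ndual-paralog organisms (charged + uncharged TatA-family paralogs): "
          f"{len(report.dual_paralog_organisms)}")
    example = report.dual_paralog_organisms[0]
    print(f"example: {example.organism}: {example.charged[0][0]} "
          f"({example.charged[0][1].value}) + {example.uncharged[0][0]} "
          f"({example.uncharged[0][1].value})")


if __name__ == "__main__":
    main()
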
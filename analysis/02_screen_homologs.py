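"""Screen the database with the TatE-type query.

Local alignment (BLOSUM62, 11/1) of the query against every complete
database entry, keeping hits with Karlin-Altschul E <= 1e-3.  Writes
hits.tsv (outfmt-6-like) and screen_tally.json under results/survey/.
"""

import argparse
import json
from pathlib import Path

from tatscan.alignment import TABULAR_HEADER, ScoringScheme
from tatscan.records import read_fasta
from tatscan.screen import ScreenConfig, screen

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--evalue", type=float, default=1e-3)
    args = parser.parse_args()
    indir = ROOT / "results" / "survey" / "input"
    out = ROOT / "results" / "survey"
    query = read_fasta(indir / "query.faa")[0]
    db = read_fasta(indir / "db.faa")
    result = screen(query, db, ScreenConfig(e_cutoff=args.evalue), ScoringScheme())
    lines = [TABULAR_HEADER] + [res.to_tabular() for _, res in result.hits]
    (out / "hits.tsv").write_text("\n".join(lines) + "\n")
    (out / "screen_tally.json").write_text(
        json.dumps(result.tally(), sort_keys=True, indent=2) + "\n"
    )
    decoy_hits = sum(1 for rec, _ in result.hits if rec.record_id.startswith("DECOY"))
    print(f"screened {result.n_input} records: {result.n_hits} hits at E <= {args.evalue:g}, "
          f"{result.n_removed_incomplete} removed as incomplete, "
          f"{result.n_above_cutoff} above cutoff")
    print(f"decoy false hits: {decoy_hits}")
    best = result.hits[0][1]
    print(f"best hit: {best.subject_id} (E = {best.e_value:.2g}, "
          f"{best.percent_identity:.1f}% identity)")


if __name__ == "__main__":
    main()
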
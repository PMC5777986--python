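"""Consensus model of the TatE-type ortholog family.

Progressively aligns the TatE-annotated hits, writes the alignment
(msa.afa), the per-column consensus model (consensus.tsv) and the logo
matrix (logo.tsv), and reports the conservation of the two charged
N-terminal positions -- the lysine at position 8 and the glutamate at
position 3 -- anchored to the first family member's coordinates.
"""

import argparse
from pathlib import Path

import pandas as pd

from tatscan.alignment import ScoringScheme
from tatscan.msa import (
    align_progressive,
    column_for_reference_position,
    consensus,
    logo_matrix_tsv,
    write_aligned_fasta,
)
from tatscan.records import SequenceSet, read_fasta

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    argparse.ArgumentParser(description=__doc__).parse_args()
    out = ROOT / "results" / "survey"
    db = read_fasta(out / "input" / "db.faa")
    tax = pd.read_csv(out / "input" / "taxonomy.tsv", sep="\t").fillna("")
    hit_ids = set(pd.read_csv(out / "hits.tsv", sep="\t")["subject"])
    fam_ids = [
        a for a in tax[tax["annotated_name"] == "TatE"]["accession"] if a in hit_ids
    ]
    fam = SequenceSet(records=[db[rid] for rid in fam_ids])
    print(f"aligning {len(fam)} TatE-annotated hits ...")
    msa = align_progressive(fam, ScoringScheme())
    write_aligned_fasta(msa, out / "msa.afa")
    model = consensus(msa)
    (out / "consensus.tsv").write_text(model.to_tsv())
    (out / "logo.tsv").write_text(logo_matrix_tsv(model))
    ref = fam.ids[0]
    for pos in (2, 3, 8):
        col = column_for_reference_position(msa, ref, pos)
        c = model.columns[col]
        print(f"position {pos}: consensus {c.consensus_residue}, "
              f"conservation {100.0 * c.conservation:.1f}%, "
              f"information {c.information_content:.2f} bits")
    print(f"consensus N-terminus: {model.consensus[:10]}")


if __name__ == "__main__":
    main()
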
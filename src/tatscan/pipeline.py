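"""End-to-end survey pipeline: screen -> classify -> align -> consensus -> survey.

Stages communicate through files (TSV/FASTA) inside a run directory so
each stage is independently inspectable, and a manifest records input
checksums, the resolved configuration and all tallies.  Reruns on the same
inputs are byte-identical: nothing written depends on wall-clock time or
dictionary order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from tatscan.alignment import TABULAR_HEADER, ScoringScheme
from tatscan.motif import classify_full, classify_set, tallies_as_dict
from tatscan.msa import align_progressive, consensus, logo_matrix_tsv, write_aligned_fasta
from tatscan.records import attach_taxonomy, read_fasta, read_taxonomy
from tatscan.screen import ScreenConfig, screen
from tatscan.survey import tabulate

logger = logging.getLogger(__name__)

_PKG_VERSION = "0.1.0"

ARTIFACTS = [
    "hits.tsv",
    "classes.tsv",
    "msa.afa",
    "consensus.tsv",
    "logo.tsv",
    "survey.tsv",
    "dual_paralogs.tsv",
    "run_manifest.json",
]


class PipelineError(RuntimeError):
    """A stage failure, prefixed with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    query_fasta: str
    db_fasta: str
    outdir: str
    taxonomy_tsv: str | None = None
    e_cutoff: float = 1e-3
    min_length: int = 40
    exclude_x_fraction: float = 0.05
    require_initiator_met: bool = True
    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lambda_: float = 0.267
    kappa: float = 0.041
    consensus_annotated_name: str = "TatE"
    reference_id: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def scheme(self) -> ScoringScheme:
        return ScoringScheme(
            matrix_name=self.matrix_name,
            gap_open=self.gap_open,
            gap_extend=self.gap_extend,
            lambda_=self.lambda_,
            kappa=self.kappa,
        )

    def screen_config(self) -> ScreenConfig:
        return ScreenConfig(
            e_cutoff=self.e_cutoff,
            min_length=self.min_length,
            exclude_x_fraction=self.exclude_x_fraction,
            require_initiator_met=self.require_initiator_met,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _classes_tsv(records, seed_order: list[str]) -> str:
    lines = ["record_id\tclass\tresidue8\tgly_glu_order\tcharges"]
    for rec in records:
        full = classify_full(rec)
        charges = ";".join(f"{p}:{r}:{pol}" for p, r, pol in full.profile.charges)
        lines.append(
            f"{rec.record_id}\t{full.motif_class.value}\t{full.profile.residue8}"
            f"\t{full.gly_glu_order}\t{charges}"
        )
    return "\n".join(lines) + "\n"


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run the full survey; returns the run directory.

    Artifacts: hits.tsv, classes.tsv, msa.afa, consensus.tsv, logo.tsv,
    survey.tsv, dual_paralogs.tsv and run_manifest.json.  A stage failure
    raises :class:`PipelineError` naming the stage; the manifest is then
    marked incomplete.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("tatscan")
    root.addHandler(handler)
    root.setLevel(getattr(logging, cfg.log_level.upper(), logging.INFO))
    manifest: dict = {
        "config": cfg.to_dict(),
        "version": _PKG_VERSION,
        "inputs": {},
        "tallies": {},
        "complete": False,
    }
    try:
        stage = "read_inputs"
        query_set = read_fasta(cfg.query_fasta)
        if len(query_set) == 0:
            raise PipelineError(stage, f"no sequences in query file {cfg.query_fasta}")
        query = query_set[0]
        db = read_fasta(cfg.db_fasta)
        manifest["inputs"]["query_fasta"] = _sha256(Path(cfg.query_fasta))
        manifest["inputs"]["db_fasta"] = _sha256(Path(cfg.db_fasta))
        if cfg.taxonomy_tsv:
            tax = read_taxonomy(cfg.taxonomy_tsv)
            db = attach_taxonomy(db, tax)
            manifest["inputs"]["taxonomy_tsv"] = _sha256(Path(cfg.taxonomy_tsv))

        stage = "screen"
        scheme = cfg.scheme()
        result = screen(query, db, cfg.screen_config(), scheme)
        lines = [TABULAR_HEADER] + [res.to_tabular() for _, res in result.hits]
        (outdir / "hits.tsv").write_text("\n".join(lines) + "\n")
        (outdir / "screen_tally.json").write_text(
            json.dumps(result.tally(), sort_keys=True, indent=2) + "\n"
        )
        manifest["tallies"]["screen"] = result.tally()
        hit_set = result.hit_set()
        logger.info("screen: %d hits of %d records", result.n_hits, result.n_input)

        stage = "classify"
        classes, tallies = classify_set(hit_set)
        (outdir / "classes.tsv").write_text(_classes_tsv(hit_set, hit_set.ids))
        manifest["tallies"]["classes"] = tallies_as_dict(tallies)

        stage = "consensus"
        group = [
            rec for rec in hit_set if rec.annotated_name == cfg.consensus_annotated_name
        ]
        if len(group) < 2:
            group = list(hit_set)
        if len(group) >= 2:
            from tatscan.records import SequenceSet

            group_set = SequenceSet(records=group, source_label="consensus group")
            msa = align_progressive(group_set, scheme)
            write_aligned_fasta(msa, outdir / "msa.afa")
            model = consensus(msa)
            (outdir / "consensus.tsv").write_text(model.to_tsv())
            (outdir / "logo.tsv").write_text(logo_matrix_tsv(model))
            manifest["tallies"]["consensus"] = {
                "n_sequences": model.n_sequences,
                "n_columns": len(model.columns),
            }
        else:
            (outdir / "msa.afa").write_text("")
            (outdir / "consensus.tsv").write_text("column\tconsensus\tconservation\tinformation_bits\n")
            (outdir / "logo.tsv").write_text("column\tresidue\theight\n")
            manifest["tallies"]["consensus"] = {"n_sequences": len(group), "n_columns": 0}

        stage = "survey"
        report = tabulate(hit_set, classes)
        (outdir / "survey.tsv").write_text(report.to_tsv())
        (outdir / "dual_paralogs.tsv").write_text(report.dual_paralogs_tsv())
        manifest["tallies"]["survey"] = {
            "grand_total": report.grand_total,
            "grand_charged": report.grand_charged,
            "n_dual_paralog_organisms": len(report.dual_paralog_organisms),
        }

        manifest["complete"] = True
    except PipelineError:
        _write_manifest(outdir, manifest)
        raise
    except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
        _write_manifest(outdir, manifest)
        raise PipelineError(stage, str(exc)) from exc
    finally:
        root.removeHandler(handler)
        handler.close()
    _write_manifest(outdir, manifest)
    return outdir


def _write_manifest(outdir: Path, manifest: dict) -> None:
    (outdir / "run_manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=2) + "\n"
    )
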
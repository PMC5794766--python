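"""End-to-end design runs: orthologs -> ORF placement -> window enumeration
-> off-target screen -> ranking -> T7 templates -> conservation report.

Every stage writes plain-text artifacts (FASTA/BED/TSV/JSON) into the output
directory, and the run report carries per-stage record counts and a filter
attrition table so the run is auditable. Output is a pure function of
(inputs, config, seed); timestamps never enter checksummed artifacts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import seq as sq
from .config import PipelineConfig
from .conserve import identity_matrix, match_catalogue
from .orthologs import OrthologFilters, find_orthologs
from .triggers import (
    TriggerConstraints,
    enumerate_windows,
    make_t7_template,
    rank_windows,
    screen_windows,
    windows_to_bed,
)


@dataclass
class RunReport:
    stages: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    config_echo: dict = field(default_factory=dict)
    version: str = ""

    def add_stage(self, name: str, n_in: int, n_kept: int, **extra) -> None:
        self.stages.append(
            {"stage": name, "input": n_in, "kept": n_kept,
             "dropped": n_in - n_kept, **extra}
        )

    def to_json(self) -> str:
        return json.dumps(
            {"version": self.version, "config": self.config_echo,
             "stages": self.stages, "warnings": self.warnings},
            indent=2, default=str,
        )


def run_design_pipeline(cfg: PipelineConfig) -> RunReport:
    """Execute the full design workflow; artifacts land under cfg.out_dir.

    A hard failure in any stage aborts the run with the stage name; partial
    artifacts are kept under a ``failed/`` marker file.
    """
    from . import __version__

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(version=__version__,
                       config_echo=json.loads(cfg.model_dump_json()))
    constraints = TriggerConstraints(**cfg.constraints.model_dump())
    stage = "setup"
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")

            stage = "load_inputs"
            transcripts = sq.read_fasta(cfg.transcriptome, "nucleotide")
            report.add_stage(stage, len(transcripts), len(transcripts))

            stage = "orthologs"
            selected_ids = [t.id for t in transcripts]
            if cfg.queries is not None:
                queries = sq.read_fasta(cfg.queries, "protein")
                filters = OrthologFilters(**cfg.filters.model_dump())
                calls = find_orthologs(queries, transcripts, filters)
                rows = []
                for c in calls:
                    rows.append({
                        "query": c.query_id, "status": c.status,
                        "subject": c.best.subject_id if c.best else None,
                        "frame": c.best.subject_frame if c.best else None,
                        "score": c.best.score if c.best else None,
                        "identity_pct": c.best.identity_pct if c.best else None,
                        "coverage_pct": c.best.coverage_pct if c.best else None,
                        "e_value": c.best.e_value if c.best else None,
                        "n_rejected": len(c.rejected),
                    })
                pd.DataFrame(rows).to_csv(out / "ortholog_calls.tsv", sep="\t", index=False)
                selected_ids = sorted({c.best.subject_id for c in calls if c.best})
                report.add_stage(stage, len(queries),
                                 sum(1 for c in calls if c.status == "found"))
            by_id = {t.id: t for t in transcripts}
            selected = [by_id[i] for i in selected_ids]

            stage = "orf_placement"
            if cfg.orfs_bed is not None:
                orfs = {
                    iv.chrom: sq.OrfAnnotation(iv.chrom, iv.start, iv.end, iv.strand)
                    for iv in sq.read_bed(cfg.orfs_bed)
                    if iv.chrom in by_id
                }
            else:
                orfs = {}
                for t in selected:
                    o = sq.principal_orf(t, min_len_nt=cfg.min_orf_nt)
                    if o is not None:
                        orfs[t.id] = o
            sq.write_bed(sq.orfs_to_bed(orfs.values()), out / "orfs.bed")
            report.add_stage(stage, len(selected), len(orfs))

            stage = "enumerate_windows"
            all_windows = {}
            for tid, orf in sorted(orfs.items()):
                ws, reason = enumerate_windows(by_id[tid], orf, constraints, step=cfg.step)
                if reason:
                    report.warnings.append(f"{tid}: {reason}")
                all_windows[tid] = ws
            n_enum = sum(len(v) for v in all_windows.values())
            report.add_stage(stage, len(orfs), n_enum)

            stage = "screen_windows"
            offtargets = {
                label: sq.read_fasta(p, "nucleotide")
                for label, p in sorted(cfg.offtarget_sets.items())
            }
            motifs = []
            if cfg.motif_list is not None:
                motifs = [ln.strip() for ln in Path(cfg.motif_list).read_text().splitlines()
                          if ln.strip() and not ln.startswith("#")]
            screened, accepted = {}, {}
            for tid, ws in all_windows.items():
                sws = screen_windows(ws, by_id[tid], offtargets, motifs, constraints)
                screened[tid] = sws
                accepted[tid] = [w for w in sws if w.accepted]
            n_acc = sum(len(v) for v in accepted.values())
            report.add_stage(stage, n_enum, n_acc)

            stage = "rank_windows"
            ranked = {tid: rank_windows(ws) for tid, ws in accepted.items()}
            rows = []
            for tid in sorted(ranked):
                for w in screened[tid]:
                    rows.append({
                        "transcript": tid, "start": w.start, "end": w.end,
                        "length": w.length, "gc_pct": round(w.gc_pct, 2),
                        "margin_5": w.margin_5, "margin_3": w.margin_3,
                        "flags": ",".join(sorted(w.flags)) or ".",
                    })
            pd.DataFrame(rows).to_csv(out / "windows.tsv", sep="\t", index=False)
            bed = []
            for tid in sorted(ranked):
                bed.extend(windows_to_bed(ranked[tid]))
            sq.write_bed(bed, out / "windows_ranked.bed")
            report.add_stage(stage, n_acc, n_acc)

            stage = "t7_templates"
            triggers, primer_rows = [], []
            for tid in sorted(ranked):
                if not ranked[tid]:
                    continue
                best = ranked[tid][0]
                insert = best.sequence(by_id[tid])
                tmpl = make_t7_template(insert)
                name = f"{tid}_trigger_{best.start}_{best.end}"
                triggers.append(sq.SequenceRecord(name, insert, "nucleotide",
                                                  f"gc={best.gc_pct:.1f}"))
                primer_rows.append({"trigger": name, "fwd_primer": tmpl.fwd_primer,
                                    "rev_primer": tmpl.rev_primer})
            if triggers:
                sq.write_fasta(triggers, out / "triggers.fasta")
            pd.DataFrame(primer_rows).to_csv(out / "t7_primers.tsv", sep="\t", index=False)
            report.add_stage(stage, len(ranked), len(triggers))

            stage = "conservation_report"
            if cfg.conservation_sets:
                cons = {label: sq.read_fasta(p, "nucleotide")
                        for label, p in sorted(cfg.conservation_sets.items())}
                lines = []
                gene_ids = sorted({r.id for recs in cons.values() for r in recs})
                for gid in gene_ids:
                    per_species = {
                        label: next((r for r in recs if r.id == gid), None)
                        for label, recs in cons.items()
                    }
                    cat = match_catalogue(per_species, gene=gid, k=cfg.k,
                                          strands=cfg.strands)
                    lines.extend(cat.report_lines())
                    present = [r for r in per_species.values() if r is not None]
                    if len(present) >= 2:
                        for rep in identity_matrix(present, "nucleotide"):
                            lines.append(
                                f"  identity {rep.id_a}|{rep.id_b}: "
                                f"{rep.identity_pct:.1f}% over {rep.alignment_length} columns"
                            )
                (out / "conservation_report.txt").write_text("\n".join(lines) + "\n")
                report.add_stage(stage, len(gene_ids), len(gene_ids))

            report.warnings.extend(str(w.message) for w in caught)
    except Exception as exc:
        (out / "failed").write_text(f"stage={stage}\nerror={exc}\n")
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    (out / "run_report.json").write_text(report.to_json())
    return report
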
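"""End-to-end orchestration: trim -> QC -> concatenate -> tree -> MK.

Stages are also exposed as individual CLI subcommands so any intermediate
(alignments, the concatemer tree, the taxon split) can be swapped for a
user-supplied one.  A run writes, under the output directory:

    qc_report.tsv           one row per input gene (QC metrics, pass flag)
    rejected/               low-quality gene alignments
    concatemer.fasta        per-genome concatenation of passing genes
    concatemer.nwk          UPGMA tree of the concatemer
    summary_<direction>.tsv per-gene MK/diversity table, one per direction
    aggregate_<direction>.tsv   NI_TG with CI and gene accounting
    sfs_<direction>.tsv     pooled unfolded site-frequency spectrum
    pipeline.log            stage-prefixed log lines

Every input gene ends up in exactly one of: summary rows, the QC-rejected
set, or the error log.  All randomness (PHI permutations, the NI_TG
bootstrap) derives from the single run seed via named substreams, so a
rerun with the same inputs and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from . import __version__
from .align_qc import QCParams, QCReport, trim_and_evaluate
from .errors import AggregateError, CoreMKError, InputError, QCError
from .mk_engine import CoreGenomeResult, MKConfig, run_direction
from .phylo import TaxonSplit, Tree, first_split, jc69_distance, upgma, write_newick
from .sequence_io import (
    GeneAlignment,
    concatenate,
    get_code,
    handle_internal_stops,
    mask_ambiguous_codons,
    read_gene_alignment,
    write_gene_alignment,
)


@dataclass
class RunConfig:
    input_dir: str
    output_dir: str
    pattern: str = "*.fasta"
    qc: QCParams = field(default_factory=QCParams)
    table_id: int = 11
    mask_internal_stops: bool = False
    outgroup_mode: str = "consensus"
    check_congruency: bool = True
    exclude_incongruent: bool = True
    run_phi: bool = True
    phi_window: int = 100
    phi_permutations: int = 1000
    phi_alpha: float = 0.05
    exclude_recombinants: bool = False
    n_bootstrap: int = 10_000
    seed: int = 0
    ingroup: Optional[List[str]] = None   # explicit split (else: auto from tree)
    outgroup: Optional[List[str]] = None

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "qc" in raw and isinstance(raw["qc"], dict):
            raw["qc"] = QCParams(**raw["qc"])
        return cls(**raw)


@dataclass
class PipelineResult:
    output_dir: Path
    tree: Tree
    split: TaxonSplit
    directions: List[CoreGenomeResult]
    qc_reports: List[QCReport]
    n_input_genes: int
    log_lines: List[str]


def _fmt(x, digits: int = 10) -> str:
    if x is None:
        return "NA"
    if isinstance(x, bool):
        return str(int(x))
    if isinstance(x, float):
        return f"{x:.{digits}g}"
    return str(x)


def write_summary_tsv(result: CoreGenomeResult, path) -> None:
    cols = [
        "gene_id", "n_ingroup", "n_outgroup", "codons_used",
        "P_N", "P_S", "D_N", "D_S", "NI", "DoS", "test_used",
        "p_value", "q_value", "pi", "theta", "sfs", "congruent", "phi_p",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in result.per_gene:
            d = r.diversity
            sfs = ",".join(str(v) for v in d.sfs_unfolded) if d else "NA"
            fh.write(
                "\t".join(
                    [
                        r.gene_id,
                        str(len(result.ingroup)),
                        str(len(result.outgroup)),
                        str(r.counts.codons_used),
                        _fmt(r.counts.P_N), _fmt(r.counts.P_S),
                        _fmt(r.counts.D_N), _fmt(r.counts.D_S),
                        _fmt(r.NI), _fmt(r.DoS), _fmt(r.test_used),
                        _fmt(r.p_value), _fmt(r.q_value),
                        _fmt(d.pi if d else None), _fmt(d.theta_w if d else None),
                        sfs,
                        _fmt(r.congruent) if r.congruent is not None else "NA",
                        _fmt(r.phi_p),
                    ]
                )
                + "\n"
            )


def write_aggregate_tsv(result: CoreGenomeResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("field\tvalue\n")
        fh.write(f"direction_label\t{result.direction_label}\n")
        fh.write(f"ingroup\t{','.join(sorted(result.ingroup))}\n")
        fh.write(f"outgroup\t{','.join(sorted(result.outgroup))}\n")
        fh.write(f"NI_TG\t{_fmt(result.NI_TG)}\n")
        fh.write(f"ci_low\t{_fmt(result.ci_low)}\n")
        fh.write(f"ci_high\t{_fmt(result.ci_high)}\n")
        fh.write(f"n_genes_included\t{result.n_genes_included}\n")
        fh.write(f"n_genes_excluded\t{result.n_genes_excluded}\n")


def write_sfs_tsv(result: CoreGenomeResult, path) -> None:
    """Pooled unfolded spectrum (two columns: frequency class, count)."""
    pooled: Dict[int, int] = {}
    for r in result.per_gene:
        if r.diversity is None:
            continue
        for k, count in enumerate(r.diversity.sfs_unfolded, start=1):
            pooled[k] = pooled.get(k, 0) + count
    with open(path, "w") as fh:
        fh.write("frequency_class\tcount\n")
        for k in sorted(pooled):
            fh.write(f"{k}\t{pooled[k]}\n")


def load_genes(input_dir, pattern: str = "*.fasta") -> List[GeneAlignment]:
    paths = sorted(Path(input_dir).glob(pattern))
    if not paths:
        raise InputError(f"no gene alignments matching {pattern!r} in {input_dir}")
    return [read_gene_alignment(p) for p in paths]


def run_pipeline(config: RunConfig) -> PipelineResult:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "rejected").mkdir(exist_ok=True)
    log: List[str] = []
    code = get_code(config.table_id)

    genes_in = load_genes(config.input_dir, config.pattern)
    log.append(f"[input] read {len(genes_in)} gene alignments from {config.input_dir}")

    passed: List[GeneAlignment] = []
    reports: List[QCReport] = []
    errored: Dict[str, str] = {}
    rejected: List[str] = []
    for gene in genes_in:
        try:
            gene, n_masked = mask_ambiguous_codons(gene)
            gene = handle_internal_stops(gene, code, mask=config.mask_internal_stops)
            trimmed, report = trim_and_evaluate(gene, config.qc)
        except QCError as exc:
            errored[gene.gene_id] = f"qc: {exc}"
            log.append(f"[qc] {gene.gene_id}: discarded ({exc})")
            continue
        except CoreMKError as exc:
            errored[gene.gene_id] = str(exc)
            log.append(f"[input] {gene.gene_id}: discarded ({exc})")
            continue
        reports.append(report)
        if report.passed:
            passed.append(trimmed)
        else:
            rejected.append(gene.gene_id)
            write_gene_alignment(trimmed, out / "rejected" / f"{gene.gene_id}.fasta")
    log.append(
        f"[qc] {len(passed)} genes passed, {len(rejected)} rejected, "
        f"{len(errored)} errored"
    )
    with open(out / "qc_report.tsv", "w") as fh:
        fh.write(
            "gene_id\toriginal_length_codons\ttrimmed_length_codons\t"
            "overlap_fraction\tlongest_indel_codons\tpassed\n"
        )
        for r in reports:
            fh.write(
                f"{r.gene_id}\t{r.original_length_codons}\t{r.trimmed_length_codons}\t"
                f"{_fmt(r.overlap_fraction)}\t{r.longest_indel_codons}\t{int(r.passed)}\n"
            )
    if not passed:
        raise InputError("no gene passed quality control")

    concatemer = concatenate(passed)
    write_gene_alignment(concatemer, out / "concatemer.fasta")
    tree = upgma(jc69_distance(concatemer))
    write_newick(tree, out / "concatemer.nwk")
    log.append(f"[tree] concatemer of {concatemer.n_codons} codons; UPGMA tree written")

    if config.ingroup and config.outgroup:
        split = TaxonSplit(frozenset(config.ingroup), frozenset(config.outgroup))
        log.append("[split] using explicit ingroup/outgroup assignment")
    else:
        split = first_split(tree)
        log.append(
            f"[split] first split: {sorted(split.clade_a)} | {sorted(split.clade_b)}"
        )

    mk_config = MKConfig(
        table_id=config.table_id,
        outgroup_mode=config.outgroup_mode,
        n_bootstrap=config.n_bootstrap,
        seed=config.seed,
        check_congruency=config.check_congruency,
        exclude_incongruent=config.exclude_incongruent,
        run_phi=config.run_phi,
        phi_window=config.phi_window,
        phi_permutations=config.phi_permutations,
        phi_alpha=config.phi_alpha,
        exclude_recombinants=config.exclude_recombinants,
    )

    directions: List[CoreGenomeResult] = []
    for i, clade in enumerate(split.clades(), start=1):
        label = f"direction{i}"
        if len(clade) < 2:
            log.append(f"[mk] {label}: skipped (ingroup clade has {len(clade)} member)")
            continue
        try:
            result = run_direction(
                passed, split, frozenset(clade), mk_config, direction_label=label
            )
        except AggregateError as exc:
            log.append(f"[mk] {label}: skipped ({exc})")
            continue
        for gid in result.failed_genes:
            log.append(f"[mk] {label}: {gid} excluded (no usable codon columns)")
        write_summary_tsv(result, out / f"summary_{label}.tsv")
        write_aggregate_tsv(result, out / f"aggregate_{label}.tsv")
        write_sfs_tsv(result, out / f"sfs_{label}.tsv")
        log.append(
            f"[mk] {label}: NI_TG={result.NI_TG:.4f} "
            f"[{result.ci_low:.4f}, {result.ci_high:.4f}] over "
            f"{result.n_genes_included} genes"
        )
        directions.append(result)
    if not directions:
        raise InputError("no direction has an ingroup clade with >= 2 members")

    manifest = {
        "version": __version__,
        "config": {
            k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
            for k, v in dataclasses.asdict(config).items()
        },
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(out / "pipeline.log", "w") as fh:
        fh.write("\n".join(log) + "\n")

    return PipelineResult(
        output_dir=out,
        tree=tree,
        split=split,
        directions=directions,
        qc_reports=reports,
        n_input_genes=len(genes_in),
        log_lines=log,
    )
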
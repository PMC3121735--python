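"""End-to-end orchestration: simulate -> calibrate -> genotype -> ASE -> AI
-> UTR -> expression -> report.

Every stage is file-to-file inside one run directory: a stage reads only
the declared outputs of earlier stages and writes its own TSV/JSON files,
so stages can be re-run individually (and the CLI exposes them as
subcommands).  All thresholds default to the pipeline's canonical values:
coverage >= 25, duplicate ceiling 50%, calibration percentile 0.95, ASE
alpha 0.01, AI alpha 0.05 with fold-change bounds 2 / 0.5, expressed at
RPM > 0.1.  A fixed seed makes a whole run reproducible file-for-file.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import ase as ase_mod
from . import expression as expr_mod
from . import imbalance as ai_mod
from . import io as io_mod
from . import simulate as sim_mod
from . import utr as utr_mod
from .counts import counts_from_frame, select_loci
from .genotype import HeterozygosityCaller
from .io import CellMeta, read_allele_counts, read_bedgraph, read_snp_table

logger = logging.getLogger(__name__)

SUMMARY_ROWS = [
    "selected loci",
    "# of Heterozygous",
    "# of ASE",
    "# expected ASE false positives",
    "# Allelic Imbalance (AI)",
    "# expected AI false positives",
    "ASE (%)",
    "AI (%)",
]


@dataclass
class RunConfig:
    """Parameters of one pipeline run."""

    seed: int = 0
    outdir: str = "scallele_run"
    n_control_cells: int = 12
    min_coverage: int = 25
    max_dup_frac: float = 0.5
    percentile: float = 0.95
    alpha_ase: float = 0.01
    alpha_ai: float = 0.05
    fc_hi: float = 2.0
    fc_lo: float = 0.5
    rpm_threshold: float = 0.1
    utr_min_step_ratio: float = 3.0
    utr_smooth_window: int = 50
    utr_min_segment: int = 100
    utr_tolerance: int = 50
    utr_min_fraction: float = 0.5
    sim: sim_mod.SimulationConfig = field(default_factory=sim_mod.SimulationConfig)

    def __post_init__(self) -> None:
        if isinstance(self.sim, dict):
            self.sim = sim_mod.SimulationConfig(**self.sim)
        self.sim.seed = self.seed
        for name in ("min_coverage", "percentile", "alpha_ase", "alpha_ai",
                     "fc_hi", "fc_lo", "rpm_threshold", "utr_min_step_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def _outdir(config: RunConfig) -> Path:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _write_cells(cells: list[CellMeta], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("cell_id\tembryo_id\tstage\tis_control\n")
        for c in cells:
            fh.write(f"{c.cell_id}\t{c.embryo_id}\t{c.stage}\t{int(c.is_control)}\n")


def _read_cells(path: Path) -> list[CellMeta]:
    df = pd.read_csv(path, sep="\t", dtype={"embryo_id": str})
    return [CellMeta(r.cell_id, "" if pd.isna(r.embryo_id) else r.embryo_id,
                     r.stage, bool(r.is_control))
            for r in df.itertuples(index=False)]


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: RunConfig) -> Path:
    """Generate all synthetic inputs into the run directory."""
    out = _outdir(config)
    result = sim_mod.generate_cells(config.sim)
    control = sim_mod.generate_control_cells(config.sim, config.n_control_cells)

    io_mod.write_allele_counts(result.counts, out / "counts.tsv")
    io_mod.write_allele_counts(control.counts, out / "control_counts.tsv")
    io_mod.write_snp_tsv(result.loci.values(), out / "snps.tsv")
    io_mod.write_snp_vcf(result.loci.values(), out / "snps.vcf")
    genes = pd.DataFrame(
        [(l.chrom, l.pos - 51, l.pos + 50, l.gene_id, 0, l.tx_strand)
         for l in sorted(result.loci.values(), key=lambda l: (l.chrom, l.pos))],
        columns=["chrom", "start", "end", "name", "score", "strand"])
    io_mod.write_bed_genes(genes, out / "genes.bed")
    result.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    control.truth.to_csv(out / "control_truth.tsv", sep="\t", index=False)
    _write_cells(result.cells + control.cells, out / "cells.tsv")

    cell_ids = [c.cell_id for c in result.cells]
    bedgraphs, utr_truth, seqs = sim_mod.generate_utr_coverage(config.sim, cell_ids)
    for cell_id, bg in bedgraphs.items():
        io_mod.write_bedgraph(bg, out / f"utr_coverage_{cell_id}.bedgraph")
    utr_truth.to_csv(out / "utr_truth.tsv", sep="\t", index=False)
    _write_fasta(seqs, out / "utr_sequences.fa")
    config.to_yaml(out / "config.yaml")
    logger.info("simulate: %d cells, %d loci, %d UTR genes",
                len(cell_ids), config.sim.n_loci, config.sim.utr_params.n_genes)
    return out


def _write_fasta(seqs: dict[str, str], path: Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in sorted(seqs.items())]
    seqio_write(records, str(path), "fasta")


def _read_fasta(path: Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def stage_calibrate(config: RunConfig) -> Path:
    out = _outdir(config)
    loci = read_snp_table(out / "snps.tsv", dialect="tsv")
    control = counts_from_frame(read_allele_counts(out / "control_counts.tsv"))
    model = HeterozygosityCaller(
        percentile=config.percentile, min_coverage=config.min_coverage,
        max_dup_frac=config.max_dup_frac).fit(control, loci)
    model.save(out / "calibration.json")
    logger.info("calibrate: threshold %.4f from %d pooled loci",
                model.threshold_, model.n_loci_pooled_)
    return out / "calibration.json"


def stage_genotype(config: RunConfig) -> Path:
    out = _outdir(config)
    loci = read_snp_table(out / "snps.tsv", dialect="tsv")
    counts = counts_from_frame(read_allele_counts(out / "counts.tsv"))
    model = HeterozygosityCaller.load(out / "calibration.json")

    rows = []
    for cell_id in sorted(counts):
        for key in sorted(counts[cell_id]):
            locus = loci.get(key)
            if locus is None:
                continue
            sac = counts[cell_id][key]
            flt = select_loci(sac, locus, config.min_coverage, config.max_dup_frac)
            ref, alt = sac.ref_alt(locus)
            genotype, maf = "", float("nan")
            if flt.criterion3 and flt.criterion4 and flt.criterion5 and ref + alt > 0:
                call = model.call(sac, locus)
                genotype, maf = call.genotype, call.maf
            rows.append((cell_id, sac.chrom, sac.pos, sac.coverage, ref, alt,
                         round(maf, 6), int(flt.criterion1), int(flt.criterion2),
                         int(flt.criterion3), int(flt.criterion4), int(flt.criterion5),
                         int(flt.passed), genotype))
    df = pd.DataFrame(rows, columns=[
        "cell_id", "chrom", "pos", "coverage", "ref_count", "alt_count", "maf",
        "c1", "c2", "c3", "c4", "c5", "selected", "genotype"])
    df.to_csv(out / "genotypes.tsv", sep="\t", index=False)
    n_sel = int(df["selected"].sum())
    logger.info("genotype: %d rows, %d selected, %d het",
                len(df), n_sel, int((df["selected"].astype(bool)
                                     & (df["genotype"] == "het")).sum()))
    return out / "genotypes.tsv"


def _het_keys(genotypes: pd.DataFrame) -> dict[str, set]:
    het = genotypes[(genotypes["selected"] == 1) & (genotypes["genotype"] == "het")]
    out: dict[str, set] = {}
    for row in het.itertuples(index=False):
        out.setdefault(row.cell_id, set()).add((row.chrom, int(row.pos)))
    return out


def stage_ase(config: RunConfig) -> Path:
    out = _outdir(config)
    loci = read_snp_table(out / "snps.tsv", dialect="tsv")
    counts = counts_from_frame(read_allele_counts(out / "counts.tsv"))
    genotypes = pd.read_csv(out / "genotypes.tsv", sep="\t")
    het_keys = _het_keys(genotypes)
    selected = genotypes[genotypes["selected"] == 1].groupby("cell_id").size()

    call_rows = []
    summary_rows = []
    for cell_id in sorted(counts):
        het = [(counts[cell_id][k], loci[k]) for k in sorted(het_keys.get(cell_id, set()))]
        if len(het) < ase_mod.MIN_NULL_LOCI:
            logger.warning("ase: cell %s has %d het loci (<%d); skipped",
                           cell_id, len(het), ase_mod.MIN_NULL_LOCI)
            continue
        calls, summary = ase_mod.call_ase(het, alpha=config.alpha_ase,
                                          n_selected=int(selected.get(cell_id, 0)))
        summary_rows.append(summary)
        call_rows.extend(
            (c.cell_id, c.chrom, c.pos, c.ref_count, c.alt_count,
             round(c.log2_ratio, 6), round(c.p_value, 6), int(c.is_ase))
            for c in calls)
    pd.DataFrame(call_rows, columns=[
        "cell_id", "chrom", "pos", "ref_count", "alt_count",
        "log2_allelic_ratio", "p_value", "is_ase"]).to_csv(
        out / "ase.tsv", sep="\t", index=False)
    pd.DataFrame(summary_rows).to_csv(out / "ase_summary.tsv", sep="\t", index=False)
    return out / "ase.tsv"


def stage_ai(config: RunConfig) -> Path:
    out = _outdir(config)
    loci = read_snp_table(out / "snps.tsv", dialect="tsv")
    counts = counts_from_frame(read_allele_counts(out / "counts.tsv"))
    genotypes = pd.read_csv(out / "genotypes.tsv", sep="\t")
    het_keys = _het_keys(genotypes)
    cells = [c for c in _read_cells(out / "cells.tsv") if not c.is_control]
    by_embryo: dict[str, list[str]] = {}
    for c in cells:
        by_embryo.setdefault(c.embryo_id, []).append(c.cell_id)

    all_calls = []
    for embryo_id, embryo_cells in sorted(by_embryo.items()):
        all_calls.extend(ai_mod.call_ai_embryo(
            counts, het_keys, loci, embryo_id, embryo_cells,
            alpha=config.alpha_ai, fc_hi=config.fc_hi, fc_lo=config.fc_lo))
    pd.DataFrame(
        [(c.embryo_id, c.cell_id_1, c.cell_id_2, c.chrom, c.pos,
          c.table[0][0], c.table[0][1], c.table[1][0], c.table[1][1],
          round(c.log2_ai, 6), round(c.chi2_stat, 6), round(c.p_value, 6),
          int(c.fc_pass), int(c.small_counts), int(c.is_ai)) for c in all_calls],
        columns=["embryo_id", "cell_id_1", "cell_id_2", "chrom", "pos",
                 "ref_1", "alt_1", "ref_2", "alt_2", "log2_ai", "chi2",
                 "p_value", "fc_pass", "small_counts", "is_ai"]).to_csv(
        out / "ai.tsv", sep="\t", index=False)
    summary = ai_mod.ai_summary(all_calls, alpha=config.alpha_ai, seed=config.seed)
    summary.to_csv(out / "ai_summary.tsv", sep="\t", index=False)
    return out / "ai.tsv"


def stage_utr(config: RunConfig) -> Path:
    out = _outdir(config)
    cells = [c for c in _read_cells(out / "cells.tsv") if not c.is_control]
    seqs = _read_fasta(out / "utr_sequences.fa")
    predictor = utr_mod.UtrEndPredictor(
        min_step_ratio=config.utr_min_step_ratio,
        smooth_window=config.utr_smooth_window,
        min_segment=config.utr_min_segment)

    per_tx: dict[str, list] = {}
    rows = []
    for cell in cells:
        path = out / f"utr_coverage_{cell.cell_id}.bedgraph"
        if not path.exists():
            continue
        bedgraph = read_bedgraph(path)
        for tx in sorted(bedgraph["chrom"].unique()):
            track = utr_mod.track_from_bedgraph(bedgraph, tx)
            pred = predictor.predict(track, cell_id=cell.cell_id)
            utr_mod.annotate_cpsf(pred, seqs.get(tx, ""))
            per_tx.setdefault(tx, []).append(pred)
            rows.append(_utr_row(pred))
    for tx, preds in sorted(per_tx.items()):
        if len(preds) >= 2:
            consensus = utr_mod.consensus_utr(
                preds, tolerance=config.utr_tolerance,
                min_fraction=config.utr_min_fraction)
            utr_mod.annotate_cpsf(consensus, seqs.get(tx, ""))
            rows.append(_utr_row(consensus))
    pd.DataFrame(rows, columns=_UTR_COLUMNS).to_csv(out / "utr.tsv", sep="\t", index=False)
    return out / "utr.tsv"


_UTR_COLUMNS = (["transcript_id", "cell_id"]
                + [f"utr_end_{i}" for i in range(1, 7)]
                + [f"abundance_{i}" for i in range(1, 7)]
                + [f"cpsf_offset_{i}" for i in range(1, 7)]
                + ["consensus_support"])


def _utr_row(pred) -> list:
    ends = list(pred.ends) + [""] * (6 - len(pred.ends))
    abund = [round(a, 4) for a in pred.abundances] + [""] * (6 - len(pred.abundances))
    cpsf = [("" if o is None else o) for o in pred.cpsf_offsets] + [""] * (6 - len(pred.cpsf_offsets))
    support = "" if pred.consensus_support is None else round(pred.consensus_support, 4)
    return [pred.transcript_id, pred.cell_id] + ends + abund + cpsf + [support]


def stage_expr(config: RunConfig) -> Path:
    """Sister-cell expression summaries on simulated transcript counts."""
    out = _outdir(config)
    cells = [c for c in _read_cells(out / "cells.tsv") if not c.is_control]
    by_embryo: dict[str, list[str]] = {}
    for c in cells:
        by_embryo.setdefault(c.embryo_id, []).append(c.cell_id)

    rows = []
    for i, (embryo_id, embryo_cells) in enumerate(sorted(by_embryo.items())):
        embryo_cells = sorted(embryo_cells)
        counts, _ = sim_mod.generate_expression(
            n_transcripts=16000, depth=10_000_000,
            seed=config.seed + i, n_cells=len(embryo_cells))
        rpm = [expr_mod.compute_rpm(counts[j], int(counts[j].sum()))
               for j in range(len(embryo_cells))]
        n_expr = [int(expr_mod.detect_expressed(r, config.rpm_threshold).sum())
                  for r in rpm]
        for j, cell_id in enumerate(embryo_cells):
            r_sister = (expr_mod.cell_correlation(rpm[j], rpm[1 - j])
                        if len(embryo_cells) == 2 else float("nan"))
            rows.append((embryo_id, cell_id, n_expr[j], round(r_sister, 6)))
    pd.DataFrame(rows, columns=["embryo_id", "cell_id", "n_expressed",
                                "sister_pearson_r"]).to_csv(
        out / "expr.tsv", sep="\t", index=False)
    return out / "expr.tsv"


def make_summary_table(config: RunConfig) -> pd.DataFrame:
    """Per-cell report with the conventional rows: selected loci, het, ASE,
    expected ASE false positives, AI, expected AI false positives, ASE% and
    AI%.  Both cells of a pair share the embryo's AI numbers."""
    out = _outdir(config)
    ase_summary = pd.read_csv(out / "ase_summary.tsv", sep="\t")
    ai_summary = pd.read_csv(out / "ai_summary.tsv", sep="\t")
    cells = [c for c in _read_cells(out / "cells.tsv") if not c.is_control]
    embryo_of = {c.cell_id: c.embryo_id for c in cells}

    columns = {}
    for row in ase_summary.itertuples(index=False):
        embryo = embryo_of.get(row.cell_id, "")
        ai_row = ai_summary[ai_summary["embryo_id"] == embryo]
        n_ai = int(ai_row["n_ai"].iloc[0]) if len(ai_row) else 0
        n_tested = int(ai_row["n_tested"].iloc[0]) if len(ai_row) else 0
        ai_fp = float(ai_row["expected_ai_fp"].iloc[0]) if len(ai_row) else float("nan")
        columns[row.cell_id] = [
            row.n_selected,
            row.n_het,
            row.n_ase,
            round(row.expected_ase_fp, 2),
            n_ai,
            round(ai_fp, 2),
            round(100.0 * row.n_ase / row.n_het, 2) if row.n_het else float("nan"),
            round(100.0 * n_ai / n_tested, 2) if n_tested else float("nan"),
        ]
    df = pd.DataFrame(columns, index=SUMMARY_ROWS)
    df.index.name = "ASE and AI determination"
    return df


def stage_report(config: RunConfig) -> Path:
    out = _outdir(config)
    summary = make_summary_table(config)
    summary.to_csv(out / "summary.tsv", sep="\t")
    return out / "summary.tsv"


PIPELINE_STAGES = [
    ("simulate", stage_simulate),
    ("calibrate", stage_calibrate),
    ("genotype", stage_genotype),
    ("ase", stage_ase),
    ("ai", stage_ai),
    ("utr", stage_utr),
    ("expr", stage_expr),
    ("report", stage_report),
]


def run_pipeline(config: RunConfig) -> Path:
    """Run all stages in dependency order; a failing stage raises an error
    naming the stage, leaving earlier outputs intact."""
    for name, stage in PIPELINE_STAGES:
        logger.info("running stage %s", name)
        try:
            stage(config)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    return _outdir(config)
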
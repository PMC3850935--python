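"""Pipeline orchestration: GFF3 parsing, gene-structure summaries, and
stage-ordered execution (classify -> dup -> date -> selection ->
diverge -> expression/promoters) with reproducible seeded runs.

Internal gene coordinates stay 1-based inclusive as parsed; all tables
are emitted as TSV with stable column order so repeat runs are
byte-identical.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd
import yaml
from Bio.Seq import Seq

from ._io import read_fasta
from .domain_classify import (
    classify_group,
    load_reference_domains,
    assign_subgroup,
    scan_wrky_domains,
)
from .duplication_map import (
    GeneModel,
    best_nonself_matches,
    classify_origin,
    find_tandem,
    segmental_blocks,
)
from .errors import GFFParseError
from .expression_promoter import (
    ElementCatalog,
    classify_breadth,
    scan_cis_elements,
    zscore_rows,
)
from .ks_clock import ClockConfig, date_block, ng86_ka_ks, codon_align

logger = logging.getLogger("famevol")


# ---------------------------------------------------------------------------
# GFF3 parsing
# ---------------------------------------------------------------------------

def _parse_attributes(text: str) -> dict[str, str]:
    out = {}
    for item in text.strip().split(";"):
        if item and "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def parse_gff3(text: str, cds_fasta: Optional[str] = None,
               protein_fasta: Optional[str] = None) -> list[GeneModel]:
    """Parse GFF3 text into gene models (one representative mRNA each).

    Coordinates stay 1-based inclusive; ordinal indices are computed
    per chromosome by start coordinate, not file order.  When a gene
    has several mRNAs the one with the longest summed CDS wins.
    Malformed lines raise ``GFFParseError`` with the line number.
    CDS/protein sequences are attached from the optional FASTAs (keyed
    by gene id).
    """
    genes: dict[str, dict] = {}
    mrna_parent: dict[str, str] = {}
    cds_of_mrna: dict[str, list[tuple[int, int]]] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 9:
            raise GFFParseError(lineno,
                                f"expected 9 tab-separated columns, "
                                f"got {len(parts)}")
        chrom, _, ftype, start_s, end_s, _, strand, _, attr_s = parts
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise GFFParseError(lineno, "non-integer coordinates") from None
        if start > end or start < 1:
            raise GFFParseError(lineno, f"bad interval {start}..{end}")
        attrs = _parse_attributes(attr_s)
        if ftype == "gene":
            gid = attrs.get("ID")
            if gid is None:
                raise GFFParseError(lineno, "gene feature without ID")
            genes[gid] = {"chromosome": chrom, "start": start, "end": end,
                          "strand": strand}
        elif ftype == "mRNA":
            mid, parent = attrs.get("ID"), attrs.get("Parent")
            if mid is None or parent is None:
                raise GFFParseError(lineno, "mRNA without ID/Parent")
            mrna_parent[mid] = parent
        elif ftype == "CDS":
            parent = attrs.get("Parent")
            if parent is None:
                raise GFFParseError(lineno, "CDS without Parent")
            cds_of_mrna.setdefault(parent, []).append((start, end))
    cds_seqs = read_fasta(cds_fasta) if cds_fasta else {}
    prot_seqs = read_fasta(protein_fasta) if protein_fasta else {}

    # representative transcript per gene: longest total CDS
    best_mrna: dict[str, tuple[int, str]] = {}
    for mid, parent in mrna_parent.items():
        total = sum(e - s + 1 for s, e in cds_of_mrna.get(mid, []))
        cur = best_mrna.get(parent)
        if cur is None or total > cur[0]:
            best_mrna[parent] = (total, mid)

    models = []
    for gid, info in genes.items():
        mid = best_mrna.get(gid, (0, None))[1]
        segments = sorted(cds_of_mrna.get(mid, [])) if mid else []
        cds = cds_seqs.get(gid, "")
        prot = prot_seqs.get(gid, "")
        if cds and not prot:
            prot = str(Seq(cds).translate()).rstrip("*")
        models.append(GeneModel(
            id=gid, chromosome=info["chromosome"], ordinal=0,
            start=info["start"], end=info["end"], strand=info["strand"],
            cds=cds, protein=prot, exon_count=max(len(segments), 1)))
    # ordinals per chromosome by start coordinate
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in models:
        by_chrom.setdefault(g.chromosome, []).append(g)
    for chrom_genes in by_chrom.values():
        chrom_genes.sort(key=lambda g: g.start)
        for i, g in enumerate(chrom_genes):
            g.ordinal = i
    return sorted(models, key=lambda g: (g.chromosome, g.start))


def summarize_gene_structure(genes: Sequence[GeneModel]) -> pd.DataFrame:
    """Per-gene exon count and CDS length (bp)."""
    return pd.DataFrame(
        {"gene": [g.id for g in genes],
         "exon_count": [g.exon_count for g in genes],
         "cds_length": [len(g.cds) for g in genes]}).set_index("gene")


# ---------------------------------------------------------------------------
# summary arithmetic
# ---------------------------------------------------------------------------

def percentage(count: int, total: int) -> float:
    """Tabulated percentage convention: round(100 * count / total, 1)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, 1)


def origin_summary(origins: dict[str, str]) -> pd.DataFrame:
    """Counts and percentages per duplication-origin class.

    'both' genes count toward both the tandem and segmental rows, so
    those two percentages describe overlapping sets (dispersed plus
    uniquely flagged genes still partition the family).
    """
    total = len(origins)
    seg = sum(1 for v in origins.values() if v in ("segmental", "both"))
    tan = sum(1 for v in origins.values() if v in ("tandem", "both"))
    disp = sum(1 for v in origins.values() if v == "dispersed")
    rows = [("segmental", seg), ("tandem", tan), ("dispersed", disp)]
    return pd.DataFrame(
        {"class": [r[0] for r in rows],
         "count": [r[1] for r in rows],
         "percent": [percentage(r[1], total) if total else 0.0
                     for r in rows],
         "total": total}).set_index("class")


# ---------------------------------------------------------------------------
# pipeline configuration and run
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run; defaults follow the
    standard analysis settings (10 intervening genes, 100-kb anchor
    window, 3 anchors, Ks saturation cutoff 1.0, Qk cutoff 0.8,
    1500-bp promoters)."""
    gff: Optional[str] = None
    cds_fasta: Optional[str] = None
    protein_fasta: Optional[str] = None
    family_list: Optional[str] = None
    expression_tsv: Optional[str] = None
    promoter_fasta: Optional[str] = None
    element_catalog: Optional[str] = None
    lambda_rate: float = 6.1e-9
    max_intervening: int = 10
    window_kb: float = 100.0
    min_anchors: int = 3
    ks_cutoff: float = 1.0
    qk_cutoff: float = 0.8
    promoter_length: int = 1500
    expressed_cutoff: float = 1.0
    seed: int = 0
    stages: tuple = ("classify", "dup", "date", "expr", "promoters")

    def __post_init__(self):
        for name in ("lambda_rate", "window_kb", "ks_cutoff", "qk_cutoff",
                     "promoter_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_intervening < 0 or self.min_anchors < 1:
            raise ValueError("bad tandem/anchor thresholds")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        unknown = sorted(set(data) - set(known))
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        if "stages" in known:
            known["stages"] = tuple(known["stages"])
        return cls(**known)


@dataclass
class PipelineReport:
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    summary: Optional[pd.DataFrame] = None

    def write(self, outdir) -> None:
        from pathlib import Path
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(out / f"{name}.tsv", sep="\t")
        if self.summary is not None:
            self.summary.to_csv(out / "summary.tsv", sep="\t")


def _hash(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig,
                 genes: Optional[list[GeneModel]] = None,
                 family_ids: Optional[list[str]] = None) -> PipelineReport:
    """Execute the configured stages in order on shared inputs.

    ``genes``/``family_ids`` may be passed directly (e.g. from the
    synthetic generator) instead of file paths.  Raises before any
    work when a requested stage lacks its inputs.
    """
    report = PipelineReport()
    need_genes = {"classify", "dup", "date"} & set(config.stages)
    if need_genes and genes is None:
        if not config.gff:
            raise ValueError("stages " + ",".join(sorted(need_genes)) +
                             " need a GFF3 (or gene models)")
        with open(config.gff) as fh:
            genes = parse_gff3(fh.read(), config.cds_fasta,
                               config.protein_fasta)
    if need_genes and family_ids is None:
        if not config.family_list:
            raise ValueError("family id list required")
        with open(config.family_list) as fh:
            family_ids = [ln.split("\t")[0].strip() for ln in fh
                          if ln.strip()]
    if "expr" in config.stages and config.expression_tsv is None:
        raise ValueError("expr stage needs expression_tsv")
    if "promoters" in config.stages and config.promoter_fasta is None:
        raise ValueError("promoters stage needs promoter_fasta")

    clusters, blocks = [], []
    if "classify" in config.stages:
        logger.info("stage=classify n_family=%d", len(family_ids))
        refs = load_reference_domains()
        rows = []
        for fid in family_ids:
            g = next(g for g in genes if g.id == fid)
            hits = scan_wrky_domains(g.protein, fid)
            asg = classify_group(hits, fid)
            if asg.group == "II":
                dom = g.protein[hits[0].span[0]:hits[0].span[1]]
                assign_subgroup(asg, dom, refs)
            rows.append({"gene": fid, "n_domains": asg.n_domains,
                         "group": asg.group, "subgroup": asg.subgroup,
                         "domains": ";".join(
                             f"{h.span[0]}-{h.span[1]}" for h in asg.hits)})
        report.tables["classification"] = \
            pd.DataFrame(rows).set_index("gene")

    if "dup" in config.stages or "date" in config.stages:
        logger.info("stage=dup genes=%d hash=%s", len(genes),
                    _hash("".join(g.id for g in genes)))
        clusters = find_tandem(genes, family_ids, config.max_intervening)
        best = best_nonself_matches({g.id: g.protein for g in genes})
        blocks = segmental_blocks(genes, family_ids, best,
                                  config.window_kb, config.min_anchors)
        origins = {fid: classify_origin(fid, clusters, blocks)
                   for fid in family_ids}
        report.tables["origin"] = pd.DataFrame(
            {"gene": list(origins), "origin": list(origins.values())}
        ).set_index("gene")
        report.summary = origin_summary(origins)

    if "date" in config.stages:
        by_id = {g.id: g for g in genes}
        clock = ClockConfig(config.lambda_rate, config.ks_cutoff)
        rows = []
        for block in blocks:
            ks_vals = []
            for a, b in block.anchors:
                try:
                    pair = pairwise_codon_alignment(by_id[a].cds,
                                                    by_id[b].cds)
                    ks_vals.append(ng86_ka_ks(*pair).ks)
                except Exception:       # saturated or unalignable anchor
                    continue
            if not ks_vals:
                continue
            date = date_block(f"{block.focal}&{block.paralog}", ks_vals,
                              clock)
            rows.append({"segment_pair": date.block_id,
                         "n_anchors": block.n_anchors,
                         "mean_ks": date.mean_ks, "sd_ks": date.sd_ks,
                         "age_myr": date.age_myr_int})
        report.tables["dating"] = (pd.DataFrame(rows).set_index(
            "segment_pair") if rows else pd.DataFrame(
            columns=["n_anchors", "mean_ks", "sd_ks", "age_myr"]))

    if "expr" in config.stages:
        matrix = pd.read_csv(config.expression_tsv, sep="\t", index_col=0)
        report.tables["zscore"] = zscore_rows(matrix)
        report.tables["breadth"] = classify_breadth(
            matrix, config.expressed_cutoff).to_frame()

    if "promoters" in config.stages:
        promoters = read_fasta(config.promoter_fasta)
        catalog = (ElementCatalog.from_tsv(open(config.element_catalog).read())
                   if config.element_catalog else ElementCatalog.default())
        report.tables["elements"] = scan_cis_elements(promoters, catalog)

    return report


def pairwise_codon_alignment(cds1: str, cds2: str) -> tuple[str, str]:
    """Protein-guided codon alignment of two CDS sequences."""
    from Bio.Align import PairwiseAligner, substitution_matrices

    p1 = str(Seq(cds1).translate()).rstrip("*")
    p2 = str(Seq(cds2).translate()).rstrip("*")
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aln = aligner.align(p1, p2)[0]
    rows = {"a": str(aln[0]), "b": str(aln[1])}
    gapped = codon_align(rows, {"a": cds1, "b": cds2})
    return gapped["a"], gapped["b"]
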
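"""Synthetic inputs with known ground truth for every pipeline stage.

Generates rooted trees, codon alignments evolved under GY94 site and
branch-site regimes, duplicated gene pairs calibrated to a target
synonymous divergence, whole genome layouts with planted tandem arrays
and segmental blocks, tissue expression matrices with group-structured
peaks, and promoter sequences with planted cis-elements.  Every
generator is a pure function of its arguments and a seed.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy.optimize import brentq

from ._codon import (
    CODON_AA,
    N_CODONS,
    NUCS,
    SENSE_CODONS,
    encode_cds,
    decode_cds,
    uniform_frequencies,
)
from ._io import write_fasta
from .codeml_lite import _Spectral, codon_rate_matrix, mixture_scale
from .duplication_map import GeneModel
from .errors import SaturationError
from .ks_clock import expected_ng86_proportions, jukes_cantor
from .trees import Tree, TreeNode

IUPAC_DNA = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


# ---------------------------------------------------------------------------
# omega regimes and simulation config
# ---------------------------------------------------------------------------

@dataclass
class M0Regime:
    omega: float

    def classes(self):
        if self.omega < 0:
            raise ValueError("omega must be non-negative")
        return [(1.0, self.omega, self.omega)]


@dataclass
class DiscreteRegime:
    """General discrete omega distribution: list of (proportion, omega)."""
    categories: Sequence[tuple[float, float]]

    def classes(self):
        props = [p for p, _ in self.categories]
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if any(w < 0 for _, w in self.categories):
            raise ValueError("omega must be non-negative")
        return [(p, w, w) for p, w in self.categories]


@dataclass
class BranchSiteRegime:
    """Four-class branch-site layout; omega2 applies on foreground only."""
    p0: float
    p1: float
    p2a: float
    p2b: float
    omega0: float
    omega2: float
    foreground: Sequence[str] = ()

    def classes(self):
        props = (self.p0, self.p1, self.p2a, self.p2b)
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if min(self.omega0, self.omega2) < 0 or min(props) < 0:
            raise ValueError("omegas and proportions must be non-negative")
        return [(self.p0, self.omega0, self.omega0),
                (self.p1, 1.0, 1.0),
                (self.p2a, self.omega0, self.omega2),
                (self.p2b, 1.0, self.omega2)]


OmegaRegime = Union[M0Regime, DiscreteRegime, BranchSiteRegime]


@dataclass
class SimConfig:
    """Settings for one codon-alignment simulation."""
    seed: int = 0
    n_taxa: int = 8
    tree_shape: str = "birth_death"
    n_codons: int = 300
    kappa: float = 2.0
    codon_freqs: Union[str, np.ndarray] = "uniform"  # or 3x4 nucleotide freqs
    omega_regime: OmegaRegime = field(default_factory=lambda: M0Regime(0.2))

    def __post_init__(self):
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        self.omega_regime.classes()  # validates proportions / omegas

    def frequencies(self) -> np.ndarray:
        if isinstance(self.codon_freqs, str):
            if self.codon_freqs != "uniform":
                raise ValueError("codon_freqs must be 'uniform' or a 3x4 "
                                 "nucleotide frequency array")
            return uniform_frequencies()
        nf = np.asarray(self.codon_freqs, dtype=float)
        if nf.shape != (3, 4):
            raise ValueError("nucleotide frequency array must be 3x4")
        nf = nf / nf.sum(axis=1, keepdims=True)
        freqs = np.array([nf[0, NUCS.index(c[0])] * nf[1, NUCS.index(c[1])]
                          * nf[2, NUCS.index(c[2])] for c in SENSE_CODONS])
        return freqs / freqs.sum()


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def simulate_tree(n_taxa: int, tree_shape: str = "birth_death",
                  seed: int = 0, mean_branch: float = 0.2) -> Tree:
    """Rooted binary tree with positive branch lengths.

    Shapes: ``birth_death`` (dendropy constant-rate birth-death
    conditioned on the tip count), ``balanced`` (as balanced as the tip
    count allows) and ``caterpillar`` (ladder).  Branch lengths are
    rescaled (birth-death) or drawn exponential (fixed shapes) so the
    mean edge length is ``mean_branch`` expected substitutions per
    codon.  Deterministic for a fixed seed.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    labels = [f"t{i + 1}" for i in range(n_taxa)]
    rng = np.random.default_rng(seed)
    if tree_shape == "birth_death":
        import dendropy
        from dendropy.model import birthdeath
        dtree = birthdeath.birth_death_tree(
            birth_rate=1.0, death_rate=0.3, num_extant_tips=n_taxa,
            rng=_random.Random(int(seed) + 12345),
            repeat_until_success=True)
        tree = Tree.from_dendropy(dtree)
        for i, leaf in enumerate(tree.leaves()):
            leaf.label = labels[i]
        edges = [n for n in tree.postorder() if n.parent is not None]
        for n in edges:
            n.length = max(n.length, 1e-4)
        mean = sum(n.length for n in edges) / len(edges)
        for n in edges:
            n.length *= mean_branch / mean
        return tree
    if tree_shape == "caterpillar":
        root = TreeNode()
        cur = root
        for i in range(n_taxa - 1):
            cur.add(TreeNode(label=labels[i], length=_exp_len(rng, mean_branch)))
            if i < n_taxa - 2:
                nxt = TreeNode(length=_exp_len(rng, mean_branch))
                cur.add(nxt)
                cur = nxt
            else:
                cur.add(TreeNode(label=labels[-1],
                                 length=_exp_len(rng, mean_branch)))
        return Tree(root)
    if tree_shape == "balanced":
        def build(names):
            if len(names) == 1:
                return TreeNode(label=names[0],
                                length=_exp_len(rng, mean_branch))
            mid = len(names) // 2
            node = TreeNode(length=_exp_len(rng, mean_branch))
            node.add(build(names[:mid]))
            node.add(build(names[mid:]))
            return node
        root = build(labels)
        root.length = 0.0
        return Tree(root)
    raise ValueError(f"unknown tree shape {tree_shape!r}")


def _exp_len(rng: np.random.Generator, mean: float) -> float:
    return float(max(rng.exponential(mean), 1e-3))


# ---------------------------------------------------------------------------
# codon alignment simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedAlignment:
    sequences: dict[str, str]
    site_classes: np.ndarray       # true class label per codon site
    classes: list                  # (weight, omega_bg, omega_fg) triples
    tree: Tree
    freqs: np.ndarray

    @property
    def n_codons(self) -> int:
        return len(self.site_classes)


def _sample_states(states: np.ndarray, P: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Draw child states given parent states and a row-stochastic P."""
    out = np.empty_like(states)
    for s in np.unique(states):
        mask = states == s
        out[mask] = rng.choice(N_CODONS, size=int(mask.sum()), p=P[s])
    return out


def simulate_codon_alignment(tree: Tree, config: SimConfig) -> SimulatedAlignment:
    """Evolve codon sequences down a tree under the configured regime.

    Returns the leaf sequences together with the true per-site class
    labels.  The rate scaling matches the likelihood engine: branch
    lengths are expected substitutions per codon under the background
    mixture.  No stop codon can be emitted (61-state chain).
    """
    if tree.n_leaves < 2:
        raise ValueError("tree must have >= 2 leaves")
    regime = config.omega_regime
    if isinstance(regime, BranchSiteRegime):
        if not regime.foreground:
            raise ValueError("branch-site regime requires foreground branches")
        n_marked = tree.set_foreground(regime.foreground)
        if n_marked == 0:
            raise ValueError("no tree edge matches the foreground labels")
    classes = regime.classes()
    freqs = config.frequencies()
    rng = np.random.default_rng(config.seed)
    weights = np.array([c[0] for c in classes])
    site_class = rng.choice(len(classes), size=config.n_codons, p=weights)

    c = mixture_scale(config.kappa, classes, freqs)
    spectral = {}
    for _, w_bg, w_fg in classes:
        for w in (w_bg, w_fg):
            if w not in spectral:
                Q = codon_rate_matrix(config.kappa, w, freqs, scale=False)
                spectral[w] = _Spectral(Q / c, freqs)

    states = {id(tree.root): rng.choice(N_CODONS, size=config.n_codons,
                                        p=freqs)}
    order = list(tree.postorder())[::-1]  # preorder
    seqs: dict[str, str] = {}
    for node in order:
        if node.parent is None:
            continue
        parent_states = states[id(node.parent)]
        child_states = np.empty_like(parent_states)
        for k, (_, w_bg, w_fg) in enumerate(classes):
            mask = site_class == k
            if not mask.any():
                continue
            w = w_fg if node.foreground else w_bg
            P = spectral[w].probs(node.length)
            child_states[mask] = _sample_states(parent_states[mask], P, rng)
        states[id(node)] = child_states
        if node.is_leaf:
            seqs[node.label] = decode_cds(child_states)
    return SimulatedAlignment(seqs, site_class, classes, tree, freqs)


# ---------------------------------------------------------------------------
# pairwise divergence to a target Ks
# ---------------------------------------------------------------------------

def evolve_pair_to_ks(cds: str, target_ks: float, seed: int = 0,
                      kappa: float = 2.0, omega: float = 0.05) -> str:
    """Mutate a copy of ``cds`` so its expected NG86 Ks hits ``target_ks``.

    The copy evolves under a purifying GY94 process (uniform codon
    frequencies, default omega 0.05, so divergence is strongly biased
    to synonymous changes).  The branch length is calibrated
    numerically so the *expected value of the NG86 estimator* — not the
    true synonymous divergence — equals the target; the two differ
    because of multiple-hit correction bias.  Raises ``SaturationError``
    when the target exceeds what the Jukes–Cantor correction can
    represent (raw synonymous proportion >= 3/4).
    """
    if target_ks < 0:
        raise ValueError("target_ks must be non-negative")
    idx = encode_cds(cds)
    if target_ks == 0:
        return cds
    freqs = uniform_frequencies()
    Q = codon_rate_matrix(kappa, omega, freqs, scale=True)
    spectral = _Spectral(Q, freqs)

    def expected_ks(t: float) -> float:
        ps, _ = expected_ng86_proportions(idx, spectral.probs(t))
        if ps >= 0.75:
            return np.inf
        return jukes_cantor(ps)

    t_hi = 0.05
    while expected_ks(t_hi) < target_ks:
        t_hi *= 2.0
        if t_hi > 200.0 or not np.isfinite(expected_ks(t_hi)):
            raise SaturationError(
                f"target Ks {target_ks} exceeds the saturation limit of "
                "the NG86/Jukes-Cantor correction for this sequence")
    t = brentq(lambda x: expected_ks(x) - target_ks, 0.0, t_hi, xtol=1e-10)
    rng = np.random.default_rng(seed)
    copy_states = _sample_states(idx, spectral.probs(t), rng)
    return decode_cds(copy_states)


# ---------------------------------------------------------------------------
# genome layout with planted duplications
# ---------------------------------------------------------------------------

@dataclass
class TandemSpec:
    chromosome: int          # 0-based chromosome number
    start_index: int         # 0-based gene slot of the first member
    size: int                # number of family genes in the array
    intervening: int = 0     # non-family genes between consecutive members


@dataclass
class SegmentalSpec:
    source_chromosome: int
    source_start: int        # slot of the focal family gene
    target_chromosome: int
    target_start: int
    n_anchors: int           # flanking genes copied alongside the focal gene
    target_ks: float

    def __post_init__(self):
        if self.n_anchors < 1:
            raise ValueError("anchor count must be >= 1")
        if self.target_ks < 0:
            raise ValueError("target Ks must be >= 0")


@dataclass
class GenomeLayoutSpec:
    n_chromosomes: int = 2
    genes_per_chromosome: int = 40
    planted_tandem: Sequence[TandemSpec] = ()
    planted_segmental: Sequence[SegmentalSpec] = ()
    family_gene_fraction: float = 0.0


@dataclass
class GenomeSim:
    genes: list[GeneModel]
    family_ids: list[str]
    truth: pd.DataFrame
    gff3: str
    cds_fasta: str
    protein_fasta: str


_AA_CODONS: dict[str, list[str]] = {}
for _i, _aa in enumerate(CODON_AA):
    _AA_CODONS.setdefault(_aa, []).append(SENSE_CODONS[_i])


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_AA_CODONS[aa]) for aa in protein)


def _random_protein(n: int, rng: np.random.Generator) -> str:
    aas = sorted(_AA_CODONS)
    return "".join(rng.choice(aas, size=n))


def wrky_like_protein(rng: np.random.Generator, group: str = "II") -> str:
    """A synthetic protein carrying a canonical WRKY-style domain.

    Group II/III carry one domain (C2H2 vs C2HC finger); group I gets
    two C2H2 domains.  Residues outside the fixed motif positions are
    random, so two independent draws share only the motif architecture.
    """
    def domain(finger: str) -> str:
        head = _random_protein(8, rng)
        core = "WRKYGQK"
        linker = _random_protein(5, rng)
        if finger == "C2H2":
            z = ("C" + _random_protein(4, rng) + "C" + _random_protein(22, rng)
                 + "H" + _random_protein(1, rng) + "H")
        else:
            z = ("C" + _random_protein(7, rng) + "C" + _random_protein(23, rng)
                 + "H" + _random_protein(1, rng) + "C")
        return head + core + linker + z

    nterm = _random_protein(40, rng)
    cterm = _random_protein(30, rng)
    if group == "I":
        return nterm + domain("C2H2") + _random_protein(20, rng) \
            + domain("C2H2") + cterm
    finger = "C2HC" if group == "III" else "C2H2"
    return nterm + domain(finger) + cterm


def simulate_genome_layout(spec: GenomeLayoutSpec,
                           seed: int = 0) -> GenomeSim:
    """Lay gene models on chromosomes with planted duplication events.

    Returns gene models, the family id list, a ground-truth event table
    (one row per planted event) and GFF3/FASTA renderings.  Planted
    segmental copies are evolved to the requested Ks; tandem members
    diverge mildly (Ks 0.05 per step).  Raises ``ValueError`` when a
    planted event does not fit on its chromosome or events collide.
    """
    rng = np.random.default_rng(seed)
    cap = spec.genes_per_chromosome
    slots: dict[tuple[int, int], dict] = {}

    def claim(chrom: int, idx: int, role: str) -> dict:
        if chrom >= spec.n_chromosomes or idx >= cap or idx < 0:
            raise ValueError(
                f"planted event exceeds chromosome capacity: "
                f"chromosome {chrom}, slot {idx}")
        key = (chrom, idx)
        if key in slots and slots[key]["role"] != "background":
            raise ValueError(f"planted events collide at {key}")
        slot = {"role": role, "cds": None, "family": False}
        slots[key] = slot
        return slot

    truth_rows = []
    event_n = 0

    for tspec in spec.planted_tandem:
        base = _reverse_translate(wrky_like_protein(rng), rng)
        members = []
        for k in range(tspec.size):
            idx = tspec.start_index + k * (tspec.intervening + 1)
            slot = claim(tspec.chromosome, idx, "tandem")
            slot["family"] = True
            slot["cds"] = (base if k == 0 else
                           evolve_pair_to_ks(base, 0.05 * k,
                                             seed=int(rng.integers(2**31))))
            members.append((tspec.chromosome, idx))
        event_n += 1
        truth_rows.append({"event_id": f"tandem{event_n}", "type": "tandem",
                           "members": members, "target_ks": np.nan,
                           "n_anchors": len(members)})

    for sspec in spec.planted_segmental:
        block_members = []
        for off in range(sspec.n_anchors + 1):
            role = "segmental_focal" if off == 0 else "anchor"
            src = claim(sspec.source_chromosome, sspec.source_start + off,
                        role)
            if off == 0:
                src["family"] = True
                src["cds"] = _reverse_translate(wrky_like_protein(rng), rng)
            else:
                src["cds"] = _reverse_translate(
                    _random_protein(int(rng.integers(250, 350)), rng), rng)
            tgt = claim(sspec.target_chromosome, sspec.target_start + off,
                        role)
            tgt["family"] = off == 0
            tgt["cds"] = evolve_pair_to_ks(src["cds"], sspec.target_ks,
                                           seed=int(rng.integers(2**31)))
            block_members.append(
                ((sspec.source_chromosome, sspec.source_start + off),
                 (sspec.target_chromosome, sspec.target_start + off)))
        event_n += 1
        truth_rows.append({"event_id": f"segmental{event_n}",
                           "type": "segmental",
                           "members": [block_members[0][0],
                                       block_members[0][1]],
                           "target_ks": sspec.target_ks,
                           "n_anchors": sspec.n_anchors})

    # background genes and extra dispersed family genes
    free = [(c, i) for c in range(spec.n_chromosomes) for i in range(cap)
            if (c, i) not in slots]
    n_extra = int(round(spec.family_gene_fraction
                        * spec.n_chromosomes * cap))
    extra = [tuple(free[j]) for j in
             rng.choice(len(free), size=min(n_extra, len(free)),
                        replace=False)] if n_extra else []
    for key in extra:
        slot = claim(*key, "dispersed_family")
        slot["family"] = True
        slot["cds"] = _reverse_translate(wrky_like_protein(rng), rng)
        event_n += 1
        truth_rows.append({"event_id": f"dispersed{event_n}",
                           "type": "dispersed", "members": [key],
                           "target_ks": np.nan, "n_anchors": 0})
    for c in range(spec.n_chromosomes):
        for i in range(cap):
            if (c, i) not in slots:
                slot = claim(c, i, "background")
                slot["cds"] = _reverse_translate(
                    _random_protein(int(rng.integers(250, 350)), rng), rng)

    # lay out coordinates and build gene models
    genes: list[GeneModel] = []
    id_of: dict[tuple[int, int], str] = {}
    for c in range(spec.n_chromosomes):
        pos = int(rng.integers(1500, 4000))
        for i in range(cap):
            slot = slots[(c, i)]
            gid = f"Gs{c + 1:02d}g{(i + 1) * 10:05d}"
            id_of[(c, i)] = gid
            cds = slot["cds"]
            exons = int(rng.integers(1, 5))
            intron_total = int(rng.integers(100, 500)) * (exons - 1)
            span = len(cds) + intron_total
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(
                id=gid, chromosome=f"Chr{c + 1:02d}", ordinal=i,
                start=pos, end=pos + span - 1, strand=strand, cds=cds,
                protein=str(Seq(cds).translate()), exon_count=exons))
            pos += span + int(rng.integers(9000, 15000))

    for row in truth_rows:
        row["members"] = ";".join(id_of[m] if isinstance(m, tuple) else m
                                  for m in row["members"])
    truth = pd.DataFrame(truth_rows,
                         columns=["event_id", "type", "members",
                                  "target_ks", "n_anchors"])
    family_ids = [id_of[k] for k in sorted(slots) if slots[k]["family"]]
    return GenomeSim(genes=genes, family_ids=family_ids, truth=truth,
                     gff3=write_gff3(genes),
                     cds_fasta=write_fasta({g.id: g.cds for g in genes}),
                     protein_fasta=write_fasta({g.id: g.protein
                                                for g in genes}))


def write_gff3(genes: Sequence[GeneModel]) -> str:
    """Serialize gene models as GFF3 (gene/mRNA/CDS, 1-based inclusive)."""
    lines = ["##gff-version 3"]
    for g in sorted(genes, key=lambda x: (x.chromosome, x.start)):
        attrs = f"ID={g.id}"
        lines.append("\t".join([g.chromosome, "famevol", "gene",
                                str(g.start), str(g.end), ".", g.strand,
                                ".", attrs]))
        mrna = f"{g.id}.1"
        lines.append("\t".join([g.chromosome, "famevol", "mRNA",
                                str(g.start), str(g.end), ".", g.strand,
                                ".", f"ID={mrna};Parent={g.id}"]))
        # split the CDS into exon_count segments laid left to right
        n, total = g.exon_count, len(g.cds)
        seg = total // n
        cds_lens = [seg] * (n - 1) + [total - seg * (n - 1)]
        gaps = ((g.end - g.start + 1 - total) // max(n - 1, 1)
                if n > 1 else 0)
        pos = g.start
        for k, ln in enumerate(cds_lens):
            lines.append("\t".join([
                g.chromosome, "famevol", "CDS", str(pos),
                str(pos + ln - 1), ".", g.strand, "0",
                f"ID={mrna}.cds{k + 1};Parent={mrna}"]))
            pos += ln + gaps
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def simulate_expression(group_labels: dict[str, Optional[str]],
                        tissues: Sequence[str], effect_size: float,
                        seed: int = 0, noise_sd: float = 0.5,
                        baseline_log_mean: float = 1.5):
    """Genes x tissues RPKM-like matrix with group-structured peaks.

    Genes whose label is not None get a planted peak tissue (one tissue
    per group, assigned round-robin over the tissue list): their
    log-expression in that tissue is raised by ``effect_size`` noise
    standard deviations.  Returns ``(matrix, truth)`` where truth maps
    gene -> planted peak tissue (or None).  All values are positive.
    """
    tissues = list(tissues)
    if len(tissues) < 2:
        raise ValueError("need at least two tissues")
    rng = np.random.default_rng(seed)
    groups = sorted({g for g in group_labels.values() if g is not None})
    peak_of_group = {g: tissues[i % len(tissues)]
                     for i, g in enumerate(groups)}
    rows, truth_rows = [], []
    for gene in group_labels:
        mu = baseline_log_mean + rng.normal(0.0, 1.0)
        log_vals = mu + (rng.normal(0.0, noise_sd, size=len(tissues))
                         if noise_sd > 0 else np.zeros(len(tissues)))
        label = group_labels[gene]
        peak = None
        if label is not None and effect_size > 0:
            peak = peak_of_group[label]
            log_vals[tissues.index(peak)] += effect_size * max(noise_sd, 1.0)
        rows.append(np.exp(log_vals))
        truth_rows.append(peak)
    matrix = pd.DataFrame(rows, index=list(group_labels), columns=tissues)
    truth = pd.Series(truth_rows, index=list(group_labels),
                      name="peak_tissue")
    return matrix, truth


# ---------------------------------------------------------------------------
# promoters
# ---------------------------------------------------------------------------

@dataclass
class PromoterSim:
    sequences: dict[str, str]
    fasta: str
    truth_counts: pd.DataFrame          # promoter x pattern planted copies
    offsets: dict[str, list[tuple[str, int]]]


def _concretize(pattern: str, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(IUPAC_DNA[c])) for c in pattern.upper())


def simulate_promoters(n: int, length: int = 1500,
                       planted: Sequence[tuple[str, int]] = (),
                       seed: int = 0,
                       background_alphabet: str = "ACGT") -> PromoterSim:
    """Promoter FASTA with planted element copies at recorded offsets.

    Each of the ``n`` promoters receives ``copies`` non-overlapping
    verbatim instances of every planted IUPAC ``pattern``; the rest of
    the sequence is i.i.d. uniform over ``background_alphabet`` (narrow
    the alphabet to make the background provably free of a pattern).
    """
    total = sum(len(p) * c for p, c in planted)
    if total > length:
        raise ValueError("planted content exceeds promoter length")
    rng = np.random.default_rng(seed)
    seqs: dict[str, str] = {}
    offsets: dict[str, list[tuple[str, int]]] = {}
    counts = []
    for i in range(n):
        name = f"prom{i + 1}"
        seq = list(rng.choice(list(background_alphabet), size=length))
        taken: list[tuple[int, int]] = []
        offsets[name] = []
        row = {}
        for pattern, copies in planted:
            row[pattern] = copies
            for _ in range(copies):
                inst = _concretize(pattern, rng)
                for _try in range(10000):
                    off = int(rng.integers(0, length - len(inst) + 1))
                    if all(off + len(inst) <= a or off >= b
                           for a, b in taken):
                        break
                else:
                    raise ValueError("could not place planted elements")
                taken.append((off, off + len(inst)))
                seq[off:off + len(inst)] = list(inst)
                offsets[name].append((pattern, off))
        seqs[name] = "".join(seq)
        counts.append(row)
    truth = pd.DataFrame(counts, index=list(seqs)).fillna(0).astype(int) \
        if planted else pd.DataFrame(index=list(seqs))
    return PromoterSim(sequences=seqs, fasta=write_fasta(seqs),
                       truth_counts=truth, offsets=offsets)
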
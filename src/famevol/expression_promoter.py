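"""Expression-atlas normalization, clustering, breadth classes, and
promoter cis-element scanning.

Expression rows (RPKM-like, genes x tissues) are standardized with a
population z-score, clustered by average linkage on one minus the
Pearson correlation, and classified by expression breadth
(not detected / constitutive / single-tissue peak / intermediate).
Promoters are scanned for IUPAC element patterns from a user-editable
catalog; counts are catalog-relative, with both strands merged so a
palindromic site is counted once.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .synthetic_data import IUPAC_DNA

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


# ---------------------------------------------------------------------------
# z-score and clustering
# ---------------------------------------------------------------------------

def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-wise (x - mean) / sd with population sd; constant rows -> 0."""
    values = matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("expression values must be non-negative")
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)  # population sd (ddof=0)
    out = np.where(sd > 0, (values - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


@dataclass
class ExpressionClustering:
    linkage_matrix: np.ndarray
    leaf_order: list[str]
    included: list[str]
    excluded: list[str]

    def cut(self, k: int) -> dict[str, int]:
        labels = fcluster(self.linkage_matrix, k, criterion="maxclust")
        return dict(zip(self.included, labels.tolist()))


def cluster_expression(standardized: pd.DataFrame) -> ExpressionClustering:
    """Average-linkage hierarchical clustering on 1 - Pearson correlation.

    Genes with zero variance carry no correlation signal and are
    excluded with a warning.  Leaf order is scipy's deterministic
    dendrogram order (earlier input index first on ties).
    """
    if len(standardized) < 2:
        raise ValueError("need at least two genes")
    values = standardized.to_numpy(dtype=float)
    sd = values.std(axis=1)
    keep = sd > 0
    excluded = list(standardized.index[~keep])
    if excluded:
        warnings.warn(f"excluded {len(excluded)} constant gene(s) "
                      f"from clustering: {excluded[:6]}")
    vals = values[keep]
    names = list(standardized.index[keep])
    corr = np.corrcoef(vals)
    dist = 1.0 - corr
    iu = np.triu_indices(len(names), k=1)
    Z = linkage(np.clip(dist[iu], 0.0, None), method="average")
    from scipy.cluster.hierarchy import leaves_list
    order = [names[i] for i in leaves_list(Z)]
    return ExpressionClustering(Z, order, names, excluded)


# ---------------------------------------------------------------------------
# breadth classification
# ---------------------------------------------------------------------------

def classify_breadth(matrix: pd.DataFrame, expressed_cutoff: float = 1.0,
                     peak_z: float = 1.5) -> pd.Series:
    """Per-gene breadth category from an RPKM-like matrix.

    not_detected: every tissue below ``expressed_cutoff``;
    constitutive: every tissue at or above it; single_tissue_peak:
    exactly one tissue is both the row maximum and has z >= ``peak_z``;
    otherwise intermediate.  Categories are exclusive and exhaustive.
    """
    z = zscore_rows(matrix)
    out = {}
    for gene in matrix.index:
        row = matrix.loc[gene].to_numpy(dtype=float)
        if (row < expressed_cutoff).all():
            out[gene] = "not_detected"
            continue
        zrow = z.loc[gene].to_numpy(dtype=float)
        is_peak = (zrow >= peak_z) & (row >= row.max())
        if is_peak.sum() == 1:
            out[gene] = "single_tissue_peak"
        elif (row >= expressed_cutoff).all():
            out[gene] = "constitutive"
        else:
            out[gene] = "intermediate"
    return pd.Series(out, name="breadth")


# ---------------------------------------------------------------------------
# cis-element scanning
# ---------------------------------------------------------------------------

@dataclass
class ElementCatalog:
    """Named IUPAC patterns with a per-element strand policy."""
    patterns: dict[str, str]
    strands: dict[str, str] = field(default_factory=dict)  # 'both'|'forward'

    def __post_init__(self):
        for name, pat in self.patterns.items():
            bad = [c for c in pat.upper() if c not in IUPAC_DNA]
            if bad:
                raise ValueError(f"element {name!r}: non-IUPAC {bad}")

    def strand_of(self, name: str) -> str:
        return self.strands.get(name, "both")

    @classmethod
    def from_tsv(cls, text: str) -> "ElementCatalog":
        patterns, strands = {}, {}
        for line in text.strip().splitlines():
            if not line or line.startswith("#") or \
                    line.lower().startswith("name\t"):
                continue
            parts = line.rstrip("\n").split("\t")
            patterns[parts[0]] = parts[1]
            if len(parts) > 2 and parts[2]:
                strands[parts[0]] = parts[2]
        return cls(patterns, strands)

    @classmethod
    def default(cls) -> "ElementCatalog":
        """The catalog fixture shipped with the package (best-effort
        literal motifs; counts are catalog-relative)."""
        pkg = resources.files("famevol") / "data"
        return cls.from_tsv((pkg / "cis_element_catalog.tsv").read_text())


def _iupac_regex(pattern: str) -> re.Pattern:
    return re.compile("".join(
        c if len(IUPAC_DNA[c]) == 1 else f"[{IUPAC_DNA[c]}]"
        for c in pattern.upper()))


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def count_occurrences(seq: str, pattern: str, strand: str = "both") -> int:
    """Overlapping occurrences of an IUPAC pattern in one sequence.

    With ``strand='both'`` a site is a forward-coordinate interval
    matching the pattern on either strand; palindromic matches are
    counted once.  Non-DNA characters raise with the position named.
    """
    seq = seq.upper()
    for pos, c in enumerate(seq):
        if c not in IUPAC_DNA:
            raise ValueError(f"non-DNA character {c!r} at position {pos}")
    fwd = _iupac_regex(pattern)
    starts = {m.start() for m in
              re.finditer(rf"(?=({fwd.pattern}))", seq)}
    if strand == "both":
        rc = _iupac_regex(revcomp(pattern))
        starts |= {m.start() for m in
                   re.finditer(rf"(?=({rc.pattern}))", seq)}
    elif strand != "forward":
        raise ValueError("strand must be 'both' or 'forward'")
    return len(starts)


def scan_cis_elements(promoters: dict[str, str],
                      catalog: Optional[ElementCatalog] = None
                      ) -> pd.DataFrame:
    """Count catalog elements in every promoter (genes x elements)."""
    catalog = catalog or ElementCatalog.default()
    rows = {}
    for name, seq in promoters.items():
        rows[name] = {el: count_occurrences(seq, pat, catalog.strand_of(el))
                      for el, pat in catalog.patterns.items()}
    return pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int) \
        if catalog.patterns else pd.DataFrame(index=list(promoters))


def group_element_means(counts: pd.DataFrame,
                        group_labels: dict[str, str]) -> pd.DataFrame:
    """Mean element copy number per group label (e.g. family subgroup)."""
    labels = pd.Series(group_labels).reindex(counts.index)
    return counts.groupby(labels).mean()
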
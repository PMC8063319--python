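"""Gene-set enrichment of high-FST windows.

Maps genes (GFF3) onto divergence windows, forms a target set from windows
above an FST threshold, and tests each annotation term with the exact
hypergeometric upper tail (two-set target-vs-background mode): the p-value of
drawing at least b term-carrying genes in n target draws from a universe of N
genes of which B carry the term. The universe is background ∪ target in
"include" mode, or background \\ target in "exclude" mode. Benjamini-Hochberg
q-values are reported alongside; the significance flag uses the raw
p <= 0.001 gate.

The term map is a flat gene -> term table (no ontology-graph propagation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "GeneRecord", "TermMap", "load_annotations", "genes_in_windows",
    "hypergeom_enrich", "SIGNIFICANCE_P",
]

#: Raw-p significance gate for enrichment calls.
SIGNIFICANCE_P = 0.001


@dataclass(frozen=True)
class GeneRecord:
    """A gene span; coordinates 1-based inclusive. Strand carried, unused."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"gene {self.id}: start {self.start} > end {self.end}")


@dataclass
class TermMap:
    """Flat gene -> set-of-terms mapping with optional term descriptions."""

    gene_terms: Dict[str, Set[str]]
    descriptions: Dict[str, str]

    def genes_with(self, term: str) -> Set[str]:
        return {g for g, ts in self.gene_terms.items() if term in ts}

    def terms(self) -> Set[str]:
        out: Set[str] = set()
        for ts in self.gene_terms.values():
            out |= ts
        return out


class GffParseError(ValueError):
    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


def _parse_attributes(field: str) -> Dict[str, str]:
    out = {}
    for item in field.split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3_genes(path: Union[str, Path],
                    feature_types: Sequence[str] = ("gene",)) -> List[GeneRecord]:
    """Parse gene records from a GFF3 file.

    Only rows whose type is in ``feature_types`` are kept; the gene id is the
    ``ID`` attribute (falling back to ``Name`` or ``gene_id``). Malformed
    lines raise :class:`GffParseError` with the line number.
    """
    genes: List[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GffParseError(
                    f"expected 9 tab-separated columns, got {len(fields)}", lineno)
            chrom, _src, ftype, start_s, end_s, _score, strand, _phase, attrs = fields
            if ftype not in feature_types:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise GffParseError(
                    f"non-integer coordinates {start_s!r}/{end_s!r}", lineno)
            at = _parse_attributes(attrs)
            gid = at.get("ID") or at.get("Name") or at.get("gene_id")
            if gid is None:
                raise GffParseError("feature has no ID/Name/gene_id attribute", lineno)
            try:
                genes.append(GeneRecord(id=gid, chrom=chrom, start=start, end=end,
                                        strand=strand))
            except ValueError as exc:
                raise GffParseError(str(exc), lineno)
    return genes


def load_annotations(gff_path: Union[str, Path],
                     termmap_path: Union[str, Path]) -> Tuple[List[GeneRecord], TermMap]:
    """Load gene records (GFF3) and the gene -> term table (2- or 3-column TSV).

    Term-map rows naming a gene absent from the GFF are skipped with a logged
    warning count. An optional third column carries the term description.
    """
    genes = read_gff3_genes(gff_path)
    known = {g.id for g in genes}
    df = pd.read_csv(termmap_path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{termmap_path}: expected at least 2 tab-separated columns")
    gene_terms: Dict[str, Set[str]] = {}
    descriptions: Dict[str, str] = {}
    skipped = 0
    for row in df.itertuples(index=False):
        gene, term = str(row[0]), str(row[1])
        if not term:
            raise ValueError("empty term name in term map")
        if gene not in known:
            skipped += 1
            continue
        gene_terms.setdefault(gene, set()).add(term)
        if len(row) > 2 and isinstance(row[2], str):
            descriptions.setdefault(term, row[2])
    if skipped:
        logger.warning("load_annotations: skipped %d term-map rows with unknown genes",
                       skipped)
    return genes, TermMap(gene_terms=gene_terms, descriptions=descriptions)


def genes_in_windows(windows: pd.DataFrame, genes: Iterable[GeneRecord],
                     fst_col: str, min_fst: float) -> Set[str]:
    """Target set: genes overlapping any window with FST > ``min_fst``.

    Overlap is any shared bp (both windows and genes 1-based inclusive); a
    gene straddling several qualifying windows is counted once. Higher
    thresholds give nested subsets of lower ones.
    """
    qual = windows[windows[fst_col].notna() & (windows[fst_col] > min_fst)]
    by_chrom: Dict[str, list] = {}
    for row in qual.itertuples(index=False):
        by_chrom.setdefault(str(row.chrom), []).append((int(row.start), int(row.end)))
    targets: Set[str] = set()
    for g in genes:
        for (s, e) in by_chrom.get(g.chrom, ()):
            if g.start <= e and s <= g.end:
                targets.add(g.id)
                break
    return targets


def hypergeom_enrich(target: Set[str], background: Set[str], termmap: TermMap,
                     mode: str = "include") -> pd.DataFrame:
    """Exact hypergeometric term enrichment of ``target`` vs ``background``.

    mode="include": universe = background ∪ target (the target genes count in
    the background, the convention of testing a subset against the whole
    genome). mode="exclude": universe = (background \\ target) ∪ target with
    the term totals B taken from background \\ target plus the target — i.e.
    the universe is the disjoint union of the target and the target-free
    background. Terms with no gene in the universe are skipped. Columns:
    term, description, b, n, B, N, ratio, p, q, significant (p <= 0.001).
    """
    if not background:
        raise ValueError("background must be nonempty")
    if mode not in ("include", "exclude"):
        raise ValueError(f"mode must be 'include' or 'exclude', got {mode!r}")
    universe = (set(background) | set(target)) if mode == "include" \
        else ((set(background) - set(target)) | set(target))
    extra = set(target) - universe
    if extra:
        raise ValueError(f"target genes outside the universe: {sorted(extra)[:5]}")
    N = len(universe)
    n = len(target)
    rows = []
    for term in sorted(termmap.terms()):
        carriers = termmap.genes_with(term) & universe
        B = len(carriers)
        if B == 0:
            continue
        b = len(carriers & target)
        # P(X >= b) drawing n from N with B successes
        p = float(stats.hypergeom.sf(b - 1, N, B, n)) if b > 0 else 1.0
        p = min(p, 1.0)
        ratio = (b / n) / (B / N) if n > 0 else np.nan
        rows.append({"term": term,
                     "description": termmap.descriptions.get(term, ""),
                     "b": b, "n": n, "B": B, "N": N, "ratio": ratio, "p": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
        df["significant"] = df["p"] <= SIGNIFICANCE_P
        df = df.sort_values("p", kind="stable").reset_index(drop=True)
    return df
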
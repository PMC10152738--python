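"""Ingestion, filtering and cross-dataset intersection of smORF predictions.

The filtering pipeline mirrors the standard curation of Ribo-seq ORF calls:

1. keep only whitelisted ORF categories where the source dataset labels them;
2. keep ORFs of 10-150 codons (inclusive);
3. keep the longest coding sequence per isoform group (ORFs sharing a stop);
4. drop ORFs overlapping annotated genes or mass-spectrometry peptides
   (reciprocal 50% exon-overlap rules, 100% peptide coverage rule);
5. intersect the two surviving prediction sets, splitting them into
   exact matches, imperfect (>= 1 bp, same strand) overlaps, and records
   unique to either set.

All coordinates are 0-based half-open BED intervals. Predictions are read and
written as BED12, with the ORF category carried in the name field as
``id|category``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from .errors import DataError, FormatError

logger = logging.getLogger(__name__)

#: ORF category labels retained from datasets that annotate them
CHEN_CATEGORY_WHITELIST = frozenset(
    {
        "upstream",
        "new",
        "start overlap",
        "stop overlap",
        "new isoform",
        "downstream",
        "long out of frame",
    }
)


@dataclass(frozen=True)
class OrfPrediction:
    """One predicted ORF from a source dataset (exon structure + label)."""

    id: str
    source: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    category: str = ""

    def __post_init__(self):
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        object.__setattr__(self, "exons", exons)
        prev = None
        for s, e in exons:
            if s >= e:
                raise DataError(f"{self.id}: empty exon [{s},{e})")
            if prev is not None and s < prev:
                raise DataError(f"{self.id}: exons overlap or are unsorted")
            prev = e
        if self.strand not in "+-":
            raise DataError(f"{self.id}: bad strand {self.strand!r}")

    @property
    def total_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def aa_length(self) -> int:
        return self.total_length // 3 - 1

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def stop_position(self) -> int:
        """Genomic coordinate anchoring the stop codon (strand-aware)."""
        return self.exons[-1][1] if self.strand == "+" else self.exons[0][0]

    @property
    def exon_chain(self) -> tuple:
        return (self.chrom, self.strand, self.exons)


@dataclass
class AnnotationGene:
    id: str
    chrom: str
    exons: tuple[tuple[int, int], ...]
    pli: float = float("nan")
    aa_length: int | None = None


@dataclass
class AnnotationSet:
    """Reference annotation: gene exon intervals with pLI, peptide intervals."""

    genes: list[AnnotationGene]
    peptide_intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self):
        for g in self.genes:
            for s, e in g.exons:
                if s >= e:
                    raise DataError(f"gene {g.id}: invalid interval [{s},{e})")
        for chrom, s, e in self.peptide_intervals:
            if s >= e:
                raise DataError(f"peptide interval [{s},{e}) invalid")
        self._gene_tree: dict[str, IntervalTree] = {}
        for i, g in enumerate(self.genes):
            tree = self._gene_tree.setdefault(g.chrom, IntervalTree())
            for s, e in g.exons:
                tree.addi(s, e, i)
        self._pep_tree: dict[str, IntervalTree] = {}
        for chrom, s, e in self.peptide_intervals:
            self._pep_tree.setdefault(chrom, IntervalTree()).addi(s, e)

    def overlapping_genes(self, chrom: str, start: int, end: int) -> list[AnnotationGene]:
        tree = self._gene_tree.get(chrom)
        if tree is None:
            return []
        idx = sorted({iv.data for iv in tree.overlap(start, end)})
        return [self.genes[i] for i in idx]

    def peptide_exons(self, chrom: str) -> list[tuple[int, int]]:
        tree = self._pep_tree.get(chrom)
        return [(iv.begin, iv.end) for iv in tree] if tree else []


# ---------------------------------------------------------------------------
# BED12 I/O


def _parse_bed12_line(line: str, source: str, lineno: int) -> OrfPrediction:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 12:
        raise FormatError(f"expected 12 BED fields, got {len(fields)}", lineno)
    try:
        chrom = fields[0]
        start = int(fields[1])
        name = fields[3]
        strand = fields[5]
        n_blocks = int(fields[9])
        sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        starts = [int(x) for x in fields[11].rstrip(",").split(",")]
    except ValueError as exc:
        raise FormatError(f"malformed BED12 record ({exc})", lineno) from None
    if len(sizes) != n_blocks or len(starts) != n_blocks:
        raise FormatError("blockCount disagrees with blockSizes/blockStarts", lineno)
    exons = tuple((start + bs, start + bs + sz) for bs, sz in zip(starts, sizes))
    if "|" in name:
        orf_id, category = name.split("|", 1)
    else:
        orf_id, category = name, ""
    try:
        pred = OrfPrediction(orf_id, source, chrom, strand, exons, category)
    except DataError as exc:
        raise FormatError(str(exc), lineno) from None
    if pred.total_length % 3 != 0:
        raise FormatError(
            f"{orf_id}: total exon length {pred.total_length} not a multiple of 3",
            lineno,
        )
    return pred


def load_predictions(
    path, source_label: str, category_whitelist=None
) -> list[OrfPrediction]:
    """Load BED12 predictions, optionally keeping only whitelisted categories.

    With no whitelist all records are retained. Malformed records raise a
    :class:`FormatError` carrying the line number; an empty file yields an
    empty list with a warning.
    """
    preds: list[OrfPrediction] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            pred = _parse_bed12_line(line, source_label, lineno)
            if category_whitelist is not None and pred.category not in category_whitelist:
                continue
            preds.append(pred)
    if not preds:
        logger.warning("no predictions loaded from %s", path)
    return preds


def write_predictions(preds: list[OrfPrediction], path) -> None:
    with open(path, "w") as fh:
        for p in preds:
            start, end = p.span
            sizes = ",".join(str(e - s) for s, e in p.exons)
            starts = ",".join(str(s - start) for s, e in p.exons)
            name = f"{p.id}|{p.category}" if p.category else p.id
            fh.write(
                "\t".join(
                    [
                        p.chrom,
                        str(start),
                        str(end),
                        name,
                        "0",
                        p.strand,
                        str(start),
                        str(end),
                        "0,0,0",
                        str(len(p.exons)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Filters


def filter_by_length(
    preds: list[OrfPrediction], min_codons: int = 10, max_codons: int = 150
) -> list[OrfPrediction]:
    """Keep predictions with min_codons <= aa_length <= max_codons (inclusive)."""
    return [p for p in preds if min_codons <= p.aa_length <= max_codons]


def select_longest_isoform(preds: list[OrfPrediction]) -> list[OrfPrediction]:
    """Keep the longest coding sequence per isoform group.

    Isoforms are grouped by (chrom, strand, stop-codon position): ORFs sharing
    a stop are reads of the same ORF with alternative starts. Length ties are
    broken by lexicographically smaller id, for determinism.
    """
    best: dict[tuple, OrfPrediction] = {}
    for p in preds:
        key = (p.chrom, p.strand, p.stop_position)
        cur = best.get(key)
        if (
            cur is None
            or p.total_length > cur.total_length
            or (p.total_length == cur.total_length and p.id < cur.id)
        ):
            best[key] = p
    kept_ids = {id(v) for v in best.values()}
    return [p for p in preds if id(p) in kept_ids]


def _merge_intervals(intervals) -> list[tuple[int, int]]:
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _intersect_length(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> int:
    total = 0
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            total += hi - lo
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total


def overlap_fraction(a_exons, b_exons) -> tuple[float, float]:
    """Reciprocal overlap fractions (|A∩B|/|A|, |A∩B|/|B|) over merged bases."""
    a = _merge_intervals(a_exons)
    b = _merge_intervals(b_exons)
    la = sum(e - s for s, e in a)
    lb = sum(e - s for s, e in b)
    if la == 0 or lb == 0:
        raise DataError("overlap_fraction requires non-empty exon sets")
    inter = _intersect_length(a, b)
    return inter / la, inter / lb


def exclude_annotation_overlaps(
    preds: list[OrfPrediction],
    annot: AnnotationSet,
    refseq_fraction: float = 0.5,
    peptide_fraction: float = 1.0,
) -> tuple[list[OrfPrediction], pd.DataFrame]:
    """Remove predictions overlapping annotated genes or peptides.

    A prediction is removed iff any of:

    * ``refseq_forward``: >= 50% of its exon bases fall in annotated gene exons;
    * ``refseq_reverse``: it covers >= 50% of some annotated gene's exon bases;
    * ``peptide``: 100% of its exon bases are covered by peptide intervals AND
      >= 50% fall in annotated gene exons.

    Overlap is strand-blind (interval arithmetic, as with ``bedtools
    intersect`` without strand flags). Returns survivors plus an exclusion log
    recording every rule that fired per removed prediction.
    """
    kept: list[OrfPrediction] = []
    log_rows = []
    eps = 1e-9
    for p in preds:
        start, end = p.span
        genes = annot.overlapping_genes(p.chrom, start, end)
        frac_smorf = 0.0
        max_gene_cov = 0.0
        worst_gene = ""
        if genes:
            gene_exons = [iv for g in genes for iv in g.exons]
            frac_smorf, _ = overlap_fraction(p.exons, gene_exons)
            for g in genes:
                _, cov = overlap_fraction(p.exons, g.exons)
                if cov > max_gene_cov:
                    max_gene_cov, worst_gene = cov, g.id
        peps = annot.peptide_exons(p.chrom)
        pep_cov = overlap_fraction(p.exons, peps)[0] if peps else 0.0
        rules = []
        if frac_smorf >= refseq_fraction:
            rules.append("refseq_forward")
        if max_gene_cov >= refseq_fraction:
            rules.append("refseq_reverse")
        if pep_cov >= peptide_fraction - eps and frac_smorf >= refseq_fraction:
            rules.append("peptide")
        if rules:
            log_rows.append(
                {
                    "id": p.id,
                    "source": p.source,
                    "rules": ";".join(rules),
                    "frac_in_refseq": frac_smorf,
                    "max_gene_covered": max_gene_cov,
                    "gene": worst_gene,
                    "frac_in_peptide": pep_cov,
                }
            )
        else:
            kept.append(p)
    log = pd.DataFrame(
        log_rows,
        columns=[
            "id",
            "source",
            "rules",
            "frac_in_refseq",
            "max_gene_covered",
            "gene",
            "frac_in_peptide",
        ],
    )
    return kept, log


# ---------------------------------------------------------------------------
# Dataset intersection


@dataclass
class IntersectionReport:
    """Partition of two prediction sets into exact / imperfect / unique classes.

    ``exact_pairs`` and ``imperfect_pairs`` hold (id_in_A, id_in_B) tuples; an
    entity is classed "exact" with priority over "imperfect". Every input id
    appears in exactly one entity class.
    """

    exact_pairs: list[tuple[str, str]]
    imperfect_pairs: list[tuple[str, str]]
    unique_to_a: list[str]
    unique_to_b: list[str]

    @property
    def n_exact(self) -> int:
        return len(self.exact_pairs)

    @property
    def imperfect_a(self) -> set[str]:
        return {a for a, _ in self.imperfect_pairs}

    @property
    def imperfect_b(self) -> set[str]:
        return {b for _, b in self.imperfect_pairs}

    def entity_partition(self) -> dict[str, set[str]]:
        return {
            "exact_a": {a for a, _ in self.exact_pairs},
            "exact_b": {b for _, b in self.exact_pairs},
            "imperfect_a": self.imperfect_a,
            "imperfect_b": self.imperfect_b,
            "unique_a": set(self.unique_to_a),
            "unique_b": set(self.unique_to_b),
        }


def intersect_datasets(
    set_a: list[OrfPrediction], set_b: list[OrfPrediction]
) -> IntersectionReport:
    """Classify predictions by cross-dataset agreement.

    Exact match: identical chromosome, strand and exon chain. Imperfect:
    >= 1 bp exon overlap on the same strand without an exact match. Overlap is
    same-strand only, since an ORF is a strand-specific object.
    """
    by_chain: dict[tuple, list[OrfPrediction]] = {}
    for b in set_b:
        by_chain.setdefault(b.exon_chain, []).append(b)

    trees: dict[tuple[str, str], IntervalTree] = {}
    for j, b in enumerate(set_b):
        tree = trees.setdefault((b.chrom, b.strand), IntervalTree())
        for s, e in b.exons:
            tree.addi(s, e, j)

    exact_pairs: list[tuple[str, str]] = []
    imperfect_pairs: list[tuple[str, str]] = []
    a_exact: set[str] = set()
    b_exact: set[str] = set()
    for a in set_a:
        for b in by_chain.get(a.exon_chain, []):
            exact_pairs.append((a.id, b.id))
            a_exact.add(a.id)
            b_exact.add(b.id)

    a_imp: set[str] = set()
    b_imp: set[str] = set()
    for a in set_a:
        if a.id in a_exact:
            continue
        tree = trees.get((a.chrom, a.strand))
        if tree is None:
            continue
        partners = sorted(
            {iv.data for s, e in a.exons for iv in tree.overlap(s, e)}
        )
        for j in partners:
            b = set_b[j]
            if b.id in b_exact:
                continue
            imperfect_pairs.append((a.id, b.id))
            a_imp.add(a.id)
            b_imp.add(b.id)

    unique_a = [a.id for a in set_a if a.id not in a_exact and a.id not in a_imp]
    unique_b = [b.id for b in set_b if b.id not in b_exact and b.id not in b_imp]
    return IntersectionReport(exact_pairs, imperfect_pairs, unique_a, unique_b)
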
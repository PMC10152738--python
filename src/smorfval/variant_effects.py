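"""Codon-level consequence annotation for single-nucleotide variants.

For every coding entity (smORF or reference gene) this module enumerates all
possible SNVs over its exonic bases (three alternate alleles per base, plus
the four canonical splice bases flanking each internal junction), classifies
each change by codon arithmetic against the standard genetic code, and
tabulates observed rare variants into nonsynonymous/synonymous (N/S) and
LoF/synonymous counts.

Conventions
-----------
* Coordinates are 0-based, half-open (BED). Positions and ref/alt alleles in
  variant tables refer to the reference plus strand; classification is done on
  the coding strand, complementing alleles for minus-strand entities.
* N (the numerator of N/S) counts missense plus stop-loss changes; LoF counts
  stop-gain, canonical +/-2 bp splice, and start-loss. Frameshifts cannot
  arise from SNVs. Single-exon entities have no splice class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _seq
from ._seq import AA_CODE, ATG_INDEX, COMP, STOP, Genome
from .errors import CoordinateError, DataError

SYNONYMOUS = 0
MISSENSE = 1
STOP_GAIN = 2
STOP_LOSS = 3
START_LOSS = 4
SPLICE = 5
NONCODING = 6

CONSEQUENCES = (
    "synonymous",
    "missense",
    "stop_gain",
    "stop_loss",
    "start_loss",
    "splice",
    "noncoding",
)

#: classes counted as N in the N/S ratio
N_CLASSES = (MISSENSE, STOP_LOSS)
#: classes counted as loss-of-function for SNVs
LOF_CLASSES = (STOP_GAIN, SPLICE, START_LOSS)

_CODON_MULT = np.array([16, 4, 1], dtype=np.int64)


@dataclass(frozen=True)
class OrfModel:
    """A transcript-like coding entity: ordered exons, strand, reading frame.

    ``exons`` are 0-based half-open intervals sorted by genomic start and
    non-overlapping. ``frame_offset`` is relative to the spliced sequence
    (0 for a complete ORF starting at its first base).
    """

    id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    frame_offset: int = 0
    source: dict = field(default_factory=dict, compare=False, hash=False)

    def __post_init__(self):
        if self.strand not in "+-":
            raise DataError(f"{self.id}: strand must be '+' or '-'")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for s, e in exons:
            if s >= e:
                raise DataError(f"{self.id}: empty exon [{s},{e})")
            if prev_end is not None and s < prev_end:
                raise DataError(f"{self.id}: exons overlap or are unsorted")
            prev_end = e

    @property
    def total_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def aa_length(self) -> int:
        """Codons excluding the stop, for a complete in-frame ORF."""
        return self.total_length // 3 - 1

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def genomic_positions(self) -> np.ndarray:
        """Genomic coordinates of exonic bases in transcription (5'->3') order."""
        parts = [np.arange(s, e, dtype=np.int64) for s, e in self.exons]
        pos = np.concatenate(parts)
        return pos[::-1] if self.strand == "-" else pos

    def splice_positions(self) -> np.ndarray:
        """Intronic bases within 2 bp of internal junctions (genomic coords)."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 - e1 >= 4:
                out.extend([e1, e1 + 1, s2 - 2, s2 - 1])
            else:  # tiny intron: whatever intronic bases exist
                out.extend(range(e1, s2))
        return np.array(sorted(set(out)), dtype=np.int64)


@dataclass(frozen=True)
class CodingView:
    """A concrete reading of a genomic entity: coding-order positions and bases.

    ``flip`` is True when the coding strand is the genome minus strand, in
    which case plus-strand alleles must be complemented before codon
    arithmetic (and vice versa for reporting).
    """

    id: str
    chrom: str
    positions: np.ndarray  # genomic coords, coding order
    codes: np.ndarray  # coding-strand base codes
    flip: bool

    @property
    def n_codons(self) -> int:
        return len(self.codes) // 3


def coding_view(orf: OrfModel, genome: Genome) -> CodingView:
    gcodes = genome.codes(orf.chrom)
    lo, hi = orf.span
    if lo < 0 or hi > len(gcodes):
        raise CoordinateError(f"{orf.id}: exons outside {orf.chrom} bounds")
    pos = orf.genomic_positions()
    codes = gcodes[pos]
    if orf.strand == "-":
        codes = COMP[codes]
    return CodingView(orf.id, orf.chrom, pos, codes, orf.strand == "-")


def spliced_sequence(orf: OrfModel, genome: Genome) -> str:
    """Spliced coding sequence, 5'->3' on the coding strand."""
    return _seq.decode(coding_view(orf, genome).codes)


def classification_matrix(codes: np.ndarray) -> np.ndarray:
    """Consequence code for every (coding position, coding alt) pair.

    Returns an int8 array of shape (L, 4); entries where alt equals the
    reference base are -1. The first codon is treated as the initiator only
    when it is ATG, in which case any change in it is a start loss. A
    reference stop codon mutating to another stop is synonymous; to a
    non-stop codon, a stop loss. Internal reference stops (possible in
    shifted-frame views) follow the same rules.
    """
    L = len(codes)
    if L % 3 != 0:
        raise DataError("coding length must be a multiple of 3")
    cidx = _seq.codon_indices(codes)
    codon_of = np.arange(L) // 3
    mult = _CODON_MULT[np.arange(L) % 3]
    ref_aa = AA_CODE[cidx][codon_of]
    out = np.full((L, 4), -1, dtype=np.int8)
    base_idx = cidx[codon_of]
    codes64 = codes.astype(np.int64)
    for alt in range(4):
        alt_idx = base_idx + (alt - codes64) * mult
        alt_aa = AA_CODE[alt_idx]
        cls = np.where(alt_aa == ref_aa, SYNONYMOUS, MISSENSE).astype(np.int8)
        cls[(ref_aa != STOP) & (alt_aa == STOP)] = STOP_GAIN
        cls[(ref_aa == STOP) & (alt_aa != STOP)] = STOP_LOSS
        cls[codes == alt] = -1
        out[:, alt] = cls
    if L >= 3 and cidx[0] == ATG_INDEX:
        head = out[:3]
        head[head != -1] = START_LOSS
    return out


def classify_consequence(orf: OrfModel, genome: Genome, pos: int, ref: str, alt: str) -> str:
    """Consequence of a single plus-strand SNV within the entity."""
    view = coding_view(orf, genome)
    gcodes = genome.codes(orf.chrom)
    ref_code = _seq.encode(ref)[0]
    alt_code = _seq.encode(alt)[0]
    if pos < 0 or pos >= len(gcodes):
        raise CoordinateError(f"position {pos} outside {orf.chrom}")
    if gcodes[pos] != ref_code:
        raise DataError(
            f"{orf.id}: ref {ref} does not match genome base "
            f"{_seq.decode(np.array([gcodes[pos]]))} at {pos}"
        )
    hits = np.nonzero(view.positions == pos)[0]
    if hits.size:
        i = int(hits[0])
        coding_alt = COMP[alt_code] if view.flip else alt_code
        cls = classification_matrix(view.codes)[i, coding_alt]
        return CONSEQUENCES[int(cls)]
    if pos in set(orf.splice_positions().tolist()):
        return CONSEQUENCES[SPLICE]
    raise CoordinateError(f"position {pos} is outside entity {orf.id}")


def _context_indices(gcodes: np.ndarray, pos: np.ndarray) -> np.ndarray:
    if (pos < 1).any() or (pos > len(gcodes) - 2).any():
        raise CoordinateError("trinucleotide context requires 1 bp of flank")
    return (
        gcodes[pos - 1].astype(np.int64) * 16
        + gcodes[pos].astype(np.int64) * 4
        + gcodes[pos + 1].astype(np.int64)
    )


def _methyl_levels(methylation, chrom: str, pos: np.ndarray) -> np.ndarray:
    if methylation is None:
        return np.zeros(len(pos), dtype=np.int64)
    return methylation.levels(chrom, pos)


def possible_snv_arrays(view: CodingView, genome: Genome, rate_table, methylation=None):
    """Low-level enumeration over a coding view (no splice records).

    Returns plus-strand (pos, ref_code, alt_code, consequence, mu) arrays with
    three rows per coding base, ordered by coding position then alt allele.
    """
    gcodes = genome.codes(view.chrom)
    cls = classification_matrix(view.codes)
    L = len(view.codes)
    plus_ref = gcodes[view.positions]
    ctx = _context_indices(gcodes, view.positions)
    lev = _methyl_levels(methylation, view.chrom, view.positions)

    # three coding alts per base -> plus-strand alts
    coding_alts = np.array(
        [[a for a in range(4) if a != b] for b in range(4)], dtype=np.uint8
    )[view.codes]
    plus_alts = COMP[coding_alts] if view.flip else coding_alts

    pos_r = np.repeat(view.positions, 3)
    ref_r = np.repeat(plus_ref, 3)
    ctx_r = np.repeat(ctx, 3)
    lev_r = np.repeat(lev, 3)
    alt_r = plus_alts.reshape(-1)
    cls_r = np.take_along_axis(cls, coding_alts.astype(np.int64), axis=1).reshape(-1)
    mu = rate_table.mu(ctx_r, alt_r, lev_r)
    return pos_r, ref_r, alt_r, cls_r.astype(np.int64), mu


def splice_snv_arrays(orf: OrfModel, genome: Genome, rate_table, methylation=None):
    """Possible splice-region SNVs (three alts per flanking intronic base)."""
    spos = orf.splice_positions()
    if spos.size == 0:
        empty = np.array([], dtype=np.int64)
        return empty, empty, empty, empty, np.array([], dtype=float)
    gcodes = genome.codes(orf.chrom)
    ref = gcodes[spos]
    ctx = _context_indices(gcodes, spos)
    lev = _methyl_levels(methylation, orf.chrom, spos)
    alts = np.array([[a for a in range(4) if a != b] for b in range(4)], dtype=np.uint8)[ref]
    pos_r = np.repeat(spos, 3)
    ref_r = np.repeat(ref, 3)
    alt_r = alts.reshape(-1)
    cls_r = np.full(len(pos_r), SPLICE, dtype=np.int64)
    mu = rate_table.mu(np.repeat(ctx, 3), alt_r, np.repeat(lev, 3))
    return pos_r, ref_r, alt_r.astype(np.int64), cls_r, mu


def enumerate_possible_snvs(
    orf: OrfModel, genome: Genome, rate_table, methylation=None
) -> pd.DataFrame:
    """All possible SNVs of an entity with context, methylation, class and mu.

    Exactly three records per exonic base, plus splice records for multi-exon
    entities. Alleles and contexts are reported on the reference plus strand.
    """
    view = coding_view(orf, genome)
    pos, ref, alt, cls, mu = possible_snv_arrays(view, genome, rate_table, methylation)
    spos, sref, salt, scls, smu = splice_snv_arrays(orf, genome, rate_table, methylation)
    gcodes = genome.codes(orf.chrom)
    all_pos = np.concatenate([pos, spos])
    all_ref = np.concatenate([ref, sref]).astype(np.uint8)
    all_alt = np.concatenate([alt, salt]).astype(np.uint8)
    all_cls = np.concatenate([cls, scls])
    all_mu = np.concatenate([mu, smu])
    lev = _methyl_levels(methylation, orf.chrom, all_pos)
    ctx_idx = _context_indices(gcodes, all_pos)
    ctx_str = _decode_contexts(ctx_idx)
    codon_index = np.full(len(all_pos), -1, dtype=np.int64)
    codon_index[: len(pos)] = np.repeat(np.arange(len(view.codes)) // 3, 3)
    return pd.DataFrame(
        {
            "chrom": orf.chrom,
            "pos": all_pos,
            "ref": [_seq.BASE_LETTERS[b] for b in all_ref],
            "alt": [_seq.BASE_LETTERS[b] for b in all_alt],
            "context": ctx_str,
            "methyl_level": lev,
            "consequence": [CONSEQUENCES[c] for c in all_cls],
            "codon_index": codon_index,
            "mu": all_mu,
        }
    )


def _decode_contexts(ctx_idx: np.ndarray) -> list[str]:
    out = []
    for i in ctx_idx:
        out.append(
            _seq.BASE_LETTERS[(i >> 4) & 3]
            + _seq.BASE_LETTERS[(i >> 2) & 3]
            + _seq.BASE_LETTERS[i & 3]
        )
    return out


@dataclass
class ObservedCounts:
    """Observed rare-variant counts for one entity (or one frame of it).

    ``n_mis`` is the N of the N/S ratio (missense + stop-loss); ``n_lof``
    counts stop-gain, splice and start-loss. Ratios are None when no
    synonymous variant was observed, and such entities are excluded from
    ratio-based summaries.
    """

    id: str
    n_syn: int
    n_mis: int
    n_lof: int
    per_class: dict

    @property
    def ns_ratio(self) -> float | None:
        return self.n_mis / self.n_syn if self.n_syn > 0 else None

    @property
    def lofs_ratio(self) -> float | None:
        return self.n_lof / self.n_syn if self.n_syn > 0 else None


def folded_maf(af: np.ndarray) -> np.ndarray:
    af = np.asarray(af, dtype=float)
    return np.minimum(af, 1.0 - af)


def observed_class_counts(
    view: CodingView,
    genome: Genome,
    variants: pd.DataFrame,
    maf_max: float = 0.001,
) -> np.ndarray:
    """Count observed variants (folded MAF < maf_max) per consequence class.

    ``variants`` needs columns chrom, pos, alt (plus-strand letters) and AF.
    Returns a length-7 count vector indexed by consequence code.
    """
    counts = np.zeros(len(CONSEQUENCES), dtype=np.int64)
    sub = variants
    if "chrom" in sub.columns:
        sub = sub[sub["chrom"] == view.chrom]
    if len(sub) == 0:
        return counts
    maf = folded_maf(sub["AF"].to_numpy())
    sub = sub[maf < maf_max]
    if len(sub) == 0:
        return counts
    order = np.argsort(view.positions, kind="stable")
    sorted_pos = view.positions[order]
    vpos = sub["pos"].to_numpy(dtype=np.int64)
    idx = np.searchsorted(sorted_pos, vpos)
    inside = (idx < len(sorted_pos)) & (sorted_pos[np.minimum(idx, len(sorted_pos) - 1)] == vpos)
    if not inside.any():
        return counts
    cls_matrix = classification_matrix(view.codes)
    coding_idx = order[idx[inside]]
    alt_codes = np.array([_seq._CODE[ord(a)] for a in sub["alt"].to_numpy()[inside]])
    if view.flip:
        alt_codes = COMP[alt_codes]
    ref_match = alt_codes != view.codes[coding_idx]
    cls = cls_matrix[coding_idx[ref_match], alt_codes[ref_match]]
    for c in cls:
        if c >= 0:
            counts[int(c)] += 1
    return counts


def tabulate_observed(
    orf: OrfModel,
    genome: Genome,
    variants: pd.DataFrame,
    maf_max: float = 0.001,
) -> ObservedCounts:
    """N/S and LoF/S tabulation of observed rare variants for one entity."""
    view = coding_view(orf, genome)
    counts = observed_class_counts(view, genome, variants, maf_max)
    # splice-region variants
    spos = set(orf.splice_positions().tolist())
    if spos:
        sub = variants[variants["chrom"] == orf.chrom]
        maf = folded_maf(sub["AF"].to_numpy())
        sub = sub[maf < maf_max]
        counts[SPLICE] += int(sub["pos"].isin(spos).sum())
    per_class = {CONSEQUENCES[i]: int(counts[i]) for i in range(len(CONSEQUENCES))}
    return ObservedCounts(
        id=orf.id,
        n_syn=int(counts[SYNONYMOUS]),
        n_mis=int(sum(counts[c] for c in N_CLASSES)),
        n_lof=int(sum(counts[c] for c in LOF_CLASSES)),
        per_class=per_class,
    )
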
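"""Synthetic cohort generator: every pipeline input, with planted truth.

The generator emulates the statistical structure the downstream analysis
assumes, at desk scale:

* a random genome with planted genes and smORFs (valid ATG..stop ORFs,
  1-3 exons, both strands, canonical GT/AG splice sites);
* two smORF prediction sets sharing a configurable mix of exact matches,
  imperfect overlaps (alternative-start isoforms shifted by one codon) and
  set-unique records, plus annotation-overlap and off-category decoys;
* a population variant table drawn per site/allele with probability
  ``mu * 2N`` from the context-dependent rate table, then thinned by the
  planted per-entity selection factors of the variant's consequence class
  (f_mis for missense/stop-loss, f_lof for stop-gain/start-loss/splice;
  synonymous variation is never thinned) — a Poisson-thinning model of a
  gnomAD-style callset, not a population simulation;
* allele frequencies split between rare (< 0.001), intermediate and common,
  the common mass spread across the five MAF bins;
* a conservation track whose per-entity mean is coupled to (1 - f_mis)
  through ``conservation_coupling``;
* a GWAS universe: array SNV lists, block-structured LD pairs, and a catalog
  sampled from the LD-expanded universe with extra weight inside smORF exons.

All planted parameters are recorded in a per-entity truth table. Identical
configurations (including the seed) regenerate byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import _seq, smorf_catalog as cat, variant_effects as ve
from ._seq import COMP, Genome
from .constraint_model import MutationRateTable
from .conservation_and_selection import ConservationTrack
from .errors import ConfigurationError, DataError, GenerationError
from .gwas_enrichment import ExonIndex, ld_expand
from .variant_effects import OrfModel

TRAITS = (
    "HDL cholesterol",
    "LDL cholesterol",
    "type 2 diabetes",
    "height",
    "breast cancer",
    "HIV infection",
    "tuberculosis",
    "asthma",
    "Crohn disease",
    "blood pressure",
    "platelet count",
    "body mass index",
)

_STOP_CODON_CODES = [
    _seq.encode(c) for c in _seq.STOP_CODONS
]
_NONSTOP = _seq.NONSTOP_CODON_INDICES


@dataclass
class SelectionProfile:
    """Per-entity depletion factors for the planted selection regime.

    A depletion factor f in [0, 1] multiplies the emission probability of the
    corresponding consequence class: 1 = neutral, 0 = fully depleted. smORFs
    are split into a constrained and a neutral subset; gene factors are tied
    to the gene's pLI annotation so that high-pLI genes are the most
    depleted.
    """

    smorf_constrained_fraction: float = 0.5
    f_mis_constrained: float = 0.3
    f_lof_constrained: float = 0.2
    f_mis_neutral: float = 1.0
    f_lof_neutral: float = 1.0
    gene_mis_slope: float = 0.75
    gene_lof_slope: float = 0.90

    def smorf_factors(self, constrained: bool) -> tuple[float, float]:
        if constrained:
            return self.f_mis_constrained, self.f_lof_constrained
        return self.f_mis_neutral, self.f_lof_neutral

    def gene_factors(self, pli: float) -> tuple[float, float]:
        return (
            float(np.clip(1.0 - self.gene_mis_slope * pli, 0.05, 1.0)),
            float(np.clip(1.0 - self.gene_lof_slope * pli, 0.05, 1.0)),
        )


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults give a desk-scale study.

    ``n_genomes`` is the diploid sample size of the emulated population
    callset (default matches a large WGS aggregation database). Fractions are
    of ``n_smorfs`` unless noted.
    """

    genome_length: int = 500_000
    gc_content: float = 0.41
    n_genes: int = 60
    n_smorfs: int = 150
    smorf_length_range: tuple[int, int] = (10, 150)
    n_genomes: int = 71_702
    selection_profile: SelectionProfile = field(default_factory=SelectionProfile)
    conservation_coupling: float = 0.9
    gwas_enrichment_ratio: float = 3.0
    n_array_snvs: int = 2_000
    n_gwas_snvs: int = 400
    seed: int = 0

    # dataset-sharing structure of the two prediction sets
    fraction_exact: float = 0.20
    fraction_jitter: float = 0.20
    unique_a_share: float = 0.75
    fraction_refseq_decoy: float = 0.06
    fraction_reverse_decoy: float = 0.04
    fraction_peptide_decoy: float = 0.04
    fraction_offlist_category: float = 0.05

    # structure
    chrom: str = "chrS"
    max_exons_smorf: int = 3
    max_exons_gene: int = 2
    intron_range: tuple[int, int] = (20, 60)
    gap_range: tuple[int, int] = (80, 300)
    margin: int = 150
    short_gene_range: tuple[int, int] = (60, 140)
    long_gene_range: tuple[int, int] = (150, 250)

    # allele-frequency mixture
    af_share_rare: float = 0.88
    af_share_common: float = 0.10

    # conservation track
    gerp_lo: float = -2.0
    gerp_hi: float = 4.0
    gerp_noise_sd: float = 1.0
    #: additive conservation for annotated genes: long-established coding
    #: sequence is conserved across species even when tolerant in humans
    gene_gerp_offset: float = 2.5

    # LD structure
    ld_block_size: int = 50_000
    ld_max_partners: int = 15

    def __post_init__(self):
        if isinstance(self.selection_profile, dict):
            self.selection_profile = SelectionProfile(**self.selection_profile)
        for name in ("genome_length", "n_smorfs", "n_genomes"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.n_genes < 0:
            raise ConfigurationError("n_genes must be >= 0")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ConfigurationError("gc_content must lie in [0, 1]")
        sp = self.selection_profile
        for fname in ("f_mis_constrained", "f_lof_constrained", "f_mis_neutral", "f_lof_neutral"):
            v = getattr(sp, fname)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"selection factor {fname} must lie in [0, 1]")
        if not 0.0 <= self.conservation_coupling <= 1.0:
            raise ConfigurationError("conservation_coupling must lie in [0, 1]")
        if self.gwas_enrichment_ratio < 1.0:
            raise ConfigurationError("gwas_enrichment_ratio must be >= 1")
        lo, hi = self.smorf_length_range
        if lo < 2 or hi < lo:
            raise ConfigurationError("invalid smorf_length_range")
        if self.fraction_exact + self.fraction_jitter > 1.0:
            raise ConfigurationError("sharing fractions exceed 1")
        if self.af_share_rare + self.af_share_common > 1.0:
            raise ConfigurationError("allele-frequency shares exceed 1")

    @property
    def emission_constant(self) -> float:
        """Expected scaling from summed mu to observed rare-variant counts:
        rare-AF share times the haploid sample size."""
        return self.af_share_rare * 2.0 * self.n_genomes

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_as_plain_dict(dataclasses.asdict(self)), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("smorf_length_range", "intron_range", "gap_range",
                    "short_gene_range", "long_gene_range"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


def _as_plain_dict(obj):
    if isinstance(obj, dict):
        return {k: _as_plain_dict(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_as_plain_dict(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# ---------------------------------------------------------------------------
# genome


def generate_genome(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> Genome:
    """Random background genome at the requested GC content."""
    if cfg.genome_length <= 0:
        raise ConfigurationError("genome_length must be positive")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    gc = cfg.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=cfg.genome_length, p=p).astype(np.uint8)
    return Genome({cfg.chrom: codes})


# ---------------------------------------------------------------------------
# methylation


class MethylationMap:
    """Per-CpG methylation level in {0, 1, 2}; non-CpG positions are level 0."""

    def __init__(self, positions_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]]):
        self._by_chrom = {
            c: (np.asarray(p, np.int64), np.asarray(l, np.int64))
            for c, (p, l) in positions_by_chrom.items()
        }

    def levels(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        pos = np.asarray(pos, np.int64)
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return np.zeros(len(pos), dtype=np.int64)
        cpos, clev = entry
        idx = np.searchsorted(cpos, pos)
        ok = (idx < len(cpos)) & (cpos[np.minimum(idx, len(cpos) - 1)] == pos)
        out = np.zeros(len(pos), dtype=np.int64)
        out[ok] = clev[idx[ok]]
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom, (pos, lev) in self._by_chrom.items():
            rows.append(pd.DataFrame({"chrom": chrom, "pos": pos, "level": lev}))
        return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
            columns=["chrom", "pos", "level"]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MethylationMap":
        data = {}
        for chrom, sub in df.groupby("chrom"):
            sub = sub.sort_values("pos")
            data[str(chrom)] = (sub["pos"].to_numpy(np.int64), sub["level"].to_numpy(np.int64))
        return cls(data)


def assign_methylation(genome: Genome, rng: np.random.Generator) -> MethylationMap:
    """Uniform {0,1,2} level per CpG dinucleotide; both bases share the level."""
    data = {}
    for chrom in genome.chroms:
        codes = genome.codes(chrom)
        cpg = np.nonzero((codes[:-1] == _seq.C) & (codes[1:] == _seq.G))[0]
        lev = rng.integers(0, 3, size=len(cpg))
        pos = np.concatenate([cpg, cpg + 1])
        levels = np.concatenate([lev, lev])
        order = np.argsort(pos, kind="stable")
        data[chrom] = (pos[order], levels[order])
    return MethylationMap(data)


# ---------------------------------------------------------------------------
# entity planting


@dataclass
class PlantedEntity:
    model: OrfModel
    kind: str  # "smorf" | "gene"
    f_mis: float
    f_lof: float
    pli: float = float("nan")
    gene_group: str = ""
    sharing_class: str = ""  # exact | jitter | unique_a | unique_b (smORFs)
    decoy: str = "none"  # none | refseq_forward | refseq_reverse | peptide
    category_a: str = ""
    pred_id_a: str = ""
    pred_id_b: str = ""
    expected_class: str = ""


@dataclass
class PlantResult:
    entities: list[PlantedEntity]
    predictions_a: list[cat.OrfPrediction]
    predictions_b: list[cat.OrfPrediction]
    annotation: cat.AnnotationSet
    decoy_annotation_ids: set[str]

    @property
    def smorfs(self) -> list[PlantedEntity]:
        return [e for e in self.entities if e.kind == "smorf"]

    @property
    def genes(self) -> list[PlantedEntity]:
        return [e for e in self.entities if e.kind == "gene"]

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for e in self.entities:
            start, end = e.model.span
            rows.append(
                {
                    "id": e.model.id,
                    "kind": e.kind,
                    "chrom": e.model.chrom,
                    "strand": e.model.strand,
                    "start": start,
                    "end": end,
                    "n_exons": len(e.model.exons),
                    "aa_length": e.model.aa_length,
                    "f_mis": e.f_mis,
                    "f_lof": e.f_lof,
                    "pli": e.pli,
                    "gene_group": e.gene_group,
                    "sharing_class": e.sharing_class,
                    "decoy": e.decoy,
                    "category_a": e.category_a,
                    "pred_id_a": e.pred_id_a,
                    "pred_id_b": e.pred_id_b,
                    "expected_class": e.expected_class,
                }
            )
        return pd.DataFrame(rows)


def _random_cds(n_aa: int, rng: np.random.Generator, internal_atg: bool = False) -> np.ndarray:
    """Coding-strand CDS codes: ATG + (n_aa - 1) non-stop codons + stop."""
    if n_aa < 2:
        raise GenerationError("ORF needs at least 2 codons before the stop")
    body = rng.choice(_NONSTOP, size=n_aa - 1)
    codons = np.empty((n_aa + 1, 3), dtype=np.uint8)
    codons[0] = _seq.encode("ATG")
    for i, cidx in enumerate(body, start=1):
        codons[i] = [(cidx >> 4) & 3, (cidx >> 2) & 3, cidx & 3]
    if internal_atg:
        codons[1] = _seq.encode("ATG")
    codons[-1] = _STOP_CODON_CODES[rng.integers(0, 3)]
    return codons.reshape(-1)


def _split_exons(
    cds_len: int, n_exons: int, rng: np.random.Generator, min_exon: int = 8
) -> list[int]:
    """Exon lengths on the spliced sequence summing to cds_len."""
    if n_exons == 1 or cds_len < n_exons * min_exon + min_exon:
        return [cds_len]
    cuts = sorted(
        rng.choice(
            np.arange(min_exon, cds_len - min_exon), size=n_exons - 1, replace=False
        )
    )
    lens, prev = [], 0
    for c in cuts:
        lens.append(int(c) - prev)
        prev = int(c)
    lens.append(cds_len - prev)
    if min(lens) < min_exon:
        return [cds_len]
    return lens


def _build_locus(
    cds: np.ndarray,
    exon_lens: list[int],
    strand: str,
    rng: np.random.Generator,
    intron_range: tuple[int, int],
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Genomic-plus-strand locus codes and exon offsets within the locus."""
    pieces, local_exons = [], []
    offset, cpos = 0, 0
    for i, elen in enumerate(exon_lens):
        pieces.append(cds[cpos : cpos + elen])
        local_exons.append((offset, offset + elen))
        offset += elen
        cpos += elen
        if i < len(exon_lens) - 1:
            ilen = int(rng.integers(intron_range[0], intron_range[1] + 1))
            intron = rng.integers(0, 4, size=ilen).astype(np.uint8)
            intron[:2] = _seq.encode("GT")
            intron[-2:] = _seq.encode("AG")
            pieces.append(intron)
            offset += ilen
    locus = np.concatenate(pieces)
    if strand == "-":
        M = len(locus)
        locus = _seq.revcomp_codes(locus)
        local_exons = sorted((M - e, M - s) for s, e in local_exons)
    return locus, local_exons


def plant_orfs(
    cfg: SimulationConfig, genome: Genome, rng: np.random.Generator | None = None
) -> PlantResult:
    """Plant genes and smORFs into the genome; emit predictions and annotation.

    Sharing classes (exact + jitter + unique_a + unique_b) partition the
    smORFs; a subset of the set-unique smORFs is marked as annotation-overlap
    or off-category decoy, with the post-filter expectation recorded per
    entity.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    chrom = cfg.chrom
    sp = cfg.selection_profile

    n_exact = int(round(cfg.fraction_exact * cfg.n_smorfs))
    n_jitter = int(round(cfg.fraction_jitter * cfg.n_smorfs))
    n_rest = cfg.n_smorfs - n_exact - n_jitter
    if n_rest < 0:
        raise ConfigurationError("sharing fractions exceed the smORF count")
    n_ua = int(round(cfg.unique_a_share * n_rest))
    n_ub = n_rest - n_ua

    specs: list[dict] = []
    lo_aa, hi_aa = cfg.smorf_length_range
    for i in range(cfg.n_smorfs):
        if i < n_exact:
            share = "exact"
        elif i < n_exact + n_jitter:
            share = "jitter"
        elif i < n_exact + n_jitter + n_ua:
            share = "unique_a"
        else:
            share = "unique_b"
        min_aa = max(lo_aa, 11) if share == "jitter" else lo_aa
        n_aa = int(rng.integers(min_aa, hi_aa + 1))
        constrained = rng.random() < sp.smorf_constrained_fraction
        f_mis, f_lof = sp.smorf_factors(constrained)
        specs.append(
            {
                "kind": "smorf",
                "n_aa": n_aa,
                "share": share,
                "f_mis": f_mis,
                "f_lof": f_lof,
                "n_exons": int(rng.integers(1, cfg.max_exons_smorf + 1)),
                "index": i,
            }
        )
    for j in range(cfg.n_genes):
        short = j < cfg.n_genes // 2
        rng_range = cfg.short_gene_range if short else cfg.long_gene_range
        n_aa = int(rng.integers(rng_range[0], rng_range[1] + 1))
        tier = j % 3  # low / moderate / high pLI in rotation
        pli = float(
            rng.uniform(*{0: (0.0, 0.05), 1: (0.3, 0.7), 2: (0.92, 1.0)}[tier])
        )
        f_mis, f_lof = sp.gene_factors(pli)
        specs.append(
            {
                "kind": "gene",
                "n_aa": n_aa,
                "pli": pli,
                "gene_group": "short" if short else "long",
                "f_mis": f_mis,
                "f_lof": f_lof,
                "n_exons": int(rng.integers(1, cfg.max_exons_gene + 1)),
                "index": j,
            }
        )
    rng.shuffle(specs)

    # choose decoys among set-unique smORFs
    uniques = [s for s in specs if s["kind"] == "smorf" and s["share"] in ("unique_a", "unique_b")]
    n_fwd = int(round(cfg.fraction_refseq_decoy * cfg.n_smorfs))
    n_rev = int(round(cfg.fraction_reverse_decoy * cfg.n_smorfs))
    n_pep = int(round(cfg.fraction_peptide_decoy * cfg.n_smorfs))
    n_off = int(round(cfg.fraction_offlist_category * cfg.n_smorfs))
    needed = n_fwd + n_rev + n_pep + n_off
    if needed > len(uniques):
        raise ConfigurationError("decoy fractions exceed available set-unique smORFs")
    pool = list(uniques)
    for label, count in (
        ("refseq_forward", n_fwd),
        ("refseq_reverse", n_rev),
        ("peptide", n_pep),
    ):
        for _ in range(count):
            pool.pop(0)["decoy"] = label
    off_pool = [s for s in pool if s["share"] == "unique_a"]
    if len(off_pool) < n_off:
        raise ConfigurationError("not enough unique-to-A smORFs for off-category decoys")
    for s in off_pool[:n_off]:
        s["off_category"] = True

    # place sequentially
    entities: list[PlantedEntity] = []
    preds_a: list[cat.OrfPrediction] = []
    preds_b: list[cat.OrfPrediction] = []
    ann_genes: list[cat.AnnotationGene] = []
    peptides: list[tuple[str, int, int]] = []
    decoy_ann_ids: set[str] = set()

    cursor = cfg.margin
    whitelist = sorted(cat.CHEN_CATEGORY_WHITELIST)
    n_ann_decoy = 0
    for spec in specs:
        n_aa = spec["n_aa"]
        internal_atg = spec.get("share") == "jitter"
        cds = _random_cds(n_aa, rng, internal_atg=internal_atg)
        exon_lens = _split_exons(len(cds), spec["n_exons"], rng)
        strand = "+" if rng.random() < 0.5 else "-"
        locus, local_exons = _build_locus(cds, exon_lens, strand, rng, cfg.intron_range)
        gap = int(rng.integers(cfg.gap_range[0], cfg.gap_range[1] + 1))
        start = cursor + gap
        end = start + len(locus)
        if end > cfg.genome_length - cfg.margin:
            raise GenerationError(
                f"cannot place all entities in {cfg.genome_length} bp "
                f"(ran out at {start})"
            )
        genome.set_slice(chrom, start, locus)
        cursor = end
        exons = tuple((start + s, start + e) for s, e in local_exons)

        if spec["kind"] == "gene":
            gid = f"gene{spec['index']:04d}"
            model = OrfModel(gid, chrom, strand, exons)
            ann_genes.append(
                cat.AnnotationGene(gid, chrom, exons, pli=spec["pli"], aa_length=n_aa)
            )
            entities.append(
                PlantedEntity(
                    model,
                    "gene",
                    spec["f_mis"],
                    spec["f_lof"],
                    pli=spec["pli"],
                    gene_group=spec["gene_group"],
                    expected_class="gene",
                )
            )
            continue

        sid = f"smorf{spec['index']:04d}"
        model = OrfModel(sid, chrom, strand, exons)
        share = spec["share"]
        decoy = spec.get("decoy", "none")
        off_category = spec.get("off_category", False)
        category = "annotated isoform" if off_category else whitelist[rng.integers(0, len(whitelist))]
        pid_a = f"chen{spec['index']:04d}"
        pid_b = f"mart{spec['index']:04d}"
        pa = pb = None
        if share in ("exact", "jitter", "unique_a"):
            pa = cat.OrfPrediction(pid_a, "chen", chrom, strand, exons, category)
        if share == "exact":
            pb = cat.OrfPrediction(pid_b, "martinez", chrom, strand, exons, "gold")
        elif share == "jitter":
            trimmed = _trim_first_codon(exons, strand)
            pb = cat.OrfPrediction(pid_b, "martinez", chrom, strand, trimmed, "gold")
        elif share == "unique_b":
            pb = cat.OrfPrediction(pid_b, "martinez", chrom, strand, exons, "gold")
        if pa is not None:
            preds_a.append(pa)
        if pb is not None:
            preds_b.append(pb)

        # attach decoy annotation intervals
        span_lo, span_hi = model.span
        total = model.total_length
        if decoy == "refseq_forward":
            aid = f"dec_fwd{n_ann_decoy:03d}"
            ann_genes.append(
                cat.AnnotationGene(
                    aid, chrom, ((span_lo - 20, span_hi + 20),), pli=float(rng.uniform(0, 1))
                )
            )
            decoy_ann_ids.add(aid)
            n_ann_decoy += 1
        elif decoy == "refseq_reverse":
            # a short annotated gene fully inside the smORF's first exon
            ex_s, ex_e = model.exons[0]
            glen = max(3, int(0.3 * total))
            glen = min(glen, ex_e - ex_s)
            aid = f"dec_rev{n_ann_decoy:03d}"
            ann_genes.append(
                cat.AnnotationGene(aid, chrom, ((ex_s, ex_s + glen),), pli=float(rng.uniform(0, 1)))
            )
            decoy_ann_ids.add(aid)
            n_ann_decoy += 1
        elif decoy == "peptide":
            for s, e in model.exons:
                peptides.append((chrom, s, e))
            aid = f"dec_pep{n_ann_decoy:03d}"
            ann_genes.append(
                cat.AnnotationGene(
                    aid, chrom, ((span_lo - 20, span_hi + 20),), pli=float(rng.uniform(0, 1))
                )
            )
            decoy_ann_ids.add(aid)
            n_ann_decoy += 1

        if off_category:
            expected = "excluded_category"
        elif decoy != "none":
            expected = "excluded_annotation"
        else:
            expected = {"exact": "exact", "jitter": "imperfect",
                        "unique_a": "unique_a", "unique_b": "unique_b"}[share]
        entities.append(
            PlantedEntity(
                model,
                "smorf",
                spec["f_mis"],
                spec["f_lof"],
                sharing_class=share,
                decoy=decoy,
                category_a=category if pa is not None else "",
                pred_id_a=pid_a if pa is not None else "",
                pred_id_b=pid_b if pb is not None else "",
                expected_class=expected,
            )
        )

    annotation = cat.AnnotationSet(ann_genes, peptides)
    return PlantResult(entities, preds_a, preds_b, annotation, decoy_ann_ids)


def _trim_first_codon(exons, strand) -> tuple[tuple[int, int], ...]:
    """Drop the first coding codon (3 nt at the 5' end, strand-aware)."""
    exons = list(exons)
    if strand == "+":
        s, e = exons[0]
        if e - s < 6:
            raise GenerationError("first exon too short to trim")
        exons[0] = (s + 3, e)
    else:
        s, e = exons[-1]
        if e - s < 6:
            raise GenerationError("last exon too short to trim")
        exons[-1] = (s, e - 3)
    return tuple(exons)


# ---------------------------------------------------------------------------
# population variants


def simulate_population_variants(
    cfg: SimulationConfig,
    genome: Genome,
    entities: list[PlantedEntity],
    rate_table: MutationRateTable,
    rng: np.random.Generator,
    methylation: MethylationMap | None = None,
) -> tuple[pd.DataFrame, MethylationMap]:
    """Poisson-thinned variant emission with class-specific selection.

    Each (site, alt) is observed with probability ``mu * 2 * n_genomes``
    times the minimum selection factor of its consequence class over the
    entities containing the site; allele frequencies are then assigned from
    the configured rare/intermediate/common mixture.
    """
    chrom = cfg.chrom
    codes = genome.codes(chrom)
    L = len(codes)
    if methylation is None:
        methylation = assign_methylation(genome, rng)
    pos_all = np.arange(1, L - 1, dtype=np.int64)
    ctx = (
        codes[pos_all - 1].astype(np.int64) * 16
        + codes[pos_all].astype(np.int64) * 4
        + codes[pos_all + 1].astype(np.int64)
    )
    lev = methylation.levels(chrom, pos_all)
    an = 2 * cfg.n_genomes

    prob = np.zeros((L, 4))
    ref_mid = codes[pos_all]
    for alt in range(4):
        mask = ref_mid != alt
        mu = rate_table.mu(ctx[mask], np.full(int(mask.sum()), alt), lev[mask])
        prob[pos_all[mask], alt] = mu * an
    if prob.max() >= 1.0:
        raise DataError(
            f"rate table too hot for n_genomes={cfg.n_genomes}: "
            f"per-site probability {prob.max():.3f} >= 1"
        )

    factor = np.ones((L, 4))
    for ent in entities:
        if ent.f_mis >= 1.0 and ent.f_lof >= 1.0:
            continue
        view = ve.coding_view(ent.model, genome)
        cls = ve.classification_matrix(view.codes)
        fac = np.ones_like(cls, dtype=float)
        fac[(cls == ve.MISSENSE) | (cls == ve.STOP_LOSS)] = ent.f_mis
        fac[(cls == ve.STOP_GAIN) | (cls == ve.START_LOSS)] = ent.f_lof
        cols = COMP[np.arange(4)] if view.flip else np.arange(4)
        target = factor[view.positions[:, None], cols[None, :]]
        factor[view.positions[:, None], cols[None, :]] = np.minimum(target, fac)
        spos = ent.model.splice_positions()
        if spos.size:
            factor[spos, :] = np.minimum(factor[spos, :], ent.f_lof)

    observed = rng.random((L, 4)) < prob * factor
    vpos, valt = np.nonzero(observed)
    vref = codes[vpos]

    n = len(vpos)
    u = rng.random(n)
    share_low = 1.0 - cfg.af_share_rare - cfg.af_share_common
    af = np.empty(n)
    rare = u < cfg.af_share_rare
    low = (~rare) & (u < cfg.af_share_rare + share_low)
    common = ~rare & ~low
    af[rare] = 10.0 ** rng.uniform(np.log10(1.0 / an), np.log10(0.001), size=int(rare.sum()))
    af[low] = rng.uniform(0.001, 0.01, size=int(low.sum()))
    if common.any():
        bins = rng.integers(0, 5, size=int(common.sum()))
        edges = np.array([[0.01, 0.10], [0.10, 0.20], [0.20, 0.30], [0.30, 0.40], [0.40, 0.50]])
        af[common] = rng.uniform(edges[bins, 0], edges[bins, 1])
    ac = np.maximum(1, np.round(af * an)).astype(np.int64)
    af = ac / an

    df = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": vpos,
            "ref": [_seq.BASE_LETTERS[b] for b in vref],
            "alt": [_seq.BASE_LETTERS[b] for b in valt],
            "AC": ac,
            "AN": an,
            "AF": af,
        }
    ).sort_values(["pos", "alt"], kind="stable").reset_index(drop=True)
    return df, methylation


# ---------------------------------------------------------------------------
# conservation


def simulate_conservation_track(
    cfg: SimulationConfig,
    entities: list[PlantedEntity],
    genome: Genome,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-base conservation scores as a bedGraph table.

    Background bases are N(0, sd) noise; entity exon bases receive an
    additive per-entity mean interpolated between ``gerp_lo`` (neutral) and
    ``gerp_hi`` (fully depleted), mixed with a uniform random component by
    ``conservation_coupling``.
    """
    chrom = cfg.chrom
    L = genome.length(chrom)
    scores = rng.normal(0.0, cfg.gerp_noise_sd, size=L)
    span = cfg.gerp_hi - cfg.gerp_lo
    coup = cfg.conservation_coupling
    for ent in entities:
        u = rng.random()
        m = cfg.gerp_lo + span * (coup * (1.0 - ent.f_mis) + (1.0 - coup) * u)
        if ent.kind == "gene":
            m += cfg.gene_gerp_offset
        pos = ent.model.genomic_positions()
        scores[pos] += m
    starts = np.arange(L, dtype=np.int64)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + 1,
            "score": np.round(scores, 4),
        }
    )


# ---------------------------------------------------------------------------
# GWAS universe


def simulate_gwas_universe(
    cfg: SimulationConfig,
    variants: pd.DataFrame,
    entities: list[PlantedEntity],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Array SNV lists, block-structured LD pairs, and a GWAS catalog.

    Catalog SNVs are sampled from the LD-expanded common-variant universe
    with sampling weight multiplied by ``gwas_enrichment_ratio`` inside the
    exons of filter-surviving smORFs. A small tail of malformed records
    (duplicates, multi-allelic, sub-threshold or missing p) exercises the
    catalog hygiene filter.
    """
    maf = ve.folded_maf(variants["AF"].to_numpy())
    common = variants[maf >= 0.01].copy()
    if len(common) == 0:
        raise GenerationError("no common variants to build a GWAS universe from")
    common["maf"] = ve.folded_maf(common["AF"].to_numpy())
    common["rsid"] = [
        f"rs{p}{a}" for p, a in zip(common["pos"], common["alt"])
    ]
    common = common.drop_duplicates(subset=["chrom", "pos"]).reset_index(drop=True)

    n_array = min(cfg.n_array_snvs, len(common))
    idx = rng.choice(len(common), size=n_array, replace=False)
    arrays = (
        common.iloc[np.sort(idx)][["rsid", "chrom", "pos", "ref", "alt", "maf"]]
        .reset_index(drop=True)
    )

    block = common["pos"].to_numpy() // cfg.ld_block_size
    block_r2 = {b: float(rng.uniform(0.5, 0.98)) for b in np.unique(block)}
    by_block: dict[int, np.ndarray] = {
        b: np.nonzero(block == b)[0] for b in np.unique(block)
    }
    arr_idx = {r: i for i, r in enumerate(common["rsid"])}
    pair_rows = []
    for rsid in arrays["rsid"]:
        i = arr_idx[rsid]
        b = block[i]
        members = by_block[b]
        members = members[members != i]
        if len(members) > cfg.ld_max_partners:
            members = rng.choice(members, size=cfg.ld_max_partners, replace=False)
        for j in np.sort(members):
            pair_rows.append(
                {
                    "snv_a": rsid,
                    "snv_b": common["rsid"].iat[j],
                    "chrom_b": common["chrom"].iat[j],
                    "pos_b": int(common["pos"].iat[j]),
                    "maf_b": float(common["maf"].iat[j]),
                    "r2": block_r2[b],
                }
            )
    ld_pairs = pd.DataFrame(
        pair_rows, columns=["snv_a", "snv_b", "chrom_b", "pos_b", "maf_b", "r2"]
    )

    universe = ld_expand(arrays, ld_pairs)
    surviving = [
        e for e in entities
        if e.kind == "smorf" and e.decoy == "none" and e.expected_class != "excluded_category"
    ]
    exon_index = ExonIndex(
        [(e.model.chrom, s, ee) for e in surviving for s, ee in e.model.exons]
    )
    catalog = draw_catalog(cfg, universe.snvs, common, exon_index, rng)
    return catalog, arrays, ld_pairs


def draw_catalog(
    cfg: SimulationConfig,
    universe_snvs: pd.DataFrame,
    common: pd.DataFrame,
    exon_index: ExonIndex,
    rng: np.random.Generator,
    enrichment_ratio: float | None = None,
    n_snvs: int | None = None,
    with_decoys: bool = True,
) -> pd.DataFrame:
    """Sample a GWAS catalog from the background universe."""
    ratio = cfg.gwas_enrichment_ratio if enrichment_ratio is None else enrichment_ratio
    n = cfg.n_gwas_snvs if n_snvs is None else n_snvs
    n = min(n, len(universe_snvs))
    inside = exon_index.contains(
        universe_snvs["chrom"].to_numpy(), universe_snvs["pos"].to_numpy()
    )
    w = np.where(inside, ratio, 1.0)
    pick = rng.choice(len(universe_snvs), size=n, replace=False, p=w / w.sum())
    chosen = universe_snvs.iloc[np.sort(pick)].reset_index(drop=True)
    alleles = common.set_index("rsid")[["ref", "alt"]]
    ref = alleles.reindex(chosen["rsid"])["ref"].fillna("A").to_numpy()
    alt = alleles.reindex(chosen["rsid"])["alt"].fillna("G").to_numpy()
    catalog = pd.DataFrame(
        {
            "rsid": chosen["rsid"],
            "chrom": chosen["chrom"],
            "pos": chosen["pos"],
            "ref": ref,
            "alt": alt,
            "p_value": 10.0 ** rng.uniform(-30.0, np.log10(5e-8), size=n),
            "maf": chosen["maf"],
            "trait": [TRAITS[i] for i in rng.integers(0, len(TRAITS), size=n)],
        }
    )
    if with_decoys and n >= 10:
        k = max(1, n // 50)
        dup = catalog.iloc[rng.integers(0, n, size=k)].copy()
        multi = catalog.iloc[rng.integers(0, n, size=k)].copy()
        multi["rsid"] = [f"{r}m" for r in multi["rsid"]]
        multi["pos"] = multi["pos"] + 1
        multi["alt"] = "A,G"
        weak = catalog.iloc[rng.integers(0, n, size=k)].copy()
        weak["rsid"] = [f"{r}w" for r in weak["rsid"]]
        weak["pos"] = weak["pos"] + 2
        weak["p_value"] = 10.0 ** rng.uniform(-7.2, -5.0, size=k)
        nop = catalog.iloc[rng.integers(0, n, size=k)].copy()
        nop["rsid"] = [f"{r}n" for r in nop["rsid"]]
        nop["pos"] = nop["pos"] + 3
        nop["p_value"] = np.nan
        catalog = pd.concat([catalog, dup, multi, weak, nop], ignore_index=True)
    return catalog


# ---------------------------------------------------------------------------
# whole-cohort orchestration


@dataclass
class Cohort:
    """An in-memory synthetic study: genome, entities, all derived tables."""

    cfg: SimulationConfig
    genome: Genome
    plant: PlantResult
    rate_table: MutationRateTable
    methylation: MethylationMap | None = None
    variants: pd.DataFrame | None = None
    conservation: pd.DataFrame | None = None
    catalog: pd.DataFrame | None = None
    arrays: pd.DataFrame | None = None
    ld_pairs: pd.DataFrame | None = None

    @property
    def truth(self) -> pd.DataFrame:
        return self.plant.truth_table()

    def conservation_track(self) -> ConservationTrack:
        return ConservationTrack(self.conservation)


def simulate_cohort(
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    rate_table: MutationRateTable | None = None,
    with_variants: bool = True,
    with_conservation: bool = True,
    with_gwas: bool = True,
) -> Cohort:
    """Generate a full cohort in memory (no file I/O)."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    rate_table = MutationRateTable.default() if rate_table is None else rate_table
    genome = generate_genome(cfg, rng)
    plant = plant_orfs(cfg, genome, rng)
    cohort = Cohort(cfg, genome, plant, rate_table)
    if with_variants:
        cohort.variants, cohort.methylation = simulate_population_variants(
            cfg, genome, plant.entities, rate_table, rng
        )
    if with_conservation:
        cohort.conservation = simulate_conservation_track(cfg, plant.entities, genome, rng)
    if with_gwas:
        if cohort.variants is None:
            raise ConfigurationError("GWAS universe requires variants")
        cohort.catalog, cohort.arrays, cohort.ld_pairs = simulate_gwas_universe(
            cfg, cohort.variants, plant.entities, rng
        )
    return cohort


@dataclass
class SyntheticBundle:
    """File layout of a written cohort."""

    root: Path
    genome: Path
    predictions_a: Path
    predictions_b: Path
    refseq: Path
    refseq_meta: Path
    peptides: Path
    variants: Path
    rates: Path
    methylation: Path
    conservation: Path
    gwas_catalog: Path
    arrays: Path
    ld_pairs: Path
    truth: Path
    meta: Path
    config: Path

    @classmethod
    def from_dir(cls, root) -> "SyntheticBundle":
        root = Path(root)
        return cls(
            root=root,
            genome=root / "genome.fa",
            predictions_a=root / "predictions_A.bed",
            predictions_b=root / "predictions_B.bed",
            refseq=root / "refseq.bed",
            refseq_meta=root / "refseq_meta.tsv",
            peptides=root / "peptides.bed",
            variants=root / "variants.tsv",
            rates=root / "rates.tsv",
            methylation=root / "methylation.tsv",
            conservation=root / "conservation.bedgraph",
            gwas_catalog=root / "gwas_catalog.tsv",
            arrays=root / "arrays.tsv",
            ld_pairs=root / "ld_pairs.tsv",
            truth=root / "truth.tsv",
            meta=root / "meta.json",
            config=root / "config.yaml",
        )


def generate_bundle(cfg: SimulationConfig, outdir) -> SyntheticBundle:
    """Generate a cohort and write every pipeline input file under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = SyntheticBundle.from_dir(outdir)
    cohort = simulate_cohort(cfg)

    cohort.genome.write_fasta(bundle.genome)
    cat.write_predictions(cohort.plant.predictions_a, bundle.predictions_a)
    cat.write_predictions(cohort.plant.predictions_b, bundle.predictions_b)
    _write_annotation(cohort.plant.annotation, bundle.refseq, bundle.refseq_meta, bundle.peptides)
    cohort.variants.to_csv(bundle.variants, sep="\t", index=False, float_format="%.6g")
    cohort.rate_table.to_tsv(bundle.rates)
    cohort.methylation.to_frame().to_csv(bundle.methylation, sep="\t", index=False)
    cohort.conservation.to_csv(
        bundle.conservation, sep="\t", index=False, header=False, float_format="%.4f"
    )
    cohort.catalog.to_csv(bundle.gwas_catalog, sep="\t", index=False, float_format="%.6g")
    cohort.arrays.to_csv(bundle.arrays, sep="\t", index=False, float_format="%.6g")
    cohort.ld_pairs.to_csv(bundle.ld_pairs, sep="\t", index=False, float_format="%.6g")
    cohort.truth.to_csv(bundle.truth, sep="\t", index=False, float_format="%.6g")
    meta = {
        "emission_constant": cfg.emission_constant,
        "n_decoy_annotations": len(cohort.plant.decoy_annotation_ids),
        "decoy_annotation_ids": sorted(cohort.plant.decoy_annotation_ids),
    }
    with open(bundle.meta, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    cfg.to_yaml(bundle.config)
    return bundle


def _write_annotation(
    annot: cat.AnnotationSet, refseq_path: Path, meta_path: Path, peptides_path: Path
) -> None:
    with open(refseq_path, "w") as fh:
        for g in annot.genes:
            start, end = g.exons[0][0], g.exons[-1][1]
            sizes = ",".join(str(e - s) for s, e in g.exons)
            starts = ",".join(str(s - start) for s, e in g.exons)
            fh.write(
                "\t".join(
                    [
                        g.chrom, str(start), str(end), g.id, "0", "+",
                        str(start), str(end), "0,0,0",
                        str(len(g.exons)), sizes, starts,
                    ]
                )
                + "\n"
            )
    pd.DataFrame(
        {
            "gene": [g.id for g in annot.genes],
            "pLI": [g.pli for g in annot.genes],
            "aa_length": [g.aa_length if g.aa_length is not None else -1 for g in annot.genes],
        }
    ).to_csv(meta_path, sep="\t", index=False, float_format="%.6g")
    with open(peptides_path, "w") as fh:
        for chrom, s, e in annot.peptide_intervals:
            fh.write(f"{chrom}\t{s}\t{e}\n")


def load_annotation(refseq_path, meta_path, peptides_path) -> cat.AnnotationSet:
    """Read back the annotation files written by :func:`generate_bundle`."""
    meta = pd.read_csv(meta_path, sep="\t").set_index("gene")
    genes = []
    with open(refseq_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            start = int(f[1])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple((start + bs, start + bs + sz) for bs, sz in zip(starts, sizes))
            gid = f[3]
            pli = float(meta.loc[gid, "pLI"]) if gid in meta.index else float("nan")
            aa = int(meta.loc[gid, "aa_length"]) if gid in meta.index else None
            genes.append(cat.AnnotationGene(gid, f[0], exons, pli=pli, aa_length=aa))
    peptides = []
    with open(peptides_path) as fh:
        for line in fh:
            if line.strip():
                f = line.split("\t")
                peptides.append((f[0], int(f[1]), int(f[2])))
    return cat.AnnotationSet(genes, peptides)
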
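"""Seed-site scanning of a circular mitochondrial genome and exact mapping.

A mature miRNA recognizes targets through its 5'-proximal seed (a heptamer
by default, starting at the first nucleotide; ``seed_start=2`` gives the
canonical 2-8 seed).  A target site on strand ``s`` at forward position
``p`` means the ``s``-strand sequence read 5'->3' over the k window equals
the reverse complement (RNA->DNA) of the seed.  Circular genomes are scanned
across the origin with a (k-1)-nt wrap window; both strands are scanned by
default since both mitochondrial strands are transcribed.

The significance of an observed hit count is a Poisson tail: the expected
random match count is ``lambda = n_positions x per-position match
probability`` with ``n_positions = 2L`` for a circular genome (both strands;
``2(L - k + 1)`` linear) and the match probability either the product of the
genome's mononucleotide frequencies over the required bases
(``composition_mode="genome"``, the default — mtDNA is AT-skewed) or the
uniform ``4^-k``.  Self-overlap (clumping) of the seed is not corrected for;
the tail is the plain Poisson P(X >= n_obs).

Coordinates are 1-based inclusive on the forward strand throughout.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenomeSequence",
    "AnnotationSet",
    "MatureMiRNA",
    "Hit",
    "SeedScanReport",
    "seed_sites",
    "poisson_match_pvalue",
    "exact_mature_match",
    "annotate_hits",
    "scan_panel",
]

_DNA = set("ACGT")
_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_DNA_COMPLEMENT)[::-1]


def rna_to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class GenomeSequence:
    """A (possibly circular) genome over {A, C, G, T}, 1-based coordinates."""

    name: str
    seq: str
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("genome sequence is empty")
        bad = set(self.seq) - _DNA
        if bad:
            raise ValueError(
                f"genome contains non-ACGT characters {sorted(bad)}; "
                "ambiguity codes are not supported"
            )

    def __len__(self) -> int:
        return len(self.seq)

    @classmethod
    def from_fasta(cls, path, circular: bool = True) -> "GenomeSequence":
        from Bio import SeqIO

        rec = next(SeqIO.parse(str(path), "fasta"))
        return cls(name=rec.id, seq=str(rec.seq).upper(), circular=circular)

    def base_frequencies(self) -> dict[str, float]:
        counts = Counter(self.seq)
        n = len(self.seq)
        return {b: counts.get(b, 0) / n for b in "ACGT"}


class Hit(NamedTuple):
    """A target site: 1-based inclusive forward-strand coordinates."""

    start: int
    end: int
    strand: str
    matched: str  # genome forward-strand bases under the site
    genes: tuple[str, ...] = ()


@dataclass(frozen=True)
class AnnotationSet:
    """Features as (gene, type, start, end, strand), 1-based inclusive.

    Origin-spanning features must be provided split in two.
    """

    features: tuple[tuple[str, str, int, int, str], ...]
    genome_length: int | None = None

    def __init__(self, features: Iterable, genome_length: int | None = None):
        feats = tuple(tuple(f) for f in features)
        for gene, ftype, start, end, strand in feats:
            if not 1 <= start <= end:
                raise ValueError(f"feature {gene}: bad interval {start}-{end}")
            if genome_length is not None and end > genome_length:
                raise ValueError(f"feature {gene}: end {end} beyond genome")
            if strand not in {"+", "-"}:
                raise ValueError(f"feature {gene}: strand must be + or -")
        object.__setattr__(self, "features", feats)
        object.__setattr__(self, "genome_length", genome_length)

    @classmethod
    def from_gff3(cls, path, genome_length: int | None = None) -> "AnnotationSet":
        df = pd.read_csv(
            str(path), sep="\t", comment="#", header=None,
            names=["seqid", "source", "type", "start", "end", "score", "strand",
                   "phase", "attributes"],
        )
        feats = []
        for _, row in df.iterrows():
            attrs = dict(
                kv.split("=", 1) for kv in str(row["attributes"]).split(";") if "=" in kv
            )
            name = attrs.get("Name") or attrs.get("gene") or attrs.get("ID") or "?"
            strand = row["strand"] if row["strand"] in {"+", "-"} else "+"
            feats.append((name, row["type"], int(row["start"]), int(row["end"]), strand))
        return cls(feats, genome_length=genome_length)

    @classmethod
    def from_genbank(cls, path) -> "AnnotationSet":
        from Bio import SeqIO

        rec = next(SeqIO.parse(str(path), "genbank"))
        feats = []
        for f in rec.features:
            if f.type in {"source"}:
                continue
            name = (f.qualifiers.get("gene") or f.qualifiers.get("product") or ["?"])[0]
            strand = "-" if f.location.strand == -1 else "+"
            feats.append(
                (name, f.type, int(f.location.start) + 1, int(f.location.end), strand)
            )
        return cls(feats, genome_length=len(rec.seq))

    def to_gff3(self, path, seqid: str = "genome") -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for gene, ftype, start, end, strand in self.features:
                fh.write(
                    f"{seqid}\tmitomir\t{ftype}\t{start}\t{end}\t.\t{strand}\t.\t"
                    f"ID={gene};Name={gene}\n"
                )


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA: miRBase-style identifier and 5'->3' RNA sequence."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        seq = self.seq.upper().replace("T", "U")
        object.__setattr__(self, "seq", seq)
        bad = set(seq) - set("ACGU")
        if bad:
            raise ValueError(f"{self.id}: non-ACGU characters {sorted(bad)}")
        if not 15 <= len(seq) <= 30:
            raise ValueError(f"{self.id}: mature length {len(seq)} outside 15-30 nt")

    def seed(self, k: int = 7, seed_start: int = 1) -> str:
        """The seed subsequence (RNA), 1-based start within the miRNA."""
        if k < 4:
            raise ValueError("seed length k must be >= 4")
        if seed_start < 1 or seed_start + k - 1 > len(self.seq):
            raise ValueError(
                f"{self.id}: seed [{seed_start}, {seed_start + k - 1}] extends "
                f"past the {len(self.seq)}-nt miRNA"
            )
        return self.seq[seed_start - 1 : seed_start - 1 + k]


def _scan_kmer(genome: GenomeSequence, kmer: str) -> list[int]:
    """1-based forward start positions where the forward strand equals kmer,
    wrapping across the origin when circular."""
    k = len(kmer)
    s = genome.seq + (genome.seq[: k - 1] if genome.circular else "")
    limit = len(genome.seq) if genome.circular else len(genome.seq) - k + 1
    hits, i = [], s.find(kmer)
    while i != -1:
        if i < limit:
            hits.append(i + 1)
        i = s.find(kmer, i + 1)
    return hits


def _wrap_end(start: int, k: int, L: int) -> int:
    return (start + k - 2) % L + 1


def seed_sites(
    mirna: MatureMiRNA,
    genome: GenomeSequence,
    k: int = 7,
    seed_start: int = 1,
    strands: str = "both",
) -> list[Hit]:
    """All seed-complementary sites of ``mirna`` in ``genome``.

    A ``+`` hit at p: forward k-mer at p equals revcomp(seed).  A ``-`` hit
    at p: the minus-strand k-mer over p..p+k-1 (read 5'->3') equals
    revcomp(seed), i.e. the forward k-mer equals the seed itself.  Hits are
    deduplicated and sorted by (start, strand).
    """
    if strands not in {"both", "+", "-"}:
        raise ValueError("strands must be 'both', '+' or '-'")
    seed_dna = rna_to_dna(mirna.seed(k=k, seed_start=seed_start))
    L = len(genome)
    found: set[Hit] = set()
    if strands in {"both", "+"}:
        target = revcomp(seed_dna)
        for p in _scan_kmer(genome, target):
            found.add(Hit(p, _wrap_end(p, k, L), "+", target))
    if strands in {"both", "-"}:
        for p in _scan_kmer(genome, seed_dna):
            found.add(Hit(p, _wrap_end(p, k, L), "-", seed_dna))
    return sorted(found, key=lambda h: (h.start, h.strand))


def poisson_match_pvalue(
    n_obs: int,
    genome: GenomeSequence,
    seed: str,
    composition_mode: str = "genome",
    strands: str = "both",
) -> tuple[float, float]:
    """(lambda, p) for observing >= ``n_obs`` random matches of ``seed``.

    lambda = n_positions x per-position match probability; the required
    genome bases are the reverse complement of the seed.  p = P(X >= n_obs)
    for X ~ Poisson(lambda); p = 1 when n_obs = 0.
    """
    if n_obs < 0:
        raise ValueError("n_obs must be >= 0")
    seed_dna = rna_to_dna(seed)
    k = len(seed_dna)
    L = len(genome)
    per_strand = L if genome.circular else max(L - k + 1, 0)
    n_positions = per_strand * (2 if strands == "both" else 1)
    if composition_mode == "uniform":
        p_match = 4.0**-k
    elif composition_mode == "genome":
        freqs = genome.base_frequencies()
        p_match = float(np.prod([freqs[b] for b in revcomp(seed_dna)]))
    else:
        raise ValueError("composition_mode must be 'genome' or 'uniform'")
    lam = n_positions * p_match
    p = 1.0 if n_obs == 0 else float(stats.poisson.sf(n_obs - 1, lam))
    return lam, p


def exact_mature_match(
    mirna: MatureMiRNA, genome: GenomeSequence
) -> list[tuple[int, int, str]]:
    """Full-length, zero-mismatch occurrences of the mature sequence (U->T)
    on either strand, as (start, end, strand) forward-strand coordinates."""
    query = rna_to_dna(mirna.seq)
    m, L = len(query), len(genome)
    out = []
    for p in _scan_kmer(genome, query):
        out.append((p, _wrap_end(p, m, L), "+"))
    for p in _scan_kmer(genome, revcomp(query)):
        out.append((p, _wrap_end(p, m, L), "-"))
    return sorted(set(out))


def _hit_intervals(hit: Hit, L: int) -> list[tuple[int, int]]:
    if hit.end >= hit.start:
        return [(hit.start, hit.end)]
    return [(hit.start, L), (1, hit.end)]  # origin-spanning


def annotate_hits(
    hits: list[Hit], annotation: AnnotationSet, genome_length: int | None = None
) -> list[Hit]:
    """Label each hit with every overlapping feature (any overlap; feature
    strand ignored — mitochondrial transcription is polycistronic, so a site
    need not lie in the gene it regulates).  Unannotated hits are labeled
    ``intergenic``."""
    L = genome_length or annotation.genome_length or (max((h.end for h in hits), default=1))
    labeled = []
    for hit in hits:
        genes = []
        for gene, _ftype, fstart, fend, _strand in annotation.features:
            for s, e in _hit_intervals(hit, L):
                if s <= fend and fstart <= e:
                    genes.append(gene)
                    break
        labeled.append(hit._replace(genes=tuple(genes) if genes else ("intergenic",)))
    return labeled


@dataclass
class SeedScanReport:
    """Per-miRNA scan outcome with the Poisson random-match statistic."""

    mirna_id: str
    seed: str
    k: int
    seed_start: int
    hits: list[Hit]
    lam: float
    p_value: float

    @property
    def n_hits(self) -> int:
        return len(self.hits)

    @property
    def genes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for h in self.hits:
            for g in h.genes:
                seen.setdefault(g, None)
        return tuple(seen)


def scan_panel(
    mirnas: list[MatureMiRNA],
    genome: GenomeSequence,
    annotation: AnnotationSet | None = None,
    k: int = 7,
    seed_start: int = 1,
    strands: str = "both",
    composition_mode: str = "genome",
    alpha: float = 0.05,
) -> tuple[dict[str, SeedScanReport], pd.DataFrame]:
    """Scan a panel of miRNAs; returns per-miRNA reports plus a merged table
    (one row per miRNA) of hit counts, hosting genes, lambda, p and a
    significance flag at ``alpha``."""
    if not mirnas:
        raise ValueError("need at least one miRNA")
    reports: dict[str, SeedScanReport] = {}
    rows = []
    for mir in mirnas:
        hits = seed_sites(mir, genome, k=k, seed_start=seed_start, strands=strands)
        if annotation is not None:
            hits = annotate_hits(hits, annotation, genome_length=len(genome))
        lam, p = poisson_match_pvalue(
            len(hits), genome, mir.seed(k=k, seed_start=seed_start),
            composition_mode=composition_mode, strands=strands,
        )
        rep = SeedScanReport(
            mirna_id=mir.id, seed=mir.seed(k=k, seed_start=seed_start), k=k,
            seed_start=seed_start, hits=hits, lam=lam, p_value=p,
        )
        reports[mir.id] = rep
        rows.append(
            {
                "mirna_id": mir.id,
                "n_hits": rep.n_hits,
                "genes": ";".join(rep.genes),
                "lambda": lam,
                "p_value": p,
                "significant": p < alpha,
            }
        )
    return reports, pd.DataFrame(rows)


def hits_to_frame(hits: list[Hit]) -> pd.DataFrame:
    """Hit list as a data frame (1-based inclusive forward coordinates)."""
    return pd.DataFrame(
        [
            {"start": h.start, "end": h.end, "strand": h.strand,
             "matched": h.matched, "genes": ";".join(h.genes)}
            for h in hits
        ],
        columns=["start", "end", "strand", "matched", "genes"],
    )
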
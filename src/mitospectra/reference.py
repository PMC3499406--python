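"""Mitochondrial reference genome, gene annotation, and genetic code.

Coordinates throughout the package are 1-based inclusive on the rCRS heavy
strand, matching m.-notation (m.3243A>G). The genome is circular; the control
region (16024-576) wraps the origin, so "coding region" means positions
577-16023. The 37 canonical genes (13 protein, 22 tRNA, 2 rRNA) are read from
a bundled TSV transcription of the NC_012920.1 feature table.

Because the full 16,569-base rCRS sequence cannot be redistributed here, the
module also provides :func:`synthetic_reference`, a deterministic generator of
a *synthetic* stand-in sequence that honours every structural property the
analyses rely on (gene coordinates, open reading frames, strand, incomplete
stop codons, the historical N placeholder at position 3107). Users with the
real NC_012920.1 FASTA should load it with :func:`load_reference`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

GENOME_LENGTH = 16569
CODING_START = 577
CODING_END = 16023
N_PLACEHOLDER_POS = 3107  # historical spacer in the rCRS, kept so numbering matches

GENE_TYPES = ("protein", "tRNA", "rRNA", "noncoding")
#: Priority used when a position must be assigned a single class (overlaps).
CLASS_PRIORITY = {"protein": 0, "tRNA": 1, "rRNA": 2, "noncoding": 3}

_TABLE2 = CodonTable.unambiguous_dna_by_id[2]

#: Vertebrate mitochondrial genetic code (translation table 2); stops map to '*'.
MITO_CODON_TABLE: dict[str, str] = dict(_TABLE2.forward_table)
MITO_CODON_TABLE.update({c: "*" for c in _TABLE2.stop_codons})
STOP_CODONS = frozenset(_TABLE2.stop_codons)  # TAA, TAG, AGA, AGG
START_CODONS = frozenset(_TABLE2.start_codons)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ReferenceError(ValueError):
    """Raised for malformed reference or annotation inputs."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str, *, first_is_start: bool = True) -> str:
    """Translate a CDS-oriented nucleotide string with translation table 2.

    Non-standard initiator codons (ATT, ATC, ATA, GTG) are rendered as Met at
    codon 1, as in the mature mitochondrial proteins. Trailing bases that do
    not fill a codon (incomplete stops) are ignored.
    """
    aas = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3]
        if i == 0 and first_is_start and codon in START_CODONS:
            aas.append("M")
        else:
            aas.append(MITO_CODON_TABLE[codon])
    return "".join(aas)


@dataclass(frozen=True)
class ReferenceGenome:
    """A circular mitochondrial reference sequence with 1-based coordinates."""

    name: str
    sequence: str
    circular: bool = True

    def __post_init__(self):
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ReferenceError(f"non-nucleotide characters in sequence: {sorted(bad)}")
        if self.sequence.count("N") > 1:
            raise ReferenceError("at most one N (the rCRS placeholder) is allowed")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """Base at a 1-based position."""
        if not 1 <= position <= self.length:
            raise ReferenceError(f"position {position} outside 1..{self.length}")
        return self.sequence[position - 1]

    def slice(self, start: int, end: int) -> str:
        """Inclusive 1-based slice, wrap-aware (start > end wraps the origin)."""
        if start <= end:
            return self.sequence[start - 1 : end]
        return self.sequence[start - 1 :] + self.sequence[:end]


@dataclass(frozen=True)
class GeneRecord:
    symbol: str
    gene_type: str  # protein | tRNA | rRNA | noncoding
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # H | L
    incomplete_stop_len: int = 0

    def __post_init__(self):
        if self.gene_type not in GENE_TYPES:
            raise ReferenceError(f"{self.symbol}: unknown gene_type {self.gene_type!r}")
        if self.strand not in ("H", "L"):
            raise ReferenceError(f"{self.symbol}: strand must be H or L")
        if self.incomplete_stop_len not in (0, 1, 2):
            raise ReferenceError(f"{self.symbol}: incomplete_stop_len must be 0..2")
        if not (1 <= self.start and self.start <= self.end):
            raise ReferenceError(f"{self.symbol}: bad interval {self.start}..{self.end}")
        if self.gene_type == "protein":
            if (self.length - self.incomplete_stop_len) % 3:
                raise ReferenceError(f"{self.symbol}: CDS length not a codon multiple")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        if self.start <= self.end:
            return self.start <= position <= self.end
        # wrap-aware for origin-spanning features
        return position >= self.start or position <= self.end

    @property
    def n_codons(self) -> int:
        """Number of complete codons in the annotated CDS (terminator included
        when the stop codon is complete)."""
        return (self.length - self.incomplete_stop_len) // 3

    @property
    def n_aa_codons(self) -> int:
        """Codons encoding residues: the complete terminator, if present, is
        excluded; incomplete stops contribute no codon at all."""
        return self.n_codons - (1 if self.incomplete_stop_len == 0 else 0)


class GenomeAnnotation:
    """The 37-gene annotation bound to a reference sequence.

    Provides coordinate queries (`genes_at`, `region_class`) and the
    length-proportional expectations (`gene_type_lengths`) used by the
    random-placement tests. Overlapping positions resolve to a single class by
    the priority protein > tRNA > rRNA > noncoding; ties go to the gene that
    starts earliest in genome order.
    """

    def __init__(self, genes: Iterable[GeneRecord], genome: ReferenceGenome):
        self.genes: list[GeneRecord] = sorted(genes, key=lambda g: (g.start, g.end))
        self.genome = genome
        counts = pd.Series([g.gene_type for g in self.genes]).value_counts()
        if not (
            counts.get("protein", 0) == 13
            and counts.get("tRNA", 0) == 22
            and counts.get("rRNA", 0) == 2
        ):
            raise ReferenceError(
                "expected the 37 canonical genes (13 protein, 22 tRNA, 2 rRNA); "
                f"got {counts.to_dict()}"
            )
        for g in self.genes:
            if g.end > genome.length:
                raise ReferenceError(f"{g.symbol} extends past the genome end")
        self._by_symbol = {g.symbol: g for g in self.genes}
        self._class_codes = self._build_class_codes()

    def _build_class_codes(self) -> np.ndarray:
        codes = np.full(self.genome.length, CLASS_PRIORITY["noncoding"], dtype=np.int8)
        # paint lowest-priority classes first so higher priority wins
        for cls in ("rRNA", "tRNA", "protein"):
            for g in self.genes:
                if g.gene_type == cls:
                    codes[g.start - 1 : g.end] = CLASS_PRIORITY[cls]
        return codes

    # -- queries ---------------------------------------------------------

    def gene(self, symbol: str) -> GeneRecord:
        return self._by_symbol[symbol]

    def genes_at(self, position: int) -> list[GeneRecord]:
        """All genes whose (wrap-aware) interval contains the position."""
        if not 1 <= position <= self.genome.length:
            raise ReferenceError(f"position {position} outside the genome")
        return [g for g in self.genes if g.contains(position)]

    def region_class(self, position: int) -> str:
        """Single gene-type class of a position under the overlap priority."""
        if not 1 <= position <= self.genome.length:
            raise ReferenceError(f"position {position} outside the genome")
        return GENE_TYPES[self._class_codes[position - 1]]

    def primary_gene_at(self, position: int) -> GeneRecord | None:
        """The gene whose class the position takes; None for noncoding."""
        hits = self.genes_at(position)
        if not hits:
            return None
        best = min(hits, key=lambda g: (CLASS_PRIORITY[g.gene_type], g.start))
        return best

    def class_codes(self) -> np.ndarray:
        """Per-position class codes (0=protein,1=tRNA,2=rRNA,3=noncoding),
        index 0 = position 1. Read-only view used by vectorised callers."""
        v = self._class_codes.view()
        v.flags.writeable = False
        return v

    def gene_type_lengths(self, start: int = 1, end: int | None = None) -> dict[str, int]:
        """Base counts per gene type within an inclusive region, each base
        counted once under the overlap priority; values sum to region length."""
        if end is None:
            end = self.genome.length
        if not (1 <= start <= end <= self.genome.length):
            raise ReferenceError(f"bad region {start}..{end}")
        counts = np.bincount(self._class_codes[start - 1 : end], minlength=4)
        return {GENE_TYPES[i]: int(counts[i]) for i in range(4)}

    # -- CDS helpers -----------------------------------------------------

    def cds_positions(self, symbol: str) -> np.ndarray:
        """Genomic positions of a protein gene's CDS in reading order
        (reversed for L-strand genes). Includes incomplete-stop bases."""
        g = self._by_symbol[symbol]
        if g.gene_type != "protein":
            raise ReferenceError(f"{symbol} is not a protein gene")
        pos = np.arange(g.start, g.end + 1)
        return pos[::-1] if g.strand == "L" else pos

    def cds_sequence(self, symbol: str) -> str:
        """CDS-oriented nucleotide sequence of a protein gene."""
        g = self._by_symbol[symbol]
        raw = self.genome.slice(g.start, g.end)
        return reverse_complement(raw) if g.strand == "L" else raw

    def protein_sequence(self, symbol: str) -> str:
        """Translated protein, terminator excluded."""
        g = self._by_symbol[symbol]
        cds = self.cds_sequence(symbol)
        return translate(cds)[: g.n_aa_codons]


# -- loading -------------------------------------------------------------


def load_reference(path) -> ReferenceGenome:
    """Load a single-record FASTA reference (e.g. the real NC_012920.1)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ReferenceError(f"expected a single-record FASTA, found {len(records)} records")
    rec = records[0]
    return ReferenceGenome(name=rec.id, sequence=str(rec.seq).upper())


def load_gene_table(path=None) -> pd.DataFrame:
    """Read the gene-annotation TSV (bundled NC_012920.1 transcription by default)."""
    if path is None:
        path = importlib.resources.files("mitospectra").joinpath("data/mt_genes.tsv")
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"symbol", "gene_type", "start", "end", "strand", "incomplete_stop_len"}
    missing = required - set(df.columns)
    if missing:
        raise ReferenceError(f"annotation table missing columns: {sorted(missing)}")
    return df


def annotation_from_table(df: pd.DataFrame, genome: ReferenceGenome) -> GenomeAnnotation:
    genes = [
        GeneRecord(
            symbol=r.symbol,
            gene_type=r.gene_type,
            start=int(r.start),
            end=int(r.end),
            strand=r.strand,
            incomplete_stop_len=int(r.incomplete_stop_len),
        )
        for r in df.itertuples()
    ]
    return GenomeAnnotation(genes, genome)


# -- synthetic reference -------------------------------------------------


def _fix_internal_stops(seq: list, ann_rows: pd.DataFrame, locked: set) -> bool:
    """Rewrite free bases until no protein gene has an internal stop codon.

    Overlapping reading frames interact, so iterate to a fixpoint. Returns
    False if a stop codon is fully locked (caller restarts with a new seed).
    """
    for _ in range(60):
        dirty = False
        for r in ann_rows.itertuples():
            if r.gene_type != "protein":
                continue
            n_codons = (r.end - r.start + 1 - r.incomplete_stop_len) // 3
            n_aa = n_codons - (1 if r.incomplete_stop_len == 0 else 0)
            pos = np.arange(r.start, r.end + 1)
            if r.strand == "L":
                pos = pos[::-1]
            for ci in range(n_aa):  # codon 0 (start) was fixed already; harmless to re-check
                p3 = pos[3 * ci : 3 * ci + 3]
                codon = "".join(
                    seq[p - 1] if r.strand == "H" else seq[p - 1].translate(_COMPLEMENT)
                    for p in p3
                )
                if codon not in STOP_CODONS:
                    continue
                free = [p for p in p3 if p not in locked]
                if not free:
                    return False
                # setting any one free base to C (CDS orientation) breaks all
                # four table-2 stop codons
                p = free[0]
                seq[p - 1] = "C" if r.strand == "H" else "G"
                dirty = True
        if not dirty:
            return True
    return False


def synthetic_reference(gene_table: pd.DataFrame | None = None, seed: int = 97) -> ReferenceGenome:
    """Build a deterministic *synthetic* rCRS-like reference sequence.

    The sequence is random apart from the constraints that matter to the
    analyses: real gene coordinates, ATG initiators (CDS-oriented), complete
    TAA terminators where the feature table has them, incomplete stops left as
    T/TA, no internal stop codon in any of the 13 reading frames (including
    the ATP8/ATP6, ND4L/ND4 and ATP6/CO3 overlaps and the L-strand ND6), and
    the historical N placeholder at position 3107. It is a labelled stand-in
    for the real NC_012920.1 sequence, not a reconstruction of it.
    """
    if gene_table is None:
        gene_table = load_gene_table()
    for attempt in range(25):
        rng = np.random.default_rng(seed + 1000 * attempt)
        seq = list(rng.choice(list("ACGT"), size=GENOME_LENGTH))
        locked: set[int] = set()

        def put(position: int, base: str):
            if position in locked and seq[position - 1] != base:
                raise ReferenceError("conflicting fixed bases in synthetic reference")
            seq[position - 1] = base
            locked.add(position)

        for r in gene_table.itertuples():
            if r.gene_type != "protein":
                continue
            pos = np.arange(r.start, r.end + 1)
            if r.strand == "L":
                pos = pos[::-1]
            for p, b in zip(pos[:3], "ATG"):
                put(int(p), b if r.strand == "H" else b.translate(_COMPLEMENT))
            if r.incomplete_stop_len == 0:
                for p, b in zip(pos[-3:], "TAA"):
                    put(int(p), b if r.strand == "H" else b.translate(_COMPLEMENT))
            else:
                for p, b in zip(pos[-r.incomplete_stop_len :], "TA"[: r.incomplete_stop_len]):
                    put(int(p), b if r.strand == "H" else b.translate(_COMPLEMENT))
        try:
            ok = _fix_internal_stops(seq, gene_table, locked)
        except ReferenceError:
            continue
        if not ok:
            continue
        seq[N_PLACEHOLDER_POS - 1] = "N"
        genome = ReferenceGenome(name="synthetic-rCRS", sequence="".join(seq))
        ann = annotation_from_table(gene_table, genome)
        if all(
            "*" not in ann.protein_sequence(g.symbol)
            for g in ann.genes
            if g.gene_type == "protein"
        ):
            return genome
    raise ReferenceError("could not construct a valid synthetic reference")


_DEFAULT: GenomeAnnotation | None = None


def load_default_annotation() -> GenomeAnnotation:
    """The bundled NC_012920.1 gene table bound to the synthetic reference
    sequence (cached; deterministic across processes)."""
    global _DEFAULT
    if _DEFAULT is None:
        table = load_gene_table()
        _DEFAULT = annotation_from_table(table, synthetic_reference(table))
    return _DEFAULT
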
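"""Genetic-consequence annotation and exhaustive variant enumeration.

Substitutions in protein genes are classified by rebuilding the codon that
contains the position (strand-aware) with the alternate base and translating
it under the vertebrate mitochondrial code: synonymous, non-synonymous,
premature termination (stop gain) or stop loss. Indels in protein genes are
frameshifts unless their length is a multiple of three. Mutations in RNA
genes are classed by gene type; everything outside a gene is noncoding.

`enumerate_all_protein_variants` generates every possible single-base
substitution across the residue-encoding codons of the 13 protein genes (the
complete terminator codon and trailing incomplete-stop bases are excluded,
since residue substitutions are what pathogenicity predictors score), with
overlap regions enumerated once per gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MutationSet, PointMutation
from .reference import GenomeAnnotation, MITO_CODON_TABLE, START_CODONS, STOP_CODONS

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}

CHANGE_CLASSES = (
    "synonymous",
    "non_synonymous",
    "premature_termination",
    "frameshift",
    "in_frame_indel",
    "stop_loss",
    "tRNA",
    "rRNA",
    "noncoding",
)

#: Lower rank = more severe; used when one mutation hits several genes.
SEVERITY = {
    "frameshift": 0,
    "premature_termination": 0,
    "stop_loss": 1,
    "non_synonymous": 2,
    "in_frame_indel": 3,
    "synonymous": 4,
    "tRNA": 5,
    "rRNA": 6,
    "noncoding": 7,
}

#: The six strand-symmetric substitution pair labels.
PAIR_LABELS = (
    "C:G→T:A",
    "T:A→C:G",
    "C:G→A:T",
    "C:G→G:C",
    "T:A→A:T",
    "T:A→G:C",
)


@dataclass(frozen=True)
class Consequence:
    """Functional call of one mutation in one gene (or intergenic)."""

    gene: str | None
    gene_type: str
    change_class: str
    aa_ref: str | None = None
    aa_alt: str | None = None
    aa_pos: int | None = None

    @property
    def aa_change(self) -> str | None:
        """p.-style one-letter label, e.g. p.L156R."""
        if self.aa_ref is None or self.aa_alt is None or self.aa_pos is None:
            return None
        return f"p.{self.aa_ref}{self.aa_pos}{self.aa_alt}"


def classify_change_type(m: PointMutation) -> str:
    """transition | transversion | insertion | deletion."""
    if m.kind != "substitution":
        return m.kind
    if m.ref == m.alt:
        raise ValueError("ref equals alt")
    if m.ref not in "ACGT" or m.alt not in "ACGT":
        raise ValueError(f"cannot classify substitution {m.ref}>{m.alt}")
    same_family = (m.ref in PURINES) == (m.alt in PURINES)
    return "transition" if same_family else "transversion"


def strand_symmetric_label(m: PointMutation) -> str:
    """Canonical strand-collapsed pair label of a substitution (6 possible).

    G→A and C→T are the same chemical event on opposite strands and both map
    to "C:G→T:A"; the pyrimidine of the ref pair names the label.
    """
    if m.kind != "substitution":
        raise ValueError("pair labels are defined for substitutions only")
    ref, alt = m.ref, m.alt
    if ref not in "ACGT" or alt not in "ACGT":
        raise ValueError(f"cannot label substitution {ref}>{alt}")
    if ref in PURINES:  # collapse onto the pyrimidine representative
        ref, alt = _COMP[ref], _COMP[alt]
    label = f"{ref}:{_COMP[ref]}→{alt}:{_COMP[alt]}"
    assert label in PAIR_LABELS
    return label


def _translate_codon(codon: str, codon_index: int) -> str:
    """Table-2 translation; any initiator codon at codon 1 reads as Met."""
    if codon_index == 1 and codon in START_CODONS:
        return "M"
    return MITO_CODON_TABLE[codon]


# -- exhaustive enumeration ----------------------------------------------


def enumerate_all_protein_variants(ann: GenomeAnnotation) -> pd.DataFrame:
    """Every possible single-base substitution in residue-encoding codons.

    Returns one row per (gene, genomic position, alt base): columns gene,
    position, ref, alt (both rCRS H-strand orientation), aa_pos, aa_ref,
    aa_alt, change_class ∈ {synonymous, non_synonymous, premature_termination}.
    Overlapping genes are enumerated once per gene, so a genomic position may
    appear in several rows.
    """
    rows = []
    for g in ann.genes:
        if g.gene_type != "protein":
            continue
        cds = ann.cds_sequence(g.symbol)
        positions = ann.cds_positions(g.symbol)
        for ci in range(g.n_aa_codons):
            codon = cds[3 * ci : 3 * ci + 3]
            aa_ref = _translate_codon(codon, ci + 1)
            for off in range(3):
                ref_b = codon[off]
                gpos = int(positions[3 * ci + off])
                for alt_b in "ACGT":
                    if alt_b == ref_b:
                        continue
                    alt_codon = codon[:off] + alt_b + codon[off + 1 :]
                    aa_alt = _translate_codon(alt_codon, ci + 1)
                    if aa_alt == "*":
                        klass = "premature_termination"
                    elif aa_alt == aa_ref:
                        klass = "synonymous"
                    else:
                        klass = "non_synonymous"
                    if g.strand == "H":
                        ref_h, alt_h = ref_b, alt_b
                    else:
                        ref_h, alt_h = _COMP[ref_b], _COMP[alt_b]
                    rows.append(
                        (g.symbol, gpos, ref_h, alt_h, ci + 1, aa_ref, aa_alt, klass)
                    )
    df = pd.DataFrame(
        rows,
        columns=["gene", "position", "ref", "alt", "aa_pos", "aa_ref", "aa_alt", "change_class"],
    )
    return df


def enumeration_totals(enum: pd.DataFrame) -> dict:
    """Class totals plus the two counting conventions for missense changes:
    nucleotide substitution events vs distinct amino-acid variations."""
    by_class = enum["change_class"].value_counts().to_dict()
    missense = enum[enum["change_class"] == "non_synonymous"]
    return {
        "n_records": int(len(enum)),
        "by_class": {k: int(v) for k, v in by_class.items()},
        "missense_events": int(len(missense)),
        "missense_distinct_aa": int(
            len(missense.drop_duplicates(["gene", "aa_pos", "aa_ref", "aa_alt"]))
        ),
    }


# -- per-mutation annotation ---------------------------------------------


def _consequence_for_gene(m: PointMutation, gene, ann: GenomeAnnotation) -> Consequence:
    if gene.gene_type in ("tRNA", "rRNA"):
        return Consequence(gene=gene.symbol, gene_type=gene.gene_type, change_class=gene.gene_type)
    # protein gene
    if m.kind != "substitution":
        length = len(m.ref) if m.kind == "deletion" else len(m.alt)
        klass = "frameshift" if length % 3 else "in_frame_indel"
        return Consequence(gene=gene.symbol, gene_type="protein", change_class=klass)
    positions = ann.cds_positions(gene.symbol)
    idx = int(np.nonzero(positions == m.position)[0][0])
    ci, off = divmod(idx, 3)
    if ci >= gene.n_aa_codons:
        # complete terminator codon or trailing incomplete-stop base(s)
        if gene.incomplete_stop_len:
            return Consequence(gene=gene.symbol, gene_type="protein", change_class="stop_loss")
        cds = ann.cds_sequence(gene.symbol)
        codon = cds[3 * ci : 3 * ci + 3]
        alt_b = m.alt if gene.strand == "H" else _COMP[m.alt]
        alt_codon = codon[:off] + alt_b + codon[off + 1 :]
        klass = "synonymous" if alt_codon in STOP_CODONS else "stop_loss"
        return Consequence(
            gene=gene.symbol,
            gene_type="protein",
            change_class=klass,
            aa_ref="*",
            aa_alt=MITO_CODON_TABLE[alt_codon],
            aa_pos=ci + 1,
        )
    cds = ann.cds_sequence(gene.symbol)
    codon = cds[3 * ci : 3 * ci + 3]
    alt_b = m.alt if gene.strand == "H" else _COMP[m.alt]
    alt_codon = codon[:off] + alt_b + codon[off + 1 :]
    aa_ref = _translate_codon(codon, ci + 1)
    aa_alt = _translate_codon(alt_codon, ci + 1)
    if aa_alt == "*":
        klass = "premature_termination"
    elif aa_alt == aa_ref:
        klass = "synonymous"
    else:
        klass = "non_synonymous"
    return Consequence(
        gene=gene.symbol,
        gene_type="protein",
        change_class=klass,
        aa_ref=aa_ref,
        aa_alt=aa_alt,
        aa_pos=ci + 1,
    )


def annotate_all(m: PointMutation, ann: GenomeAnnotation) -> list[Consequence]:
    """One Consequence per overlapping gene (empty-gene case → [noncoding])."""
    genes = ann.genes_at(m.position)
    if not genes:
        return [Consequence(gene=None, gene_type="noncoding", change_class="noncoding")]
    return [_consequence_for_gene(m, g, ann) for g in genes]


def annotate(m: PointMutation, ann: GenomeAnnotation) -> Consequence:
    """Single consequence for tabulation: most severe class wins; ties break
    to the gene earliest in genome order."""
    calls = annotate_all(m, ann)
    order = {c.gene: i for i, c in enumerate(calls)}
    return min(calls, key=lambda c: (SEVERITY[c.change_class], order[c.gene]))


def annotate_set(ms: MutationSet, ann: GenomeAnnotation) -> pd.DataFrame:
    """Annotate a whole MutationSet; returns its DataFrame plus gene,
    gene_type, change_class and aa_change columns."""
    records = []
    for m in ms:
        c = annotate(m, ann)
        records.append((c.gene, c.gene_type, c.change_class, c.aa_pos, c.aa_ref, c.aa_alt, c.aa_change))
    extra = pd.DataFrame(
        records,
        columns=["gene", "gene_type", "change_class", "aa_pos", "aa_ref", "aa_alt", "aa_change"],
        index=ms.df.index,
    )
    return pd.concat([ms.df, extra], axis=1)


def change_type_spectrum(ms: MutationSet) -> pd.DataFrame:
    """Counts and percentages of transitions / transversions / indels."""
    types = [classify_change_type(m) for m in ms]
    counts = pd.Series(types).value_counts()
    counts = counts.reindex(["transition", "transversion", "insertion", "deletion"], fill_value=0)
    return pd.DataFrame({"count": counts, "percent": 100 * counts / counts.sum()})


def consequence_spectrum(annotated: pd.DataFrame, pool_truncating: bool = True) -> pd.DataFrame:
    """Consequence-class spectrum over protein-gene mutations only.

    With pool_truncating (default), premature_termination and frameshift are
    pooled into one "frameshift_or_ptc" reporting category, the three-way
    split used to compare cohorts (synonymous / non-synonymous / truncating).
    """
    prot = annotated[annotated["gene_type"] == "protein"].copy()
    classes = prot["change_class"]
    if pool_truncating:
        classes = classes.replace(
            {"premature_termination": "frameshift_or_ptc", "frameshift": "frameshift_or_ptc"}
        )
        order = ["synonymous", "non_synonymous", "frameshift_or_ptc", "stop_loss", "in_frame_indel"]
    else:
        order = ["synonymous", "non_synonymous", "premature_termination", "frameshift",
                 "stop_loss", "in_frame_indel"]
    counts = classes.value_counts().reindex(order, fill_value=0)
    counts = counts[counts.index.isin(order[:3]) | (counts > 0)]
    total = counts.sum()
    pct = 100 * counts / total if total else counts * 0.0
    return pd.DataFrame({"count": counts.astype(int), "percent": pct})


def gene_location_spectrum(annotated: pd.DataFrame) -> pd.DataFrame:
    """Gene-type location spectrum (protein / tRNA / rRNA / noncoding)."""
    counts = annotated["gene_type"].value_counts().reindex(
        ["protein", "tRNA", "rRNA", "noncoding"], fill_value=0
    )
    return pd.DataFrame({"count": counts, "percent": 100 * counts / counts.sum()})
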